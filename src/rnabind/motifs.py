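"""Motif discovery from trained convolution filters.

Filters are turned into position weight matrices the DeepBind way: every
window of a bound (positive) input whose filter activation exceeds half of
that filter's maximum activation is collected, the aligned windows are
stacked into per-position letter counts, and the first ``width`` (default
7 of 10) columns become the PWM.  Enrichment of each PWM in the bound set
relative to shuffled backgrounds is scored with a one-sided Fisher exact
test, Bonferroni-corrected over the number of filters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats



@dataclass
class PWM:
    """Column-stochastic position probability matrix over a small alphabet."""

    probs: np.ndarray  # (width, D)
    alphabet: tuple[str, ...]
    counts: np.ndarray | None = None
    n_sites: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.alphabet):
            raise ValueError("probs must be (width, alphabet size)")
        if self.n_sites > 0 and not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def is_empty(self) -> bool:
        return self.n_sites == 0

    def consensus(self) -> str:
        return "".join(self.alphabet[j] for j in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        """Total information content in bits (uniform background)."""
        D = len(self.alphabet)
        p = np.clip(self.probs, 1e-12, 1.0)
        return float(np.sum(p * np.log2(p * D)))


@dataclass
class MotifHit:
    """One above-threshold filter activation on a positive input."""

    seq_id: str
    filter_index: int
    position: int  # start of the filter window in unpadded coordinates (may be < 0)
    activation: float
    window: str  # letters covered, clipped at the input boundaries


@dataclass
class EnrichmentResult:
    filter_index: int
    motif_name: str
    pos_hits: int
    pos_total: int
    bg_hits: int
    bg_total: int
    odds_ratio: float
    p_value: float
    adjusted_p: float


def collect_hits(results, dataset, branch: str = "sequence") -> list[MotifHit]:
    """Scan positive-class inputs with one branch's trained filters.

    The activation of filter f at position i is its ReLU cross-correlation
    with the padded one-hot input.  A hit is any (input m, filter f,
    position i) with activation strictly above half of filter f's maximum
    over all positive inputs and positions.  The returned window holds the
    input letters the filter covered, clipped at the boundaries.
    """
    from .nn.layers import conv_forward
    from .encoding import encode_sequence, encode_structure, standardize_length

    cfg = results.config
    pos = dataset.positives()
    if branch == "sequence":
        W = results.state.params["seq/W"]
        b = results.state.params["seq/b"]
        L = cfg.filter_len_seq
        enc = lambda s: encode_sequence(s, L)
        letters = [
            standardize_length(s, None, cfg.input_length, cfg.struct_filler)[0]
            for s in pos.sequences
        ]
    elif branch == "structure":
        if pos.structures is None:
            raise ValueError("dataset has no structure strings")
        W = results.state.params["str/W"]
        b = results.state.params["str/b"]
        L = cfg.filter_len_struct
        letters = [
            standardize_length(s, t, cfg.input_length, cfg.struct_filler)[1]
            for s, t in zip(pos.sequences, pos.structures)
        ]
        enc = lambda s: encode_structure(s, L)
    else:
        raise ValueError("branch must be 'sequence' or 'structure'")
    F = W.shape[0]
    acts = [conv_forward(enc(s), W, b) for s in letters]  # each (F, T)
    if not acts:
        return []
    maxima = np.max([a.max(axis=1) for a in acts], axis=0)  # per-filter max
    hits: list[MotifHit] = []
    for sid, s, a in zip(pos.ids, letters, acts):
        n = len(s)
        for f in range(F):
            tau = 0.5 * maxima[f]
            for i in np.flatnonzero(a[f] > tau):
                start = int(i) - (L - 1)  # unpadded frame
                window = s[max(start, 0) : start + L]
                hits.append(MotifHit(sid, f, start, float(a[f, i]), window))
    return hits


def build_pwm(
    windows: list[str],
    alphabet: tuple[str, ...],
    width: int = 7,
    pseudocount: float = 0.1,
    name: str = "",
) -> PWM:
    """Stack aligned hit windows into a PWM over the first ``width`` columns.

    Windows shorter than ``width`` (boundary clips) are dropped.  With no
    usable windows an explicit empty motif (n_sites = 0) is returned.
    """
    D = len(alphabet)
    index = {c: j for j, c in enumerate(alphabet)}
    counts = np.zeros((width, D))
    n_sites = 0
    for w in windows:
        if len(w) < width:
            continue
        ok = True
        for c in w[:width]:
            if c not in index and c != "N":
                ok = False
                break
        if not ok:
            continue
        for p, c in enumerate(w[:width]):
            if c == "N":
                counts[p] += 1.0 / D
            else:
                counts[p, index[c]] += 1.0
        n_sites += 1
    if n_sites == 0:
        return PWM(np.full((width, D), 1.0 / D), alphabet, counts, 0, name)
    probs = (counts + pseudocount) / (n_sites + D * pseudocount)
    return PWM(probs, alphabet, counts, n_sites, name)


def pwms_from_hits(
    hits: list[MotifHit],
    alphabet: tuple[str, ...],
    n_filters: int,
    width: int = 7,
    pseudocount: float = 0.1,
    prefix: str = "filter",
) -> list[PWM]:
    """One PWM per filter from its hit windows."""
    by_filter: dict[int, list[str]] = {f: [] for f in range(n_filters)}
    for h in hits:
        if h.position >= 0:  # left-clipped windows lose their alignment
            by_filter[h.filter_index].append(h.window)
    return [
        build_pwm(by_filter[f], alphabet, width, pseudocount, name=f"{prefix}_{f}")
        for f in range(n_filters)
    ]


# --- MEME minimal format ---------------------------------------------------

def write_meme(pwms: list[PWM], alphabet: tuple[str, ...], path: str | Path | None = None) -> str:
    """Write PWMs in MEME minimal motif format (custom FHIMST alphabet for
    structure motifs); returns the text."""
    D = len(alphabet)
    buf = _io.StringIO()
    buf.write("MEME version 4\n\n")
    buf.write(f"ALPHABET= {''.join(alphabet)}\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{c} {1.0 / D:.6f}" for c in alphabet) + "\n\n")
    for pwm in pwms:
        if not np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"motif {pwm.name!r} is not column-stochastic")
        if tuple(pwm.alphabet) != tuple(alphabet):
            raise ValueError("PWM alphabet does not match file alphabet")
        buf.write(f"MOTIF {pwm.name or 'motif'}\n")
        buf.write(
            f"letter-probability matrix: alength= {D} w= {pwm.width} nsites= {max(pwm.n_sites, 1)}\n"
        )
        for row in pwm.probs:
            buf.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_meme(source: str | Path) -> list[PWM]:
    """Parse the MEME minimal format written by :func:`write_meme`."""
    text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
    lines = text.splitlines()
    alphabet: tuple[str, ...] | None = None
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = tuple(line.split("=", 1)[1].strip())
        elif line.startswith("MOTIF"):
            name = line.split(None, 1)[1].strip() if len(line.split()) > 1 else ""
            i += 1
            header = lines[i].strip()
            if not header.startswith("letter-probability matrix:"):
                raise ValueError(f"malformed motif {name!r}")
            fields = dict(
                zip(*(iter(header.split(":", 1)[1].replace("=", " ").split()),) * 2)
            )
            w = int(fields["w"])
            nsites = int(fields.get("nsites", 1))
            rows = []
            for _ in range(w):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            if alphabet is None:
                raise ValueError("motif before ALPHABET line")
            pwms.append(PWM(np.array(rows), alphabet, None, nsites, name))
        i += 1
    return pwms


# --- scanning and enrichment ----------------------------------------------

def scan_pwm(
    pwm: PWM, seq: str, score_fraction: float = 0.75
) -> tuple[float, list[int]]:
    """Log-odds scan of a PWM against one string (uniform background).

    Returns the best score over all offsets and the offsets whose score
    reaches ``score_fraction`` times the PWM's maximum attainable score.
    An information-free PWM (max attainable score <= 0) never hits.
    """
    D = len(pwm.alphabet)
    if len(seq) < pwm.width:
        raise ValueError("string shorter than motif width")
    logodds = np.log2(np.clip(pwm.probs, 1e-12, 1.0) * D)  # (width, D)
    index = {c: j for j, c in enumerate(pwm.alphabet)}
    best_possible = float(logodds.max(axis=1).sum())
    idx = np.array([index.get(c, -1) for c in seq])
    win = np.lib.stride_tricks.sliding_window_view(idx, pwm.width)  # (T, width)
    # unknown letters (N) contribute 0, the uniform-background value
    vals = np.where(win >= 0, logodds[np.arange(pwm.width), win.clip(min=0)], 0.0)
    scores = vals.sum(axis=1)
    best = float(scores.max())
    if best_possible <= 0:
        return best, []
    thresh = score_fraction * best_possible
    return best, [int(o) for o in np.flatnonzero(scores >= thresh)]


def has_hit(pwm: PWM, seq: str, score_fraction: float = 0.75) -> bool:
    return len(scan_pwm(pwm, seq, score_fraction)[1]) > 0


def shuffle_background(seqs: list[str], seed: int) -> list[str]:
    """Per-string letter shuffle (mononucleotide-preserving), seeded."""
    if not seqs:
        raise ValueError("no sequences to shuffle")
    rng = np.random.default_rng(seed)
    return ["".join(rng.permutation(list(s))) for s in seqs]


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric tail probability of enrichment (greater direction)
    for the 2x2 table [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrichment_report(
    pwms: list[PWM],
    positives: list[str],
    n_filters: int | None = None,
    seed: int = 0,
    score_fraction: float = 0.75,
    background: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Fisher/Bonferroni motif enrichment of each PWM in the bound set.

    The background defaults to a per-string shuffle of the positives; a
    different background (e.g. structures re-predicted from shuffled
    sequences) may be supplied.  Results are sorted by adjusted p-value.
    """
    if n_filters is None:
        n_filters = len(pwms)
    if background is None:
        background = shuffle_background(positives, seed)
    results = []
    for f, pwm in enumerate(pwms):
        if pwm.is_empty:
            results.append(
                EnrichmentResult(f, pwm.name, 0, len(positives), 0, len(background), 0.0, 1.0, 1.0)
            )
            continue
        a = sum(has_hit(pwm, s, score_fraction) for s in positives)
        c = sum(has_hit(pwm, s, score_fraction) for s in background)
        b = len(positives) - a
        d = len(background) - c
        p = fisher_exact_one_sided(a, b, c, d)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else 0.0
        results.append(
            EnrichmentResult(f, pwm.name, a, len(positives), c, len(background),
                             float(odds), p, min(1.0, p * n_filters))
        )
    return sorted(results, key=lambda r: (r.adjusted_p, r.p_value))


def enrichment_to_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False)


def pwm_alignment_correlation(pwm: PWM, reference: PWM, min_overlap: int = 4) -> float:
    """Mean per-column Pearson correlation at the best alignment offset.

    The query is slid along the reference; columns outside the overlap are
    ignored.  Used to quantify recovery of a planted motif.
    """
    A, B = pwm.probs, reference.probs
    best = -1.0
    for off in range(-(A.shape[0] - min_overlap), B.shape[0] - min_overlap + 1):
        cols = []
        for qa in range(A.shape[0]):
            qb = qa + off
            if 0 <= qb < B.shape[0]:
                x, y = A[qa], B[qb]
                sx, sy = x.std(), y.std()
                if sx < 1e-12 or sy < 1e-12:
                    cols.append(0.0)
                else:
                    cols.append(float(np.corrcoef(x, y)[0, 1]))
        if len(cols) >= min_overlap:
            best = max(best, float(np.mean(cols)))
    return best


def consensus_pwm(consensus: str, alphabet: tuple[str, ...], strength: float = 1.0) -> PWM:
    """PWM concentrated on a consensus string (probability ``strength`` on
    the consensus letter, remainder uniform)."""
    D = len(alphabet)
    index = {c: j for j, c in enumerate(alphabet)}
    probs = np.full((len(consensus), D), (1.0 - strength) / (D - 1))
    for p, c in enumerate(consensus):
        probs[p, index[c]] = strength
    return PWM(probs, alphabet, None, 1, name=f"planted_{consensus}")
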