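"""Synthetic benchmark data: fixed-length reads with planted motifs.

The generator emulates the shape of CLIP-seq-derived binding-site data —
fixed-length reads (101 nt), bound/unbound labels, train/validation/test
splits — without any download.  Positives carry a planted sequence motif
and/or a planted structure context at configurable frequencies; negatives
are background.  Structure strings are produced by annotating the
base-pair-maximization fold of each read (so sequence and structure are
correlated, as they are when structures are predicted from sequence); an
i.i.d. structure mode exists for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SEQ_ALPHABET, STRUCT_ALPHABET
from .io import LabeledDataset
from .structure import annotate_loops, fold_baseline, parse_dotbracket


@dataclass
class SimConfig:
    """The stated world of the benchmark.

    Defaults: 101-nt reads, uniform background, a UGUGUGU consensus motif
    planted in every positive with a co-located HHHHH hairpin context, and
    0.6/0.15/0.25 splits mirroring the 24,000/6,000/10,000 shape of the
    CLIP-seq experiments at reduced n.
    """

    n_pos: int = 1650
    n_neg: int = 1650
    length: int = 101
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seq_motif: str = "UGUGUGU"  # consensus string
    seq_motif_freq: float = 1.0
    struct_motif: str = "HHHHH"
    struct_motif_freq: float = 1.0
    struct_placement: str = "colocated"  # or "independent"
    struct_background: str = "fold"  # or "iid"
    noise: float = 0.0  # per-position motif mutation probability
    seed: int = 0
    split_fracs: tuple[float, float, float] = (0.6, 0.15, 0.25)
    split_counts: tuple[int, int, int] | None = None  # overrides fractions

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not np.isclose(sum(self.background), 1.0):
            raise ValueError("background composition must sum to 1")
        for f in (self.seq_motif_freq, self.struct_motif_freq, self.noise):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies and noise must be in [0, 1]")
        if self.struct_placement not in ("colocated", "independent"):
            raise ValueError("struct_placement must be 'colocated' or 'independent'")
        if self.struct_background not in ("fold", "iid"):
            raise ValueError("struct_background must be 'fold' or 'iid'")
        if len(self.seq_motif) > self.length or len(self.struct_motif) > self.length:
            raise ValueError("motif wider than read length")
        if self.split_counts is None and not np.isclose(sum(self.split_fracs), 1.0):
            raise ValueError("split fractions must sum to 1")
        bad = (set(self.seq_motif) - set(SEQ_ALPHABET)) | (set(self.struct_motif) - set(STRUCT_ALPHABET))
        if bad:
            raise ValueError(f"invalid motif letters: {sorted(bad)}")


def sample_background(
    n: int, length: int, composition: tuple[float, ...], seed_or_rng
) -> list[str]:
    """n i.i.d. background reads of the given length and composition."""
    comp = np.asarray(composition, dtype=float)
    if not np.isclose(comp.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    letters = np.array(list(SEQ_ALPHABET))
    draws = rng.choice(4, size=(n, length), p=comp)
    return ["".join(letters[row]) for row in draws]


def _mutate(motif: str, noise: float, rng: np.random.Generator) -> str:
    if noise <= 0:
        return motif
    out = []
    for c in motif:
        if rng.random() < noise:
            out.append(SEQ_ALPHABET[rng.integers(4)])
        else:
            out.append(c)
    return "".join(out)


def plant(
    seq: str, struct: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str]:
    """Plant the sequence motif and/or structure context into one read.

    The sequence motif goes to a uniformly random offset (per-position
    mutation at the noise rate); the structure pattern overwrites the
    annotation at the co-located offset, or at an independent random
    offset, per the placement rule.
    """
    seq_off = None
    if cfg.seq_motif and rng.random() < cfg.seq_motif_freq:
        wm = len(cfg.seq_motif)
        seq_off = int(rng.integers(0, len(seq) - wm + 1))
        inserted = _mutate(cfg.seq_motif, cfg.noise, rng)
        seq = seq[:seq_off] + inserted + seq[seq_off + wm :]
    if cfg.struct_motif and rng.random() < cfg.struct_motif_freq:
        ws = len(cfg.struct_motif)
        if cfg.struct_placement == "colocated" and seq_off is not None:
            off = min(seq_off, len(struct) - ws)
        else:
            off = int(rng.integers(0, len(struct) - ws + 1))
        struct = struct[:off] + cfg.struct_motif + struct[off + ws :]
    return seq, struct


def _annotate(seq: str, mode: str, rng: np.random.Generator) -> str:
    if mode == "fold":
        return annotate_loops(parse_dotbracket(fold_baseline(seq)), len(seq))
    states = np.array(list(STRUCT_ALPHABET))
    return "".join(states[rng.integers(0, 6, size=len(seq))])


def _split_sizes(total: int, cfg: SimConfig) -> tuple[int, int, int]:
    if cfg.split_counts is not None:
        n_tr, n_va, n_te = cfg.split_counts
        if n_tr + n_va + n_te != total:
            raise ValueError("split_counts do not sum to the dataset size")
        return n_tr, n_va, n_te
    n_tr = round(total * cfg.split_fracs[0])
    n_va = round(total * cfg.split_fracs[1])
    return n_tr, n_va, total - n_tr - n_va


def generate(cfg: SimConfig) -> LabeledDataset:
    """Generate a labeled, split dataset; fully reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    pos_seqs = sample_background(cfg.n_pos, cfg.length, cfg.background, rng)
    neg_seqs = sample_background(cfg.n_neg, cfg.length, cfg.background, rng)
    records = []
    for j, s in enumerate(pos_seqs):
        struct = _annotate(s, cfg.struct_background, rng)
        s, struct = plant(s, struct, cfg, rng)
        records.append((f"pos_{j}", s, struct, 1))
    for j, s in enumerate(neg_seqs):
        struct = _annotate(s, cfg.struct_background, rng)
        records.append((f"neg_{j}", s, struct, 0))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    n_tr, n_va, n_te = _split_sizes(len(records), cfg)
    splits = ["train"] * n_tr + ["validation"] * n_va + ["test"] * n_te
    ids, seqs, structs, labels = zip(*records)
    return LabeledDataset(list(ids), list(seqs), list(structs), np.array(labels), splits)
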