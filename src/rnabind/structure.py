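"""RNA secondary structure: dot-bracket parsing, loop annotation, folding.

The per-nucleotide annotation uses six states: S (paired, stem), H
(hairpin loop), I (internal loop or bulge), M (multiloop), F (exterior
unpaired before the first helix, "dangling start") and T (every other
exterior unpaired position, "dangling end").

A base-pair-maximization dynamic program (Watson-Crick plus GU wobble,
minimum hairpin loop of 3) provides a self-contained, deterministic
structure source; adapters for external folders or precomputed annotation
files plug in through :func:`annotate_sequence`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# position indices are 1-based in pair tables, matching dot-bracket convention


def parse_dotbracket(s: str) -> dict[int, int]:
    """Parse a dot-bracket string into a symmetric 1-based pair table.

    Raises ``ValueError`` naming the first offending position for
    unbalanced input or characters outside ``(.)``.
    """
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for pos, c in enumerate(s, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {pos}")
            p = stack.pop()
            pairs[p] = pos
            pairs[pos] = p
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[0]}")
    return pairs


def _loop_scan(pairs: dict[int, int], start: int, stop: int) -> tuple[list[int], int]:
    """Unpaired members and branch count of the region (start, stop) exclusive."""
    unpaired: list[int] = []
    branches = 0
    j = start + 1
    while j < stop:
        if j in pairs:
            branches += 1
            j = pairs[j] + 1
        else:
            unpaired.append(j)
            j += 1
    return unpaired, branches


def annotate_loops(pairs: dict[int, int], n: int) -> str:
    """Classify every position of a length-``n`` structure into the six states.

    Paired positions are S.  An unpaired position inside the loop closed by
    a pair is H, I or M according to whether that loop has 0, 1 or >= 2
    inner branches.  Exterior unpaired positions are F before the first
    paired position and T afterwards (a structure with no pairs at all is
    all F).
    """
    labels = ["?"] * n
    for p in pairs:
        labels[p - 1] = "S"
    # exterior region
    first_paired = min(pairs) if pairs else n + 1
    exterior, _ = _loop_scan(pairs, 0, n + 1)
    for j in exterior:
        labels[j - 1] = "F" if j < first_paired else "T"
    # loops closed by each pair
    for p, q in pairs.items():
        if p > q:
            continue
        unpaired, branches = _loop_scan(pairs, p, q)
        if not unpaired:
            continue
        state = "H" if branches == 0 else ("I" if branches == 1 else "M")
        for j in unpaired:
            labels[j - 1] = state
    return "".join(labels)


# Nussinov-style base-pair maximization ------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# AU, UA, CG, GC, GU, UG
_CAN_PAIR = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _CAN_PAIR[_a, _b] = True


@njit(cache=True)
def _nussinov_fill(code: np.ndarray, can_pair: np.ndarray, min_loop: int) -> np.ndarray:
    n = code.shape[0]
    N = np.zeros((n, n), dtype=np.int32)
    for d in range(min_loop + 1, n):
        for i in range(n - d):
            j = i + d
            best = N[i, j - 1]
            for k in range(i, j - min_loop):
                if can_pair[code[k], code[j]]:
                    v = 1
                    if k > i:
                        v += N[i, k - 1]
                    if k + 1 <= j - 1:
                        v += N[k + 1, j - 1]
                    if v > best:
                        best = v
            N[i, j] = best
    return N


@njit(cache=True)
def _nussinov_traceback(
    N: np.ndarray, code: np.ndarray, can_pair: np.ndarray, min_loop: int
) -> np.ndarray:
    n = code.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    stack = np.empty((2 * n + 2, 2), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        if i >= j or N[i, j] == 0:
            continue
        paired = False
        # pair j with the smallest admissible partner k that achieves the optimum
        for k in range(i, j - min_loop):
            if can_pair[code[k], code[j]]:
                v = 1
                if k > i:
                    v += N[i, k - 1]
                if k + 1 <= j - 1:
                    v += N[k + 1, j - 1]
                if v == N[i, j]:
                    partner[k] = j
                    partner[j] = k
                    if k > i:
                        stack[top, 0] = i
                        stack[top, 1] = k - 1
                        top += 1
                    if k + 1 <= j - 1:
                        stack[top, 0] = k + 1
                        stack[top, 1] = j - 1
                        top += 1
                    paired = True
                    break
        if not paired:
            stack[top, 0] = i
            stack[top, 1] = j - 1
            top += 1
    return partner


def fold_baseline(seq: str, min_loop: int = 3) -> str:
    """Fold a sequence by base-pair maximization; returns a dot-bracket string.

    Allowed pairs are AU, CG and GU; hairpin loops contain at least
    ``min_loop`` unpaired bases.  The traceback is deterministic: position j
    is paired with its smallest admissible partner whenever pairing is
    optimal, otherwise left unpaired.
    """
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    code = np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)
    if n <= min_loop + 1:
        return "." * n
    N = _nussinov_fill(code, _CAN_PAIR, min_loop)
    partner = _nussinov_traceback(N, code, _CAN_PAIR, min_loop)
    out = []
    for i in range(n):
        if partner[i] < 0:
            out.append(".")
        elif partner[i] > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def structure_from_dotbracket(db: str) -> str:
    """Dot-bracket string -> six-state annotation."""
    return annotate_loops(parse_dotbracket(db), len(db))


def annotate_sequence(
    seq: str,
    source: str = "baseline_fold",
    provided: str | None = None,
    dotbracket: str | None = None,
    annotations: dict[str, str] | None = None,
    seq_id: str | None = None,
    min_loop: int = 3,
) -> str:
    """Produce the six-state annotation of ``seq`` from the chosen source.

    source = "provided":  validate and return ``provided``.
    source = "dotbracket": parse ``dotbracket`` and classify loops.
    source = "baseline_fold": fold with :func:`fold_baseline`, then classify.
    source = "external_file": look up ``seq_id`` in ``annotations``.
    """
    from .encoding import STRUCT_ALPHABET

    if source == "provided":
        if provided is None:
            raise ValueError("source='provided' needs a structure string")
        struct = provided
    elif source == "dotbracket":
        if dotbracket is None:
            raise ValueError("source='dotbracket' needs a dot-bracket string")
        struct = structure_from_dotbracket(dotbracket)
    elif source == "baseline_fold":
        struct = structure_from_dotbracket(fold_baseline(seq, min_loop=min_loop))
    elif source == "external_file":
        if annotations is None or seq_id is None:
            raise ValueError("source='external_file' needs annotations and seq_id")
        if seq_id not in annotations:
            raise KeyError(f"no structure annotation for id {seq_id!r}")
        struct = annotations[seq_id]
    else:
        raise ValueError(f"unknown structure source {source!r}")
    if len(struct) != len(seq):
        raise ValueError("structure length does not match sequence length")
    bad = set(struct) - set(STRUCT_ALPHABET)
    if bad:
        raise ValueError(f"invalid structure states: {sorted(bad)}")
    return struct
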