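"""One-hot encoding of RNA sequences and six-state structure strings.

A detector (convolution filter) of width ``w`` sees ``w - 1`` uniform
padding rows on each side of the sequence, so that every alignment of the
filter against the sequence — including partial overlaps at the ends — is a
valid window of the padded matrix.  Unknown nucleotides (``N``) are encoded
as the uniform distribution over the four bases.
"""

from __future__ import annotations

import numpy as np

SEQ_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")
STRUCT_ALPHABET: tuple[str, ...] = ("F", "H", "I", "M", "S", "T")

_SEQ_INDEX = {c: i for i, c in enumerate(SEQ_ALPHABET)}
_STRUCT_INDEX = {c: i for i, c in enumerate(STRUCT_ALPHABET)}


def normalize_sequence(raw: str) -> str:
    """Normalize raw sequence text to the A/C/G/U/N alphabet.

    Uppercases, converts T to U (DNA-style input), and maps every other
    unknown character to N.  Raises ``ValueError`` on empty input.
    """
    if not raw:
        raise ValueError("empty sequence")
    up = raw.upper().replace("T", "U")
    return "".join(c if c in _SEQ_INDEX else "N" for c in up)


def encode_sequence(seq: str, m: int) -> np.ndarray:
    """Encode a normalized sequence as an ``(n + 2(m-1)) x 4`` matrix.

    Interior rows are one-hot in the (A, C, G, U) column order; an N row
    and the ``m - 1`` padding rows at each end are uniform 0.25.
    """
    if m < 1:
        raise ValueError("detector width m must be >= 1")
    n = len(seq)
    if n < 1:
        raise ValueError("empty sequence")
    pad = m - 1
    out = np.full((n + 2 * pad, 4), 0.25)
    for t, c in enumerate(seq):
        row = out[pad + t]
        if c == "N":
            continue
        try:
            j = _SEQ_INDEX[c]
        except KeyError:
            raise ValueError(f"invalid nucleotide {c!r} at position {t + 1}") from None
        row[:] = 0.0
        row[j] = 1.0
    return out


def encode_structure(struct: str, k: int) -> np.ndarray:
    """Encode a six-state structure string as an ``(n + 2(k-1)) x 6`` matrix.

    Interior rows are one-hot in the (F, H, I, M, S, T) column order;
    padding rows are uniform 1/6.
    """
    if k < 1:
        raise ValueError("detector width k must be >= 1")
    n = len(struct)
    if n < 1:
        raise ValueError("empty structure string")
    pad = k - 1
    out = np.full((n + 2 * pad, 6), 1.0 / 6.0)
    for t, c in enumerate(struct):
        try:
            j = _STRUCT_INDEX[c]
        except KeyError:
            raise ValueError(f"invalid structure state {c!r} at position {t + 1}") from None
        row = out[pad + t]
        row[:] = 0.0
        row[j] = 1.0
    return out


def standardize_length(
    seq: str,
    struct: str | None,
    target: int,
    fill_state: str = "T",
) -> tuple[str, str | None]:
    """Center-truncate or symmetrically pad a (sequence, structure) pair.

    Sequences are padded with N, structure strings with ``fill_state``
    (default T, a dangling end).  The two strings stay aligned.
    """
    if target < 1:
        raise ValueError("target length must be >= 1")
    if struct is not None and len(struct) != len(seq):
        raise ValueError("sequence and structure lengths differ")
    n = len(seq)
    if n > target:
        start = (n - target) // 2
        seq = seq[start : start + target]
        if struct is not None:
            struct = struct[start : start + target]
    elif n < target:
        left = (target - n) // 2
        right = target - n - left
        seq = "N" * left + seq + "N" * right
        if struct is not None:
            struct = fill_state * left + struct + fill_state * right
    return seq, struct


def decode_sequence_rows(matrix: np.ndarray, m: int) -> str:
    """Argmax-decode the interior rows of an encoded sequence matrix.

    Uniform rows (N or padding) decode to N.
    """
    pad = m - 1
    interior = matrix[pad : matrix.shape[0] - pad] if pad else matrix
    letters = []
    for row in interior:
        if np.allclose(row, 0.25):
            letters.append("N")
        else:
            letters.append(SEQ_ALPHABET[int(np.argmax(row))])
    return "".join(letters)
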