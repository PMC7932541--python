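"""One-hot encoding of 100-base windows for the convolutional classifier.

A window is first doubled to 200 symbols — the forward sequence followed by
its reverse complement, so the model sees both strands of every site — and
then one-hot encoded over the five-symbol alphabet ``(null, a, t, c, g)``:

    null = 10000, a = 01000, t = 00100, c = 00010, g = 00001

The ``null`` column absorbs ``n`` and every other ambiguity code.  Row ``i``
of the doubled matrix and row ``199 - i`` always describe the same genomic
base on opposite strands; occlusion saliency relies on that mirror identity.
"""

from __future__ import annotations

import numpy as np

WINDOW_LENGTH = 100
ENCODED_LENGTH = 2 * WINDOW_LENGTH
ALPHABET = "natcg"  # column order: null, a, t, c, g
N_SYMBOLS = len(ALPHABET)

_COMPLEMENT = str.maketrans("atcgn", "tagcn")

# symbol -> one-hot column; anything not in atcg is a null
_COLUMN_OF = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _COLUMN_OF[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ``{a,t,c,g,n}`` alphabet (``n`` maps to ``n``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def double_sequence(seq: str) -> str:
    """Concatenate a 100-base window with its reverse complement.

    The forward-then-reverse-complement order is a frozen convention: the
    occlusion routine zeroes row ``i`` together with row ``199 - i`` and
    depends on it.
    """
    if len(seq) != WINDOW_LENGTH:
        raise ValueError(
            f"double_sequence expects a {WINDOW_LENGTH}-base window, got {len(seq)}"
        )
    return seq + reverse_complement(seq)


def one_hot(seq200: str) -> np.ndarray:
    """Encode a 200-symbol doubled sequence as a (200, 5) binary matrix.

    Unknown symbols fall into the null column; every row sums to exactly 1.
    """
    if len(seq200) != ENCODED_LENGTH:
        raise ValueError(
            f"one_hot expects a {ENCODED_LENGTH}-symbol doubled sequence, got {len(seq200)}"
        )
    cols = _COLUMN_OF[np.frombuffer(seq200.encode("ascii"), dtype=np.uint8)]
    mat = np.zeros((ENCODED_LENGTH, N_SYMBOLS), dtype=np.float32)
    mat[np.arange(ENCODED_LENGTH), cols] = 1.0
    return mat


def encode_window(seq: str) -> np.ndarray:
    """100-base window -> (200, 5) matrix (doubling + one-hot in one step)."""
    return one_hot(double_sequence(seq))


def encode_batch(seqs: list[str] | tuple[str, ...]) -> np.ndarray:
    """Encode many windows into a (n, 200, 5) array."""
    if len(seqs) == 0:
        return np.zeros((0, ENCODED_LENGTH, N_SYMBOLS), dtype=np.float32)
    joined = "".join(double_sequence(s) for s in seqs)
    cols = _COLUMN_OF[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    n = len(seqs)
    mat = np.zeros((n * ENCODED_LENGTH, N_SYMBOLS), dtype=np.float32)
    mat[np.arange(n * ENCODED_LENGTH), cols] = 1.0
    return mat.reshape(n, ENCODED_LENGTH, N_SYMBOLS)


def decode(matrix: np.ndarray) -> str:
    """Invert :func:`one_hot`; exact on the five-symbol alphabet."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != N_SYMBOLS:
        raise ValueError(f"expected a (*, {N_SYMBOLS}) matrix, got {matrix.shape}")
    return "".join(ALPHABET[j] for j in matrix.argmax(axis=1))


def dump_matrix_tsv(matrix: np.ndarray, path) -> None:
    """Debug dump of an encoded matrix as 0/1 TSV with the symbol header."""
    header = "\t".join({"n": "null"}.get(c, c) for c in ALPHABET)
    np.savetxt(path, matrix.astype(int), fmt="%d", delimiter="\t",
               header=header, comments="")
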