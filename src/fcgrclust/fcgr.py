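"""Frequency Chaos Game Representation (FCGR) of DNA sequences.

The chaos game places a sequence inside the unit square whose corners
represent the four bases (A bottom-left, C top-left, G top-right,
T bottom-right).  Starting from the centre, each base moves the current
point halfway toward its corner; quantizing the square into a 2^k x 2^k
grid makes each cell count occurrences of exactly one k-mer, so the grid
is an alignment-free summary of k-mer composition (the genomic signature).

Because the midpoint map halves the remaining displacement at every step,
the *last* base of a k-mer decides the quadrant, the one before it the
sub-quadrant, and so on: the cell address is a bit-interleaving of the
k-mer read back-to-front.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .sequence_io import Sequence

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# Corner coordinates in (x right, y up) convention: A=(0,0), C=(0,1),
# G=(1,1), T=(1,0).  Indexed by base code A=0, C=1, G=2, T=3.
_CX = np.array([0, 0, 1, 1], dtype=np.int64)
_CY = np.array([0, 1, 1, 0], dtype=np.int64)


@dataclass(frozen=True)
class Fcgr:
    """A 2^k x 2^k grid of k-mer counts (raw) or frequencies (normalized)."""

    k: int
    matrix: np.ndarray
    normalized: bool
    total_kmers_counted: int

    def __post_init__(self) -> None:
        side = 2 ** self.k
        if self.matrix.shape != (side, side):
            raise ValueError(f"matrix must be {side}x{side} for k={self.k}")


def cgr_cell(kmer: str) -> tuple[int, int]:
    """Grid cell (row, col) of a k-mer; row 0 is the top row.

    The j-th base (1-based) contributes bit 2^(j-1) to both the x and y
    coordinates, so the final base is the most significant — exactly the
    quantized endpoint of the chaos-game midpoint iteration.  The map is a
    bijection from the 4^k k-mers onto the grid.  Raises on any character
    outside A/C/G/T ("unmappable k-mer"); callers skip such windows.
    """
    k = len(kmer)
    if k < 1:
        raise ValueError("empty k-mer")
    x = y = 0
    for j, ch in enumerate(kmer):
        code = _CODE[ord(ch)] if ord(ch) < 256 else -1
        if code < 0:
            raise ValueError(f"unmappable k-mer {kmer!r}")
        x |= int(_CX[code]) << j
        y |= int(_CY[code]) << j
    side = 2 ** k
    return side - 1 - y, x


def fcgr_matrix(seq: Sequence | str, k: int) -> Fcgr:
    """Count all length-k sliding windows of a sequence into the CGR grid.

    Windows containing any non-ACGT character are skipped.  Raises
    ``ValueError`` if the sequence is shorter than k.
    """
    residues = seq.residues if isinstance(seq, Sequence) else seq
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(residues) < k:
        raise ValueError(f"sequence too short for k={k} (length {len(residues)})")

    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    weights = 1 << np.arange(k, dtype=np.int64)  # base j -> bit 2^(j-1)

    safe = np.where(windows < 0, 0, windows)
    x = _CX[safe] @ weights
    y = _CY[safe] @ weights
    side = 2 ** k
    rows = side - 1 - y
    cells = rows * side + x

    counts = np.bincount(cells[valid], minlength=side * side)
    matrix = counts.reshape(side, side)
    return Fcgr(k=k, matrix=matrix, normalized=False, total_kmers_counted=int(valid.sum()))


def normalize_l1(fcgr: Fcgr) -> Fcgr:
    """Divide every cell by the total count so entries sum to 1."""
    total = fcgr.matrix.sum()
    if total <= 0:
        raise ValueError("empty FCGR: no countable k-mers")
    return replace(fcgr, matrix=fcgr.matrix / total, normalized=True)


def flatten(fcgr: Fcgr) -> np.ndarray:
    """Row-major flattening into a length-4^k vector."""
    return np.asarray(fcgr.matrix, dtype=np.float64).reshape(-1)


def unflatten(vector: np.ndarray, k: int) -> np.ndarray:
    side = 2 ** k
    vec = np.asarray(vector)
    if vec.size != side * side:
        raise ValueError(f"vector of length {vec.size} is not 4^{k}")
    return vec.reshape(side, side)


def fcgr_vector(seq: Sequence | str, k: int) -> np.ndarray:
    """Normalized, flattened FCGR — the network input representation."""
    return flatten(normalize_l1(fcgr_matrix(seq, k)))


def save_tsv(fcgr: Fcgr, path: str | Path) -> None:
    np.savetxt(path, fcgr.matrix, delimiter="\t", fmt="%.10g")


def save_png(fcgr: Fcgr, path: str | Path) -> None:
    """Grayscale rendering of log-scaled counts (dark = frequent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.log1p(np.asarray(fcgr.matrix, dtype=float))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, cmap="Greys", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
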