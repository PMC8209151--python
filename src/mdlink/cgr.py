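"""Chaos game representation (CGR) features for miRNA sequences.

Each nucleotide pulls the current point half-way toward its assigned corner
of the unit square (A=(0,0), C=(0,1), U=(1,0), G=(1,1)), starting from the
centre.  The resulting point cloud is summarised on an 8x8 grid: per cell we
keep the sum of x coordinates, the sum of y coordinates, and the z-scored
point count, giving a 64 x 3 = 192-long descriptor per sequence.  Sequence
similarity is the Pearson correlation of two descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Corner assignment for the four RNA bases (T is read as U).
_CORNERS = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "U": (1.0, 0.0),
    "G": (1.0, 1.0),
}

N_CELLS = 64  # 8 x 8 partition of the unit square
DESCRIPTOR_LEN = 3 * N_CELLS


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, U, T}."""


def nucleotide_corner(base: str) -> tuple[float, float]:
    """Unit-square corner assigned to ``base`` (case-insensitive, T == U)."""
    b = base.upper().replace("T", "U")
    try:
        return _CORNERS[b]
    except KeyError:
        raise AlphabetError(f"invalid nucleotide {base!r}") from None


def cgr_trajectory(seq: str, c: float = 0.5) -> np.ndarray:
    """Map a sequence to its CGR point trajectory.

    Starting from T0 = (0.5, 0.5), each base moves the point a fraction ``c``
    of the way toward its corner: ``T_i = T_{i-1} + c * (G_i - T_{i-1})``.
    Returns an ``(len(seq), 2)`` array; the start point is not emitted.  All
    points lie strictly inside the unit square for 0 < c < 1.
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 < c < 1.0:
        raise ValueError(f"contraction ratio must be in (0, 1), got {c}")
    points = np.empty((len(seq), 2))
    x, y = 0.5, 0.5
    for i, base in enumerate(seq):
        try:
            gx, gy = nucleotide_corner(base)
        except AlphabetError:
            raise AlphabetError(
                f"invalid nucleotide {base!r} at position {i}"
            ) from None
        x += c * (gx - x)
        y += c * (gy - y)
        points[i] = (x, y)
    return points


def subspace_index(p: Iterable[float]) -> int:
    """Index in [0, 63] of the 8x8 grid cell containing point ``p``.

    Cells are half-open ``[k/8, (k+1)/8)``; a coordinate of exactly 1.0
    clamps into the last row/column.  ``index = floor(8x) + 8 * floor(8y)``.
    """
    x, y = p
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise ValueError(f"point ({x}, {y}) outside the unit square")
    col = min(int(np.floor(8.0 * x)), 7)
    row = min(int(np.floor(8.0 * y)), 7)
    return col + 8 * row


@dataclass(frozen=True)
class CgrDescriptor:
    """Per-cell CGR statistics of one sequence.

    Attributes
    ----------
    x_sums, y_sums : (64,) coordinate sums per cell.
    z_counts : (64,) z-scored point counts (population std over the 64
        cells); all-zero when every cell holds the same count.
    counts : (64,) raw point counts; sums to the sequence length.
    """

    x_sums: np.ndarray
    y_sums: np.ndarray
    z_counts: np.ndarray
    counts: np.ndarray

    @property
    def flat(self) -> np.ndarray:
        """192-long vector (X_1, Y_1, Z_1, ..., X_64, Y_64, Z_64)."""
        return np.column_stack([self.x_sums, self.y_sums, self.z_counts]).ravel()


def cgr_descriptor(seq: str, c: float = 0.5) -> CgrDescriptor:
    """Compute the 64-subspace descriptor of a sequence."""
    points = cgr_trajectory(seq, c=c)
    cols = np.minimum(np.floor(8.0 * points[:, 0]).astype(int), 7)
    rows = np.minimum(np.floor(8.0 * points[:, 1]).astype(int), 7)
    cells = cols + 8 * rows
    counts = np.bincount(cells, minlength=N_CELLS).astype(float)
    x_sums = np.bincount(cells, weights=points[:, 0], minlength=N_CELLS)
    y_sums = np.bincount(cells, weights=points[:, 1], minlength=N_CELLS)
    std = counts.std()  # population std, ddof=0
    if std == 0.0:
        z = np.zeros(N_CELLS)
    else:
        z = (counts - counts.mean()) / std
    return CgrDescriptor(x_sums=x_sums, y_sums=y_sums, z_counts=z, counts=counts)


def mirna_similarity(a: CgrDescriptor, b: CgrDescriptor) -> float:
    """Pearson correlation of two flattened descriptors, in [-1, 1]."""
    va, vb = a.flat, b.flat
    if va.std() == 0.0 or vb.std() == 0.0:
        raise ValueError("zero-variance descriptor: similarity undefined")
    r = float(np.corrcoef(va, vb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def similarity_matrix(seqs: Mapping[str, str], c: float = 0.5) -> pd.DataFrame:
    """Pairwise CGR-descriptor Pearson similarity, keyed by miRNA id.

    Rows/columns follow sorted id order; the matrix is symmetric with unit
    diagonal.
    """
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    flats = np.array([cgr_descriptor(seqs[i], c=c).flat for i in ids])
    if np.any(flats.std(axis=1) == 0.0):
        raise ValueError("zero-variance descriptor: similarity undefined")
    sim = np.corrcoef(flats)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=ids, columns=ids)
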