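"""Chaos-game representations and their segment-frequency histograms.

A CGR maps a sequence to an ordered 2-D point trajectory: starting from the
geometry's start point, each symbol moves the current point halfway toward
the vertex assigned to that symbol's class.  Two geometries are used:

* **Protein (CGR-24)** — a regular 12-gon inscribed in the unit circle,
  vertex ``V_k = (cos((k-1)*pi/6), sin((k-1)*pi/6))`` so ``V1 = (1, 0)``,
  start at the center ``(0, 0)``.  Each amino acid is sent to one of 12
  vertex classes.  The trajectory is summarized by counting points in 24
  segments: 12 angular sectors of 30 degrees crossed with 2 radial bands
  split at r = 0.5, ``segment = 2*(sector-1) + band + 1`` with band 0 the
  inner disc (r < 0.5).  Any fixed segment labeling gives an equivalent
  feature vector up to column permutation; this one is a deterministic
  one-line rule with 24 congruent-by-rotation cells.
* **RNA (CGR-16)** — the unit square with vertices A=(0,0), C=(1,0),
  G=(1,1), U=(0,1), start at the center (0.5, 0.5); the histogram is the
  4x4 grid occupancy (the resolution-2 frequency-CGR), row-major from the
  (0,0) corner, with the top/right boundary clamped inward.

Histogram frequencies are ``D_k = L_k / n`` where ``L_k`` is the number of
trajectory points in segment k and n the sequence length, so they sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .seqio import (
    MolType,
    RNA_VERTEX_MAP,
    TWELVE_GROUP_MAP,
    SequenceRecord,
    SequenceError,
)

N_SEGMENTS_PROTEIN = 24
N_SEGMENTS_RNA = 16

#: Radius separating the inner and outer bands of the 12-gon histogram;
#: r == RADIUS_SPLIT belongs to the outer band.
RADIUS_SPLIT = 0.5


def polygon_vertex(k: int) -> tuple[float, float]:
    """Coordinates of vertex k (1..12) of the unit-circle 12-gon."""
    if not 1 <= k <= 12:
        raise ValueError(f"vertex index {k} out of range 1..12")
    theta = (k - 1) * np.pi / 6.0
    return (float(np.cos(theta)), float(np.sin(theta)))


POLYGON_VERTICES = np.array([polygon_vertex(k) for k in range(1, 13)])
SQUARE_VERTICES = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])
POLYGON_START = np.array([0.0, 0.0])
SQUARE_START = np.array([0.5, 0.5])


@dataclass(frozen=True)
class CGRHistogram:
    """Per-segment point counts and frequencies of a CGR trajectory."""

    counts: np.ndarray
    values: np.ndarray  # frequencies D_k = L_k / n

    @property
    def dim(self) -> int:
        return len(self.values)


def _trajectory(seq: str, vertices: np.ndarray, start: np.ndarray,
                vertex_of: Mapping[str, int]) -> np.ndarray:
    idx = np.array([vertex_of[c] - 1 for c in seq])
    points = np.empty((len(seq), 2))
    current = start.astype(float)
    for i, j in enumerate(idx):
        current = 0.5 * (current + vertices[j])
        points[i] = current
    return points


def cgr_trajectory_protein(record: SequenceRecord,
                           group_map: Optional[Mapping[str, int]] = None
                           ) -> np.ndarray:
    """Ordered 12-gon CGR points, one per residue, starting from (0,0)."""
    if MolType(record.moltype) is not MolType.protein:
        raise SequenceError(f"{record.id}: protein record required")
    m = TWELVE_GROUP_MAP if group_map is None else group_map
    return _trajectory(record.seq, POLYGON_VERTICES, POLYGON_START, m)


def cgr_trajectory_rna(record: SequenceRecord) -> np.ndarray:
    """Ordered unit-square CGR points, one per base, starting from (0.5, 0.5)."""
    if MolType(record.moltype) is not MolType.rna:
        raise SequenceError(f"{record.id}: rna record required")
    return _trajectory(record.seq, SQUARE_VERTICES, SQUARE_START, RNA_VERTEX_MAP)


def segment_index_24(point, *, radius_split: float = RADIUS_SPLIT) -> int:
    """Segment (1..24) of a 12-gon CGR point: 30-degree sector x radial band.

    The sector is ``1 + floor(angle / 30deg)`` with the angle measured
    counterclockwise from the positive x axis in [0, 360); the band is
    inner (0) for r < radius_split, outer (1) otherwise;
    ``segment = 2*(sector-1) + band + 1``.
    """
    x, y = float(point[0]), float(point[1])
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    # trajectory points attracted toward a vertex can sit exactly on a
    # sector edge; snap sub-ulp atan2 noise so boundary membership follows
    # the floor rule, not libm rounding
    nearest = round(angle / 30.0) * 30.0
    if abs(angle - nearest) < 1e-9:
        angle = nearest % 360.0
    sector = int(angle // 30.0) % 12
    band = 0 if np.hypot(x, y) < radius_split else 1
    return 2 * sector + band + 1


def segment_index_16(point) -> int:
    """Cell (1..16) of a unit-square CGR point on the 4x4 grid, row-major
    from the (0,0) corner; points on the top/right boundary are clamped
    into the last row/column."""
    x, y = float(point[0]), float(point[1])
    c = min(int(x * 4), 3)
    r = min(int(y * 4), 3)
    return 4 * r + c + 1


def _histogram(points: np.ndarray, classify, n_segments: int) -> CGRHistogram:
    counts = np.zeros(n_segments, dtype=int)
    for p in points:
        counts[classify(p) - 1] += 1
    return CGRHistogram(counts=counts, values=counts / len(points))


def encode_cgr_protein(record: SequenceRecord,
                       group_map: Optional[Mapping[str, int]] = None,
                       *, radius_split: float = RADIUS_SPLIT) -> np.ndarray:
    """24-dim segment-frequency vector of the protein 12-gon CGR."""
    points = cgr_trajectory_protein(record, group_map)
    hist = _histogram(
        points, lambda p: segment_index_24(p, radius_split=radius_split),
        N_SEGMENTS_PROTEIN,
    )
    return hist.values


def encode_cgr_rna(record: SequenceRecord) -> np.ndarray:
    """16-dim cell-frequency vector of the RNA square CGR (4x4 FCGR)."""
    points = cgr_trajectory_rna(record)
    return _histogram(points, segment_index_16, N_SEGMENTS_RNA).values


def cgr_histogram_protein(record: SequenceRecord,
                          group_map: Optional[Mapping[str, int]] = None
                          ) -> CGRHistogram:
    points = cgr_trajectory_protein(record, group_map)
    return _histogram(points, segment_index_24, N_SEGMENTS_PROTEIN)


def cgr_histogram_rna(record: SequenceRecord) -> CGRHistogram:
    points = cgr_trajectory_rna(record)
    return _histogram(points, segment_index_16, N_SEGMENTS_RNA)


def plot_trajectory(points: np.ndarray, ax=None, **scatter_kw):
    """Scatter a CGR trajectory (convenience; requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(points[:, 0], points[:, 1], s=4, **scatter_kw)
    ax.set_aspect("equal")
    return ax
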