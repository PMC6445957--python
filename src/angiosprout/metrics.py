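"""Vessel-network quantification from binary occupancy masks.

Relative vessel area, skeleton-based branch-point analysis (closing ->
skeletonize -> junction clustering -> length-weighted branch density), and
tip-cell timing metrics.  The sentinel first-tip time of 1000 h marks runs
in which no tip cell ever appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import closing, footprint_rectangle, skeletonize

__all__ = [
    "NetworkMetrics",
    "NO_TIP_SENTINEL",
    "arel_ec",
    "branch_analysis",
    "skeleton_length_mm",
    "tip_metrics",
    "analyze_record",
]

#: first-tip time reported when no tip cell appears within a run
NO_TIP_SENTINEL = 1000.0

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass
class NetworkMetrics:
    """Derived vessel-network quantities for one mask / run."""

    arel_ec: float
    branch_points: int = 0
    total_branch_length_mm: float = 0.0
    branch_points_per_mm: float = 0.0
    max_tip_count: int = 0
    first_tip_time: float = NO_TIP_SENTINEL
    empty: bool = False


def arel_ec(mask: np.ndarray) -> float:
    """Percentage of lattice sites occupied by endothelial cells."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask array")
    return 100.0 * float(mask.sum()) / mask.size


def _skeletonize(mask: np.ndarray, closing_size: int) -> np.ndarray:
    work = np.asarray(mask, dtype=bool)
    if closing_size > 1:
        # pad so closing near the border behaves like in a larger image
        pad = closing_size
        work = np.pad(work, pad)
        work = closing(work, footprint_rectangle((closing_size, closing_size)))
        work = work[pad:-pad, pad:-pad]
    return skeletonize(work)


def skeleton_length_mm(skeleton: np.ndarray, dx_um: float) -> float:
    """Total skeleton length: 1 per orthogonal adjacency, sqrt(2) per diagonal."""
    s = np.asarray(skeleton, dtype=bool)
    horiz = np.count_nonzero(s[:, :-1] & s[:, 1:])
    vert = np.count_nonzero(s[:-1, :] & s[1:, :])
    diag1 = np.count_nonzero(s[:-1, :-1] & s[1:, 1:])
    diag2 = np.count_nonzero(s[:-1, 1:] & s[1:, :-1])
    length_sites = horiz + vert + math.sqrt(2.0) * (diag1 + diag2)
    return length_sites * dx_um / 1000.0


def branch_analysis(mask: np.ndarray, dx_um: float = 10.0,
                    closing_size: int = 3) -> NetworkMetrics:
    """Skeleton-based branch counting on a binary vessel mask.

    The mask is smoothed by one binary closing (``closing_size`` square
    structuring element), skeletonized to one-pixel width, and junction
    pixels (more than two skeleton neighbors) are merged into 8-connected
    clusters that each count as one branch point.
    """
    mask = np.asarray(mask, dtype=bool)
    metrics = NetworkMetrics(arel_ec=arel_ec(mask))
    if not mask.any():
        metrics.empty = True
        return metrics
    skel = _skeletonize(mask, closing_size)
    if not skel.any():
        metrics.empty = True
        return metrics
    neighbors = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL,
                                 mode="constant")
    junctions = skel & (neighbors > 2)
    n_clusters = int(label(junctions, connectivity=2).max())
    length = skeleton_length_mm(skel, dx_um)
    metrics.branch_points = n_clusters
    metrics.total_branch_length_mm = length
    metrics.branch_points_per_mm = n_clusters / length if length > 0 else 0.0
    return metrics


def tip_metrics(record) -> tuple[int, float]:
    """Maximal concurrent tip count and time of the first tip cell.

    Uses the step-resolved tip series when present, falling back to the
    output snapshots.  Returns the 1000 h sentinel when no tip ever forms.
    """
    if record.step_times:
        times, counts = record.step_times, record.step_tip_counts
    else:
        times, counts = record.snapshot_times, record.tip_counts
    max_tips = max(counts, default=0)
    first = next((t for t, n in zip(times, counts) if n > 0), NO_TIP_SENTINEL)
    return int(max_tips), float(first)


def analyze_record(record, closing_size: int = 3) -> NetworkMetrics:
    """Full network metrics for the final snapshot of a simulation record."""
    metrics = branch_analysis(record.occupancy[-1], record.dx_um, closing_size)
    metrics.max_tip_count, metrics.first_tip_time = tip_metrics(record)
    return metrics
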