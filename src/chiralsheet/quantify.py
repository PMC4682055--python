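"""Boundary-angle statistics, rose histograms, planar cell chirality (PCC),
intercalation frequency and directional velocity.

These mirror the measurements made on live-imaged tissue: the angle theta of
each cell boundary to the AP axis, its classification as left (-90, 0] or
right (0, 90] oblique, 30-degree rose diagrams of intercalating-boundary
angles, the percentage of boundaries that intercalate, and the mean rightward
velocity of tracked cells.  The same functions run on simulated meshes and on
segmented-image output, so in-vivo and in-silico numbers are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .mesh import APFrame, TissueMesh, junction_angles

__all__ = [
    "RoseHistogram",
    "PCCResult",
    "VelocityResult",
    "boundary_angles",
    "pcc_fraction",
    "rose_histogram",
    "intercalation_frequency",
    "mean_tangential_velocity",
]


@dataclass
class RoseHistogram:
    """Angular histogram over (-90, 90] with half-open bins (a, a+width]."""

    bin_edges: np.ndarray       # length n_bins + 1, from -90 to 90
    counts: np.ndarray
    frequencies: np.ndarray | None  # None when the histogram is empty

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class PCCResult:
    """Left/right classification of boundary angles.

    Right oblique is theta in (0, 90] (the fold convention sends exactly
    perpendicular boundaries to +90, hence to the right class); left oblique
    is (-90, 0].
    """

    n_left: int
    n_right: int

    @property
    def total(self) -> int:
        return self.n_left + self.n_right

    @property
    def right_fraction(self) -> float:
        return self.n_right / self.total

    @property
    def standard_error(self) -> float:
        p = self.right_fraction
        return float(np.sqrt(p * (1.0 - p) / self.total))


@dataclass
class VelocityResult:
    per_cell: pd.Series         # mean rightward speed per cell (length/time)
    grand_mean: float
    std: float


def boundary_angles(
    tissue,
    frame: APFrame,
    include_passive: bool = False,
) -> np.ndarray:
    """theta for every scored cell boundary.

    Accepts a ``TissueMesh`` (junction endpoints; junctions touching only
    passive faces are excluded unless ``include_passive``) or a
    ``SegmentedTissue`` from the imaging pipeline (endpoint chords;
    image-border boundaries excluded).
    """
    if isinstance(tissue, TissueMesh):
        theta = junction_angles(tissue, frame)
        if include_passive or not tissue.passive.any():
            return theta
        jf = tissue.topology()["junction_faces"]
        active = np.zeros(len(theta), dtype=bool)
        for j, (f1, f2) in enumerate(jf):
            for f in (f1, f2):
                if f >= 0 and not tissue.passive[f]:
                    active[j] = True
        return theta[active]
    # Duck-typed SegmentedTissue (avoids importing the imaging module here).
    from .imaging import boundary_angle_from_pixels

    out = []
    for boundary in tissue.boundaries.values():
        if boundary.touches_border:
            continue
        theta = boundary_angle_from_pixels(boundary, frame)
        if theta is not None:
            out.append(theta)
    return np.asarray(out, dtype=float)


def pcc_fraction(angles) -> PCCResult:
    """Classify angles into left (-90, 0] vs right (0, 90] oblique."""
    theta = np.asarray(angles, dtype=float)
    if theta.size == 0:
        raise ValueError("pcc_fraction of an empty angle set is undefined")
    if np.any(theta <= -90.0) or np.any(theta > 90.0):
        raise ValueError("angles must lie in (-90, 90]")
    n_right = int(np.count_nonzero(theta > 0.0))
    return PCCResult(n_left=theta.size - n_right, n_right=n_right)


def rose_histogram(angles, bin_width: float = 30.0) -> RoseHistogram:
    """Histogram of angles at ``bin_width``-degree intervals over (-90, 90].

    Bins are half-open (a, a+width] so each angle lands in exactly one bin;
    the fold convention already places -90 at +90.
    """
    if not np.isclose(180.0 % bin_width, 0.0):
        raise ValueError("bin_width must divide 180")
    n_bins = int(round(180.0 / bin_width))
    edges = -90.0 + bin_width * np.arange(n_bins + 1)
    theta = np.asarray(angles, dtype=float)
    counts = np.zeros(n_bins, dtype=np.int64)
    if theta.size:
        if np.any(theta <= -90.0) or np.any(theta > 90.0):
            raise ValueError("angles must lie in (-90, 90]")
        idx = np.ceil((theta + 90.0) / bin_width).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
        freqs = counts / counts.sum()
    else:
        freqs = None
    return RoseHistogram(bin_edges=edges, counts=counts, frequencies=freqs)


def intercalation_frequency(n_events: int, n_boundaries: int) -> float:
    """Percentage of scored boundaries that underwent intercalation,
    rounded half-up to one decimal (e.g. 83 of 607 -> 13.7)."""
    if n_boundaries <= 0:
        raise ValueError("n_boundaries must be positive")
    if not (0 <= n_events <= n_boundaries):
        raise ValueError("need 0 <= n_events <= n_boundaries")
    pct = Decimal(100 * n_events) / Decimal(n_boundaries)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def mean_tangential_velocity(
    tracks: pd.DataFrame,
    frame: APFrame,
    dt_frame: float,
    period_x: float | None = None,
) -> VelocityResult:
    """Mean rightward (perpendicular-to-AP) velocity of tracked cells.

    ``tracks`` has columns cell_id, time, x, y with time in frame indices.
    Each frame-pair displacement is projected onto the local rightward unit
    vector evaluated at the segment start; a cell's mean is its total
    projected distance over total elapsed time, and the grand mean averages
    over cells.  Tracks with fewer than two points are skipped.
    """
    if dt_frame <= 0:
        raise ValueError("dt_frame must be positive")
    per_cell = {}
    for cell_id, grp in tracks.groupby("cell_id"):
        grp = grp.sort_values("time")
        if len(grp) < 2:
            continue
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        t = grp["time"].to_numpy(dtype=float)
        disp = np.diff(pts, axis=0)
        if period_x is not None:
            disp[:, 0] = (disp[:, 0] + period_x / 2.0) % period_x - period_x / 2.0
        right = frame.rightward(pts[:-1])
        projected = np.sum(disp * right, axis=1)
        total_time = (t[-1] - t[0]) * dt_frame
        if total_time <= 0:
            continue
        per_cell[cell_id] = float(projected.sum() / total_time)
    if not per_cell:
        raise ValueError("no track has two or more points")
    series = pd.Series(per_cell, name="rightward_velocity")
    return VelocityResult(
        per_cell=series,
        grand_mean=float(series.mean()),
        std=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
    )
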