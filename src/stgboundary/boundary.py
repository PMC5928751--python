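"""STG length analysis: spatial profiles, boundary detection, ROIs.

The gyrus is treated as a 1-D strip.  The voxelwise clear-vs-noisy contrast
t-statistic is sampled onto surface nodes (averaging 15 equal steps through
the cortical thickness, as volume-to-surface mappers do), averaged within
1-mm bins from anterior to posterior, and the *functional boundary* is the
bin containing the first zero-crossing of the binned t-statistic moving
anterior-to-posterior within the posterior third of the strip.  The
*anatomical boundary* is the Heschl's-gyrus posterior-margin landmark.  ROIs
are built relative to a boundary: 0-30 mm anterior and 0-15 mm posterior,
keeping only voxels whose omnibus F exceeds a responsiveness threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GyrusModel
from .stats import paired_t

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceProfile",
    "BoundaryEstimate",
    "RoiMembership",
    "sample_volume_to_surface",
    "bin_profile",
    "find_functional_boundary",
    "anatomical_boundary",
    "estimate_boundary",
    "define_rois",
    "boundary_report",
]


def sample_volume_to_surface(
    t_volume: np.ndarray,
    pos_grid_mm: np.ndarray,
    node_positions_mm: np.ndarray,
    f_steps: int = 15,
) -> np.ndarray:
    """Sample a (position x thickness) statistical volume onto surface nodes.

    For each node, the segment through the cortical thickness at that strip
    position is subdivided into ``f_steps`` equal steps; the volume values at
    the steps (linear interpolation along the thickness axis) are averaged.
    """
    vol = np.asarray(t_volume, dtype=float)
    if vol.ndim != 2:
        raise ValueError("t_volume must be 2-D (position x thickness)")
    grid = np.asarray(pos_grid_mm, dtype=float)
    if grid.size != vol.shape[0]:
        raise ValueError("pos_grid_mm length must match t_volume rows")
    nodes = np.asarray(node_positions_mm, dtype=float)
    if nodes.size and (nodes.min() < grid.min() - 1e-9 or nodes.max() > grid.max() + 1e-9):
        raise ValueError("node position outside the sampled volume")
    n_depth = vol.shape[1]
    depth_pts = np.linspace(0.0, n_depth - 1.0, f_steps)
    lo = np.floor(depth_pts).astype(int)
    hi = np.minimum(lo + 1, n_depth - 1)
    frac = depth_pts - lo
    out = np.empty(nodes.size)
    for i, p in enumerate(nodes):
        col_idx = int(np.argmin(np.abs(grid - p)))
        col = vol[col_idx]
        samples = col[lo] * (1.0 - frac) + col[hi] * frac
        out[i] = samples.mean()
    return out


@dataclass
class SurfaceProfile:
    """Binned anterior-to-posterior profile of a node statistic.

    ``bin_edges_mm`` has length n_bins + 1 and covers [0, length]; bins with
    no nodes have NaN mean and count 0.
    """

    bin_edges_mm: np.ndarray
    mean_t: np.ndarray
    node_count: np.ndarray
    length_mm: float

    @property
    def n_bins(self) -> int:
        return self.mean_t.size

    @property
    def bin_starts_mm(self) -> np.ndarray:
        return self.bin_edges_mm[:-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_mm": self.bin_edges_mm[:-1],
                "bin_end_mm": self.bin_edges_mm[1:],
                "mean_t": self.mean_t,
                "node_count": self.node_count,
            }
        )


def bin_profile(
    node_values: np.ndarray,
    node_positions_mm: np.ndarray,
    length_mm: float,
    bin_mm: float = 1.0,
) -> SurfaceProfile:
    """Average node values within contiguous anterior-to-posterior bins."""
    vals = np.asarray(node_values, dtype=float)
    pos = np.asarray(node_positions_mm, dtype=float)
    if vals.size == 0 or vals.shape != pos.shape:
        raise ValueError("need matching, non-empty node values and positions")
    if (pos < 0).any() or (pos > length_mm).any():
        raise ValueError("node positions must lie within [0, length]")
    n_bins = int(np.ceil(length_mm / bin_mm))
    edges = np.arange(n_bins + 1) * bin_mm
    edges[-1] = max(edges[-1], length_mm)
    idx = np.minimum((pos / bin_mm).astype(int), n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
    return SurfaceProfile(
        bin_edges_mm=edges, mean_t=mean, node_count=count, length_mm=length_mm
    )


def find_functional_boundary(
    profile: SurfaceProfile, posterior_third_start_mm: float | None = None
) -> float | None:
    """First anterior-to-posterior zero-crossing in the posterior third.

    Scans the 1-mm bins of the posterior third (by default [2L/3, L]) in
    anterior-to-posterior order and returns the start position of the first
    bin whose mean t changes sign relative to the nearest preceding non-empty
    bin; a bin mean of exactly zero counts as a crossing at that bin.  The
    reference sign is seeded from the mean over all populated bins anterior
    to the posterior third (a robust summary of the anterior regime), so a
    posterior third that begins already sign-flipped reports its first bin
    rather than missing a transition that completed just ahead of the search
    region.  Returns None when no crossing exists; empty bins never
    fabricate one.
    """
    if np.all(np.isnan(profile.mean_t)):
        raise ValueError("profile has no populated bins")
    if posterior_third_start_mm is None:
        posterior_third_start_mm = 2.0 * profile.length_mm / 3.0
    starts = profile.bin_starts_mm
    in_third = starts >= posterior_third_start_mm

    anterior_vals = profile.mean_t[~in_third & (profile.node_count > 0)]
    prev_sign = 0
    if anterior_vals.size:
        m = float(anterior_vals.mean())
        if m != 0:
            prev_sign = int(np.sign(m))
    for i in np.where(in_third)[0]:
        if profile.node_count[i] == 0:
            continue
        v = profile.mean_t[i]
        if v == 0:
            return float(starts[i])
        s = int(np.sign(v))
        if prev_sign != 0 and s != prev_sign:
            return float(starts[i])
        prev_sign = s
    return None


def anatomical_boundary(gyrus: GyrusModel) -> float:
    """Position of the Heschl's-gyrus posterior-margin landmark (mm)."""
    return float(gyrus.anatomical_landmark_mm)


@dataclass(frozen=True)
class BoundaryEstimate:
    """Functional (zero-crossing) and anatomical (landmark) boundaries."""

    functional_mm: float | None
    anatomical_mm: float
    functional_y: float | None
    anatomical_y: float
    distance_mm: float | None

    @property
    def found(self) -> bool:
        return self.functional_mm is not None


def estimate_boundary(profile: SurfaceProfile, gyrus: GyrusModel) -> BoundaryEstimate:
    """Combine zero-crossing detection with the anatomical landmark."""
    func = find_functional_boundary(profile, gyrus.posterior_third_start_mm)
    anat = anatomical_boundary(gyrus)
    return BoundaryEstimate(
        functional_mm=func,
        anatomical_mm=anat,
        functional_y=float(gyrus.to_standard_y(func)) if func is not None else None,
        anatomical_y=float(gyrus.to_standard_y(anat)),
        distance_mm=abs(func - anat) if func is not None else None,
    )


@dataclass
class RoiMembership:
    """Boundary-relative anterior/posterior ROI voxel masks."""

    boundary_mm: float
    anterior_mask: np.ndarray
    posterior_mask: np.ndarray
    anterior_empty: bool
    posterior_empty: bool

    @property
    def any_empty(self) -> bool:
        return self.anterior_empty or self.posterior_empty


def define_rois(
    boundary_mm: float,
    voxel_positions_mm: np.ndarray,
    f_stats: np.ndarray,
    length_mm: float,
    extents_mm: tuple[float, float] = (30.0, 15.0),
    f_threshold: float = 5.0,
) -> RoiMembership:
    """Anterior [boundary-30, boundary) and posterior [boundary, boundary+15]
    ROIs, keeping only voxels with omnibus F above threshold.

    Extents that run past the ends of the strip are clipped (with a warning);
    the two ROIs are disjoint by construction.
    """
    if not 0 <= boundary_mm <= length_mm:
        raise ValueError("boundary must lie on the strip")
    if extents_mm[0] <= 0 or extents_mm[1] <= 0:
        raise ValueError("ROI extents must be positive")
    pos = np.asarray(voxel_positions_mm, dtype=float)
    f = np.asarray(f_stats, dtype=float)
    if pos.shape != f.shape:
        raise ValueError("positions and F statistics must align")
    a_lo = boundary_mm - extents_mm[0]
    p_hi = boundary_mm + extents_mm[1]
    if a_lo < 0 or p_hi > length_mm:
        logger.warning("ROI extent clipped at the strip ends")
    responsive = f > f_threshold
    ant = responsive & (pos >= a_lo) & (pos < boundary_mm)
    post = responsive & (pos >= boundary_mm) & (pos <= p_hi)
    if not ant.any():
        logger.warning("anterior ROI empty after F filtering")
    if not post.any():
        logger.warning("posterior ROI empty after F filtering")
    return RoiMembership(
        boundary_mm=boundary_mm,
        anterior_mask=ant,
        posterior_mask=post,
        anterior_empty=not ant.any(),
        posterior_empty=not post.any(),
    )


def boundary_report(estimates: list[BoundaryEstimate]) -> dict:
    """Group summary of functional vs anatomical boundary positions.

    With >= 2 hemispheres, includes a paired t-test of the per-hemisphere
    functional vs anatomical positions; hemispheres without a detected
    functional boundary are excluded (and counted).
    """
    found = [e for e in estimates if e.found]
    out: dict = {
        "n_hemispheres": len(estimates),
        "n_with_functional_boundary": len(found),
    }
    if not found:
        return out
    fy = np.array([e.functional_y for e in found])
    ay = np.array([e.anatomical_y for e in found])
    dist = np.array([e.distance_mm for e in found])
    out.update(
        functional_y_mean=float(fy.mean()),
        functional_y_sd=float(fy.std(ddof=1)) if fy.size > 1 else 0.0,
        anatomical_y_mean=float(ay.mean()),
        anatomical_y_sd=float(ay.std(ddof=1)) if ay.size > 1 else 0.0,
        distance_mean_mm=float(dist.mean()),
        distance_max_mm=float(dist.max()),
    )
    if len(found) >= 2:
        res = paired_t(fy, ay)
        out["paired_t"] = res.t
        out["paired_df"] = res.df
        out["paired_p"] = res.p
        out["degenerate"] = res.degenerate
        if res.degenerate:
            out["conclusion"] = "no difference"
    return out
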