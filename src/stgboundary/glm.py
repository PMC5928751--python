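"""Voxelwise GLM analysis of event-related BOLD time series.

Two design-matrix families are supported:

* a *block* model: one regressor per stimulus condition, built by convolving
  a 2-s neural boxcar per trial with a fixed unit-peak HRF and sampling on
  the TR grid (betas are then per-trial percent-signal amplitudes), plus six
  motion nuisance columns -- ten regressors in total;
* a *tent* (piecewise-linear FIR) model estimating the response amplitude
  independently at each post-stimulus lag: one column per knot per condition
  over a 0-15 s window at TR spacing (11 knots, 44 condition columns, 50
  with motion), making no assumption about response shape.

Per-run intercept and linear-drift columns are appended at fit time as
baseline nuisance (standard practice for concatenated runs; they absorb the
scanner drift and the mean-100 offset of percent-signal-scaled data and are
not counted among the model's regressors of interest).

The main dependent measure is the general linear test with weights
``+1 +1 -1 -1`` over the condition betas: the contrast between the two
auditory-clear and the two auditory-noisy conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CONDITIONS, EventSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "GlmResult",
    "block_hrf_kernel",
    "build_block_design",
    "build_tent_design",
    "scale_to_psc",
    "fit_glm",
    "contrast_clear_vs_noisy",
    "estimate_hrf_tent",
    "localizer_response",
]

CLEAR_NOISY_WEIGHTS = np.array([1.0, 1.0, -1.0, -1.0])


@dataclass
class DesignMatrix:
    """A labelled design: condition (or tent) columns plus motion nuisance."""

    matrix: pd.DataFrame
    roles: dict[str, str]  # column -> 'condition' | 'tent' | 'motion'
    basis: str  # 'block' | 'tent'
    run_lengths: list[int]
    conditions: tuple[str, ...] = CONDITIONS
    knot_times_s: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]


def block_hrf_kernel(dt_s: float = 0.1, duration_s: float = 25.0) -> np.ndarray:
    """Default block-model HRF: gamma-variate (shape 4, scale 1.1 s).

    Convolved with the 2-s neural boxcar inside the design builder, this
    kernel yields a single-trial response peaking between 4.5 and 6 s, the
    shape-level behaviour expected of an event-related BOLD response.
    """
    t = np.arange(0.0, duration_s, dt_s)
    k = stats.gamma.pdf(t, 4.0, scale=1.1)
    return k


def _condition_regressors(
    schedule: EventSchedule,
    hrf_kernel: np.ndarray,
    dt_s: float,
    block_s: float,
) -> dict[str, np.ndarray]:
    from .synthetic import condition_regressors

    return condition_regressors(schedule, hrf_kernel, dt_s, block_s)


def build_block_design(
    schedule: EventSchedule,
    motion_table: pd.DataFrame,
    hrf_kernel: np.ndarray | None = None,
    hrf_dt_s: float = 0.1,
    block_s: float = 2.0,
) -> DesignMatrix:
    """One unit-peak HRF-convolved regressor per condition + 6 motion columns."""
    n_vol = schedule.total_volumes
    if len(motion_table) != n_vol:
        raise ValueError("motion table length must match total volumes")
    if hrf_kernel is None:
        hrf_kernel = block_hrf_kernel(dt_s=hrf_dt_s)
    regs = _condition_regressors(schedule, hrf_kernel, hrf_dt_s, block_s)
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    n_trials = len(schedule.trials)
    for c in CONDITIONS:
        if n_trials:
            cols[c] = regs[c]
            roles[c] = "condition"
    for m in motion_table.columns:
        cols[m] = motion_table[m].to_numpy(dtype=float)
        roles[m] = "motion"
    return DesignMatrix(
        matrix=pd.DataFrame(cols),
        roles=roles,
        basis="block",
        run_lengths=[schedule.volumes_per_run] * schedule.n_runs,
    )


def build_tent_design(
    schedule: EventSchedule,
    motion_table: pd.DataFrame,
    window_s: tuple[float, float] = (0.0, 15.0),
    n_knots: int = 11,
) -> DesignMatrix:
    """Piecewise-linear FIR basis: one column per knot per condition.

    Knots span ``window_s`` at TR spacing; each column's value at volume time
    T is the tent function ``max(0, 1 - |T - onset - knot| / TR)`` summed over
    that condition's trials, so a trial aligned to the TR grid contributes a
    unit impulse at each lag.
    """
    tr = schedule.tr_s
    if window_s[0] != 0.0:
        raise ValueError("tent window must start at 0 s")
    knot_times = np.linspace(window_s[0], window_s[1], n_knots)
    spacing = knot_times[1] - knot_times[0] if n_knots > 1 else tr
    if abs(spacing - tr) > 1e-9:
        raise ValueError(
            f"knot spacing ({spacing} s) must equal the TR ({tr} s); "
            f"use n_knots = window/TR + 1"
        )
    n_vol = schedule.total_volumes
    if len(motion_table) != n_vol:
        raise ValueError("motion table length must match total volumes")

    vol_times = np.arange(schedule.volumes_per_run) * tr
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for c in CONDITIONS:
        for ki, kt in enumerate(knot_times):
            per_run = []
            for run in range(schedule.n_runs):
                trials = schedule.run_trials(run)
                onsets = trials.loc[trials["condition"] == c, "onset_s"].to_numpy()
                col = np.zeros(schedule.volumes_per_run)
                for onset in onsets:
                    col += np.maximum(
                        0.0, 1.0 - np.abs(vol_times - onset - kt) / tr
                    )
                per_run.append(col)
            name = f"{c}@{kt:g}s"
            cols[name] = np.concatenate(per_run)
            roles[name] = "tent"
    for m in motion_table.columns:
        cols[m] = motion_table[m].to_numpy(dtype=float)
        roles[m] = "motion"
    return DesignMatrix(
        matrix=pd.DataFrame(cols),
        roles=roles,
        basis="tent",
        run_lengths=[schedule.volumes_per_run] * schedule.n_runs,
        knot_times_s=knot_times,
    )


def scale_to_psc(voxel_series: np.ndarray) -> np.ndarray:
    """Rescale each voxel series to mean 100 (percent-signal-change units).

    Betas fit to scaled data are directly interpretable as percent of
    baseline.  Voxels with non-positive mean (outside the head, or corrupted)
    cannot be meaningfully scaled: they are set to NaN and logged.
    """
    x = np.asarray(voxel_series, dtype=float)
    single = x.ndim == 1
    x2 = x[None, :] if single else x
    means = x2.mean(axis=1)
    bad = means <= 0
    if bad.any():
        logger.warning("masking %d voxel(s) with non-positive mean", int(bad.sum()))
    out = np.full_like(x2, np.nan)
    good = ~bad
    out[good] = x2[good] * (100.0 / means[good, None])
    return out[0] if single else out


@dataclass
class GlmResult:
    """Ordinary-least-squares fit of one design to one or many voxels.

    Arrays are vectorized over voxels: ``betas`` is (n_voxels, n_columns) in
    the order of ``column_names``; ``sigma2`` the residual variance with
    ``dof`` degrees of freedom.  Baseline (per-run intercept/drift) betas are
    kept separately and are not part of the named model columns.
    """

    column_names: list[str]
    roles: dict[str, str]
    basis: str
    conditions: tuple[str, ...]
    betas: np.ndarray
    baseline_betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    xtx_inv: np.ndarray  # full augmented (X'X)^-1
    n_model_columns: int
    knot_times_s: np.ndarray | None = None
    zero_residual: np.ndarray | None = None

    def _col_idx(self, names: list[str]) -> np.ndarray:
        return np.array([self.column_names.index(c) for c in names])

    def contrast(self, weights: np.ndarray, columns: list[str] | None = None):
        """Estimate and t-statistic of w'beta over the given (model) columns.

        Voxels flagged zero-residual get a +/-inf sentinel t.
        """
        if columns is None:
            columns = [c for c in self.column_names if self.roles[c] != "motion"]
        idx = self._col_idx(columns)
        w = np.asarray(weights, dtype=float)
        if w.size != idx.size:
            raise ValueError("weight vector length must match column count")
        est = self.betas[:, idx] @ w
        quad = float(w @ self.xtx_inv[np.ix_(idx, idx)] @ w)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(self.sigma2 * quad)
        if self.zero_residual is not None and self.zero_residual.any():
            t = np.where(self.zero_residual, np.sign(est) * np.inf, t)
        return est, t

    @property
    def f_omnibus(self) -> np.ndarray:
        """Omnibus F over all condition/tent columns (the 'Full-F' filter)."""
        cond_cols = [c for c in self.column_names if self.roles[c] in ("condition", "tent")]
        idx = self._col_idx(cond_cols)
        sub = self.xtx_inv[np.ix_(idx, idx)]
        sub_inv = np.linalg.inv(sub)
        b = self.betas[:, idx]
        q = idx.size
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.einsum("vi,ij,vj->v", b, sub_inv, b) / (q * self.sigma2)
        if self.zero_residual is not None:
            f = np.where(self.zero_residual, np.inf, f)
        return f


def _baseline_columns(run_lengths: list[int]) -> np.ndarray:
    """Per-run intercept + linear trend nuisance block."""
    n = sum(run_lengths)
    cols = []
    start = 0
    for rl in run_lengths:
        ic = np.zeros(n)
        ic[start : start + rl] = 1.0
        lin = np.zeros(n)
        lin[start : start + rl] = np.linspace(-1.0, 1.0, rl)
        cols.extend([ic, lin])
        start += rl
    return np.column_stack(cols)


def fit_glm(
    scaled_series: np.ndarray,
    design: DesignMatrix,
    add_baseline_per_run: bool = True,
) -> GlmResult:
    """OLS fit of the design to one voxel (1-D) or a voxel stack (2-D).

    t for a weight vector w is ``w'beta / sqrt(sigma2 * w'(X'X)^-1 w)``.
    Voxels with exactly zero residual variance are flagged and reported with
    infinite-sentinel statistics rather than NaNs.
    """
    y = np.asarray(scaled_series, dtype=float)
    single = y.ndim == 1
    y2 = y[None, :] if single else y
    x_model = design.matrix.to_numpy(dtype=float)
    if y2.shape[1] != x_model.shape[0]:
        raise ValueError("series length must match design rows")
    if add_baseline_per_run:
        x = np.hstack([x_model, _baseline_columns(design.run_lengths)])
    else:
        x = x_model
    p = x.shape[1]
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    betas_all, _, _, _ = np.linalg.lstsq(x, y2.T, rcond=None)
    betas_all = betas_all.T  # (n_vox, p)
    resid = y2 - betas_all @ x.T
    dof = y2.shape[1] - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    rss = np.sum(resid**2, axis=1)
    sigma2 = rss / dof
    zero_resid = rss <= np.finfo(float).eps * np.maximum(1.0, np.sum(y2**2, axis=1))
    if zero_resid.any():
        logger.warning(
            "%d voxel(s) with zero residual variance; statistics are sentinels",
            int(zero_resid.sum()),
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    n_model = x_model.shape[1]
    return GlmResult(
        column_names=list(design.matrix.columns),
        roles=dict(design.roles),
        basis=design.basis,
        conditions=design.conditions,
        betas=betas_all[:, :n_model],
        baseline_betas=betas_all[:, n_model:],
        sigma2=sigma2,
        dof=dof,
        xtx_inv=xtx_inv,
        n_model_columns=n_model,
        knot_times_s=design.knot_times_s,
        zero_residual=zero_resid,
    )


def contrast_clear_vs_noisy(result: GlmResult) -> tuple[np.ndarray, np.ndarray]:
    """The +1 +1 -1 -1 general linear test: clear minus noisy auditory speech.

    Requires a block-model fit with the four condition columns in canonical
    order (AclearVclear, AclearVblur, AnoisyVclear, AnoisyVblur).
    """
    cond_cols = [c for c in result.column_names if result.roles[c] == "condition"]
    if tuple(cond_cols) != CONDITIONS:
        raise ValueError(
            f"expected condition columns in canonical order {CONDITIONS}, got {cond_cols}"
        )
    return result.contrast(CLEAR_NOISY_WEIGHTS, cond_cols)


def estimate_hrf_tent(result: GlmResult, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """The FIR response estimate for one condition from a tent-model fit.

    Returns (knot_times_s, betas) with betas shaped (n_voxels, n_knots); the
    knot betas *are* the estimated response shape at each lag.
    """
    if result.basis != "tent" or result.knot_times_s is None:
        raise ValueError("requires a tent-design fit")
    if condition not in result.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cols = [f"{condition}@{kt:g}s" for kt in result.knot_times_s]
    missing = [c for c in cols if c not in result.column_names]
    if missing:
        raise ValueError(f"condition {condition!r} absent from fit: {missing}")
    idx = result._col_idx(cols)
    return result.knot_times_s.copy(), result.betas[:, idx]


def localizer_response(
    knot_times_s: np.ndarray,
    knot_betas: np.ndarray,
    at_s: tuple[float, ...] = (4.5, 6.0, 7.5),
) -> np.ndarray:
    """Scalar response amplitude: mean of the knot betas at the named times.

    Used with a long-window tent fit (0-30 s, 21 knots) to summarize slow
    block responses by averaging the betas near the response peak.
    """
    times = np.asarray(knot_times_s, dtype=float)
    b = np.atleast_2d(np.asarray(knot_betas, dtype=float))
    idx = []
    for t in at_s:
        match = np.where(np.isclose(times, t))[0]
        if match.size == 0:
            raise ValueError(f"knot at {t} s missing from the tent grid")
        idx.append(match[0])
    out = b[:, idx].mean(axis=1)
    return out[0] if np.asarray(knot_betas).ndim == 1 else out
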