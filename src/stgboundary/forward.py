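"""ECoG-to-BOLD forward modelling.

High-gamma power and the BOLD signal are two views of the same underlying
neural activity, separated by the hemodynamic response: BOLD is (to first
order) the neural timecourse convolved with a hemodynamic response function
(HRF) and sampled on the slow TR grid of the scanner.  This module builds a
canonical double-gamma HRF from three interpretable descriptors (peak time,
undershoot offset, peak-to-undershoot ratio), convolves millisecond-resolution
high-gamma percent-change timecourses with it, downsamples the prediction to
the TR grid, and fits a single per-condition scale factor mapping ECoG percent
change onto BOLD percent signal change.

The scale factor is a *divisor*: a fitted scale of 600 means that a 600%
high-gamma response corresponds to a 1% BOLD response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HrfModel",
    "ScaleFit",
    "make_double_gamma_hrf",
    "predict_bold_from_ecog",
    "fit_scale_factor",
    "compare_predicted_actual",
    "aggregate_scale_factors",
]


@dataclass(frozen=True)
class HrfModel:
    """A sampled double-gamma hemodynamic response kernel.

    The kernel is normalized so its realized maximum is 1 and occurs at
    ``peak_time_s``; its realized minimum (the post-stimulus undershoot)
    occurs at ``peak_time_s + undershoot_offset_s`` and has magnitude
    ``1 / response_undershoot_ratio``.
    """

    peak_time_s: float
    undershoot_offset_s: float
    response_undershoot_ratio: float
    dt_s: float
    kernel: np.ndarray = field(repr=False)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.kernel.size) * self.dt_s

    @property
    def duration_s(self) -> float:
        return self.kernel.size * self.dt_s


def _gamma_peak_normalized(t: np.ndarray | float, shape: float, scale: float):
    """Gamma density rescaled to peak value 1 (mode at (shape-1)*scale)."""
    mode = (shape - 1.0) * scale
    peak = gamma_dist.pdf(mode, shape, scale=scale)
    return gamma_dist.pdf(t, shape, scale=scale) / peak


def _gamma_peak_normalized_deriv(t: float, shape: float, scale: float) -> float:
    # d/dt of the gamma pdf: pdf(t) * ((shape-1)/t - 1/scale)
    return _gamma_peak_normalized(t, shape, scale) * ((shape - 1.0) / t - 1.0 / scale)


def make_double_gamma_hrf(
    peak_time_s: float = 6.0,
    undershoot_offset_s: float = 10.0,
    ratio: float = 4.0,
    dt_s: float = 0.001,
    duration_s: float = 32.0,
    shape: float = 6.0,
) -> HrfModel:
    """Construct a canonical double-gamma HRF from its printed descriptors.

    The kernel is the difference of two peak-normalized gamma-density lobes,
    ``h(t) = g1(t) - c * g2(t)``.  The two lobe scales and the mixing
    coefficient ``c`` are solved numerically so that the three descriptors are
    exact properties of the realized kernel:

    * ``h`` is stationary (a maximum) at ``peak_time_s``,
    * ``h`` is stationary (the undershoot minimum) at
      ``peak_time_s + undershoot_offset_s``,
    * ``max(h) / |min(h)| == ratio``.

    The result is then renormalized to unit peak.

    Parameters
    ----------
    peak_time_s : time of the positive response peak (s).
    undershoot_offset_s : delay from the peak to the undershoot minimum (s).
    ratio : peak amplitude divided by undershoot magnitude (dimensionless).
    dt_s : sampling interval of the returned kernel (s).
    duration_s : total kernel length (s).
    shape : gamma shape parameter shared by the two lobes.
    """
    trough_time = peak_time_s + undershoot_offset_s
    if not (0 < peak_time_s < trough_time < duration_s):
        raise ValueError(
            "require 0 < peak_time_s < peak_time_s + undershoot_offset_s < duration_s"
        )
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if dt_s <= 0 or duration_s <= 0:
        raise ValueError("dt_s and duration_s must be positive")

    def residuals(params: np.ndarray) -> list[float]:
        s1, s2, c = params
        if s1 <= 0 or s2 <= 0:
            return [1e3, 1e3, 1e3]
        d_peak = _gamma_peak_normalized_deriv(peak_time_s, shape, s1) - c * (
            _gamma_peak_normalized_deriv(peak_time_s, shape, s2)
        )
        d_trough = _gamma_peak_normalized_deriv(trough_time, shape, s1) - c * (
            _gamma_peak_normalized_deriv(trough_time, shape, s2)
        )
        h_peak = _gamma_peak_normalized(peak_time_s, shape, s1) - c * (
            _gamma_peak_normalized(peak_time_s, shape, s2)
        )
        h_trough = _gamma_peak_normalized(trough_time, shape, s1) - c * (
            _gamma_peak_normalized(trough_time, shape, s2)
        )
        return [d_peak, d_trough, h_peak + ratio * h_trough]

    x0 = np.array([peak_time_s / (shape - 1.0), trough_time / (shape - 1.0), 0.2])
    sol, info, ier, msg = optimize.fsolve(residuals, x0, full_output=True)
    if ier != 1 or np.max(np.abs(residuals(sol))) > 1e-8:
        raise RuntimeError(f"HRF descriptor solve failed: {msg}")
    s1, s2, c = sol

    t = np.arange(0.0, duration_s, dt_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = _gamma_peak_normalized(t, shape, s1) - c * _gamma_peak_normalized(
            t, shape, s2
        )
    kernel[0] = 0.0
    peak_val = kernel.max()
    if peak_val <= 0 or kernel.min() >= 0:
        raise RuntimeError("HRF solve produced a degenerate kernel")
    kernel = kernel / peak_val
    # the solved stationary points must be the realized global extrema;
    # closely spaced peak/trough times need sharper lobes (larger `shape`)
    if (
        abs(np.argmax(kernel) * dt_s - peak_time_s) > 2 * dt_s + 1e-12
        or abs(np.argmin(kernel) * dt_s - trough_time) > 2 * dt_s + 1e-12
        or abs(kernel.max() / abs(kernel.min()) - ratio) > 1e-3 * ratio
    ):
        raise RuntimeError(
            "HRF descriptors not realized by the kernel; "
            "increase `shape` for closely spaced peak and undershoot"
        )
    return HrfModel(
        peak_time_s=peak_time_s,
        undershoot_offset_s=undershoot_offset_s,
        response_undershoot_ratio=ratio,
        dt_s=dt_s,
        kernel=kernel,
    )


def predict_bold_from_ecog(
    highgamma_1ms: np.ndarray,
    hrf: HrfModel,
    tr_s: float = 1.5,
    n_out: int = 11,
) -> np.ndarray:
    """Convolve a 1 ms high-gamma timecourse with the HRF, sample on the TR grid.

    ``highgamma_1ms`` is the condition-mean percent-change timecourse starting
    at stimulus onset (t = 0) with 1 ms resolution.  The prediction is the
    discrete convolution with the HRF kernel (which must also be sampled at
    1 ms), read out at stimulus-locked multiples of the TR (nearest sample, no
    anti-alias filter: the convolved signal is smooth on the seconds scale).
    Output units are arbitrary until divided by a fitted scale factor.
    """
    if abs(hrf.dt_s - 0.001) > 1e-12:
        raise ValueError("HRF kernel must be sampled at 1 ms to match the input")
    x = np.asarray(highgamma_1ms, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D timecourse")
    conv = np.convolve(x, hrf.kernel)
    step = int(round(tr_s / hrf.dt_s))
    idx = np.arange(n_out) * step
    out = np.zeros(n_out)
    valid = idx < conv.size
    out[valid] = conv[idx[valid]]
    return out


@dataclass(frozen=True)
class ScaleFit:
    """Result of fitting a single ECoG%-per-BOLD% divisor to one curve."""

    scale_factor: float
    pearson_r: float
    sse: float
    reliable: bool
    condition: str | None = None
    region: str | None = None


def fit_scale_factor(
    predicted_unscaled: np.ndarray,
    actual: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 1e6),
    condition: str | None = None,
    region: str | None = None,
) -> ScaleFit:
    """Find the divisor ``s`` minimizing ``sum((predicted/s - actual)**2)``.

    Implemented as a bounded 1-D minimization (on log s, for uniform relative
    precision across the ten-decade search interval).  When the inner product
    of predicted and actual is positive the optimum has the closed form
    ``s* = <pred, pred> / <pred, actual>``; a non-positive inner product means
    the curves disagree in sign and the fit is flagged unreliable.
    """
    p = np.asarray(predicted_unscaled, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("predicted and actual must be 1-D and equal length")
    if p.size < 3:
        raise ValueError("need at least 3 samples to fit a scale factor")

    pp = float(p @ p)
    pa = float(p @ a)
    reliable = pa > 0

    def sse_of_log_s(x: float) -> float:
        s = np.exp(x)
        r = p / s - a
        return float(r @ r)

    res = optimize.minimize_scalar(
        sse_of_log_s,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-12},
    )
    s_hat = float(np.exp(res.x))
    if np.std(p) > 0 and np.std(a) > 0:
        r_val = float(stats.pearsonr(p / s_hat, a).statistic)
    else:
        r_val = np.nan
    return ScaleFit(
        scale_factor=s_hat,
        pearson_r=r_val,
        sse=float(res.fun),
        reliable=reliable,
        condition=condition,
        region=region,
    )


def compare_predicted_actual(predicted_scaled: np.ndarray, actual: np.ndarray) -> float:
    """Pearson correlation between a scaled prediction and the measured curve."""
    p = np.asarray(predicted_scaled, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 3:
        raise ValueError("predicted and actual must be equal length >= 3")
    if np.std(p) == 0 or np.std(a) == 0:
        raise ValueError("zero-variance input has no defined correlation")
    return float(stats.pearsonr(p, a).statistic)


def aggregate_scale_factors(fits: Sequence[ScaleFit | float]) -> float:
    """Arithmetic mean of scale factors across region x condition curves."""
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    vals = [f.scale_factor if isinstance(f, ScaleFit) else float(f) for f in fits]
    return float(np.mean(vals))
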