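"""Group-level statistics: mixed-effects factorial models and paired tests.

The central model is a linear mixed-effects (LME) analysis of response
amplitude (percent signal change from baseline) with three crossed fixed
factors -- location (anterior vs posterior), auditory noise (clear vs noisy)
and visual blur (clear vs blurred) -- with all interactions, treatment-coded
against the anterior / auditory-clear / visual-clear cell, plus a random
intercept per participant (units such as electrodes or hemispheres are
correlated within a participant).

The solver maximizes the REML criterion for the random-intercept structure
directly (profiled fixed effects, Woodbury identities per participant
block), and reports Satterthwaite-approximate denominator degrees of freedom
for each fixed effect: df = 2 f^2 / Var(f) with f = w'(X'V^-1X)^-1 w, the
variance obtained by the delta method from the REML information of the two
variance components.  Fractional dfs of this kind are what mixed-model
packages such as lmerTest report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "LmeResult",
    "PairedTResult",
    "fit_lme",
    "behavioral_accuracy",
    "paired_t",
    "EFFECT_NAMES",
]

EFFECT_NAMES = (
    "baseline",
    "An",
    "Vb",
    "posterior",
    "An:Vb",
    "posterior:An",
    "posterior:Vb",
    "posterior:An:Vb",
)


@dataclass
class LmeResult:
    """Fixed-effect table plus variance components of a random-intercept LME.

    ``effects`` is indexed by effect name with columns Estimate, StdError,
    DF, t, p (the layout of a standard mixed-model coefficient table).
    """

    effects: pd.DataFrame
    sigma2: float  # residual variance
    tau2: float  # participant random-intercept variance
    converged: bool
    singular: bool
    n_obs: int
    n_participants: int


def _lme_design(table: pd.DataFrame, response: str):
    req = {"participant", "location", "auditory", "visual", response}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    an = (table["auditory"].astype(str) == "noisy").to_numpy(dtype=float)
    vb = (table["visual"].astype(str).isin(["blurred", "blurry", "blur"])).to_numpy(dtype=float)
    post = (table["location"].astype(str) == "posterior").to_numpy(dtype=float)
    x = np.column_stack(
        [
            np.ones(len(table)),
            an,
            vb,
            post,
            an * vb,
            post * an,
            post * vb,
            post * an * vb,
        ]
    )
    y = table[response].to_numpy(dtype=float)
    groups, group_codes = np.unique(table["participant"].astype(str), return_inverse=True)
    cells = set(zip(post.astype(int), an.astype(int), vb.astype(int)))
    if len(cells) < 8:
        raise ValueError("all 8 location x auditory x visual cells must be present")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    return x, y, group_codes, len(groups)


def _reml_pieces(theta: np.ndarray, x: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Per-group Woodbury assembly of X'V^-1X, X'V^-1y, y'V^-1y, log|V|."""
    se2, sb2 = theta
    p = x.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for g in range(codes.max() + 1):
        sel = codes == g
        xg = x[sel]
        yg = y[sel]
        n_g = xg.shape[0]
        gamma = sb2 / (se2 + n_g * sb2)
        sx = xg.sum(axis=0)
        sy = yg.sum()
        xtvx += (xg.T @ xg - gamma * np.outer(sx, sx)) / se2
        xtvy += (xg.T @ yg - gamma * sx * sy) / se2
        ytvy += (yg @ yg - gamma * sy * sy) / se2
        logdet_v += (n_g - 1) * np.log(se2) + np.log(se2 + n_g * sb2)
    return xtvx, xtvy, ytvy, logdet_v


def _reml_neg2loglik(theta, x, y, codes) -> float:
    if not np.all(np.isfinite(theta)) or np.any(theta <= 0):
        return np.inf
    xtvx, xtvy, ytvy, logdet_v = _reml_pieces(theta, x, y, codes)
    sign, logdet_a = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - xtvy @ beta
    return logdet_v + logdet_a + quad


def fit_lme(table: pd.DataFrame, response: str = "response") -> LmeResult:
    """Fit the three-factor random-intercept LME to a response table.

    The table must hold one row per unit x condition cell with columns
    ``unit``, ``participant``, ``location`` (anterior/posterior), ``auditory``
    (clear/noisy), ``visual`` (clear/blurred) and the response.  Requires at
    least 2 participants and all 8 factorial cells.  A fit whose
    random-intercept variance collapses to (near) zero is flagged singular;
    its dfs fall back to the residual df.
    """
    x, y, codes, n_groups = _lme_design(table, response)
    if n_groups < 2:
        raise ValueError("need at least 2 participants")
    n, p = x.shape

    # OLS start values
    beta0, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta0
    s2 = float(resid @ resid) / max(n - p, 1)

    def objective(log_theta):
        with np.errstate(over="ignore", invalid="ignore"):
            return _reml_neg2loglik(np.exp(log_theta), x, y, codes)

    res = optimize.minimize(
        objective,
        x0=np.log([s2 * 0.8 + 1e-12, s2 * 0.2 + 1e-12]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    se2, sb2 = np.exp(res.x)
    singular = sb2 < 1e-8 * (se2 + sb2)
    theta = np.array([se2, sb2])

    xtvx, xtvy, _, _ = _reml_pieces(theta, x, y, codes)
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ xtvy
    se_beta = np.sqrt(np.diag(cov_beta))

    # Satterthwaite df via delta method on the REML information.
    dfs = np.empty(p)
    if singular:
        dfs[:] = n - p
    else:
        step = np.maximum(theta * 1e-4, 1e-12)

        def cov_diag(th):
            a, _, _, _ = _reml_pieces(th, x, y, codes)
            return np.diag(np.linalg.inv(a))

        grads = np.empty((2, p))
        for k in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += step[k]
            tm[k] -= step[k]
            grads[k] = (cov_diag(tp) - cov_diag(tm)) / (2 * step[k])

        hess = np.empty((2, 2))
        f0 = _reml_neg2loglik(theta, x, y, codes)
        for i in range(2):
            for j in range(i, 2):
                ti = theta.copy()
                ti[i] += step[i]
                ti[j] += step[j]
                tj = theta.copy()
                tj[i] += step[i]
                tj[j] -= step[j]
                tk = theta.copy()
                tk[i] -= step[i]
                tk[j] += step[j]
                tl = theta.copy()
                tl[i] -= step[i]
                tl[j] -= step[j]
                hess[i, j] = hess[j, i] = (
                    _reml_neg2loglik(ti, x, y, codes)
                    - _reml_neg2loglik(tj, x, y, codes)
                    - _reml_neg2loglik(tk, x, y, codes)
                    + _reml_neg2loglik(tl, x, y, codes)
                ) / (4 * step[i] * step[j])
        del f0
        try:
            var_theta = 2.0 * np.linalg.inv(hess)
            for j in range(p):
                g = grads[:, j]
                denom = float(g @ var_theta @ g)
                fj = cov_beta[j, j]
                dfs[j] = 2.0 * fj**2 / denom if denom > 0 else n - p
        except np.linalg.LinAlgError:
            dfs[:] = n - p
    dfs = np.clip(dfs, 1.0, n - p)

    t_vals = beta / se_beta
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), dfs)
    effects = pd.DataFrame(
        {
            "Estimate": beta,
            "StdError": se_beta,
            "DF": dfs,
            "t": t_vals,
            "p": p_vals,
        },
        index=list(EFFECT_NAMES),
    )
    if singular:
        logger.warning("singular LME fit: random-intercept variance ~ 0")
    return LmeResult(
        effects=effects,
        sigma2=float(se2),
        tau2=float(sb2),
        converged=bool(res.success),
        singular=bool(singular),
        n_obs=n,
        n_participants=n_groups,
    )


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool
    mean_diff: float


def paired_t(values_a, values_b) -> PairedTResult:
    """Standard paired t on differences, df = n - 1.

    Zero-variance differences (e.g. identical vectors) make t undefined; the
    result is flagged degenerate rather than raising, since 'no measurable
    difference' is a meaningful outcome for boundary comparisons.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        return PairedTResult(
            t=np.nan, df=n - 1, p=np.nan, degenerate=True, mean_diff=float(d.mean())
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(
        t=float(t), df=n - 1, p=float(p), degenerate=False, mean_diff=float(d.mean())
    )


def behavioral_accuracy(trials: pd.DataFrame) -> dict:
    """Per-condition accuracy and the noisy-auditory visual-benefit test.

    ``trials`` holds one row per trial with ``participant``, ``condition``
    and 0/1 ``correct``.  Accuracy is proportion correct per condition; the
    paired comparison contrasts the two noisy-auditory conditions
    (visual-clear vs visual-blurred) across participants -- identical
    auditory input, different intelligibility.
    """
    req = {"participant", "condition", "correct"}
    if not req <= set(trials.columns):
        raise ValueError(f"trial table must have columns {sorted(req)}")
    by_cond = trials.groupby("condition")["correct"]
    if (by_cond.count() == 0).any():
        raise ValueError("empty condition cell")
    accuracy = by_cond.mean().to_dict()
    per_part = (
        trials.groupby(["participant", "condition"])["correct"].mean().unstack()
    )
    out = {"accuracy": accuracy}
    if len(per_part) >= 2 and {"AnoisyVclear", "AnoisyVblur"} <= set(per_part.columns):
        res = paired_t(per_part["AnoisyVclear"], per_part["AnoisyVblur"])
        out["visual_benefit"] = res
        if res.degenerate:
            out["conclusion"] = "no difference"
    return out
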