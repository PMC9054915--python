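"""Non-compartmental analysis and paired geometric-mean-ratio statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class PKSummary:
    """Per-profile exposure metrics (concentrations ng/mL, times h)."""

    auc_0_t: float                      # ng·h/mL, to the last positive sample
    auc_0_inf: Optional[float]          # with terminal-slope extrapolation
    auc_tau_ss: Optional[float]         # over the requested dosing interval
    cmax: float
    tmax: float
    cl_over_f: Optional[float]          # L/h
    lambda_z: Optional[float]           # 1/h
    extrapolated_fraction: Optional[float]
    n_lambda_points: int = 0


@dataclass
class GMRResult:
    geo_mean_ratio: float
    ci90_low: float
    ci90_high: float
    n: int


def _linuplogdown_auc(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-trapezoid on rising, log-trapezoid on falling segments."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if dt <= 0:
            continue
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def _terminal_slope(t: np.ndarray, c: np.ndarray):
    """λz by log-linear regression over the terminal run of ≥3 post-peak points
    maximizing adjusted R² (ties favour fewer points)."""
    i_max = int(np.argmax(c))
    cand_t, cand_c = t[i_max + 1 :], c[i_max + 1 :]
    pos = cand_c > 0
    cand_t, cand_c = cand_t[pos], cand_c[pos]
    m = len(cand_t)
    if m < 3:
        return None
    best = None
    for k in range(3, m + 1):
        tt = cand_t[m - k :]
        cc = np.log(cand_c[m - k :])
        slope, intercept, r, _, _ = stats.linregress(tt, cc)
        if slope >= 0:
            continue
        r2adj = 1.0 - (1.0 - r * r) * (k - 1) / (k - 2) if k > 2 else r * r
        # ties (within 1e-9) resolved toward fewer points: strict improvement
        if best is None or r2adj > best[0] + 1e-9:
            best = (r2adj, -slope, k)
    if best is None:
        return None
    return best[1], best[2]


def nca_single(
    time: Sequence[float],
    conc: Sequence[float],
    dose: float,
    tau: Optional[float] = None,
) -> PKSummary:
    """NCA of a single-dose (or steady-state interval) profile.

    ``time`` is measured from the dose; ``dose`` in mg; concentrations in
    ng/mL.  AUC uses the linear-up/log-down trapezoid; AUC0–∞ adds
    C_last/λz when a terminal slope is estimable, otherwise the
    extrapolation-dependent fields are ``None``.
    """
    t = np.asarray(time, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("time and concentration must be 1-D arrays of equal length")
    if np.sum(c > 0) < 3:
        raise ValueError("need at least 3 positive concentrations")

    auc_0_t = _linuplogdown_auc(t, c)
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])

    auc_tau = None
    if tau is not None:
        m = t <= tau + 1e-9
        auc_tau = _linuplogdown_auc(t[m], c[m])

    fit = _terminal_slope(t, c)
    if fit is None:
        return PKSummary(auc_0_t, None, auc_tau, cmax, tmax, None, None, None, 0)
    lambda_z, n_pts = fit
    pos = np.nonzero(c > 0)[0]
    c_last = float(c[pos[-1]])
    tail = c_last / lambda_z
    auc_inf = auc_0_t + tail
    cl_over_f = dose * 1000.0 / auc_inf if dose > 0 else None  # mg→µg over µg·h/L
    return PKSummary(
        auc_0_t=auc_0_t,
        auc_0_inf=auc_inf,
        auc_tau_ss=auc_tau,
        cmax=cmax,
        tmax=tmax,
        cl_over_f=cl_over_f,
        lambda_z=lambda_z,
        extrapolated_fraction=tail / auc_inf,
        n_lambda_points=n_pts,
    )


def renal_clearance(ae_mg: float, auc_0_inf_mg_h_per_l: float) -> float:
    """CL_R = Ae / AUC0–∞ (amount excreted unchanged over systemic exposure)."""
    if auc_0_inf_mg_h_per_l <= 0:
        raise ValueError("AUC must be positive")
    if ae_mg < 0:
        raise ValueError("Ae must be non-negative")
    return ae_mg / auc_0_inf_mg_h_per_l


def paired_gmr(
    metric_with: Sequence[float], metric_without: Sequence[float]
) -> GMRResult:
    """Geometric-mean ratio of paired metrics with a 90% t-based CI.

    The ratio of geometric means of paired values equals the geometric mean
    of within-subject ratios; the CI comes from the t distribution on the
    within-subject log differences.
    """
    w = np.asarray(metric_with, dtype=float)
    wo = np.asarray(metric_without, dtype=float)
    if w.shape != wo.shape or w.ndim != 1:
        raise ValueError("arms must be 1-D and of equal length")
    for arr, arm in ((w, "with"), (wo, "without")):
        bad = np.nonzero(~(arr > 0))[0]
        if bad.size:
            raise ValueError(f"non-positive value in '{arm}' arm at subject index {bad[0]}")
    d = np.log(w) - np.log(wo)
    n = d.size
    gmr = float(np.exp(d.mean()))
    if n < 2 or np.allclose(d, d[0]):
        return GMRResult(gmr, gmr, gmr, n)
    se = d.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.95, n - 1)
    return GMRResult(
        gmr, float(np.exp(d.mean() - tcrit * se)), float(np.exp(d.mean() + tcrit * se)), n
    )


def geometric_mean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.exp(np.mean(np.log(v))))


def geometric_cv(values: Sequence[float]) -> float:
    """Geometric CV (fraction): sqrt(exp(var(log x)) − 1); NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.sqrt(np.expm1(np.var(np.log(v), ddof=1))))
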