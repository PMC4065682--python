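"""Noncompartmental analysis (NCA) of single-dose concentration data.

Areas are computed by the linear trapezoidal rule over the measurable
(non-censored) samples up to the last quantifiable concentration; the
lin-up/log-down variant is available as an option.  The terminal slope
lambda_z comes from a log-linear regression whose point window is
chosen automatically by adjusted R-squared, excluding Cmax.

Two half-life conventions coexist and are reported side by side,
never mixed:

* terminal-slope based: hl = ln 2 / lambda_z (``hl_lambda_z``);
* moment based: Kel = 1/MRT and t1/2 = 0.693 * MRT
  (``kel_eq2``/``hl_eq2``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConcentrationTimeProfile, NCAResult

__all__ = [
    "auc_trapezoid",
    "aumc_trapezoid",
    "estimate_lambda_z",
    "nca_full",
    "LambdaZResult",
    "summarize_nca",
]

# windows whose adjusted R^2 is within this of the best are resolved in
# favor of MORE points (standard terminal-slope selection practice)
_ADJ_R2_TIE = 1e-4


def _usable(profile: ConcentrationTimeProfile) -> tuple[np.ndarray, np.ndarray]:
    m = profile.measurable
    return profile.times[m], profile.concentrations[m]


def _trapz(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def auc_trapezoid(
    profile: ConcentrationTimeProfile, method: str = "linear"
) -> float:
    """AUC(0 -> tlast) in hr*mg/L over the measurable samples.

    ``method="linear"`` is the plain trapezoid (default);
    ``method="linlog"`` uses the logarithmic trapezoid on strictly
    decreasing positive segments (lin-up/log-down).
    """
    t, c = _usable(profile)
    if t.size < 2:
        raise ValueError("need at least 2 measurable points for AUC")
    if method == "linear":
        return _trapz(t, c)
    if method != "linlog":
        raise ValueError(f"unknown trapezoid method: {method!r}")
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    return float(total)


def aumc_trapezoid(profile: ConcentrationTimeProfile) -> float:
    """Area under the first-moment curve t*C(t), linear trapezoid."""
    t, c = _usable(profile)
    if t.size < 2:
        raise ValueError("need at least 2 measurable points for AUMC")
    return _trapz(t, t * c)


@dataclass(frozen=True)
class LambdaZResult:
    lambda_z: float  # 1/hr (NaN when not estimable)
    half_life: float  # hr
    n_points: int
    r_squared: float
    adj_r_squared: float
    estimable: bool


def _loglin(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of ln C on t; returns slope, intercept, R^2."""
    y = np.log(c)
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum((y - slope * t - intercept) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return slope, float(intercept), r2


def estimate_lambda_z(profile: ConcentrationTimeProfile) -> LambdaZResult:
    """Terminal elimination rate constant by best-window log regression.

    Candidate windows are the suffixes (>= 3 points) of the positive,
    measurable samples strictly after Tmax; the window maximizing the
    adjusted R-squared wins, with near-ties going to the longer window.
    A nonpositive slope or fewer than 3 usable post-peak points makes
    lambda_z not estimable (extrapolation is then disabled).
    """
    t, c = _usable(profile)
    not_est = LambdaZResult(math.nan, math.nan, 0, math.nan, math.nan, False)
    if t.size < 3:
        return not_est
    imax = int(np.argmax(c))  # earliest maximum
    tt, cc = t[imax + 1 :], c[imax + 1 :]
    keep = cc > 0
    tt, cc = tt[keep], cc[keep]
    n = tt.size
    if n < 3:
        return not_est
    best = None
    for start in range(0, n - 2):
        wt, wc = tt[start:], cc[start:]
        slope, _, r2 = _loglin(wt, wc)
        if slope >= 0:
            continue
        k = wt.size
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[0] + _ADJ_R2_TIE:
            best = (adj, r2, slope, k)
    if best is None:
        return not_est
    adj, r2, slope, k = best
    lam = -slope
    return LambdaZResult(lam, math.log(2) / lam, k, r2, adj, True)


def nca_full(
    profile: ConcentrationTimeProfile,
    dosing_interval: float = 24.0,
    method: str = "linear",
) -> NCAResult:
    """Complete single-profile NCA.

    Cmax/Tmax come from the observed maximum (earliest time on ties);
    AUCinf adds the extrapolated tail C_last/lambda_z; Cl/F = Dose/AUCinf;
    Vz/F = Dose/(lambda_z * AUCinf); Css over the dosing interval is
    AUCinf / tau.  When lambda_z is not estimable every extrapolated
    quantity is NaN and the result is flagged.
    """
    t, c = _usable(profile)
    if t.size < 2:
        raise ValueError("need at least 2 measurable points")
    imax = int(np.argmax(c))
    tmax, cmax = float(t[imax]), float(c[imax])
    auc_last = auc_trapezoid(profile, method=method)
    if auc_last <= 0:
        raise ValueError("AUC(0-tlast) must be positive")
    aumc_last = aumc_trapezoid(profile)
    mrt_last = aumc_last / auc_last
    lz = estimate_lambda_z(profile)
    # last measurable (positive) concentration for tail extrapolation
    pos = c > 0
    c_last = float(c[pos][-1]) if pos.any() else 0.0
    if lz.estimable:
        auc_inf = auc_last + c_last / lz.lambda_z
        cl_f = profile.dose / auc_inf
        vz_f = profile.dose / (lz.lambda_z * auc_inf)
        css = auc_inf / dosing_interval
    else:
        auc_inf = cl_f = vz_f = css = math.nan
    return NCAResult(
        subject_id=profile.subject_id,
        dose=profile.dose,
        tmax=tmax,
        cmax=cmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        aumc_last=aumc_last,
        mrt_last=mrt_last,
        lambda_z=lz.lambda_z,
        hl_lambda_z=lz.half_life,
        vz_f=vz_f,
        cl_f=cl_f,
        kel_eq2=1.0 / mrt_last,
        hl_eq2=math.log(2) * mrt_last,
        css_24h=css,
        n_lambda_points=lz.n_points,
        lambda_r2=lz.r_squared,
        lambda_estimable=lz.estimable,
        product_id=profile.product_id,
    )


_SUMMARY_PARAMS = [
    "tmax", "cmax", "auc_last", "lambda_z", "hl_lambda_z", "auc_inf",
    "vz_f", "cl_f", "aumc_last", "mrt_last",
]


def summarize_nca(results: list[NCAResult]) -> pd.DataFrame:
    """Mean +/- SD block over subjects (one column pair per parameter)."""
    df = pd.DataFrame([r.to_dict() for r in results])
    out = {}
    for p in _SUMMARY_PARAMS:
        out[p] = {"mean": df[p].mean(), "sd": df[p].std(ddof=1), "n": df[p].count()}
    return pd.DataFrame(out).T
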