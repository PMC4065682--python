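"""Compartmental model fitting for single-dose concentration profiles.

Fitting proceeds in two stages, mirroring classical practice:

1. *Curve stripping* (method of residuals): a log-linear fit of the
   terminal phase gives (B, beta); the positive residuals of the
   earlier post-peak points give (A, alpha).  This supplies starting
   values only.
2. *Nonlinear least squares* on the full curve with all rate constants
   log-parameterized (positivity enforced by construction).

Four model variants are supported: two-compartment disposition with
first-order oral absorption (default, 5 parameters), iv-bolus
biexponential (4), one-compartment oral (Bateman, 3) and iv-bolus
monoexponential (2).  ``select_model`` ranks variants by AICc computed
from the residual sum of squares with k = number of structural
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .datatypes import ConcentrationTimeProfile, TwoCompartmentFit
from .models import (
    DegenerateModelError,
    biexponential,
    disposition_rates,
    monoexponential,
    oral_one_compartment,
    oral_two_compartment,
    oral_two_compartment_macro,
)

__all__ = [
    "strip_residuals",
    "fit_compartment_model",
    "derive_microconstants",
    "predict_tmax_cmax",
    "predict_conc",
    "select_model",
    "StrippingInit",
    "MicroConstants",
    "ModelFit",
    "aicc",
]

_VARIANT_NPARAMS = {
    "oral_first_order": 5,
    "iv_biexponential": 4,
    "oral_one_compartment": 3,
    "iv_monoexponential": 2,
}

# relative-SSE convergence tolerance and iteration cap of the optimizer
_FTOL = 1e-10
_MAX_ITER = 500


class InconsistentFitError(ValueError):
    """Macro constants imply a negative distribution rate constant."""


@dataclass(frozen=True)
class StrippingInit:
    A: float
    B: float
    alpha: float
    beta: float
    fallback: bool  # residual stage degenerated to one-compartment init


@dataclass(frozen=True)
class MicroConstants:
    k21: float
    k10: float
    k12: float
    v1_f: Optional[float] = None


@dataclass(frozen=True)
class ModelFit:
    """Generic fit record used for model ranking."""

    variant: str
    params: dict
    sse: float
    n_obs: int
    n_params: int
    converged: bool


def aicc(sse: float, n_obs: int, n_params: int) -> float:
    """Small-sample-corrected Akaike criterion from a residual SSE."""
    if n_obs <= n_params + 1:
        return math.inf
    if sse <= 0:
        sse = 1e-300
    return (
        n_obs * math.log(sse / n_obs)
        + 2 * n_params
        + 2 * n_params * (n_params + 1) / (n_obs - n_params - 1)
    )


# ---------------------------------------------------------------------------
# curve stripping


def _loglin(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    y = np.log(c)
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 - float(np.sum((y - slope * t - intercept) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return slope, float(intercept), r2


def strip_residuals(profile: ConcentrationTimeProfile) -> StrippingInit:
    """Feathering initialization (A, B, alpha, beta) with alpha > beta.

    The terminal window (>= 3 points) is chosen by adjusted R-squared
    among suffixes of the post-peak samples; residuals of the earlier
    post-peak points against the fitted beta phase give the alpha
    phase.  If fewer than two positive residuals remain (monoexponential
    data), a flagged one-compartment-style initialization is returned.
    """
    m = profile.measurable & (profile.concentrations > 0)
    t, c = profile.times[m], profile.concentrations[m]
    if t.size < 3:
        raise ValueError("need at least 3 positive measurable points")
    imax = int(np.argmax(c))
    tt, cc = t[imax + 1 :], c[imax + 1 :]
    if tt.size < 3:
        raise ValueError("need at least 3 post-peak points for stripping")
    best = None
    for start in range(0, tt.size - 2):
        slope, intercept, r2 = _loglin(tt[start:], cc[start:])
        if slope >= 0:
            continue
        k = tt.size - start
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        # strict best (longest window on exact ties): a window reaching
        # into the fast phase would bias beta and poison the residuals
        if best is None or adj > best[0]:
            best = (adj, start, slope, intercept)
    if best is None:
        raise ValueError("no decaying terminal phase found")
    _, start, slope, intercept = best
    beta = -slope
    B = math.exp(intercept)
    te, ce = tt[:start], cc[:start]
    resid = ce - B * np.exp(-beta * te)
    pos = resid > 0
    if int(pos.sum()) >= 2:
        a_slope, a_int, _ = _loglin(te[pos], resid[pos])
        if a_slope < 0 and -a_slope > beta:
            return StrippingInit(math.exp(a_int), B, -a_slope, beta, False)
    # monoexponential-looking data: nominal fast phase, flagged
    return StrippingInit(0.1 * B, B, 5.0 * beta, beta, True)


# ---------------------------------------------------------------------------
# micro <-> macro identities


def derive_microconstants(
    A: float,
    B: float,
    alpha: float,
    beta: float,
    dose: Optional[float] = None,
    tol: float = 1e-8,
) -> MicroConstants:
    """Micro rate constants from iv-bolus macro constants.

    k21 = (A*beta + B*alpha)/(A + B);  k10 = alpha*beta/k21;
    k12 = alpha + beta - k21 - k10.  V1/F = dose/(A + B) when a dose is
    given.  Macro constants implying k12 < 0 beyond tolerance raise
    ``InconsistentFitError``.
    """
    if A < 0 or B < 0 or A + B <= 0:
        raise ValueError("need A, B >= 0 with A + B > 0")
    if not (alpha > beta > 0):
        raise ValueError("need alpha > beta > 0")
    k21 = (A * beta + B * alpha) / (A + B)
    k10 = alpha * beta / k21
    k12 = alpha + beta - k21 - k10
    if k12 < -tol * (alpha + beta):
        raise InconsistentFitError(
            f"macro constants imply k12 = {k12:.3g} < 0"
        )
    k12 = max(k12, 0.0)
    v1 = dose / (A + B) if dose is not None else None
    return MicroConstants(k21=float(k21), k10=float(k10), k12=float(k12), v1_f=v1)


# ---------------------------------------------------------------------------
# nonlinear fitting


def _fit_data(
    profile: ConcentrationTimeProfile, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    m = profile.measurable
    t, c = profile.times[m], profile.concentrations[m]
    if variant.startswith("iv_"):
        # an observed zero at t=0 contradicts the iv-bolus model form
        keep = t > 0
        t, c = t[keep], c[keep]
    return t, c


def _curve(variant: str, theta: np.ndarray, t: np.ndarray, dose: float):
    p = np.exp(theta)
    try:
        if variant == "oral_first_order":
            ka, v1, k10, k12, k21 = p
            return oral_two_compartment(t, ka, v1, k10, k12, k21, dose)
        if variant == "iv_biexponential":
            A, B, beta, dab = p
            return biexponential(t, A, B, beta + dab, beta)
        if variant == "oral_one_compartment":
            ka, v, ke = p
            return oral_one_compartment(t, ka, v, ke, dose)
        if variant == "iv_monoexponential":
            c0, ke = p
            return monoexponential(t, c0, ke)
    except DegenerateModelError:
        return None
    raise ValueError(f"unknown variant: {variant!r}")


def _weights(c_obs: np.ndarray, weighting: str, floor: float) -> np.ndarray:
    if weighting == "uniform":
        return np.ones_like(c_obs)
    cc = np.maximum(c_obs, floor)
    if weighting == "inv_c":
        return 1.0 / np.sqrt(cc)
    if weighting == "inv_c2":
        return 1.0 / cc
    raise ValueError(f"unknown weighting: {weighting!r}")


def _initial_theta(
    profile: ConcentrationTimeProfile, variant: str, t: np.ndarray, c: np.ndarray
) -> np.ndarray:
    imax = int(np.argmax(c))
    tmax_obs = max(float(t[imax]), float(np.min(t[t > 0], initial=0.25)))
    if variant in ("oral_first_order", "iv_biexponential"):
        init = strip_residuals(profile)
        A, B, alpha, beta = init.A, init.B, init.alpha, init.beta
        if variant == "iv_biexponential":
            return np.log([A, B, beta, alpha - beta])
        try:
            micro = derive_microconstants(A, B, alpha, beta)
            k21, k10, k12 = micro.k21, micro.k10, max(micro.k12, 1e-3)
        except (InconsistentFitError, ValueError):
            k21, k10, k12 = beta * 2, alpha / 2, 0.1
        ka0 = max(2.0 * alpha, 2.0 / tmax_obs)
        v10 = profile.dose / (A + B)
        return np.log([ka0, v10, k10, k12, k21])
    # one-compartment inits from the terminal slope and trapezoid area
    slope, intercept, _ = _loglin(t[c > 0], c[c > 0])
    ke0 = max(-slope, 1e-3)
    if variant == "iv_monoexponential":
        return np.log([math.exp(intercept), ke0])
    auc = float(np.trapezoid(c, t))
    v0 = profile.dose / max(ke0 * auc, 1e-6)
    ka0 = max(3.0 * ke0, 2.0 / tmax_obs)
    return np.log([ka0, v0, ke0])


def _fit_variant(
    profile: ConcentrationTimeProfile,
    variant: str,
    weighting: str = "uniform",
) -> ModelFit:
    if variant not in _VARIANT_NPARAMS:
        raise ValueError(f"unknown variant: {variant!r}")
    t, c = _fit_data(profile, variant)
    n_par = _VARIANT_NPARAMS[variant]
    min_pts = 6 if variant == "oral_first_order" else max(n_par, 4) if variant == "iv_biexponential" else n_par + 1
    if t.size < min_pts:
        raise ValueError(
            f"{variant} needs at least {min_pts} usable points, got {t.size}"
        )
    floor = max(profile.loq, 1e-3 * float(np.max(c)))
    w = _weights(c, weighting, floor)
    theta0 = _initial_theta(profile, variant, t, c)

    def resid(theta: np.ndarray) -> np.ndarray:
        pred = _curve(variant, theta, t, profile.dose)
        if pred is None or not np.all(np.isfinite(pred)):
            return np.full(t.size, 1e6)
        return w * (pred - c)

    sse0 = float(np.sum(resid(theta0) ** 2))
    try:
        sol = least_squares(
            resid,
            theta0,
            method="trf",
            ftol=_FTOL,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=_MAX_ITER * (n_par + 1),
        )
        sse = float(np.sum(sol.fun**2))
        if sse <= sse0:
            theta, converged = sol.x, bool(sol.success)
        else:  # pragma: no cover - optimizer never worsens in practice
            theta, sse, converged = theta0, sse0, False
    except Exception:
        theta, sse, converged = theta0, sse0, False
    p = np.exp(theta)
    names = {
        "oral_first_order": ["ka", "v1_f", "k10", "k12", "k21"],
        "iv_biexponential": ["A", "B", "beta", "alpha_minus_beta"],
        "oral_one_compartment": ["ka", "v_f", "ke"],
        "iv_monoexponential": ["c0", "ke"],
    }[variant]
    return ModelFit(
        variant=variant,
        params=dict(zip(names, p.tolist())),
        sse=sse,
        n_obs=int(t.size),
        n_params=n_par,
        converged=converged,
    )


def fit_compartment_model(
    profile: ConcentrationTimeProfile,
    variant: str = "oral_first_order",
    weighting: str = "uniform",
) -> TwoCompartmentFit:
    """Fit a two-compartment open model and derive all summary constants.

    ``variant="oral_first_order"`` (default) fits (ka, V1/F, k10, k12,
    k21); ``variant="iv_biexponential"`` fits the macro constants
    (A, B, alpha, beta) directly.  Non-convergence is flagged in the
    result, which then retains the stripping-initialization values.
    """
    if variant not in ("oral_first_order", "iv_biexponential"):
        raise ValueError(
            "fit_compartment_model supports the two-compartment variants; "
            "use select_model for one-compartment candidates"
        )
    mf = _fit_variant(profile, variant, weighting)
    if variant == "oral_first_order":
        ka = mf.params["ka"]
        v1 = mf.params["v1_f"]
        k10, k12, k21 = mf.params["k10"], mf.params["k12"], mf.params["k21"]
        alpha, beta = disposition_rates(k10, k12, k21)
        A, B, _ = oral_two_compartment_macro(
            ka, v1, k10, k12, k21, profile.dose
        )
        auc = profile.dose / (k10 * v1)
    else:
        A, B = mf.params["A"], mf.params["B"]
        beta = mf.params["beta"]
        alpha = beta + mf.params["alpha_minus_beta"]
        micro = derive_microconstants(A, B, alpha, beta, dose=profile.dose)
        k21, k10, k12 = micro.k21, micro.k10, micro.k12
        v1 = micro.v1_f
        ka = math.nan
        auc = A / alpha + B / beta
    fit = TwoCompartmentFit(
        subject_id=profile.subject_id,
        variant=variant,
        A=A,
        B=B,
        alpha=alpha,
        beta=beta,
        ka=ka,
        k12=k12,
        k21=k21,
        k10=k10,
        v1_f=v1,
        v2_f=v1 * k12 / k21,
        cl_f=k10 * v1,
        alpha_hl=math.log(2) / alpha,
        beta_hl=math.log(2) / beta,
        auc_model=auc,
        tmax_pred=math.nan,
        cmax_pred=math.nan,
        sse=mf.sse,
        converged=mf.converged,
        n_obs=mf.n_obs,
        product_id=profile.product_id,
    )
    tmax, cmax = predict_tmax_cmax(fit)
    return TwoCompartmentFit(
        **{**fit.to_dict(), "tmax_pred": tmax, "cmax_pred": cmax}
    )


def predict_conc(fit: TwoCompartmentFit, t) -> np.ndarray:
    """Model curve of a fit at arbitrary times (hr)."""
    t = np.asarray(t, dtype=float)
    c = biexponential(t, fit.A, fit.B, fit.alpha, fit.beta)
    if fit.variant == "oral_first_order":
        # coefficients of the three-exponential oral curve sum to zero
        c = c - (fit.A + fit.B) * np.exp(-fit.ka * t)
    return np.maximum(c, 0.0)


def predict_tmax_cmax(fit: TwoCompartmentFit) -> tuple[float, float]:
    """Model-predicted time and height of the concentration peak.

    The iv-bolus curve decays monotonically, so its peak is (0, A+B);
    the oral curve is maximized numerically on (0, 5 beta half-lives].
    """
    if fit.variant != "oral_first_order" or not math.isfinite(fit.ka):
        return 0.0, fit.A + fit.B
    upper = 5.0 * fit.beta_hl
    sol = minimize_scalar(
        lambda x: -float(predict_conc(fit, x)),
        bounds=(1e-9, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(sol.x), float(-sol.fun)


def select_model(
    profile: ConcentrationTimeProfile,
    candidates: Sequence[str] = ("oral_one_compartment", "oral_first_order"),
    weighting: str = "uniform",
) -> pd.DataFrame:
    """Rank candidate model variants by AICc (best first).

    Returns a table with sse, n_params, aicc and delta_aicc per
    variant; ties in SSE resolve toward fewer parameters through the
    AICc penalty.  Raises if every candidate fails to fit.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate variants")
    rows = []
    for variant in candidates:
        try:
            mf = _fit_variant(profile, variant, weighting)
        except Exception:
            continue
        rows.append(
            {
                "variant": mf.variant,
                "n_params": mf.n_params,
                "sse": mf.sse,
                "aicc": aicc(mf.sse, mf.n_obs, mf.n_params),
                "converged": mf.converged,
            }
        )
    if not rows:
        raise RuntimeError("all candidate model fits failed")
    df = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    return df
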