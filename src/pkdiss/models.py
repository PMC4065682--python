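"""Closed-form concentration-time curves for mammillary compartment models.

The two-compartment open model has central (1) and peripheral (2)
compartments with first-order micro rate constants k10 (elimination),
k12 and k21 (distribution).  Its disposition eigenvalues alpha > beta
are the roots of

    s**2 - (k10 + k12 + k21) * s + k10 * k21 = 0.

With first-order oral absorption (rate ka, apparent central volume
V1/F) the plasma concentration is a three-exponential curve that starts
at zero, peaks, and decays with terminal slope beta.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "disposition_rates",
    "macro_from_micro",
    "biexponential",
    "monoexponential",
    "oral_one_compartment",
    "oral_two_compartment",
]


class DegenerateModelError(ValueError):
    """Raised when parameters make the closed-form curve singular."""


def disposition_rates(k10: float, k12: float, k21: float) -> tuple[float, float]:
    """Hybrid (macro) rate constants alpha > beta from micro constants."""
    if min(k10, k12, k21) < 0 or k10 <= 0 or k21 <= 0:
        raise ValueError("rate constants must be positive (k12 >= 0)")
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    # disc >= (k10 - k21)^2 >= 0 algebraically; clamp rounding noise
    root = np.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return float(alpha), float(beta)


def macro_from_micro(
    k10: float, k12: float, k21: float, c0: float = 1.0
) -> tuple[float, float, float, float]:
    """IV-bolus macro constants (A, B, alpha, beta) for initial concentration c0.

    A + B = c0; the split depends on how far k21 sits between beta and alpha.
    """
    alpha, beta = disposition_rates(k10, k12, k21)
    if alpha == beta:
        raise DegenerateModelError("alpha == beta: macro split undefined")
    A = c0 * (alpha - k21) / (alpha - beta)
    B = c0 * (k21 - beta) / (alpha - beta)
    return float(A), float(B), alpha, beta


def biexponential(t, A: float, B: float, alpha: float, beta: float):
    """C(t) = A*exp(-alpha*t) + B*exp(-beta*t)."""
    t = np.asarray(t, dtype=float)
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


def monoexponential(t, c0: float, ke: float):
    t = np.asarray(t, dtype=float)
    return c0 * np.exp(-ke * t)


def oral_one_compartment(t, ka: float, v_f: float, ke: float, dose: float):
    """Bateman curve for first-order absorption into one compartment."""
    t = np.asarray(t, dtype=float)
    if abs(ka - ke) <= 1e-10 * max(ka, ke):
        raise DegenerateModelError("ka == ke: Bateman curve degenerate")
    coef = dose * ka / (v_f * (ka - ke))
    return coef * (np.exp(-ke * t) - np.exp(-ka * t))


def oral_two_compartment(
    t,
    ka: float,
    v1_f: float,
    k10: float,
    k12: float,
    k21: float,
    dose: float,
    rtol: float = 1e-8,
):
    """First-order absorption into a two-compartment open model.

    C(t) = (ka*Dose/V1) * [ (k21-a)/((ka-a)(b-a)) e^{-a t}
                          + (k21-b)/((ka-b)(a-b)) e^{-b t}
                          + (k21-ka)/((a-ka)(b-ka)) e^{-ka t} ]

    with a = alpha, b = beta.  C(0) = 0 exactly (the three coefficients
    sum to zero); tiny negative round-off is clipped to zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    alpha, beta = disposition_rates(k10, k12, k21)
    scale = max(alpha, beta, ka)
    if abs(ka - alpha) <= rtol * scale or abs(ka - beta) <= rtol * scale:
        raise DegenerateModelError(
            "ka coincides with a disposition rate; the three-exponential "
            "form is singular"
        )
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    pref = ka * dose / v1_f
    c = pref * (
        ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + ck * np.exp(-ka * t)
    )
    # the coefficients sum to zero analytically; make C(0) = 0 exact
    c = np.where(t == 0.0, 0.0, c)
    return np.maximum(c, 0.0)


def oral_two_compartment_macro(
    ka: float, v1_f: float, k10: float, k12: float, k21: float, dose: float
) -> tuple[float, float, float]:
    """Coefficients (A, B, C_ka) of the alpha-, beta- and ka-phase terms."""
    alpha, beta = disposition_rates(k10, k12, k21)
    pref = ka * dose / v1_f
    A = pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    B = pref * (k21 - beta) / ((ka - beta) * (alpha - beta))
    Cka = pref * (k21 - ka) / ((alpha - ka) * (beta - ka))
    return float(A), float(B), float(Cka)
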