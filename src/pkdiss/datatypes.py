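"""Core data containers shared across the dissolution and PK modules.

Units are fixed study-wide and never inferred: minutes for dissolution
time, hours for plasma sampling time, mg/L for plasma concentration,
mg for dose, L for volumes, 1/hr for rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "DissolutionProfile",
    "ConcentrationTimeProfile",
    "NCAResult",
    "TwoCompartmentFit",
]


def _float_array(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_strictly_increasing(t: np.ndarray, name: str) -> None:
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class DissolutionProfile:
    """One product's in-vitro release curve.

    Parameters
    ----------
    product_id : str
        Brand/formulation label.
    times : array-like
        Sampling times in minutes, strictly increasing, >= 0.
    values : array-like
        Mean percent of label claim dissolved at each time, in [0, 110].
    n_units : int
        Number of dosage units (tablets) averaged per point.
    """

    product_id: str
    times: np.ndarray
    values: np.ndarray
    n_units: int = 6

    def __post_init__(self) -> None:
        t = _float_array(self.times, "times")
        v = _float_array(self.values, "values")
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size == 0:
            raise ValueError("profile must contain at least one point")
        if t[0] < 0:
            raise ValueError("times must be nonnegative")
        _check_strictly_increasing(t, "times")
        if np.any(v < 0) or np.any(v > 110):
            raise ValueError("dissolution values must lie in [0, 110] % label")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """A single subject's plasma concentration-time series.

    Censored points are below the assay's limit of quantification (LOQ);
    their stored concentration value carries no information (the flag
    does).  The pre-dose sample at t = 0 is an exact zero, not censored.
    """

    subject_id: str
    times: np.ndarray  # hr
    concentrations: np.ndarray  # mg/L
    dose: float  # mg
    censored: Optional[np.ndarray] = None
    loq: float = 0.0  # mg/L
    product_id: str = ""

    def __post_init__(self) -> None:
        t = _float_array(self.times, "times")
        c = _float_array(self.concentrations, "concentrations")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if t.size == 0:
            raise ValueError("profile must contain at least one sample")
        if t[0] < 0:
            raise ValueError("first sampling time must be >= 0")
        _check_strictly_increasing(t, "times")
        if self.censored is None:
            cen = np.zeros(t.size, dtype=bool)
        else:
            cen = np.atleast_1d(np.asarray(self.censored, dtype=bool))
            if cen.size != t.size:
                raise ValueError("censored mask must match times in length")
        if np.any(c[~cen] < 0):
            raise ValueError("non-censored concentrations must be >= 0")
        if not self.dose > 0:
            raise ValueError("dose must be positive")
        if self.loq < 0:
            raise ValueError("loq must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "censored", cen)

    @property
    def measurable(self) -> np.ndarray:
        """Boolean mask of points usable for analysis (not censored)."""
        return ~self.censored

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental analysis summary for one subject.

    ``kel_eq2``/``hl_eq2`` are the moment-based variants (1/MRT and
    0.693*MRT); they are reported separately from the terminal-slope
    quantities ``lambda_z``/``hl_lambda_z`` and the two are never mixed.
    """

    subject_id: str
    dose: float  # mg
    tmax: float  # hr
    cmax: float  # mg/L
    auc_last: float  # hr*mg/L
    auc_inf: float  # hr*mg/L
    aumc_last: float  # hr^2*mg/L
    mrt_last: float  # hr
    lambda_z: float  # 1/hr
    hl_lambda_z: float  # hr
    vz_f: float  # L
    cl_f: float  # L/hr
    kel_eq2: float  # 1/hr
    hl_eq2: float  # hr
    css_24h: float  # mg/L
    n_lambda_points: int
    lambda_r2: float
    lambda_estimable: bool = True
    product_id: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class TwoCompartmentFit:
    """Fitted two-compartment open model for one subject.

    Macro constants A, B are the coefficients of the alpha- and
    beta-phase exponentials; ``ka`` is NaN for the iv-bolus variant.
    Micro constants satisfy alpha*beta = k10*k21 and
    alpha + beta = k10 + k12 + k21 by construction.
    """

    subject_id: str
    variant: str
    A: float  # mg/L
    B: float  # mg/L
    alpha: float  # 1/hr
    beta: float  # 1/hr
    ka: float  # 1/hr (NaN when absent)
    k12: float  # 1/hr
    k21: float  # 1/hr
    k10: float  # 1/hr
    v1_f: float  # L
    v2_f: float  # L
    cl_f: float  # L/hr
    alpha_hl: float  # hr
    beta_hl: float  # hr
    auc_model: float  # hr*mg/L
    tmax_pred: float  # hr
    cmax_pred: float  # mg/L
    sse: float  # (mg/L)^2
    converged: bool
    n_obs: int = 0
    product_id: str = ""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
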