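"""Synthetic dissolution curves and plasma PK studies with known truth.

The simulator emulates a six-brand single-dose crossover-free design in
rabbits: n = 6 animals per brand, a 500 mg oral dose, plasma sampled
pre-dose and at 0.25, 0.5, 1, 1.5, 2, 4, 8, 12 and 24 hr, and an assay
LOQ of 0.05 mg/L.  Disposition is two-compartment with first-order oral
absorption; dissolution curves follow a Weibull release model.

Ground truth is always known, so every downstream stage (dissolution
comparison, NCA, compartmental fitting, brand statistics) can be tested
for parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import ConcentrationTimeProfile, DissolutionProfile
from .models import disposition_rates, oral_two_compartment

__all__ = [
    "ReleaseModelParams",
    "PKTruth",
    "StudyDesign",
    "weibull_release",
    "conc_two_compartment_oral",
    "simulate_study",
    "rabbit_cipro_pk_truth",
    "rabbit_cipro_design",
    "rabbit_cipro_release_params",
    "DEFAULT_SAMPLE_TIMES_HR",
    "DEFAULT_DISSOLUTION_TIMES_MIN",
]

# in-vivo sampling grid (hr): pre-dose plus nine post-dose draws
DEFAULT_SAMPLE_TIMES_HR: tuple[float, ...] = (
    0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 8.0, 12.0, 24.0,
)
# in-vitro paddle-method sampling grid (min) over one hour
DEFAULT_DISSOLUTION_TIMES_MIN: tuple[float, ...] = (5, 10, 15, 20, 30, 45, 60)


@dataclass(frozen=True)
class ReleaseModelParams:
    """Weibull release model: f(t) = f_max * (1 - exp(-(t/td)**b)).

    td is the time scale at which 63.2 % of f_max has dissolved; b
    shapes the curve (b = 1 is first-order release).  noise_sd adds
    zero-mean Gaussian measurement noise in % label units.
    """

    f_max: float  # % label, asymptotic release
    td: float  # minutes
    b: float = 1.0
    noise_sd: float = 0.0  # % label

    def __post_init__(self) -> None:
        if not (0 < self.f_max <= 110):
            raise ValueError("f_max must be in (0, 110]")
        if self.td <= 0 or self.b <= 0:
            raise ValueError("td and b must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PKTruth:
    """Generative PK parameters for one brand.

    Between-subject variability is log-normal (median-preserving) on
    ka, V1/F and k10 only; k12 and k21 are fixed across subjects.
    Residual error is proportional with coefficient ``residual_cv``.
    """

    ka: float  # 1/hr
    v1_f: float  # L
    k10: float  # 1/hr
    k12: float  # 1/hr
    k21: float  # 1/hr
    dose: float  # mg
    between_subject_cv: float = 0.0
    residual_cv: float = 0.0
    loq: float = 0.0  # mg/L

    def __post_init__(self) -> None:
        for name in ("ka", "v1_f", "k10", "k12", "k21", "dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("between_subject_cv", "residual_cv"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.loq < 0:
            raise ValueError("loq must be >= 0")

    @property
    def alpha(self) -> float:
        return disposition_rates(self.k10, self.k12, self.k21)[0]

    @property
    def beta(self) -> float:
        return disposition_rates(self.k10, self.k12, self.k21)[1]

    @property
    def cl_f(self) -> float:
        """Apparent clearance Cl/F = k10 * V1/F (L/hr)."""
        return self.k10 * self.v1_f


@dataclass(frozen=True)
class StudyDesign:
    n_subjects: int
    sample_times: Sequence[float] = DEFAULT_SAMPLE_TIMES_HR  # hr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or t[0] < 0 or not np.all(np.diff(t) > 0):
            raise ValueError("sample_times must be strictly increasing and >= 0")
        object.__setattr__(self, "sample_times", tuple(float(x) for x in t))


def weibull_release(
    params: ReleaseModelParams,
    times: Sequence[float],
    seed: Optional[int] = None,
    product_id: str = "synthetic",
) -> DissolutionProfile:
    """Generate a dissolution profile from the Weibull release model.

    With ``noise_sd = 0`` the exact (monotone) model curve is returned;
    otherwise zero-mean Gaussian noise is added and the result clipped
    to the physical range [0, 110] % label.  Identical seeds give
    identical output.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(t < 0) or not np.all(np.diff(t) > 0):
        raise ValueError("times must be nonnegative and strictly increasing")
    mean = params.f_max * (1.0 - np.exp(-np.power(t / params.td, params.b)))
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        mean = mean + rng.normal(0.0, params.noise_sd, size=t.size)
    values = np.clip(mean, 0.0, 110.0)
    return DissolutionProfile(product_id=product_id, times=t, values=values)


def conc_two_compartment_oral(pk: PKTruth, t) -> np.ndarray:
    """Noise-free plasma concentration (mg/L) at time(s) t (hr)."""
    return oral_two_compartment(
        t, pk.ka, pk.v1_f, pk.k10, pk.k12, pk.k21, pk.dose
    )


def simulate_study(
    pk: PKTruth, design: StudyDesign, product_id: str = ""
) -> list[ConcentrationTimeProfile]:
    """Simulate one brand's study arm: ``design.n_subjects`` profiles.

    Per subject, ka, V1/F and k10 are perturbed log-normally with CV
    ``pk.between_subject_cv`` (median preserved), the noise-free curve
    is evaluated on the design grid, proportional residual noise with
    CV ``pk.residual_cv`` is applied, and post-dose values below
    ``pk.loq`` are marked censored (stored value 0).  A t = 0 sample is
    an exact, uncensored zero.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.sample_times, dtype=float)
    sigma = float(np.sqrt(np.log1p(pk.between_subject_cv**2)))
    profiles: list[ConcentrationTimeProfile] = []
    for i in range(design.n_subjects):
        if sigma > 0:
            eta = rng.normal(0.0, sigma, size=3)
        else:
            eta = np.zeros(3)
        subj = replace(
            pk,
            ka=pk.ka * float(np.exp(eta[0])),
            v1_f=pk.v1_f * float(np.exp(eta[1])),
            k10=pk.k10 * float(np.exp(eta[2])),
        )
        c = conc_two_compartment_oral(subj, t)
        if pk.residual_cv > 0:
            eps = rng.normal(0.0, pk.residual_cv, size=t.size)
            c = np.maximum(c * (1.0 + eps), 0.0)
        pre_dose = t == 0.0
        c = np.where(pre_dose, 0.0, c)
        censored = (c < pk.loq) & ~pre_dose
        c = np.where(censored, 0.0, c)
        sid = f"{product_id or 'S'}-{i + 1:02d}"
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=sid,
                times=t,
                concentrations=c,
                dose=pk.dose,
                censored=censored,
                loq=pk.loq,
                product_id=product_id,
            )
        )
    return profiles


def rabbit_cipro_pk_truth(
    dose: float = 500.0,
    between_subject_cv: float = 0.03,
    residual_cv: float = 0.05,
) -> PKTruth:
    """Reference-brand PK truth for the rabbit ciprofloxacin preset.

    Micro constants reproduce the reported reference disposition
    (alpha = 2.22/hr, beta = 0.16/hr, Cl/F = 8.0 L/hr, AUCinf = 62.5
    hr*mg/L); ka = 3.5/hr puts Tmax at 0.59 hr and Cmax at 10.5 mg/L,
    inside the observed ranges.  The 3 % between-subject CV matches the
    few-percent spread of the published brand summaries.
    """
    return PKTruth(
        ka=3.5,
        v1_f=30.41,
        k10=0.263,
        k12=0.77,
        k21=1.35,
        dose=dose,
        between_subject_cv=between_subject_cv,
        residual_cv=residual_cv,
        loq=0.05,
    )


def rabbit_cipro_design(seed: int = 0, n_subjects: int = 6) -> StudyDesign:
    """Six animals per brand on the standard 0-24 hr sampling grid."""
    return StudyDesign(
        n_subjects=n_subjects, sample_times=DEFAULT_SAMPLE_TIMES_HR, seed=seed
    )


def rabbit_cipro_release_params(noise_sd: float = 0.8) -> dict[str, ReleaseModelParams]:
    """Weibull release parameters for six look-alike brands.

    Chosen so brands B, C, E track the reference F closely (similar by
    the f1/f2 criteria) while A and D release more slowly (A below 85 %
    at 15 min, both dissimilar to F), mirroring the published
    qualitative pattern.
    """
    return {
        "A": ReleaseModelParams(f_max=96.0, td=8.5, b=1.30, noise_sd=noise_sd),
        "B": ReleaseModelParams(f_max=99.0, td=5.8, b=1.25, noise_sd=noise_sd),
        "C": ReleaseModelParams(f_max=98.5, td=5.2, b=1.35, noise_sd=noise_sd),
        "D": ReleaseModelParams(f_max=97.0, td=7.7, b=1.30, noise_sd=noise_sd),
        "E": ReleaseModelParams(f_max=99.5, td=5.5, b=1.30, noise_sd=noise_sd),
        "F": ReleaseModelParams(f_max=99.0, td=5.0, b=1.30, noise_sd=noise_sd),
    }
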