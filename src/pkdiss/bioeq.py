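"""Brand-level aggregation, relative bioavailability and cross-brand
comparison statistics.

Relative bioavailability of a test brand against the reference is the
dose-corrected AUC ratio in percent:

    Fr = 100 * (AUC_T * D_R) / (AUC_R * D_T)

Brands are compared parameter-by-parameter with a one-way ANOVA
followed by Tukey's A (studentized range, equal group sizes) pairwise
test.  A brand is flagged interchangeable with the reference when its
Fr is at least 90 %.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NCAResult

__all__ = [
    "relative_bioavailability",
    "one_way_anova",
    "tukey_hsd",
    "run_bioeq_study",
    "AnovaResult",
    "TukeyPair",
    "StudyResult",
    "INTERCHANGEABLE_FR_MIN",
]

INTERCHANGEABLE_FR_MIN = 90.0  # % relative bioavailability floor

# parameters entering the cross-brand ANOVA/Tukey screen
ANOVA_PARAMS = (
    "auc_last", "auc_inf", "aumc_last", "cmax", "tmax",
    "hl_lambda_z", "cl_f", "vz_f",
)


def relative_bioavailability(
    auc_t: float, auc_r: float, dose_t: float, dose_r: float
) -> float:
    """Dose-corrected relative bioavailability Fr in percent."""
    if min(auc_t, auc_r, dose_t, dose_r) <= 0:
        raise ValueError("AUCs and doses must be positive")
    return 100.0 * (auc_t * dose_r) / (auc_r * dose_t)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard between/within one-way ANOVA over >= 2 groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    dfb, dfw = k - 1, n_total - k
    ssw = float(sum(np.sum((a - a.mean()) ** 2) for a in arrs))
    if ssw == 0.0:
        means = [a.mean() for a in arrs]
        if np.ptp(means) > 0:
            # perfectly separated groups: F diverges, p -> 0
            return AnovaResult(math.inf, 0.0, dfb, dfw)
        return AnovaResult(0.0, 1.0, dfb, dfw)
    f, p = stats.f_oneway(*arrs)
    return AnovaResult(float(f), float(p), dfb, dfw)


@dataclass(frozen=True)
class TukeyPair:
    mean_diff: float
    q_statistic: float
    p_value: float
    significant: bool


@functools.lru_cache(maxsize=None)
def _q_critical(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range (cached: the
    distribution's quadrature is expensive and (alpha, k, df) repeats)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    compute_p: bool = True,
) -> dict[tuple[str, str], TukeyPair]:
    """All-pairs Tukey A test on the studentized range distribution.

    For each pair, q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
    (the Tukey-Kramer standard error, which reduces to sqrt(MSW/n) for
    equal group sizes) and the p-value comes from the studentized range
    with k groups and N - k error degrees of freedom.  Significance is
    decided against the cached critical quantile; ``compute_p=False``
    skips the expensive per-pair tail integral and reports NaN p-values
    (flags unaffected), useful in large simulation loops.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    df = n_total - k
    msw = float(sum(np.sum((a - a.mean()) ** 2) for a in arrs)) / df
    q_crit = _q_critical(alpha, k, df)
    out: dict[tuple[str, str], TukeyPair] = {}
    for i, j in itertools.combinations(range(k), 2):
        diff = float(arrs[i].mean() - arrs[j].mean())
        if msw > 0:
            se = math.sqrt(msw / 2.0 * (1.0 / arrs[i].size + 1.0 / arrs[j].size))
            q = abs(diff) / se
            sig = q > q_crit
            p = float(stats.studentized_range.sf(q, k, df)) if compute_p else math.nan
        else:
            q = math.inf if diff != 0 else 0.0
            sig = diff != 0
            p = 0.0 if diff != 0 else 1.0
        out[(labels[i], labels[j])] = TukeyPair(
            mean_diff=diff, q_statistic=q, p_value=p, significant=sig
        )
    return out


@dataclass(frozen=True)
class StudyResult:
    reference_brand: str
    fr_by_brand: dict[str, float]  # ratio of mean AUCs, %
    fr_mean_of_ratios: dict[str, float]  # index-paired subject ratios, %
    interchangeable: dict[str, bool]
    brand_summaries: pd.DataFrame
    anova_tables: dict[str, AnovaResult]
    tukey_flags: dict[str, dict[tuple[str, str], TukeyPair]]
    alpha: float = 0.05


def _brand_frame(nca_by_brand: Mapping[str, Sequence[NCAResult]]) -> pd.DataFrame:
    rows = []
    for brand, results in nca_by_brand.items():
        for r in results:
            d = r.to_dict()
            d["brand"] = brand
            rows.append(d)
    return pd.DataFrame(rows)


def run_bioeq_study(
    nca_by_brand: Mapping[str, Sequence[NCAResult]],
    reference_brand: str,
    alpha: float = 0.05,
    auc_field: str = "auc_inf",
    params: Sequence[str] = ANOVA_PARAMS,
    compute_p: bool = True,
) -> StudyResult:
    """Full cross-brand comparison from per-subject NCA results.

    Computes per-brand mean/SD summaries, relative bioavailability
    against the reference in both conventions (ratio of mean AUCs,
    default, and index-paired mean of individual ratios), and
    ANOVA + Tukey screens on the exposure parameters in ``params``.
    """
    if reference_brand not in nca_by_brand:
        raise ValueError(f"reference brand {reference_brand!r} not in study")
    if len(nca_by_brand) < 2:
        raise ValueError("need at least 2 brands")
    df = _brand_frame(nca_by_brand)

    summaries = (
        df.groupby("brand")[list(params)]
        .agg(["mean", "std", "count"])
        .sort_index()
    )

    ref = nca_by_brand[reference_brand]
    ref_auc = np.array([getattr(r, auc_field) for r in ref], dtype=float)
    ref_dose = float(np.mean([r.dose for r in ref]))
    fr: dict[str, float] = {}
    fr_ratios: dict[str, float] = {}
    inter: dict[str, bool] = {}
    for brand, results in nca_by_brand.items():
        auc = np.array([getattr(r, auc_field) for r in results], dtype=float)
        dose = float(np.mean([r.dose for r in results]))
        fr[brand] = relative_bioavailability(
            float(auc.mean()), float(ref_auc.mean()), dose, ref_dose
        )
        n = min(auc.size, ref_auc.size)
        fr_ratios[brand] = float(
            np.mean(100.0 * (auc[:n] * ref_dose) / (ref_auc[:n] * dose))
        )
        inter[brand] = fr[brand] >= INTERCHANGEABLE_FR_MIN

    brands = sorted(nca_by_brand)
    anova: dict[str, AnovaResult] = {}
    tukey: dict[str, dict[tuple[str, str], TukeyPair]] = {}
    for param in params:
        groups = [
            df.loc[df["brand"] == b, param].to_numpy(dtype=float)
            for b in brands
        ]
        if any(g.size < 2 or not np.all(np.isfinite(g)) for g in groups):
            continue
        anova[param] = one_way_anova(groups)
        tukey[param] = tukey_hsd(
            groups, alpha=alpha, labels=brands, compute_p=compute_p
        )
    return StudyResult(
        reference_brand=reference_brand,
        fr_by_brand=fr,
        fr_mean_of_ratios=fr_ratios,
        interchangeable=inter,
        brand_summaries=summaries,
        anova_tables=anova,
        tukey_flags=tukey,
        alpha=alpha,
    )
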