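"""Model-independent dissolution profile comparison (f1/f2) and
release-rate classification.

The difference factor f1 is the summed absolute percent-label
difference between a test and a reference curve, expressed as a
percentage of the cumulative reference release:

    f1 = 100 * sum_t |R_t - T_t| / sum_t R_t

The similarity factor f2 is a logarithmic reciprocal square-root
transform of the mean squared difference:

    f2 = 50 * log10( 100 / sqrt(1 + mean_t (R_t - T_t)^2) )

Two profiles are declared similar when 0 <= f1 <= 15 and
50 <= f2 <= 100 (an average difference of at most ~10 % label).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import DissolutionProfile

__all__ = [
    "difference_factor_f1",
    "similarity_factor_f2",
    "classify_release",
    "compare_pair",
    "compare_all",
    "DissolutionComparison",
    "ReleaseClass",
]

F1_SIMILAR_MAX = 15.0
F2_SIMILAR_MIN = 50.0


class ReleaseClass(str, enum.Enum):
    """Immediate-release classification from pharmacopoeial thresholds."""

    very_rapid = "very_rapid"  # > 85 % dissolved within 15 min
    rapid = "rapid"  # >= 85 % within 30 min
    compliant_30min = "compliant_30min"  # >= 80 % within 30 min
    noncompliant = "noncompliant"


@dataclass(frozen=True)
class DissolutionComparison:
    product_id: str
    f1: float  # %
    f2: float
    similar: bool
    n_points_used: int


def _common_grid(ref: DissolutionProfile, test: DissolutionProfile) -> None:
    if len(ref) != len(test) or not np.allclose(
        ref.times, test.times, rtol=0.0, atol=1e-9
    ):
        raise ValueError(
            "reference and test profiles must share identical time points"
        )


def _truncated(
    ref: DissolutionProfile, test: DissolutionProfile, truncate_after_85: bool
) -> tuple[np.ndarray, np.ndarray]:
    r, t = ref.values, test.values
    if truncate_after_85:
        both = (r > 85.0) & (t > 85.0)
        if both.any():
            # keep everything up to and including the first point where
            # both curves exceed 85 % dissolved
            cut = int(np.argmax(both)) + 1
            r, t = r[:cut], t[:cut]
    return r, t


def difference_factor_f1(
    ref: DissolutionProfile, test: DissolutionProfile
) -> float:
    """Difference factor f1 (%) between reference and test profiles.

    Not symmetric: the reference curve normalizes the difference.
    """
    _common_grid(ref, test)
    denom = float(np.sum(ref.values))
    if denom == 0.0:
        raise ValueError("f1 undefined: reference profile sums to zero")
    return float(100.0 * np.sum(np.abs(ref.values - test.values)) / denom)


def similarity_factor_f2(
    ref: DissolutionProfile,
    test: DissolutionProfile,
    truncate_after_85: bool = False,
) -> float:
    """Similarity factor f2; 100 for identical curves, >= 50 means similar.

    When ``truncate_after_85`` is set, at most one point where both
    profiles exceed 85 % dissolved is retained (the plateau carries no
    discriminating information).
    """
    _common_grid(ref, test)
    r, t = _truncated(ref, test, truncate_after_85)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def classify_release(profile: DissolutionProfile) -> ReleaseClass:
    """Classify an immediate-release curve by its 15- and 30-min values.

    Values at 15 and 30 min are obtained by linear interpolation
    between bracketing points; a (0, 0) anchor is assumed when the
    first sample is after t = 0 (no release before the test starts).
    """
    times, values = profile.times, profile.values
    if times[-1] < 30.0:
        raise ValueError("profile must extend to at least 30 minutes")
    if times[0] > 0.0:
        times = np.concatenate(([0.0], times))
        values = np.concatenate(([0.0], values))
    at15 = float(np.interp(15.0, times, values))
    at30 = float(np.interp(30.0, times, values))
    if at15 > 85.0:
        return ReleaseClass.very_rapid
    if at30 >= 85.0:
        return ReleaseClass.rapid
    if at30 >= 80.0:
        return ReleaseClass.compliant_30min
    return ReleaseClass.noncompliant


def compare_pair(
    ref: DissolutionProfile,
    test: DissolutionProfile,
    truncate_after_85: bool = False,
) -> DissolutionComparison:
    """f1, f2 and the similarity verdict for one test product."""
    f1 = difference_factor_f1(ref, test)
    f2 = similarity_factor_f2(ref, test, truncate_after_85)
    r, _ = _truncated(ref, test, truncate_after_85)
    similar = (0.0 <= f1 <= F1_SIMILAR_MAX) and (
        F2_SIMILAR_MIN <= f2 <= 100.0
    )
    return DissolutionComparison(
        product_id=test.product_id,
        f1=f1,
        f2=f2,
        similar=similar,
        n_points_used=int(r.size),
    )


def compare_all(
    test_profiles: Sequence[DissolutionProfile],
    ref: DissolutionProfile,
    truncate_after_85: bool = False,
) -> pd.DataFrame:
    """One row of f1/f2/verdict per test product against the reference."""
    rows = [
        compare_pair(ref, p, truncate_after_85).__dict__ for p in test_profiles
    ]
    return pd.DataFrame(
        rows, columns=["product_id", "f1", "f2", "similar", "n_points_used"]
    )
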