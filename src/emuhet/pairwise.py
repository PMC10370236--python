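"""Per-pair differences, standardized differences, and heterogeneity tests.

For a study pair with trial estimate :math:`\\hat\\theta_{RCT}` and pooled
emulation estimate :math:`\\hat\\theta_{RWE}` (both log hazard ratios), the
difference is taken trial minus emulation and standardized by the standard
error of the difference,

.. math:: z = \\frac{\\hat\\theta_{RCT} - \\hat\\theta_{RWE}}
              {\\sqrt{se_{RCT}^2 + se_{RWE}^2}}.

Under pairwise agreement z is standard normal, so :math:`Q = z^2` is
chi-squared with 1 degree of freedom; summing Q over the n pairs gives an
overall chi-squared(n) test of whether the pairs vary more than their
standard errors allow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_io import PairedDataset, TrialEstimate, ValidationError

__all__ = [
    "PairDifference",
    "OverallHeterogeneityTest",
    "pair_difference",
    "pair_differences",
    "overall_q_test",
    "export_calibration_data",
]


@dataclass(frozen=True)
class PairDifference:
    """Difference in log hazard ratio for one study pair, with its Q-test."""

    trial_id: str
    diff: float
    se_diff: float
    z: float
    q_stat: float
    p_value: float


@dataclass(frozen=True)
class OverallHeterogeneityTest:
    """Sum of per-pair Q statistics, chi-squared(n) under pairwise agreement."""

    q_total: float
    df: int
    p_value: float


def pair_difference(rct: TrialEstimate, rwe: TrialEstimate) -> PairDifference:
    """Standardized difference and Q-test for one RCT-emulation pair."""
    if rct.trial_id != rwe.trial_id:
        raise ValidationError(
            f"cannot pair estimates from different trials: {rct.trial_id!r} vs {rwe.trial_id!r}"
        )
    diff = rct.log_hr - rwe.log_hr
    se_diff = float(np.hypot(rct.se, rwe.se))
    z = diff / se_diff
    q = z * z
    p = float(stats.chi2.sf(q, 1))
    return PairDifference(
        trial_id=rct.trial_id, diff=diff, se_diff=se_diff, z=z, q_stat=q, p_value=p
    )


def pair_differences(dataset: PairedDataset) -> list[PairDifference]:
    """Per-pair differences for every pair of a dataset, in dataset order."""
    return [pair_difference(p.rct, p.rwe_pooled) for p in dataset.pairs]


def overall_q_test(diffs: Sequence[PairDifference]) -> OverallHeterogeneityTest:
    """Overall heterogeneity test over all study pairs.

    Each pair contributes an independent chi-squared(1) statistic under the
    null of pairwise agreement, so the total is tested against a
    chi-squared distribution with n degrees of freedom.
    """
    if not diffs:
        raise ValidationError("overall Q-test needs at least one pair")
    q_total = float(sum(d.q_stat for d in diffs))
    df = len(diffs)
    return OverallHeterogeneityTest(q_total=q_total, df=df, p_value=float(stats.chi2.sf(q_total, df)))


def export_calibration_data(diffs: Sequence[PairDifference]) -> pd.DataFrame:
    """Numeric content of the calibration diagnostics.

    Returns one row per pair with the sorted observed standardized
    differences against standard-normal theoretical quantiles (QQ view) and
    the sorted per-pair Q-test p-values against uniform quantiles, using
    plotting positions ``(i - 0.5) / n``.
    """
    n = len(diffs)
    positions = (np.arange(1, n + 1) - 0.5) / n
    z_sorted = np.sort([d.z for d in diffs])
    p_sorted = np.sort([d.p_value for d in diffs])
    return pd.DataFrame(
        {
            "plotting_position": positions,
            "z_observed": z_sorted,
            "z_theoretical": stats.norm.ppf(positions),
            "p_observed": p_sorted,
            "p_theoretical": positions,
        }
    )
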