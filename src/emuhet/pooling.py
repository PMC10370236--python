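"""Fixed-effects pooling of per-database emulation estimates.

When a trial emulation was implemented in several claims databases, the
per-database log hazard ratios are combined by inverse-variance weighted
(fixed-effects) meta-analysis into a single pooled estimate per trial.
Pooling is gated on Cochran's Q: when the database-level results are
heterogeneous (Q-test p-value below ``alpha``) a common underlying effect is
not tenable and the trial is excluded from the pair-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .study_io import Source, TrialEstimate, ValidationError

__all__ = ["PooledEstimate", "pool_fixed_effects", "cross_database_q", "apply_poolability_gate"]


@dataclass(frozen=True)
class PooledEstimate:
    """Fixed-effects pool of one trial's database estimates.

    ``q_stat`` / ``q_df`` / ``q_pvalue`` carry Cochran's Q for cross-database
    homogeneity; with a single database the test is vacuous (Q = 0, p = 1).
    """

    trial_id: str
    log_hr: float
    se: float
    k: int
    q_stat: float
    q_df: int
    q_pvalue: float
    poolable: bool

    def as_estimate(self) -> TrialEstimate:
        """View the pool as a pooled-emulation :class:`TrialEstimate`."""
        return TrialEstimate(
            trial_id=self.trial_id,
            source=Source.RWE_POOLED,
            log_hr=self.log_hr,
            se=self.se,
        )


def _check_inputs(estimates: Sequence[TrialEstimate]) -> tuple[str, np.ndarray, np.ndarray]:
    if not estimates:
        raise ValidationError("cannot pool an empty list of estimates")
    trial_ids = {e.trial_id for e in estimates}
    if len(trial_ids) != 1:
        raise ValidationError(f"cannot pool estimates from different trials: {sorted(trial_ids)}")
    for e in estimates:
        if e.source is not Source.RWE_DB:
            raise ValidationError(
                f"trial {e.trial_id!r}: pooling expects per-database estimates, got {e.source.value}"
            )
    y = np.array([e.log_hr for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    return next(iter(trial_ids)), y, se


def pool_fixed_effects(estimates: Sequence[TrialEstimate], alpha: float = 0.05) -> PooledEstimate:
    """Inverse-variance pool of one trial's per-database estimates.

    With weights :math:`w_i = 1/\\mathrm{se}_i^2`, the pooled log hazard
    ratio is :math:`\\sum w_i y_i / \\sum w_i` with standard error
    :math:`(\\sum w_i)^{-1/2}`.  ``alpha`` sets the homogeneity-gate level
    recorded in ``poolable``.
    """
    trial_id, y, se = _check_inputs(estimates)
    w = 1.0 / se**2
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    k = len(y)
    if k == 1:
        q, df, p = 0.0, 0, 1.0
    else:
        q, df, p = cross_database_q(estimates)
    return PooledEstimate(
        trial_id=trial_id,
        log_hr=pooled,
        se=pooled_se,
        k=k,
        q_stat=q,
        q_df=df,
        q_pvalue=p,
        poolable=p >= alpha,
    )


def cross_database_q(estimates: Sequence[TrialEstimate]) -> tuple[float, int, float]:
    """Cochran's Q for homogeneity across databases.

    Returns ``(q_stat, df, p_value)`` where Q is the weighted sum of squared
    deviations from the fixed-effects pool and the p-value is the upper tail
    of a chi-squared distribution with ``k - 1`` degrees of freedom.
    """
    trial_id, y, se = _check_inputs(estimates)
    k = len(y)
    if k < 2:
        raise ValidationError(f"trial {trial_id!r}: Q-test needs at least 2 databases, got {k}")
    w = 1.0 / se**2
    pooled = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - pooled) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def apply_poolability_gate(
    db_estimates: Mapping[str, Sequence[TrialEstimate]] | Iterable[TrialEstimate],
    alpha: float = 0.05,
) -> tuple[dict[str, PooledEstimate], list[str]]:
    """Pool every trial's database estimates and exclude heterogeneous trials.

    Accepts either a mapping ``trial_id -> per-database estimates`` or a flat
    iterable of database estimates (grouped here by trial).  Returns the
    pooled estimates for trials passing the gate (Q-test p >= ``alpha``) and
    the sorted list of excluded trial ids.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if isinstance(db_estimates, Mapping):
        groups = {t: list(ests) for t, ests in db_estimates.items()}
    else:
        groups = {}
        for est in db_estimates:
            if est.source is Source.RWE_DB:
                groups.setdefault(est.trial_id, []).append(est)
    kept: dict[str, PooledEstimate] = {}
    excluded: list[str] = []
    for trial_id in sorted(groups):
        pooled = pool_fixed_effects(groups[trial_id], alpha=alpha)
        if pooled.poolable:
            kept[trial_id] = pooled
        else:
            excluded.append(trial_id)
    return kept, excluded
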