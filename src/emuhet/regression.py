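"""Weighted meta-regression with multiplicative heterogeneity.

The pair differences :math:`d_i` are modelled as

.. math:: d_i = x_i'\\beta + \\varepsilon_i, \\qquad
          \\varepsilon_i \\sim N(0, \\phi^2 \\, se_{d,i}^2),

with inverse-variance weights :math:`w_i = 1/se_{d,i}^2`.  The
overdispersion factor :math:`\\phi` — the multiplicative heterogeneity — is
the residual standard error of the weighted fit,

.. math:: \\hat\\phi_{raw} = \\sqrt{\\frac{\\sum_i w_i r_i^2}{n - p}},

floored at 1: values below 1 would claim the pairs agree better than their
standard errors allow, which the model does not entertain.  A fit with no
covariates (intercept only) quantifies the total heterogeneity between the
pairs; adding emulation-difference covariates and watching :math:`\\hat\\phi`
drop quantifies how much of that variation the covariates explain.

Coefficient standard errors are scaled by the floored :math:`\\hat\\phi` and
confidence intervals use t quantiles with :math:`n - p` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pairwise import PairDifference
from .study_io import (
    CANDIDATE_COVARIATES,
    CLOSE_EMULATION,
    CONTINUOUS_COVARIATES,
    PairedDataset,
    ValidationError,
)

__all__ = [
    "DesignMatrix",
    "MetaRegressionFit",
    "build_design",
    "fit_weighted",
    "fit_dataset",
    "heterogeneity_reduction",
]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix for the meta-regression, intercept first.

    Continuous covariates are mean-centered on the analysis sample;
    ``centering_means`` records the subtracted means so that new covariate
    patterns can be mapped into the same parameterization.
    """

    trial_ids: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray
    centering_means: Mapping[str, float]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def row_for_pattern(self, pattern: Mapping[str, float]) -> np.ndarray:
        """Design row for a covariate pattern, applying the stored centering."""
        row = np.empty(self.p)
        for j, name in enumerate(self.columns):
            if name == INTERCEPT:
                row[j] = 1.0
                continue
            if name not in pattern:
                raise ValidationError(f"pattern is missing covariate {name!r}")
            row[j] = pattern[name] - self.centering_means.get(name, 0.0)
        return row


@dataclass(frozen=True)
class MetaRegressionFit:
    """Result of a weighted meta-regression fit.

    ``cov_unscaled`` is :math:`(X'WX)^{-1}`; multiply by the squared floored
    heterogeneity ``phi`` to obtain the covariance used for inference.
    ``residuals`` are on the response (log-hazard-ratio difference) scale.
    """

    columns: tuple[str, ...]
    coefficients: dict[str, float]
    cov_unscaled: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    weights: np.ndarray
    phi_raw: float
    phi: float
    df_resid: int
    level: float
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]

    @property
    def n(self) -> int:
        return len(self.residuals)


def build_design(dataset: PairedDataset, selected: Sequence[str]) -> DesignMatrix:
    """Assemble the design matrix: intercept plus the selected covariates.

    ``selected`` may contain any of the ten candidate covariates or the
    derived close-emulation indicator.  Continuous covariates are centered
    at their mean over the analysis sample so that the intercept is the
    expected difference at reference levels and average population overlap.
    """
    allowed = set(CANDIDATE_COVARIATES) | {CLOSE_EMULATION}
    unknown = [c for c in selected if c not in allowed]
    if unknown:
        raise ValidationError(f"unknown covariates: {unknown}")
    if len(set(selected)) != len(selected):
        raise ValidationError("duplicate covariates in selection")
    p = len(selected) + 1
    if p >= dataset.n:
        raise ValidationError(
            f"cannot fit {p} parameters to {dataset.n} pairs (need p < n)"
        )
    cols = [np.ones(dataset.n)]
    means: dict[str, float] = {}
    for name in selected:
        col = dataset.covariate_column(name)
        if name in CONTINUOUS_COVARIATES:
            means[name] = float(col.mean())
            col = col - means[name]
        cols.append(col)
    return DesignMatrix(
        trial_ids=dataset.trial_ids,
        columns=(INTERCEPT, *selected),
        values=np.column_stack(cols),
        centering_means=means,
    )


def fit_weighted(
    diffs: Sequence[PairDifference], X: DesignMatrix, level: float = 0.95
) -> MetaRegressionFit:
    """Weighted least squares of pair differences on the design matrix.

    Weights are the inverse squared standard errors of the differences.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    if tuple(d.trial_id for d in diffs) != X.trial_ids:
        raise ValidationError("differences and design matrix are not aligned by trial")
    y = np.array([d.diff for d in diffs])
    se_diff = np.array([d.se_diff for d in diffs])
    w = 1.0 / se_diff**2
    n, p = X.values.shape
    if n - p < 1:
        raise ValidationError(f"residual degrees of freedom {n - p} < 1")

    sw = np.sqrt(w)
    Xw = X.values * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        bad = _collinear_columns(Xw, X.columns)
        raise ValidationError(f"singular design matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    fitted = X.values @ beta
    resid = y - fitted
    df_resid = n - p
    phi_raw = float(np.sqrt(np.sum(w * resid**2) / df_resid))
    phi = max(phi_raw, 1.0)
    cov_unscaled = np.linalg.inv(Xw.T @ Xw)
    se_coef = phi * np.sqrt(np.diag(cov_unscaled))
    tq = stats.t.ppf(0.5 + level / 2, df_resid)
    coefficients = dict(zip(X.columns, map(float, beta)))
    se_map = dict(zip(X.columns, map(float, se_coef)))
    ci = {
        name: (coefficients[name] - tq * se_map[name], coefficients[name] + tq * se_map[name])
        for name in X.columns
    }
    return MetaRegressionFit(
        columns=X.columns,
        coefficients=coefficients,
        cov_unscaled=cov_unscaled,
        residuals=resid,
        fitted=fitted,
        weights=w,
        phi_raw=phi_raw,
        phi=phi,
        df_resid=df_resid,
        level=level,
        se=se_map,
        ci=ci,
    )


def fit_dataset(
    dataset: PairedDataset,
    selected: Sequence[str] = (),
    level: float = 0.95,
    diffs: Sequence[PairDifference] | None = None,
) -> MetaRegressionFit:
    """Convenience wrapper: build the design and fit in one step."""
    from .pairwise import pair_differences

    if diffs is None:
        diffs = pair_differences(dataset)
    return fit_weighted(diffs, build_design(dataset, selected), level=level)


def heterogeneity_reduction(
    fit_simple: MetaRegressionFit, fit_adjusted: MetaRegressionFit
) -> float:
    """Drop in multiplicative heterogeneity from adding covariates.

    Positive values mean the adjusted model explains part of the variation
    between study pairs.
    """
    return fit_simple.phi - fit_adjusted.phi


def _collinear_columns(Xw: np.ndarray, columns: tuple[str, ...]) -> list[str]:
    """Greedily identify columns that do not increase the design rank."""
    bad = []
    kept = np.empty((Xw.shape[0], 0))
    for j, name in enumerate(columns):
        trial = np.column_stack([kept, Xw[:, j]])
        if np.linalg.matrix_rank(trial) > kept.shape[1]:
            kept = trial
        else:
            bad.append(name)
    return bad
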