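"""Exhaustive best-subset search scored by leave-one-out cross-validation.

Every subset of the candidate covariates (2^p models, including the
intercept-only model) is fitted by weighted meta-regression and scored by
the leave-one-out mean squared prediction error of the pair differences.
The final model is chosen by the one-standard-error rule: among all models
whose LOO MSE is within one standard error of the smallest LOO MSE, take
the one with the fewest covariates.  This trades a little predictive
performance for parsimony, which matters with only a few dozen study pairs.

Leave-one-out predictions for a weighted linear model are computed in
closed form from the full fit via the leverage identity
:math:`e_{(-i)} = r_i / (1 - h_{ii})` with
:math:`h_{ii} = w_i \\, x_i'(X'WX)^{-1}x_i`; this is algebraically
identical to refitting on each fold (mean-centering of continuous
covariates per training fold does not change fold predictions, because
predictions of a linear model with an intercept are invariant to shifting
a column).  Models whose design becomes singular on some fold (a leverage
of 1, e.g. a binary flag carried by a single trial) are marked infeasible
and excluded from selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .pairwise import PairDifference, pair_differences
from .regression import INTERCEPT, MetaRegressionFit, build_design, fit_weighted
from .study_io import CANDIDATE_COVARIATES, PairedDataset, ValidationError

__all__ = [
    "CandidateModelResult",
    "SelectionResult",
    "enumerate_subsets",
    "loo_mse",
    "select_one_se",
    "selection_path",
    "run_selection",
]

logger = logging.getLogger(__name__)

_MAX_CANDIDATES = 20
_LEVERAGE_TOL = 1e-8


@dataclass(frozen=True)
class CandidateModelResult:
    """One covariate subset with its cross-validation score.

    ``loo_errors`` are the per-trial out-of-fold prediction errors on the
    log-hazard-ratio-difference scale; ``phi_resid`` is the (floored)
    multiplicative heterogeneity of the full-data fit of the same subset.
    Infeasible models carry NaN scores and ``feasible=False``.
    """

    subset: tuple[str, ...]
    size: int
    loo_errors: np.ndarray
    loo_mse: float
    loo_mse_se: float
    phi_resid: float
    feasible: bool
    fit: MetaRegressionFit | None = None


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the exhaustive search and the one-standard-error rule."""

    all_models: tuple[CandidateModelResult, ...]
    best_by_size: dict[int, CandidateModelResult]
    min_mse_model: CandidateModelResult
    selected_model: CandidateModelResult
    threshold: float


def enumerate_subsets(candidates: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^p covariate subsets, ordered by size then candidate order."""
    if len(set(candidates)) != len(candidates):
        raise ValidationError("duplicate candidate names")
    if len(candidates) > _MAX_CANDIDATES:
        raise ValidationError(
            f"{len(candidates)} candidates would give {2 ** len(candidates)} models; "
            f"pass an explicit subset list instead"
        )
    subsets: list[tuple[str, ...]] = []
    for size in range(len(candidates) + 1):
        subsets.extend(combinations(candidates, size))
    return subsets


def loo_mse(
    dataset: PairedDataset,
    subset: Sequence[str],
    weighted: bool = False,
    diffs: Sequence[PairDifference] | None = None,
    keep_fit: bool = False,
) -> CandidateModelResult:
    """Score one covariate subset by leave-one-out cross-validation.

    With ``weighted=True`` the squared errors are averaged with the
    inverse-variance weights of the differences instead of equally.
    """
    if diffs is None:
        diffs = pair_differences(dataset)
    subset = tuple(subset)
    n = dataset.n
    if n - len(subset) - 2 < 0:
        raise ValidationError(
            f"{n} pairs cannot support leave-one-out folds with {len(subset)} covariates"
        )
    try:
        X = build_design(dataset, subset)
        fit = fit_weighted(diffs, X)
    except ValidationError as err:
        logger.debug("subset %s infeasible: %s", subset, err)
        return _infeasible(subset, n)
    h = fit.weights * np.einsum("ij,jk,ik->i", X.values, fit.cov_unscaled, X.values)
    one_minus_h = 1.0 - h
    if np.any(one_minus_h < _LEVERAGE_TOL):
        logger.debug("subset %s infeasible: singular leave-one-out fold", subset)
        return _infeasible(subset, n, phi=fit.phi)
    errors = fit.residuals / one_minus_h
    sq = errors**2
    if weighted:
        sq = sq * fit.weights / fit.weights.mean()
    mse = float(sq.mean())
    mse_se = float(sq.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return CandidateModelResult(
        subset=subset,
        size=len(subset),
        loo_errors=errors,
        loo_mse=mse,
        loo_mse_se=mse_se,
        phi_resid=fit.phi,
        feasible=True,
        fit=fit if keep_fit else None,
    )


def _infeasible(subset: tuple[str, ...], n: int, phi: float = math.nan) -> CandidateModelResult:
    return CandidateModelResult(
        subset=subset,
        size=len(subset),
        loo_errors=np.full(n, np.nan),
        loo_mse=math.nan,
        loo_mse_se=math.nan,
        phi_resid=phi,
        feasible=False,
    )


def select_one_se(results: Sequence[CandidateModelResult]) -> SelectionResult:
    """Apply the one-standard-error rule over scored candidate models.

    The threshold is the minimum LOO MSE plus the standard error of that
    minimum-MSE model's score; the selected model is the smallest (fewest
    covariates) among models at or below the threshold, ties broken by
    smaller MSE, then by subset order.
    """
    feasible = [r for r in results if r.feasible]
    if not feasible:
        raise ValidationError("no feasible candidate models to select from")
    min_model = min(feasible, key=lambda r: (r.loo_mse, r.size, r.subset))
    threshold = min_model.loo_mse + min_model.loo_mse_se
    eligible = [r for r in feasible if r.loo_mse <= threshold]
    selected = min(eligible, key=lambda r: (r.size, r.loo_mse, r.subset))
    best_by_size: dict[int, CandidateModelResult] = {}
    for r in feasible:
        cur = best_by_size.get(r.size)
        if cur is None or (r.loo_mse, r.subset) < (cur.loo_mse, cur.subset):
            best_by_size[r.size] = r
    return SelectionResult(
        all_models=tuple(results),
        best_by_size=best_by_size,
        min_mse_model=min_model,
        selected_model=selected,
        threshold=threshold,
    )


def run_selection(
    dataset: PairedDataset,
    candidates: Sequence[str] = CANDIDATE_COVARIATES,
    weighted: bool = False,
    diffs: Sequence[PairDifference] | None = None,
) -> SelectionResult:
    """Enumerate, score, and select over all subsets of ``candidates``."""
    if diffs is None:
        diffs = pair_differences(dataset)
    results = [
        loo_mse(dataset, subset, weighted=weighted, diffs=diffs)
        for subset in enumerate_subsets(candidates)
    ]
    n_infeasible = sum(not r.feasible for r in results)
    if n_infeasible:
        logger.warning(
            "%d of %d candidate models infeasible (singular design or fold) "
            "and excluded from selection",
            n_infeasible,
            len(results),
        )
    return select_one_se(results)


def selection_path(
    selection: SelectionResult,
    dataset: PairedDataset,
    diffs: Sequence[PairDifference] | None = None,
) -> pd.DataFrame:
    """Best model per size with its full-data coefficients and heterogeneity.

    One row per number of covariates from 0 up to the largest feasible
    model: the subset minimizing LOO MSE within that size, its coefficient
    estimates (NaN for excluded covariates), the residual multiplicative
    heterogeneity, and the cross-validation score.
    """
    if diffs is None:
        diffs = pair_differences(dataset)
    all_names = sorted(
        {name for r in selection.all_models for name in r.subset},
        key=lambda s: (CANDIDATE_COVARIATES.index(s) if s in CANDIDATE_COVARIATES else -1),
    )
    rows = []
    for size in sorted(selection.best_by_size):
        best = selection.best_by_size[size]
        fit = fit_weighted(diffs, build_design(dataset, best.subset))
        row: dict[str, object] = {
            "size": size,
            "subset": "+".join(best.subset) if best.subset else "(intercept only)",
            "loo_mse": best.loo_mse,
            "loo_mse_se": best.loo_mse_se,
            "phi_resid": best.phi_resid,
            INTERCEPT: fit.coefficients[INTERCEPT],
        }
        for name in all_names:
            row[name] = fit.coefficients.get(name, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
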