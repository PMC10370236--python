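"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's fitting code paths: weighted least
squares is solved by explicit normal equations, and leave-one-out scores
are obtained by literally refitting on every fold (recentering continuous
covariates on the training fold and predicting with training-fold means).
"""

from __future__ import annotations

import numpy as np

from emuhet.study_io import CONTINUOUS_COVARIATES, PairedDataset


def wls_normal_equations(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Solve the weighted normal equations explicitly.

    Returns (beta, cov_unscaled, residuals, phi_raw) with
    phi_raw = sqrt(sum w r^2 / (n - p)).
    """
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta
    n, p = X.shape
    phi_raw = np.sqrt(float(resid @ W @ resid) / (n - p))
    return beta, np.linalg.inv(XtWX), resid, phi_raw


def loo_refit_errors(dataset: PairedDataset, subset, diffs) -> np.ndarray:
    """Leave-one-out prediction errors by explicit per-fold refits."""
    n = dataset.n
    y = np.array([d.diff for d in diffs])
    w = np.array([d.se_diff for d in diffs]) ** -2.0
    cols = {name: dataset.covariate_column(name) for name in subset}
    errors = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        X_parts = [np.ones(train.sum())]
        x_row = [1.0]
        for name in subset:
            col = cols[name][train]
            if name in CONTINUOUS_COVARIATES:
                mean = col.mean()
                X_parts.append(col - mean)
                x_row.append(cols[name][i] - mean)
            else:
                X_parts.append(col)
                x_row.append(cols[name][i])
        X = np.column_stack(X_parts)
        beta, *_ = wls_normal_equations(X, y[train], w[train])
        errors[i] = y[i] - np.array(x_row) @ beta
    return errors


def loo_mse_refit(dataset: PairedDataset, subset, diffs, weighted: bool = False):
    """LOO MSE (and its SE) from explicit per-fold refits."""
    errors = loo_refit_errors(dataset, subset, diffs)
    sq = errors**2
    if weighted:
        w = np.array([d.se_diff for d in diffs]) ** -2.0
        sq = sq * w / w.mean()
    n = len(sq)
    return float(sq.mean()), float(sq.std(ddof=1) / np.sqrt(n))
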