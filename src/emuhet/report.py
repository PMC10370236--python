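"""Full-pipeline orchestration and export of table/figure data.

Runs the whole analysis in order — pool per-database emulation estimates,
compute per-pair differences and the overall heterogeneity test, fit the
intercept-only and close-emulation meta-regressions, fit each candidate
covariate univariately, and run exhaustive subset selection — and collects
everything in an :class:`AnalysisReport` that serializes to JSON and to a
set of CSV tables (coefficient tables, calibration data, per-pair
differences by emulation closeness, and group-level prediction intervals).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .pairwise import (
    OverallHeterogeneityTest,
    PairDifference,
    export_calibration_data,
    overall_q_test,
    pair_differences,
)
from .pooling import apply_poolability_gate
from .regression import (
    INTERCEPT,
    DesignMatrix,
    MetaRegressionFit,
    build_design,
    fit_weighted,
)
from .selection import SelectionResult, run_selection, selection_path
from .study_io import (
    CANDIDATE_COVARIATES,
    CLOSE_EMULATION,
    PairedDataset,
    Source,
    ValidationError,
    read_covariates,
    read_estimates,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze", "run_full_analysis", "prediction_intervals", "write_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full pipeline."""

    alpha: float = 0.05  # cross-database homogeneity gate level
    level: float = 0.95  # confidence level for coefficient intervals
    candidates: tuple[str, ...] = CANDIDATE_COVARIATES
    weighted_loo: bool = False  # inverse-variance weighting of LOO errors
    hr_scale: bool = False  # estimates file carries hr instead of log_hr


@dataclass(frozen=True)
class AnalysisReport:
    """All pipeline outputs for one dataset."""

    dataset: PairedDataset
    diffs: tuple[PairDifference, ...]
    overall_test: OverallHeterogeneityTest
    simple_fit: MetaRegressionFit
    close_emulation_fit: MetaRegressionFit
    univariate_fits: dict[str, MetaRegressionFit]
    selection: SelectionResult
    selected_fit: MetaRegressionFit
    excluded: tuple[str, ...]
    config: AnalysisConfig

    def table2(self) -> pd.DataFrame:
        """Intercept-only vs close-emulation-adjusted model summary."""
        rows = [
            _coef_row("simple", self.simple_fit, None),
            _coef_row("close_emulation", self.close_emulation_fit, CLOSE_EMULATION),
        ]
        return pd.DataFrame(rows)

    def table3(self) -> pd.DataFrame:
        """Univariate model summary, one row per candidate covariate."""
        return pd.DataFrame(
            [_coef_row(name, fit, name) for name, fit in self.univariate_fits.items()]
        )

    def table4(self) -> pd.DataFrame:
        """Best model per size along the selection path."""
        return selection_path(self.selection, self.dataset, self.diffs)

    def fig2_data(self) -> pd.DataFrame:
        """Calibration of standardized differences and Q-test p-values."""
        return export_calibration_data(self.diffs)

    def fig3_data(self) -> pd.DataFrame:
        """Per-pair differences annotated with the close-emulation flag."""
        close = {p.trial_id: p.covariates.close_emulation for p in self.dataset.pairs}
        return pd.DataFrame(
            {
                "trial_id": [d.trial_id for d in self.diffs],
                "diff": [d.diff for d in self.diffs],
                "se_diff": [d.se_diff for d in self.diffs],
                "weight": [d.se_diff**-2 for d in self.diffs],
                CLOSE_EMULATION: [close[d.trial_id] for d in self.diffs],
            }
        )

    def fig5_data(self) -> pd.DataFrame:
        """Group-level predictions with intervals, for the close-emulation
        model and for the selected model (observed patterns only)."""
        frames = []
        for label, fit, selected in (
            ("close_emulation", self.close_emulation_fit, (CLOSE_EMULATION,)),
            ("selected", self.selected_fit, self.selection.selected_model.subset),
        ):
            X = build_design(self.dataset, selected)
            df = prediction_intervals(fit, X, self.diffs)
            df.insert(0, "model", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        """Lossless JSON-serializable view of the report."""
        sel = self.selection
        return {
            "n_pairs": self.dataset.n,
            "excluded_trials": list(self.excluded),
            "overall_test": dataclasses.asdict(self.overall_test),
            "simple_fit": _fit_dict(self.simple_fit),
            "close_emulation_fit": _fit_dict(self.close_emulation_fit),
            "univariate_fits": {k: _fit_dict(v) for k, v in self.univariate_fits.items()},
            "selection": {
                "threshold": sel.threshold,
                "min_mse_subset": list(sel.min_mse_model.subset),
                "min_mse": sel.min_mse_model.loo_mse,
                "selected_subset": list(sel.selected_model.subset),
                "selected_loo_mse": sel.selected_model.loo_mse,
                "selected_phi": sel.selected_model.phi_resid,
                "n_models": len(sel.all_models),
                "n_feasible": sum(r.feasible for r in sel.all_models),
            },
            "selected_fit": _fit_dict(self.selected_fit),
            "config": {
                **dataclasses.asdict(self.config),
                "candidates": list(self.config.candidates),
            },
        }


def _coef_row(label: str, fit: MetaRegressionFit, coef: str | None) -> dict:
    row: dict[str, object] = {
        "model": label,
        "intercept": fit.coefficients[INTERCEPT],
        "intercept_low": fit.ci[INTERCEPT][0],
        "intercept_high": fit.ci[INTERCEPT][1],
        "phi": fit.phi,
    }
    if coef is not None:
        row.update(
            coefficient=fit.coefficients[coef],
            coefficient_low=fit.ci[coef][0],
            coefficient_high=fit.ci[coef][1],
        )
    return row


def _fit_dict(fit: MetaRegressionFit) -> dict:
    return {
        "columns": list(fit.columns),
        "coefficients": fit.coefficients,
        "se": fit.se,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "phi_raw": fit.phi_raw,
        "phi": fit.phi,
        "df_resid": fit.df_resid,
        "level": fit.level,
    }


def prediction_intervals(
    fit: MetaRegressionFit,
    X: DesignMatrix,
    diffs: Sequence[PairDifference],
    patterns: Sequence[Mapping[str, float]] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted difference with interval for each observed covariate pattern.

    For pattern x the interval is
    ``x'b +- t_{n-p} * phi * sqrt(x' (X'WX)^{-1} x + median se_diff^2)``,
    combining coefficient uncertainty with observation-level noise; the
    observation-variance term uses the median squared standard error of the
    pattern's observed trials.  Only patterns observed in the data are
    admissible; an unobserved pattern raises.
    """
    names = [c for c in X.columns if c != INTERCEPT]
    observed: dict[tuple, dict] = {}
    for i, trial_id in enumerate(X.trial_ids):
        raw = tuple(
            X.values[i, j] + X.centering_means.get(X.columns[j], 0.0)
            for j in range(1, X.p)
        )
        grp = observed.setdefault(raw, {"rows": [], "se2": []})
        grp["rows"].append(X.values[i])
        grp["se2"].append(diffs[i].se_diff ** 2)
    if patterns is None:
        keys = sorted(observed)
    else:
        keys = []
        for pat in patterns:
            key = tuple(float(pat[name]) for name in names)
            if key not in observed:
                raise ValidationError(f"pattern {dict(zip(names, key))} not observed in the data")
            keys.append(key)
    beta = np.array([fit.coefficients[c] for c in X.columns])
    tq = stats.t.ppf(0.5 + level / 2, fit.df_resid)
    rows = []
    for key in keys:
        grp = observed[key]
        x = grp["rows"][0]
        med_se2 = float(np.median(grp["se2"]))
        point = float(x @ beta)
        half = tq * fit.phi * float(np.sqrt(x @ fit.cov_unscaled @ x + med_se2))
        row = dict(zip(names, key))
        row.update(
            n_trials=len(grp["rows"]),
            predicted=point,
            lower=point - half,
            upper=point + half,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze(dataset: PairedDataset, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Run every analysis stage on an assembled paired dataset."""
    diffs = tuple(pair_differences(dataset))
    logger.info("pairwise: n=%d pairs", dataset.n)
    overall = overall_q_test(diffs)
    logger.info("overall Q=%.3f df=%d p=%.4g", overall.q_total, overall.df, overall.p_value)

    simple = fit_weighted(diffs, build_design(dataset, ()), level=config.level)
    close = fit_weighted(diffs, build_design(dataset, (CLOSE_EMULATION,)), level=config.level)
    logger.info("phi: simple=%.3f close-emulation=%.3f", simple.phi, close.phi)

    univariate: dict[str, MetaRegressionFit] = {}
    for name in config.candidates:
        try:
            univariate[name] = fit_weighted(
                diffs, build_design(dataset, (name,)), level=config.level
            )
        except ValidationError as err:
            # a covariate constant in the analysis sample cannot be fitted
            logger.warning("skipping univariate fit for %s: %s", name, err)
    selection = run_selection(dataset, config.candidates, weighted=config.weighted_loo, diffs=diffs)
    selected_fit = fit_weighted(
        diffs, build_design(dataset, selection.selected_model.subset), level=config.level
    )
    logger.info(
        "selected subset %s with phi=%.3f",
        selection.selected_model.subset,
        selected_fit.phi,
    )
    return AnalysisReport(
        dataset=dataset,
        diffs=diffs,
        overall_test=overall,
        simple_fit=simple,
        close_emulation_fit=close,
        univariate_fits=univariate,
        selection=selection,
        selected_fit=selected_fit,
        excluded=dataset.excluded,
        config=config,
    )


def run_full_analysis(
    estimates_path, covariates_path, config: AnalysisConfig = AnalysisConfig()
) -> AnalysisReport:
    """Read input tables, pool databases, gate, assemble, and analyze."""
    from .study_io import assemble_pairs

    estimates = read_estimates(estimates_path, hr_scale=config.hr_scale)
    covariates = read_covariates(covariates_path)

    db = [e for e in estimates if e.source is Source.RWE_DB]
    others = [e for e in estimates if e.source is not Source.RWE_DB]
    supplied_pooled = {e.trial_id for e in others if e.source is Source.RWE_POOLED}
    pooled, excluded = apply_poolability_gate(db, alpha=config.alpha)
    if excluded:
        logger.info("poolability gate excluded trials: %s", excluded)
    merged = others + [
        p.as_estimate() for t, p in pooled.items() if t not in supplied_pooled
    ]
    dataset = assemble_pairs(merged, covariates, excluded=excluded)
    return analyze(dataset, config)


def write_report(report: AnalysisReport, out_dir, manifest_extra: Mapping | None = None) -> None:
    """Write the CSV tables, the JSON report, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table2().to_csv(out / "table2.csv", index=False)
    report.table3().to_csv(out / "table3.csv", index=False)
    report.table4().to_csv(out / "table4.csv", index=False)
    report.fig2_data().to_csv(out / "fig2_data.csv", index=False)
    report.fig3_data().to_csv(out / "fig3_data.csv", index=False)
    report.fig5_data().to_csv(out / "fig5_data.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    manifest = {
        "package": "emuhet",
        "version": __version__,
        "n_pairs": report.dataset.n,
        "excluded_trials": list(report.excluded),
        "config": dataclasses.asdict(report.config),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
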