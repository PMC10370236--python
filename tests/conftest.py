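"""Shared fixtures: tiny hand-constructible paired datasets."""

from __future__ import annotations

import numpy as np
import pytest

from emuhet.study_io import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    EmulationCovariates,
    PairedDataset,
    Source,
    StudyPair,
    TrialEstimate,
    with_close_emulation,
)


def make_covariates(trial_id: str, **values) -> EmulationCovariates:
    """Covariate row with all fields zero unless overridden."""
    kwargs = {name: 0 for name in BINARY_COVARIATES}
    kwargs.update({name: 0.0 for name in CONTINUOUS_COVARIATES})
    kwargs.update(values)
    return EmulationCovariates(trial_id=trial_id, **kwargs)


def make_dataset(diffs, se_diffs, covariates=None) -> PairedDataset:
    """Paired dataset with prescribed differences and difference SEs.

    The difference is split symmetrically around zero and each arm gets
    standard error se_diff / sqrt(2), so the pairwise formulas reproduce
    the prescribed values exactly up to floating point.
    """
    diffs = np.asarray(diffs, dtype=float)
    se_diffs = np.asarray(se_diffs, dtype=float)
    n = len(diffs)
    if covariates is None:
        covariates = [make_covariates(f"t{i + 1}") for i in range(n)]
    pairs = []
    for i in range(n):
        tid = covariates[i].trial_id
        se_arm = se_diffs[i] / np.sqrt(2.0)
        rct = TrialEstimate(tid, Source.RCT, log_hr=diffs[i] / 2, se=se_arm)
        rwe = TrialEstimate(tid, Source.RWE_POOLED, log_hr=-diffs[i] / 2, se=se_arm)
        pairs.append(
            StudyPair(trial_id=tid, rct=rct, rwe_pooled=rwe, covariates=with_close_emulation(covariates[i]))
        )
    return PairedDataset(pairs=tuple(pairs))


def random_dataset(rng: np.random.Generator, n: int, binary=(), continuous=()) -> PairedDataset:
    """Random dataset with the requested covariates filled with noise."""
    covs = []
    for i in range(n):
        values = {name: int(rng.random() < 0.5) for name in binary}
        values.update({name: float(rng.normal(0, 2)) for name in continuous})
        covs.append(make_covariates(f"t{i + 1:03d}", **values))
    diffs = rng.normal(0, 0.3, n)
    se_diffs = np.exp(rng.uniform(np.log(0.08), np.log(0.5), n))
    return make_dataset(diffs, se_diffs, covs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230713)
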