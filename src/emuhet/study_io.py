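"""Input tables, validation, and the paired-study data model.

The analysis operates on *study pairs*: for each randomized trial there is
one effect estimate from the trial itself (a hazard ratio and its standard
error) and one from a real-world-data emulation of the trial, usually pooled
over several claims databases.  All effect estimates are carried on the
natural-log scale, where the hazard-ratio estimator is approximately normal.

Each pair also carries ten study-level covariates describing how the
emulation differed from the trial: eight binary design-difference flags and
two continuous population differences (difference in mean age in years and
in percentage of female participants, trial minus pooled emulation).  A
composite "close emulation" indicator is derived from the binary flags, not
supplied by the user.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Source",
    "TrialEstimate",
    "EmulationCovariates",
    "StudyPair",
    "PairedDataset",
    "BINARY_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "CANDIDATE_COVARIATES",
    "CLOSE_EMULATION",
    "SchemaError",
    "ValidationError",
    "read_estimates",
    "read_covariates",
    "write_estimates",
    "write_covariates",
    "derive_close_emulation",
    "assemble_pairs",
]

#: Binary design-emulation difference flags, in canonical order.
BINARY_COVARIATES: tuple[str, ...] = (
    "comparator_good",
    "outcome_good",
    "runin_one_arm",
    "placebo_control",
    "in_hospital_start",
    "dose_titration",
    "discontinuation_no_washout",
    "delayed_effect",
)

#: Continuous population-difference covariates (trial minus pooled emulation).
CONTINUOUS_COVARIATES: tuple[str, ...] = ("diff_mean_age", "diff_pct_female")

#: The full candidate set for meta-regression and model selection (p = 10).
CANDIDATE_COVARIATES: tuple[str, ...] = BINARY_COVARIATES + CONTINUOUS_COVARIATES

#: Name of the derived composite indicator.
CLOSE_EMULATION = "close_emulation"

#: Flags whose presence disqualifies a pair from being a close emulation.
_DISQUALIFYING_FLAGS = (
    "in_hospital_start",
    "runin_one_arm",
    "discontinuation_no_washout",
    "delayed_effect",
)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input row violates a domain invariant."""


class Source(str, enum.Enum):
    """Provenance of one effect estimate."""

    RCT = "RCT"
    RWE_DB = "RWE_DB"
    RWE_POOLED = "RWE_POOLED"


@dataclass(frozen=True)
class TrialEstimate:
    """One log-hazard-ratio estimate with its standard error.

    Parameters
    ----------
    trial_id : str
        Identifier of the randomized trial the estimate belongs to.
    source : Source
        Whether the estimate comes from the trial, a single database
        emulation, or the fixed-effects pool of database emulations.
    log_hr : float
        Natural-log hazard ratio.
    se : float
        Standard error of ``log_hr``; must be positive.
    database : str, optional
        Database name; required exactly when ``source`` is ``RWE_DB``.
    """

    trial_id: str
    source: Source
    log_hr: float
    se: float
    database: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_hr):
            raise ValidationError(f"trial {self.trial_id!r}: log_hr must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"trial {self.trial_id!r}: se must be positive")
        if self.source is Source.RWE_DB and not self.database:
            raise ValidationError(
                f"trial {self.trial_id!r}: database is required for RWE_DB estimates"
            )
        if self.source is not Source.RWE_DB and self.database:
            raise ValidationError(
                f"trial {self.trial_id!r}: database only allowed for RWE_DB estimates"
            )


@dataclass(frozen=True)
class EmulationCovariates:
    """The ten emulation-difference characteristics for one trial.

    Binary flags are coded 1 = difference present (or emulation "good" for
    the two quality flags), 0 = reference.  The continuous covariates are
    the trial value minus the pooled-emulation value.  ``close_emulation``
    is derived via :func:`derive_close_emulation`, never user-supplied.
    """

    trial_id: str
    comparator_good: int
    outcome_good: int
    runin_one_arm: int
    placebo_control: int
    in_hospital_start: int
    dose_titration: int
    discontinuation_no_washout: int
    delayed_effect: int
    diff_mean_age: float
    diff_pct_female: float
    close_emulation: int | None = None

    def __post_init__(self) -> None:
        for name in BINARY_COVARIATES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(
                    f"trial {self.trial_id!r}: {name} must be 0 or 1, got {v!r}"
                )
        for name in CONTINUOUS_COVARIATES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(
                    f"trial {self.trial_id!r}: {name} must be finite, got {v!r}"
                )

    def value(self, name: str) -> float:
        """Return a covariate value by name (including the derived one)."""
        if name == CLOSE_EMULATION:
            if self.close_emulation is None:
                raise ValidationError(
                    f"trial {self.trial_id!r}: close_emulation not derived yet"
                )
            return float(self.close_emulation)
        if name not in CANDIDATE_COVARIATES:
            raise KeyError(name)
        return float(getattr(self, name))


@dataclass(frozen=True)
class StudyPair:
    """One trial's RCT estimate, pooled-emulation estimate, and covariates."""

    trial_id: str
    rct: TrialEstimate
    rwe_pooled: TrialEstimate
    covariates: EmulationCovariates

    def __post_init__(self) -> None:
        ids = {self.rct.trial_id, self.rwe_pooled.trial_id, self.covariates.trial_id}
        if ids != {self.trial_id}:
            raise ValidationError(f"inconsistent trial ids in pair: {sorted(ids)}")
        if self.rct.source is not Source.RCT:
            raise ValidationError(f"trial {self.trial_id!r}: rct slot must hold an RCT estimate")
        if self.rwe_pooled.source is Source.RCT:
            raise ValidationError(
                f"trial {self.trial_id!r}: rwe slot must hold an emulation estimate"
            )


@dataclass(frozen=True)
class PairedDataset:
    """An ordered collection of complete study pairs."""

    pairs: tuple[StudyPair, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [p.trial_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate trial ids in dataset")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def trial_ids(self) -> tuple[str, ...]:
        return tuple(p.trial_id for p in self.pairs)

    def covariate_column(self, name: str) -> np.ndarray:
        """Vector of one covariate across pairs, in dataset order."""
        return np.array([p.covariates.value(name) for p in self.pairs], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: estimates, standard errors, and covariates per pair."""
        rows = []
        for p in self.pairs:
            row = {
                "trial_id": p.trial_id,
                "log_hr_rct": p.rct.log_hr,
                "se_rct": p.rct.se,
                "log_hr_rwe": p.rwe_pooled.log_hr,
                "se_rwe": p.rwe_pooled.se,
            }
            for name in CANDIDATE_COVARIATES:
                row[name] = p.covariates.value(name)
            row[CLOSE_EMULATION] = p.covariates.close_emulation
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reading and writing


_TRUE_LEVELS = {"1", "yes", "true"}
_FALSE_LEVELS = {"0", "no", "false"}


def _coerce_binary(value: object, column: str, trial_id: str) -> int:
    text = str(value).strip().lower()
    if text in _TRUE_LEVELS:
        return 1
    if text in _FALSE_LEVELS:
        return 0
    raise ValidationError(
        f"trial {trial_id!r}, column {column!r}: unrecognized level {value!r} "
        f"(accepted: 0/1, yes/no, true/false, case-insensitive)"
    )


def read_estimates(path, hr_scale: bool = False) -> list[TrialEstimate]:
    """Read an effect-estimates table from CSV.

    The table must have columns ``trial_id``, ``source``, ``database`` and
    ``se``, plus either ``log_hr`` or — with ``hr_scale=True`` — ``hr``,
    in which case the natural log is taken.
    """
    df = pd.read_csv(path, dtype={"trial_id": str, "database": str}, float_precision="round_trip")
    effect_col = "hr" if hr_scale else "log_hr"
    for col in ("trial_id", "source", "se", effect_col):
        if col not in df.columns:
            raise SchemaError(f"estimates table is missing required column {col!r}")
    if "database" not in df.columns:
        df["database"] = None

    out: list[TrialEstimate] = []
    seen: set[tuple] = set()
    for rec in df.itertuples(index=False):
        trial_id = str(rec.trial_id)
        try:
            source = Source(str(rec.source))
        except ValueError:
            raise ValidationError(
                f"trial {trial_id!r}: unknown source {rec.source!r} "
                f"(accepted: {', '.join(s.value for s in Source)})"
            ) from None
        effect = float(getattr(rec, effect_col))
        if hr_scale:
            if not effect > 0:
                raise ValidationError(f"trial {trial_id!r}: hr must be positive, got {effect}")
            log_hr = math.log(effect)
        else:
            log_hr = effect
        database = rec.database if isinstance(rec.database, str) and rec.database else None
        est = TrialEstimate(
            trial_id=trial_id,
            source=source,
            log_hr=log_hr,
            se=float(rec.se),
            database=database,
        )
        key = (est.trial_id, est.source, est.database)
        if key in seen:
            raise ValidationError(f"duplicate estimate for {key}")
        seen.add(key)
        out.append(est)
    return out


def write_estimates(estimates: Iterable[TrialEstimate], path) -> None:
    """Write estimates to CSV on the log scale (inverse of :func:`read_estimates`)."""
    df = pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in estimates],
            "source": [e.source.value for e in estimates],
            "database": [e.database or "" for e in estimates],
            "log_hr": [repr(e.log_hr) for e in estimates],
            "se": [repr(e.se) for e in estimates],
        }
    )
    df.to_csv(path, index=False)


def read_covariates(path) -> list[EmulationCovariates]:
    """Read the per-trial covariates table from CSV.

    Binary columns accept 0/1, yes/no or true/false (case-insensitive).
    Missing cells are rejected: the analysis assumes complete covariate data.
    """
    df = pd.read_csv(path, dtype={"trial_id": str}, float_precision="round_trip")
    for col in ("trial_id",) + CANDIDATE_COVARIATES:
        if col not in df.columns:
            raise SchemaError(f"covariates table is missing required column {col!r}")
    out: list[EmulationCovariates] = []
    seen: set[str] = set()
    for rec in df.to_dict("records"):
        trial_id = str(rec["trial_id"])
        if trial_id in seen:
            raise ValidationError(f"duplicate covariate row for trial {trial_id!r}")
        seen.add(trial_id)
        kwargs: dict[str, object] = {"trial_id": trial_id}
        for name in BINARY_COVARIATES:
            v = rec[name]
            if pd.isna(v):
                raise ValidationError(f"trial {trial_id!r}: missing value in column {name!r}")
            kwargs[name] = _coerce_binary(v, name, trial_id)
        for name in CONTINUOUS_COVARIATES:
            v = rec[name]
            if pd.isna(v):
                raise ValidationError(f"trial {trial_id!r}: missing value in column {name!r}")
            kwargs[name] = float(v)
        out.append(EmulationCovariates(**kwargs))  # type: ignore[arg-type]
    return out


def write_covariates(covariates: Iterable[EmulationCovariates], path) -> None:
    """Write covariates to CSV (inverse of :func:`read_covariates`)."""
    rows = []
    for c in covariates:
        row: dict[str, object] = {"trial_id": c.trial_id}
        for name in BINARY_COVARIATES:
            row[name] = int(getattr(c, name))
        for name in CONTINUOUS_COVARIATES:
            row[name] = repr(getattr(c, name))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derivation and assembly


def derive_close_emulation(cov: EmulationCovariates) -> int:
    """Composite indicator of a close emulation.

    A pair is a close emulation when at least one of the comparator or
    outcome emulations was rated good, and none of the four disqualifying
    design differences is present: in-hospital treatment start, a run-in
    window selecting responders to one arm, discontinuation of baseline
    therapy without washout, or a delayed treatment effect.
    """
    quality_ok = cov.comparator_good == 1 or cov.outcome_good == 1
    disqualified = any(getattr(cov, f) == 1 for f in _DISQUALIFYING_FLAGS)
    return int(quality_ok and not disqualified)


def with_close_emulation(cov: EmulationCovariates) -> EmulationCovariates:
    """Return a copy of ``cov`` with the derived composite flag set."""
    return replace(cov, close_emulation=derive_close_emulation(cov))


def assemble_pairs(
    estimates: Sequence[TrialEstimate],
    covariates: Sequence[EmulationCovariates],
    excluded: Sequence[str] = (),
) -> PairedDataset:
    """Match RCT and pooled-emulation estimates with covariates by trial.

    ``excluded`` lists trials already removed upstream (for example by the
    cross-database poolability gate); they are recorded on the dataset and
    not required to be complete.  Every remaining trial must contribute
    exactly one RCT estimate, one pooled estimate, and one covariate row.
    """
    excluded_set = set(excluded)
    by_trial: dict[str, dict[Source, TrialEstimate]] = {}
    for est in estimates:
        if est.trial_id in excluded_set or est.source is Source.RWE_DB:
            continue
        slot = by_trial.setdefault(est.trial_id, {})
        if est.source in slot:
            raise ValidationError(
                f"trial {est.trial_id!r}: duplicate {est.source.value} estimate"
            )
        slot[est.source] = est
    cov_by_trial = {c.trial_id: c for c in covariates if c.trial_id not in excluded_set}

    missing_cov = sorted(t for t in by_trial if t not in cov_by_trial)
    missing_est = sorted(
        t
        for t in cov_by_trial
        if t not in by_trial
        or Source.RCT not in by_trial[t]
        or Source.RWE_POOLED not in by_trial[t]
    )
    if missing_cov or missing_est:
        parts = []
        if missing_cov:
            parts.append(f"trials without covariates: {missing_cov}")
        if missing_est:
            parts.append(f"trials without a complete estimate pair: {missing_est}")
        raise ValidationError("; ".join(parts))

    pairs = tuple(
        StudyPair(
            trial_id=t,
            rct=by_trial[t][Source.RCT],
            rwe_pooled=by_trial[t][Source.RWE_POOLED],
            covariates=with_close_emulation(cov_by_trial[t]),
        )
        for t in sorted(by_trial)
    )
    return PairedDataset(pairs=pairs, excluded=tuple(sorted(excluded_set)))
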