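"""Cohort data model for competing-risks analysis.

A cohort is one row per subject with a follow-up time in days, an integer
event code, a treatment-arm label, and baseline covariates.  Event coding
follows the conventional competing-risks scheme:

* ``0`` — censored (lost to follow-up, administrative end of study, or a
  censoring event such as a subsequent therapy),
* ``1`` — the event of interest (e.g. a urinary adverse event),
* ``2`` — the competing event (e.g. death), with codes ``3..K`` available
  for additional competing causes.

Times are kept in days throughout; no internal rescaling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

#: event code for censored observations
CENSORED = 0
#: event code for the event of interest
EVENT_OF_INTEREST = 1
#: event code for the (first) competing event
COMPETING_EVENT = 2

REQUIRED_COLUMNS = ("subject_id", "time", "event", "arm")


class CohortError(ValueError):
    """Raised when a cohort table violates its schema or invariants."""


@dataclass
class CohortTable:
    """Subject-level cohort: times, event codes, arms, covariates.

    Parameters
    ----------
    data
        One row per subject.  Must contain columns ``subject_id``, ``time``
        (positive, days), ``event`` (integer code), ``arm`` (label), and may
        contain ``weight`` plus arbitrary covariate columns.
    reference_arm
        The designated reference / control arm.
    covariates
        Names of the covariate columns used by downstream modelling.  If
        omitted, every column that is not structural is treated as a
        covariate.
    max_cause
        Largest admissible event code (``2`` for the standard two-cause
        setting; raise it for K competing causes).
    """

    data: pd.DataFrame
    reference_arm: str
    covariates: list[str] = field(default_factory=list)
    max_cause: int = 2

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if not self.covariates:
            structural = set(REQUIRED_COLUMNS) | {"weight"}
            self.covariates = [c for c in self.data.columns if c not in structural]
        findings = validate_cohort(self)
        if findings:
            raise CohortError("invalid cohort: " + "; ".join(findings))

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def arm(self) -> pd.Series:
        return self.data["arm"]

    @property
    def arms(self) -> list[str]:
        """Arm labels, reference first, others in order of appearance."""
        seen = list(dict.fromkeys(self.data["arm"].astype(str)))
        others = [a for a in seen if a != self.reference_arm]
        return [self.reference_arm] + others

    @property
    def has_weights(self) -> bool:
        return "weight" in self.data.columns

    @property
    def weight(self) -> np.ndarray:
        if self.has_weights:
            return self.data["weight"].to_numpy(dtype=float)
        return np.ones(self.n)

    def with_weights(self, weights: Sequence[float]) -> "CohortTable":
        """Return a copy carrying ``weights`` in the ``weight`` column."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n,):
            raise CohortError(f"expected {self.n} weights, got {w.shape}")
        df = self.data.copy()
        df["weight"] = w
        return replace(self, data=df)

    def subset(self, mask) -> "CohortTable":
        """Row subset (boolean mask or index array); keeps metadata."""
        mask = np.asarray(mask)
        df = self.data.loc[mask] if mask.dtype == bool else self.data.iloc[mask]
        df = df.reset_index(drop=True)
        present = set(df["arm"].astype(str))
        # a subset may drop the reference arm (e.g. per-arm curves); re-point it
        ref = self.reference_arm if str(self.reference_arm) in present else str(df["arm"].iloc[0])
        return CohortTable(
            df,
            reference_arm=ref,
            covariates=list(self.covariates),
            max_cause=self.max_cause,
        )

    def resample(self, rng: np.random.Generator) -> "CohortTable":
        """Subject-level bootstrap resample (with replacement, same n)."""
        idx = rng.integers(0, self.n, size=self.n)
        df = self.data.iloc[idx].reset_index(drop=True)
        # resampled subjects get fresh unique ids so downstream joins stay 1:1
        df["subject_id"] = np.arange(self.n)
        return replace(self, data=df)


def validate_cohort(cohort: CohortTable) -> list[str]:
    """Check cohort invariants; return one finding per violation.

    An empty list means the table is valid.  The input is never mutated.
    """
    findings: list[str] = []
    df = cohort.data
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            findings.append(f"missing required column '{col}'")
    if findings:
        return findings

    for col in ("time", "event", "arm"):
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()[:5]
            findings.append(f"missing values in '{col}' (rows {rows})")
    times = pd.to_numeric(df["time"], errors="coerce")
    bad_t = df.index[~(times > 0)].tolist()
    if bad_t:
        findings.append(f"non-positive or unparseable time in rows {bad_t[:5]}")
    events = pd.to_numeric(df["event"], errors="coerce")
    valid_codes = set(range(cohort.max_cause + 1))
    bad_e = df.index[~events.isin(valid_codes)].tolist()
    if bad_e:
        findings.append(
            f"event codes outside {sorted(valid_codes)} in rows {bad_e[:5]}"
        )
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
        findings.append(f"duplicate subject_id values: {dup}")
    if str(cohort.reference_arm) not in set(df["arm"].astype(str)):
        findings.append(f"reference arm '{cohort.reference_arm}' absent from data")
    if "weight" in df.columns:
        w = pd.to_numeric(df["weight"], errors="coerce")
        bad_w = df.index[~(w > 0)].tolist()
        if bad_w:
            findings.append(f"non-positive weight in rows {bad_w[:5]}")
    return findings


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    reference_arm: str,
    covariates: Sequence[str] | None = None,
    categories: Mapping[str, Sequence[str]] | None = None,
    max_cause: int = 2,
) -> CohortTable:
    """Read a cohort from a headed CSV file.

    Parameters
    ----------
    path
        CSV file (comma separated, UTF-8, header row).
    schema
        Mapping from canonical names (``time``, ``event``, ``arm``,
        ``subject_id``, ``weight``) to the column names in the file.
        Unmapped canonical names are assumed to match literally.
    reference_arm
        Label of the control arm.
    covariates
        Covariate columns to retain; default: everything else.
    categories
        Declared level order for categorical covariates; levels are
        preserved as ordered pandas categoricals.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such file: {path}")
    df = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise CohortError(f"schema maps to missing column(s): {missing}")
    df = df.rename(columns=rename)
    for col in ("time", "event", "arm"):
        if col not in df.columns:
            raise CohortError(f"missing required column '{col}'")
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", np.arange(len(df)))

    times = pd.to_numeric(df["time"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        raise CohortError(f"unparseable time at data row(s) {bad.tolist()[:5]}")
    df["time"] = times.astype(float)
    df["event"] = pd.to_numeric(df["event"], errors="coerce")

    if categories:
        for col, levels in categories.items():
            df[col] = pd.Categorical(df[col], categories=list(levels))
    keep = list(covariates) if covariates is not None else None
    if keep is not None:
        cols = [c for c in ("subject_id", "time", "event", "arm", "weight") if c in df.columns]
        df = df[cols + keep]
    return CohortTable(
        df,
        reference_arm=reference_arm,
        covariates=list(keep) if keep is not None else [],
        max_cause=max_cause,
    )


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV (header, comma separated, UTF-8)."""
    cohort.data.to_csv(path, index=False)
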