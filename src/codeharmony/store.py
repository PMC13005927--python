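"""Data model and I/O for coded EHR events, covariates, code groups, and
derived per-patient matrices.

The on-disk formats are deliberately plain: comma-delimited UTF-8 with a
header row and ISO-8601 dates.  Events are day-granular; time-of-day is
never recorded because every downstream computation (rates, co-occurrence
windows) operates on calendar days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CODE_TYPES = ("ICD9", "ICD10", "CPT", "LOINC", "HCPCS", "REVENUE", "LOCAL", "OTHER")

COVARIATE_COLUMNS = ("person_time", "age", "sex", "insulin_use", "elixhauser")

EVENT_COLUMNS = ("patient_id", "date", "code", "code_type")

#: Matrix transforms understood by :func:`patient_code_matrix`.
TRANSFORMS = ("count", "rate", "log1p_count", "binary")

UNGROUPED = "ungrouped"


class FormatError(ValueError):
    """A file does not conform to the expected delimited layout."""


@dataclass
class EventTable:
    """Longitudinal coded events for one site.

    ``frame`` has columns ``patient_id`` (str), ``date`` (datetime64[ns],
    day granularity), ``code`` (str, nonempty), ``code_type`` (one of
    :data:`CODE_TYPES`).
    """

    site_id: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        if len(self.frame) and (self.frame["code"].astype(str) == "").any():
            raise ValueError("empty code string in event table")
        bad = set(self.frame["code_type"].unique()) - set(CODE_TYPES)
        if bad:
            raise ValueError(f"unknown code_type values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def codes(self) -> pd.Series:
        return self.frame["code"]


@dataclass
class CovariateTable:
    """One row per patient: person_time (years > 0), age, sex, insulin_use,
    elixhauser.  Indexed by ``patient_id``.  Missing values are rejected,
    not imputed."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"covariate table missing columns: {missing}")
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient rows: {dupes[:5]}")
        if self.frame[list(COVARIATE_COLUMNS)].isna().any().any():
            raise ValueError("missing covariate values are not supported")
        if (self.frame["person_time"] <= 0).any():
            raise ValueError("person_time must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patients(self) -> pd.Index:
        return self.frame.index

    @property
    def person_time(self) -> pd.Series:
        return self.frame["person_time"]

    def design_matrix(self, include_person_time: bool = True) -> np.ndarray:
        """Covariate matrix Z in a fixed column order (no intercept)."""
        cols = ["age", "sex", "insulin_use", "elixhauser"]
        if include_person_time:
            cols.append("person_time")
        return self.frame[cols].to_numpy(dtype=float)


@dataclass
class GroupCatalog:
    """Bidirectional code <-> clinical-category lookup (phecode-style for
    diagnoses, CCS-style for procedures).  A code belongs to at most one
    group; codes absent from the catalog report :data:`UNGROUPED`."""

    code_to_group: dict[str, str] = field(default_factory=dict)

    def group_of(self, code: str) -> str:
        return self.code_to_group.get(code, UNGROUPED)

    @property
    def group_to_codes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for code, g in self.code_to_group.items():
            out.setdefault(g, []).append(code)
        for g in out:
            out[g].sort()
        return out

    def members(self, group_id: str) -> list[str]:
        return self.group_to_codes.get(group_id, [])

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.code_to_group.values()))


@dataclass
class FrequencyTable:
    """Per-code endorsement totals for one site together with the site's
    total person-time, so that rate = frequency / person_time."""

    site_id: str
    frame: pd.DataFrame  # index: code; columns: frequency, rate
    person_time: float  # total person-years across all cohort members

    def frequency(self, code: str) -> int:
        if code in self.frame.index:
            return int(self.frame.loc[code, "frequency"])
        return 0

    def rate(self, code: str) -> float:
        return self.frequency(code) / self.person_time

    def nonrare_codes(self, min_frequency: int = 10) -> list[str]:
        keep = self.frame.index[self.frame["frequency"] >= min_frequency]
        return sorted(keep)


@dataclass
class CodeMatrix:
    """Patients x codes numeric matrix with a transform tag."""

    values: np.ndarray
    patients: list[str]
    vocabulary: list[str]
    transform: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patients), len(self.vocabulary)):
            raise ValueError("matrix shape does not match patients x vocabulary")
        if (self.values < 0).any():
            raise ValueError("code matrix entries must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patients, columns=self.vocabulary)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_events(path: str | Path, site_id: str) -> EventTable:
    """Read a delimited event file into an :class:`EventTable`.

    Unknown ``code_type`` values are coerced to ``OTHER`` with a warning so
    that feeds containing e.g. drug codes do not abort a run.  Unparseable
    dates abort with the offending line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        # +2: one for the header, one for 0-based positions
        lines = (np.flatnonzero(dates.isna().to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: unparseable date on line(s) {lines[:20]}")
    ct = df["code_type"].str.upper()
    unknown = ~ct.isin(CODE_TYPES)
    if unknown.any():
        bad = sorted(ct[unknown].unique())
        warnings.warn(
            f"{path}: coercing unknown code_type values {bad} to OTHER", stacklevel=2
        )
        ct = ct.where(~unknown, "OTHER")
    frame = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "date": dates.dt.normalize(),
            "code": df["code"],
            "code_type": ct,
        }
    )
    return EventTable(site_id=site_id, frame=frame)


def write_events(events: EventTable, path: str | Path) -> None:
    out = events.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_covariates(path: str | Path) -> CovariateTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise FormatError(f"{path}: missing required column patient_id")
    df = df.set_index("patient_id")
    return CovariateTable(frame=df)


def write_covariates(covars: CovariateTable, path: str | Path) -> None:
    covars.frame.reset_index().rename(columns={"index": "patient_id"}).to_csv(
        path, index=False
    )


def read_code_groups(path: str | Path) -> GroupCatalog:
    """Read a (code, group_id) file; conflicting duplicate assignments are an
    error naming the code."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return GroupCatalog()
    for col in ("code", "group_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    mapping: dict[str, str] = {}
    for code, gid in zip(df["code"], df["group_id"]):
        if code in mapping and mapping[code] != gid:
            raise ValueError(
                f"code {code!r} assigned to conflicting groups "
                f"{mapping[code]!r} and {gid!r}"
            )
        mapping[code] = gid
    return GroupCatalog(code_to_group=mapping)


def write_code_groups(catalog: GroupCatalog, path: str | Path) -> None:
    rows = sorted(catalog.code_to_group.items())
    pd.DataFrame(rows, columns=["code", "group_id"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived summaries
# ---------------------------------------------------------------------------


def summarize_frequencies(events: EventTable, covars: CovariateTable) -> FrequencyTable:
    """Per-code endorsement totals and the site's total person-time.

    Every covariate-table patient contributes person-time, including
    patients with no events; every event row counts as one endorsement
    (repeat endorsements on the same day count multiply).
    """
    _check_patients(events, covars)
    pt = float(covars.person_time.sum())
    counts = events.frame["code"].value_counts().sort_index()
    frame = pd.DataFrame({"frequency": counts.astype(int)})
    frame["rate"] = frame["frequency"] / pt
    frame.index.name = "code"
    return FrequencyTable(site_id=events.site_id, frame=frame, person_time=pt)


def patient_code_matrix(
    events: EventTable,
    covars: CovariateTable,
    vocab: list[str],
    transform: str = "count",
) -> CodeMatrix:
    """Patients x vocab matrix of endorsement counts under ``transform``.

    ``rate`` divides each patient's counts by their person-time; codes
    outside ``vocab`` are ignored.  Row order follows the covariate table
    (so zero-event patients appear as zero rows).
    """
    if not vocab:
        raise ValueError("vocab must be nonempty")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")
    _check_patients(events, covars)
    patients = list(covars.patients)
    p_index = {p: i for i, p in enumerate(patients)}
    v_index = {c: j for j, c in enumerate(vocab)}
    mat = np.zeros((len(patients), len(vocab)))
    ev = events.frame
    keep = ev["code"].isin(v_index)
    rows = ev.loc[keep, "patient_id"].map(p_index).to_numpy()
    cols = ev.loc[keep, "code"].map(v_index).to_numpy()
    np.add.at(mat, (rows, cols), 1.0)
    if transform == "rate":
        mat = mat / covars.person_time.to_numpy()[:, None]
    elif transform == "log1p_count":
        mat = np.log1p(mat)
    elif transform == "binary":
        mat = (mat > 0).astype(float)
    return CodeMatrix(values=mat, patients=patients, vocabulary=list(vocab), transform=transform)


def _check_patients(events: EventTable, covars: CovariateTable) -> None:
    event_patients = set(events.frame["patient_id"].unique())
    absent = event_patients - set(covars.patients)
    if absent:
        raise ValueError(
            f"event patients missing from covariate table: {sorted(absent)[:5]}"
        )
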