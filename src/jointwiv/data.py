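"""Data containers and validated CSV input/output.

Longitudinal CSV columns: ``id,time,biomarker,value`` (biomarker coded
1..K; missing values are simply absent rows).  Survival CSV columns:
``id,entry,time,event,<covariate columns...>`` with event in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LONG_COLUMNS = ["id", "time", "biomarker", "value"]
SURV_COLUMNS = ["id", "entry", "time", "event"]


class DataValidationError(ValueError):
    """Raised when input tables violate the data contract."""


@dataclass
class LongitudinalDataset:
    """Long-format biomarker measurements: one row per subject/visit/biomarker."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"longitudinal table missing columns {missing}")
        df = self.table
        if len(df) == 0:
            raise DataValidationError("longitudinal table is empty")
        t = df["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise DataValidationError("visit times must be finite and nonnegative")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise DataValidationError("biomarker values must be finite")
        k = df["biomarker"].to_numpy()
        if not np.array_equal(k, k.astype(int)) or k.min() < 1:
            raise DataValidationError("biomarker index must be an integer >= 1")
        dup = df.duplicated(subset=["id", "time", "biomarker"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise DataValidationError(f"duplicate (id,time,biomarker) rows: {rows}")
        # keep visits sorted within subject
        self.table = df.sort_values(["id", "time", "biomarker"]).reset_index(drop=True)

    @property
    def n_biomarkers(self) -> int:
        return int(self.table["biomarker"].max())

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.subject_ids.size

    def last_visit_times(self) -> pd.Series:
        return self.table.groupby("id")["time"].max()

    def for_biomarker(self, k: int) -> pd.DataFrame:
        return self.table[self.table["biomarker"] == k]


@dataclass
class SurvivalData:
    """One row per subject: entry (left-truncation) time, observed time,
    event indicator, and baseline covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SURV_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"survival table missing columns {missing}")
        df = self.table
        if df["id"].duplicated().any():
            raise DataValidationError("duplicate subject ids in survival table")
        entry = df["entry"].to_numpy(dtype=float)
        time = df["time"].to_numpy(dtype=float)
        if np.any(entry < 0) or not np.all(np.isfinite(entry)):
            raise DataValidationError("entry times must be finite and nonnegative")
        if not np.all(np.isfinite(time)):
            raise DataValidationError("observed times must be finite")
        bad = np.flatnonzero(entry > time)
        if bad.size:
            raise DataValidationError(
                f"entry time exceeds observed time for rows {bad.tolist()[:5]}"
            )
        ev = df["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise DataValidationError("event indicator must be 0 or 1")
        self.table = df.reset_index(drop=True)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in SURV_COLUMNS]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.table)


# convenience record view used by the closure-style likelihood functions
@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: object
    entry_time: float
    observed_time: float
    event: int
    covariates: np.ndarray

    def __post_init__(self) -> None:
        if self.entry_time > self.observed_time:
            raise ValueError("entry time exceeds observed time")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


def survival_records(surv: SurvivalData) -> list[SurvivalRecord]:
    names = surv.covariate_names
    out = []
    for _, row in surv.table.iterrows():
        out.append(
            SurvivalRecord(
                subject_id=row["id"],
                entry_time=float(row["entry"]),
                observed_time=float(row["time"]),
                event=int(row["event"]),
                covariates=row[names].to_numpy(dtype=float),
            )
        )
    return out


def validate_joint(
    long_data: LongitudinalDataset, surv_data: SurvivalData
) -> None:
    """Cross-checks between the two tables; raises with row-level messages."""
    long_ids = set(long_data.table["id"])
    surv_ids = set(surv_data.table["id"])
    orphans = long_ids - surv_ids
    if orphans:
        raise DataValidationError(
            f"longitudinal subjects absent from survival table: {sorted(orphans)[:5]}"
        )
    obs_time = surv_data.table.set_index("id")["time"]
    last = long_data.last_visit_times()
    late = last[last > obs_time.reindex(last.index) + 1e-12]
    if len(late):
        sid = late.index[0]
        raise DataValidationError(
            f"subject {sid!r} has a longitudinal visit at t={late.iloc[0]:g} "
            f"after its observed time {obs_time[sid]:g}"
        )


def read_joint_data(
    long_path, surv_path
) -> tuple[LongitudinalDataset, SurvivalData]:
    """Read and cross-validate the longitudinal and survival CSVs."""
    long_data = LongitudinalDataset(pd.read_csv(long_path))
    surv_data = SurvivalData(pd.read_csv(surv_path))
    validate_joint(long_data, surv_data)
    return long_data, surv_data


def write_joint_data(
    long_data: LongitudinalDataset, surv_data: SurvivalData, long_path, surv_path
) -> None:
    long_data.table.to_csv(long_path, index=False)
    surv_data.table.to_csv(surv_path, index=False)
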