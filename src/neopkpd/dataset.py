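"""NONMEM-style longitudinal PK dataset container and CSV I/O.

Columns: ``ID, TIME, EVID, AMT, DUR, DV, MDV, GA, BW`` — dose rows have
EVID=1 with AMT (mg) and DUR (h); observation rows have EVID=0, MDV=0 and DV
(mg/L). GA is gestational age in weeks, BW birth weight in kg; both are
subject-constant. TIME is hours since birth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .population import VirtualSubject
from .regimens import DoseEvent, DoseSchedule

COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "GA", "BW"]


@dataclass
class ObservationDataset:
    """Validated dose + observation records for a study population."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        errors = self.validate()
        if errors:
            listing = "\n".join(errors[:20])
            raise ValueError(f"invalid observation dataset:\n{listing}")

    def validate(self) -> list[str]:
        """Row-level validation; returns a list of error strings (empty = valid)."""
        df = self.records
        errors: list[str] = []
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            return [f"missing columns: {missing}"]
        if (df["TIME"] < 0).any():
            errors.append("negative TIME values present")
        for sid, sub in df.groupby("ID", sort=False):
            times = sub["TIME"].to_numpy()
            if np.any(np.diff(times) < 0):
                errors.append(f"subject {sid}: records not sorted by TIME")
            doses = sub[sub["EVID"] == 1]
            obs = sub[(sub["EVID"] == 0) & (sub["MDV"] == 0)]
            if (doses["AMT"] <= 0).any() or (doses["DUR"] <= 0).any():
                errors.append(f"subject {sid}: dose rows need AMT > 0 and DUR > 0")
            if obs.empty and doses.empty:
                errors.append(f"subject {sid}: no records")
            if not obs.empty:
                if doses.empty:
                    errors.append(f"subject {sid}: observations without any dose")
                elif obs["TIME"].min() < doses["TIME"].min():
                    errors.append(f"subject {sid}: observation precedes first dose")
                if (obs["DV"] <= 0).any():
                    errors.append(f"subject {sid}: non-positive DV in observation rows")
            if sub["GA"].nunique() > 1 or sub["BW"].nunique() > 1:
                errors.append(f"subject {sid}: GA/BW must be subject-constant")
            if (sub["GA"] <= 0).any() or (sub["BW"] <= 0).any():
                errors.append(f"subject {sid}: GA and BW must be positive")
        return errors

    @property
    def subject_ids(self) -> list:
        return list(self.records["ID"].drop_duplicates())

    @property
    def n_observations(self) -> int:
        df = self.records
        return int(((df["EVID"] == 0) & (df["MDV"] == 0)).sum())

    def iter_subjects(self) -> Iterator[tuple[object, pd.DataFrame]]:
        for sid, sub in self.records.groupby("ID", sort=False):
            yield sid, sub

    def subject(self, sid) -> "SubjectRecords":
        sub = self.records[self.records["ID"] == sid]
        if sub.empty:
            raise KeyError(f"no records for subject {sid}")
        return SubjectRecords(sub)


@dataclass
class SubjectRecords:
    """One subject's slice of the dataset, with PK-model-ready views."""

    records: pd.DataFrame

    @property
    def virtual_subject(self) -> VirtualSubject:
        row = self.records.iloc[0]
        return VirtualSubject(
            subject_id=str(row["ID"]), ga_weeks=float(row["GA"]), birth_weight=float(row["BW"])
        )

    @property
    def schedule(self) -> DoseSchedule:
        doses = self.records[self.records["EVID"] == 1]
        events = [
            DoseEvent(float(r["TIME"]), float(r["AMT"]), float(r["DUR"]))
            for _, r in doses.iterrows()
        ]
        return DoseSchedule(str(self.records.iloc[0]["ID"]), events)

    @property
    def observation_times(self) -> np.ndarray:
        obs = self.records[(self.records["EVID"] == 0) & (self.records["MDV"] == 0)]
        return obs["TIME"].to_numpy(dtype=float)

    @property
    def dv(self) -> np.ndarray:
        obs = self.records[(self.records["EVID"] == 0) & (self.records["MDV"] == 0)]
        return obs["DV"].to_numpy(dtype=float)


def read_dataset(path: str | Path) -> ObservationDataset:
    """Read and validate a NONMEM-style CSV."""
    df = pd.read_csv(path, na_values=["."])
    df["DV"] = df["DV"].fillna(0.0)
    return ObservationDataset(df)


def write_dataset(dataset: ObservationDataset, path: str | Path) -> None:
    """Write to CSV; round-trips through :func:`read_dataset`."""
    cols = COLUMNS + [c for c in dataset.records.columns if c not in COLUMNS]
    dataset.records[cols].to_csv(path, index=False)
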