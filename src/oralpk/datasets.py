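"""Long-format oral PK datasets (NONMEM-style columns).

A study is a delimited text table with one row per observation and columns

    ID    subject identifier
    TIME  sampling time after the oral dose (h), strictly increasing per subject
    DV    observed plasma concentration (missing rows flagged via MDV)
    DOSE  administered oral dose (carried on every row; single dose per subject)
    MDV   optional missing-data flag (1 = row excluded from the likelihood)

Comma- or tab-delimited files are auto-detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["SubjectRecords", "StudyDataset", "read_dataset", "write_dataset"]

REQUIRED_COLUMNS = ("ID", "TIME", "DV", "DOSE")


@dataclass(frozen=True)
class SubjectRecords:
    """Observed records of one subject (MDV rows already excluded)."""

    subject_id: str
    times: np.ndarray
    conc: np.ndarray
    dose: float


@dataclass(frozen=True)
class StudyDataset:
    """Validated multi-subject oral concentration-time dataset."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if "MDV" not in df.columns:
            df = df.copy()
            df["MDV"] = 0
            object.__setattr__(self, "frame", df)
        if (df["TIME"] < 0).any():
            rows = df.index[df["TIME"] < 0].tolist()
            raise ValueError(f"negative TIME values at rows {rows}")
        obs = df[df["MDV"] == 0]
        if (obs["DV"] < 0).any():
            rows = obs.index[obs["DV"] < 0].tolist()
            raise ValueError(f"negative DV values at rows {rows} (flag with MDV=1)")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"TIME not strictly increasing within subject {sid!r}"
                )
            d = g["DOSE"].to_numpy(dtype=float)
            if not np.all(d > 0):
                raise ValueError(f"subject {sid!r} has a non-positive DOSE")
            if np.ptp(d) != 0:
                raise ValueError(f"subject {sid!r} has varying DOSE values")

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.frame["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subjects(self) -> Iterator[SubjectRecords]:
        """Iterate observed (MDV = 0) records per subject."""
        for sid, g in self.frame.groupby("ID", sort=False):
            obs = g[g["MDV"] == 0]
            yield SubjectRecords(
                subject_id=sid,
                times=obs["TIME"].to_numpy(dtype=float),
                conc=obs["DV"].to_numpy(dtype=float),
                dose=float(g["DOSE"].iloc[0]),
            )


def read_dataset(path, sep: str | None = None, metadata: dict | None = None) -> StudyDataset:
    """Read a delimited long-format study file (delimiter auto-detected)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    try:
        return StudyDataset(frame=df, metadata=metadata or {"source": str(path)})
    except ValueError as exc:
        raise ValueError(f"{Path(path).name}: {exc}") from exc


def write_dataset(dataset: StudyDataset, path, sep: str = ",") -> None:
    dataset.frame.to_csv(path, sep=sep, index=False)
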