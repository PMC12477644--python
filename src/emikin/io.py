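"""Tidy time-course dataset container and CSV round-trip.

One schema serves observed and synthetic data alike: one row per
(condition, replicate, time) with the full condition description inlined
so a file is self-contained.  Lipid is carried in uM (converted to site
concentrations only inside design construction); all other concentrations
are nM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCHEMA = [
    "condition_id",
    "M_nM",
    "FX_nM",
    "FIXa_nM",
    "TFVIIa_nM",
    "lipid_uM",
    "replicate",
    "time_s",
    "readout",
    "value_nM",
]

READOUTS = ("total_FXa", "chromophore")


class SchemaError(ValueError):
    pass


def validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    bad = frame.index[~frame["readout"].isin(READOUTS)].tolist()
    if bad:
        raise SchemaError(f"unknown readout at row(s) {bad[:10]}")
    for col in ("M_nM", "FX_nM", "FIXa_nM", "TFVIIa_nM", "lipid_uM",
                "time_s", "value_nM"):
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()].tolist()
        if bad:
            raise SchemaError(f"non-numeric {col} at row(s) {bad[:10]}")
        neg = frame.index[frame[col].astype(float) < 0].tolist()
        if neg:
            raise SchemaError(f"negative {col} at row(s) {neg[:10]}")


@dataclass
class TimecourseData:
    """Observed or synthetic readout time courses with replicate structure."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        validate_frame(self.frame)
        self.frame = self.frame[SCHEMA].copy()

    def conditions(self) -> pd.DataFrame:
        """One row per condition with its concentration settings."""
        cols = ["condition_id", "M_nM", "FX_nM", "FIXa_nM", "TFVIIa_nM",
                "lipid_uM", "readout"]
        return self.frame[cols].drop_duplicates().reset_index(drop=True)

    def condition(self, condition_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["condition_id"] == condition_id]
        if sub.empty:
            raise KeyError(f"no rows for condition {condition_id!r}")
        return sub

    def __len__(self):
        return len(self.frame)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_timecourses(data: TimecourseData, path) -> None:
    path = Path(path)
    data.frame.to_csv(path, index=False)
    if data.meta:
        _meta_path(path).write_text(json.dumps(data.meta, indent=1, default=str))


def read_timecourses(path) -> TimecourseData:
    path = Path(path)
    frame = pd.read_csv(path)
    validate_frame(frame)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    return TimecourseData(frame=frame, meta=meta)
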