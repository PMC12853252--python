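"""Binocular eye-tracker sample records.

The single ingestion format is a 1,000 Hz CSV with one row per millisecond:
``time_ms, xl, yl, pl, vl, xr, yr, pr, vr`` (gaze x/y in pixels, pupil
diameter in arbitrary units, validity flag 0/1 per eye).  Real exports (e.g.
EyeLink ASC sample lines) can be converted to this schema externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COLUMNS = ["time_ms", "xl", "yl", "pl", "vl", "xr", "yr", "pr", "vr"]


@dataclass
class SampleTrace:
    """One block of binocular samples at a fixed 1 ms step."""

    time_ms: np.ndarray
    xl: np.ndarray
    yl: np.ndarray
    pl: np.ndarray
    vl: np.ndarray   # bool: sample valid (eye open / tracked)
    xr: np.ndarray
    yr: np.ndarray
    pr: np.ndarray
    vr: np.ndarray

    fs_hz: int = 1000

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=np.int64)
        for name in ("xl", "yl", "pl", "xr", "yr", "pr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.vl = np.asarray(self.vl, dtype=bool)
        self.vr = np.asarray(self.vr, dtype=bool)
        n = self.time_ms.size
        for name in COLUMNS[1:]:
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.time_ms) == 1):
            raise ValueError("timestamps must increase in 1 ms steps")

    def __len__(self):
        return self.time_ms.size

    def eye(self, which: str):
        """(gaze_x, gaze_y, pupil, valid) for ``which`` in {'left','right'}."""
        if which == "left":
            return self.xl, self.yl, self.pl, self.vl
        if which == "right":
            return self.xr, self.yr, self.pr, self.vr
        raise ValueError(f"unknown eye {which!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.time_ms,
            "xl": self.xl, "yl": self.yl, "pl": self.pl,
            "vl": self.vl.astype(int),
            "xr": self.xr, "yr": self.yr, "pr": self.pr,
            "vr": self.vr.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTrace":
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(**{c: df[c].to_numpy() for c in COLUMNS})

    @classmethod
    def from_csv(cls, path) -> "SampleTrace":
        return cls.from_frame(pd.read_csv(path))
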