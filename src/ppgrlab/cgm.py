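"""CGM traces on a regular 5-minute grid.

A continuous glucose monitor samples interstitial glucose every 5 minutes.
Each patient's trace is stored as a :class:`CgmSeries`: a start timestamp
anchored on a 5-minute boundary plus one value (or NaN for a dropped
sample) per grid slot.  All downstream computation — gap imputation,
postprandial windows, response metrics — works on this grid.

Canonical unit is mg/dL; mmol/L inputs are converted once at load time
(factor 18.016) and never again.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: minutes between consecutive grid slots
GRID_MINUTES = 5

#: sensor-plausible glucose range, mg/dL; readings outside are rejected
GLUCOSE_MIN, GLUCOSE_MAX = 20.0, 600.0

#: mg/dL per mmol/L (molar mass of glucose / 10)
MMOL_TO_MGDL = 18.016

MISSING = float("nan")


class CgmLoadError(ValueError):
    """Raised when a CGM file cannot be parsed into valid series."""


@dataclass
class CgmSeries:
    """One patient's glucose trace on the 5-minute grid.

    ``values[k]`` is the reading at ``start + 5*k`` minutes, in mg/dL,
    or NaN where the sensor produced no sample.
    """

    patient_id: str
    start: pd.Timestamp
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        if self.start != self.start.floor(f"{GRID_MINUTES}min"):
            raise ValueError(
                f"series start {self.start} not on the {GRID_MINUTES}-minute grid"
            )
        self.values = np.asarray(self.values, dtype=float)
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (
            observed.min() < GLUCOSE_MIN or observed.max() > GLUCOSE_MAX
        ):
            raise ValueError(
                f"glucose values outside sensor range [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mg/dL"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp one slot past the last value (half-open span)."""
        return self.start + pd.Timedelta(minutes=GRID_MINUTES * len(self.values))

    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.values)) * GRID_MINUTES, unit="min"
        )

    def slot_of(self, t: pd.Timestamp) -> int:
        """Grid slot index of timestamp ``t`` (may lie outside the span).

        ``t`` must sit exactly on the grid.
        """
        t = pd.Timestamp(t)
        delta = (t - self.start).total_seconds() / 60.0
        if delta % GRID_MINUTES != 0:
            raise ValueError(f"{t} is not on this series' {GRID_MINUTES}-minute grid")
        return int(delta // GRID_MINUTES)

    def window(
        self, t0: pd.Timestamp, offset_start: int, offset_end: int
    ) -> np.ndarray:
        """Values in the half-open window ``[t0+offset_start, t0+offset_end)``.

        Offsets are minutes and must be multiples of the grid cadence.
        Slots outside the recorded span are returned as NaN — callers
        decide whether partial coverage is acceptable.
        """
        if offset_start >= offset_end:
            raise ValueError("offset_start must be < offset_end")
        if offset_start % GRID_MINUTES or offset_end % GRID_MINUTES:
            raise ValueError("window offsets must be multiples of the grid cadence")
        k0 = self.slot_of(pd.Timestamp(t0) + pd.Timedelta(minutes=offset_start))
        n = (offset_end - offset_start) // GRID_MINUTES
        out = np.full(n, np.nan)
        lo, hi = max(k0, 0), min(k0 + n, len(self.values))
        if hi > lo:
            out[lo - k0 : hi - k0] = self.values[lo:hi]
        return out

    def window_times(
        self, t0: pd.Timestamp, offset_start: int, offset_end: int
    ) -> pd.DatetimeIndex:
        n = (offset_end - offset_start) // GRID_MINUTES
        return (
            pd.Timestamp(t0)
            + pd.Timedelta(minutes=offset_start)
            + pd.to_timedelta(np.arange(n) * GRID_MINUTES, unit="min")
        )


@dataclass
class GapReport:
    """Maximal runs of missing slots in a series."""

    runs: list[tuple[int, int]] = field(default_factory=list)  # (start_slot, length)
    total_missing_fraction: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "runs": [{"start_slot": s, "length": n} for s, n in self.runs],
                "total_missing_fraction": self.total_missing_fraction,
            }
        )


def detect_gaps(series: CgmSeries) -> GapReport:
    """Locate maximal missing runs and the overall missing fraction."""
    miss = np.isnan(series.values)
    if len(miss) == 0:
        return GapReport([], 0.0)
    # run boundaries: slots where missingness flips
    padded = np.concatenate([[False], miss, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    runs = [(int(s), int(e - s)) for s, e in zip(starts, ends)]
    return GapReport(runs, float(miss.mean()))


def _snap_slot(t: pd.Timestamp, anchor: pd.Timestamp) -> int:
    """Nearest grid slot for a raw timestamp; 2.5-minute ties round up."""
    delta = (t - anchor).total_seconds() / 60.0
    return int(np.floor(delta / GRID_MINUTES + 0.5))


def load_cgm(path: str | Path, unit: str = "mgdl") -> dict[str, CgmSeries]:
    """Read a delimited CGM file into per-patient series.

    Expected header: ``patient_id,timestamp,glucose`` with ISO-8601
    timestamps.  Readings snap to a 5-minute grid anchored at each
    patient's earliest reading (rounded down to a grid boundary); slots
    with no reading are missing.  ``unit`` is ``mgdl`` or ``mmol``
    (converted at this boundary only).
    """
    if unit not in ("mgdl", "mmol"):
        raise ValueError(f"unknown unit {unit!r}; expected 'mgdl' or 'mmol'")
    df = pd.read_csv(path)
    required = {"patient_id", "timestamp", "glucose"}
    if not required.issubset(df.columns):
        raise CgmLoadError(f"CGM file must have columns {sorted(required)}")

    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    bad = glucose.isna() & df["glucose"].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise CgmLoadError(
            f"row {row}: non-numeric glucose value {df['glucose'][row]!r}"
        )
    times = pd.to_datetime(df["timestamp"], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise CgmLoadError(f"row {row}: unparseable timestamp {df['timestamp'][row]!r}")

    values = glucose.to_numpy(dtype=float)
    if unit == "mmol":
        values = values * MMOL_TO_MGDL
    out_of_range = (values < GLUCOSE_MIN) | (values > GLUCOSE_MAX)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0])
        raise CgmLoadError(
            f"row {row}: glucose {values[row]:.1f} mg/dL outside "
            f"[{GLUCOSE_MIN}, {GLUCOSE_MAX}]"
        )

    series: dict[str, CgmSeries] = {}
    work = pd.DataFrame(
        {"patient_id": df["patient_id"].astype(str), "time": times, "value": values}
    )
    for pid, grp in work.groupby("patient_id", sort=True):
        anchor = grp["time"].min().floor(f"{GRID_MINUTES}min")
        slots = [_snap_slot(t, anchor) for t in grp["time"]]
        n = max(slots) + 1
        vals = np.full(n, np.nan)
        for slot, v in zip(slots, grp["value"]):
            if not np.isnan(vals[slot]):
                raise CgmLoadError(
                    f"patient {pid}: two readings map to the same grid slot "
                    f"{anchor + pd.Timedelta(minutes=GRID_MINUTES * slot)}"
                )
            vals[slot] = v
        series[pid] = CgmSeries(patient_id=pid, start=anchor, values=vals)
    return series


def save_cgm(series: Iterable[CgmSeries], path: str | Path) -> None:
    """Write series to the delimited format ``load_cgm`` reads.

    Missing slots are simply not written, so a write/load round trip
    reproduces both values and the missing pattern exactly.
    """
    frames = []
    for s in series:
        keep = ~np.isnan(s.values)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "timestamp": s.times()[keep],
                    "glucose": s.values[keep],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def window(
    series: CgmSeries, t0: pd.Timestamp, offset_start: int, offset_end: int
) -> np.ndarray:
    """Functional alias for :meth:`CgmSeries.window`."""
    return series.window(t0, offset_start, offset_end)
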