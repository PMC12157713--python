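"""Domain containers and CSV I/O for 8-channel MOS e-Nose measurements.

A measurement is a three-phase resistance recording: "before" (clean,
humidified reference air — the baseline), "during" (exhaled breath drawn
from the sampling bag over the sensors) and "after" (clean air again,
recovery).  The containers here are what every downstream stage — FiO2
correction, feature extraction, classification — operates on.

File format: one CSV per measurement, ``#``-prefixed ``key=value`` header
lines, then a ``time_s,<channel>,...`` table.  A cohort manifest CSV lists
measurement files with their metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PHASE_BOUNDS",
    "DEFAULT_CHANNELS",
    "TIMEPOINTS",
    "REFERENCE_FIO2",
    "CALIBRATION_LEVELS",
    "ParseError",
    "ValidationError",
    "SensorCurve",
    "ENoseMeasurement",
    "CalibrationSeries",
    "slice_phase",
    "read_measurement",
    "write_measurement",
    "write_cohort",
    "read_cohort",
]

#: before ends at 1 min, during at 6 min, recording stops at 16 min.
DEFAULT_PHASE_BOUNDS: tuple[float, float, float] = (60.0, 360.0, 960.0)

#: The sensor chamber holds two physical units of TGS2603 and TGS2600;
#: duplicated models get _a/_b suffixes because the units need not match.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "TGS2603_a",
    "TGS2603_b",
    "TGS2600_a",
    "TGS2600_b",
    "TGS2610",
    "TGS2620",
    "TGS2611",
    "TGS2602",
)

TIMEPOINTS: tuple[str, ...] = ("t0", "t5", "t30", "t60", "t90", "t120", "t150", "t180")

GROUPS: tuple[str, ...] = ("control", "LPS", "calibration")

#: room air — the reference level of every correction surface.
REFERENCE_FIO2: float = 0.21

#: FiO2 levels of the clean-air characterization protocol.
CALIBRATION_LEVELS: tuple[float, ...] = (0.21, 0.25, 0.30, 0.35, 0.40, 0.50)

PHASES: tuple[str, ...] = ("before", "during", "after")


class ParseError(ValueError):
    """A measurement file violates the documented layout or an invariant."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass
class SensorCurve:
    """One channel's resistance time series with phase boundaries.

    Parameters
    ----------
    channel_id : str
        Physical channel name (e.g. ``TGS2603_a``).
    times : array of float
        Seconds from analysis start; strictly increasing, uniform spacing.
    resistance : array of float
        Sensor resistance in ohms.  Strictly positive for raw curves;
        baseline-removed curves (``baseline_mode`` set) may be <= 0.
    phase_bounds : (before_end_s, during_end_s, total_s)
    baseline_mode : {None, "subtract", "divide"}
        ``None`` for raw ohm-scale curves; set by
        :func:`enose.correction.remove_baseline`.
    """

    channel_id: str
    times: np.ndarray
    resistance: np.ndarray
    phase_bounds: tuple[float, float, float] = DEFAULT_PHASE_BOUNDS
    baseline_mode: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.times.ndim != 1 or self.resistance.ndim != 1:
            raise ValidationError(f"{self.channel_id}: times/resistance must be 1-D")
        if len(self.times) != len(self.resistance):
            raise ValidationError(
                f"{self.channel_id}: times ({len(self.times)}) and resistance "
                f"({len(self.resistance)}) lengths differ"
            )
        if len(self.times) < 2:
            raise ValidationError(f"{self.channel_id}: need at least 2 samples")
        b, d, t = self.phase_bounds
        if not (0 < b < d < t):
            raise ValidationError(
                f"{self.channel_id}: phase_bounds must satisfy 0 < before_end "
                f"< during_end < total, got {self.phase_bounds}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.channel_id}: times not strictly increasing")
        if self.baseline_mode is None and np.any(self.resistance <= 0):
            raise ValidationError(
                f"{self.channel_id}: resistance must be strictly positive "
                "(required for ratio baseline removal)"
            )
        if not np.all(np.isfinite(self.resistance)):
            raise ValidationError(f"{self.channel_id}: non-finite resistance")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    def check_uniform(self) -> None:
        """Reject non-uniform grids (correction surfaces assume a common grid)."""
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError(f"{self.channel_id}: non-uniform time grid")

    def phase_mask(self, phase: str) -> np.ndarray:
        b, d, t = self.phase_bounds
        if phase == "before":
            return (self.times >= 0) & (self.times < b)
        if phase == "during":
            return (self.times >= b) & (self.times < d)
        if phase == "after":
            return (self.times >= d) & (self.times <= t)
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")


def slice_phase(c: SensorCurve, phase: str) -> SensorCurve:
    """Restrict a curve to one protocol phase.

    Covers ``[0, before_end)``, ``[before_end, during_end)`` or
    ``[during_end, total]``; times are preserved (not re-zeroed), so the
    three slices partition the original curve.
    """
    mask = c.phase_mask(phase)
    return replace(c, times=c.times[mask], resistance=c.resistance[mask])


@dataclass
class ENoseMeasurement:
    """One e-Nose run: a set of synchronized SensorCurves plus metadata."""

    animal_id: str
    group: str
    timepoint: str
    fio2: float
    curves: dict[str, SensorCurve]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.group != "calibration" and self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if not (REFERENCE_FIO2 <= self.fio2 <= 1.0):
            raise ValidationError(f"fio2 {self.fio2} outside [0.21, 1.0]")
        if not self.curves:
            raise ValidationError("measurement has no curves")
        for cid, c in self.curves.items():
            if cid != c.channel_id:
                raise ValidationError(f"curve key {cid!r} != channel_id {c.channel_id!r}")
        first = next(iter(self.curves.values()))
        for c in self.curves.values():
            if c.phase_bounds != first.phase_bounds:
                raise ValidationError("curves disagree on phase_bounds")
            if len(c.times) != len(first.times) or not np.array_equal(c.times, first.times):
                raise ValidationError("curves do not share a common time grid")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.curves)

    @property
    def times(self) -> np.ndarray:
        return next(iter(self.curves.values())).times

    @property
    def phase_bounds(self) -> tuple[float, float, float]:
        return next(iter(self.curves.values())).phase_bounds

    def map_curves(self, fn) -> "ENoseMeasurement":
        """Return a copy with ``fn`` applied to every SensorCurve."""
        return replace(self, curves={cid: fn(c) for cid, c in self.curves.items()})


@dataclass
class CalibrationSeries:
    """Clean-air measurements at several FiO2 levels, replicated.

    The reference level 0.21 (room air) must be present; correction
    surfaces are differences/ratios against it.
    """

    levels: tuple[float, ...]
    replicates: dict[float, list[ENoseMeasurement]]

    def __post_init__(self) -> None:
        self.levels = tuple(float(v) for v in self.levels)
        if list(self.levels) != sorted(self.levels) or len(set(self.levels)) != len(self.levels):
            raise ValidationError("calibration levels must be strictly increasing")
        if not any(math.isclose(v, REFERENCE_FIO2) for v in self.levels):
            raise ValidationError("reference level 0.21 missing from calibration levels")
        for lvl in self.levels:
            reps = self.replicates.get(lvl, [])
            if not reps:
                raise ValidationError(f"no replicates at level {lvl}")
            for m in reps:
                if not math.isclose(m.fio2, lvl, abs_tol=1e-9):
                    raise ValidationError(
                        f"replicate at level {lvl} carries fio2={m.fio2}"
                    )

    @property
    def n_replicates(self) -> dict[float, int]:
        return {lvl: len(self.replicates[lvl]) for lvl in self.levels}

    def measurements(self) -> Iterable[ENoseMeasurement]:
        for lvl in self.levels:
            yield from self.replicates[lvl]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # repr of a python float is the shortest string that round-trips exactly,
    # which gives both byte-stable writes and exact read-back.
    return repr(float(x))


def write_measurement(m: ENoseMeasurement, path: str | Path) -> Path:
    """Write one measurement as a self-describing CSV. Bit-stable."""
    path = Path(path)
    first = next(iter(m.curves.values()))
    b, d, t = first.phase_bounds
    lines = [
        f"# animal_id={m.animal_id}",
        f"# group={m.group}",
        f"# timepoint={m.timepoint}",
        f"# fio2={_fmt(m.fio2)}",
        f"# rate_hz={_fmt(first.rate_hz)}",
        f"# phase_bounds_s={_fmt(b)},{_fmt(d)},{_fmt(t)}",
        "time_s," + ",".join(m.channels),
    ]
    cols = [m.curves[cid].resistance for cid in m.channels]
    for i, ts in enumerate(first.times):
        lines.append(_fmt(ts) + "," + ",".join(_fmt(col[i]) for col in cols))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_measurement(path: str | Path, dialect: str = "csv") -> ENoseMeasurement:
    """Read and validate a measurement file written by :func:`write_measurement`."""
    if dialect != "csv":
        raise ParseError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if "=" not in body:
                raise ParseError(f"{path.name}: malformed header line {line!r}")
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    for key in ("animal_id", "group", "timepoint", "fio2", "rate_hz", "phase_bounds_s"):
        if key not in meta:
            raise ParseError(f"{path.name}: missing header field {key!r}")
    try:
        fio2 = float(meta["fio2"])
        rate = float(meta["rate_hz"])
        bounds = tuple(float(x) for x in meta["phase_bounds_s"].split(","))
    except ValueError as exc:
        raise ParseError(f"{path.name}: unparseable header value ({exc})") from exc
    if len(bounds) != 3:
        raise ParseError(f"{path.name}: phase_bounds_s needs 3 values")

    df = pd.read_csv(path, skiprows=header_rows, float_precision="round_trip")
    if df.columns[0] != "time_s" or df.shape[1] < 2:
        raise ParseError(f"{path.name}: expected 'time_s,<channel>,...' header row")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ParseError(f"{path.name}: need at least 2 samples")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParseError(f"{path.name}: non-uniform or non-increasing time grid")
    if not math.isclose(1.0 / dt[0], rate, rel_tol=1e-6):
        raise ParseError(
            f"{path.name}: header rate_hz={rate} inconsistent with time grid"
        )
    curves: dict[str, SensorCurve] = {}
    for cid in df.columns[1:]:
        res = df[cid].to_numpy(dtype=float)
        if np.any(res <= 0):
            raise ParseError(
                f"{path.name}: channel {cid} violates resistance positivity invariant"
            )
        try:
            curves[cid] = SensorCurve(cid, times, res, phase_bounds=tuple(bounds))
        except ValidationError as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
    try:
        return ENoseMeasurement(
            animal_id=meta["animal_id"],
            group=meta["group"],
            timepoint=meta["timepoint"],
            fio2=fio2,
            curves=curves,
        )
    except ValidationError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


# -- cohort manifests -------------------------------------------------------

def write_cohort(measurements: Sequence[ENoseMeasurement], outdir: str | Path) -> Path:
    """Write each measurement CSV plus a manifest listing files and metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in measurements:
        fname = f"{m.group}_{m.animal_id}_{m.timepoint}.csv"
        write_measurement(m, outdir / fname)
        rows.append(
            {
                "path": fname,
                "animal_id": m.animal_id,
                "group": m.group,
                "timepoint": m.timepoint,
                "fio2": m.fio2,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[ENoseMeasurement]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [read_measurement(manifest.parent / p) for p in df["path"]]
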