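"""FiO2 correction surfaces for MOS sensor response curves.

n-type MOS sensors raise their resistance with the oxygen fraction of the
sample, and the inspired-oxygen fraction (FiO2) of a ventilated subject is
adjusted clinically — so oxygen is a confounder of the breath signal.  The
remedy characterized here: clean-air measurements at several FiO2 levels
give, per channel, a bivariate correction function k(t, FiO2) built as the
point-by-point difference (k_diff) or ratio (k_ratio) between the mean
curve at each level and the mean curve at the 21 % reference, linearly
interpolated in time and level.  Sample curves are baseline-removed
(subtraction for the diff strategy, division for ratio) and then corrected
by subtracting / dividing by k evaluated at the sample's FiO2.

One deliberate deviation from a literal reading of the published table:
the calibration mean curves are baseline-removed with the strategy's own
mode *before* differencing/ratioing, so that k has the same units as the
baseline-removed sample curve it is applied to (k_diff(0,·)=0,
k_ratio(0,·)=1).  ``raw_calibration=True`` reproduces the literal reading.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .io import (
    REFERENCE_FIO2,
    CalibrationSeries,
    SensorCurve,
    ValidationError,
)

__all__ = [
    "CorrectionSurface",
    "ExtrapolationWarning",
    "mean_level_curve",
    "build_surface",
    "build_surfaces",
    "evaluate_surface",
    "remove_baseline",
    "apply_correction",
    "write_surfaces",
    "read_surfaces",
]

#: strategy label -> the baseline-removal mode its samples must carry.
STRATEGY_BASELINE = {"diff": "subtract", "ratio": "divide"}


class ExtrapolationWarning(UserWarning):
    """Queried FiO2 outside the characterized range; value clamped."""


@dataclass
class CorrectionSurface:
    """Per-channel bivariate correction function k(t, FiO2).

    ``k_values`` is a (time x level) matrix on the calibration grid;
    evaluation is bilinear inside the hull, clamped (with a warning) in
    level outside it, and an error in time outside it.
    """

    channel_id: str
    strategy: str  # "diff" or "ratio"
    grid_times: np.ndarray
    grid_levels: np.ndarray
    k_values: np.ndarray
    reference_level: float = REFERENCE_FIO2

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.grid_levels = np.asarray(self.grid_levels, dtype=float)
        self.k_values = np.asarray(self.k_values, dtype=float)
        if self.strategy not in STRATEGY_BASELINE:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.k_values.shape != (len(self.grid_times), len(self.grid_levels)):
            raise ValidationError("k_values shape mismatch with grid")
        if self.strategy == "ratio" and np.any(self.k_values <= 0):
            raise ValidationError("ratio surface must be strictly positive")

    def __call__(self, t, fio2: float):
        return evaluate_surface(self, t, fio2)

    @property
    def _interpolator(self) -> RegularGridInterpolator:
        interp = getattr(self, "_interp_cache", None)
        if interp is None:
            interp = RegularGridInterpolator(
                (self.grid_times, self.grid_levels),
                self.k_values,
                method="linear",
                bounds_error=True,
            )
            object.__setattr__(self, "_interp_cache", interp)
        return interp


def mean_level_curve(cs: CalibrationSeries, channel: str, level: float) -> SensorCurve:
    """Pointwise arithmetic mean of the replicate curves at one FiO2 level."""
    matches = [lvl for lvl in cs.levels if np.isclose(lvl, level)]
    if not matches:
        raise ValidationError(f"level {level} not in calibration series")
    reps = cs.replicates[matches[0]]
    curves = [m.curves[channel] for m in reps]
    t0 = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, t0):
            raise ValidationError(f"{channel}: replicates on mismatched time grids")
    mean = np.mean([c.resistance for c in curves], axis=0)
    return SensorCurve(channel, t0, mean, phase_bounds=curves[0].phase_bounds)


def remove_baseline(c: SensorCurve, mode: str) -> SensorCurve:
    """Normalize a curve by its initial resistance.

    ``subtract``: R(t) - R(0), first value exactly 0.
    ``divide``:   R(t) / R(0), first value exactly 1 (requires R(0) > 0).
    """
    if mode == "subtract":
        res = c.resistance - c.resistance[0]
    elif mode == "divide":
        if c.resistance[0] <= 0:
            raise ValidationError(f"{c.channel_id}: zero/negative baseline under divide")
        res = c.resistance / c.resistance[0]
    else:
        raise ValueError(f"unknown baseline mode {mode!r}")
    return replace(c, resistance=res, baseline_mode=mode)


def build_surface(
    cs: CalibrationSeries,
    channel: str,
    strategy: str,
    raw_calibration: bool = False,
) -> CorrectionSurface:
    """Build k_diff or k_ratio for one channel from a calibration series.

    k_diff(t, f) = M_f(t) - M_ref(t);  k_ratio(t, f) = M_f(t) / M_ref(t),
    where M_f is the (by default baseline-removed) mean clean-air curve at
    level f.  The reference-level column is exactly 0 / 1 by construction.
    """
    if strategy not in STRATEGY_BASELINE:
        raise ValueError(f"unknown strategy {strategy!r}")
    means = {}
    for lvl in cs.levels:
        m = mean_level_curve(cs, channel, lvl)
        if not raw_calibration:
            m = remove_baseline(m, STRATEGY_BASELINE[strategy])
        means[lvl] = m
    ref_lvl = next(l for l in cs.levels if np.isclose(l, REFERENCE_FIO2))
    ref = means[ref_lvl].resistance
    cols = []
    for lvl in cs.levels:
        if strategy == "diff":
            col = means[lvl].resistance - ref
        else:
            if np.any(ref <= 0) or np.any(means[lvl].resistance <= 0):
                raise ValidationError(
                    f"{channel}: non-positive mean curve under ratio strategy"
                )
            col = means[lvl].resistance / ref
        if np.isclose(lvl, REFERENCE_FIO2):
            # force the reference identity exactly (guards against 0/0-type
            # rounding when the mean curve passes through tiny values)
            col = np.zeros_like(col) if strategy == "diff" else np.ones_like(col)
        cols.append(col)
    k = np.column_stack(cols)
    return CorrectionSurface(
        channel_id=channel,
        strategy=strategy,
        grid_times=means[ref_lvl].times,
        grid_levels=np.asarray(cs.levels, dtype=float),
        k_values=k,
    )


def build_surfaces(
    cs: CalibrationSeries, strategy: str, raw_calibration: bool = False
) -> dict[str, CorrectionSurface]:
    """One surface per channel of the calibration measurements."""
    channels = next(cs.measurements()).channels
    return {
        ch: build_surface(cs, ch, strategy, raw_calibration=raw_calibration)
        for ch in channels
    }


def evaluate_surface(k: CorrectionSurface, t, fio2: float):
    """Bilinear interpolation of k at time(s) t and a single FiO2.

    Levels outside the calibration range clamp to the nearest level with an
    :class:`ExtrapolationWarning`; times outside the grid raise.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tv = np.atleast_1d(t)
    lo, hi = k.grid_times[0], k.grid_times[-1]
    if np.any(tv < lo) or np.any(tv > hi):
        raise ValueError(
            f"{k.channel_id}: time outside surface grid [{lo}, {hi}]"
        )
    f_lo, f_hi = k.grid_levels[0], k.grid_levels[-1]
    if fio2 < f_lo or fio2 > f_hi:
        warnings.warn(
            f"{k.channel_id}: FiO2={fio2} outside characterized range "
            f"[{f_lo}, {f_hi}]; clamping",
            ExtrapolationWarning,
            stacklevel=2,
        )
        fio2 = float(np.clip(fio2, f_lo, f_hi))
    pts = np.column_stack([tv, np.full_like(tv, fio2)])
    vals = k._interpolator(pts)
    return float(vals[0]) if scalar else vals


def apply_correction(
    c: SensorCurve, k: CorrectionSurface, fio2: float
) -> SensorCurve:
    """Correct a baseline-removed sample curve for its FiO2.

    diff:  R_corr(t) = R_bas(t) - k(t, fio2)
    ratio: R_corr(t) = R_bas(t) / k(t, fio2)

    The curve's baseline mode must match the surface strategy
    (subtract <-> diff, divide <-> ratio).  The surface is resampled
    (linearly in t) onto the sample's grid; at the 21 % reference the
    correction is the identity map exactly.
    """
    expected = STRATEGY_BASELINE[k.strategy]
    if c.baseline_mode != expected:
        raise ValidationError(
            f"{c.channel_id}: curve baseline_mode={c.baseline_mode!r} does not "
            f"match strategy {k.strategy!r} (expected {expected!r})"
        )
    if np.isclose(fio2, k.reference_level):
        return c  # exact identity at the reference level
    kvals = evaluate_surface(k, c.times, fio2)
    if k.strategy == "diff":
        res = c.resistance - kvals
    else:
        if np.any(kvals == 0):
            raise ValidationError(f"{c.channel_id}: ratio correction value of 0")
        res = c.resistance / kvals
    return replace(c, resistance=res)


# ---------------------------------------------------------------------------
# Serialization: long-format CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_surfaces(surfaces: dict[str, CorrectionSurface], path: str | Path) -> Path:
    """Write surfaces as long CSV (channel, time_s, fio2, k) + JSON sidecar."""
    path = Path(path)
    rows = []
    for ch, s in surfaces.items():
        for i, t in enumerate(s.grid_times):
            for j, f in enumerate(s.grid_levels):
                rows.append((ch, t, f, s.k_values[i, j]))
    pd.DataFrame(rows, columns=["channel", "time_s", "fio2", "k"]).to_csv(
        path, index=False, float_format="%.12g"
    )
    meta = {
        ch: {"strategy": s.strategy, "reference_level": s.reference_level}
        for ch, s in surfaces.items()
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_surfaces(path: str | Path) -> dict[str, CorrectionSurface]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    out = {}
    for ch, sub in df.groupby("channel", sort=False):
        times = np.unique(sub["time_s"])
        levels = np.unique(sub["fio2"])
        k = (
            sub.pivot(index="time_s", columns="fio2", values="k")
            .loc[times, levels]
            .to_numpy()
        )
        out[ch] = CorrectionSurface(
            channel_id=ch,
            strategy=meta[ch]["strategy"],
            grid_times=times,
            grid_levels=levels,
            k_values=k,
            reference_level=meta[ch]["reference_level"],
        )
    return out
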