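"""Curve shape/dynamics features and IQR outlier screening.

Each corrected (or merely baseline-removed) measurement is reduced to one
feature vector: per channel, the response amplitude, area under the
deviation curve, on/off slopes, time to the extremum and the residual
deviation at the end of recovery.  Outliers are screened per (timepoint,
feature) cell with Tukey fences on the interquartile range; flagged cells
are masked and median-imputed rather than dropping the whole sample, so
the leave-one-out design stays balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ENoseMeasurement, SensorCurve, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "extract_features",
    "build_feature_table",
    "iqr_screen",
]

#: the implemented superset; the documented minimum is the first three
#: (amplitude, auc, slope) — "shape and dynamics" of the resistance course.
FEATURE_NAMES: tuple[str, ...] = (
    "amplitude",
    "auc",
    "max_slope_on",
    "max_slope_off",
    "t_to_extremum",
    "recovery_fraction",
)

DEFAULT_WINDOW: tuple[str, ...] = ("during", "after")


def _curve_features(
    c: SensorCurve, window: Sequence[str], features: Sequence[str]
) -> dict[str, float]:
    if c.baseline_mode is None:
        raise ValidationError(
            f"{c.channel_id}: features require a baseline-removed curve"
        )
    dev = c.resistance - c.resistance[0]  # deviation from the start value (0 or 1)
    dt = float(c.times[1] - c.times[0])
    wmask = np.zeros(len(c.times), dtype=bool)
    for ph in window:
        wmask |= c.phase_mask(ph)
    if not wmask.any():
        raise ValueError(f"{c.channel_id}: empty window {window!r}")
    absdev = np.abs(dev)
    amplitude = float(absdev[wmask].max())

    out: dict[str, float] = {}
    for name in features:
        if name == "amplitude":
            out[name] = amplitude
        elif name == "auc":
            out[name] = float(np.trapezoid(absdev[wmask], c.times[wmask]))
        elif name == "max_slope_on":
            dmask = c.phase_mask("during")
            d = np.diff(dev[dmask]) / dt
            out[name] = float(d.min()) if len(d) else 0.0
        elif name == "max_slope_off":
            amask = c.phase_mask("after")
            d = np.diff(dev[amask]) / dt
            out[name] = float(d.max()) if len(d) else 0.0
        elif name == "t_to_extremum":
            idx = np.flatnonzero(wmask)
            i_ext = idx[np.argmax(absdev[idx])]
            out[name] = float(c.times[i_ext] - c.phase_bounds[0])
        elif name == "recovery_fraction":
            amask = c.phase_mask("after")
            end_dev = float(absdev[np.flatnonzero(amask)[-1]]) if amask.any() else 0.0
            out[name] = end_dev / amplitude if amplitude > 0 else 0.0
        else:
            raise ValueError(f"unknown feature {name!r}")
    return out


def extract_features(
    m: ENoseMeasurement,
    window: Sequence[str] = DEFAULT_WINDOW,
    features: Sequence[str] = FEATURE_NAMES,
) -> dict[str, float]:
    """Feature vector of one measurement: ``{channel:feature -> value}``.

    Deterministic, metadata-independent, and name-ordered by channel then
    feature.  Curves must be baseline-removed (subtract mode starts at 0,
    divide mode at 1; features are defined on the deviation from that
    start value).
    """
    vec: dict[str, float] = {}
    for cid in m.channels:
        fv = _curve_features(m.curves[cid], window, features)
        for name in features:
            vec[f"{cid}:{name}"] = fv[name]
    return vec


@dataclass
class FeatureTable:
    """samples x (channel:feature) matrix with labels and an outlier mask.

    ``values`` is indexed by (animal_id, timepoint); ``labels`` gives the
    group per row; ``mask`` flags cells removed by the IQR screen (their
    values have been imputed in ``values``).
    """

    values: pd.DataFrame
    labels: pd.Series
    mask: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.is_unique:
            raise ValidationError("duplicate sample keys in feature table")
        if not self.labels.index.equals(self.values.index):
            raise ValidationError("labels misaligned with feature rows")
        if self.labels.isna().any():
            raise ValidationError("every row needs a label")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite feature values")

    def select_rows(self, row_mask) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[row_mask].copy(),
            self.labels.loc[row_mask].copy(),
            self.mask.loc[row_mask].copy(),
        )

    def to_csv(self, path: str | Path) -> Path:
        df = self.values.copy()
        df.insert(0, "label", self.labels)
        df.to_csv(path, float_format="%.12g")
        return Path(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col=[0, 1])
        labels = df.pop("label")
        return cls(df, labels)


def build_feature_table(
    measurements: Iterable[ENoseMeasurement],
    window: Sequence[str] = DEFAULT_WINDOW,
    features: Sequence[str] = FEATURE_NAMES,
) -> FeatureTable:
    """Stack per-measurement feature vectors into a labelled table."""
    rows, keys, labels = [], [], []
    for m in measurements:
        rows.append(extract_features(m, window, features))
        keys.append((m.animal_id, m.timepoint))
        labels.append(m.group)
    idx = pd.MultiIndex.from_tuples(keys, names=["animal_id", "timepoint"])
    values = pd.DataFrame(rows, index=idx)
    return FeatureTable(values, pd.Series(labels, index=idx, name="label"))


def iqr_screen(
    t: FeatureTable,
    fence_mult: float = 1.5,
    min_group: int = 4,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Mask per-(timepoint, feature) outliers by Tukey fences and impute.

    A cell is an outlier when its value falls outside
    ``[Q1 - fence_mult*IQR, Q3 + fence_mult*IQR]`` computed over the cell's
    (timepoint, feature) group; ``fence_mult=0`` is the literal
    outside-the-IQR rule.  Masked cells are imputed with the median of the
    surviving values of their group.  Groups smaller than ``min_group`` or
    with zero IQR are left untouched.  Returns the screened table and a
    removal report (timepoint, feature, n_masked, fences).
    """
    if fence_mult < 0:
        raise ValueError("fence_mult must be >= 0")
    vals_all = t.values.to_numpy(dtype=float).copy()
    mask_all = t.mask.to_numpy(dtype=bool).copy()
    report_rows = []
    columns = list(t.values.columns)
    tp_level = t.values.index.get_level_values("timepoint")
    for tp in pd.unique(tp_level):
        rows = np.asarray(tp_level == tp)
        vals = vals_all[rows]  # (n_rows_in_tp, n_features)
        prior = mask_all[rows]
        work = np.where(prior, np.nan, vals)  # exclude already-masked cells
        n_ok = (~prior).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            q1, q3 = np.nanpercentile(work, [25, 75], axis=0)
        iqr = q3 - q1
        active = (n_ok >= min_group) & (iqr > 0)
        if not active.any():
            continue
        lo = q1 - fence_mult * iqr
        hi = q3 + fence_mult * iqr
        out = active & ~prior & ((work < lo) | (work > hi))
        if not out.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.where(out, np.nan, work), axis=0)
        for j in np.flatnonzero(out.any(axis=0)):
            vals[out[:, j], j] = med[j]
            report_rows.append(
                {
                    "timepoint": tp,
                    "feature": columns[j],
                    "n_masked": int(out[:, j].sum()),
                    "fence_lo": lo[j],
                    "fence_hi": hi[j],
                }
            )
        vals_all[rows] = vals
        mask_all[rows] = prior | out
    report = pd.DataFrame(
        report_rows, columns=["timepoint", "feature", "n_masked", "fence_lo", "fence_hi"]
    )
    values = pd.DataFrame(vals_all, index=t.values.index, columns=t.values.columns)
    mask = pd.DataFrame(mask_all, index=t.values.index, columns=t.values.columns)
    return FeatureTable(values, t.labels.copy(), mask), report
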