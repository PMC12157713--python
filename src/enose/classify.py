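"""Per-timepoint classification of control vs LPS animals.

Two pipelines are compared at every sampling timepoint: a physiological
model (MAP/DBP/SBP/HR/T -> z-score -> 5-component PCA -> logistic
regression) and e-Nose models (curve features -> per-fold IQR screen ->
z-score -> 2-component PCA -> decision tree), the latter in three variants
differing only in the FiO2 correction applied before feature extraction
(none / k_diff / k_ratio).  Data are assembled cumulatively: the model at
t60 trains on everything from t5 through t60 (baseline t0 excluded).
Evaluation is leave-one-out with the *animal* as the held-out unit, all
transformations refit inside each fold; metrics carry Wald 95 % CIs.

The statsmodels-style entry point is :class:`BreathStudy` (model object)
whose :meth:`~BreathStudy.fit` returns :class:`StudyResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .correction import apply_correction, build_surfaces, remove_baseline
from .features import FeatureTable, build_feature_table, iqr_screen
from .io import TIMEPOINTS, CalibrationSeries, ENoseMeasurement
from .simulate import PhysioRecord

__all__ = [
    "VARIANTS",
    "PHYSIO_FEATURES",
    "ModelSpec",
    "TimePointResult",
    "TrajectorySummary",
    "assemble_cumulative",
    "zscore_fit",
    "zscore_apply",
    "pca_fit",
    "pca_apply",
    "metrics_with_ci",
    "loo_evaluate",
    "physio_trajectories",
    "physio_table",
    "prepare_variant_table",
    "run_study",
    "BreathStudy",
    "StudyResults",
]

VARIANTS: tuple[str, ...] = ("physio", "enose_raw", "enose_kdiff", "enose_kratio")
PHYSIO_FEATURES: tuple[str, ...] = ("MAP", "DBP", "SBP", "HR", "T")
POSITIVE_LABEL = "LPS"  # sensitivity = detection of the endotoxemic animal


@dataclass
class ModelSpec:
    """Configuration of one classification variant.

    Defaults follow the study's choices: the physiological model uses
    5 PCA components with logistic regression; e-Nose models use 2
    components with a depth-3 decision tree and screen outliers inside
    each training fold.
    """

    variant: str = "enose_kratio"
    n_components: int | None = None
    classifier: str | None = None  # "logistic" or "tree"
    tree_max_depth: int = 3
    fence_mult: float = 1.5
    screen_outliers: bool | None = None
    ci_method: str = "wald"  # or "wilson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_components is None:
            self.n_components = 5 if self.variant == "physio" else 2
        if self.classifier is None:
            self.classifier = "logistic" if self.variant == "physio" else "tree"
        if self.classifier not in ("logistic", "tree"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.screen_outliers is None:
            self.screen_outliers = self.variant != "physio"


@dataclass
class TimePointResult:
    """Accuracy/sensitivity/specificity (+ 95 % CIs) at one timepoint."""

    timepoint: str
    variant: str
    n_samples: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float  # nan when no positive truth
    specificity: float
    ci: dict[str, tuple[float, float]]
    n_excluded_folds: int = 0

    def to_rows(self) -> list[dict]:
        rows = []
        for metric in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, metric)
            lo, hi = self.ci.get(metric, (np.nan, np.nan))
            rows.append(
                {
                    "variant": self.variant,
                    "timepoint": self.timepoint,
                    "metric": metric,
                    "value": v,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n": self.n_samples,
                }
            )
        return rows


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def assemble_cumulative(table, timepoint: str, include_t0: bool = False):
    """Rows from t5 up to and including ``timepoint`` (t0 excluded).

    Works on a :class:`FeatureTable` or any DataFrame with a ``timepoint``
    index level.  The study's own worked example: the t60 model trains on
    t5, t30 and t60.
    """
    order = list(TIMEPOINTS)
    if timepoint not in order or timepoint == "t0":
        raise ValueError(
            f"timepoint {timepoint!r} not a valid cumulative target (t5..t180)"
        )
    keep = set(order[(0 if include_t0 else 1) : order.index(timepoint) + 1])
    if isinstance(table, FeatureTable):
        tp = table.values.index.get_level_values("timepoint")
        return table.select_rows(np.asarray([t in keep for t in tp]))
    tp = table.index.get_level_values("timepoint")
    return table.loc[[t in keep for t in tp]]


@dataclass
class Scaler:
    mean_: pd.Series
    scale_: pd.Series


def zscore_fit(train: pd.DataFrame) -> Scaler:
    """Column-wise z-score statistics (population SD, ddof=0).

    Zero-SD columns get scale 1 (so they map to 0) with a warning.
    """
    if len(train) < 2:
        raise ValueError("need >= 2 rows to fit a z-score scaler")
    mean = train.mean()
    sd = train.std(ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-SD columns mapped to 0: {list(train.columns[zero])[:5]}...",
            UserWarning,
            stacklevel=2,
        )
        sd = sd.mask(zero, 1.0)
    return Scaler(mean_=mean, scale_=sd)


def zscore_apply(scaler: Scaler, table: pd.DataFrame) -> pd.DataFrame:
    return (table - scaler.mean_) / scaler.scale_


@dataclass
class Projection:
    components_: np.ndarray  # (n_components, n_features), orthonormal rows
    mean_: np.ndarray
    explained_variance_ratio_: np.ndarray
    columns: list


def pca_fit(train: pd.DataFrame, n_components: int) -> Projection:
    """PCA with a deterministic sign convention.

    Each loading vector is flipped so its largest-magnitude element is
    positive, removing the eigenvector sign ambiguity.
    """
    max_rank = min(len(train) - 1, train.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds usable rank {max_rank}"
        )
    p = _SkPCA(n_components=n_components, svd_solver="full")
    p.fit(train.to_numpy(dtype=float))
    comp = p.components_.copy()
    for i in range(comp.shape[0]):
        j = np.argmax(np.abs(comp[i]))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return Projection(
        components_=comp,
        mean_=p.mean_,
        explained_variance_ratio_=p.explained_variance_ratio_,
        columns=list(train.columns),
    )


def pca_apply(proj: Projection, table: pd.DataFrame) -> np.ndarray:
    x = table[proj.columns].to_numpy(dtype=float)
    return (x - proj.mean_) @ proj.components_.T


def _wald_ci(p_hat: float, n: int) -> tuple[float, float]:
    half = 1.96 * np.sqrt(p_hat * (1 - p_hat) / n)
    return (
        float(np.clip(100 * (p_hat - half), 0, 100)),
        float(np.clip(100 * (p_hat + half), 0, 100)),
    )


def _wilson_ci(p_hat: float, n: int) -> tuple[float, float]:
    z = 1.96
    denom = 1 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return (
        float(np.clip(100 * (center - half), 0, 100)),
        float(np.clip(100 * (center + half), 0, 100)),
    )


def metrics_with_ci(
    tp: int,
    tn: int,
    fp: int,
    fn: int,
    timepoint: str = "",
    variant: str = "",
    ci_method: str = "wald",
) -> TimePointResult:
    """Accuracy/sensitivity/specificity in percent with 95 % CIs.

    Each metric's CI uses its own denominator (n, TP+FN, TN+FP).  A zero
    denominator makes the metric (and its CI) NaN — reported missing, not
    zero.
    """
    n = tp + tn + fp + fn
    if n <= 0:
        raise ValueError("empty confusion matrix")
    ci_fn = {"wald": _wald_ci, "wilson": _wilson_ci}[ci_method]
    metrics: dict[str, float] = {}
    cis: dict[str, tuple[float, float]] = {}
    for name, num, den in (
        ("accuracy", tp + tn, n),
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
    ):
        if den == 0:
            metrics[name] = float("nan")
            cis[name] = (float("nan"), float("nan"))
        else:
            p_hat = num / den
            metrics[name] = 100 * p_hat
            cis[name] = ci_fn(p_hat, den)
    return TimePointResult(
        timepoint=timepoint,
        variant=variant,
        n_samples=n,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        ci=cis,
    )


# ---------------------------------------------------------------------------
# Leave-one-out evaluation
# ---------------------------------------------------------------------------

def _as_frame(samples) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(samples, FeatureTable):
        return samples.values, samples.labels
    df = samples.copy()
    labels = df.pop("label") if "label" in df.columns else None
    if labels is None:
        raise ValueError("DataFrame input needs a 'label' column")
    return df, labels


def _fit_fold(
    train: pd.DataFrame, train_labels: pd.Series, spec: ModelSpec
) -> tuple[Scaler, Projection, object]:
    """Fit the per-fold pipeline: (optional IQR screen) -> z-score -> PCA
    -> classifier.  All statistics come from training rows only."""
    if spec.screen_outliers:
        screened, _ = iqr_screen(
            FeatureTable(train.copy(), train_labels.copy()), fence_mult=spec.fence_mult
        )
        train = screened.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # zero-SD cols are fine per-fold
        scaler = zscore_fit(train)
    z = zscore_apply(scaler, train)
    n_comp = min(spec.n_components, len(train) - 1, train.shape[1])
    proj = pca_fit(z, n_comp)
    scores = pca_apply(proj, z)
    y = (train_labels == POSITIVE_LABEL).to_numpy()
    # class_weight="balanced" neutralizes the leave-one-out fold-imbalance
    # bias: the majority class of every training fold is the opposite of the
    # held-out unit's, which otherwise drags null-data accuracy below chance.
    if spec.classifier == "logistic":
        clf = LogisticRegression(C=np.inf, max_iter=2000, class_weight="balanced")
    else:
        clf = DecisionTreeClassifier(
            max_depth=spec.tree_max_depth,
            criterion="gini",
            random_state=spec.seed,
            class_weight="balanced",
        )
    clf.fit(scores, y)
    return scaler, proj, clf


def loo_evaluate(
    samples,
    spec: ModelSpec,
    unit: str = "animal",
    timepoint: str = "",
) -> TimePointResult:
    """Leave-one-unit-out evaluation with per-fold refitting.

    ``unit="animal"`` holds out all rows of one animal (the default: with
    cumulative assembly an animal contributes several rows, and leaving
    out single rows would leak its identity); ``unit="sample"`` holds out
    one row.  Training folds missing a class are excluded from pooling
    and counted in ``n_excluded_folds``.
    """
    df, labels = _as_frame(samples)
    if unit == "animal":
        units = df.index.get_level_values(0)
    elif unit == "sample":
        units = pd.Index(range(len(df)))
    else:
        raise ValueError(f"unknown LOO unit {unit!r}")
    unique_units = pd.unique(units)
    if len(unique_units) < 2:
        raise ValueError("need >= 2 units for leave-one-out")

    tp = tn = fp = fn = 0
    excluded = 0
    for u in unique_units:
        test_mask = np.asarray(units == u)
        train_df, train_lab = df.loc[~test_mask], labels.loc[~test_mask]
        if train_lab.nunique() < 2:
            excluded += 1
            continue
        scaler, proj, clf = _fit_fold(train_df, train_lab, spec)
        z_test = zscore_apply(scaler, df.loc[test_mask])
        pred = clf.predict(pca_apply(proj, z_test))
        truth = (labels.loc[test_mask] == POSITIVE_LABEL).to_numpy()
        tp += int(np.sum(pred & truth))
        tn += int(np.sum(~pred & ~truth))
        fp += int(np.sum(pred & ~truth))
        fn += int(np.sum(~pred & truth))
    result = metrics_with_ci(
        tp, tn, fp, fn, timepoint=timepoint, variant=spec.variant,
        ci_method=spec.ci_method,
    )
    result.n_excluded_folds = excluded
    return result


# ---------------------------------------------------------------------------
# Physiological PCA trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySummary:
    """Displacement of each animal in baseline (t0) PCA space over time."""

    displacements: pd.DataFrame  # index (animal_id, timepoint), cols PC1..; plus modulus
    group_means: pd.DataFrame  # index (group, timepoint): mean vector + mean_modulus


def physio_table(records: Iterable[PhysioRecord]) -> pd.DataFrame:
    """PhysioRecords -> DataFrame indexed by (animal_id, timepoint) with a
    label column (group)."""
    rows = [
        {
            "animal_id": r.animal_id,
            "timepoint": r.timepoint,
            "label": r.group,
            **{f: getattr(r, f) for f in PHYSIO_FEATURES},
        }
        for r in records
    ]
    df = pd.DataFrame(rows).set_index(["animal_id", "timepoint"])
    return df


def physio_trajectories(
    records, n_components: int = 2
) -> TrajectorySummary:
    """Project every timepoint into the z-scored PCA space of t0 and track
    each animal's displacement from its own baseline.

    The displacement vector is modulus x direction; group means average the
    per-animal vectors (n per group = animal count), and ``mean_modulus``
    averages the per-animal moduli.  Animals without a t0 record are
    excluded with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else physio_table(records)
    labels = df["label"]
    feats = df.drop(columns="label")
    tps = df.index.get_level_values("timepoint")
    t0 = feats.loc[tps == "t0"]
    if len(t0) < 2:
        raise ValueError("need >= 2 animals with t0 records")
    have_t0 = set(t0.index.get_level_values("animal_id"))
    all_animals = set(df.index.get_level_values("animal_id"))
    missing = all_animals - have_t0
    if missing:
        warnings.warn(f"animals without t0 excluded: {sorted(missing)}", UserWarning)
        keep = [a in have_t0 for a in df.index.get_level_values("animal_id")]
        df, labels, feats = df.loc[keep], labels.loc[keep], feats.loc[keep]
        t0 = feats.loc[df.index.get_level_values("timepoint") == "t0"]

    scaler = zscore_fit(t0)
    proj = pca_fit(zscore_apply(scaler, t0), min(n_components, len(t0) - 1, t0.shape[1]))
    scores = pca_apply(proj, zscore_apply(scaler, feats))
    pc_cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    sdf = pd.DataFrame(scores, index=feats.index, columns=pc_cols)
    base = sdf.loc[sdf.index.get_level_values("timepoint") == "t0"]
    base = base.droplevel("timepoint")
    disp = sdf.sub(
        base.loc[sdf.index.get_level_values("animal_id")].to_numpy(), axis=0
    )
    disp["modulus"] = np.linalg.norm(disp[pc_cols], axis=1)
    gm = (
        disp.assign(group=labels.to_numpy())
        .groupby(["group", disp.index.get_level_values("timepoint")])
        .mean()
    )
    gm = gm.rename(columns={"modulus": "mean_modulus"})
    gm.index.names = ["group", "timepoint"]
    return TrajectorySummary(displacements=disp, group_means=gm)


# ---------------------------------------------------------------------------
# Study orchestration: variants x timepoints
# ---------------------------------------------------------------------------

def prepare_variant_table(
    variant: str,
    measurements: Sequence[ENoseMeasurement] | None = None,
    physio_records: Sequence[PhysioRecord] | None = None,
    calibration: CalibrationSeries | None = None,
    raw_calibration: bool = False,
):
    """Feature table for one model variant.

    e-Nose variants differ only in the correction applied before feature
    extraction: none (baseline subtraction only), k_diff, or k_ratio.
    """
    if variant == "physio":
        if physio_records is None:
            raise ValueError("physio variant needs physio records")
        df = physio_table(physio_records)
        return FeatureTable(df.drop(columns="label"), df["label"])
    if measurements is None:
        raise ValueError(f"{variant} needs e-Nose measurements")
    if variant == "enose_raw":
        corrected = [
            m.map_curves(lambda c: remove_baseline(c, "subtract")) for m in measurements
        ]
    elif variant in ("enose_kdiff", "enose_kratio"):
        if calibration is None:
            raise ValueError(f"{variant} needs a calibration series")
        strategy = "diff" if variant == "enose_kdiff" else "ratio"
        mode = "subtract" if strategy == "diff" else "divide"
        surfaces = build_surfaces(calibration, strategy, raw_calibration=raw_calibration)
        corrected = [
            m.map_curves(
                lambda c, f=m.fio2: apply_correction(
                    remove_baseline(c, mode), surfaces[c.channel_id], f
                )
            )
            for m in measurements
        ]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return build_feature_table(corrected)


def run_study(
    measurements: Sequence[ENoseMeasurement],
    physio_records: Sequence[PhysioRecord],
    calibration: CalibrationSeries,
    specs: Sequence[ModelSpec] | None = None,
    timepoints: Sequence[str] = TIMEPOINTS[1:],
    unit: str = "animal",
) -> "StudyResults":
    """Evaluate every model variant at every timepoint (cumulative LOO)."""
    if specs is None:
        specs = [ModelSpec(variant=v) for v in VARIANTS]
    tables = {
        s.variant: prepare_variant_table(
            s.variant, measurements, physio_records, calibration
        )
        for s in specs
    }
    results: list[TimePointResult] = []
    for s in specs:
        for tpt in timepoints:
            subset = assemble_cumulative(tables[s.variant], tpt)
            results.append(loo_evaluate(subset, s, unit=unit, timepoint=tpt))
    return StudyResults(results=results, specs=list(specs), timepoints=list(timepoints))


@dataclass
class StudyResults:
    """Per-timepoint, per-variant classification performance.

    ``frame`` is the tidy results table (variant, timepoint, metric, value,
    ci_lo, ci_hi, n); ``summary()`` prints an accuracy matrix.
    """

    results: list[TimePointResult]
    specs: list[ModelSpec] = field(default_factory=list)
    timepoints: list[str] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([row for r in self.results for row in r.to_rows()])

    def accuracy_table(self) -> pd.DataFrame:
        acc = self.frame.query("metric == 'accuracy'")
        return acc.pivot(index="timepoint", columns="variant", values="value").reindex(
            [t for t in TIMEPOINTS if t in set(acc["timepoint"])]
        )

    def get(self, variant: str, timepoint: str) -> TimePointResult:
        for r in self.results:
            if r.variant == variant and r.timepoint == timepoint:
                return r
        raise KeyError((variant, timepoint))

    def summary(self) -> str:
        lines = [
            "Per-timepoint LOO classification (accuracy %, [95 % CI])",
            "=" * 64,
        ]
        for r in self.results:
            lo, hi = r.ci["accuracy"]
            lines.append(
                f"{r.variant:>13} {r.timepoint:>5}: "
                f"{r.accuracy:5.1f} [{lo:5.1f}, {hi:5.1f}]  (n={r.n_samples})"
            )
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Accuracy vs time per variant with CI whiskers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.frame.query("metric == 'accuracy'")
        for variant, sub in df.groupby("variant"):
            sub = sub.set_index("timepoint").reindex(
                [t for t in TIMEPOINTS if t in set(sub["timepoint"])]
            )
            x = np.arange(len(sub))
            ax.errorbar(
                x,
                sub["value"],
                yerr=[sub["value"] - sub["ci_lo"], sub["ci_hi"] - sub["value"]],
                label=variant,
                marker="o",
                capsize=3,
            )
            ax.set_xticks(x, sub.index)
        ax.axhline(50, color="grey", ls=":")
        ax.set_ylabel("LOO accuracy (%)")
        ax.set_xlabel("timepoint")
        ax.legend()
        return ax


class BreathStudy:
    """Model object for one synthetic (or loaded) study.

    Parameters
    ----------
    measurements, physio_records, calibration
        The cohort's e-Nose measurements, physiological records, and the
        clean-air FiO2 calibration series.
    specs
        Model variants to evaluate; defaults to all four.
    timepoints
        Cumulative evaluation targets; defaults to t5..t180.

    ``fit()`` runs the per-timepoint leave-one-out evaluation and returns
    a :class:`StudyResults`.
    """

    def __init__(
        self,
        measurements,
        physio_records,
        calibration,
        specs: Sequence[ModelSpec] | None = None,
        timepoints: Sequence[str] = TIMEPOINTS[1:],
        unit: str = "animal",
    ) -> None:
        self.measurements = list(measurements)
        self.physio_records = list(physio_records)
        self.calibration = calibration
        self.specs = list(specs) if specs is not None else [
            ModelSpec(variant=v) for v in VARIANTS
        ]
        self.timepoints = list(timepoints)
        self.unit = unit

    @classmethod
    def from_spec(cls, cohort_spec, models=None, calibration_seed: int | None = None, **kw):
        """Simulate a cohort + calibration series and wrap them as a study."""
        from .simulate import default_sensor_models, simulate_calibration_series, simulate_cohort

        if models is None:
            models = default_sensor_models()
        meas, physio = simulate_cohort(cohort_spec, models)
        cal_seed = (
            calibration_seed
            if calibration_seed is not None
            else (cohort_spec.seed + 7919) % (2**31)
        )
        cal = simulate_calibration_series(
            models,
            phase_bounds=cohort_spec.phase_bounds,
            rate_hz=cohort_spec.rate_hz,
            seed=cal_seed,
        )
        return cls(meas, physio, cal, **kw)

    def fit(self) -> StudyResults:
        return run_study(
            self.measurements,
            self.physio_records,
            self.calibration,
            specs=self.specs,
            timepoints=self.timepoints,
            unit=self.unit,
        )
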