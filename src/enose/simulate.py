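"""Synthetic e-Nose and physiology generator.

Real study data is unavailable, so every downstream stage is exercised on
synthetic cohorts with the statistical structure the analysis assumes:

* n-type MOS channels whose resistance *drops* on exposure to breath
  volatile compounds (VCs) and *rises* with the oxygen fraction of the
  sample — the FiO2 confound the correction surfaces exist to remove;
* a control vs LPS (endotoxin) contrast whose VC divergence grows with
  time since administration, mirroring the stepped LPS dose escalation;
* group-correlated FiO2 escalation (sicker LPS animals need more oxygen),
  which makes FiO2 a genuine confounder for classification;
* per-timepoint physiological records (MAP/DBP/SBP, HR, T) with the
  hypotension / tachycardia / fever pattern of endotoxemia.

The sensor forward model is a first-order on/off envelope g(t) with
separable VC and O2 terms; ``o2_mode`` selects whether the O2 term adds to
or multiplies the VC-depressed resistance.  The additive mode is corrected
*exactly* by the k_diff surface and the multiplicative mode by k_ratio,
which is the core cross-module test harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    CALIBRATION_LEVELS,
    DEFAULT_CHANNELS,
    DEFAULT_PHASE_BOUNDS,
    REFERENCE_FIO2,
    TIMEPOINTS,
    CalibrationSeries,
    ENoseMeasurement,
    SensorCurve,
    ValidationError,
)

__all__ = [
    "SensorModel",
    "PhysioRecord",
    "CohortSpec",
    "default_sensor_models",
    "simulate_curve",
    "simulate_calibration_series",
    "simulate_cohort",
    "null_cohort_spec",
    "strong_effect_spec",
    "confounded_spec",
]


@dataclass
class SensorModel:
    """Forward model of one MOS channel.

    r0
        clean-air baseline resistance at room air, ohms.
    beta_o2
        fractional resistance increase per unit FiO2 above 0.21.
    alpha_vc
        maximal fractional resistance decrease at unit VC load; < 1 so the
        resistance stays positive.
    tau_on, tau_off
        first-order response / recovery time constants, seconds.
    noise_cv
        coefficient of variation of the multiplicative lognormal noise.
    o2_mode
        "additive" or "multiplicative" coupling of the O2 term (see module
        docstring).
    """

    channel_id: str
    r0: float
    beta_o2: float
    alpha_vc: float
    tau_on: float = 20.0
    tau_off: float = 60.0
    noise_cv: float = 0.01
    o2_mode: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValidationError(f"{self.channel_id}: r0 must be > 0")
        if not 0 <= self.alpha_vc < 1:
            raise ValidationError(f"{self.channel_id}: alpha_vc must be in [0, 1)")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValidationError(f"{self.channel_id}: time constants must be > 0")
        if self.o2_mode not in ("additive", "multiplicative"):
            raise ValidationError(f"{self.channel_id}: unknown o2_mode {self.o2_mode!r}")


def default_sensor_models(
    o2_mode: str = "multiplicative", noise_cv: float = 0.01
) -> dict[str, SensorModel]:
    """The default 8-channel array with per-channel plausible Figaro-like
    baselines and sensitivities (assumptions, not estimates of any device)."""
    params = {
        # channel:            r0 (ohm), beta_o2, alpha_vc, tau_on, tau_off
        "TGS2603_a": (40_000.0, 0.90, 0.45, 18.0, 55.0),
        "TGS2603_b": (45_000.0, 0.95, 0.42, 20.0, 60.0),
        "TGS2600_a": (30_000.0, 0.70, 0.35, 22.0, 65.0),
        "TGS2600_b": (33_000.0, 0.65, 0.38, 21.0, 62.0),
        "TGS2610": (8_000.0, 0.50, 0.25, 17.0, 50.0),
        "TGS2620": (15_000.0, 0.80, 0.40, 19.0, 58.0),
        "TGS2611": (10_000.0, 0.55, 0.22, 18.0, 52.0),
        "TGS2602": (55_000.0, 1.20, 0.50, 24.0, 70.0),
    }
    assert tuple(params) == DEFAULT_CHANNELS
    return {
        cid: SensorModel(cid, r0, b, a, ton, toff, noise_cv=noise_cv, o2_mode=o2_mode)
        for cid, (r0, b, a, ton, toff) in params.items()
    }


def _envelope(
    times: np.ndarray,
    phase_bounds: tuple[float, float, float],
    tau_on: float,
    tau_off: float,
) -> np.ndarray:
    """First-order exposure envelope: 0 in "before", saturating rise while
    breath flows, exponential recovery in "after"."""
    b, d, _ = phase_bounds
    g = np.zeros_like(times)
    during = (times >= b) & (times < d)
    g[during] = 1.0 - np.exp(-(times[during] - b) / tau_on)
    g_end = 1.0 - np.exp(-(d - b) / tau_on)
    after = times >= d
    g[after] = g_end * np.exp(-(times[after] - d) / tau_off)
    return g


def simulate_curve(
    s: SensorModel,
    vc_load: float,
    fio2: float,
    phase_bounds: tuple[float, float, float] = DEFAULT_PHASE_BOUNDS,
    rate_hz: float = 1.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> SensorCurve:
    """Forward-simulate one channel's response curve.

    Additive O2 mode::

        R(t) = r0·(1 − alpha_vc·vc·g(t)) + r0·beta_o2·(fio2 − 0.21)·g(t)

    Multiplicative mode::

        R(t) = r0·(1 − alpha_vc·vc·g(t))·(1 + beta_o2·(fio2 − 0.21)·g(t))

    with g(t) the first-order on/off envelope.  Multiplicative lognormal
    noise with CV ``noise_cv``; deterministic per seed.
    """
    if vc_load < 0:
        raise ValueError("vc_load must be >= 0")
    b, d, total = phase_bounds
    times = np.arange(0, round(total * rate_hz) + 1) / rate_hz
    g = _envelope(times, phase_bounds, s.tau_on, s.tau_off)
    vc_term = 1.0 - s.alpha_vc * vc_load * g
    o2_term = s.beta_o2 * (fio2 - REFERENCE_FIO2) * g
    if s.o2_mode == "additive":
        clean = s.r0 * vc_term + s.r0 * o2_term
    else:
        clean = s.r0 * vc_term * (1.0 + o2_term)
    if np.any(clean <= 0):
        raise ValueError(
            f"{s.channel_id}: vc_load={vc_load} drives resistance non-positive"
        )
    if s.noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(s.noise_cv**2))
        clean = clean * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=len(times)))
    return SensorCurve(s.channel_id, times, clean, phase_bounds=phase_bounds)


def simulate_calibration_series(
    models: dict[str, SensorModel],
    levels: tuple[float, ...] = CALIBRATION_LEVELS,
    n_replicates: int = 3,
    phase_bounds: tuple[float, float, float] = DEFAULT_PHASE_BOUNDS,
    rate_hz: float = 1.0,
    seed: int = 0,
) -> CalibrationSeries:
    """Clean-air (vc_load = 0) measurements at each FiO2 level, replicated.

    The study protocol is 6 levels (21–50 %) with 3 bags per level, i.e.
    18 measurements; replicate-to-replicate variation comes from sensor
    noise alone.
    """
    if not any(np.isclose(levels, REFERENCE_FIO2)):
        raise ValidationError("reference level 0.21 missing")
    rng = np.random.default_rng(seed)
    replicates: dict[float, list[ENoseMeasurement]] = {}
    for lvl in levels:
        reps = []
        for i in range(n_replicates):
            curves = {
                cid: simulate_curve(
                    m, 0.0, lvl, phase_bounds, rate_hz, rng=rng
                )
                for cid, m in models.items()
            }
            reps.append(
                ENoseMeasurement(
                    animal_id=f"cal{int(round(lvl * 100)):02d}_{i}",
                    group="calibration",
                    timepoint="cal",
                    fio2=float(lvl),
                    curves=curves,
                )
            )
        replicates[float(lvl)] = reps
    return CalibrationSeries(levels=tuple(float(v) for v in levels), replicates=replicates)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class PhysioRecord:
    """Per-timepoint physiological record of one animal."""

    animal_id: str
    group: str
    timepoint: str
    MAP: float  # mmHg
    DBP: float
    SBP: float
    HR: float  # beats/min
    T: float  # degC
    fio2: float
    peep: float = 5.0  # cmH2O
    pip: float = 20.0

    def __post_init__(self) -> None:
        if not (self.DBP <= self.MAP <= self.SBP):
            raise ValidationError(
                f"{self.animal_id}/{self.timepoint}: DBP <= MAP <= SBP violated "
                f"({self.DBP:.1f}, {self.MAP:.1f}, {self.SBP:.1f})"
            )
        for name in ("MAP", "DBP", "SBP", "HR", "T", "fio2", "peep", "pip"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{self.animal_id}: {name} must be positive")


# Default schedules.  LPS VC load tracks the stepped dose escalation
# (1.75 -> 2.00 -> 2.25 ug/kg/h) monotonically; control stays at a small
# constant background.  FiO2: control flat at 0.30, LPS escalating after
# t30 toward 0.50 as oxygenation worsens.
_DEFAULT_VC_EFFECT: dict[str, tuple[float, float]] = {
    "t0": (0.05, 0.05),
    "t5": (0.05, 0.10),
    "t30": (0.05, 0.20),
    "t60": (0.05, 0.35),
    "t90": (0.05, 0.50),
    "t120": (0.05, 0.65),
    "t150": (0.05, 0.80),
    "t180": (0.05, 0.90),
}

_DEFAULT_FIO2_POLICY: dict[tuple[str, str], float] = {
    **{("control", tp): 0.30 for tp in TIMEPOINTS},
    ("LPS", "t0"): 0.30,
    ("LPS", "t5"): 0.30,
    ("LPS", "t30"): 0.30,
    ("LPS", "t60"): 0.35,
    ("LPS", "t90"): 0.40,
    ("LPS", "t120"): 0.45,
    ("LPS", "t150"): 0.50,
    ("LPS", "t180"): 0.50,
}

# Physiology means per timepoint: (MAP, HR, T).  Control is kept above
# 80 mmHg; the LPS group is allowed to drop to 40-60 mmHg with rising HR
# and temperature.
_PHYSIO_CONTROL = {tp: (86.0, 80.0, 38.5) for tp in TIMEPOINTS}
_PHYSIO_LPS = {
    "t0": (86.0, 80.0, 38.5),
    "t5": (80.0, 88.0, 38.6),
    "t30": (68.0, 100.0, 38.9),
    "t60": (56.0, 112.0, 39.3),
    "t90": (50.0, 122.0, 39.7),
    "t120": (50.0, 128.0, 40.0),
    "t150": (50.0, 133.0, 40.2),
    "t180": (50.0, 137.0, 40.4),
}


@dataclass
class CohortSpec:
    """Stated world of one synthetic study arm pair.

    ``vc_effect`` maps timepoint -> (control load, LPS load); per-animal
    loads are drawn around the group mean with SD ``vc_sd``.  ``fio2_policy``
    maps (group, timepoint) -> FiO2 — the confounding channel, recorded in
    both the measurement and the physio record.
    """

    n_control: int = 9
    n_lps: int = 10
    timepoints: tuple[str, ...] = TIMEPOINTS
    vc_effect: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_VC_EFFECT)
    )
    vc_sd: float = 0.05
    fio2_policy: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_FIO2_POLICY)
    )
    physio_means: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {"control": dict(_PHYSIO_CONTROL), "LPS": dict(_PHYSIO_LPS)}
    )
    physio_sds: tuple[float, float, float] = (5.0, 8.0, 0.3)  # MAP, HR, T
    rate_hz: float = 1.0
    phase_bounds: tuple[float, float, float] = DEFAULT_PHASE_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_lps < 1:
            raise ValidationError("group counts must be >= 1")
        for (g, tp), f in self.fio2_policy.items():
            if not (REFERENCE_FIO2 <= f <= 0.50):
                raise ValidationError(
                    f"fio2_policy[{g},{tp}]={f} outside calibration hull [0.21, 0.50]"
                )
        for tp in self.timepoints:
            if tp not in self.vc_effect:
                raise ValidationError(f"vc_effect missing timepoint {tp}")


def null_cohort_spec(seed: int = 0, n_control: int = 10, n_lps: int = 10) -> CohortSpec:
    """Zero VC effect, shared flat FiO2, identical physiology: the null world.

    Group labels carry no information; any classifier should sit at chance.
    """
    return CohortSpec(
        n_control=n_control,
        n_lps=n_lps,
        vc_effect={tp: (0.05, 0.05) for tp in TIMEPOINTS},
        fio2_policy={(g, tp): 0.30 for g in ("control", "LPS") for tp in TIMEPOINTS},
        physio_means={"control": dict(_PHYSIO_CONTROL), "LPS": dict(_PHYSIO_CONTROL)},
        seed=seed,
    )


def strong_effect_spec(seed: int = 0) -> CohortSpec:
    """Fast-onset, large VC divergence with flat shared FiO2 (no confound).

    The group separation is many within-group SDs from t5 onward (not a
    slow ramp): per-timepoint models pool all cumulative rows, so a
    recovery check needs the signal strong over the whole evaluated
    window, not only at its end.  The dose-tracking ramp lives in the
    default :class:`CohortSpec`.
    """
    spec = CohortSpec(
        vc_effect={
            "t0": (0.05, 0.05),
            "t5": (0.05, 0.45),
            "t30": (0.05, 0.55),
            "t60": (0.05, 0.65),
            "t90": (0.05, 0.75),
            "t120": (0.05, 0.80),
            "t150": (0.05, 0.85),
            "t180": (0.05, 0.90),
        },
        fio2_policy={(g, tp): 0.30 for g in ("control", "LPS") for tp in TIMEPOINTS},
        seed=seed,
    )
    return spec


def confounded_spec(seed: int = 0) -> CohortSpec:
    """No VC effect, but group-coupled FiO2 escalation.

    The only group signal in the sensor curves is the oxygen response;
    an uncorrected model can (spuriously) classify on it, a corrected one
    cannot.  Physiology is shared so the contrast is purely the confound.
    """
    spec = CohortSpec(
        vc_effect={tp: (0.05, 0.05) for tp in TIMEPOINTS},
        physio_means={"control": dict(_PHYSIO_CONTROL), "LPS": dict(_PHYSIO_CONTROL)},
        seed=seed,
    )
    return spec


def _physio_record(
    rng: np.random.Generator,
    animal_id: str,
    group: str,
    tp: str,
    spec: CohortSpec,
    fio2: float,
) -> PhysioRecord:
    map_mu, hr_mu, t_mu = spec.physio_means[group][tp]
    map_sd, hr_sd, t_sd = spec.physio_sds
    MAP = max(20.0, rng.normal(map_mu, map_sd))
    pulse_up = max(5.0, rng.normal(30.0, 5.0))
    pulse_down = max(3.0, rng.normal(15.0, 4.0))
    return PhysioRecord(
        animal_id=animal_id,
        group=group,
        timepoint=tp,
        MAP=MAP,
        DBP=MAP - pulse_down,
        SBP=MAP + pulse_up,
        HR=max(30.0, rng.normal(hr_mu, hr_sd)),
        T=rng.normal(t_mu, t_sd),
        fio2=fio2,
        peep=max(1.0, rng.normal(5.0, 0.5)),
        pip=max(10.0, rng.normal(20.0, 1.0)),
    )


def simulate_cohort(
    spec: CohortSpec, models: dict[str, SensorModel] | None = None
) -> tuple[list[ENoseMeasurement], list[PhysioRecord]]:
    """One measurement and one physio record per animal per timepoint.

    VC loads are drawn per animal/timepoint around the group schedule;
    FiO2 follows ``spec.fio2_policy`` and is recorded in both outputs
    (it is the confounding channel).  Exactly reproducible per
    ``spec.seed``.
    """
    if models is None:
        models = default_sensor_models()
    rng = np.random.default_rng(spec.seed)
    animals = [("control", f"ctl{i:02d}") for i in range(1, spec.n_control + 1)]
    animals += [("LPS", f"lps{i:02d}") for i in range(1, spec.n_lps + 1)]
    measurements: list[ENoseMeasurement] = []
    physio: list[PhysioRecord] = []
    for group, aid in animals:
        for tp in spec.timepoints:
            mu = spec.vc_effect[tp][0 if group == "control" else 1]
            vc = max(0.0, rng.normal(mu, spec.vc_sd))
            fio2 = spec.fio2_policy[(group, tp)]
            curves = {
                cid: simulate_curve(
                    m, vc, fio2, spec.phase_bounds, spec.rate_hz, rng=rng
                )
                for cid, m in models.items()
            }
            measurements.append(
                ENoseMeasurement(
                    animal_id=aid, group=group, timepoint=tp, fio2=fio2, curves=curves
                )
            )
            physio.append(_physio_record(rng, aid, group, tp, spec, fio2))
    return measurements, physio
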