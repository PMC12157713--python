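"""End-to-end orchestration: simulate -> calibrate -> correct -> featurize
-> train-eval -> report, as one reproducible run.

A run is driven by a :class:`RunConfig` (YAML-serializable); all randomness
flows from named seeds in the config, every intermediate artifact is
persisted so each stage is independently inspectable, and re-running the
same config reproduces a byte-identical results CSV.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import ModelSpec, VARIANTS, run_study
from .correction import build_surfaces, write_surfaces
from .features import iqr_screen
from .io import TIMEPOINTS, write_cohort, write_measurement
from .simulate import (
    CohortSpec,
    default_sensor_models,
    simulate_calibration_series,
    simulate_cohort,
)

__all__ = ["RunConfig", "run_all", "demo_config"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    outdir: str = "enose_run"
    seed: int = 0
    scenario: str = "default"  # default | null | strong | confounded
    n_control: int = 9
    n_lps: int = 10
    rate_hz: float = 1.0
    o2_mode: str = "multiplicative"
    noise_cv: float = 0.01
    strategies: tuple[str, ...] = ("diff", "ratio")
    variants: tuple[str, ...] = VARIANTS
    timepoints: tuple[str, ...] = TIMEPOINTS[1:]
    tree_max_depth: int = 3
    fence_mult: float = 1.5
    loo_unit: str = "animal"

    def __post_init__(self) -> None:
        for s in self.strategies:
            if s not in ("diff", "ratio"):
                raise ValueError(f"unknown correction strategy {s!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown model variant {v!r}")
        for t in self.timepoints:
            if t not in TIMEPOINTS or t == "t0":
                raise ValueError(f"invalid evaluation timepoint {t!r}")
        if self.scenario not in ("default", "null", "strong", "confounded"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def cohort_spec(self) -> CohortSpec:
        from .simulate import confounded_spec, null_cohort_spec, strong_effect_spec

        if self.scenario == "null":
            spec = null_cohort_spec(self.seed, self.n_control, self.n_lps)
        elif self.scenario == "strong":
            spec = strong_effect_spec(self.seed)
        elif self.scenario == "confounded":
            spec = confounded_spec(self.seed)
        else:
            spec = CohortSpec(seed=self.seed)
        spec.n_control = self.n_control
        spec.n_lps = self.n_lps
        spec.rate_hz = self.rate_hz
        return spec

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        for k in ("strategies", "variants", "timepoints"):
            d[k] = list(d[k])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("strategies", "variants", "timepoints"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def demo_config(outdir: str = "enose_demo", seed: int = 1) -> RunConfig:
    """Small, fast demonstration run (coarse grid, small cohort)."""
    return RunConfig(outdir=outdir, seed=seed, n_control=5, n_lps=5, rate_hz=0.25)


def run_all(config: RunConfig) -> Path:
    """Execute every stage, persisting intermediates, logs and results.

    Writes into ``config.outdir``: the config echo, cohort manifest +
    measurement CSVs, physio CSV, correction-surface CSVs, per-variant
    feature tables, outlier-removal report, the tidy results CSV and a
    JSONL log with per-stage timings.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_entries: list[dict] = []

    def log(stage: str, t_start: float, **info) -> None:
        log_entries.append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - t_start, 3), **info}
        )

    config.to_yaml(out / "config.yaml")

    models = default_sensor_models(o2_mode=config.o2_mode, noise_cv=config.noise_cv)

    t0 = time.perf_counter()
    spec = config.cohort_spec()
    measurements, physio = simulate_cohort(spec, models)
    cal = simulate_calibration_series(
        models,
        phase_bounds=spec.phase_bounds,
        rate_hz=spec.rate_hz,
        seed=(config.seed + 7919) % (2**31),
    )
    log("simulate", t0, n_measurements=len(measurements), n_physio=len(physio))

    t0 = time.perf_counter()
    write_cohort(measurements, out / "measurements")
    caldir = out / "calibration"
    caldir.mkdir(exist_ok=True)
    for m in cal.measurements():
        write_measurement(m, caldir / f"{m.animal_id}.csv")
    pd.DataFrame([dataclasses.asdict(r) for r in physio]).to_csv(
        out / "physio.csv", index=False, float_format="%.12g"
    )
    log("write_inputs", t0)

    t0 = time.perf_counter()
    for strat in config.strategies:
        surfaces = build_surfaces(cal, strat)
        write_surfaces(surfaces, out / f"surface_k{strat}.csv")
    log("calibrate", t0, strategies=list(config.strategies))

    t0 = time.perf_counter()
    from .classify import prepare_variant_table

    tables = {}
    for v in config.variants:
        tables[v] = prepare_variant_table(v, measurements, physio, cal)
        tables[v].to_csv(out / f"features_{v}.csv")
    log("featurize", t0, variants=list(config.variants))

    # Global removal report (diagnostic only; the LOO loop re-screens
    # inside each training fold).
    t0 = time.perf_counter()
    reports = []
    for v in config.variants:
        if v == "physio":
            continue
        _, rep = iqr_screen(tables[v], fence_mult=config.fence_mult)
        rep.insert(0, "variant", v)
        reports.append(rep)
    if reports:
        pd.concat(reports, ignore_index=True).to_csv(
            out / "outlier_report.csv", index=False, float_format="%.12g"
        )
    log("outlier_report", t0)

    t0 = time.perf_counter()
    specs = [
        ModelSpec(
            variant=v,
            tree_max_depth=config.tree_max_depth,
            fence_mult=config.fence_mult,
            seed=config.seed,
        )
        for v in config.variants
    ]
    study = run_study(
        measurements, physio, cal, specs=specs,
        timepoints=config.timepoints, unit=config.loo_unit,
    )
    results_csv = out / "results.csv"
    study.frame.to_csv(results_csv, index=False, float_format="%.10g")
    log("train_eval", t0, n_rows=len(study.frame))

    with log_path.open("w") as fh:
        for e in log_entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")
    return out
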