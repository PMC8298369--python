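"""Synthetic experimental campaign: design, sampling schedules, noisy series.

Emulates the bench campaign this model was built for: a full 3 x 3 x 2
factorial of initial H2O2 (94.5, 189, 378 mg/L = half, one and two times
the stoichiometric mineralization dose of 40 mg/L PCT) by initial Fe2+
(5, 7.5, 10 mg/L) by irradiation (dark / UV), eighteen 120-min runs in
total, all at 40 mg/L PCT, pH 2.8.

Species are sampled on their instrument schedules — HPLC for PCT at 0, 1.5,
2.5, 5, 7.5, 10 and 15 min; spectrophotometric H2O2 and iron every 5 min to
30 min then every 15 min to 120 min — and corrupted with independent
Gaussian noise at the standard errors of the measurement techniques (PCT
0.15, H2O2 1.43 mg/L), truncated at zero the way instruments report
near-zero readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParams
from .radiation import LvrpaTable, ReactorGeometry
from .reactor import SimulationResult, simulate

__all__ = [
    "ExperimentRun",
    "MeasurementSeries",
    "NoiseModel",
    "canonical_design",
    "sampling_schedule",
    "sample_series",
    "generate",
    "design_to_csv",
    "design_from_csv",
    "measurements_to_frame",
    "measurements_from_frame",
]

H2O2_LEVELS = (94.5, 189.0, 378.0)  # mg/L: R = 10.5, 21, 42
FE2_LEVELS = (5.0, 7.5, 10.0)  # mg/L
PCT_0 = 40.0  # mg/L
DURATION_MIN = 120.0

PCT_SCHEDULE = (0.0, 1.5, 2.5, 5.0, 7.5, 10.0, 15.0)
#: every 5 min to 30 min, then every 15 min to 120 min
SLOW_SCHEDULE = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 120.0)


@dataclass(frozen=True)
class ExperimentRun:
    """One run of the campaign: initial composition, irradiation, duration."""

    run_id: str
    c_pct_0: float
    c_h2o2_0: float
    c_fe2_0: float
    irradiated: bool
    duration: float = DURATION_MIN
    c_fe3_0: float = 0.0  # catalyst dosed as ferrous sulfate

    def __post_init__(self) -> None:
        for name in ("c_pct_0", "c_h2o2_0", "c_fe2_0", "c_fe3_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class MeasurementSeries:
    """Sampled, possibly noisy observations of one species in one run."""

    run_id: str
    species: str
    times: np.ndarray  # min
    values: np.ndarray  # mg/L
    noise_sd: float = 0.0
    seed: int | None = None
    model_backed: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size == 0 or t[0] != 0.0 or (t.size > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("times must be ascending and start at 0")
        if v.shape != t.shape or np.any(v < 0):
            raise ValueError("values must be non-negative, same shape as times")


@dataclass(frozen=True)
class NoiseModel:
    """Per-species measurement noise standard deviations (mg/L).

    PCT and H2O2 carry the instrument standard errors (0.15 and 1.43 mg/L);
    the iron default of 0.05 mg/L is an assumption (the phenanthroline
    method error was not characterized), and TOC uses the total-carbon
    analyzer error.
    """

    pct: float = 0.15
    h2o2: float = 1.43
    fe: float = 0.05
    toc: float = 0.23

    def sd_for(self, species: str) -> float:
        return {
            "PCT": self.pct,
            "H2O2": self.h2o2,
            "Fe2": self.fe,
            "FeTOT": self.fe,
            "TOC": self.toc,
        }[species]

    def scaled(self, factor: float) -> "NoiseModel":
        return NoiseModel(
            self.pct * factor, self.h2o2 * factor, self.fe * factor, self.toc * factor
        )


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0)


def canonical_design() -> list[ExperimentRun]:
    """The 18-run factorial design, ids E1-E18.

    E1-E9 are dark, E10-E18 irradiated; within each block Fe2+ is the outer
    factor (5, 7.5, 10 mg/L) and H2O2 the inner one (94.5, 189, 378 mg/L).
    """
    runs = []
    i = 1
    for irradiated in (False, True):
        for fe2 in FE2_LEVELS:
            for h2o2 in H2O2_LEVELS:
                runs.append(
                    ExperimentRun(
                        run_id=f"E{i}",
                        c_pct_0=PCT_0,
                        c_h2o2_0=h2o2,
                        c_fe2_0=fe2,
                        irradiated=irradiated,
                    )
                )
                i += 1
    return runs


def sampling_schedule(species: str) -> np.ndarray:
    """Sampling instants (min) for one measured species."""
    if species == "PCT":
        return np.array(PCT_SCHEDULE)
    if species in ("H2O2", "Fe2", "FeTOT", "TOC"):
        return np.array(SLOW_SCHEDULE)
    raise ValueError(f"unknown species {species!r}")


def sample_series(
    sim: SimulationResult,
    species: str,
    schedule_min: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    run_id: str | None = None,
) -> MeasurementSeries:
    """Sample one species on a schedule and add truncated-Gaussian noise."""
    clean = np.interp(schedule_min, sim.times_min, sim.species_mg_per_L(species))
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return MeasurementSeries(
        run_id=run_id or sim.run_id,
        species=species,
        times=np.asarray(schedule_min, dtype=float),
        values=np.clip(noisy, 0.0, None),
        noise_sd=noise_sd,
    )


def generate(
    run: ExperimentRun,
    params: KineticParams,
    geometry: ReactorGeometry,
    lvrpa_table: LvrpaTable | None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    include_toc: bool = False,
) -> dict[str, MeasurementSeries]:
    """Simulate one run and emit its noisy measurement series.

    Returns a dict keyed by species (PCT, H2O2, Fe2, FeTOT and, when
    requested, a TOC series that is *not model-backed* — it is the carbon
    equivalent of the PCT trajectory only, ignores intermediates, and must
    never enter fitting). The seed fully determines the output.
    """
    from .chem import toc_equivalent

    rng = np.random.default_rng(seed)
    schedules = {sp: sampling_schedule(sp) for sp in ("PCT", "H2O2", "Fe2", "FeTOT")}
    t_all = np.unique(np.concatenate(list(schedules.values())))
    sim = simulate(run, params, geometry, lvrpa_table, t_eval_min=t_all)
    out: dict[str, MeasurementSeries] = {}
    for sp, sched in schedules.items():
        out[sp] = sample_series(sim, sp, sched, noise.sd_for(sp), rng)
    if include_toc:
        sched = sampling_schedule("TOC")
        clean = toc_equivalent(1.0) * np.interp(
            sched, sim.times_min, sim.species_mg_per_L("PCT")
        )
        sd = noise.sd_for("TOC")
        noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
        out["TOC"] = MeasurementSeries(
            run_id=run.run_id,
            species="TOC",
            times=sched,
            values=np.clip(noisy, 0.0, None),
            noise_sd=sd,
            model_backed=False,
        )
    return out


# ---------------------------------------------------------------- file I/O

_DESIGN_COLS = [
    "run_id",
    "c_pct_0_mg_L",
    "c_h2o2_0_mg_L",
    "c_fe2_0_mg_L",
    "irradiated",
    "duration_min",
]


def design_to_csv(runs: list[ExperimentRun], path: str) -> None:
    pd.DataFrame(
        [
            (r.run_id, r.c_pct_0, r.c_h2o2_0, r.c_fe2_0, r.irradiated, r.duration)
            for r in runs
        ],
        columns=_DESIGN_COLS,
    ).to_csv(path, index=False)


def design_from_csv(path: str) -> list[ExperimentRun]:
    df = pd.read_csv(path, comment="#")
    missing = set(_DESIGN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"design CSV missing columns {sorted(missing)}")
    return [
        ExperimentRun(
            run_id=str(row.run_id),
            c_pct_0=float(row.c_pct_0_mg_L),
            c_h2o2_0=float(row.c_h2o2_0_mg_L),
            c_fe2_0=float(row.c_fe2_0_mg_L),
            irradiated=bool(row.irradiated),
            duration=float(row.duration_min),
        )
        for row in df.itertuples(index=False)
    ]


def measurements_to_frame(
    series: list[MeasurementSeries],
) -> pd.DataFrame:
    """Tidy frame: run_id, species, time_min, conc_mg_L."""
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            rows.append((s.run_id, s.species, float(t), float(v)))
    return pd.DataFrame(rows, columns=["run_id", "species", "time_min", "conc_mg_L"])


def measurements_from_frame(df: pd.DataFrame) -> list[MeasurementSeries]:
    out = []
    for (run_id, sp), g in df.groupby(["run_id", "species"], sort=True):
        g = g.sort_values("time_min")
        out.append(
            MeasurementSeries(
                run_id=str(run_id),
                species=str(sp),
                times=g["time_min"].to_numpy(),
                values=g["conc_mg_L"].to_numpy(),
            )
        )
    return out
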