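"""Multi-experiment nonlinear least squares for the kinetic constants.

The objective stacks, over every run of the campaign, the differences
between observed and predicted *normalized* PCT and H2O2 concentrations
(each series divided by its run's initial concentration); iron and TOC
series never enter the objective. Minimization is Levenberg-Marquardt over
log-transformed free parameters, which enforces positivity without a
constrained solver.

Because the rate laws depend on k4 and k5 only through their ratio, fitting
both simultaneously is structurally degenerate; by default k4 is held at
its literature-anchored value and (k1, k3, k5) are free. Per-species RMSE
on the normalized concentrations,

    RMSE_i = 100 * sqrt( sum_k (y_ik - y*_ik)^2 / n_i )  [%],

summarizes model reliability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .kinetics import KineticParams
from .radiation import LvrpaTable, ReactorGeometry
from .reactor import SimulationError, simulate
from .synthetic import ExperimentRun, MeasurementSeries

__all__ = ["FitResult", "residuals", "fit", "rmse"]

#: species entering the objective, in stacking order
FIT_SPECIES = ("PCT", "H2O2")
_FIT_PARAMS = ("k1", "k3", "k4", "k5")


def _natural_key(run_id: str):
    m = re.match(r"([A-Za-z]*)(\d+)$", run_id)
    return (m.group(1), int(m.group(2))) if m else (run_id, 0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-experiment fit."""

    params: KineticParams
    fixed: tuple[str, ...]
    residual_norm: float  # sum of squared residuals at params
    rmse_by_species: dict[str, float]  # %, per fitted species
    n_obs: dict[str, int]
    converged: bool
    n_iter: int
    message: str = ""


def _ordered_series(
    dataset: list[MeasurementSeries], runs: dict[str, ExperimentRun]
) -> list[tuple[ExperimentRun, MeasurementSeries]]:
    """Fitted series in deterministic (run, species, time) order."""
    picked = [s for s in dataset if s.species in FIT_SPECIES]
    for s in picked:
        if s.run_id not in runs:
            raise KeyError(f"measurement series references unknown run {s.run_id!r}")
    picked.sort(key=lambda s: (_natural_key(s.run_id), FIT_SPECIES.index(s.species)))
    return [(runs[s.run_id], s) for s in picked]


def residuals(
    params: KineticParams,
    dataset: list[MeasurementSeries],
    runs: dict[str, ExperimentRun] | list[ExperimentRun],
    geometry: ReactorGeometry,
    lvrpa_table: LvrpaTable | None,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Stacked normalized residuals (observed - predicted) over all runs.

    One entry per PCT or H2O2 observation, in deterministic (run, species,
    time) order; each run is simulated once on the union of its observation
    times.
    """
    if not isinstance(runs, dict):
        runs = {r.run_id: r for r in runs}
    ordered = _ordered_series(dataset, runs)

    # simulate each run once on the union of its fitted schedules
    by_run: dict[str, list[MeasurementSeries]] = {}
    for run, s in ordered:
        by_run.setdefault(run.run_id, []).append(s)
    predictions: dict[tuple[str, str], np.ndarray] = {}
    for run_id, series_list in by_run.items():
        run = runs[run_id]
        t_all = np.unique(np.concatenate([s.times for s in series_list]))
        sim = simulate(run, params, geometry, lvrpa_table, t_eval_min=t_all, rtol=rtol)
        for s in series_list:
            pred = np.interp(s.times, sim.times_min, sim.species_mg_per_L(s.species))
            predictions[(run_id, s.species)] = pred

    chunks = []
    for run, s in ordered:
        y0 = run.c_pct_0 if s.species == "PCT" else run.c_h2o2_0
        if y0 <= 0:
            raise ValueError(
                f"run {run.run_id!r}: initial {s.species} must be > 0 to normalize"
            )
        pred = predictions[(run.run_id, s.species)]
        chunks.append((s.values - pred) / y0)
    return np.concatenate(chunks) if chunks else np.array([])


def rmse(observed, predicted) -> float:
    """Root mean square error between normalized series, in percent."""
    y = np.asarray(observed, dtype=float)
    ystar = np.asarray(predicted, dtype=float)
    if y.shape != ystar.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {ystar.shape}")
    if y.size == 0:
        raise ValueError("need at least one observation")
    return 100.0 * float(np.sqrt(np.mean((y - ystar) ** 2)))


def fit(
    dataset: list[MeasurementSeries],
    runs: dict[str, ExperimentRun] | list[ExperimentRun],
    geometry: ReactorGeometry,
    lvrpa_table: LvrpaTable | None,
    initial_guess: KineticParams,
    fixed: tuple[str, ...] = ("k4",),
    tol: float = 1e-8,
    sim_rtol: float = 1e-8,
    max_nfev: int | None = None,
) -> FitResult:
    """Estimate the free rate constants by Levenberg-Marquardt.

    ``fixed`` names the rate constants held at their ``initial_guess``
    values (default: k4, breaking the k4/k5 ratio degeneracy); ``phi_bar``
    is always held. Returns ``converged=False`` — never raises — when the
    solver fails or the data carry no information (zero Jacobian).
    """
    if not isinstance(runs, dict):
        runs = {r.run_id: r for r in runs}
    unknown = set(fixed) - set(_FIT_PARAMS)
    if unknown:
        raise ValueError(f"unknown fixed parameters {sorted(unknown)}")
    free = [p for p in _FIT_PARAMS if p not in fixed]
    if not free:
        raise ValueError("no free parameters to fit")

    def unpack(x: np.ndarray) -> KineticParams:
        return initial_guess.replace(**{p: float(np.exp(v)) for p, v in zip(free, x)})

    n_residuals = sum(
        s.times.size for s in dataset if s.species in FIT_SPECIES
    )

    def objective(x: np.ndarray) -> np.ndarray:
        try:
            return residuals(
                unpack(x), dataset, runs, geometry, lvrpa_table, rtol=sim_rtol
            )
        except SimulationError:
            # transient excursion into an unsolvable parameter region:
            # a uniformly huge residual steers the optimizer back
            return np.full(n_residuals, 1e3)

    x0 = np.log([getattr(initial_guess, p) for p in free])
    try:
        res = least_squares(
            objective,
            x0,
            method="lm",
            xtol=tol,
            ftol=tol,
            gtol=tol,
            max_nfev=max_nfev,
        )
    except Exception as exc:  # solver blow-up stays diagnosable
        n = {sp: sum(s.times.size for s in dataset if s.species == sp) for sp in FIT_SPECIES}
        return FitResult(
            params=initial_guess,
            fixed=tuple(fixed),
            residual_norm=float("nan"),
            rmse_by_species={},
            n_obs=n,
            converged=False,
            n_iter=0,
            message=f"solver error: {exc}",
        )

    params_hat = unpack(res.x)
    informative = bool(np.max(np.abs(res.jac)) > 1e-12) if res.jac is not None else False
    final = objective(res.x)

    # per-species RMSE on normalized concentrations at the optimum
    rmse_by_species: dict[str, float] = {}
    n_obs: dict[str, int] = {}
    ordered = _ordered_series(dataset, runs)
    offsets = np.cumsum([0] + [s.times.size for _, s in ordered])
    for sp in FIT_SPECIES:
        parts = [
            final[offsets[i] : offsets[i + 1]]
            for i, (_, s) in enumerate(ordered)
            if s.species == sp
        ]
        if parts:
            r = np.concatenate(parts)
            rmse_by_species[sp] = 100.0 * float(np.sqrt(np.mean(r**2)))
            n_obs[sp] = int(r.size)
    return FitResult(
        params=params_hat,
        fixed=tuple(fixed),
        residual_norm=float(np.sum(final**2)),
        rmse_by_species=rmse_by_species,
        n_obs=n_obs,
        converged=bool(res.success and informative),
        n_iter=int(res.nfev),
        message=res.message if informative else "non-identifiable: zero Jacobian",
    )
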