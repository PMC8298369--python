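"""Shared fixtures: bench geometry, synthetic radiation data, LVRPA table,
generating parameters, and the canonical noiseless campaign."""

import numpy as np
import pytest

import photofenton as pf
from photofenton.synthetic import ZERO_NOISE

#: Fe3+ grid (mg/L) used for LVRPA tabulation throughout the suite; spans
#: the canonical catalyst range with headroom.
LVRPA_GRID = [0.0, 1.0, 2.5, 5.0, 7.5, 10.0, 12.5]


@pytest.fixture(scope="session")
def geometry():
    return pf.default_geometry()


@pytest.fixture(scope="session")
def spectrum():
    return pf.synthetic_spectrum()


@pytest.fixture(scope="session")
def absorptivity():
    return pf.synthetic_absorptivity()


@pytest.fixture(scope="session")
def lvrpa_table(geometry, spectrum, absorptivity):
    return pf.build_lvrpa_table(LVRPA_GRID, geometry, spectrum, absorptivity)


@pytest.fixture(scope="session")
def params():
    return pf.default_params()


@pytest.fixture(scope="session")
def design():
    return pf.canonical_design()


@pytest.fixture(scope="session")
def noiseless_dataset(design, params, geometry, lvrpa_table):
    """Noiseless measurements for all 18 canonical runs."""
    dataset = []
    for i, run in enumerate(design):
        series = pf.generate(
            run, params, geometry, lvrpa_table, noise=ZERO_NOISE, seed=i
        )
        dataset.extend(series.values())
    return dataset


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_dataset, design, params, geometry, lvrpa_table):
    """Round-trip fit on the noiseless campaign from a 3x-perturbed guess,
    k4 held fixed."""
    guess = params.replace(k1=params.k1 * 3, k3=params.k3 * 3, k5=params.k5 * 3)
    return pf.fit(
        noiseless_dataset, design, geometry, lvrpa_table, guess, fixed=("k4",)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def rk4_crosscheck(geometry):
    """Stiff-solver endpoint vs classic fixed-step RK4 at dt = 1e-3 s.

    Slowed-down rate constants keep the whole transient inside the 10-min
    window at amplitudes where relative comparison is meaningful; the
    oracle integrates the same rate laws independently.
    """
    from photofenton.synthetic import ExperimentRun

    params = pf.default_params().replace(k1=14.729, k3=0.316)
    run = ExperimentRun(
        run_id="RK4", c_pct_0=40.0, c_h2o2_0=94.5, c_fe2_0=5.0,
        irradiated=False, duration=10.0,
    )
    sim = pf.simulate(run, params, geometry, None, t_eval_min=[0.0, 10.0])

    k1, k3, k4, k5 = params.k1, params.k3, params.k4, params.k5

    def rhs(cp, ch, cf2, cf3):
        a, b = k5 * max(cp, 0.0), k4 * max(ch, 0.0)
        s = a + b
        idelta = a / s if s > 0 else 0.0
        irho = b / s if s > 0 else 0.0
        fenton = k1 * max(cf2, 0.0) * max(ch, 0.0)
        g = k3 * max(cf3, 0.0) * max(ch, 0.0)
        return (
            -fenton * idelta,
            -fenton - fenton * irho - g,
            -fenton + g,
            +fenton - g,
        )

    y = list(sim.conc[0])
    dt = 1e-3
    for _ in range(600_000):
        q1 = rhs(*y)
        q2 = rhs(*(yi + dt / 2 * ki for yi, ki in zip(y, q1)))
        q3 = rhs(*(yi + dt / 2 * ki for yi, ki in zip(y, q2)))
        q4 = rhs(*(yi + dt * ki for yi, ki in zip(y, q3)))
        y = [
            yi + dt / 6 * (a + 2 * b + 2 * c + d)
            for yi, a, b, c, d in zip(y, q1, q2, q3, q4)
        ]
    return sim.conc[1], np.array(y)
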