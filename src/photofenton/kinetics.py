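"""Reduced rate laws for Fenton / photo-Fenton paracetamol degradation.

The mechanism has five steps:

1. Fe2+ + H2O2 -> Fe3+ + OH- + HO.          (Fenton, k1)
2. Fe(OH)2+ + hv -> Fe2+ + HO.              (photolysis, quantum yield phi_bar)
3. Fe3+ + H2O2 -> Fe2+ + H+ + HO2.          (Fenton-like, k3)
4. H2O2 + HO. -> HO2. + H2O                 (k4)
5. PCT + HO. -> intermediates               (k5)

Applying the steady-state approximation to HO. collapses the radical balance
into two partition factors:

    1/delta = k5 C_PCT / (k5 C_PCT + k4 C_H2O2)   (fraction attacking PCT)
    1/rho   = k4 C_H2O2 / (k5 C_PCT + k4 C_H2O2)  (fraction attacking H2O2)

so 1/delta + 1/rho = 1 identically. Each HO. produced by the Fenton or
photolysis step is consumed either by PCT or by H2O2; iron cycles between
the +2 and +3 states and is conserved.

Rates depend on (k4, k5) only through their ratio — the structural
non-identifiability that forces one of the two to be fixed during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ConcentrationState",
    "KineticParams",
    "RateVector",
    "default_params",
    "delta",
    "rho",
    "radical_partition",
    "gamma_rate",
    "thermal_rates",
    "total_rates",
]


@dataclass(frozen=True)
class ConcentrationState:
    """Molar concentrations (mol/L) of the four kinetic species."""

    c_pct: float
    c_h2o2: float
    c_fe2: float
    c_fe3: float

    def __post_init__(self) -> None:
        for name in ("c_pct", "c_h2o2", "c_fe2", "c_fe3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants (M-1 s-1) and wavelength-averaged quantum yield.

    ``phi_bar`` is the primary quantum yield of ferric-hydroxo complex
    photolysis averaged over 300-420 nm, in mol per Einstein absorbed.
    """

    k1: float
    k3: float
    k4: float
    k5: float
    phi_bar: float

    def __post_init__(self) -> None:
        for name in ("k1", "k3", "k4", "k5", "phi_bar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


def default_params() -> KineticParams:
    """Rate constants estimated for paracetamol degradation at pH 2.8.

    k1 (Fenton) = 147.29, k3 (Fenton-like) = 3.16, k4 (HO. + H2O2) = 7.00e7,
    k5 (HO. + PCT) = 3.58e9, all M-1 s-1. ``phi_bar`` = 0.14 mol/Einstein, a
    representative literature magnitude for Fe(OH)2+ photolysis in the
    near-UV.
    """
    return KineticParams(k1=147.29, k3=3.16, k4=7.00e7, k5=3.58e9, phi_bar=0.14)


@dataclass(frozen=True)
class RateVector:
    """Net production rates (mol/L/s); negative = consumption."""

    r_pct: float
    r_h2o2: float
    r_fe2: float
    r_fe3: float

    def __add__(self, other: "RateVector") -> "RateVector":
        return RateVector(
            self.r_pct + other.r_pct,
            self.r_h2o2 + other.r_h2o2,
            self.r_fe2 + other.r_fe2,
            self.r_fe3 + other.r_fe3,
        )


def delta(state: ConcentrationState, params: KineticParams) -> float:
    """Partition factor delta = 1 + (k4/k5)(C_H2O2/C_PCT).

    1/delta is the fraction of hydroxyl radicals attacking PCT.
    """
    if state.c_pct <= 0:
        raise ZeroDivisionError("delta undefined at c_pct = 0")
    return 1.0 + (params.k4 / params.k5) * (state.c_h2o2 / state.c_pct)


def rho(state: ConcentrationState, params: KineticParams) -> float:
    """Partition factor rho = 1 + (k5/k4)(C_PCT/C_H2O2).

    1/rho is the fraction of hydroxyl radicals attacking H2O2.
    """
    if state.c_h2o2 <= 0:
        raise ZeroDivisionError("rho undefined at c_h2o2 = 0")
    return 1.0 + (params.k5 / params.k4) * (state.c_pct / state.c_h2o2)


def radical_partition(
    c_pct: float, c_h2o2: float, k4: float, k5: float
) -> tuple[float, float]:
    """(1/delta, 1/rho) evaluated robustly, including the degenerate limits.

    When both sinks vanish (c_pct = c_h2o2 = 0) there is no radical sink and
    both fractions are defined as 0; when exactly one vanishes the continuous
    limit (0 or 1) is returned.
    """
    a = k5 * c_pct
    b = k4 * c_h2o2
    s = a + b
    if s <= 0.0:
        return 0.0, 0.0
    return a / s, b / s


def gamma_rate(state: ConcentrationState, params: KineticParams) -> float:
    """Fenton-like iron-recycling rate gamma = k3 C_Fe3+ C_H2O2 (mol/L/s)."""
    return params.k3 * state.c_fe3 * state.c_h2o2


def thermal_rates(state: ConcentrationState, params: KineticParams) -> RateVector:
    """Dark (thermal) rate vector.

    With F = k1 C_Fe2+ C_H2O2 the Fenton step feeds HO. which partitions
    between PCT (1/delta) and H2O2 (1/rho); the Fenton-like step gamma
    recycles iron while consuming peroxide.
    """
    inv_delta, inv_rho = radical_partition(
        state.c_pct, state.c_h2o2, params.k4, params.k5
    )
    fenton = params.k1 * state.c_fe2 * state.c_h2o2
    g = gamma_rate(state, params)
    return RateVector(
        r_pct=-fenton * inv_delta,
        r_h2o2=-fenton * (1.0 + inv_rho) - g,
        r_fe2=-fenton + g,
        r_fe3=+fenton - g,
    )


def total_rates(
    state: ConcentrationState,
    params: KineticParams,
    lvrpa_vol_avg: float,
    v_ratio: float,
) -> RateVector:
    """Thermal plus photochemical rate vector.

    ``lvrpa_vol_avg`` is the volume-averaged LVRPA in Einstein/L/s;
    ``v_ratio`` is V_irr/V_total. The photolysis step consumes Fe3+ and
    regenerates Fe2+ at rate v_ratio * phi_bar * <e_a>, and its HO. output
    partitions over PCT and H2O2 with the same (1/delta, 1/rho) fractions as
    the thermal radicals.
    """
    if lvrpa_vol_avg < 0:
        raise ValueError(f"lvrpa must be >= 0, got {lvrpa_vol_avg}")
    if not (0.0 < v_ratio <= 1.0):
        raise ValueError(f"v_ratio must be in (0, 1], got {v_ratio}")
    base = thermal_rates(state, params)
    if lvrpa_vol_avg == 0.0:
        return base
    inv_delta, inv_rho = radical_partition(
        state.c_pct, state.c_h2o2, params.k4, params.k5
    )
    photo = v_ratio * params.phi_bar * lvrpa_vol_avg
    return base + RateVector(
        r_pct=-photo * inv_delta,
        r_h2o2=-photo * inv_rho,
        r_fe2=+photo,
        r_fe3=-photo,
    )
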