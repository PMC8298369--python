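"""Stoichiometry, unit conversion and scalar process metrics.

The mineralization stoichiometry of paracetamol (PCT, C8H9NO2) with
hydrogen peroxide as sole oxidant is

    C8H9NO2 + 21 H2O2 -> 8 CO2 + 25 H2O + H+ + NO3-

so 21 mol of H2O2 are required per mol of PCT for total mineralization.
Everything in this module is plain arithmetic on that stoichiometry plus
the molar masses of the species involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SpeciesInfo",
    "SPECIES",
    "M_PCT",
    "M_H2O2",
    "M_FE",
    "M_C",
    "STOICH_H2O2_PER_PCT",
    "mg_per_L_to_molar",
    "molar_to_mg_per_L",
    "stoichiometric_h2o2_dose",
    "molar_ratio_R",
    "toc_equivalent",
    "specific_oxidant_consumption",
    "removal_time",
    "load_species_table",
]


@dataclass(frozen=True)
class SpeciesInfo:
    """A chemical species: identifier, molar mass (g/mol) and carbon count."""

    name: str
    molar_mass: float  # g mol-1
    carbon_atoms: int = 0

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if self.carbon_atoms < 0:
            raise ValueError(f"carbon_atoms must be >= 0, got {self.carbon_atoms}")


# IUPAC 2021 atomic masses.
M_C = 12.011
M_PCT = 151.16  # C8H9NO2
M_H2O2 = 34.01
M_FE = 55.85

#: mol H2O2 per mol PCT for total mineralization
STOICH_H2O2_PER_PCT = 21.0

SPECIES: dict[str, SpeciesInfo] = {
    "PCT": SpeciesInfo("PCT", M_PCT, 8),
    "H2O2": SpeciesInfo("H2O2", M_H2O2, 0),
    "Fe2": SpeciesInfo("Fe2", M_FE, 0),
    "Fe3": SpeciesInfo("Fe3", M_FE, 0),
    "FeTOT": SpeciesInfo("FeTOT", M_FE, 0),
}


def load_species_table(path: str) -> dict[str, SpeciesInfo]:
    """Load a species table from CSV (name, molar_mass_g_mol, carbon_atoms).

    Rows override or extend the built-in table.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"name", "molar_mass_g_mol", "carbon_atoms"}
    if not required.issubset(df.columns):
        raise ValueError(f"species CSV must have columns {sorted(required)}")
    table = dict(SPECIES)
    for row in df.itertuples(index=False):
        table[str(row.name)] = SpeciesInfo(
            str(row.name), float(row.molar_mass_g_mol), int(row.carbon_atoms)
        )
    return table


def mg_per_L_to_molar(conc_mg_L: float, species: SpeciesInfo) -> float:
    """Convert mg/L to mol/L for the given species."""
    if conc_mg_L < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_mg_L}")
    return conc_mg_L / (1000.0 * species.molar_mass)


def molar_to_mg_per_L(conc_M: float, species: SpeciesInfo) -> float:
    """Convert mol/L back to mg/L."""
    return conc_M * 1000.0 * species.molar_mass


def stoichiometric_h2o2_dose(c_pct_mg_L: float) -> float:
    """H2O2 dose (mg/L) for total mineralization of ``c_pct_mg_L`` of PCT.

    Uses the 21:1 molar stoichiometry of complete mineralization.
    """
    if c_pct_mg_L < 0:
        raise ValueError(f"c_pct must be >= 0, got {c_pct_mg_L}")
    return STOICH_H2O2_PER_PCT * (c_pct_mg_L / M_PCT) * M_H2O2


def molar_ratio_R(c_h2o2_mg_L: float, c_pct_mg_L: float) -> float:
    """Initial molar ratio R = H2O2 : PCT (dimensionless)."""
    if c_pct_mg_L <= 0:
        raise ZeroDivisionError("molar ratio undefined for c_pct <= 0")
    return (c_h2o2_mg_L / M_H2O2) / (c_pct_mg_L / M_PCT)


def toc_equivalent(c_pct_mg_L: float) -> float:
    """Total organic carbon (mg C / L) carried by a PCT concentration.

    PCT has 8 carbon atoms, so the carbon mass fraction is 8*M_C/M_PCT.
    """
    if c_pct_mg_L < 0:
        raise ValueError(f"c_pct must be >= 0, got {c_pct_mg_L}")
    return c_pct_mg_L * (8.0 * M_C / M_PCT)


def specific_oxidant_consumption(
    h2o2_t0: float, h2o2_tf: float, toc_t0: float, toc_tf: float
) -> float:
    """Specific oxidant consumption, mg H2O2 consumed per mg TOC mineralized.

    ``tf`` is either the time at which the oxidant is depleted or the end of
    the run. Raises if no mineralization occurred (zero denominator).
    """
    if toc_t0 <= toc_tf:
        raise ZeroDivisionError(
            "specific consumption undefined: no TOC decrease "
            f"(t0={toc_t0}, tf={toc_tf})"
        )
    return (h2o2_t0 - h2o2_tf) / (toc_t0 - toc_tf)


def removal_time(
    times_min: Sequence[float],
    conc_mg_L: Sequence[float],
    threshold: float,
    interpolate: bool = True,
) -> float | None:
    """First time (min) at which a trajectory drops below ``threshold``.

    With ``interpolate=True`` (default) the crossing is located by linear
    interpolation between the bracketing samples; otherwise the first sampling
    instant with a value below threshold is returned. Returns ``None`` when
    the trajectory never goes below threshold ("not reached").
    """
    t = np.asarray(times_min, dtype=float)
    c = np.asarray(conc_mg_L, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if t.size != c.size:
        raise ValueError("times and concentrations must have equal length")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    below = c < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0 or not interpolate:
        return float(t[i])
    # linear interpolation on the bracketing segment [i-1, i]
    t0, t1 = t[i - 1], t[i]
    c0, c1 = c[i - 1], c[i]
    if c1 == c0:  # flat segment already below: crossing at its start
        return float(t1)
    return float(t0 + (c0 - threshold) / (c0 - c1) * (t1 - t0))
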