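"""Radiation field of the annular photoreactor: the LSSE model and LVRPA.

The lamp is modelled as a line source with spherical, isotropic emission
(LSSE): every axial element of the lamp emits uniformly in all directions.
At a point (r, z) in the annular liquid the local volumetric rate of photon
absorption (LVRPA) at wavelength lambda is

    e_a(r, z) = kappa_lam * P_lam / (2 pi L_L)
                * Int_{theta2}^{theta1} exp[-kappa_T (r - r_int)/cos(theta)] dtheta

where P_lam is the lamp spectral photon power, L_L the useful lamp length,
kappa_lam the volumetric absorption coefficient of the absorbing species,
kappa_T that of the whole medium, and theta1 >= 0 >= theta2 the limiting
angles subtended by the lamp ends. At pH 2.8 the dominant absorber in
300-420 nm is the ferric-hydroxo complex Fe(OH)2+, whose concentration is
taken equal to total Fe3+, so kappa_lam = kappa_T = alpha(lambda) * C_Fe3+.

The photochemical driving force of the reactor model is the LVRPA averaged
over the irradiated volume and summed over wavelengths,

    <Sum_lam e_a> = (2 pi / V_irr) Int_0^h Int_{r_int}^{r_ext}
                    Sum_lam e_a(r, z) r dr dz.

Volume averages are returned in Einstein/cm3/s (the natural bench units);
`LvrpaTable.in_einstein_per_L_s` converts to the Einstein/L/s the ODE layer
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ReactorGeometry",
    "LampSpectrum",
    "AbsorptivityTable",
    "LvrpaTable",
    "default_geometry",
    "synthetic_spectrum",
    "synthetic_absorptivity",
    "limiting_angles",
    "total_absorption_coeff",
    "lvrpa_local",
    "lvrpa_volume_average",
    "build_lvrpa_table",
]

from .chem import M_FE


@dataclass(frozen=True)
class ReactorGeometry:
    """Geometry of the annular photoreactor and its lamp (lengths in cm).

    ``lamp_offset`` is the axial position of the bottom of the irradiated
    annulus measured from the bottom end of the lamp; ``None`` centres the
    annulus on the lamp.
    """

    r_int: float = 3.5
    r_ext: float = 7.0
    h_irr: float = 13.0
    lamp_length: float = 58.98
    lamp_offset: float | None = None
    v_irr: float = 1.5  # L
    v_total: float = 15.0  # L

    def __post_init__(self) -> None:
        if not (0 < self.r_int < self.r_ext):
            raise ValueError("need 0 < r_int < r_ext")
        if self.h_irr > self.lamp_length:
            raise ValueError("irradiated height exceeds lamp length")
        if not (self.v_irr < self.v_total):
            raise ValueError("need v_irr < v_total")
        annulus_L = math.pi * (self.r_ext**2 - self.r_int**2) * self.h_irr / 1000.0
        if abs(annulus_L - self.v_irr) / self.v_irr > 0.01:
            raise ValueError(
                f"annular volume {annulus_L:.4f} L disagrees with v_irr={self.v_irr} L"
            )
        off = self.offset
        if off < 0 or off + self.h_irr > self.lamp_length + 1e-9:
            raise ValueError("irradiated annulus extends beyond the lamp")

    @property
    def offset(self) -> float:
        if self.lamp_offset is None:
            return (self.lamp_length - self.h_irr) / 2.0
        return self.lamp_offset

    @property
    def v_ratio(self) -> float:
        """V_irr / V_total."""
        return self.v_irr / self.v_total

    @property
    def annular_volume_L(self) -> float:
        """Volume of the annulus computed from the radii and height."""
        return math.pi * (self.r_ext**2 - self.r_int**2) * self.h_irr / 1000.0


def default_geometry() -> ReactorGeometry:
    """Bench geometry: 3.5/7.0 cm radii, 13 cm irradiated height, 58.98 cm
    lamp, 1.5 L irradiated in a 15 L loop."""
    return ReactorGeometry()


@dataclass(frozen=True)
class LampSpectrum:
    """Lamp spectral photon emission on an ascending nm grid.

    ``spectral_photon_power`` is in Einstein/min/nm; the trapezoid integral
    over the grid is the total photon power E in Einstein/min.
    """

    wavelengths: np.ndarray
    spectral_photon_power: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        p = np.asarray(self.spectral_photon_power, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "spectral_photon_power", p)
        if w.ndim != 1 or w.size < 2 or not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be 1-D ascending with >= 2 points")
        if p.shape != w.shape or np.any(p < 0):
            raise ValueError("spectral power must be non-negative, same shape as grid")

    @property
    def total_photon_power(self) -> float:
        """Total photon power E (Einstein/min), trapezoid-integrated."""
        return float(np.trapezoid(self.spectral_photon_power, self.wavelengths))

    def spectral_power_at(self, lam: float) -> float:
        """Interpolated spectral photon power (Einstein/min/nm) at ``lam``."""
        w = self.wavelengths
        if lam < w[0] or lam > w[-1]:
            raise ValueError(f"wavelength {lam} nm outside spectrum coverage")
        return float(np.interp(lam, w, self.spectral_photon_power))

    @classmethod
    def from_csv(cls, path: str) -> "LampSpectrum":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        cols = {"wavelength_nm", "photon_power_einstein_per_min_per_nm"}
        if not cols.issubset(df.columns):
            raise ValueError(f"spectrum CSV must have columns {sorted(cols)}")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["photon_power_einstein_per_min_per_nm"].to_numpy(),
        )

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "photon_power_einstein_per_min_per_nm": self.spectral_photon_power,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class AbsorptivityTable:
    """Naperian molar absorptivity (M-1 cm-1) of the absorbing ferric complex
    on an ascending nm grid.

    If the source data are decadic (base-10) absorptivities, multiply by
    ln(10) before constructing the table; the CSV header should state the
    basis.
    """

    wavelengths: np.ndarray
    molar_absorptivity: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.molar_absorptivity, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "molar_absorptivity", a)
        if w.ndim != 1 or w.size < 2 or not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be 1-D ascending with >= 2 points")
        if a.shape != w.shape or np.any(a < 0):
            raise ValueError("absorptivity must be non-negative, same shape as grid")

    def absorptivity_at(self, lam: float) -> float:
        w = self.wavelengths
        if lam < w[0] or lam > w[-1]:
            raise ValueError(f"wavelength {lam} nm outside absorptivity coverage")
        return float(np.interp(lam, w, self.molar_absorptivity))

    @classmethod
    def from_csv(cls, path: str) -> "AbsorptivityTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        cols = {"wavelength_nm", "molar_absorptivity_per_M_per_cm"}
        if not cols.issubset(df.columns):
            raise ValueError(f"absorptivity CSV must have columns {sorted(cols)}")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["molar_absorptivity_per_M_per_cm"].to_numpy(),
        )

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "molar_absorptivity_per_M_per_cm": self.molar_absorptivity,
            }
        ).to_csv(path, index=False)


def synthetic_spectrum(
    total_photon_power: float = 3.36e-4,
    lam_min: float = 300.0,
    lam_max: float = 420.0,
    n: int = 25,
) -> LampSpectrum:
    """Synthetic actinic-BL-like lamp spectrum.

    A smooth unimodal raised-cosine shape on [lam_min, lam_max], normalized
    so the trapezoid-integrated photon power equals ``total_photon_power``
    (default: the actinometrically measured 3.36e-4 Einstein/min of the
    bench lamp). This is a stand-in for the manufacturer's spectral table,
    adequate for every self-contained computation; supply the measured
    spectrum as CSV to reproduce bench-specific absolute values.
    """
    w = np.linspace(lam_min, lam_max, n)
    shape = np.sin(np.pi * (w - lam_min) / (lam_max - lam_min)) ** 2
    shape /= np.trapezoid(shape, w)
    return LampSpectrum(w, total_photon_power * shape)


def synthetic_absorptivity(
    alpha_300: float = 2300.0,
    decay_nm: float = 30.0,
    lam_min: float = 300.0,
    lam_max: float = 420.0,
    n: int = 25,
) -> AbsorptivityTable:
    """Synthetic Fe(OH)2+-like naperian absorptivity table.

    An exponential fall-off alpha(lam) = alpha_300 * exp(-(lam-300)/decay_nm)
    mimicking the near-UV tail of the ferric-hydroxo complex band (order
    1e3 M-1 cm-1 naperian at 300 nm, negligible by 420 nm). A stand-in for
    literature data; supply measured absorptivities as CSV for bench work.
    """
    w = np.linspace(lam_min, lam_max, n)
    return AbsorptivityTable(w, alpha_300 * np.exp(-(w - lam_min) / decay_nm))


def limiting_angles(r: float, z: float, lamp_length: float) -> tuple[float, float]:
    """Limiting polar angles (theta1 >= 0, theta2 <= 0) subtended by the lamp
    ends at a point at radius ``r`` and axial position ``z`` along the lamp.

    theta1 = atan(r/(L_L - z)) looks toward the far lamp end, theta2 =
    atan(-r/z) toward the near end; at z = 0 or z = L_L the degenerate angle
    is the limit -pi/2 or +pi/2.
    """
    if r <= 0:
        raise ValueError(f"r must be > 0, got {r}")
    if not (0 <= z <= lamp_length):
        raise ValueError(f"z must lie in [0, {lamp_length}], got {z}")
    theta1 = math.pi / 2 if z == lamp_length else math.atan(r / (lamp_length - z))
    theta2 = -math.pi / 2 if z == 0 else math.atan(-r / z)
    return theta1, theta2


def total_absorption_coeff(
    c_fe3: float, lam: float, table: AbsorptivityTable
) -> float:
    """Volumetric absorption coefficient of the medium (cm-1) at ``lam``.

    All ferric iron is treated as the absorbing Fe(OH)2+ complex, so
    kappa_T = alpha(lam) * C_Fe3+ with C in mol/L.
    """
    if c_fe3 < 0:
        raise ValueError(f"c_fe3 must be >= 0, got {c_fe3}")
    return table.absorptivity_at(lam) * c_fe3


def lvrpa_local(
    r: float,
    z: float,
    lam: float,
    kappa: float,
    kappa_T: float,
    geometry: ReactorGeometry,
    spectrum: LampSpectrum,
) -> float:
    """Monochromatic LVRPA (Einstein/cm3/s) at reactor point (r, z).

    ``z`` is measured from the bottom of the irradiated annulus; the lamp
    coordinate is z + geometry.offset. Adaptive quadrature over the limiting
    angles, relative tolerance 1e-8.
    """
    if not (geometry.r_int <= r <= geometry.r_ext):
        raise ValueError(f"r={r} outside annulus [{geometry.r_int}, {geometry.r_ext}]")
    if kappa < 0 or kappa_T < 0:
        raise ValueError("absorption coefficients must be >= 0")
    if kappa == 0.0:
        return 0.0
    z_lamp = z + geometry.offset
    theta1, theta2 = limiting_angles(r, z_lamp, geometry.lamp_length)
    depth = r - geometry.r_int
    p_s = spectrum.spectral_power_at(lam) / 60.0  # Einstein/s/nm

    if kappa_T == 0.0:
        integral = theta1 - theta2
    else:
        integral, _ = quad(
            lambda th: math.exp(-kappa_T * depth / math.cos(th)),
            theta2,
            theta1,
            epsrel=1e-8,
            epsabs=0.0,
            limit=200,
        )
    return kappa * p_s / (2.0 * math.pi * geometry.lamp_length) * integral


def _gauss_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (b - a) * x + 0.5 * (b + a), 0.5 * (b - a) * w


def _volume_average_fixed(
    c_fe3_M: float,
    geometry: ReactorGeometry,
    spectrum: LampSpectrum,
    table: AbsorptivityTable,
    nr: int,
    nz: int,
    ntheta: int,
) -> float:
    """Polychromatic volume-averaged LVRPA on a fixed Gauss-Legendre grid."""
    if c_fe3_M == 0.0:
        return 0.0
    lam = spectrum.wavelengths
    # spectral photon power per second, integrated with trapezoid weights
    p_s = spectrum.spectral_photon_power / 60.0  # Einstein/s/nm
    w_lam = np.empty_like(lam)
    w_lam[0] = (lam[1] - lam[0]) / 2
    w_lam[-1] = (lam[-1] - lam[-2]) / 2
    w_lam[1:-1] = (lam[2:] - lam[:-2]) / 2
    alpha = np.interp(lam, table.wavelengths, table.molar_absorptivity)
    kappa = alpha * c_fe3_M  # cm-1, per wavelength

    r_nodes, r_w = _gauss_nodes(geometry.r_int, geometry.r_ext, nr)
    z_nodes, z_w = _gauss_nodes(0.0, geometry.h_irr, nz)
    x, tw = np.polynomial.legendre.leggauss(ntheta)  # on [-1, 1]

    z_lamp = z_nodes + geometry.offset
    theta1 = np.arctan(r_nodes[:, None] / (geometry.lamp_length - z_lamp)[None, :])
    theta2 = np.arctan(-r_nodes[:, None] / z_lamp[None, :])
    half = 0.5 * (theta1 - theta2)  # (nr, nz)
    mid = 0.5 * (theta1 + theta2)
    theta = mid[:, :, None] + half[:, :, None] * x[None, None, :]  # (nr, nz, nt)
    depth = (r_nodes - geometry.r_int)[:, None, None]  # (nr, 1, 1)
    # attenuation path: depth / cos(theta); exponent per wavelength
    path = depth / np.cos(theta)  # (nr, nz, nt)
    # Sum over wavelengths of kappa_l * P_l * w_l * exp(-kappa_l * path)
    expo = np.exp(-path[:, :, :, None] * kappa[None, None, None, :])
    spect_weight = kappa * p_s * w_lam  # (nl,)
    integrand = expo @ spect_weight  # (nr, nz, nt)
    theta_int = (integrand * tw[None, None, :]).sum(axis=2) * half  # (nr, nz)
    e_a = theta_int / (2.0 * math.pi * geometry.lamp_length)  # (nr, nz)
    # (2 pi / V_irr) Int Int e_a r dr dz ; V_irr in cm3
    v_irr_cm3 = geometry.v_irr * 1000.0
    inner = (e_a * r_nodes[:, None] * r_w[:, None] * z_w[None, :]).sum()
    return float(2.0 * math.pi / v_irr_cm3 * inner)


def lvrpa_volume_average(
    c_fe3_M: float,
    geometry: ReactorGeometry,
    spectrum: LampSpectrum,
    table: AbsorptivityTable,
    base_grid: tuple[int, int, int] = (16, 16, 32),
    richardson_tol: float = 0.005,
    max_refine: int = 3,
) -> float:
    """Volume-averaged polychromatic LVRPA (Einstein/cm3/s) at ``c_fe3_M``.

    Evaluated on a tensor Gauss-Legendre grid; the grid is doubled until the
    result changes by less than ``richardson_tol`` relative (default 0.5%).
    """
    if c_fe3_M < 0:
        raise ValueError(f"c_fe3 must be >= 0, got {c_fe3_M}")
    if c_fe3_M == 0.0:
        return 0.0
    nr, nz, nt = base_grid
    prev = _volume_average_fixed(c_fe3_M, geometry, spectrum, table, nr, nz, nt)
    for _ in range(max_refine):
        nr, nz, nt = 2 * nr, 2 * nz, 2 * nt
        cur = _volume_average_fixed(c_fe3_M, geometry, spectrum, table, nr, nz, nt)
        if prev != 0.0 and abs(cur - prev) / abs(cur) < richardson_tol:
            return cur
        prev = cur
    return prev


@dataclass(frozen=True)
class LvrpaTable:
    """Tabulated volume-averaged LVRPA vs ferric iron concentration.

    ``fe3_grid`` in mg/L ascending from 0; ``lvrpa`` in Einstein/cm3/s.
    Interpolation is monotone piecewise-cubic (PCHIP); beyond the last node
    the table extrapolates linearly with the end slope (clamped at 0 below
    the first node).
    """

    fe3_grid: np.ndarray
    lvrpa: np.ndarray
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.fe3_grid, dtype=float)
        v = np.asarray(self.lvrpa, dtype=float)
        object.__setattr__(self, "fe3_grid", g)
        object.__setattr__(self, "lvrpa", v)
        if g.ndim != 1 or g.size < 1 or (g.size > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError("fe3 grid must be ascending")
        if v.shape != g.shape:
            raise ValueError("lvrpa and grid shapes differ")
        if g[0] == 0.0 and v[0] != 0.0:
            raise ValueError("lvrpa must vanish at zero iron")
        if g.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("lvrpa must be strictly increasing in iron")
        if g.size > 2:
            d2 = np.diff(np.diff(v) / np.diff(g))
            if np.any(d2 > 1e-12 * max(abs(v[-1]), 1e-300)):
                raise ValueError("lvrpa table must be concave (self-shielding)")
        if g.size > 1:
            from scipy.interpolate import PchipInterpolator

            object.__setattr__(self, "_interp", PchipInterpolator(g, v))

    def __call__(self, c_fe3_mg_L: float) -> float:
        """Interpolated LVRPA (Einstein/cm3/s) at ``c_fe3_mg_L``."""
        g, v = self.fe3_grid, self.lvrpa
        if g.size == 1:
            return float(v[0])
        if c_fe3_mg_L <= g[0]:
            return float(v[0])
        if c_fe3_mg_L > g[-1]:
            end_slope = float(self._interp.derivative()(g[-1]))
            return float(v[-1] + end_slope * (c_fe3_mg_L - g[-1]))
        return float(self._interp(c_fe3_mg_L))

    def in_einstein_per_L_s(self, c_fe3_mg_L: float) -> float:
        """Interpolated LVRPA converted to Einstein/L/s (x1000)."""
        return 1000.0 * self(c_fe3_mg_L)

    def derivative(self, c_fe3_mg_L: float) -> float:
        """Slope d<e_a>/dC_Fe3 (Einstein/cm3/s per mg/L), clamped like the value."""
        g = self.fe3_grid
        if g.size == 1:
            return 0.0
        d = self._interp.derivative()
        if c_fe3_mg_L <= g[0]:
            return 0.0
        if c_fe3_mg_L > g[-1]:
            return float(d(g[-1]))
        return float(d(c_fe3_mg_L))

    @classmethod
    def from_csv(cls, path: str) -> "LvrpaTable":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        cols = {"c_fe3_mg_L", "lvrpa_einstein_per_cm3_per_s"}
        if not cols.issubset(df.columns):
            raise ValueError(f"LVRPA CSV must have columns {sorted(cols)}")
        return cls(
            df["c_fe3_mg_L"].to_numpy(), df["lvrpa_einstein_per_cm3_per_s"].to_numpy()
        )

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "c_fe3_mg_L": self.fe3_grid,
                "lvrpa_einstein_per_cm3_per_s": self.lvrpa,
            }
        ).to_csv(path, index=False)


def build_lvrpa_table(
    grid_mg_L,
    geometry: ReactorGeometry,
    spectrum: LampSpectrum,
    table: AbsorptivityTable,
    **kwargs,
) -> LvrpaTable:
    """Tabulate the volume-averaged LVRPA on an ascending mg/L iron grid."""
    g = np.asarray(grid_mg_L, dtype=float)
    if g.size == 0 or (g.size > 1 and not np.all(np.diff(g) > 0)):
        raise ValueError("grid must be non-empty ascending")
    vals = np.array(
        [
            lvrpa_volume_average(
                c / (1000.0 * M_FE), geometry, spectrum, table, **kwargs
            )
            for c in g
        ]
    )
    return LvrpaTable(g, vals)
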