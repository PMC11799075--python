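"""Photon interaction physics: materials, attenuation, filters, Compton.

Elemental mass-attenuation coefficients are packaged as small text tables on
a 20-500 keV grid (K edges of I, W and Pb carried as double grid points so
log-log interpolation never crosses an edge).  Compound materials use the
standard mixture rule on mass fractions.  The Compton component of the
attenuation is computed analytically from the Klein-Nishina total cross
section and the material's Z/A; photoelectric absorption is the remainder
(coherent scatter is ignored, adequate above ~50 keV in low-Z media).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ElementData",
    "Material",
    "FilterSpec",
    "element",
    "weight_fractions",
    "mass_attenuation",
    "compton_mass_attenuation",
    "transmission",
    "compton_scattered_energy",
    "klein_nishina_dcs",
    "klein_nishina_total",
    "sample_compton_angle",
    "lead",
    "tungsten_functional_paper",
    "water",
    "sodium_iodide",
    "ELECTRON_REST_KEV",
]

ELECTRON_REST_KEV = 510.998950
#: classical electron radius in cm
R_E_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23

_ATOMIC = {
    # symbol: (Z, atomic mass g/mol)
    "H": (1, 1.008),
    "C": (6, 12.011),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Al": (13, 26.982),
    "I": (53, 126.904),
    "W": (74, 183.84),
    "Pb": (82, 207.2),
}


@dataclass(frozen=True)
class ElementData:
    """One element's identity plus its mass-attenuation table (cm^2/g)."""

    symbol: str
    atomic_number: int
    atomic_mass: float
    energies_kev: np.ndarray
    mu_rho: np.ndarray

    def __post_init__(self) -> None:
        e = self.energies_kev
        if not np.all(np.diff(e) > 0):
            raise ValueError(f"{self.symbol}: table energies must strictly increase")
        if e[0] > 20 or e[-1] < 500:
            raise ValueError(f"{self.symbol}: table must span at least 20-500 keV")
        if not np.all(self.mu_rho > 0):
            raise ValueError(f"{self.symbol}: coefficients must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.energies_kev[0]), float(self.energies_kev[-1])


@lru_cache(maxsize=None)
def element(symbol: str) -> ElementData:
    """Load the packaged attenuation table for one element."""
    if symbol not in _ATOMIC:
        raise KeyError(f"no packaged data for element {symbol!r}")
    z, a = _ATOMIC[symbol]
    path = Path(str(resources.files("gammadt").joinpath(f"data/mu_rho_{symbol}.txt")))
    table = np.loadtxt(path, ndmin=2)
    return ElementData(symbol, z, a, table[:, 0].copy(), table[:, 1].copy())


@dataclass(frozen=True)
class Material:
    """A named mixture of elements by mole fraction, with a bulk density."""

    name: str
    composition: tuple[tuple[ElementData, float], ...]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        total = sum(x for _, x in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total}")

    @classmethod
    def from_mole_fractions(
        cls, name: str, fractions: dict[str, float], density: float
    ) -> "Material":
        return cls(
            name,
            tuple((element(sym), x) for sym, x in fractions.items()),
            density,
        )

    @property
    def electrons_per_gram_factor(self) -> float:
        """Sum of w_i * Z_i / A_i (multiplied by N_A gives electrons/g)."""
        w = weight_fractions(self)
        return sum(
            w[el.symbol] * el.atomic_number / el.atomic_mass
            for el, _ in self.composition
        )


@dataclass(frozen=True)
class FilterSpec:
    """A shielding filter: a material slab of given thickness in cm."""

    material: Material
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.thickness_cm < 0:
            raise ValueError("filter thickness must be non-negative")


def weight_fractions(material: Material) -> dict[str, float]:
    """Per-element mass fractions: w_i = x_i M_i / sum_j x_j M_j."""
    masses = {el.symbol: x * el.atomic_mass for el, x in material.composition}
    total = sum(masses.values())
    return {sym: m / total for sym, m in masses.items()}


def _interp_loglog(el: ElementData, energy_kev: np.ndarray) -> np.ndarray:
    lo, hi = el.span
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(
            f"energy outside {el.symbol} table span [{lo}, {hi}] keV"
        )
    return np.exp(
        np.interp(np.log(e), np.log(el.energies_kev), np.log(el.mu_rho))
    )


def mass_attenuation(material: Material, energy_kev) -> np.ndarray | float:
    """Total mass-attenuation coefficient of a mixture in cm^2/g.

    Mixture rule: sum_i w_i (mu/rho)_i(E), each element interpolated
    log-log on its packaged table.
    """
    e = np.asarray(energy_kev, dtype=float)
    w = weight_fractions(material)
    out = np.zeros_like(e)
    for el, _ in material.composition:
        out = out + w[el.symbol] * _interp_loglog(el, e)
    return out if out.ndim else float(out)


def compton_mass_attenuation(material: Material, energy_kev) -> np.ndarray | float:
    """Incoherent (Compton) mass-attenuation via the Klein-Nishina total
    cross section and the material's electrons per gram (binding ignored)."""
    e = np.asarray(energy_kev, dtype=float)
    sigma = klein_nishina_total(e)  # cm^2 per electron
    out = sigma * AVOGADRO * material.electrons_per_gram_factor
    return out if out.ndim else float(out)


def transmission(filt: FilterSpec | None, energy_kev) -> np.ndarray | float:
    """Narrow-beam fraction transmitted through a filter, exp(-mu/rho * rho * d)."""
    e = np.asarray(energy_kev, dtype=float)
    if filt is None:
        out = np.ones_like(e)
        return out if out.ndim else float(out)
    mu = mass_attenuation(filt.material, e)
    out = np.exp(-np.asarray(mu) * filt.material.density * filt.thickness_cm)
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# Compton kinematics and Klein-Nishina sampling
# ----------------------------------------------------------------------

def compton_scattered_energy(energy_kev, angle_rad) -> np.ndarray | float:
    """Photon energy after Compton scattering through a given angle,
    E' = E / (1 + (E/m_e c^2)(1 - cos theta))."""
    e = np.asarray(energy_kev, dtype=float)
    mu = np.cos(np.asarray(angle_rad, dtype=float))
    out = e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - mu))
    return out if out.ndim else float(out)


def klein_nishina_dcs(energy_kev, cos_theta) -> np.ndarray | float:
    """Klein-Nishina differential cross section per electron, cm^2/sr."""
    e = np.asarray(energy_kev, dtype=float)
    mu = np.asarray(cos_theta, dtype=float)
    k = e / ELECTRON_REST_KEV
    p = 1.0 / (1.0 + k * (1.0 - mu))  # = E'/E
    out = 0.5 * R_E_CM**2 * p**2 * (p + 1.0 / p - (1.0 - mu**2))
    return out if out.ndim else float(out)


def klein_nishina_total(energy_kev) -> np.ndarray | float:
    """Total Klein-Nishina cross section per electron in cm^2 (closed form)."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    t = 1.0 + 2.0 * k
    log_t = np.log(t)
    out = (
        2.0
        * math.pi
        * R_E_CM**2
        * (
            (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - log_t / k)
            + log_t / (2.0 * k)
            - (1.0 + 3.0 * k) / t**2
        )
    )
    return out if out.ndim else float(out)


def sample_compton_mu(
    energy_kev: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` scattering-angle cosines from the Klein-Nishina density.

    Plain rejection against the forward-peak envelope: the differential cross
    section has its maximum at cos theta = 1 for all energies.
    """
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    peak = klein_nishina_dcs(energy_kev, 1.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.5), 64)
        mu = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        acc = mu[u * peak < klein_nishina_dcs(energy_kev, mu)]
        take = min(len(acc), n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out


def sample_compton_angle(
    energy_kev: float,
    seed: int | np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Scattering angles (radians) sampled from Klein-Nishina; seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.arccos(sample_compton_mu(energy_kev, n, rng))


def sample_compton_mu_many(
    energies_kev: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample one scattering cosine per photon, each at its own
    energy (vectorised across the whole batch)."""
    e = np.asarray(energies_kev, dtype=float)
    out = np.empty(e.size)
    peak = np.asarray(klein_nishina_dcs(e, np.ones_like(e)))
    todo = np.arange(e.size)
    while todo.size:
        mu = rng.uniform(-1.0, 1.0, size=todo.size)
        u = rng.uniform(0.0, 1.0, size=todo.size)
        acc = u * peak[todo] < np.asarray(klein_nishina_dcs(e[todo], mu))
        out[todo[acc]] = mu[acc]
        todo = todo[~acc]
    return out


# ----------------------------------------------------------------------
# Stock materials
# ----------------------------------------------------------------------

def lead(density: float = 11.35) -> Material:
    return Material.from_mole_fractions("lead", {"Pb": 1.0}, density)


def tungsten_functional_paper(density: float = 3.4) -> Material:
    """Tungsten functional paper: cellulose-bound tungsten powder.

    Elemental composition H 24.2 / C 40.4 / O 20.2 / W 15.2 mol% (about 77%
    tungsten by weight).  The bulk density of commercial sheet is not pinned
    down by the composition; the 3.4 g/cm^3 default is a packaged choice and
    should be overridden if the actual areal density is known.
    """
    return Material.from_mole_fractions(
        "tungsten functional paper",
        {"H": 0.242, "C": 0.404, "O": 0.202, "W": 0.152},
        density,
    )


def water(density: float = 1.0) -> Material:
    return Material.from_mole_fractions("water", {"H": 2 / 3, "O": 1 / 3}, density)


def sodium_iodide(density: float = 3.67) -> Material:
    return Material.from_mole_fractions("NaI", {"Na": 0.5, "I": 0.5}, density)
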