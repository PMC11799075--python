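"""Lu-177 photon source term.

Lu-177 decays with two gamma lines usable for camera imaging (208.4 keV,
11 %/decay and 113.0 keV, 6.4 %/decay) plus a handful of Yb K X-rays near
55-65 keV.  The X-rays and the 113-keV gamma never enter the 208-keV
analysis window, but they dominate the full-window count rate and therefore
the dead time -- which is why shielding them with a thin filter shortens the
apparent dead time.

Line intensities are stored as fractions per decay (0.110, not 11.0 %);
percent values are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "EmissionLine",
    "EmissionSpectrum",
    "default_lu177_lines",
    "load_lines",
    "photon_emission_rate",
    "sample_line",
]


@dataclass(frozen=True)
class EmissionLine:
    """A single photon emission: energy in keV, intensity in photons/decay."""

    energy_kev: float
    intensity: float

    def __post_init__(self) -> None:
        if self.energy_kev <= 0:
            raise ValueError(f"line energy must be positive, got {self.energy_kev}")
        if not 0 < self.intensity <= 1:
            raise ValueError(
                f"line intensity must be in (0, 1] per decay, got {self.intensity}"
            )


@dataclass(frozen=True)
class EmissionSpectrum:
    """An ordered set of emission lines with unique energies."""

    lines: tuple[EmissionLine, ...]

    def __post_init__(self) -> None:
        if len(self.lines) == 0:
            raise ValueError("emission spectrum must contain at least one line")
        energies = [ln.energy_kev for ln in self.lines]
        if len(set(energies)) != len(energies):
            raise ValueError("line energies must be unique")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "EmissionSpectrum":
        return cls(tuple(EmissionLine(e, i) for e, i in pairs))

    @property
    def energies(self) -> np.ndarray:
        return np.array([ln.energy_kev for ln in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([ln.intensity for ln in self.lines])

    @property
    def total_intensity(self) -> float:
        """Total photons emitted per decay, summed over lines."""
        return float(self.intensities.sum())

    def line_at(self, energy_kev: float) -> EmissionLine:
        for ln in self.lines:
            if ln.energy_kev == energy_kev:
                return ln
        raise KeyError(f"no line at {energy_kev} keV")


def _packaged_lines_path() -> Path:
    return Path(str(resources.files("gammadt").joinpath("data/lu177_lines.txt")))


def load_lines(path: str | Path) -> EmissionSpectrum:
    """Load a nuclide line set from a two-column text table.

    Columns are ``energy_keV intensity_fraction``; lines beginning with ``#``
    are comments.  This is the hook for studying nuclides other than Lu-177.
    """
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] != 2:
        raise ValueError("line table must have two columns (energy_keV, intensity)")
    return EmissionSpectrum.from_pairs((float(e), float(i)) for e, i in table)


def default_lu177_lines() -> EmissionSpectrum:
    """The six main photon lines of Lu-177 (two gammas, four X-rays).

    Intensities sum to 0.229 photons per decay.
    """
    return load_lines(_packaged_lines_path())


def photon_emission_rate(activity_bq: float, line: EmissionLine) -> float:
    """Photons per second emitted in one line by a source of given activity."""
    if activity_bq < 0:
        raise ValueError(f"activity must be non-negative, got {activity_bq}")
    return activity_bq * line.intensity


def sample_line(
    spectrum: EmissionSpectrum,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` emission energies with probability proportional to intensity."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = spectrum.intensities / spectrum.total_intensity
    idx = rng.choice(len(spectrum.lines), size=n, p=p)
    return spectrum.energies[idx]
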