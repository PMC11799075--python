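"""Detector response: crystal efficiency, energy blur, dead time, pile-up.

The incident spectrum is converted into a recorded measurement in four
steps: (1) intrinsic efficiency of the NaI crystal (probability that a
photon interacts at all; interacting photons are assumed to deposit their
full energy), (2) a homogeneous Poisson event stream at the detected rate,
(3) a Gaussian energy blur whose FWHM fraction is anchored at the photopeak
(9.4% at 208.4 keV by default) and scales as 1/sqrt(E), and (4) a
paralyzable dead-time filter acting on the *full* arrival stream, optionally
with pile-up summing.

The paralyzable rule is the defining physics here: an event is recorded only
if the gap since the immediately preceding arrival -- recorded or not --
exceeds the dead time tau.  Because every arrival in the full energy range
restarts the dead period, the loss seen inside a narrow analysis window is
governed by the full-window rate, which is what makes the apparent dead time
scale with the window fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .phantom import IncidentSpectrum
from .physics import Material, mass_attenuation, sodium_iodide

__all__ = [
    "DetectorConfig",
    "EventStream",
    "RecordedMeasurement",
    "intrinsic_efficiency",
    "fwhm_fraction",
    "blur_energy",
    "generate_event_stream",
    "apply_paralyzable",
    "record_measurement",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class DetectorConfig:
    """Camera-head parameters.

    Defaults model a Symbia-class head: 9.5-mm NaI crystal, 9.4% FWHM
    energy resolution at the 208.4-keV photopeak, 0.5-us full-window dead
    time.  ``full_window`` is the energy range whose arrivals drive the dead
    time; pile-up sums arrivals landing within ``integration_time_s`` of a
    recorded event into that event's energy.
    """

    crystal_thickness_cm: float = 0.95
    crystal: Material = field(default_factory=sodium_iodide)
    resolution_fwhm: float = 0.094
    resolution_ref_kev: float = 208.4
    resolution_exponent: float = -0.5
    full_window: tuple[float, float] = (20.0, 400.0)
    tau_full_s: float = 5e-7
    pileup: bool = True
    integration_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.tau_full_s < 0:
            raise ValueError("dead time must be non-negative")
        if self.full_window[0] >= self.full_window[1]:
            raise ValueError("full window must have low < high")

    @property
    def integration(self) -> float:
        return self.tau_full_s if self.integration_time_s is None else self.integration_time_s


@dataclass
class EventStream:
    """Time-stamped detected photons (times in s, energies post-blur in keV).

    ``is_scatter`` tags events originating from the scattered component of
    the incident spectrum; it is carried so the loss-free primary reference
    can be formed without a second simulation.
    """

    times: np.ndarray
    energies: np.ndarray
    is_scatter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be sorted")
        if self.times.size != self.energies.size:
            raise ValueError("times and energies must have equal length")

    def __len__(self) -> int:
        return int(self.times.size)


def intrinsic_efficiency(energy_kev, config: DetectorConfig) -> np.ndarray | float:
    """Probability a photon interacts in the crystal, 1 - exp(-mu d)."""
    mu = np.asarray(mass_attenuation(config.crystal, energy_kev))
    out = 1.0 - np.exp(-mu * config.crystal.density * config.crystal_thickness_cm)
    return out if out.ndim else float(out)


def fwhm_fraction(energy_kev, config: DetectorConfig) -> np.ndarray | float:
    """Relative FWHM at an energy: f(E) = f_ref (E/E_ref)^exponent."""
    e = np.asarray(energy_kev, dtype=float)
    out = config.resolution_fwhm * (e / config.resolution_ref_kev) ** config.resolution_exponent
    return out if out.ndim else float(out)


def blur_energy(
    energy_kev,
    config: DetectorConfig,
    seed: int | np.random.Generator,
) -> np.ndarray | float:
    """Gaussian energy blur; negative draws are redrawn."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any(e <= 0):
        raise ValueError("energies must be positive")
    sigma = np.asarray(fwhm_fraction(e, config)) * e * FWHM_TO_SIGMA
    out = rng.normal(e, sigma)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(e[bad], sigma[bad])
        bad = out <= 0
    return out if np.ndim(energy_kev) else float(out[0])


def generate_event_stream(
    incident: IncidentSpectrum,
    config: DetectorConfig,
    duration_s: float,
    seed: int | np.random.Generator,
) -> EventStream:
    """Realise the detected arrivals as a homogeneous Poisson process.

    The rate is the incident rate weighted by intrinsic efficiency per bin;
    event energies are drawn bin-wise (uniform within a bin) and blurred.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = incident.centers
    eff = np.asarray(intrinsic_efficiency(centers, config))
    rate_p = incident.primary * eff
    rate_s = incident.scatter * eff
    total = float(rate_p.sum() + rate_s.sum())
    if total == 0:
        z = np.empty(0)
        return EventStream(z, z.copy(), np.empty(0, dtype=bool))
    n = rng.poisson(total * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    rates = np.concatenate([rate_p, rate_s])
    idx = rng.choice(rates.size, size=n, p=rates / rates.sum())
    nbin = centers.size
    is_scatter = idx >= nbin
    b = idx % nbin
    lo = incident.bin_edges[:-1]
    width = np.diff(incident.bin_edges)
    raw = lo[b] + rng.uniform(0.0, 1.0, size=n) * width[b]
    energies = np.asarray(blur_energy(raw, config, rng)) if n else np.empty(0)
    return EventStream(times, energies, is_scatter)


def apply_paralyzable(
    stream: EventStream,
    tau_s: float,
    pileup: bool = False,
    integration_s: float | None = None,
) -> EventStream:
    """Apply the paralyzable dead-time rule to an arrival stream.

    An arrival is recorded iff the gap since the immediately preceding
    arrival (recorded or not) exceeds ``tau_s``.  With ``pileup``, every
    unrecorded arrival falling within ``integration_s`` of the latest
    recorded event adds its energy to that event.
    """
    if tau_s < 0:
        raise ValueError("dead time must be non-negative")
    if len(stream) == 0 or tau_s == 0.0:
        return stream
    t = stream.times
    e = stream.energies
    gaps = np.diff(t, prepend=-np.inf)
    recorded = gaps > tau_s
    rec_idx = np.flatnonzero(recorded)
    if not pileup:
        sc = stream.is_scatter[rec_idx] if stream.is_scatter is not None else None
        return EventStream(t[rec_idx], e[rec_idx], sc)
    window = tau_s if integration_s is None else integration_s
    end = np.searchsorted(t, t[rec_idx] + window, side="left")
    next_rec = np.append(rec_idx[1:], t.size)
    stop = np.minimum(end, next_rec)
    csum = np.concatenate([[0.0], np.cumsum(e)])
    e_rec = csum[stop] - csum[rec_idx]
    sc = stream.is_scatter[rec_idx] if stream.is_scatter is not None else None
    return EventStream(t[rec_idx], e_rec, sc)


@dataclass
class RecordedMeasurement:
    """Per-second spectra and window counts of one simulated acquisition.

    ``window_counts`` is a tidy frame (second, window, true_counts,
    observed_counts); ``true_primary_counts`` are the loss-free unscattered
    arrivals inside the main analysis window each second.
    """

    bin_edges: np.ndarray
    true_spectra: np.ndarray  # (seconds, bins)
    observed_spectra: np.ndarray
    window_counts: pd.DataFrame
    true_primary_counts: np.ndarray
    duration_s: int

    def counts(self, window: str, which: str = "observed") -> np.ndarray:
        col = f"{which}_counts"
        sub = self.window_counts[self.window_counts["window"] == window]
        return sub.sort_values("second")[col].to_numpy()


def record_measurement(
    incident: IncidentSpectrum,
    config: DetectorConfig,
    windows: Mapping[str, tuple[float, float]],
    seed: int | np.random.SeedSequence,
    main_window: str = "main",
    target_counts: int = 10_000,
    min_seconds: int = 1,
    max_seconds: int = 3_600,
) -> RecordedMeasurement:
    """Simulate whole seconds until the cumulative observed counts in the
    main analysis window exceed ``target_counts`` (and at least
    ``min_seconds`` have elapsed)."""
    if main_window not in windows:
        raise ValueError(f"windows must include {main_window!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    edges = incident.bin_edges
    true_spectra: list[np.ndarray] = []
    obs_spectra: list[np.ndarray] = []
    rows: list[dict] = []
    true_primary: list[int] = []
    cum_main = 0
    main_lo, main_hi = windows[main_window]

    for sec in range(max_seconds):
        arrivals = generate_event_stream(incident, config, 1.0, rng)
        observed = apply_paralyzable(
            arrivals, config.tau_full_s, config.pileup, config.integration
        )
        true_spectra.append(np.histogram(arrivals.energies, bins=edges)[0])
        obs_spectra.append(np.histogram(observed.energies, bins=edges)[0])
        for name, (lo, hi) in windows.items():
            n_true = int(((arrivals.energies >= lo) & (arrivals.energies < hi)).sum())
            n_obs = int(((observed.energies >= lo) & (observed.energies < hi)).sum())
            rows.append(
                {
                    "second": sec,
                    "window": name,
                    "true_counts": n_true,
                    "observed_counts": n_obs,
                }
            )
            if name == main_window:
                cum_main += n_obs
        prim = (
            (arrivals.energies >= main_lo)
            & (arrivals.energies < main_hi)
            & ~arrivals.is_scatter
        )
        true_primary.append(int(prim.sum()))
        if cum_main > target_counts and sec + 1 >= min_seconds:
            break
    else:
        raise RuntimeError(
            f"observed main-window counts did not exceed {target_counts} "
            f"within {max_seconds} s (rate too low?)"
        )

    return RecordedMeasurement(
        bin_edges=edges,
        true_spectra=np.asarray(true_spectra),
        observed_spectra=np.asarray(obs_spectra),
        window_counts=pd.DataFrame(rows),
        true_primary_counts=np.asarray(true_primary),
        duration_s=len(true_spectra),
    )
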