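"""Isotropic first-derivative EPR spectrum simulation for nitroxide spin adducts.

A trapped-radical nitroxide gives a six-line pattern: a 1:1:1 nitrogen
triplet (splitting ``a_N``) further split into a 1:1 doublet by the
beta-hydrogen (splitting ``a_H``).  Spectra are built by summing analytic
first-derivative lineshapes at the six resonance positions of each species.

Field values are gauss throughout; amplitudes are arbitrary units and all
quantitative comparisons downstream are ratio-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import scipy.constants

__all__ = [
    "SpinSystem",
    "AcquisitionSettings",
    "Spectrum",
    "resonance_center",
    "line_positions",
    "simulate_spectrum",
    "add_noise",
]

# CODATA values via scipy
_PLANCK = scipy.constants.h  # J s
_BOHR_MAGNETON = scipy.constants.value("Bohr magneton")  # J/T

Lineshape = Literal["lorentzian", "gaussian", "pseudo-voigt"]


class NarrowWindowWarning(UserWarning):
    """Sweep window does not cover all lines plus 10 linewidths of margin."""


@dataclass(frozen=True)
class SpinSystem:
    """One nitroxide adduct species.

    Parameters
    ----------
    label : str
        Human-readable identifier.
    g : float
        Isotropic g-factor; must lie in (1.9, 2.1).
    a_N : float
        Nitrogen hyperfine constant, gauss (> 0).
    a_H : float
        Beta-hydrogen hyperfine constant, gauss (>= 0).
    linewidth_pp : float
        Peak-to-peak linewidth of the derivative line, gauss.
    lineshape : {"lorentzian", "gaussian", "pseudo-voigt"}
        Analytic lineshape; pseudo-Voigt mixes Lorentzian and Gaussian
        with fraction ``eta``.
    weight : float
        Non-negative relative double-integral fraction of this species.
    eta : float
        Lorentzian fraction for pseudo-Voigt (ignored otherwise).
    """

    label: str
    g: float = 2.0057
    a_N: float = 14.90
    a_H: float = 2.48
    linewidth_pp: float = 1.5
    lineshape: Lineshape = "lorentzian"
    weight: float = 1.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if not (1.9 < self.g < 2.1):
            raise ValueError(f"g={self.g} outside the nitroxide range (1.9, 2.1)")
        if self.a_N <= 0:
            raise ValueError("a_N must be positive")
        if self.a_H < 0:
            raise ValueError("a_H must be non-negative")
        if self.linewidth_pp <= 0:
            raise ValueError("linewidth_pp must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.lineshape not in ("lorentzian", "gaussian", "pseudo-voigt"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Field-sweep and noise settings for a simulated acquisition.

    ``modulation_amplitude`` (mT) is carried as metadata only; modulation
    broadening is not modelled.
    """

    microwave_frequency: float = 9.4  # GHz
    center_field: float | None = None  # gauss; None -> resonance of first system
    sweep_width: float = 100.0  # gauss
    n_points: int = 1024
    modulation_amplitude: float = 0.106  # mT, metadata only
    noise_sd: float = 0.0
    seed: int | None = None
    window_warning: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be positive")
        if self.microwave_frequency <= 0:
            raise ValueError("microwave_frequency must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("an explicit seed is required when noise_sd > 0")


@dataclass
class Spectrum:
    """A first-derivative EPR trace on a uniform, strictly increasing field axis."""

    field: np.ndarray  # gauss
    intensity: np.ndarray  # arbitrary units, first-derivative convention
    meta: AcquisitionSettings = field(default_factory=AcquisitionSettings)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.shape != self.intensity.shape or self.field.ndim != 1:
            raise ValueError("field and intensity must be 1-D arrays of equal length")
        diffs = np.diff(self.field)
        if not np.all(diffs > 0):
            raise ValueError("field axis must be strictly increasing")
        if diffs.size and not np.allclose(diffs, diffs[0], rtol=1e-9, atol=0.0):
            raise ValueError("field axis must be uniformly spaced")

    @property
    def step(self) -> float:
        return float(self.field[1] - self.field[0])

    def copy(self) -> "Spectrum":
        return Spectrum(self.field.copy(), self.intensity.copy(), self.meta)


def resonance_center(g: float, frequency: float) -> float:
    """Resonance field B0 = h*nu / (g*muB) in gauss for ``frequency`` in GHz."""
    if g <= 0 or frequency <= 0:
        raise ValueError("g and frequency must be positive")
    tesla = _PLANCK * frequency * 1e9 / (g * _BOHR_MAGNETON)
    return tesla * 1e4


def line_positions(system: SpinSystem, center: float) -> list[tuple[float, float]]:
    """Six (field, relative amplitude) pairs for a nitrogen triplet x H doublet.

    Positions are ``center + mN*a_N + mH*a_H`` with ``mN`` in {-1, 0, +1} and
    ``mH`` in {-1/2, +1/2}; all six relative amplitudes are equal.  Sorted by
    field.
    """
    pairs = [
        (center + m_n * system.a_N + m_h * system.a_H, 1.0 / 6.0)
        for m_n in (-1, 0, 1)
        for m_h in (-0.5, 0.5)
    ]
    pairs.sort(key=lambda p: p[0])
    return pairs


# ---------------------------------------------------------------------------
# Lineshape primitives.  Each returns the first derivative of a unit-area
# absorption profile, parameterised by the peak-to-peak derivative linewidth.
# Lorentzian: pp width = 2*Gamma/sqrt(3) (Gamma = HWHM).
# Gaussian:   pp width = 2*sigma.
# ---------------------------------------------------------------------------

def _dlorentzian(x: np.ndarray, width_pp: float) -> np.ndarray:
    gamma = width_pp * math.sqrt(3.0) / 2.0
    return -(2.0 / math.pi) * gamma * x / (gamma**2 + x**2) ** 2


def _dgaussian(x: np.ndarray, width_pp: float) -> np.ndarray:
    sigma = width_pp / 2.0
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    return -norm * (x / sigma**2) * np.exp(-0.5 * (x / sigma) ** 2)


def _dline(x: np.ndarray, system: SpinSystem) -> np.ndarray:
    if system.lineshape == "lorentzian":
        return _dlorentzian(x, system.linewidth_pp)
    if system.lineshape == "gaussian":
        return _dgaussian(x, system.linewidth_pp)
    return system.eta * _dlorentzian(x, system.linewidth_pp) + (
        1.0 - system.eta
    ) * _dgaussian(x, system.linewidth_pp)


def simulate_spectrum(
    systems: Sequence[SpinSystem],
    settings: AcquisitionSettings | None = None,
) -> Spectrum:
    """Simulate the summed first-derivative spectrum of one or more species.

    Each species contributes six lines scaled so that its total double
    integral equals its ``weight``.  Gaussian noise of sd ``noise_sd`` is
    added reproducibly from ``settings.seed``; ``noise_sd=0`` is fully
    deterministic.  If the sweep window does not extend at least ten
    linewidths past the outermost line, a :class:`NarrowWindowWarning` is
    issued and flagged on the returned metadata.
    """
    systems = list(systems)
    if not systems:
        raise ValueError("at least one spin system is required")
    if settings is None:
        settings = AcquisitionSettings()

    center = settings.center_field
    if center is None:
        center = resonance_center(systems[0].g, settings.microwave_frequency)
    lo = center - settings.sweep_width / 2.0
    hi = center + settings.sweep_width / 2.0
    fld = np.linspace(lo, hi, settings.n_points)

    narrow = False
    intensity = np.zeros_like(fld)
    for sys_ in systems:
        b0 = resonance_center(sys_.g, settings.microwave_frequency)
        for pos, rel in line_positions(sys_, b0):
            margin = 10.0 * sys_.linewidth_pp
            if pos - margin < lo or pos + margin > hi:
                narrow = True
            intensity += sys_.weight * rel * _dline(fld - pos, sys_)

    if narrow:
        warnings.warn(
            "sweep window does not cover all lines plus 10 linewidths",
            NarrowWindowWarning,
            stacklevel=2,
        )

    meta = replace(settings, center_field=center, window_warning=narrow)
    spec = Spectrum(fld, intensity, meta)
    if settings.noise_sd > 0:
        spec = add_noise(spec, settings.noise_sd, settings.seed)
    return spec


def add_noise(spectrum: Spectrum, sd: float, seed: int | None = None) -> Spectrum:
    """Return a copy with additive i.i.d. Gaussian noise (deterministic in seed)."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return spectrum.copy()
    if seed is None:
        raise ValueError("an explicit seed is required when sd > 0")
    rng = np.random.default_rng(seed)
    noisy = spectrum.intensity + rng.normal(0.0, sd, size=spectrum.intensity.shape)
    return Spectrum(spectrum.field.copy(), noisy, spectrum.meta)
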