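"""Hairpin/quencher binding kinetics and their modulation of the emission PSD.

A fluorophore-quencher tagged ssDNA strand exchanges between an unquenched
random-coil conformation and a quenched hairpin at first-order rates k_on
(hairpin formation) and k_off (opening).  At equilibrium the unquenched
fraction is k_off/(k_on+k_off); a perturbation relaxes exponentially at rate
k_on+k_off, so the conformational fluctuation spectrum is a Lorentzian with
3 dB corner (k_on+k_off)/2π.  Treating quenching as linear, the spectrum of
the quench process multiplies the fluorescence emission PSD pointwise and
band-limits it.
"""

from __future__ import annotations

import math
import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np

from .counting import SpectrumModel

__all__ = [
    "HairpinKinetics",
    "builtin_hairpin",
    "equilibrium_unquenched",
    "relaxation_response",
    "binding_psd",
    "modulated_psd",
]


@dataclass(frozen=True)
class HairpinKinetics:
    """Two-state hairpin exchange parameters.

    k_on : hairpin (quenched) formation rate, s⁻¹
    k_off : hairpin opening rate, s⁻¹
    concentration : total strand concentration [X₀], molar
    strand_count : number of strands in the observed volume
    temperature : descriptive label, °C
    """

    k_on: float
    k_off: float
    concentration: float = 0.0
    strand_count: int = 1
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.strand_count < 1:
            raise ValueError("strand count must be >= 1")

    @property
    def relaxation_rate(self) -> float:
        """k_on + k_off, s⁻¹."""
        return self.k_on + self.k_off

    @property
    def unquenched_fraction(self) -> float:
        """Equilibrium open (fluorescent) fraction k_off/(k_on+k_off)."""
        return self.k_off / (self.k_on + self.k_off)

    @property
    def corner_hz(self) -> float:
        """Lorentzian 3 dB corner (k_on+k_off)/2π, Hz."""
        return self.relaxation_rate / (2.0 * math.pi)


def builtin_hairpin(name: str) -> HairpinKinetics:
    """Shipped hairpin presets ("50C" and "10C" 22-nt ssDNA conditions)."""
    text = resources.files("fluorstat.data").joinpath("hairpins.json").read_text()
    presets = json.loads(text)
    if name not in presets:
        raise KeyError(f"unknown hairpin preset {name!r}; known: {sorted(presets)}")
    return HairpinKinetics(**presets[name])


def equilibrium_unquenched(kinetics: HairpinKinetics) -> float:
    """Equilibrium unquenched-strand concentration k_off/(k_on+k_off)·[X₀]."""
    return kinetics.unquenched_fraction * kinetics.concentration


def relaxation_response(kinetics: HairpinKinetics, t: np.ndarray | float) -> np.ndarray | float:
    """Normalized impulse response of the open-strand concentration,
    h(t) = e^{−t·(k_on+k_off)}."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    out = np.exp(-arr * kinetics.relaxation_rate)
    return out if isinstance(t, np.ndarray) else float(out)


def binding_psd(kinetics: HairpinKinetics, mode: str = "kinetic") -> SpectrumModel:
    """Fluctuation spectrum of the unquenched state.

    ``mode='kinetic'`` (default) is the rate-form spectrum: DC impulse weight
    4π·(k_on·k_off/(k_on+k_off))² and Lorentzian part

        (1/(k_on+k_off)) · 4·(k_on·k_off/(k_on+k_off)) / (1 + (ω/(k_on+k_off))²).

    ``mode='telegraph'`` is the normalized two-state telegraph-process
    alternative (dimensionless occupancy, variance q(1−q) with
    q = k_off/(k_on+k_off)): DC weight 2π·q² and Lorentzian
    4·q(1−q)·k_s/(k_s² + ω²), k_s = k_on+k_off.  Use it when a dimensionally
    consistent per-molecule fraction spectrum is needed; the kinetic form is
    kept as the primary convention.  Both share the corner (k_on+k_off)/2π.
    """
    ks = kinetics.relaxation_rate
    if mode == "kinetic":
        hmean = kinetics.k_on * kinetics.k_off / ks
        dc = 4.0 * math.pi * hmean**2
        peak = 4.0 * hmean / ks

        def _density(omega: np.ndarray) -> np.ndarray:
            return peak / (1.0 + (omega / ks) ** 2)

    elif mode == "telegraph":
        q = kinetics.unquenched_fraction
        dc = 2.0 * math.pi * q**2
        peak = 4.0 * q * (1.0 - q) / ks

        def _density(omega: np.ndarray) -> np.ndarray:
            return peak / (1.0 + (omega / ks) ** 2)

    else:
        raise ValueError("mode must be 'kinetic' or 'telegraph'")
    return SpectrumModel(
        dc_weight=dc,
        low_plateau=peak,
        high_plateau=0.0,
        transition_hz=kinetics.corner_hz,
        _density=_density,
    )


def modulated_psd(
    kinetics: HairpinKinetics,
    fluorescence: SpectrumModel,
    n_strands: int | None = None,
    mode: str = "kinetic",
) -> SpectrumModel:
    """Binding-modulated emission spectrum M(ω) = N·S(ω)·B(ω).

    Quenching is treated as a linear modulation, so the spectra multiply
    pointwise and the DC impulse weights multiply as scalars.  ``n_strands``
    defaults to the kinetics' strand count (one fluorophore per strand).
    The product inherits the binding corner whenever binding is slower than
    the fluorescence transition, band-limiting the emission fluctuations.
    """
    n = kinetics.strand_count if n_strands is None else int(n_strands)
    if n < 1:
        raise ValueError("strand count must be >= 1")
    b = binding_psd(kinetics, mode=mode)

    def _density(omega: np.ndarray) -> np.ndarray:
        return n * fluorescence.density(omega) * b.density(omega)

    return SpectrumModel(
        dc_weight=n * fluorescence.dc_weight * b.dc_weight,
        low_plateau=n * fluorescence.low_plateau * b.low_plateau,
        high_plateau=0.0,
        transition_hz=min(b.transition_hz, fluorescence.transition_hz),
        _density=_density,
    )
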