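"""SNR and detection-limit calculators for CW and TG fluorescence readout.

The quantum-limited SNR (QSNR) is set purely by the photon-count statistics
of the fluorophores:

    QSNR = 10·log10( G·(⟨n_p⟩·γ_e·η_e)² / (σ²_np·γ_e·η_e) )   [dB]

with G imaging pixels, emission coupling γ_e and quantum efficiency η_e.
Extrinsic noise only subtracts from it.  For CW, the excitation background
leaking through an emission filter of optical density d (linear rejection
10^d), read noise σ_r, and dark current β give

    SNR = QSNR − 10·log10(1 + [10^{−d}·⟨F_x⟩·T_int·γ_x·η_x + σ_r² + β·T_int]
                              / (σ²_np·γ_e·η_e)).

For TG, the background term is the integrated exponential excitation tail
(time constant τ_s) over the K gate windows.  The minimum detection limit
(MDL) is the smallest fluorophore count N with SNR ≥ 0 dB.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
import json

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .counting import (
    CountStatistics,
    cw_count_stats,
    eigenrates,
    tg_count_stats,
)
from .photophysics import Fluorophore, excitation_rate

__all__ = [
    "ImagerModel",
    "DetectionResult",
    "ScalingScenario",
    "builtin_imager",
    "qsnr",
    "snr_cw",
    "snr_tg",
    "minimum_detection_limit",
    "spot_scaling_sweep",
]


@dataclass(frozen=True)
class ImagerModel:
    """Imaging-system performance bundle.

    pixels : G, number of imaging pixels per spot
    emission_coupling / excitation_coupling : γ_e, γ_x fractions
    qe_emission / qe_excitation : η_e, η_x fractions
    read_noise : σ_r, e⁻ rms per integration
    dark_current : β, e⁻/s
    well_capacity : W, e⁻ (validated for saturation; enters no SNR formula)
    filter_od : d, optical density of the emission filter (rejection 10^d)
    excitation_tail : τ_s, source shutoff decay time constant, s
    """

    pixels: int = 100
    emission_coupling: float = 0.01
    excitation_coupling: float = 0.01
    qe_emission: float = 0.45
    qe_excitation: float = 0.45
    read_noise: float = 2.0
    dark_current: float = 5.0
    well_capacity: float = 50_000.0
    filter_od: float = 6.0
    excitation_tail: float = 50e-9

    def __post_init__(self) -> None:
        if self.pixels < 1 or int(self.pixels) != self.pixels:
            raise ValueError("pixel count must be an integer >= 1")
        for name in ("emission_coupling", "excitation_coupling", "qe_emission", "qe_excitation"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("read_noise", "dark_current", "filter_od", "excitation_tail"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.well_capacity <= 0:
            raise ValueError("well capacity must be > 0")

    def with_od(self, filter_od: float) -> "ImagerModel":
        return replace(self, filter_od=filter_od)


def builtin_imager(name: str = "benchmark") -> ImagerModel:
    """Shipped imager presets (the 100-pixel benchmark imager by default)."""
    text = resources.files("fluorstat.data").joinpath("imagers.json").read_text()
    presets = json.loads(text)
    if name not in presets:
        raise KeyError(f"unknown imager preset {name!r}; known: {sorted(presets)}")
    return ImagerModel(**presets[name])


@dataclass(frozen=True)
class DetectionResult:
    """SNR computation output with its noise breakdown (electron units)."""

    qsnr_db: float
    snr_db: float
    signal_electrons: float
    quantum_variance: float  # σ²_np·γ_e·η_e, the intrinsic noise term
    background_electrons: float
    read_variance: float
    dark_electrons: float

    @property
    def extrinsic_total(self) -> float:
        return self.background_electrons + self.read_variance + self.dark_electrons


def qsnr(stats: CountStatistics, imager: ImagerModel) -> float:
    """Quantum-limited SNR in dB from photon-count statistics."""
    if stats.mean <= 0:
        raise ValueError("QSNR is undefined for zero mean photon count")
    ge = imager.emission_coupling * imager.qe_emission
    signal = stats.mean * ge
    if signal / imager.pixels > imager.well_capacity:
        warnings.warn(
            "signal electrons per pixel exceed the well capacity; "
            "the imager would saturate at this operating point",
            stacklevel=2,
        )
    return 10.0 * math.log10(imager.pixels * signal**2 / (stats.variance * ge))


def _assemble(stats, imager, background: float, t_int: float) -> DetectionResult:
    ge = imager.emission_coupling * imager.qe_emission
    quantum = stats.variance * ge
    read = imager.read_noise**2
    dark = imager.dark_current * t_int
    q_db = qsnr(stats, imager)
    snr_db = q_db - 10.0 * math.log10(1.0 + (background + read + dark) / quantum)
    return DetectionResult(
        qsnr_db=q_db,
        snr_db=snr_db,
        signal_electrons=stats.mean * ge,
        quantum_variance=quantum,
        background_electrons=background,
        read_variance=read,
        dark_electrons=dark,
    )


def snr_cw(
    stats: CountStatistics,
    imager: ImagerModel,
    excitation_flux_mean: float,
    t_int: float,
) -> DetectionResult:
    """CW SNR with filter leakage, read noise, and dark current.

    ``excitation_flux_mean`` is the excitation photon rate reaching the
    detector plane before filtering (photons/s); the filter passes a 10^{−d}
    fraction into background electrons.
    """
    if excitation_flux_mean < 0 or t_int <= 0:
        raise ValueError("flux must be >= 0 and t_int > 0")
    background = (
        10.0 ** (-imager.filter_od)
        * excitation_flux_mean
        * t_int
        * imager.excitation_coupling
        * imager.qe_excitation
    )
    return _assemble(stats, imager, background, t_int)


def snr_tg(
    stats: CountStatistics,
    imager: ImagerModel,
    excitation_flux_mean: float,
    shots: int,
    gate_delay: float,
    t_int: float,
) -> DetectionResult:
    """TG SNR: background is the source's exponential shutoff tail integrated
    over the K gate windows,

        K·τ_s·10^{−d}·⟨F_x⟩·e^{−ΔT_D/τ_s}·(1 − e^{−T_int/τ_s})·γ_x·η_x.

    Gating well past the tail (ΔT_D ≫ τ_s) leaves only read/dark noise.
    """
    if excitation_flux_mean < 0 or t_int <= 0 or gate_delay < 0:
        raise ValueError("invalid TG parameters")
    if shots < 1:
        raise ValueError("shots must be >= 1")
    tau_s = imager.excitation_tail
    if tau_s == 0.0:
        leakage = 0.0
    else:
        leakage = (
            shots
            * tau_s
            * 10.0 ** (-imager.filter_od)
            * excitation_flux_mean
            * math.exp(-gate_delay / tau_s)
            * (1.0 - math.exp(-t_int / tau_s))
            * imager.excitation_coupling
            * imager.qe_excitation
        )
    return _assemble(stats, imager, leakage, t_int)


def _snr_at_n(
    n: float,
    mode: str,
    fluorophore: Fluorophore,
    flux: float,
    imager: ImagerModel,
    t_int: float,
    shots: int,
    gate_delay: float,
    detector_flux: float,
    coupling: float,
) -> float:
    r_x = excitation_rate(flux, fluorophore, coupling)
    if mode == "cw":
        model = eigenrates(r_x, fluorophore.relaxation_rate, fluorophore.quantum_yield)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = cw_count_stats(model, t_int, n_total=n)
            return snr_cw(stats, imager, detector_flux, t_int).snr_db
    stats = tg_count_stats(fluorophore, r_x, shots, gate_delay, t_int, n_total=n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return snr_tg(stats, imager, detector_flux, shots, gate_delay, t_int).snr_db


def minimum_detection_limit(
    fluorophore: Fluorophore,
    flux: float,
    imager: ImagerModel,
    *,
    mode: str = "cw",
    t_int: float,
    shots: int = 1,
    gate_delay: float = 0.0,
    detector_flux: float | None = None,
    coupling: float = 1.0,
    bracket: tuple[float, float] = (1e-3, 1e15),
) -> int:
    """Smallest fluorophore count N with SNR ≥ 0 dB.

    SNR is monotone increasing in N, so the continuous root of SNR(N) = 0 is
    bisected within ``bracket`` and rounded up (never below 1).
    ``detector_flux`` is the excitation photon rate at the detector plane
    (defaults to flux·10⁻⁴ cm², the benchmark spot area).
    """
    if mode not in ("cw", "tg"):
        raise ValueError("mode must be 'cw' or 'tg'")
    if detector_flux is None:
        detector_flux = flux * 1e-4
    f = lambda logn: _snr_at_n(
        10.0**logn, mode, fluorophore, flux, imager,
        t_int, shots, gate_delay, detector_flux, coupling,
    )
    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo >= 0.0:
        return 1
    if fhi < 0.0:
        raise ValueError(
            f"SNR does not reach 0 dB within bracket (SNR at N={bracket[1]:g} is {fhi:.2f} dB)"
        )
    logn = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    n = math.ceil(10.0**logn - 1e-9)
    return max(1, int(n))


@dataclass(frozen=True)
class ScalingScenario:
    """Isomorphic spot-scaling sweep description.

    alpha : spot scaling ratios in (0, 1] (1 = unscaled)
    total_time : T_C, total array acquisition time, s
    n_values : fluorophores per spot to evaluate
    spot_diameter : unscaled spot diameter, m (descriptive)
    pixel_block : M, spot maps to an M×M pixel region (descriptive)
    """

    alphas: tuple[float, ...]
    total_time: float
    n_values: tuple[float, ...]
    spot_diameter: float | None = None
    pixel_block: int | None = None

    def __post_init__(self) -> None:
        if any(not (0.0 < a <= 1.0) for a in self.alphas):
            raise ValueError("scaling ratios must be in (0, 1]")
        if self.total_time <= 0:
            raise ValueError("total acquisition time must be > 0")
        if any(n <= 0 for n in self.n_values):
            raise ValueError("fluorophore counts must be > 0")


def spot_scaling_sweep(
    scenario: ScalingScenario,
    fluorophore: Fluorophore,
    flux: float,
    imager: ImagerModel,
    *,
    coupling: float = 1.0,
) -> pd.DataFrame:
    """CW QSNR across spot scaling ratios.

    Scaling the spots by α divides the per-spot dwell time to T_C·α/2, so
    fewer photons are collected per spot and the QSNR degrades with
    shrinking α.  Rows: (alpha, n, t_int, mean_photons, qsnr_db).
    """
    r_x = excitation_rate(flux, fluorophore, coupling)
    model = eigenrates(r_x, fluorophore.relaxation_rate, fluorophore.quantum_yield)
    rows = []
    for alpha in scenario.alphas:
        t_int = scenario.total_time * alpha / 2.0
        for n in scenario.n_values:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats = cw_count_stats(model, t_int, n_total=n)
                q = qsnr(stats, imager)
            rows.append(
                {
                    "alpha": alpha,
                    "n": n,
                    "t_int": t_int,
                    "mean_photons": stats.mean,
                    "qsnr_db": q,
                }
            )
    return pd.DataFrame(rows)
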