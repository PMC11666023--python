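"""Analytic photon-counting statistics of a single fluorophore (and N copies).

One excitation-relaxation cycle is the sum of two exponential sojourns
(ground, rate r_x; excited, rate r_l), and each relaxation emits a photon
with probability Φ.  Thinning the cycle renewal process by Φ leaves the
photon inter-arrival times hypoexponential with eigenrates

    λ1, λ2 = (r_x + r_l ± γ)/2,    γ = sqrt((r_x + r_l)² − 4·Φ·r_x·r_l),

which determine the CW flux mean λ1λ2/(λ1+λ2) and variance rate
λ1λ2(λ1²+λ2²)/(λ1+λ2)³.  The Fano factor (λ1²+λ2²)/(λ1+λ2)² is strictly
below one: fluorescence emission is a sub-Poisson point process.  The
one-sided power spectral density interpolates between the sub-Poisson
plateau 2σ²_F at low frequency and the Poisson plateau 2⟨F⟩ at high
frequency, with transition frequency f_c = (λ1+λ2)/2π.

Time-gated statistics follow from Bernoulli thinning of the shutoff-time
excited-state occupancy (Burgess variance theorem).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .photophysics import Fluorophore

__all__ = [
    "InterArrivalModel",
    "CountStatistics",
    "SpectrumModel",
    "TGStatistics",
    "eigenrates",
    "interarrival_pdf",
    "cw_flux_stats",
    "cw_count_stats",
    "analytic_psd",
    "tg_emission_probability",
    "tg_count_stats",
]


@dataclass(frozen=True)
class InterArrivalModel:
    """Hypoexponential photon inter-arrival model for one fluorophore."""

    r_x: float
    r_l: float
    emission_probability: float  # p = Φ per relaxation
    lam1: float  # larger eigenrate, s⁻¹
    lam2: float  # smaller eigenrate, s⁻¹
    gamma: float  # discriminant sqrt((r_x+r_l)² − 4Φ r_x r_l), s⁻¹

    @property
    def mean_interarrival(self) -> float:
        return 1.0 / self.lam1 + 1.0 / self.lam2

    @property
    def var_interarrival(self) -> float:
        return 1.0 / self.lam1**2 + 1.0 / self.lam2**2


@dataclass(frozen=True)
class CountStatistics:
    """Mean/variance pair (flux units s⁻¹ or counts, per context)."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")

    @property
    def fano(self) -> float:
        return self.variance / self.mean


@dataclass(frozen=True)
class TGStatistics:
    """Per-shot, per-fluorophore time-gated emission statistics."""

    emission_probability: float  # p, photon in gate | one excited fluorophore
    excited_probability: float  # ⟨n_e⟩ = r_x/(r_x+r_l) at shutoff
    excited_variance: float  # ⟨n_e⟩(1−⟨n_e⟩)
    shots: int


def eigenrates(r_x: float, r_l: float, quantum_yield: float) -> InterArrivalModel:
    """Eigenrates of the photon inter-arrival law (λ1 ≥ λ2 > 0).

    By Vieta, λ1+λ2 = r_x+r_l and λ1·λ2 = Φ·r_x·r_l; the discriminant is
    non-negative for every Φ ≤ 1 (AM–GM), so both rates are always real.
    """
    if r_x <= 0 or r_l <= 0:
        raise ValueError("rates must be > 0")
    if not (0.0 < quantum_yield <= 1.0):
        raise ValueError("quantum yield must be in (0, 1]")
    s = r_x + r_l
    disc = s * s - 4.0 * quantum_yield * r_x * r_l
    gamma = math.sqrt(max(disc, 0.0))
    lam1 = 0.5 * (s + gamma)
    # product form for the small root avoids catastrophic cancellation
    lam2 = quantum_yield * r_x * r_l / lam1
    return InterArrivalModel(
        r_x=r_x,
        r_l=r_l,
        emission_probability=quantum_yield,
        lam1=lam1,
        lam2=lam2,
        gamma=gamma,
    )


def interarrival_pdf(model: InterArrivalModel, t: np.ndarray | float) -> np.ndarray | float:
    """Hypoexponential density λ1λ2/(λ2−λ1)·(e^{−λ1 t} − e^{−λ2 t}).

    Vanishes at t = 0, integrates to 1, mean 1/λ1 + 1/λ2.  The equal-rate
    limit λ1 → λ2 = λ degenerates to the Erlang-2 density λ²·t·e^{−λt}.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    l1, l2 = model.lam1, model.lam2
    if (l1 - l2) <= 1e-12 * l1:
        out = l1 * l1 * arr * np.exp(-l1 * arr)
    else:
        out = l1 * l2 / (l2 - l1) * (np.exp(-l1 * arr) - np.exp(-l2 * arr))
        out = np.clip(out, 0.0, None)
    return out if isinstance(t, np.ndarray) else float(out)


def cw_flux_stats(model: InterArrivalModel) -> CountStatistics:
    """Asymptotic emission-flux mean and variance rate (renewal theorem).

    mean = λ1λ2/(λ1+λ2) = Φ·r_x·r_l/(r_x+r_l) photons/s,
    variance rate = λ1λ2(λ1²+λ2²)/(λ1+λ2)³ photons/s (counts variance per
    second of integration).
    """
    l1, l2 = model.lam1, model.lam2
    s = l1 + l2
    return CountStatistics(mean=l1 * l2 / s, variance=l1 * l2 * (l1 * l1 + l2 * l2) / s**3)


def cw_count_stats(model: InterArrivalModel, t_int: float, n_total: float = 1.0) -> CountStatistics:
    """Photon-count statistics for N fluorophores observed for T_int.

    ⟨n_ph⟩ = N·⟨F⟩·T_int and σ² = N·σ²_F·T_int; both are asymptotic renewal
    results, so a warning is emitted when T_int is within 10 mean
    inter-arrival times.
    """
    if t_int <= 0:
        raise ValueError("t_int must be > 0")
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if t_int < 10.0 * model.mean_interarrival:
        warnings.warn(
            "integration window is within 10 mean inter-arrival times; "
            "renewal-asymptotic count statistics may be inaccurate",
            stacklevel=2,
        )
    flux = cw_flux_stats(model)
    return CountStatistics(
        mean=n_total * flux.mean * t_int, variance=n_total * flux.variance * t_int
    )


@dataclass(frozen=True)
class SpectrumModel:
    """One-sided emission-flux PSD with its DC impulse weight kept separate.

    ``density(omega)`` evaluates the continuous part at angular frequency ω
    (rad/s); the Dirac impulse at DC carries weight ``dc_weight``
    (2π⟨F⟩² for the analytic fluorescence spectrum).  ``low_plateau`` is the
    sub-Poisson floor 2σ²_F, ``high_plateau`` the Poisson ceiling 2⟨F⟩, and
    ``transition_hz`` the corner f_c = (λ1+λ2)/2π separating the regimes.
    """

    dc_weight: float
    low_plateau: float
    high_plateau: float
    transition_hz: float
    _density: Callable[[np.ndarray], np.ndarray]

    def density(self, omega: np.ndarray | float) -> np.ndarray | float:
        arr = np.asarray(omega, dtype=float)
        if np.any(arr < 0):
            raise ValueError("omega must be >= 0")
        out = self._density(arr)
        return out if isinstance(omega, np.ndarray) else float(out)

    def density_hz(self, freq_hz: np.ndarray | float) -> np.ndarray | float:
        return self.density(2.0 * math.pi * np.asarray(freq_hz, dtype=float))

    @property
    def fano(self) -> float:
        if self.high_plateau == 0.0:
            return math.inf
        return self.low_plateau / self.high_plateau


def analytic_psd(model: InterArrivalModel, n_total: float = 1.0) -> SpectrumModel:
    """Closed-form one-sided PSD of the emission pulse train (Dirac pulses).

    S(ω) = 2πF̄²δ(ω) + 2σ²_F · (1 + ω²/(λ1²+λ2²)) / (1 + ω²/(λ1+λ2)²),
    scaled by N for N independent fluorophores.  The ω→0 limit is the
    sub-Poisson plateau 2σ²_F; the ω→∞ limit is the Poisson plateau 2⟨F⟩.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    flux = cw_flux_stats(model)
    l1, l2 = model.lam1, model.lam2
    sumsq = l1 * l1 + l2 * l2
    ssq = (l1 + l2) ** 2

    def _density(omega: np.ndarray) -> np.ndarray:
        w2 = omega * omega
        return n_total * 2.0 * flux.variance * (1.0 + w2 / sumsq) / (1.0 + w2 / ssq)

    return SpectrumModel(
        dc_weight=n_total * 2.0 * math.pi * flux.mean**2,
        low_plateau=n_total * 2.0 * flux.variance,
        high_plateau=n_total * 2.0 * flux.mean,
        transition_hz=(l1 + l2) / (2.0 * math.pi),
        _density=_density,
    )


def tg_emission_probability(
    fluorophore: Fluorophore, gate_delay: float, t_int: float
) -> float:
    """Probability a photon lands in the gate [ΔT_D, ΔT_D+T_int] after
    shutoff, given exactly one excited fluorophore at shutoff:

        p = Φ·(e^{−ΔT_D/τ_l} − e^{−(T_int+ΔT_D)/τ_l}).

    Monotone decreasing in ΔT_D, increasing in T_int, bounded by Φ.
    """
    if gate_delay < 0 or t_int < 0:
        raise ValueError("durations must be >= 0")
    tau = fluorophore.lifetime
    return fluorophore.quantum_yield * (
        math.exp(-gate_delay / tau) - math.exp(-(t_int + gate_delay) / tau)
    )


def tg_shot_model(
    fluorophore: Fluorophore, r_x: float, shots: int, gate_delay: float, t_int: float
) -> TGStatistics:
    """Per-shot TG model assuming steady state before each shutoff."""
    if shots < 1 or int(shots) != shots:
        raise ValueError("shot count must be an integer >= 1")
    if r_x <= 0:
        raise ValueError("excitation rate must be > 0")
    p = tg_emission_probability(fluorophore, gate_delay, t_int)
    ne = r_x / (r_x + fluorophore.relaxation_rate)
    return TGStatistics(
        emission_probability=p,
        excited_probability=ne,
        excited_variance=ne * (1.0 - ne),
        shots=int(shots),
    )


def tg_count_stats(
    fluorophore: Fluorophore,
    r_x: float,
    shots: int,
    gate_delay: float,
    t_int: float,
    n_total: float = 1.0,
) -> CountStatistics:
    """Accumulated TG count statistics for N fluorophores over K shots.

    The photon count per shot per fluorophore is a Bernoulli selection
    (probability p) of the Bernoulli excited-state occupancy ⟨n_e⟩; by the
    Burgess variance theorem,

        ⟨n_ph⟩ = N·K·p·⟨n_e⟩,
        σ²     = N·K·(p²·σ²_ne + ⟨n_e⟩·p·(1−p)),

    which collapses exactly to the Bernoulli(p·⟨n_e⟩) variance.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    m = tg_shot_model(fluorophore, r_x, shots, gate_delay, t_int)
    p, ne = m.emission_probability, m.excited_probability
    mean = n_total * shots * p * ne
    var = n_total * shots * (p * p * m.excited_variance + ne * p * (1.0 - p))
    return CountStatistics(mean=mean, variance=var)
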