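"""Fluorophore photophysics: rate bundles, excitation profiles, parameter library.

A fluorophore is summarized by its commonly tabulated figures of merit —
molar extinction coefficient ε(λ_x), quantum yield Φ, and fluorescence
lifetime τ_l — which this module converts into the microscopic flux rates
(r_x, r_r, r_nr, r_b) that every other module consumes.

Units are SI seconds throughout; photon fluxes are per cm², extinction
coefficients in M⁻¹·cm⁻¹, cross-sections in cm². Wavelengths are stored in
nm as labels only.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AVOGADRO",
    "Fluorophore",
    "ExcitationProfile",
    "RateSet",
    "absorption_cross_section",
    "excitation_rate",
    "decompose_lifetime",
    "builtin_fluorophores",
    "get_fluorophore",
    "load_fluorophores",
]

#: Avogadro constant, mol⁻¹ (SI exact).
AVOGADRO = 6.02214076e23

#: Decadic-to-natural conversion for extinction coefficients, cm³·M per mol⁻¹cm⁻¹.
#: σ [cm²] = ln(10)·10³·ε / N_A.  The ln(10) factor converts the base-10
#: absorbance convention of ε into a natural (e-folding) cross-section.
_GAMMA_X = math.log(10.0) * 1.0e3 / AVOGADRO


def absorption_cross_section(epsilon: float) -> float:
    """Absorption cross-section σ (cm²) from a decadic molar extinction
    coefficient ε (M⁻¹·cm⁻¹)."""
    if epsilon <= 0:
        raise ValueError(f"extinction coefficient must be positive, got {epsilon}")
    return _GAMMA_X * epsilon


def decompose_lifetime(quantum_yield: float, lifetime: float) -> tuple[float, float]:
    """Split a measured lifetime into radiative and non-radiative rates.

    Φ = r_r/(r_r + r_nr) and τ_l = 1/(r_r + r_nr) give
    r_r = Φ/τ_l and r_nr = (1 − Φ)/τ_l.

    Returns
    -------
    (r_r, r_nr) in s⁻¹, satisfying r_r + r_nr = 1/τ_l exactly.
    """
    if not (0.0 < quantum_yield <= 1.0):
        raise ValueError(f"quantum yield must be in (0, 1], got {quantum_yield}")
    if lifetime <= 0:
        raise ValueError(f"lifetime must be positive, got {lifetime}")
    r_r = quantum_yield / lifetime
    r_nr = (1.0 - quantum_yield) / lifetime
    return r_r, r_nr


@dataclass(frozen=True)
class Fluorophore:
    """Photophysical parameter bundle for a single fluorophore.

    Parameters
    ----------
    epsilon : molar extinction coefficient at λ_x, M⁻¹·cm⁻¹
    quantum_yield : Φ, probability an excited-state relaxation emits a photon
    lifetime : τ_l, mean excited-state dwell time, s
    bleach_rate : r_b, irreversible excited→dark rate, s⁻¹
    excitation_wavelength, emission_wavelength : nm, descriptive labels only
    """

    name: str
    epsilon: float
    quantum_yield: float
    lifetime: float
    bleach_rate: float = 0.0
    excitation_wavelength: float | None = None
    emission_wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"{self.name}: epsilon must be > 0, got {self.epsilon}")
        if not (0.0 < self.quantum_yield <= 1.0):
            raise ValueError(
                f"{self.name}: quantum yield must be in (0, 1], got {self.quantum_yield}"
            )
        if self.lifetime <= 0:
            raise ValueError(f"{self.name}: lifetime must be > 0, got {self.lifetime}")
        if self.bleach_rate < 0:
            raise ValueError(
                f"{self.name}: bleach rate must be >= 0, got {self.bleach_rate}"
            )

    @property
    def radiative_rate(self) -> float:
        """r_r = Φ/τ_l, s⁻¹."""
        return self.quantum_yield / self.lifetime

    @property
    def nonradiative_rate(self) -> float:
        """r_nr = (1 − Φ)/τ_l, s⁻¹."""
        return (1.0 - self.quantum_yield) / self.lifetime

    @property
    def relaxation_rate(self) -> float:
        """Total excited-state relaxation rate r_l = r_r + r_nr = 1/τ_l, s⁻¹."""
        return 1.0 / self.lifetime

    @property
    def cross_section(self) -> float:
        """Absorption cross-section σ at λ_x, cm²."""
        return absorption_cross_section(self.epsilon)

    def with_bleaching(self, bleach_rate: float) -> "Fluorophore":
        """Copy of this fluorophore with a different bleach rate."""
        return replace(self, bleach_rate=bleach_rate)

    def rates(self, flux: float, coupling: float = 1.0) -> "RateSet":
        """Full microscopic rate set under an excitation flux (photons·s⁻¹·cm⁻²)."""
        r_r, r_nr = decompose_lifetime(self.quantum_yield, self.lifetime)
        return RateSet(
            r_x=excitation_rate(flux, self, coupling),
            r_r=r_r,
            r_nr=r_nr,
            r_b=self.bleach_rate,
        )


@dataclass(frozen=True)
class RateSet:
    """Microscopic flux rates of the three-state system, all s⁻¹.

    r_x : ground→excited excitation rate
    r_r : excited→ground radiative relaxation (photon emitted)
    r_nr : excited→ground non-radiative relaxation
    r_b : excited→bleached irreversible loss
    """

    r_x: float
    r_r: float
    r_nr: float
    r_b: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_x", "r_r", "r_nr", "r_b"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.r_r + self.r_nr <= 0:
            raise ValueError("total relaxation rate r_r + r_nr must be > 0")

    @property
    def r_l(self) -> float:
        """Total relaxation rate r_r + r_nr, s⁻¹."""
        return self.r_r + self.r_nr

    @property
    def quantum_yield(self) -> float:
        return self.r_r / self.r_l


def excitation_rate(flux: float, fluorophore: Fluorophore, coupling: float = 1.0) -> float:
    """Per-fluorophore excitation rate r_x = k_x·F_x·σ, s⁻¹.

    Parameters
    ----------
    flux : excitation photon flux F_x, photons·s⁻¹·cm⁻²
    coupling : dipole coupling constant k_x (≈1 for ensemble-averaged dipole
        orientations; exposed for completeness)
    """
    if flux < 0:
        raise ValueError(f"flux must be >= 0, got {flux}")
    if coupling < 0:
        raise ValueError(f"coupling must be >= 0, got {coupling}")
    return coupling * flux * fluorophore.cross_section


@dataclass(frozen=True)
class ExcitationProfile:
    """Piecewise-constant excitation flux with an optional exponential shutoff tail.

    ``segments`` is an ordered sequence of (start_time s, flux photons·s⁻¹·cm⁻²);
    each segment holds until the next start time.  When ``shutoff_tail`` (τ_s,
    seconds) is set, every downward flux step decays exponentially toward its
    new level with time constant τ_s instead of switching instantaneously,
    emulating a leaky (e.g. LED) source.
    """

    segments: tuple[tuple[float, float], ...]
    shutoff_tail: float | None = None
    coupling: float = 1.0

    def __post_init__(self) -> None:
        segs = tuple((float(s), float(f)) for s, f in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("profile needs at least one segment")
        starts = [s for s, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(f < 0 for _, f in segs):
            raise ValueError("fluxes must be >= 0")
        if self.shutoff_tail is not None and self.shutoff_tail <= 0:
            raise ValueError("shutoff tail time constant must be > 0")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def constant(cls, flux: float, *, coupling: float = 1.0) -> "ExcitationProfile":
        return cls(((0.0, flux),), coupling=coupling)

    @classmethod
    def pulse(
        cls,
        flux: float,
        on: float,
        off: float,
        *,
        shutoff_tail: float | None = None,
        coupling: float = 1.0,
    ) -> "ExcitationProfile":
        """Rectangular pulse: flux from ``on`` to ``off``, zero elsewhere."""
        if off <= on:
            raise ValueError("pulse off time must exceed on time")
        segs: list[tuple[float, float]] = []
        if on > 0:
            segs.append((0.0, 0.0))
            segs.append((on, flux))
        else:
            segs.append((0.0, flux))
        segs.append((off, 0.0))
        return cls(tuple(segs), shutoff_tail=shutoff_tail, coupling=coupling)

    @classmethod
    def pulse_train(
        cls,
        flux: float,
        period: float,
        duty: float,
        cycles: int,
        *,
        shutoff_tail: float | None = None,
        coupling: float = 1.0,
    ) -> "ExcitationProfile":
        """K repeated rectangular pulses (on for ``duty`` s each ``period``)."""
        if not (0 < duty < period):
            raise ValueError("need 0 < duty < period")
        if cycles < 1:
            raise ValueError("cycles must be >= 1")
        segs: list[tuple[float, float]] = []
        for k in range(cycles):
            segs.append((k * period, flux))
            segs.append((k * period + duty, 0.0))
        return cls(tuple(segs), shutoff_tail=shutoff_tail, coupling=coupling)

    # -- evaluation --------------------------------------------------------
    @property
    def start(self) -> float:
        return self.segments[0][0]

    def resolved_segments(self, t_end: float) -> tuple["list[float]", "list[float]"]:
        """Flatten the profile into strictly piecewise-constant segments.

        Returns (starts, fluxes) covering [start, t_end].  An exponential
        shutoff tail is discretized into sub-segments of width τ_s/20 out to
        10·τ_s (each carrying the mean flux over its sub-interval), which
        keeps every segment exactly constant so the downstream propagators
        and the stochastic simulator stay exact within segments.
        """
        starts: list[float] = []
        fluxes: list[float] = []
        segs = [(s, f) for s, f in self.segments if s < t_end]
        if not segs:
            raise ValueError("profile does not start before t_end")
        tau = self.shutoff_tail
        prev_flux = None
        for i, (s, f) in enumerate(segs):
            seg_end = segs[i + 1][0] if i + 1 < len(segs) else t_end
            if tau is not None and prev_flux is not None and f < prev_flux:
                # decaying step: sub-discretize the tail
                width = tau / 20.0
                n_sub = min(200, max(1, int(math.ceil(min(10.0 * tau, seg_end - s) / width))))
                for k in range(n_sub):
                    a = s + k * width
                    if a >= seg_end:
                        break
                    b = min(a + width, seg_end)
                    # mean of f + (prev-f)·exp(-(t-s)/τ) over [a, b]
                    ea = math.exp(-(a - s) / tau)
                    eb = math.exp(-(b - s) / tau)
                    mean = f + (prev_flux - f) * tau * (ea - eb) / (b - a)
                    starts.append(a)
                    fluxes.append(mean)
                tail_end = s + n_sub * width
                if tail_end < seg_end:
                    starts.append(tail_end)
                    fluxes.append(f)
            else:
                starts.append(s)
                fluxes.append(f)
            prev_flux = f
        return starts, fluxes

    def flux_at(self, t: float) -> float:
        """Instantaneous flux at time t (tail evaluated exactly)."""
        if t < self.start:
            return 0.0
        segs = self.segments
        idx = 0
        for i, (s, _) in enumerate(segs):
            if s <= t:
                idx = i
            else:
                break
        f = segs[idx][1]
        if self.shutoff_tail is not None and idx > 0:
            prev = segs[idx - 1][1]
            if prev > f:
                f = f + (prev - f) * math.exp(-(t - segs[idx][0]) / self.shutoff_tail)
        return f


# ---------------------------------------------------------------------------
# Parameter library
# ---------------------------------------------------------------------------

_ALIASES = {
    "ru": "[Ru(bpy)3]Br2",
    "ru(bpy)3": "[Ru(bpy)3]Br2",
    "[ru(bpy)3]br2": "[Ru(bpy)3]Br2",
    "eu": "Eu3+L2",
    "eu3+l2": "Eu3+L2",
    "fitc": "FITC",
    "egfp": "EGFP",
}


def _fluorophore_from_record(rec: dict) -> Fluorophore:
    return Fluorophore(
        name=str(rec["name"]),
        epsilon=float(rec["epsilon"]),
        quantum_yield=float(rec["quantum_yield"]),
        lifetime=float(rec["lifetime"]),
        bleach_rate=float(rec.get("bleach_rate", 0.0) or 0.0),
        excitation_wavelength=(
            float(rec["excitation_wavelength"])
            if rec.get("excitation_wavelength") not in (None, "")
            else None
        ),
        emission_wavelength=(
            float(rec["emission_wavelength"])
            if rec.get("emission_wavelength") not in (None, "")
            else None
        ),
    )


def builtin_fluorophores() -> dict[str, Fluorophore]:
    """The shipped four-fluorophore parameter library (FITC, [Ru(bpy)3]Br2,
    Eu3+L2, EGFP), keyed by name."""
    text = resources.files("fluorstat.data").joinpath("fluorophores.json").read_text()
    records = json.loads(text)
    return {rec["name"]: _fluorophore_from_record(rec) for rec in records}


def get_fluorophore(name: str) -> Fluorophore:
    """Look up a built-in fluorophore by name (short aliases accepted).

    Raises KeyError for unknown names.
    """
    lib = builtin_fluorophores()
    if name in lib:
        return lib[name]
    canonical = _ALIASES.get(name.lower())
    if canonical is not None and canonical in lib:
        return lib[canonical]
    raise KeyError(f"unknown fluorophore {name!r}; known: {sorted(lib)}")


def load_fluorophores(path: str | Path) -> dict[str, Fluorophore]:
    """Load user fluorophores from a JSON list or a CSV with the library's
    column names (name, epsilon, quantum_yield, lifetime, bleach_rate,
    excitation_wavelength, emission_wavelength)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records: Iterable[dict] = json.loads(path.read_text())
    elif path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            records = list(csv.DictReader(fh))
    else:
        raise ValueError(f"unsupported fluorophore file type: {path.suffix}")
    out = {}
    for rec in records:
        fl = _fluorophore_from_record(rec)
        out[fl.name] = fl
    return out
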