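"""Continuous-time Markov chain machinery for single-fluorophore state dynamics.

A single fluorophore hops between quantum states as a homogeneous CTMC with
generator Q, where Q[i, j] (i ≠ j) is the j→i flux rate and each column sums
to zero so that the pmf S(t) evolves by dS/dt = Q·S and S(t) = e^{Qt}·S(0)
conserves probability.  For N statistically independent fluorophores, the
occupancy count of any state is Binomial(N, S_state(t)).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from scipy.linalg import expm
from scipy.stats import binom

from .photophysics import RateSet

__all__ = [
    "GeneratorMatrix",
    "StatePMF",
    "build_generator",
    "evolve_pmf",
    "pmf_trajectory",
    "occupancy_distribution",
]

_PMF_TOL = 1e-12
_STANDARD_LABELS = ("ground", "excited", "bleached")


@dataclass(frozen=True)
class GeneratorMatrix:
    """CTMC generator with column-conservation convention dS/dt = Q·S."""

    Q: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        m = Q.shape[0]
        if Q.ndim != 2 or Q.shape != (m, m):
            raise ValueError("generator must be square")
        if len(self.labels) != m:
            raise ValueError("one label per state required")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal generator entries must be >= 0")
        scale = max(1.0, float(np.abs(Q).max()))
        if np.any(np.abs(Q.sum(axis=0)) > 1e-10 * scale):
            raise ValueError("generator columns must sum to zero")

    @property
    def size(self) -> int:
        return self.Q.shape[0]

    def index(self, state: str) -> int:
        try:
            return self.labels.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}; states: {self.labels}") from None


@dataclass(frozen=True)
class StatePMF:
    """Probability mass function over chain states at one time stamp."""

    probabilities: np.ndarray
    time: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or len(self.labels) != p.size:
            raise ValueError("pmf and labels must align")
        if np.any(p < -_PMF_TOL) or np.any(p > 1 + _PMF_TOL):
            raise ValueError("pmf entries must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"pmf must sum to 1, got {p.sum()!r}")

    def __getitem__(self, state: str) -> float:
        try:
            return float(self.probabilities[self.labels.index(state)])
        except ValueError:
            raise KeyError(f"unknown state {state!r}; states: {self.labels}") from None


def build_generator(rates: RateSet) -> GeneratorMatrix:
    """Three-state generator (ground, excited, bleached) from a rate set.

    Transitions: ground→excited at r_x, excited→ground at r_l = r_r+r_nr,
    excited→bleached at r_b; the bleached state is absorbing.
    """
    r_x, r_l, r_b = rates.r_x, rates.r_l, rates.r_b
    Q = np.array(
        [
            [-r_x, r_l, 0.0],
            [r_x, -(r_l + r_b), 0.0],
            [0.0, r_b, 0.0],
        ]
    )
    return GeneratorMatrix(Q=Q, labels=_STANDARD_LABELS)


def evolve_pmf(generator: GeneratorMatrix, pmf0: StatePMF | np.ndarray, t: float) -> StatePMF:
    """Advance a state pmf by t seconds: S(t) = e^{Qt}·S(0).

    Uses scipy's scaling-and-squaring Padé matrix exponential.  Tiny negative
    round-off (≤1e-12) is clipped; the result is renormalized to machine
    precision and returned as a valid pmf.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if isinstance(pmf0, StatePMF):
        if pmf0.labels != generator.labels:
            raise ValueError("pmf labels do not match generator labels")
        p0 = pmf0.probabilities
        t0 = pmf0.time
    else:
        p0 = np.asarray(pmf0, dtype=float)
        t0 = 0.0
    if p0.size != generator.size:
        raise ValueError("pmf length must match generator size")
    p = expm(generator.Q * t) @ p0
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return StatePMF(probabilities=p, time=t0 + t, labels=generator.labels)


def pmf_trajectory(
    segments: list[tuple[float, GeneratorMatrix]],
    pmf0: StatePMF | np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Piecewise-homogeneous pmf evolution.

    ``segments`` is a list of (duration, generator) applied in order starting
    at t = 0; ``times`` are absolute evaluation times within the covered
    horizon.  Returns an array of shape (len(times), m).  This is the
    composition rule for time-varying excitation: the chain is only
    homogeneous within segments, so the pmf is chained across them.
    """
    times = np.asarray(times, dtype=float)
    horizon = sum(d for d, _ in segments)
    if np.any(times < 0) or np.any(times > horizon + 1e-15):
        raise ValueError("evaluation times must lie within the segment horizon")
    if isinstance(pmf0, StatePMF):
        p = pmf0.probabilities.copy()
        labels = pmf0.labels
    else:
        p = np.asarray(pmf0, dtype=float).copy()
        labels = segments[0][1].labels
    out = np.empty((times.size, p.size))
    order = np.argsort(times)
    seg_start = 0.0
    k = 0
    for duration, gen in segments:
        if gen.labels != labels:
            raise ValueError("segment generators must share state labels")
        seg_end = seg_start + duration
        while k < times.size and times[order[k]] <= seg_end + 1e-15:
            tt = min(times[order[k]], seg_end)
            out[order[k]] = evolve_pmf(gen, p, max(0.0, tt - seg_start)).probabilities
            k += 1
        p = evolve_pmf(gen, p, duration).probabilities
        seg_start = seg_end
    while k < times.size:  # times equal to horizon within tolerance
        out[order[k]] = p
        k += 1
    return out


def occupancy_distribution(n_total: int, pmf: StatePMF, state: str) -> np.ndarray:
    """Pmf over the occupancy count 0..N of ``state`` for N independent
    fluorophores: Binomial(N, S_state(t))."""
    if n_total < 1 or int(n_total) != n_total:
        raise ValueError("n_total must be an integer >= 1")
    p = pmf[state]  # KeyError for unknown labels
    counts = np.arange(n_total + 1)
    return binom.pmf(counts, n_total, p)
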