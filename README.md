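# fluorstat

Ensemble and stochastic modeling of fluorescence signal generation for
optical biosensor design: expected-value photon budgets, photon-counting
statistics, power spectral densities, exact stochastic simulation, and
CW/time-gated signal-to-noise and detection-limit calculators.

## Who this is for

Designers of fluorescence detection systems — microarray imagers, qPCR
readers, point-of-care sensors — who need to predict, before building
hardware, how many photons a labeled spot will deliver, how noisy that
signal intrinsically is, and how many fluorophores a given imager and
filter stack can resolve.

## The model

A fluorophore cycles between ground, excited, and (irreversibly) bleached
states with rates

- `r_x = k_x·F_x·σ` — excitation, with `σ = ln(10)·10³·ε/N_A` the absorption
  cross-section from the decadic molar extinction coefficient ε,
- `r_r = Φ/τ_l`, `r_nr = (1−Φ)/τ_l` — radiative/non-radiative relaxation
  from quantum yield Φ and lifetime τ_l (`r_l = r_r + r_nr = 1/τ_l`),
- `r_b` — photobleaching.

Three complementary pictures are implemented and cross-validated:

1. **Ensemble rate equations** (`fluorstat.ensemble`) for the expected state
   occupancies of N fluorophores, with closed forms for steady state
   (`n̄_e = N·r_x/(r_x + τ_l⁻¹)`), the emission rise time
   (`τ_ph = 1/(r_x + τ_l⁻¹)`), and photon budgets under continuous-wave
   (`n_ph = F_ph·(T_int − τ_ph)`) and time-gated
   (`n_ph = K·F_ph·τ_l·e^{−ΔT_D/τ_l}(1 − e^{−T_int/τ_l})`) readout.
2. **Single-molecule statistics** (`fluorstat.markov`, `fluorstat.counting`):
   a continuous-time Markov chain whose photon inter-arrival times are
   hypoexponential with eigenrates `λ₁,λ₂ = (r_x+r_l ± γ)/2`,
   `γ² = (r_x+r_l)² − 4Φr_x r_l`.  CW counts obey
   `⟨F_ph⟩ = λ₁λ₂/(λ₁+λ₂)` and `σ²_F = λ₁λ₂(λ₁²+λ₂²)/(λ₁+λ₂)³`, a strictly
   **sub-Poisson** process (Fano `(λ₁²+λ₂²)/(λ₁+λ₂)² < 1`); the one-sided
   PSD runs from plateau `2σ²_F` up to `2⟨F_ph⟩` across
   `f_c = (λ₁+λ₂)/2π`.  Time-gated counts follow the Burgess variance
   theorem for Bernoulli-thinned Bernoulli occupancies.
3. **Exact stochastic simulation** (`fluorstat.gillespie`): a direct-method
   Gillespie sampler of the four-reaction network with photon-event logging,
   used to verify every analytic result (trajectories, count moments,
   occupancy histograms, empirical periodograms).

On top sit detector-level calculators (`fluorstat.detection`) — quantum-
limited SNR `10·log₁₀(G·(⟨n_p⟩γη)²/(σ²_np·γη))`, CW/TG SNR with filter
optical density, read noise and dark current, minimum detection limits — and
hairpin-quencher binding modulation of the PSD (`fluorstat.binding`).

## Worked example

```python
import numpy as np
from fluorstat import counting, ensemble
from fluorstat.photophysics import get_fluorophore, excitation_rate

ru = get_fluorophore("Ru")                   # [Ru(bpy)3]Br2: Φ=0.063, τ_l=840 ns
r_x = excitation_rate(1.28e21, ru)           # photons/s/cm² → 5.92e4 s⁻¹

n_g, n_e = ensemble.steady_state_occupancy(r_x, ru.lifetime, 1e5)
flux = ensemble.emission_flux(ru, n_e)       # photons/s from the 10⁻⁴ cm² spot
tau_ph = ensemble.rise_time_constant(r_x, ru.lifetime)
print(f"n_e = {n_e:.0f}, tau_ph = {tau_ph*1e9:.1f} ns")
print(f"CW 20 µs: {ensemble.photons_cw(flux, 20e-6, tau_ph):.0f} photons")
print(f"TG 10x:   {ensemble.photons_tg(10, flux, ru.lifetime, 250e-9, 4.75e-6):.0f} photons")

model = counting.eigenrates(r_x, ru.relaxation_rate, ru.quantum_yield)
print(f"Fano = {counting.cw_flux_stats(model).fano:.4f}  (sub-Poisson)")
```

prints

```
n_e = 4739, tau_ph = 800.2 ns
CW 20 µs: 6824 photons
TG 10x:   2209 photons
Fano = 0.9943  (sub-Poisson)
```

i.e. at this operating point ~4.7% of the population is excited, the
emission settles within ~4 µs, a 20 µs CW window collects ~6.8k photons
versus ~2.2k for ten gated shots, and the photon stream is measurably more
regular than Poisson.

The same computations are scriptable from the shell:

```bash
fluorstat benchmark                       # full closed-form benchmark table
fluorstat psd --fluorophore Ru --flux 1.28e21
fluorstat snr --mode cw --fluorophore Ru --flux 1.28e21 --t-int 2e-5 --od 6
fluorstat simulate-ssa --fluorophore Ru --flux 1.28e21 --n 100 \
    --t-off 3e-5 --t-end 3.6e-5 --trials 10 --seed 42
```

## Documentation

See `docs/methods.md` for the modeling assumptions, parameter conventions,
numerical choices, and known limitations.
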