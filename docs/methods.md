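# Methods

## Scope and state space

The package models an ensemble of N identical, statistically independent
fluorophores, each occupying one of three states — ground, excited,
bleached — with memoryless transitions: excitation at `r_x`, relaxation at
`r_l = r_r + r_nr` (a fraction Φ = r_r/r_l of relaxations emits a photon),
and irreversible bleaching at `r_b`.  Triplet/phosphorescence pathways,
FRET, and collisional quenching are not modeled separately; their net
effect is assumed to be absorbed into the non-radiative rate.  There is no
spatial or spectral structure: wavelengths are stored as labels, fluxes are
scalars per cm².

## Parameter conventions

| symbol | meaning | units | default / source |
|---|---|---|---|
| ε(λ_x) | decadic molar extinction coefficient | M⁻¹cm⁻¹ | library file |
| Φ | quantum yield | – | library file |
| τ_l | fluorescence lifetime | s | library file |
| r_b | bleach rate | s⁻¹ | 0 |
| F_x | excitation photon flux | photons·s⁻¹·cm⁻² | operating point |
| k_x | dipole coupling | – | 1 |
| T_int | integration window | s | protocol |
| ΔT_D | gate delay after shutoff | s | protocol |
| K | accumulated gated shots | – | protocol |
| τ_s | excitation source decay constant | s | 50 ns imager preset |

**Cross-section conversion.** `σ = ln(10)·10³·ε/N_A` (cm²), with
N_A = 6.02214076×10²³ mol⁻¹ exactly.  The ln(10) factor converts the
base-10 absorbance convention of ε to a natural (e-folding) cross-section.
The shipped benchmark table is reproduced within 1% only with this factor
included, which fixes the convention; a "1000/N_A" conversion without ln 10
under-predicts every benchmark excitation rate by ~2.3×.

**Shipped data.** Four fluorophores (FITC, [Ru(bpy)3]Br2, Eu3+L2, EGFP)
with their published ε, Φ, τ_l, wavelengths; one imager preset (100 pixels,
1% coupling, 45% QE, 2 e⁻ read noise, 5 e⁻/s dark current, 50 ns source
tail); two hairpin kinetic presets (22-nt ssDNA at 10 °C and 50 °C).

**Known data inconsistencies.** Two reference cells of the shipped
benchmark are internally inconsistent and are flagged rather than silently
"fixed": (i) the Eu3+L2 reference emission flux (1.34×10¹⁰ cm⁻²s⁻¹) is
~22% above the value its own Φ, τ_l and occupancy imply, although the Eu
CW/TG photon references are consistent with that flux — the Eu flux-derived
cells carry `excluded=True` in `benchmark.run_benchmark()`; (ii) the EGFP
reference excitation rate (1.76×10⁷ s⁻¹) is 1.3% below the value implied by
its own flux and ε under the conversion that reproduces the other three
fluorophores to <1%, while every downstream EGFP reference value matches
the *recomputed* rate to <0.3% — indicating the reference r_x, not the
chain, is the outlier.

## Ensemble model

The expected occupancies obey a linear system (per N fluorophores):
`ṅ_g = r_l n_e − r_x n_g`, `ṅ_e = r_x n_g − (r_l+r_b) n_e`,
`ṅ_b = r_b n_e`, plus the photon tally `ṅ_ph = r_r n_e`.  Excitation
profiles are piecewise constant (an exponential shutoff tail is discretized
into τ_s/20 sub-segments out to 10 τ_s, each carrying its exact mean flux),
so the system is linear time-invariant within every segment and
trajectories are propagated with per-segment matrix exponentials.  This is
exact to expm round-off — no step-size tolerance exists to tune — and was
chosen over an implicit ODE stepper because the rate magnitudes span nine
decades across the library, which is hostile to any fixed accuracy budget.

The photon tally uses the operative emission rate `r_r·n_e` in all cases.
With bleaching the cumulative-photon prefactor admits an alternative
algebraic form (a multiplicative `r_l/(r_l+r_b)` correction); the two
agree identically for `r_b = 0`, and the rate-equation form is kept as
primary because it is what the stochastic simulator realizes reaction by
reaction.

Closed forms (bleach-free): steady state `n̄_e = N r_x/(r_x+τ_l⁻¹)`; rise
time `τ_ph = 1/(r_x+τ_l⁻¹)`; CW budget `F_ph(T_int − τ_ph)`, valid for
T_int ≫ τ_ph and rejected outright for T_int ≤ τ_ph; TG budget
`K F_ph τ_l e^{−ΔT_D/τ_l}(1−e^{−T_int/τ_l})` with the gate spanning
[ΔT_D, ΔT_D+T_int] after shutoff.  TG assumes steady state before each
shutoff; a pulse of ~5 τ_ph is enough in practice (residual < 1%).

## Markov-chain machinery

The single-fluorophore pmf evolves by `dS/dt = Q·S` with the column
conservation convention `Q[i,j] = r_{j→i}` (i≠j), columns summing to zero.
This orientation is the unique one that conserves probability for the
published transition structure and reproduces the stochastic-simulation
trajectories; transposed presentations of the same generator are treated
as notational variants.  `S(t) = e^{Qt}S(0)` is evaluated with scipy's
scaling-and-squaring Padé `expm`; results are clipped at −0 and
renormalized (drift < 1e-12).  Generators of any size m are supported
(property-tested to m = 6), but only the 3-state chain is wired to the rest
of the toolkit.  Time-varying excitation breaks homogeneity, so pmfs are
chained across piecewise-constant segments (`pmf_trajectory`).  For N
independent fluorophores the occupancy count of a state is exactly
Binomial(N, S_state(t)).

## Counting statistics

One excitation-relaxation cycle is a sum of two exponential sojourns;
thinning by the emission probability Φ leaves photon inter-arrivals
hypoexponential with eigenrates λ₁ ≥ λ₂, λ₁+λ₂ = r_x+r_l,
λ₁λ₂ = Φ r_x r_l.  The smaller eigenrate is computed from the product
identity (`λ₂ = Φ r_x r_l/λ₁`) to avoid catastrophic cancellation when the
rates are far apart; the equal-rate degenerate case falls back to the
Erlang-2 density.  CW count moments are renewal-asymptotic: a warning is
emitted when T_int < 10·(1/λ₁+1/λ₂).  The Fano factor
`(λ₁²+λ₂²)/(λ₁+λ₂)²` is < 1 strictly (sub-Poisson) and → 1 only when one
rate dominates.

The one-sided PSD of the emission pulse train is
`S(ω) = 2πF̄²δ(ω) + 2σ²_F (1+ω²/(λ₁²+λ₂²))/(1+ω²/(λ₁+λ₂)²)`; the DC
impulse weight is reported as a scalar separate from the continuous part
(a numeric grid cannot represent a delta).  The plateau ratio equals the
inverse Fano factor exactly.

Time-gated: given one excited fluorophore at shutoff, the gate captures a
photon with `p = Φ(e^{−ΔT_D/τ_l} − e^{−(T_int+ΔT_D)/τ_l})`; the occupancy
at shutoff is Bernoulli(⟨n_e⟩ = r_x/(r_x+r_l)).  Burgess variance
propagation through the two Bernoulli stages gives per-shot variance
`p²σ²_ne + ⟨n_e⟩p(1−p)`, which collapses to the Bernoulli(p⟨n_e⟩)
variance — an identity the test suite checks to machine precision.

Bleaching has no closed-form counting statistics here; with `r_b > 0` the
stochastic simulator is the only statistical surface.

## Stochastic simulator

Direct-method Gillespie (two uniforms per event — the reaction network has
only four channels, so the next-reaction method buys nothing).  Piecewise-
constant excitation is handled by drawing the waiting time within the
current segment and, on overshoot, advancing to the boundary and redrawing;
this is exact because exponential waiting times are memoryless.  How pulse
edges are treated is a free implementation choice; this scheme was chosen
and validated against the rate-equation mean.

Reproducibility: trial i of a run seeded s consumes an independent uniform
stream from `PCG64(SeedSequence([s, i]))`.  The inner loop is written
against flat arrays and scalars and is JIT-compiled with numba when
available; the pure-NumPy fallback consumes the identical uniform stream,
so results are bit-identical with or without acceleration.

Bulk count statistics (`steady_state_window_counts`) stream photon tallies
into periodic windows without storing events, in constant memory: each
trial starts from a draw of the stationary excited-state binomial, burns in
10 rise times, and windows are separated by a 5 τ_ph guard gap to
decorrelate consecutive counts.

The empirical PSD is the trial-averaged periodogram of binned photon
counts, `2|FFT(c−c̄)|²/T`, DC excluded.  Binning time-quantizes arrivals,
which sinc²-filters and aliases the *correlated* part of the spectrum but
leaves the flat shot-noise floor 2ν untouched; the default estimator
inverts the dominant distortion using the observed mean rate, and the raw
estimator is available for exact comparisons against the alias-folded
analytic spectrum.

## Detection calculators

`QSNR = 10 log₁₀(G(⟨n_p⟩γ_eη_e)²/(σ²_np γ_eη_e))` with G pixels and
emission-path coupling×QE `γ_eη_e`.  Extrinsic noise enters as
`SNR = QSNR − 10 log₁₀(1 + (background + σ_r² + βT_int)/(σ²_np γ_eη_e))`;
the sign convention is fixed so extrinsic terms can only subtract
(SNR ≤ QSNR always, a tested invariant).  The CW background is the
excitation flux at the detector plane attenuated by the emission filter,
`10^{−d}·⟨F_x⟩·T_int·γ_xη_x`, with the optical density d interpreted as the
standard log₁₀ rejection (10^d linear) — the only reading under which the
documented OD 4–8 design space behaves sensibly.  The TG background is the
source's exponential shutoff tail integrated over the K gates,
`K τ_s 10^{−d} ⟨F_x⟩ e^{−ΔT_D/τ_s}(1−e^{−T_int/τ_s}) γ_xη_x`.  Excitation-
path conversion uses γ_x·η_x at the excitation wavelength.  Well capacity
is validated (a saturation warning when signal electrons per pixel exceed
W) but enters no SNR formula.

The minimum detection limit is the smallest N with SNR ≥ 0 dB; since both
⟨n_p⟩ and σ²_np scale linearly in N, SNR is monotone in N and the
continuous root is bisected (brentq on log N) and rounded up.

Spot scaling: imaging a surface at isomorphic scaling ratio α leaves each
spot `T_C·α/2` of dwell time (taken at face value as a multiplicative
factor; whether α is a linear or area ratio is left to the caller's
convention), so the sweep reports QSNR versus (α, N) at fixed total
acquisition time.

## Binding modulation

Hairpin-quencher exchange is a two-state process with relaxation rate
`k_on+k_off`, equilibrium open fraction `k_off/(k_on+k_off)`, and a
Lorentzian fluctuation spectrum with 3 dB corner `(k_on+k_off)/2π`.  The
primary ("kinetic") spectrum form carries DC weight
`4π(k_on k_off/(k_on+k_off))²` and Lorentzian peak `4k_on k_off/(k_on+k_off)²`;
its dimensional normalization is not that of a textbook telegraph process,
so a clearly-labelled alternative `mode="telegraph"` (variance q(1−q)) is
provided for users needing a per-molecule occupancy spectrum.  Quenching is
treated as a linear modulation (static quenching only; dynamic quenching is
out of scope), so the modulated emission spectrum is the pointwise product
`M(ω) = N·S(ω)·B(ω)` with DC impulse weights multiplying as scalars; N is
the strand count, one fluorophore per strand.

## Validation strategy and what it does (not) show

Every analytic layer is checked against an independent route:

- closed forms against the shipped benchmark table (FITC/Ru/EGFP cells to
  1%; the two flagged inconsistent references excluded as above);
- the hypoexponential inter-arrival law against a brute-force geometric
  mixture of numerically self-convolved cycle densities (1e-6 pointwise on
  a 2¹⁷-sample grid);
- renewal variance and Burgess variance against closed-form moment
  identities at machine precision;
- SSA trajectories, CW/TG count moments, occupancy histograms (TV < 0.05
  against the binomial law, 10,000 trials), and periodogram plateaus
  against the Markov predictions at 3-standard-error tolerance;
- the sub-Poisson claim via a one-sided 3σ test of `s² − x̄ < 0` over ~1.6
  million steady-state CW windows (2,000 trials × 800 windows) — the
  per-window Fano deficit at the ruthenium benchmark is only ≈0.6%, so a
  smaller sample cannot resolve it.

Validation sample sizes (2,000 trial ensembles, 10,000-trial histograms,
40-trial periodograms) were sized so each statistical check has ≥3σ
expected resolving power for the effect it tests.

These checks validate the *internal consistency* of the three pictures and
the correctness of the implementation.  They do not validate the physics
against real instruments: real fluorophores show triplet blinking, spectral
crosstalk, and excitation-source noise (all out of scope), and real
extinction/yield/lifetime values carry measurement uncertainty far above
the numerical tolerances here.

## Known limitations

- No triplet states, FRET, collisional or dynamic quenching, diffusion, or
  photon antibunching/g²(τ) beyond the PSD.
- CW/TG count statistics assume negligible bleaching; with `r_b > 0` only
  the ensemble means and the stochastic simulator apply.
- The renewal count formulas are asymptotic in T_int (warned below
  10 mean inter-arrivals).
- Excitation-source intensity noise is not propagated into the emission
  statistics.
- The spot-scaling dwell-time rule and the kinetic binding-spectrum
  normalization are implemented as published conventions, with their
  ambiguities documented above rather than resolved.
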