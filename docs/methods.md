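# Methods

## State space and generators

The density operator of n spins-1/2 is expanded in the orthonormal
product-operator basis built from E/√2, √2·Iz, I₊ and I₋ per spin, so a state
is a complex coefficient vector of length 4ⁿ and Hermiticity is the condition
c(adjoint term) = conj(c(term)).  The coherent generator is −i[H,·] with the
isotropic-coupling Hamiltonian

    H = Σᵢ 2πνᵢ Iᵢz + Σᵢ<ⱼ 2πJᵢⱼ (IᵢxIⱼx + IᵢyIⱼy + IᵢzIⱼz).

The **full (non-secular) coupling term is mandatory**: the quenching of J
modulation by rapid refocusing works precisely because the refocused spins
become effectively strongly coupled, which a secular ZZ truncation cannot
express.

Relaxation is the phenomenological **T1T2 model**: a superoperator diagonal in
the product basis, each term decaying at the sum over spins of 0 (unit part),
R1ᵢ (z part) or R2ᵢ (transverse part), plus a drive returning single-spin z
terms to equilibrium.  Because the equilibrium state (total z) commutes with
H, the drive is applied exactly by the affine fixed-point form of `evolve`,
c(t) = c_eq + exp(Gt)(c₀ − c_eq).  This is the minimal model that reproduces
every benchmark phenomenon — including scalar relaxation of a spin by its
partner's T1, which *emerges* from the coupling between in-phase and
antiphase coherences rather than being coded anywhere.  (When a
time-dependent RF term is present, equilibrium is no longer a fixed point
and the shaped-pulse path uses an augmented-matrix exponential for the
inhomogeneous system instead.)

Cross-correlated relaxation, dipolar cross-relaxation and Redfield theory are
deliberately outside the engine; a longitudinal cross-relaxation rate exists
only in the analytic two-site recovery model, where it is needed to express a
known bias mechanism.

Practical size limit: the Liouville dimension is 4ⁿ and generators are dense,
so explicit simulation is capped at n = 6 spins (equivalent groups enter the
analytic scalar-rate formulas through a multiplicity count instead).

## Pulses, gradients, detection

Rotations are right-handed with 90°(x): Iz → −Iy; hard pulses are
instantaneous.  A selective pulse in **ideal mode** is an instantaneous
rotation of the target spins followed by relaxation-only evolution for the
pulse duration: in a selective echo the coherent shift/J evolution during the
pulse is refocused by construction, while relaxation is not, and an ~18.5 ms
element is not negligible against T2 ~ 0.2 s.  **Shaped mode** propagates a
user-supplied amplitude/phase waveform (applied at the target spins' mean
offset) piecewise-constantly through the full generator; no specific
published pulse shape is bundled, and the test suite uses ideal mode plus a
rectangular stand-in.

Field gradients act as ideal coherence-pathway filters: a purge zeros every
basis term with transverse character on a non-survivor spin (or non-observed
exchange site), keeping longitudinal/unit terms.  A test verifies that
purge–selective-180–purge equals the explicit average over 64 uniformly
spaced gradient phases of gradient–pulse–gradient.  Spatial (slice-selection)
physics is out of scope.

Detection returns Σᵢ⟨Iᵢ₋⟩ over observed spins — the integral-equivalent
in-phase signal, to which antiphase terms contribute zero, matching
peak-amplitude fitting of resolved resonances.  Spectra are acquired by
stepping the full generator at the dwell time (power-of-two point counts,
aliasing guard at max|shift| + 5·J), zero-filling ×4, and zero-order phasing
on the **total integral** (the first FID point).  Phasing on the tallest peak
is avoided deliberately: relaxation-coupled multiplet components are slightly
phase-twisted, and peak-top phasing propagates one component's twist to the
whole spectrum.  For the same reason the benchmark linewidth checks average
the two components of each doublet, whose twists are antisymmetric.
Linewidths are full widths at half height by linear interpolation.

## Sequences and time bookkeeping

* CPMG: 90x − [τ − 180y − τ]ⁿ, encoding time n·2τ; PROJECT:
  90x − [τ − 180y − τ − 90y − τ − 180y − τ]ⁿ, encoding time n·4τ.  Refocusing
  phase is y (the Meiboom–Gill choice).
* TRUE: 90x − [τₑ − purge − selective 180(observed) − purge − τₑ]ⁿ.  Two
  schedulings are provided.  With **variable τₑ at fixed n** (the default,
  n = 1) the time axis is the transverse delay time 2nτₑ; the selective
  element is then a constant overhead whose attenuation is absorbed by the
  fitted amplitude, which is what lets encoding times shorter than the pulse
  itself (6.4 ms against an 18.5 ms element) sit on the same exponential.
  With **variable n at fixed τₑ** the per-loop overhead scales with the
  point, so the axis counts n·(2τₑ + t_sel).  The two schedulings agree
  exactly at J = 0 and to ≲0.1 % for the benchmark's spin A; for spin X they
  differ by ~1.6 % because J·T1(partner) = 2 sits at the edge of the
  J·T1 ≫ 1 validity condition of the exponential-decay description, and
  partner flips *during* a long selective pulse scramble refocusing in a
  loop-count-dependent way.
* Inversion recovery: hard or ideal-selective 180 − delay − longitudinal
  readout per site.

## Fitting conventions

Decay fitting is weighted least squares of A₀·exp(−Rt).  Per-point sigmas,
when present, are used as absolute uncertainties.  For noiseless simulated
decays the benchmark study uses **relative weighting** (σ ∝ |amplitude| with
a 5 % floor): the only residual source there is multiplicative (residual
coupling modulation and mixing), for which proportional errors are the
correct model; log-space fitting is rejected because noisy late points can be
non-positive.  The default for user data remains uniform weights.  A
Wald–Wolfowitz runs test on the ordered residuals (two-sided, normal
approximation, α = 0.01, needing ≥ 8 points for power) sets the
`modulation_flag` that marks systematic J-modulation structure.

`modulation_depth` measures nonexponentiality as max|residual|/max|amplitude|
against a lenient best-fit exponential, or — for echo-scale oscillation
specifically — against a Savitzky–Golay smooth on a fine echo grid.  J
modulation is periodic in echo number, so the TRUE no-modulation check runs
in the constant-echo-unit scheduling, with the nonselective Hahn echo on the
same time grid as the fully modulated yardstick.

Exchange extraction is k = R2(echo) − R2⁰ − Σ nᵢ/(2T1ᵢ) − (optional extra
rate), with quadrature error propagation and a consistency flag when
k < −3·SE.  R2⁰ comes from T1 in extreme narrowing or from a CPMG-apparent
rate outside it; the choice is recorded on the result.  "Resolved coupling"
is an input flag, never inferred from a spectrum.

## Two-site exchange models

The bandshape is the closed-form steady-state solution
I(ν) = Re[1ᵀ(R + K − i2π(ν−N))⁻¹ p] with hop rates k_ab = 2p_b·k,
k_ba = 2p_a·k (detailed balance; both reduce to k at equal populations, and k
is the rate constant of the site-interconversion process in the matrix
[[−k, k], [k, −k]]).  Instrumental broadening is Lorentzian, entering as
π·l_inst on the diagonal; Gaussian inhomogeneity is out of scope.  Its exact
value being unknowable, `fit_bandshape` pins l_inst at a user-supplied lower
and upper bound and reports the [k_low, k_high] interval as the uncertainty —
k_high from the lower bound (all unexplained broadening attributed to
exchange).  Conservation (integral independent of k to numerical precision)
and site-relabelling symmetry are property-tested; the classic equal-
population coalescence estimate k = πΔν/√2 is verified by bracketing the
two-maxima → one-maximum transition.

Selective inversion recovery uses the exact eigendecomposition of the
symmetric 2×2 matrix A = [[R1a + k, σ − k], [σ − k, R1b + k]] acting on the
deviation from equilibrium; the initial condition is −2·η·M_eq on the
inverted site (η the inversion efficiency).  The joint fit over both
inversion experiments (all four trajectories) estimates k, both R1s,
equilibrium amplitudes and per-experiment η; a single experiment is rejected
unless the R1s are fixed, because k and R1 trade off.  σ is fixed at zero by
default and fittable on request; its sign is unconstrained (either sign
produces a spectator transient — below equilibrium for σ < 0, the
negative-NOE regime).  When data contain cross-relaxation but σ is fixed to
zero, the fitted rate aliases to k − σ with small statistical error: the
mechanism by which unmodelled through-space transfer biases low-temperature
selective-inversion rates.

Arrhenius analysis is weighted linear regression of ln k on 1/T with weights
from δ(ln k) = k_se/k (unit weights and residual-scaled covariance when no
uncertainties are stated); Ea = −slope·R with R = 8.314 J mol⁻¹ K⁻¹.
Exclusion flags on individual records are honoured but the records are kept
for plotting.

## Synthetic data and what passing tests show

The fixture generator emulates the benchmark study conditions: AX system with
a 500 Hz shift difference, T1 = 0.2/0.8 s, T2 = T1, J ∈ {0, 10} Hz, CPMG
τ = 200 µs, PROJECT τ = 800 µs, an 18.5 ms selective element, and encoding
times 6.4, 12.8, …, 819.2 ms.  The exchanging-doublet fixture uses Δν = 60 Hz
and R2 = 2 s⁻¹ at both sites with hop rates {1, 3, 10} s⁻¹ — safely in slow
exchange (k ≪ 2πΔν) where the echo-rate decomposition holds.  The recovery
fixture uses R1 = 0.8/1.2 s⁻¹, k ladder {0.5, 1.5, 5} s⁻¹, η = 0.95, ten
delays spanning 20 ms–4 s; the Arrhenius fixture generates rates from
Ea = 78.3 kJ/mol, ln A = 32 over 298–358 K, spanning ~1.5–300 s⁻¹, the range
over which selective-inversion, echo and bandshape methods hand over to one
another.  Gaussian noise (fraction of the initial amplitude) and seeds are
explicit; streams are spawned per file from one SeedSequence so outputs are
byte-reproducible.

Synthetic data contain none of the things that make real measurements hard:
no field or B1 inhomogeneity, no phase cycling artefacts, no baseline or
overlap problems, no temperature instability, and ideal (or stand-in) pulse
shapes.  Passing tests therefore demonstrate the correctness of the
propagation, models and estimators under the stated physics — not robustness
to instrumental imperfection.

## Known limitations

* The relaxation model is phenomenological; there is no spectral-density
  machinery, radiation damping, or spatial encoding.
* The experimentally observed excess of CPMG residual modulation over
  PROJECT arises from B1 inhomogeneity and wide shift ranges and is **not**
  reproduced by ideal-pulse simulation, where CPMG sampled at echo tops is
  extremely smooth; the tests assert PROJECT's echo-scale oscillation bound
  and the measurable nonexponentiality of both multi-echo methods instead.
* The exponential description of the selective-echo decay assumes
  J·T1(partner) ≫ 1; the benchmark's spin X (J·T1 = 2) shows percent-level
  scheduling sensitivity, correctly reproduced by the simulator.
* Two-site mutual exchange only; unequal populations are supported in the
  bandshape but not in the recovery model or the engine's kinetic coupling.
* Bandshape fitting assumes known site frequencies, populations and intrinsic
  R2s, fitting only the rate and an amplitude at each instrumental bound.
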