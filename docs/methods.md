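# Methods

## Model

Six phase oscillators, one per leg, coupled through an endogenous wiring
diagram `A` and a trio-averaging sensory feedback `C`:

    dφₙ/dt = Γ Σₘ Aₙₘ H(φₘ − φₙ) + k·H(fₙ(φ) − φₙ) + ν(t),
    fₙ(φ) = Σₘ Cₙₘ φₘ,    ν(t) ~ N(0, σ²).

The phase reduction assumes each leg's CPG is an autonomous oscillator whose
interactions depend only on phase differences; amplitude dynamics, joint
biomechanics, and descending control are outside the model.  Gait-level
quantities are therefore invariant under a global phase shift and under 2π
wraps, and the model cannot distinguish synchronous oscillation from rest
("idling").

### Leg indexing

Legs are numbered 1 = right pro, 2 = left pro, 3 = left meso, 4 = right
meso, 5 = right meta, 6 = left meta.  This is the labeling in which the two
anatomically valid tripods are the odd legs {1,3,5} and the even legs
{2,4,6}, the double-tripod pattern is (0,π,0,π,0,π), and the left-right
mirror is the within-segment swap 1↔2, 3↔4, 5↔6.

### Connectivity

`A` carries 14 directed links — contralateral pairs in each segment (l₁, l₂,
l₃, both directions) plus descending (b₁: pro→meso, b₂: meso→meta) and
ascending (f₁: meso→pro, f₂: meta→meso) ipsilateral links on both sides.
Under left-right symmetry this is the unique placement of 7 parameters on 14
links in which **every link joins the two trios**.  That bipartite structure
is load-bearing: together with unit row sums it makes the alternating vector
v₆ = (1,−1,1,−1,1,−1)/√6 an exact eigenvector of A with eigenvalue −1, which
is what pins the gait eigenvalues −2ΓH′(0) (idling) and −2ΓH′(π)
(double-tripod) exactly rather than approximately.

Default weights: l₁ = 0.5, f₁ = 0.5, b₁ = 0.3, l₂ = 0.4, f₂ = 0.3, b₂ = 1.5,
l₃ = −0.5.  These are **constrained surrogates**, not measured values: they
satisfy the sign constraints (l₃ < 0 metathoracic anti-phase preference;
l₁, l₂ > 0), row normalization (l₁+f₁ = b₁+l₂+f₂ = b₂+l₃ = 1), and — checked
numerically — a non-positive idling spectrum with a simple zero mode.  All
seven weights are overridable via config or the `ConnectivityParams` type.
Row normalization itself is a modeling choice; it is what makes the spectral
identities exact, and `validate_connectivity` treats it as an invariant.

### Feedback

`C` mixes each leg's phase with its own trio only (Cₙₘ = 0 across trios,
rows sum to 1).  The default is the uniform average 1/3 including self,
the simplest member of the family, and an exact projector: C² = C, and
(C − I) annihilates both v₅ (uniform) and v₆ (alternating).  The latter is
why the tripod's unstable eigenvalue is independent of k.  fₙ is a *linear*
form in the unwrapped phases, not a circular mean; trajectories are
integrated on the real-line lift so no wrap discontinuities arise.  Only the
own-trio ("positive") feedback variant is implemented; a counter-tripod
variant would mirror the opposite trio instead.

### Coupling function

Any 2π-periodic H with H(0) = H(π) = 0 and H′(π) < 0 < H′(0) is accepted via
`register_coupling`, which validates these constraints at registration.  The
default is H = sin, the minimal compliant choice (H′(0) = 1, H′(π) = −1).
All analytic results are expressed in units of H′(0) and H′(π), so any
compliant H can be substituted.

## Stability analysis

Jacobians at the two gaits have closed forms (`jacobian_idle`,
`jacobian_tripod`); `jacobian_general` evaluates the drift Jacobian at any
state and agrees with them at the gaits to machine precision (tested).  `A`
is non-symmetric, so `classify_stability` computes right *and* left
eigenvectors and biorthonormalizes them (LᴴR = I), falling back to
pseudo-inverse left vectors near degeneracies.  Eigenvalues with
|Re λ| < 10⁻⁹·‖J‖ are treated as structural zeros; "stable" requires a
simple zero mode and all other real parts strictly negative.

Without feedback, J^Tri = [H′(π)/H′(0)]·J^Idl exactly, so the spectra map
into each other by a negative factor: stability of idling and of the
double-tripod are mutually exclusive.  `exclusivity_check` verifies both the
elementwise eigenvalue mapping and the sign-flip equivalence, and holds on
random row-normalized sign-compliant connectivities (property-tested).

## Perturbation theory and the bout lifetime

A perturbation of the double-tripod is expanded in the eigenbasis of J^Tri.
Because the basis is oblique (non-normal J), two per-mode quantities differ
and the package keeps both:

- **expansion coefficients** Bᵢ (left-eigenvector projections) — exact for
  propagation: Σ Bᵢ vᵢ exp(λᵢt) equals the matrix-exponential solution;
- **mode amplitudes** bᵢ = v̂ᵢᴴδφ(0) against unit-norm right eigenvectors —
  the quantity for which the noise-scaling identity E[Σ bᵢ²] = 6σ² holds
  exactly for i.i.d. N(0, σ²) components, irrespective of basis angles.
  (For the oblique coefficients the same expectation is σ²·tr(LᴴL), which
  exceeds 6σ² by the basis conditioning — a property of the geometry, not of
  the noise.)

The uniform-mode coefficient is zeroed (a global phase shift carries no gait
information).  With k ≳ Γ the remaining four modes decay on the fast scale
τ₀ ~ 1/k and the alternating mode grows on τ₆ = −1/(2ΓH′(π)), giving the
first-order plateau profile ξ_Tri ≈ 1, ξ_Idl ≈ (σ/√6)·e^{t/τ₆} — the √6
comes from the normalization of v₆ together with B₆ ≈ σ — valid while
σ·e^{t/τ₆} ≪ 1 (flagged at 0.5), and the lifetime τ = −τ₆ ln σ.  These are
leading-order escape-time estimates; simulated mean half-lives agree within
a factor of two, and their Γ⁻¹ and ln σ scalings hold quantitatively
(tested).

## Simulation

Euler–Maruyama with per-step increment σ√dt·z (the white-noise reading,
which makes results dt-independent; a per-step-σ legacy reading sits behind
`noise_per_step=True`).  Defaults dt = 0.01, horizon T_max = 50, in the
model's dimensionless time.  Mode `initial_kick` perturbs the initial state
once by N(0, σ²) and integrates deterministically — the single-perturbation
protocol of the linear theory.

Bouts start at the **exact** double-tripod pattern; under white noise the
noise itself supplies the escape perturbation.  A bout has terminated once
ξ_Tri stays below 0.05 for one time unit; bouts that have not terminated by
T_max are labeled `censored` and excluded from fractions (with counts
reported), never dropped silently.

Duration conventions (both last-crossing, interpolated linearly between
samples): full duration = last down-crossing of ξ_Tri = 0.15; half-life =
last down-crossing of 0.5.  A decayed bout is **sharp** when the interval
between its last down-crossings of 0.85 and of 0.15 is at most 3·τ₆ (window
exposed as a parameter), else **irregular**.  The rule reproduces the
step-vs-plateau dichotomy without reference to the ensemble: a pure
alternating-mode escape under H = sin completes the 0.85→0.15 drop in
≈ 1.18/Γ < 3τ₆ = 1.5/Γ, with margin for noise.

Ensembles are integrated vectorized over realizations from a single seeded
generator (`numpy.random.default_rng`), so identical (params, dt, seed) give
bit-identical results.

## Synthetic velocity bouts

The bout-statistics utilities operate on velocity traces.  As a stand-in for
recorded locomotion data, `generate_synthetic_bouts` emulates the *shape* of
an empirical bout ensemble: plateau at 1 after onset normalization, logistic
drop of width 0.1 centered at 1 + Exp(rate 0.5) time units (every bout keeps
a minimal plateau), additive Gaussian noise (SD 0.03), default n = 43
traces.  The generator is shape-matched, not scale-matched: real recordings
have units (seconds, cm/s), autocorrelated measurement noise, variable
sampling, and an onset-detection problem, none of which are modeled.
Passing tests on these fixtures therefore validate the *statistics code*
(averaging, confidence bands, exponential fits), not any claim about real
animals.  The 95% confidence band is 2·SD/√n.  Exponential duration fits are
maximum-likelihood (rate = 1/mean excess, optional location shift), with the
R² of the empirical log-survival against a straight line as the goodness
summary.

## Problem sizes and determinism

Default ensemble sizes (200 bouts for fractions, 50 per grid point for
lifetime sweeps, 10⁴-scale reduced to desk scale) were chosen so the full
test suite and the acceptance script each complete in well under a minute on
one CPU while keeping proportion standard errors near 0.035; all are
overridable (`--reps`).  Every stochastic entry point takes an explicit seed.

## Known limitations

- The seven default connectivity weights are surrogates constrained by the
  published structure, not fitted values; quantities that depend on the full
  idling spectrum (e.g. the k = 0 sharp fraction, ≈ 0.41 under the defaults)
  inherit that uncertainty, while the exact identities (±2ΓH′ eigenvalues,
  exclusivity) do not.
- First-order theory only: τ = −τ₆ ln σ ignores the O(1) time the nonlinear
  escape itself takes, so simulated lifetimes exceed it by a bounded factor.
- No bout-initiation model: bouts are initiated externally at φ_Tri.
- Phase-only description: no amplitudes, muscles, joints, or load feedback.
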