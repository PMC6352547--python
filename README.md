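# hexacpg

A coupled phase-oscillator model of hexapod locomotion: why an insect whose
endogenous pattern-generator network stabilizes *synchrony* can still walk in
a double-tripod gait — but only in metastable, sharply terminated bouts.

## The model

Each of the six legs carries a central pattern generator, reduced to a single
phase φₙ(t).  The network evolves as

    dφₙ/dt = Γ Σₘ Aₙₘ H(φₘ − φₙ) + k·H(fₙ(φ) − φₙ) + ν(t),

where

- **A** is the endogenous wiring diagram: 14 directed links between the six
  thoracic CPGs, reduced by left-right symmetry to 7 weights
  (l₁, l₂, l₃ contralateral per segment; b₁, b₂ descending; f₁, f₂ ascending).
  The metathoracic contralateral weight is negative (anti-phase preference),
  the rostral ones positive.  Rows are normalized to sum to 1.
- **H** is a 2π-periodic coupling function with H(0) = H(π) = 0 and
  H′(π) < 0 < H′(0) (default H = sin).
- **fₙ(φ) = Σₘ Cₙₘ φₘ** is a tripod-reinforcing sensory feedback: each leg
  compares its phase with a weighted average of its own tripod trio
  ({1,3,5} or {2,4,6}); k is the feedback gain (k = 0 for the isolated,
  *fictive* preparation).
- **ν(t) ~ N(0, σ²)** is internal noise.

Both gaits are fixed points: idling φ_Idl = (0,…,0) and the double-tripod
φ_Tri = (0,π,0,π,0,π).  Proximity is measured by the order parameters
ξ_Idl = |⟨e^{iφ}⟩| and ξ_Tri = |⟨(−1)ⁿ e^{iφ}⟩|.

The central spectral facts, all reproduced exactly by this package:

- the alternating mode v₆ ∝ (1,−1,1,−1,1,−1) has eigenvalue **−2ΓH′(0)** at
  idling and **−2ΓH′(π)** at the double-tripod, for *any* feedback gain k;
- without feedback the two gait Jacobians are proportional with a negative
  ratio, so their stabilities are mutually exclusive — a network whose
  isolated rhythms synchronize *cannot* hold a stable double-tripod;
- feedback k ≳ Γ damps every other deviation, leaving a single unstable
  direction.  Noise of scale σ then escapes along v₆ after a lifetime
  **τ = −τ₆ ln σ**, with τ₆ = −1/(2ΓH′(π)): a plateau of clean double-tripod
  walking that ends in one sharp transition.

## Worked example

```python
import numpy as np
import hexacpg as hx

mp = hx.ModelParams(gamma=1.0, k=1.0, sigma=0.01)

rep_idl = hx.classify_stability(hx.jacobian_idle(mp))
rep_tri = hx.classify_stability(hx.jacobian_tripod(mp))
print("idle:", rep_idl.classification, np.round(rep_idl.eigenvalues.real, 4))
print("tripod:", rep_tri.classification, np.round(rep_tri.eigenvalues.real, 4))

recs = hx.run_bouts(mp, 100, seed=0)
hl = np.array([r.duration_halflife for r in recs if r.decayed])
rho = sum(r.label == "sharp" for r in recs if r.decayed) / sum(r.decayed for r in recs)
print(f"mean half-life {hl.mean():.2f}, predicted {hx.predict_tau(1.0, 0.01):.2f}, rho {rho:.2f}")
```

prints

```
idle: stable [ 0.     -1.1169 -1.7169 -2.     -2.2831 -2.8831]
tripod: unstable [ 2.      0.8831  0.2831 -0.     -0.2831 -0.8831]
mean half-life 3.72, predicted 2.30, rho 1.00
```

Idling is stable (one structural zero mode — the global phase shift — and
five negative eigenvalues, among them −2ΓH′(0) = −2 on the alternating
mode).  The double-tripod is unstable with the mirror eigenvalue
−2ΓH′(π) = +2.  At k = Γ = 1 and σ = 0.01 every simulated bout terminates
sharply (ρ = 1.00); the mean half-life sits within a factor of two of the
first-order prediction −τ₆ ln σ ≈ 2.30, as expected of a leading-order
estimate of a noise-driven escape time.

## Command line

```
hexacpg list                             # available experiment presets
hexacpg validate --gamma -1              # names the violated constraint
hexacpg run spectra --k 0 --out out/     # both gait spectra + exclusivity report
hexacpg run fig4_sweep_k --out out/      # rho(k) table over an ensemble
hexacpg run fig5_tau_gamma --out out/    # mean lifetime vs Gamma with power-law fit
```

Every run writes a `manifest.json` (resolved configuration and seeds) that
makes re-runs bit-identical.

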