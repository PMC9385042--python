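# Methods

## Problem and model

`odorinverse` solves an inverse design problem in olfaction: given a target
odor impression — scores on 21 perceptual descriptors such as 'fruit',
'sweet', 'musky' — find a physically meaningful electron-ionization (EI)
mass spectrum, and a mixture of real library molecules, whose predicted
impression matches the target.  Mass spectra are used as the sensing
modality because mixture spectra superpose linearly in the mixing ratios,
so any predicted spectrum can in principle be realized by blending
molecules.

The forward model is a nine-layer sigmoid multilayer perceptron
X⁽⁹⁾ = f⁽¹,⁹⁾(X⁽¹⁾) assembled from three pretrained parts:

| part | layers | default sizes |
|---|---|---|
| MS encoder (autoencoder half) | 1→3 | 212, 85, 70 |
| feature converter | 3→7 | 70, 30, 70, 45, 15 |
| sensory decoder (autoencoder half) | 7→9 | 15, 20, 21 |

Each layer computes X⁽ᵏ⁺¹⁾ = ζ(W⁽ᵏ,ᵏ⁺¹⁾X⁽ᵏ⁾ + B⁽ᵏ,ᵏ⁺¹⁾) with the logistic
ζ(a) = 1/(1+e⁻ᵃ).  Spectra enter base-peak normalized on the unit m/z grid
[51, 262] (212 bins; below 51 solvent ions dominate, above 262 fragments
contribute little to odor); sensory scores are panel averages divided by one
global dataset maximum, so all signals live in [0, 1] as the sigmoid
requires.

Training is plain backpropagation on L = ½Σ‖error‖² (averaged per sample)
plus a ridge penalty λ·½‖W‖² (biases unpenalized), with momentum
Δθ_τ = −η_τ∇ + αΔθ_{τ−1} and a geometric step schedule η_τ = η₀γ^τ.
Weights start Glorot-uniform, biases at zero.  The two autoencoders and the
converter are pretrained separately — the spectrum autoencoder on synthetic
mixtures of three random library spectra at Dirichlet-uniform ratios,
renormalized to unit max — then the composed stack is fine-tuned end to end.
Composition itself copies parameters, so predictions through the combined
stack equal decoder(converter(encoder(x))) bit for bit.

## Inverse search

The inversion does not touch raw spectrum space (sparse, mostly zero, and
known to resist direct gradient descent).  It works in the 70-dimensional
autoencoder bottleneck:

1. **Feature descent.**  Minimize the weighted half-SSE
   L = ½Σᵢ mᵢ(tᵢ − xᵢ⁽⁹⁾)² over the feature X⁽³⁾ by gradient descent.  The
   gradient flows through the tail f⁽³,⁹⁾ by the chain rule; each layer
   contributes diag(ζ(1−ζ))·W.  Steps decay as η₀γ^τ (defaults 0.1·0.99^τ;
   the heavier-damped 0.1·0.999^τ with more iterations is used when only one
   descriptor carries weight).  The iterate with the smallest objective
   anywhere along the trajectory is returned — descent on this non-convex
   surface need not end at its best point.  The search is unconstrained
   (the tail map is defined for all reals); an optional flag clips iterates
   to [0,1].  Design targets may exceed 1 (tripling a score above 1/3): the
   "virtual true value" is kept unclipped with a warning, and the sigmoid
   output simply saturates toward it.
2. **Spectrum recovery.**  A greedy randomized coordinate line search maps
   the optimized feature back to a physical spectrum: per iteration one m/z
   bin is nudged by ±Δ_τ (Δ_τ = 0.5·0.9999^τ by default), the candidate is
   clipped to ≥0 and renormalized to unit max, and the move is accepted only
   if the squared feature-space distance to the target strictly decreases.
   Strict decrease guarantees a monotone error trajectory and termination of
   accepted-move counting.  The search warm-starts from the autoencoder
   decoder output, so it can only improve on that baseline; starting from an
   arbitrary or corrupted spectrum is also supported.  The single-bin ±Δ
   proposal is one concrete instance of a randomized line search; it is
   isolated behind a `propose` hook so alternative proposal rules can be
   swapped in without touching the acceptance logic.
3. **Unmixing.**  The recovered spectrum is expressed as a nonnegative
   combination of library spectra by Lawson–Hanson NNLS (scipy's `nnls`),
   whose active-set structure yields exact zeros — "number of contributing
   molecules" is the count of strictly positive coefficients.  Because the
   solver can leave O(machine-ε) dust on passive coordinates, coefficients
   below 10⁻¹⁰ of the largest are pruned to exact zero and the residual is
   recomputed from the pruned vector.  Errors are reported in raw spectrum
   space and, when a model is supplied, in feature space (both spectra
   base-peak normalized before encoding, matching training).

## Hyperparameters

Stage subscripts: M = spectrum autoencoder, S = sensory autoencoder,
P = converter, F = fine-tuning.  Full-scale defaults (`TABLE_DEFAULTS`):

| stage | λ | η_τ | α |
|---|---|---|---|
| M | 7.5×10⁻⁵ | 0.5·0.99^τ | 0.3 |
| S | 2.0×10⁻⁹ | 0.4·0.99^τ | 0.3 |
| P | 1.0×10⁻⁵ | 0.4·0.99^τ | 0.25 |
| F | 2.0×10⁻⁵ | 0.35·0.99^τ | 0.025 |

with 2000 updates per stage and a 500,000-mixture pretraining set.  Two
numerical readings deserve note.  First, 0.99^2000 ≈ 2×10⁻⁹: decayed per
update, the printed schedules die long before 2000 updates.  τ therefore
counts *epochs* by default (identical to updates in full-batch mode), and
`schedule_unit` exposes the per-update reading.  Second, the fine-tuning
rate is implemented as 0.35·0.99^τ, reading the printed "0.35×0.99" as
carrying the same exponent as every other stage.

## Desk-scale operating point

The full-scale volumes are not needed to exercise the method, and the test
suite and acceptance script run a *desk-scale* protocol chosen once
(`PipelineConfig.desk_scale()`): a 100-molecule synthetic library, a
3,000-mixture pretraining set, and an 80/20 train/held-out split from a
shuffled 5-fold partition.  At this scale the sum-of-squares-on-sigmoid
loss needs help: most spectrum bins are zero, the output units saturate
toward them, and the surviving gradients are tiny.  The desk schedules
therefore use heavy momentum and longer budgets — spectrum autoencoder
η = 3.0·0.99993^τ, α = 0.9, 40,000 minibatch-128 updates; sensory
autoencoder and converter η = 1.0·0.9997^τ, α = 0.9, 12,000 full-batch
updates; fine-tuning η = 0.35·0.9998^τ, α = 0.9, 8,000 updates — while the
loss, penalty, and update rule stay exactly the model's.  For reference,
a 70-component PCA puts a linear ceiling of about 0.96 on held-out mixture
reconstruction correlation at this scale; the sigmoid autoencoder lands a
few points below it.

## The synthetic world

Real inputs (a NIST-style spectral library and a DREAM-style sensory panel)
require downloads and licenses, so the `synthetic` module fabricates a
self-contained study with the statistical structure the method relies on:

* **Library.**  EI spectra of organic odorants are built from recurring
  fragment series (alkyl ions at m/z 43/57/71…, aromatic ions at 77/91/105,
  …); molecules in one flavor library overlap heavily in peak positions,
  and this shared structure is precisely what makes spectrum→odor
  prediction generalize.  The generator draws 15 sparse fragment motifs
  (4–8 peaks, log-uniform intensities over two decades) and composes each
  molecule from 1–3 motifs at Dirichlet proportions, plus two faint
  molecule-specific peaks (≤10% of the base peak) that keep the library
  full-rank.  Supports are trimmed/padded into 5–25 peaks and the base peak
  scaled to exactly 1.  An earlier iid-random-bins design was rejected:
  with no shared structure across molecules, a labelled 80/20 split cannot
  generalize no matter how well the optimizer works.
* **Planted truth map.**  Sensory scores come from a small random
  nine-layer sigmoid network.  A naively initialized deep random net maps
  every molecule to nearly the same scores (uncentered preactivations
  saturate and the signal contracts layer by layer), so the planted weights
  use a per-layer variance-preserving scale (σ_w = 4·amp/√n_in, amp = 1.2)
  with biases centering each layer at zero for mean-level inputs, plus a
  ±1 uniform output-bias spread so descriptor base rates differ.  Scores
  are the planted predictions plus optional truncated Gaussian panel noise
  (default sd 0.02, clipped to [0,1]); the noiseless setting is used for
  recovery checks.
* **What it does not emulate.**  Chemically realistic fragmentation,
  isotope patterns, instrument noise, inter-rater disagreement, and the
  semantic correlation structure of real descriptors.  Passing tests show
  the machinery — optimization, inversion, recovery, unmixing — is correct
  on data with the assumed structure; they say nothing about predictive
  accuracy on real NIST/DREAM data, and the headline full-data figures
  reported elsewhere are out of desk-scale reach by construction.

## Numerical choices and degenerate inputs

* Loss is per-sample mean (not sum) half-SSE, making η independent of
  dataset size; λ is interpreted against this convention.
* Biases are excluded from the ridge penalty (standard practice).
* All-zero spectra cannot be base-peak normalized and are rejected;
  mixtures require at least one positive ratio; descriptor weights must be
  nonnegative with at least one positive.
* Mixtures fed to the model are renormalized to unit max (the model trained
  on unit-max inputs); mixtures used as NNLS targets are kept raw, since
  the ratios are only meaningful against the unnormalized combination.
* Recovery proposals with exactly equal SSE are rejected (strict decrease),
  and a proposal that would zero the whole spectrum is discarded.
* Inversion runs a fixed iteration count; an early-stop on plateau exists
  but is off by default.
* k-fold partitions come from scikit-learn's shuffled `KFold`; fold sizes
  differ by at most one.
* Model files are versioned JSON holding layer sizes, all weights, the
  descriptor list and the sensory normalization constant.

## Known limitations

* Gradient recovery in raw spectrum space is deliberately not implemented
  (sparse nonnegative spectra make it ill-behaved); the feature-space
  detour is the method.
* The single-bin proposal rule for recovery is an interpretation of
  "randomized line search"; other rules may converge faster.
* Not every target impression is realizable (e.g. simultaneously 'warm'
  and 'cold'); the inversion then converges to the closest achievable
  impression under the chosen weights, and only weighted descriptors are
  pulled toward their targets.
* Pooled Pearson correlation mixes between-descriptor and between-molecule
  agreement; per-descriptor correlations are reported alongside it.
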