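# Methods

## The model

`cryoclass` implements regularized-likelihood 2D classification of
single-particle cryo-EM images.  The Fourier transform `x_i ∈ C^L` of each
particle image is modelled as a transformed copy of one of `K` unknown
class references `v_k` plus noise:

    x = H_q v + e,   e ~ CN(0, σ),   v ~ CN(0, τ),

where `H_q` composes an in-plane rotation ψ, a translation `t = (tx, ty)`
(a phase ramp `exp(−2πi k·t / box)`), and multiplication by the particle's
contrast transfer function (CTF).  `σ²(s)` and `τ²(s)` are per-resolution-
shell variances of the noise and of the signal prior.  The maximum
a-posteriori objective marginalizes the latent pose `q` over a discrete
grid `Q` (uniform prior over rotations, isotropic Gaussian prior over
translations) and sums over classes with uniform weights `1/K`:

    L(V, X) = Σ_i log Σ_k (1/K) Σ_q P(x_i | v_k, q) P(q) + Σ_k log P(v_k).

Expectation–Maximization alternates posterior computation
`P_k(q | x_i) ∝ P(x_i | v_k, q) P(q)` with the closed-form update

    v_k ← B_k / (F_k + τ⁻²),
    B_k = Σ_i Σ_q P_k(q|x_i) H_q* (x_i / σ²),
    F_k = Σ_i Σ_q P_k(q|x_i) diag(H_q* σ⁻² H_q).

### VDAM

The EM update equals a gradient-descent step preconditioned by the
diagonal variable metric `D = diag[(F + τ⁻²)⁻¹]`; with the data-term
negative gradient `G := F∘v − B`,

    v ← v − η (G + τ⁻² v) / (F + τ⁻²)

reproduces EM exactly at η = 1 on a full batch (this identity fixes the
sign convention: `G` excludes the prior term, consistent with decoupling
regularization from the adaptive moments).  VDAM runs this on mini-batches
with the regularizer expressed through the half-set Fourier shell
correlation (`SNR = FSC/(1−FSC)`), and Adam-style running moments of the
batch-size-invariant rescaled gradient `Ĝ = G/(F + ε₁)`:

    m_h ← β₁ m_h + (1−β₁) Ĝ_h                 (per half-set, β₁ = 0.9)
    u   ← β₂ u + (1−β₂) |Ĝ_h1 − Ĝ_h2|²        (shared, β₂ = 0.999)
    v_h ← v_h − η [ FSC · m_h / (√û + ε₂) + (1 − FSC) v_h ],

where `û = u / (1 − β₂ⁿ)`.  The second moment tracks the *difference*
between the two half-sets' gradients — an online estimate of the
gradient's noise amplitude — so well-determined coefficients take larger
steps.  Two numerical choices stabilize this step (see "Numerical
choices").

Classes whose running likelihood mass `P(X|k)` falls below `ρ/K`
(inactivity threshold `ρ = 0.1`) are replaced: the least-likely class `a`
receives a one-step-ahead copy of the class `b` with the largest
`|m_b/(u_b + ε)|²` (the class changing the most), while `b` keeps its
previous state; the class count never changes, a class is not substituted
twice within 10 mini-batches, and at most one substitution fires per
batch.

Mini-batch schedule (2D): an initial stage (first quarter of the run) with
batch size `clamp(0.005 N, 200, 10000)` at learning rate 0.9, then
`clamp(0.05 N, 1000, 100000)` at 0.3, with a linear rate ramp over 10
batches at the switch (3D constants: maxima 5000/50000, later fraction
10%, later rate 0.5).  The default run length is 200 mini-batches; both
half-sets are sampled without replacement within epochs and balanced per
batch.  A final full pass computes only `P(X|k)` and per-particle
assignments against the combined (half-averaged) references.

References are initialized as randomly positioned Gaussian blobs (centres
uniform in the inner half of the box, widths in `[box/12, box/7]` px),
identical across half-sets; the blob diversity drives early class
separation.

## Discretization and operators

* All FFTs are orthonormal.  Real images are carried as rfft2 half-planes
  with multiplicity weights for full-grid sums; the model uses only
  coefficients strictly inside the Nyquist disc (the aliased Nyquist ring
  is ambiguous for an astigmatic CTF and carries no isotropic shell).
  Friedel mates are counted twice in likelihood sums — a uniform factor
  that cancels from every posterior.
* Rotation acts on the Fourier plane by bilinear interpolation of the
  de-centred spectrum (the ±1 checkerboard phase of a centred object is
  removed before interpolating and restored afterwards); the
  back-projection adjoint is the exact matrix transpose.  For multiples of
  90° the operator is an exact permutation, which is why the analytic
  identity tests (gradient vs finite differences, EM monotonicity, EM↔VMGD
  equivalence) run on 90° grids: there `F = diag(H*σ⁻²H)` exactly and the
  printed equations hold to float64 precision.  (Real-space interpolation
  was evaluated first and rejected: its interpolation kernel attenuates
  the true diagonal of `H*σ⁻²H` at high frequency, and the mismatch
  between `B` and `F` degrades every M-step.)
* `F` is accumulated by scattering CTF²/σ² through the same transposed
  interpolation weights as the data (gridding convention), which keeps the
  Wiener ratio `B/F` unbiased under interpolation.
* The CTF is `−(√(1−A²) sin γ + A cos γ)` with
  `γ = πλΔz(θ)s² − (π/2)Cs λ³s⁴ + phase shift` — negative at low frequency
  for underfocus; no envelope.  This functional form is a convention of
  this package.

## Numerical choices

* **ε constants.**  `ε₁ = ε₂ = ε_sub = 1e−8 ×` mean of `F` over the first
  mini-batch (scale-aware "suitably small" stabilizers), unless set
  explicitly.
* **Stability of the adaptive step.**  The raw step
  `FSC·m/(√u + ε₂)` amplifies by the gradient's signal-to-noise ratio and
  diverges when the half-set gradients agree too well (weak noise, u → 0).
  Two measures restore stability without altering the printed recursions:
  the second moment is bias-corrected for its zero initialization
  (`û = u/(1−β₂ⁿ)`, standard in the Adam family), and the data-term
  multiplier `η·FSC/(√û + ε₂)` is clipped at 1 — a step never exceeds the
  preconditioned EM displacement that the variable metric is derived to
  reproduce.  The clip only engages in high-SNR regimes; on the standard
  noisy conditions it leaves the trajectory essentially unchanged.
* **Truncated marginalization.**  After the first 10 mini-batches VDAM (i)
  truncates posteriors to the smallest set of (class, pose) entries
  holding 99.9% of the mass before accumulation, and (ii) skips
  low-probability orientations from the marginalization itself: every
  (class, rotation) is scored on a coarse translation subset and only the
  best `max(16, K·n_rot/4)` pairs per particle are evaluated on the full
  translation grid.  EM and all exactness tests use the full integral.
* **Spectra.**  σ²(s) is estimated from posterior-weighted residual power
  (floored), on the first mini-batch and every 25 thereafter (EM: every
  iteration); the initial value is the data power spectrum, a deliberate
  overestimate.  τ²(s) (EM only; VDAM replaces it by the FSC form) is
  `SNR/mean_shell(F)` with FSC clipped to [0, 0.999] — the per-shell SSNR
  relation is a convention, floored at 1e−10.  FSC shells with fewer than
  3 coefficients inherit the previous shell's value.
* **Class weights** are uniform and fixed; `P(X|k)` is tracked for
  substitution and reporting only.  The running class mass uses an
  exponential average with decay β₁ (per-batch mass at batch size 200 is
  too noisy to gate substitutions).
* Ties in substitution (several classes below ρ/K) resolve to the smallest
  mass among classes outside the 10-batch cooldown.

## The synthetic data generator

The generator realizes the generative model exactly: particles are
Fourier-interpolated rotations (uniform ψ), phase-ramp translations
(Gaussian, σ_t = 1 px, clipped at box/4) and CTF multiplications of one of
K ground-truth class images, plus Fourier-domain Gaussian noise shaped per
shell — so σ-recovery and residual tests are exact by construction.
Standard desk-scale conditions: box 32 at 3 Å/px, K = 3 (disc / ring / bar
from a parametric shape library, pairwise correlations ≤ 0.8, smoothed to
band-limit), N = 2000, defocus uniform in 0.5–2.5 µm (no astigmatism),
300 kV, Cs 2.7 mm, amplitude contrast 0.1, and colored noise
σ²(s) = 0.35 + 0.7·exp(−(s/3)²), stronger at low frequency as in ice
background.  The noise level was fixed by a single design rule: the
true-model Bayes accuracy under pose marginalization on these conditions
is ≈ 0.97, leaving measurable but not dominant confusion.  What the
simulator deliberately omits: ice gradients, motion blur, amplitude
falloff envelopes beyond the CTF, structural heterogeneity within a class,
particle-crowding artefacts.  Passing recovery tests therefore show the
estimator works when its model is correct — not that it is robust to the
model violations of real micrographs.

## Problem sizes used in tests

All tests and the acceptance script generate their data at run time.
Identity checks use 8–16 px boxes with ≤ 64 particles.  EM monotonicity
uses N = 256 at box 32 on a 90° grid.  Recovery checks use the standard
conditions above; the test suite runs VDAM at the default 200 mini-batches
across 10 seeds plus one 25-iteration EM run for the quality-parity gap,
and the substitution check (K = 6 on 3 true classes) at 60 mini-batches,
by which point the substitution dynamics have long equilibrated.  The
acceptance script repeats the recovery measurement on 5 seeds and reports
the median with an explicit success count: both optimizers are
multi-modal at this scale (a run can trap a junk class whose mass stays
above the inactivity threshold, so substitution rightly does not fire),
and a majority summary separates mode membership from within-mode
quality.

## The class ranker

Each class average is cropped to the circular classification mask,
rescaled to 64×64 and standardized inside the mask.  An 18-component
feature vector accompanies it: mean/variance/skewness/kurtosis of the
density in an automatically segmented protein region, in the solvent
region and in a 3 px outer ring (12 values); rotational and translational
alignment accuracies (posterior spread around the best pose); estimated
resolution 1/d and weighted resolution d²/ln N; log₁₀ class size; and the
protein-mask area fraction.  The published tool's exact 18-feature
composition is not public; this composition is this package's
reconstruction, with the order fixed in `FEATURE_NAMES`.  The protein mask
is a smoothed threshold segmentation (mean + 0.5·sd inside the circle).

The scoring network — three convolutional blocks (two 3×3 convolutions
plus a strided, channel-doubling 3×3; channels 1→16→32→64), global average
pooling, concatenation with the 18 features and two fully connected layers
with ReLU, sigmoid output — is implemented in NumPy with exact backprop
and an Adam trainer.  Channel counts, kernel sizes and hidden width are
conventions of this package.  Classes with score ≥ 0.15 (inclusive) are
selected by default.  Training the network to its published quality
requires a large curated corpus of manually scored classes and is out of
scope; the trainer is exercised on synthetic good/bad toy sets.

## Known limitations

* Only a 2D forward model is provided; the 3D schedule constants exist in
  `batch_schedule` but there is no slice-extraction reconstruction.
* A single optics group; no per-group noise spectra, anisotropic
  magnification or beam tilt.
* The pose grid is global and fixed (no local searches or adaptive
  oversampling).
* The strict zero-noise limit exposes the adaptive step's reliance on
  gradient noise; the documented clip makes it converge, but the method is
  designed for stochastic gradients.
* The exact per-shell SSNR→τ² rule and the CTF functional form are
  conventions; absolute τ scales should not be compared against other
  software.
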