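# Methods

## Model

`normatt` implements the normalization model of attention (NMA) for a
center–surround motion display.  All fields live on a discretized
space × direction lattice; the default grid has 121 spatial samples spanning
±60 a.u. (1 a.u. spacing) and 72 directions at 5° spacing.  This resolves
the narrowest default tuning widths (x_e ≈ 3.7 a.u., θ_e ≈ 24°) with at
least four samples per SD while keeping brute-force convolution oracles
tractable on reduced grids.

The stimulus field `N` is a sum of separable 2D Gaussians, one per grating.
Each component is peak-normalized so that a lone component attains exactly
its contrast at its own position/direction.  The center patch has spatial SD
1.5 a.u. and the annular surround is modeled as a single broad Gaussian
(SD 12 a.u.) co-centered with the center patch — no explicit annulus hole.
Only the relative spatial geometry matters because model space is in
arbitrary units; the two widths are proportional to the 1.5° and 12°
stimulus diameters.  Gratings have one physical drift direction, so each
component's direction profile is a near-delta circular Gaussian (SD 5°, one
lattice step).  Opposite-direction trials place the surround component 180°
from the center direction.

The excitatory drive is `E = e * N` with a separable Gaussian kernel
(SD x_e in space, θ_e in direction); the suppressive drive is
`S = s * (E × M)` with a broader kernel (x_s, θ_s).  Kernels are
area-normalized (a uniform field maps to a uniform field away from the
spatial boundary).  Convolution is circular along direction — direction is
physically an angle — and zero-padded along space; the ±60 a.u. extent keeps
stimulus-driven boundary effects negligible at the readout.  Internally both
convolutions are dense Toeplitz/circulant matrix products, which at these
lattice sizes are faster than FFTs and agree with the nested-sum definition
to machine precision (verified against a brute-force oracle at 1e-10).

The attention field is `M = 1 + (peak − 1)·Gauss(x; width)·circGauss(θ)`,
baseline 1 far from the attended locus.  The peak gain is fixed at 2 and the
direction width at 180° (effectively direction-nonselective): the task cues
a *location*, not a direction, so only the two spatial widths are fitted —
`mg_narrow` for narrow-attention (and center-only) trials and `mg_wide` for
wide-attention trials.  Because the peak is fixed, the field's value at the
center stimulus is the same for both conditions; widening the field only
recruits more of the surround into the suppressive pool, which is why the
center-population response is monotonically non-increasing in attention
width (a property the tests check).

The population response is `R = E × M / (S + σ_eff)`.  The semi-saturation
constant is specified in normalized drive units: σ_eff = σ · Ê, where Ê is
the excitatory peak the center-only stimulus would produce at unit contrast.
This makes σ's effect invariant to the overall drive scale set by the
pooling widths (which would otherwise let σ trade off against them) while
preserving contrast dependence; the default σ = 1e-2 places the same-
direction surround firmly in the suppressive regime, reproducing the
narrow < wide suppression ordering and the weak opposite-direction
suppression.  σ is fixed, not fitted: the model deliberately has exactly six
free scalars (x_e, x_s, θ_e, θ_s, mg_narrow, mg_wide) in five functional
roles, and σ would trade off with the threshold constant under center-only
normalization.

The fMRI proxy `R_peak` is the mean of `R` over a (2 r_w + 1)² window around
the response peak, with r_w fixed at 2 lattice steps; normalization by the
center-only condition cancels the first-order dependence on r_w.  The argmax
is global with deterministic tie-breaking (nearest lattice point to the
center stimulus, then lowest direction index).  Predicted thresholds follow
`T = C / R_peak`; `C` is a free linking constant that cancels in suppression
indices, so by default it is calibrated to put the center-only threshold at
50 ms.

## Fitting and validation

The model is fitted to the five per-condition responses normalized by the
center-only mean, minimizing the MSE averaged across all five conditions
(center-only contributes zero error but stays in the denominator).
Optimization is bounded L-BFGS-B restarted from random points drawn within
the bounds (x_e ∈ [0.5, 20], x_s ∈ [5, 100], θ_e ∈ [5, 90], θ_s ∈ [10, 180],
Mg ∈ [0.5, 100]), run in the unit box so finite-difference steps are equally
scaled for parameters whose natural ranges differ by orders of magnitude.
Parameter sets violating the broader-than-excitatory invariants return a
large smooth penalty rather than raising, so permutation loops never abort.
The reported MSE is always recomputed from the reported parameters (an audit
identity the tests enforce).  The default protocol is 20 pure random starts;
an optional screened mode scores a larger candidate sample once and polishes
only the best few — used where many fits must run in a limited time, since
pure low-count multistarts occasionally settle in local minima whose
attention-width ordering is inverted even though the global optimum
preserves it.

Joint identifiability of all six parameters is *not* claimed: noiseless
self-generated data are refit to MSE ≈ 0 by several parameter combinations.
What the tests do claim is (a) the refit reaches the reported fit quality
(MSE ≤ 0.01), and (b) each parameter is identifiable alone — a
one-dimensional fit with the others frozen recovers its generating value
within 1%.  The flat 1-D objective near the optimum requires tight optimizer
tolerances (ftol 1e-20) to pin the minimum to that precision.

Shuffle-null validation permutes the condition labels of the beta weights
within each participant (preserving participant-level scale), re-normalizes
and refits, optionally enforcing mg_wide > mg_narrow; the empirical p-value
is (1 + #{null ≤ observed}) / (1 + n).  Cross-validation partitions
*participants* (the only replicable unit once conditions are averaged) into
k folds, fits on the training participants' normalized means, and scores MSE
on the held-out participants' normalized means.

## Behavioral simulation

A simulated observer answers the two-alternative direction judgment with
probability `p(d) = γ + (1 − γ − λ)(1 − exp(−(d/α_w)^β))`, γ = 0.5,
λ ∈ [0, 0.06], with α_w parameterized so the nominal threshold α sits at 79%
correct — the level a 1-up/3-down staircase converges to (0.5^{1/3} ≈ 79.4%).
Two interleaved staircases start at 33 ms (hard) and 158 ms (easy), 100
trials each, alternating trial by trial.  Steps are multiplicative with
factor 1.26 (≈2 dB) — log-spaced steps are standard for duration staircases —
bounded by an 8.3 ms floor (one frame at 120 Hz) and a 500 ms ceiling.
Duration is treated as a continuous variable.  Thresholds are re-estimated
by a pooled maximum-likelihood Weibull fit over both tracks (γ fixed, λ
bounded), read out at the absolute 79%-correct level under the fitted lapse.

## Synthetic data

The generator emulates the study conditions: 10 participants, five
conditions (center-only, narrow/wide × same/opposite).  Per participant,
beta = lognormal scale factor (SD 0.2) × model R_peak + Gaussian noise with
SD equal to 10% of the center-only response; behavioral observers get the
model-predicted thresholds jittered by a participant-level lognormal factor
(SD 0.2), slopes drawn from [2, 4] and lapses from [0, 0.04].  The
participant-level variance components are not identifiable from published
group statistics; these defaults are chosen so that group effects at n = 10
reach significance roughly as in the reference analyses, and they are
documented as placeholders.  The generator produces exchangeable
participants, beta-level data only (no voxel time series, no hemodynamics),
and Gaussian noise — so passing tests demonstrate that the *pipeline*
recovers built-in structure, not that real fMRI noise is this benign.

## Problem sizes and numerical choices

Test and validation runs scale the expensive stages down: staircase
convergence uses 10,000 post-burn-in trials; noisy-replicate ordering
recovery uses 100 replicates with the screened multistart (40 candidates,
2 polished starts, ≤300 objective evaluations each); the shuffle-null
ordering check uses 10 constrained shuffles; the pipeline integration tests
use 4 participants and 2 shuffles/folds.  Degenerate inputs are handled
explicitly: zero-variance t tests return flagged sentinels; degenerate
shuffles (non-positive center-only mean) are resampled; all-correct
psychometric data raise (threshold unidentifiable).  All randomness flows
from explicit integer seeds through `numpy` generators, and fits, null
distributions, CV partitions, staircases and generated tables are
bit-reproducible given the same seed.

## Known limitations

* The annular surround has no hole; its drive overlaps the center location.
  Relative geometry is configurable if a different mapping is wanted.
* The wide-attention field is a single wider Gaussian centered on the
  display center, not an annulus-plus-center composite; the two are not
  distinguishable from five condition means.
* fMRI responses are taken as linearly proportional to R_peak; no
  hemodynamic model.
* Joint parameter uncertainty is summarized only by cross-validation SEM;
  no Bayesian posterior.
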