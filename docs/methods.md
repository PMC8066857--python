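# Methods

## Detector

The detector is a two-step cellular-automaton transition rule applied in
one synchronous pass over the image lattice. For a pixel `X_ij`, the
selected-neighbor absolute-difference sum is
`φ = Σ |X_ij − X_{i+k,j+l}|` over the offsets chosen by the 9-bit linear
rule; the edge membership is `μ = φ/(Δ+φ)` and the output state is
`1 iff μ > τ` (exactly 0 at `μ = τ`). The automaton is *not* iterated:
the binary state after one pass is the edge map, and all adaptivity
comes from optimizing `(Δ, τ, r)` rather than from CA dynamics.

Conventions the formulas do not fix:

* **Bit-to-offset assignment.** Bit `b` of the rule selects offset `b`
  in the row-major enumeration `(−1,−1),(−1,0),…,(+1,+1)`. Any bijection
  produces the same family of detectors — only the integer label of each
  rule permutes — so nothing downstream depends on this choice.
* **Borders.** Out-of-bounds neighbors replicate the nearest in-bounds
  pixel, so border pixels see zero difference toward the outside and the
  frame never registers as an edge.
* **Degenerate membership.** `μ := 0` when `Δ = 0` and `φ = 0`: a flat
  neighborhood is not an edge. For `Δ = 0, φ > 0`, `μ = 1`.
* **Center bit.** Offset (0,0) contributes `|X−X| = 0`; rules differing
  only in that bit are exactly equivalent (tested as an invariant).
* Filtered images are real-valued; the rule is applied to them without
  re-quantization.

## Optimization

The triplet is searched in normalized form `(Δ/255, τ, r/511) ∈ [0,1]³`
with a standard global-best PSO: velocity
`v ← ωv + r₁c₁(pbest−x) + r₂c₂(gbest−x)` with `r₁, r₂` uniform in (0,1)
drawn independently per dimension, then clamped to ±v_max; position
`x ← x + v` clamped to the cube. Defaults: 100 particles, 25 epochs per
training unit, ω = 0.05, c₁ = 2.1, c₂ = 1.2, v_max = 1.0; positions
initialize uniformly in the cube and velocities uniformly in
[−0.1, 0.1]³. Personal/global bests update only on strict improvement.
Decoding back to integers rounds half up; τ is clamped to [0, 1−1e−9].

Fitness is the Dice coefficient of the detected map against truth
(mean over the unit's images in the batched protocol). Two maps that
are both empty score DSC = 1; empty-vs-non-empty scores 0. The fitness
image is the *scenario's pre-filtered input* — the pre+post variant is
optimized on the smoothed image it will actually see — but scores the
plain CA map by default; optimizing through thinning/fragment-removal
is available (`include_post`) at a significant cost, since the fast
evaluator otherwise reduces each particle evaluation to a cached
plane-sum, a ratio, and a threshold.

Between consecutive training units the global best is reset, so the
swarm is not anchored in the previous unit's optimum. The personal
bests are reset to the particles' current positions and re-evaluated on
the new unit: fitness values measured on different units are not
comparable, and carrying them over would freeze stale memories.
Positions and velocities carry over. The returned rule is the final
unit's global best; the full per-epoch history (unit, epoch, gbest
fitness, decoded triplet) is returned so callers can consolidate
differently.

## Phantom generator

Training and test data are 128×128 synthetic phantoms: a filled circle
(radius 20–50 px, center jittered ±5 px) on a uniform background, in two
intensity classes — **low** (background 10, disk 200: dark,
high-contrast) and **high** (background 120, disk 180: bright,
low-contrast) — degraded by Gaussian blur (σ ∈ [0.5, 1.5]) and additive
Gaussian noise (σ ∈ [2, 8], clipped to [0, 255]). About half the shapes
are distorted into an ellipse (axis ratio 0.85–1.0) with a sinusoidal
radial perturbation (2–4 lobes, amplitude 10 % of the radius). The
ground truth is the one-pixel inner boundary of the clean shape,
rasterized *before* degradation; it is a closed 8-connected curve whose
length is within 15 % of `2πR`. The class levels make the two classes'
global SNR (mean/std) distributions well separated, with the low class
lower — mirroring the kind of intensity split the generator emulates.
All sampling flows from explicit seeds; identical specs produce
bit-identical samples.

What the phantoms do *not* model: MRI physics (Rician noise, coil bias,
partial volume), background texture, and multi-structure anatomy. The
consequences matter for interpreting the experiments: piecewise-constant
phantoms give an optimized detector large decision margins
(`φ* ≈ Δτ/(1−τ)` can sit far above any noise contribution to φ), so
low-amplitude injected noise (σ ≤ 3 on the 0–255 scale) often moves the
high-contrast class's outputs by only a few pixels per image, and the
pre-smoothed pipeline barely at all. Passing trend tests on phantoms
therefore demonstrates the harness mechanics and the noise response of
*low-margin* configurations (the low-contrast class without
pre-smoothing); they do not certify equal behavior on textured clinical
images, where small margins are the norm rather than the exception.

## Pipelines and metrics

* Pre-processing: Gaussian smoothing (reflective boundary), σ_smooth = 0
  meaning none; sweep values {0, 0.5, 1.0, 1.25, 1.5}.
* Post-processing: Zhang–Suen thinning to 1-px curves, then deletion of
  8-connected components smaller than `min_component_size` (default 8,
  matching the Moore-neighborhood connectivity). Both operators only
  remove pixels; thinning is idempotent.
* Canny baseline: scikit-image's implementation with hysteresis
  thresholds at 10 %/20 % of 255; the CA path deliberately has no
  hysteresis.
* Metrics: DSC as above; PSNR = 10·log10(255²/MSE) and SSIM (11×11
  Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03) computed on the binary
  maps scaled to {0, 255} with data range 255 — the scale is stated here
  because dB magnitudes depend on it. Image SNR is global mean/std;
  difficulty is the mean Sobel gradient magnitude (3×3 kernels,
  reflective boundary); correlations are sample Pearson r.

## Experiments

All four designs (noise robustness, smoothing sweep, batch-size sweep,
difficulty analysis) return a per-image table plus a summary aggregated
from it, so every reported mean is exactly the mean of its reported
per-image values, and all randomness derives from one master seed.

Noise injection in the robustness experiment is *paired*: one
standard-normal field is drawn per test image and scaled by each σ
level, so differences between levels isolate the noise amplitude rather
than realization jitter, and every pipeline variant sees the same noisy
copies. Each variant uses a rule optimized on its own fitness input
(plain/post share one run on the raw images; pre+post optimizes on the
smoothed ones).

Problem sizes follow the study conditions: 20-image training and test
sets per intensity class, full swarm settings for optimization-quality
checks; reduced settings (20 particles, 10 epochs) are used for
mechanics-only runs and exposed as `--fast` in the CLI.

## Known limitations

* The rule search space is discrete under a continuous optimizer; many
  triplets decode to identical edge maps, so replicate runs often report
  different triplets on the same fitness plateau with identical test
  scores.
* PSNR between binary maps is a harsh, localization-sensitive score: a
  1-px-offset contour scores like a gross error. SSIM is gentler but
  still window-based.
* The global SNR definition (mean/std) conflates structural contrast
  with noise; it orders the two phantom classes correctly but is not a
  noise estimate.
* `exhaustive_search` is practical only for small images/grids; it
  exists as an independent check on the swarm, not as a production
  optimizer.
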