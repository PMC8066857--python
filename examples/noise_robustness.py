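"""Noise-robustness experiment: how each pipeline degrades with noise.

Optimizes one detector per pipeline variant on high-intensity (low
contrast) phantoms, then evaluates all variants on held-out phantoms with
paired Gaussian noise injected at sigma = 0, 1, 2, 3.
"""

from caedge.experiments import learn_variant_params, run_noise_robustness
from caedge.image_synthesis import make_optimization_set
from caedge.pso_optimizer import SwarmConfig

train = make_optimization_set(10, "high", master_seed=0)
test = make_optimization_set(10, "high", master_seed=1)

params = learn_variant_params(
    train, SwarmConfig(n_particles=40, epochs_per_unit=15, seed=0), batch_size=3
)
for variant, p in params.items():
    print(f"{variant:>8}: delta={p.delta}, tau={p.tau:.3f}, rule={p.rule}")

result = run_noise_robustness(test, params, (0.0, 1.0, 2.0, 3.0), seed=0)
print()
print(result.summary.to_string(index=False))
# Mean PSNR/SSIM per variant and noise level, against the clean ground
# truth.  The plain CA map is most noise-sensitive on these low-contrast
# phantoms; pre-smoothing plus post-cleanup stays nearly flat.
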