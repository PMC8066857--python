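"""Apply the CA edge detector to a synthetic phantom and inspect the result.

Builds one blurred, noisy circle phantom, runs the detector with a
hand-picked rule under the three pipeline variants, and scores each map
against the known boundary.
"""

from caedge import DetectorParams, ScenarioConfig, dsc, psnr, run_scenario, ssim
from caedge.image_synthesis import PhantomSpec, make_circle_image

sample = make_circle_image(
    PhantomSpec(radius=35, intensity_class="low", sigma_blur=1.0, sigma_noise=5.0, seed=7)
)
# delta damps the membership ratio, tau is the edge threshold, rule 495
# selects all eight non-center Moore neighbors
params = DetectorParams(delta=100, tau=0.35, rule=495)

print(f"phantom: 128x128 low-intensity circle, {int(sample.truth.sum())} true edge pixels")
for scenario in ("plain", "post", "pre_post"):
    cfg = ScenarioConfig(scenario, sigma_smooth=1.5)
    edges = run_scenario(sample.image, params, cfg)
    print(
        f"{scenario:>8}: {int(edges.sum()):4d} edge pixels, "
        f"DSC={dsc(edges, sample.truth):.3f}, "
        f"PSNR={psnr(edges, sample.truth):.2f} dB, "
        f"SSIM={ssim(edges, sample.truth):.3f}"
    )
# Higher DSC/PSNR/SSIM = closer to the true boundary; post-processing
# removes disconnected fragments, pre-smoothing suppresses noise responses.
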