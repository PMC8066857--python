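# caedge — cellular-automaton edge detection tuned by particle swarms

`caedge` is a supervised edge-detection toolkit for 2-D grayscale images,
built around a cellular-automaton (CA) transition rule whose three
parameters are optimized with particle swarm optimization (PSO) against
ground-truth edge maps. It targets workflows where expert annotation is
scarce — for example delineating cardiac cavities on MRI — by optimizing
the detector on synthetic circle phantoms that mimic the target images
and *transferring* the learned rule to the real data.

## The model

Each pixel `X_ij` is a CA cell with the radius-1 Moore neighborhood. A
9-bit *linear rule* `r ∈ {0,…,511}` selects which neighbors participate
in the local absolute-difference sum

```
φ(X_ij) = Σ_{(k,l) selected} |X_ij − X_{i+k,j+l}|
```

The edge membership is the saturating ratio

```
μ(X_ij) = φ / (Δ + φ),        Δ ∈ {0,…,255}
```

and one synchronous pass of the threshold step `F(X_ij) = 1 iff μ > τ`
(with `τ ∈ [0,1)`) produces the binary edge map. Larger Δ damps the
membership (fewer edges); τ sets how much local contrast counts as an
edge.

The triplet `(Δ, τ, r)` is normalized to the unit cube
`(Δ′, τ, r′) = (Δ/255, τ, r/511)` and optimized by a PSO swarm
(100 particles, 25 epochs per training unit, ω = 0.05, c1 = 2.1,
c2 = 1.2) with the Dice similarity coefficient

```
DSC = 2·TP / (2·TP + FP + FN)
```

as fitness — robust to the extreme edge/non-edge class imbalance. Two
protocols are provided: sequential (one image per unit) and batched
(mean DSC over a batch per unit), with the swarm's global best reset
between units. Around the detector sit three pipeline variants — the
plain CA map, CA + post-processing (Zhang–Suen thinning + removal of
small 8-connected fragments), and Gaussian pre-smoothing + CA + post —
plus a Canny baseline (hysteresis thresholds at 10 % / 20 % of 255),
PSNR/SSIM scoring, and a seeded generator of 128×128 circle phantoms in
two intensity classes (dark/high-contrast and bright/low-contrast).

## Worked example

`examples/noise_robustness.py` optimizes one detector per pipeline
variant on 10 bright, low-contrast phantoms and evaluates on 10 held-out
phantoms with paired Gaussian noise injected at σ ∈ {0,1,2,3}:

```
   plain: delta=134, tau=0.397, rule=509
    post: delta=134, tau=0.397, rule=509
pre_post: delta=54, tau=0.559, rule=511

 variant  sigma_noise  mean_psnr  mean_ssim
   plain          0.0  14.691957   0.418182
   plain          3.0  12.607947   0.240339
    post          0.0  19.025068   0.859337
    post          3.0  18.009420   0.814310
pre_post          0.0  20.486995   0.903125
pre_post          3.0  20.439142   0.902723
```

The plain CA map loses ≈ 2 dB PSNR between σ = 0 and σ = 3 as noise
creates false edge points; post-processing removes the disconnected
ones, and the pre-smoothed pipeline is essentially flat — the Gaussian
filter clears the noise before the automaton sees it. The other
examples (`detect_edges.py`, `optimize_rule.py`, `batch_size_sweep.py`)
demonstrate single-image detection, rule optimization, and the
batch-size analysis; each prints the numbers it computes with a note on
their meaning. A thin CLI mirrors the library:

```
caedge synthesize --class low --n 20 --seed 42 --out-dir data/low/
caedge detect --image in.png --params p.yaml --scenario pre_post --sigma-smooth 1.5 --out edges.png
caedge experiment noise --out results/ --fast
```

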