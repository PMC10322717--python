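# camopath

Quantitative analysis of camouflage dynamics in cuttlefish skin.

Cuttlefish (*Sepia officinalis*) match their appearance to the substrate by
controlling the expansion of hundreds of thousands of pigment organs
(chromatophores), each driven by motoneurons in the brain. Filmed at 25
frames/s, the whole-animal skin pattern at each moment is a point in a
high-dimensional pattern space, and a camouflage change is a trajectory
through that space. `camopath` provides the analysis chain for this kind of
data, for researchers studying cephalopod camouflage or, more generally,
high-dimensional motor behaviour:

- **Chromatophore imaging** — difference-of-Gaussians detection, a per-frame
  focus statistic, body masking, watershed segmentation of the mean darkness
  score into chromatophore regions, per-region area time series
  (frames × chromatophores `AreaMatrix`), and artifact cleanup.
- **Pattern-space dynamics** — speed of pattern change
  `s(t) = ||x(t+dt) − x(t)||/dt` in the top 200 PCs (2 s Gaussian
  smoothing), transition-chunk detection, slow points (local speed minima)
  with dwell phases, and a test of two heading rules at each slow-point exit:
  with exit vector `v = p(n) − p(n−1)`, the angle
  `α = ∠(v, goal − p(n−1))` probes the *update* rule (re-aim at the goal
  from the current state) and `β = ∠(v, goal − start)` probes the *memory*
  rule (keep the initial direction). Rayleigh tests on α and β discriminate
  the two: both rules concentrate α near 0, only the memory rule also
  concentrates β.
- **Pattern components** — chromatophores embedded by their loadings on the
  top 50 PCs of the z-scored area matrix, k-nearest-neighbour graph (k = 10),
  Leiden community detection; component stability across trials scored by
  matched-pair intersection-over-union, Wallace coefficients and the adjusted
  Rand index against the distance between transitions; reconstruction power
  as the variance explained after replacing every trace by its component
  mean; spatial interdigitation via occupancy-histogram overlap and
  earth-mover (Wasserstein) distance.
- **Blanching** — threat-evoked whole-body paling: trial selection, fast
  outward/return phases, per-chromatophore recruitment onsets and ranks
  during recovery, rank-density histograms with the analytic bin s.d.
  `σ = sqrt(Σᵢ pᵢ(1 − pᵢ))`, Kruskal–Wallis plus permutation tests of
  component rank order, hierarchical clustering of blanched vs final
  patterns (pattern memory), and trajectory curvature `||T(n+1) − T(n)||`
  after arclength reparameterization.
- **Texture statistics** — Fourier slope/intercept (FFT-α, FFT-β), isotropy,
  autocorrelation half-height frequency, Weibull contrast energy and spatial
  coherence, contrast skewness/kurtosis; canonical correlation between
  background and skin features; GLM deviance-reduction model comparison.
- **Dimensionality** — parallel analysis: the number of leading PCs whose
  eigenvalues exceed a column-shuffled null.
- **Synthetic data** — every fixture the pipeline needs (rendered disc
  scenes, planted-component area series, meandering/ballistic trajectories,
  blanching trials with planted recruitment order, checkerboard and 1/f
  textures, looming-stimulus profiles `r(t) = d·(l/v)/τ`), with exported
  ground truth.

## Worked example

Run the packaged demo pipeline (synthetic scene of 150 chromatophores, 3
planted components, one planted update-model transition and one blanching
trial):

```bash
camopath run --out demo --seed 7
```

The stage summaries in `demo/*_summary.json` read, in part:

```
segment        n_regions: 150          mean_region_area: 52.05
components     k: 3                    ari_vs_truth: 1.0
               explained_variance: 0.999   shuffled: 0.371
dynamics       n_slow_points: 8        model: "update"
               alpha_rayleigh: {rbar: 0.985, p: 0.0}
               beta_rayleigh:  {rbar: 0.027, p: 0.994}
blanching      recovered_order: [2, 0, 1]   true_order: [2, 0, 1]
               kruskal_H: 140.5, kruskal_p: 3.1e-31
dimensionality n_significant: 3
```

Reading these: the watershed recovered all 150 rendered chromatophores; the
Leiden decomposition found exactly the 3 planted components (adjusted Rand
index 1.0), and replacing each chromatophore by its component mean preserves
99.9% of the trajectory variance (37% for shuffled groupings); the
transition trajectory is classified as *update*-driven because α is tightly
concentrated at 0 (Rayleigh R̄ = 0.985, p ≈ 0) while β is indistinguishable
from uniform (p = 0.99); recruitment after blanching follows the planted
component order with a highly significant Kruskal–Wallis rank separation;
and parallel analysis reports the 3 planted temporal dimensions.

Running the same command twice with the same seed produces byte-identical
summaries.

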