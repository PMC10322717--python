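# Methods

This note documents the models, conventions and design choices behind
`camopath`, and what the synthetic-data generators do and do not emulate.

## Data model and conventions

The central object is the `AreaMatrix`: a frames × chromatophores matrix of
non-negative expansion states at a fixed sampling rate (default 25 frames/s,
the acquisition rate of the imaging system this pipeline targets). Frame `i`
maps to time `i / rate` seconds, frame 0 is t = 0. Invalid (blanked or
artifact) frames carry a per-frame mask and are excluded from every
statistic rather than zero-filled. Images use row-major, 0-based pixel
coordinates with the origin at the top-left. CSV is the interchange format
(header row of integer chromatophore ids, `NA` marks invalid frames, floats
written at full `%.17g` precision so round trips are exact); a compressed
`.npz` container serves as the binary format.

## Chromatophore imaging

Chromatophore-scale features are detected with a difference of Gaussians,
convention `G(s1)∗I − G(s2)∗I` with the sigma pair (2, 1) px by default.
These values are calibrated to a mean chromatophore footprint of 54 px and
should be rescaled proportionally for other magnifications. The per-frame
focus statistic is the **sum of |DoG|** over pixels: the raw DoG integrates
to approximately zero on any frame, so the absolute value is what carries
the band energy. The in-focus threshold is dataset-specific and deliberately
has no default.

The body mask thresholds the 25 px-smoothed band energy. Because band energy
concentrates on boundaries, the thresholded foreground is hole-filled before
the largest connected component is taken.

Segmentation runs a watershed on the inverted time-averaged darkness score,
seeded at regional maxima of the score smoothed with sigma = 1 px
(minimum seed separation 3 px; plateau ties resolve by first-scan order, so
the result is deterministic). Intensity rather than a distance transform is
flooded; both are plausible and the choice is exposed through the score
argument. Regions under `min_region_px = 9` pixels (the smallest credible
chromatophore at the 54 px mean) are dropped and flagged. Areas are the sum
of the (fractional) darkness score within each region, so a probabilistic
per-pixel score yields sub-pixel area resolution, and the per-frame total
score is conserved between regions and unassigned pixels.

Compression artifacts (sharp periodic spikes in PCA-space speed, detected at
median + 8·MAD) are removed either by blanking a symmetric 10-frame window
(5 before through 4 after the spike) or by a centered 1 s median filter; the
median filter is the right choice when per-frame activation order matters.

## Pattern-space dynamics

Speed is the per-frame displacement norm in the top 200 PCs divided by the
frame interval, assigned to inter-frame midpoints, then smoothed over a 2 s
window. The smoothing kernel is a **Gaussian** (sigma = window/4, NaN-aware
normalized convolution, output invalid where more than half the kernel mass
is missing). A boxcar average was rejected because it is not a scale-space
kernel: it can create local minima as the window widens, which would break
the slow-point count's monotonicity in the smoothing width.

Slow points are interior local minima of the smoothed profile (plateau
minima resolve to the plateau midpoint). Around each minimum the
deceleration/acceleration segment is split fast/slow at the segment's 25th
speed percentile; the dwell interval is the contiguous slow run containing
the minimum. Transition chunks grow around candidate frames (cluster-label
jumps of a k-means partition, or speed above mean + 1 s.d.) to the
surrounding above-baseline interval, with the whole-recording mean as the
baseline, and merge across gaps shorter than 20 s unless a background
switch intervenes.

Heading angles are measured in the top-2-PC plane, signed via
`atan2(cross, dot)`. The goal defaults to the trajectory's final frame (the
stabilized pattern) and the start to its first; both are overridable. The
model classifier exploits the asymmetry of the two rules' predictions: the
update and memory rules both concentrate α near 0, but only the memory rule
also concentrates β, so a trajectory is called *update* exactly when the
Rayleigh test does not reject uniformity of β at the 1% level. The Rayleigh
p-value uses the standard series approximation, clipped to [0, 1] (the
series degenerates below zero at large z with small n).

Pattern-change duration is bounded by the first upward and last downward
crossing of baseline + 10% of (peak − baseline), with linear interpolation
between samples; the baseline defaults to the mean speed over a 10 s
pre-event window. A per-pulse mode reports each above-threshold pulse
separately.

## Pattern components

Chromatophores are embedded by their loadings on the top 50 PCs of the
**z-scored** area matrix (each chromatophore centered and scaled by its own
s.d. — without this, large chromatophores dominate the covariance).
Communities of the symmetric unweighted 10-NN graph are found by Leiden
with the RBConfiguration objective and a fixed seed. The resolution defaults
to 2.0, the value appropriate for decomposing populations of tens of
thousands of chromatophores into ~30 components; 0.5 is used for blanching
analyses. On desk-scale synthetic populations (~150 chromatophores, K ≤ 8
planted components) resolution 2 systematically over-splits any community
holding more than about a third of the graph — a property of the
configuration-null scaling, not of the data — so the demo pipeline and the
planted-recovery analyses run at resolution 1.0.

Partition matching defaults to greedy pairing by descending shared
chromatophore count (ties toward the smaller label pair); an optimal
linear-assignment matcher maximizing summed IoU is available and is what the
optimality checks compare against exhaustive enumeration. Mean IoU averages
matched pairs; Wallace coefficients (both directions) and the adjusted Rand
index are computed over the full partitions.

Reconstruction variance replaces each trace by its component's mean trace
and reports the explained fraction
`1 − Σ||P(x) − P(x̃)||² / Σ||P(x)||²` in the trajectory's own top-200-PC
space; a singleton partition reconstructs exactly, and a fully
anticorrelated pair under one label explains nothing — both are enforced to
numerical tolerance. Component activity is judged on the mean z-scored
trace: a component is active when that trace changes by more than 1 (i.e.
one per-chromatophore s.d.) between the 0.2 s endpoint averages of the
window.

Spatial interdigitation uses cosine overlap of 2-D occupancy histograms
(bin 16 px by default), mean pairwise distance, and the earth-mover
distance with Euclidean ground metric in pixels; clouds are equalized by
subsampling (cap 1,000 points, logged) so the linear-assignment solution is
the exact optimal transport for uniform weights.

## Blanching

Trials enter the analysis when the mean chromatophore size drops below 90%
of its starting value within the first 2 s; trials whose blanching minimum
stays above 50% of start are low-vigour — kept for return-speed statistics,
excluded from component analyses. The return segment starts at the global
minimum of the mean area (maximum blanching). Recruitment selection and
onsets both use chromatophore-wise min–max normalization (the 0.15 increase
filter and the 0.1 upward-crossing threshold share this normalization);
onsets follow a 1 s Hann smoothing, and ranks use the average method for
ties. Per-trial ranks are normalized to [0, 1] before cross-trial
aggregation so trials with different numbers of recruited chromatophores are
commensurable. The rank-density s.d. formula σ = sqrt(Σ pᵢ(1−pᵢ)) treats
each chromatophore as an independent Bernoulli indicator per bin with
Normal(μᵢ, σᵢ) rank; Normal mass outside [0, 1] belongs to no bin, and
σᵢ = 0 is a point mass.

The component rank-order test is Kruskal–Wallis on component-wise
collections of chromatophore mean ranks, with post hoc pairwise
label-permutation tests (1,000 permutations by default) and
Benjamini–Hochberg correction. The permutation is flat at the chromatophore
level rather than hierarchical by trial; this is anticonservative when ranks
are correlated within trials, and the output carries that flag.

Pattern-memory clustering takes 0.4 s (10-frame) averages at the blanch and
end events, clusters each set hierarchically (correlation distance, complete
linkage), and reports the Pearson correlation between the two trees'
cophenetic distance matrices plus a Mantel test (Pearson on vectorized
distances, permutation of trial labels, 9,999 permutations by default).

Curvature reparameterizes each trial by arclength: coordinates are
PCA-rotated per trial, dwell samples (zero displacement) collapsed, cubic
splines (scipy's not-a-knot boundaries) fit against cumulative arclength and
resampled at unit arclength steps (1 feature unit, configurable), and the
curvature per step is the norm of the difference of successive unit
tangents — `2·sin(Δs/2R)` on a circle of radius R, zero on a line, invariant
to rigid motion and to how fast the path was traversed. For blanching
trials, curvature is computed over the fast phases only.

By-trial vs all-trial generalizability fits Leiden partitions per trial and
on the time-concatenated pool, reconstructs each trial under both, and
reports the per-trial ratio plus a shuffled control. Camouflage trial
subsets are selected by Ward linkage on pairwise symmetric Hausdorff
distances in the first two PCs, cut at a dataset-dependent cophenetic
distance (default 100 feature units).

## Texture statistics

The radially averaged 2-D power spectrum is fit with a line in log–log over
4 cycles/image to half Nyquist (the low-frequency end is dominated by the
image envelope, the high end by pixel noise). FFT-α is the slope (≈ −α for
1/f^α noise), FFT-β the intercept, FFT-peak the largest in-band residual.
FFT-iso is the major/minor axis ratio of the top-energy region holding 60%
of spectral energy in the smoothed, DC-removed 2-D spectrum (level-set
reading of the 60%-energy contour; ≈ 1 for isotropic images). The
autocorrelation comes from the inverse FFT of the power spectrum
(Wiener–Khinchin); its radial profile's first downward 0.5-crossing at lag L
gives auto-freq = 1/(2L) cycles/pixel, with the lag floored at half a pixel.
Contrast moments use a 5×5 difference-of-Gaussians kernel (sigma pair
(2, 1)) and **Pearson conventions** (a Gaussian has kurtosis 3). Weibull
contrast statistics fit `weibull_min` by maximum likelihood (location pinned
at 0) to absolute band-pass contrast at three dyadic scales and average the
fitted (scale, shape) = (CE, SC).

The high-dimensional feature extractor is pluggable; the default is an
untrained 4-orientation × 4-frequency Gabor band-energy bank plus four
intensity moments (length 20, deterministic), so the package carries no
trained weights. A deep extractor can be registered under its own id.
Stimulus–response CCA reduces both sets to 50 PCs and solves the canonical
system by QR/SVD; significance of the leading correlation is assessed by row
permutation (1,000 shuffles by default) rather than a parametric test. GLM
comparison fits Gaussian linear models per response dimension under 3-fold
cross-validation and reports out-of-fold deviance reduction
`1 − RSS/RSS_null` averaged over folds and repeats; singular designs fall
back to the minimum-norm solution with a warning.

## Dimensionality

Parallel analysis standardizes features (zero-variance columns dropped with
a warning), takes correlation-matrix eigenvalues (population normalization,
so the spectrum sums to the feature count), builds the null by independently
permuting each column (fresh permutations per round, 100 rounds, 95th
percentile by default — the percentile and round count are reported in the
result), and counts leading eigenvalues above the null, stopping at the
first failure. The method is known to undercount linear dimensionality above
roughly 20 (the planted-rank-40 check asserts only non-overestimation); a
PCA 90%-variance benchmark is provided as a linear comparison.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed) and export the ground
truth needed to score every downstream stage. Scenes place gamma-distributed
disc areas (mean 54 px, CV 0.2) without overlap by rejection sampling;
rendering selects exactly the nearest ⌊area⌉ pixels to each center
(deterministic tie-break), so rendered pixel count tracks the planted area
exactly and segmentation accuracy is attributable to the segmenter, not the
renderer. Planted-component series add iid Gaussian noise to shared
component loadings, clipped at zero; heavier-tailed noise is available as an
option. Trajectories move between waypoints with raised-cosine speed
(sin² profile), so planted slow points are unambiguous local minima, and
dwell at each waypoint; the update rule covers the full remaining distance
per step with angular noise on the heading (so the miss direction
randomizes step to step, reproducing the α-tight/β-spread signature), while
the memory rule keeps the fixed initial heading and ends wherever it ends —
its endpoint is the measured goal. Blanching trials drop all areas to a
stated fraction over 0.5 s and re-expand components in a planted order with
1.5 s staggered onsets and optional per-chromatophore jitter. The looming
stimulus follows r(t) = d·(l/v)/τ from the frame where the angular size
equals the onset angle to one frame before collision; l/v is a free input
because the mapping from printed collision times to l/v is
apparatus-specific.

None of this emulates real skin: no papillae or 3-D texture, no light
chromatophore classes, no photometric variation, no body motion or
alignment error, and component membership is exactly constant within a
trial. Passing the planted-recovery checks therefore demonstrates
correctness of the analysis chain under its own assumptions, not performance
on real imagery — on real data, alignment error, flicker and non-stationary
component structure will dominate.

## Problem sizes

The packaged demo and the reproduction script run at desk scale: scenes of
100–150 chromatophores, 300–1,100-frame series, 100-trajectory model
ensembles, 2,000 × 100 matrices for parallel analysis, and 1,000-simulation
calibration runs. These sizes were chosen so the statistical properties
under test (recovery rates, type-I error within ±2 points) are resolvable
while a full run stays in the tens of seconds.
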