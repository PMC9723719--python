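# Methods

This note documents the statistical models implemented in `sarcycle`, the
defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Community handling

A `CountMatrix` is a samples × ASVs table of non-negative integers with one
calendar date per sample. Rarefaction subsamples each retained sample to a
common depth without replacement (multivariate hypergeometric), so the
rarefied relative abundance of an ASV is an unbiased estimate of its
pre-rarefaction relative abundance. The default depth is the minimum total
among samples with at least 1000 reads; shallower samples are dropped first
and reported. A single seeded draw is used (not repeated/averaged
rarefaction); the tests check the estimator's unbiasedness against the
hypergeometric expectation.

Ecotype aggregation sums member-ASV counts under a fixed label vocabulary
(Ia.1, Ia.3, Ia.4, Ib, Ib.2, I, II, IIa, IIa.A, IIa.B, IIb, IIIa, IV,
other); labels outside the vocabulary are coerced to `other` with a warning
rather than an error, to tolerate annotation dialects. Aggregation
conserves per-sample totals exactly.

## Time-decay curves

All unordered sample pairs contribute one Bray-Curtis dissimilarity at lag
`|dateᵢ − dateⱼ|` in whole days; pairs are grouped by identical lag (no
tolerance binning) and averaged. The curve is summarised by an ordinary
least-squares fit of `df = 4` exactly periodic cubic B-splines with period
366 days. The basis is built on uniform knots with spacing `period/df` and
made circular by folding the wrapped columns of the open design matrix, so
every basis function satisfies `B(t) = B(t + period)` to machine precision.
The basis forms a partition of unity; the intercept column is therefore
collinear with it and the system is solved by minimum-norm least squares,
which leaves the fitted values unique. The half-period of community
turnover is read off the fitted curve as the smallest positive lag at which
it attains a local maximum on a 1-day grid — peak detection on the smooth
fit, not the noisy lag means.

## Per-ASV seasonality

Fisher's exact G-test assumes evenly spaced observations, so each ASV
series is first linearly interpolated onto a regular grid (7 days for
weekly designs, 30.4375 days for monthly). The periodogram is
`I(f_k) = |DFT(y − ȳ)|²/N` at Fourier frequencies `k = 1..⌊(N−1)/2⌋`
(zero and Nyquist excluded), and

    g = max_k I(f_k) / Σ_k I(f_k),
    P(G > g) = Σ_{j=1}^{⌊1/g⌋} (−1)^{j−1} C(m, j) (1 − j g)^{m−1},

accumulated on the log scale and clipped to [0, 1]. The type-I error of
this closed form is verified by simulation in the tests (0.05 ± 0.01 at
α = 0.05, N = 100, 2000 runs).

p-values are adjusted across ASVs with Benjamini–Hochberg by default
(`none` and `bonferroni` are available); the screening rule is
`q < α` **and** harmonic-model F-test `p < α`, combining the spectral and
regression evidence. The harmonic design uses two anchored annual
predictors: `Xc = cos 2πt` with `t = d/365` and `d` the days since the most
recent December 21, and `Xs = sin 2πt` with `d` the days since January 1;
leap days are ignored (`t = d/365` exactly). Both harmonic terms are fitted
jointly. The fitted seasonal component `β_c·Xc(d) + β_s·Xs(d)` is evaluated
on a 1-day grid over the year; its argmax is the peak day, and an ASV is
"summer" when the peak falls in the warm window May 2 – September 21
(0-based days 121–263), otherwise "winter". Relative abundances enter the
regression untransformed.

## Ordination and clustering

PCoA applies Gower double-centering to `−d²/2` and eigendecomposes;
negative eigenvalues (Bray-Curtis matrices are generally non-Euclidean) are
discarded without Lingoes/Cailliez correction, keeping the constrained
proportion interpretable. db-RDA regresses the principal coordinates on the
column-standardized environmental design (collinear columns dropped
greedily with a warning); the constrained inertia is the inertia of the
fitted values, and the constrained axes are the PCA of those fitted values.
Because Ezekiel's adjustment is undefined for non-Euclidean dissimilarities,
adjusted R² is computed by permutation: the mean R² of 999 row-permuted
designs is subtracted and the remainder rescaled. Biplot scores are the
correlations of each variable with the constrained axes.

PERMANOVA partitions squared dissimilarities by group
(`F = (SS_b/df_b)/(SS_w/df_w)`), with seeded label permutations and
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`; with 999 permutations the
smallest attainable p is 0.001. The implementation is checked against
exhaustive enumeration on six-sample instances and against an independent
reference implementation.

Hierarchical clustering uses average linkage (UPGMA) by default; samples
are processed in sample-id order so merge ties resolve identically for any
input ordering. Clusters are annotated warm/cold by the share of their
sampling dates inside the warm window. The dendrogram serializes to Newick.

## Environment coupling

Sampling dates are reassigned to the nearest Monday (offsets of 0–3 days
snap backwards, 4–6 forwards, so no date moves more than 3 days); when two
samples collide on one Monday the nearer original date wins. Gaps in the
resulting 7-day grid are filled by linear interpolation (per ASV for the
community, per variable for the environment), and interpolated weeks are
flagged. Week-to-week change is summarised as consecutive-sample distances:
Bray-Curtis for community composition, Euclidean over the 17
min–max-standardized variables for the environment
(interpolate-then-distance; the alternative order is not used). Wavelet
analysis is performed on these two change series.

The continuous wavelet transform uses the analytic Morlet mother with
ω₀ = 6 (Fourier period ≈ 1.033·scale), computed by FFT on a dyadic scale
grid of 1/20-octave steps covering periods from 2 weeks to half the record.
Squared coherence is

    R²(s, t) = |S(W_x W_y*/s)|² / (S(|W_x|²/s) · S(|W_y|²/s)),

with smoothing `S` a Gaussian in time and a 0.6-octave boxcar across
scales. The time-smoothing width is 2 scales (standard deviation of the
Gaussian); the wider-than-minimal window favours sustained season-scale
coherence and gives the Monte-Carlo null more degrees of freedom, and the
null calibration is re-verified in the tests (≤ 5% significant cells on
independent noise). Significance is the cell-wise 95th percentile of
coherence over 100 white-noise surrogate pairs (white noise rather than
AR(1), exposed as a config choice); the cone of influence excludes cells
whose scale exceeds `edge distance / √2`.

A week's coupling score is the fraction of reliable (in-COI) scales that
are simultaneously significant and in phase (|Δφ| < π/4); a centered
12-week rolling mean at or above 0.2 labels the week coupled, and
contiguous runs are reported as intervals. Environmental variables are
compared between coupled and uncoupled weeks with two-sided Mann–Whitney U
tests and BH adjustment.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw sequence data.

**Environment.** 17 named variables on a monthly or weekly grid:
temperature is an annual sinusoid (mean 13.4 °C, amplitude 5 °C, trough in
mid-February, matching a temperate coastal range of roughly 8–19 °C) plus
weekly anomalies; nitrate, silicate and phosphate cycle in anti-phase with
temperature and are floored at zero; chlorophyll has a spring Gaussian
bloom; wind and river flow are lognormal with levels scaled by a per-year
storminess factor. Short-term variability is synoptic: one shared
"weather anomaly" process (AR(1), ρ = 0.3) loads on most variables — storms
raise wind, river flow and turbidity, depress pressure, and perturb
temperature simultaneously — while idiosyncratic noise is a smooth AR(1)
(ρ = 0.85) completing a unit variance budget per variable. The weather
anomaly's innovation amplitude is modulated with a 16-week period
(depth 0.8), alternating calm and stormy spells; this gives the
environmental change series its dominant oscillation band.

**Community.** Seasonal ASV `i` has log-affinity

    log aᵢ(t) = A·cos(2π(doyₜ − peakᵢ)/365) + rᵢ(t) + baseᵢ,

with amplitude `A = 1.5` (dominant taxa swing over roughly an order of
magnitude across the year), peaks scattered around mid-July and mid-January
(sd 10 days), and lognormal base abundances (sd 1) giving the uneven
rank-abundance structure typical of amplicon data. `rᵢ(t)` is a
mean-reverting weather displacement: each week every seasonal ASV takes a
random step with standard deviation `0.6·|Δu(t)|`, where `u` is the
standardized temperature anomaly — larger environmental changes displace
the community further, in an unpredictable direction, and the displacement
decays with factor 0.7 per week. `coupling_strength` blends this same-week
signal with its own 8-week moving average: at 1 week-scale community change
mirrors week-scale environmental change; at 0 only the smoothed trajectory
remains, decoupling the two timescales while preserving the annual cycle.

Aperiodic ASVs hold a fixed expected share (0.4) of the community with
fixed uneven weights, and the seasonal guilds trade off within the
remainder. This closure-by-construction matters: if aperiodic taxa simply
had constant affinities, renormalization against the seasonally varying
guild total would imprint an annual signal on them and the false-positive
rate of the seasonality screen would be meaningless.

Counts are Dirichlet-multinomial: proportions drawn with concentration
`200 × expected` (amplicon-scale overdispersion) and totals lognormal
(median ≈ 2·10⁴ reads). All randomness derives from the config seed;
identical seeds give identical datasets.

Presets: `bats_like` (monthly, 3 y), `wec_like` (weekly, 7 y, 10% missing
dates, ±2-day sampling jitter), `coupled_year` (weekly, 2 y, coupling 1,
low storminess) and `decoupled_year` (coupling 0, high storminess).

**What the generator does not emulate:** sequencing error and chimeras,
primer and platform biases beyond library-size differences, taxa appearing
or disappearing across years, trends or regime shifts in the environment,
autocorrelated Dirichlet noise, and phylogenetic structure among ASVs.
Passing tests therefore demonstrate that the pipeline recovers the planted
structure under realistic sampling noise — not that real communities obey
this model.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data at
the scale of the emulated designs: ~330 weekly samples for the multiannual
analyses, 104-week records for coherence (100 surrogate pairs per map),
2000 white-noise series for the G-test calibration, and 10⁴ draws for the
rarefaction oracle. Every stochastic step (rarefaction, permutations,
surrogates, the generator itself) takes an explicit seed, and the pipeline
manifest records input/output hashes so a rerun with the same config and
seed reproduces identical files.

## Known limitations

- Fisher's G-test is applied after linear interpolation onto a regular
  grid; heavy gap interpolation mildly reddens the spectrum and the test is
  exact only under Gaussian white noise. Lomb–Scargle for irregular series
  is noted as an alternative but not implemented.
- The coherence significance is pointwise (cell-wise quantiles), not
  corrected for the multiplicity of the time–period plane; the coupling
  score aggregates over scales precisely to damp isolated false cells.
- db-RDA discards negative-eigenvalue axes, so a small part of the
  Bray-Curtis structure is invisible to the constrained model.
- The warm/cold annotation of clusters assumes the two-cluster cut aligns
  with the seasons; for k > 2 the per-cluster majority rule can label
  several clusters identically.
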