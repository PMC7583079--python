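# Methods

This note records the statistical model behind `temposig`, the defaults and
why they are set where they are, and the numerical choices a maintainer
would otherwise have to reverse-engineer.

## Data model

The central object is an m×n matrix of log occupancy ratios over a strictly
increasing time axis (default emulation: days 1, 3, 5, 7, 10, 14). Cells may
be missing, but every variable must have at least one observation. When the
input arrives as a replicate-level long table, treated and control
occupancies are paired by replicate index; each matched pair with a positive
control contributes the ratio treated/control, and the cell is log (base 2
by default) of the mean ratio. Pairs with a zero control occupancy are
discarded rather than imputed as infinite; a (variable, time) with no usable
pair becomes a missing cell. Replicates are never cross-paired: an
unmatched replicate is dropped, because inventing a pairing would fabricate
covariance structure.

The fold-change pre-filter removes variables whose dynamics never reach the
threshold (default 1.2-fold) in either direction: keep variable *i* iff
max over observed t of |cell(i,t)| ≥ log_b(threshold). The filter is
two-sided on the magnitude because the purpose is to remove variables with
*no* dynamic range, regardless of direction, and it is idempotent by
construction. It operates on the collapsed log-ratio matrix, i.e. after
replicate averaging.

## Preprocessing

### Cubic regression splines

Each variable with ≥ 4 observed points is fit by a least-squares cubic
B-spline whose flexibility is indexed by its degrees of freedom = number of
basis functions: dof 2 is a straight line, 3 a quadratic, 4 a cubic with no
interior knots, and dof k ≥ 5 adds k−4 interior knots at quantiles of the
observed times. This regression-spline family was chosen over a penalized
(natural) smoothing spline because its dof semantics are exact and
discrete — dof 2 reproduces any line exactly, dof 4 any cubic, dof equal to
the number of observations interpolates — which makes cross-validated
selection over the default grid {2, 3, 4, 5} directly interpretable at
n = 6. A natural smoothing spline cannot represent even a cubic exactly
(its boundary conditions force zero second derivatives at the ends), so
"the fit at dof 4 recovers a cubic" would only hold approximately.

Outside the observed time range the fitted curve is continued **linearly**
with its boundary slope. Cubic extrapolation at a missing boundary cell is
numerically explosive (a cubic through 4–5 interior points can swing by
several signal amplitudes by day 14) and, before this choice was made,
seeded the completed matrix with outliers that dominated Euclidean
clustering. Linear continuation is the behaviour natural splines exhibit
and is the conservative default for imputation.

### Cross-validated dof selection

Leave-one-observation-out per variable, summing squared prediction errors;
`global` mode picks one dof minimising the total over all eligible
variables (≥ 5 observations), `per_variable` minimises per row. Only
*interior* observations are held out: deleting a boundary point would score
cubic extrapolation rather than interpolation, and that error term is so
large for dof ≥ 4 that it forces the global choice to dof 2 (pure lines)
regardless of the data. Numerically tied errors (e.g. all zero on noiseless
data) break toward the smallest dof.

### PCA route, SVDImpute and NIPALS

The alternative route completes the matrix and reconstructs it from its top
r principal components of the row-centered matrix (centering isolates
temporal shape from a variable's overall level; the centers are restored
afterwards). `r="auto"` takes the smallest rank capturing ≥ 90% of the
variance.

*SVDImpute*: missing cells start at their row mean (column mean fallback)
and are repeatedly overwritten with the rank-r truncated-SVD reconstruction
until the change of the imputed cells, relative to the overall matrix norm,
drops below 1e−6 (at most 100 iterations; non-convergence returns the best
iterate with a warning). Observed cells are never altered.

*NIPALS*: components are extracted sequentially by alternating regressions
that skip missing cells, deflating after each. With missing data the purely
sequential pass is biased (each component's masked regressions leak error
into the deflation), so the factors are polished by alternating least
squares over the observed cells and re-orthogonalised through an SVD of the
reconstruction; on an exactly low-rank matrix this drives the completion to
numerical accuracy.

### Quality control

The preprocessed matrix is compared with the input over the originally
observed cells: per-variable Pearson correlation (rows with < 3
observations or zero variance on either side are excluded from the Pearson
median and counted) and per-variable mean squared difference, summarised by
medians. On the default synthetic study (snr 4, 15–20% missing) the median
Pearson is ≈ 0.98 and the median MSD a fraction of the noise variance.

A limitation worth stating: cells imputed at the *boundary* of the time
axis are extrapolations. Their RMSE is ≈ 4σ on curved templates at snr 4,
versus ≈ 1.3σ for interior imputations; consequently a per-row bound like
"MSD below σ² for 90% of rows" is unattainable at 20% missingness — even
with exactly-quadratic truths only ~76% of rows meet it, because rows that
lose a boundary cell carry leverage > 1. The tests therefore assert the
median characterisation.

## Clustering

K-means is Lloyd's algorithm with k-means++ seeding, best of 20 restarts by
WCSS (scikit-learn's implementation behind the module's interface), with
clusters renumbered by descending size for stable reporting and centers
recomputed as exact label means. Hierarchical clustering builds the
agglomerative tree from pairwise Euclidean or DTW distances (average,
complete, or — Euclidean only — Ward linkage) and cuts at K groups. DTW is
the classical cumulative-cost recursion with squared pointwise cost, steps
{match, insert, delete}, an optional Sakoe–Chiba band, and no path-length
normalisation; the returned value is the square root of the terminal cost,
so it coincides with (and never exceeds) the Euclidean distance for
equal-length series. Only equal-length series are supported: the platform's
time axis is shared by construction.

K selection is advisory. `wcss_scree` reports WCSS over a K range and
`elbow_k` implements the max-second-difference heuristic, but nothing picks
K silently — at these problem sizes the scree bends gradually and the
final choice (K = 5 in the motivating study) is a judgment about pattern
distinctness. Profiles are clustered as-is (log ratios on a shared scale);
a z-scoring flag exists but is off by default.

## Jackstraw evaluation

### Scheme

Observed statistic: the regression F of each row on its assigned cluster
mean. Null synthesis, B iterations: draw s rows without replacement,
replace each by a permuted copy of itself (destroying temporal association
while preserving the marginal distribution), re-cluster, and record the
permuted rows' F against their newly assigned centers. Defaults
s = ⌈0.1·m⌉ and B = ⌈10000/s⌉, giving an add-one empirical p-value
resolution of ~1/10001. A perfect fit (RSS = 0) is capped at a large finite
sentinel so ordering against the null pool stays defined.

Two symmetry refinements proved necessary for calibration; both exist so
that synthetic nulls traverse *exactly* the pipeline the observed rows
traversed:

1. **Restart symmetry.** The observed clustering is the best of R
   restarts; a null re-clustering warm-started at the observed centers
   alone lacks that selection pressure, leaving observed F stochastically
   larger than null F (pooled p-values anti-conservative, KS ≈ 0.06
   against uniform at m = 500). The re-clustering therefore takes the
   better, by WCSS, of the warm start and a fresh best-of-R fit; pooled
   KS drops to ≈ 0.015 and the type-I error at 0.05 sits in [0.03, 0.07].

2. **Preprocessing symmetry** (`jackstraw_membership`). When the
   clustering was computed on spline-smoothed data, membership F-statistics
   are evaluated on the *imputed-but-unsmoothed* matrix while clustering
   and re-clustering stay in the smoothed space. Evaluating F on the
   smoothed matrix itself is powerless at n = 6: with CV-chosen dof 3 all
   rows live in an effectively two-dimensional centered space where any
   null row chance-aligns with some center. Conversely, comparing raw
   observed rows against raw permuted rows ignores that observed rows
   carry self-consistent imputed cells and were assigned via their smooth
   profiles. The null construction therefore permutes each selected row's
   *observed* values among its observed positions, keeps its missing
   pattern, re-imputes/re-smooths it with the same per-row spline, and
   only then re-clusters. With this mirror the planted-noise rows' p-values
   are uniform (median ≈ 0.5) and, at the default study conditions
   (m = 1000, snr 4, 15% missing, 10% noise rows), ≥ 94% of true members
   get PIP > 0.8 while ≥ 81% of noise rows fall at or below it across
   probe seeds.

### π₀, local FDR, PIPs

π₀ is Storey's estimator π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ ∈ {0.05, …, 0.95}, smoothed by a cubic polynomial weighted by √(1−λ)
(the variance of π₀(λ) grows like 1/(1−λ)) and read as the mean of the
smoothed curve over the top five grid points, clamped to [1/m, 1]. Reading
a single extrapolated value at λ = 0.95 is noise-dominated below m ≈ 2000
and occasionally collapsed to the clamp. Below m = 20 the estimator returns
the conservative π₀ = 1 with a warning.

The p-value density is an equal-width histogram (bin count
min(50, max(10, m/50))) made monotone non-increasing by
pool-adjacent-violators; lfdr(p) = π₀/f̂(p) clamped to [0, 1], and
PIP = 1 − lfdr exactly. Monotone f̂ guarantees lfdr is non-decreasing in p.
Selection retains PIP strictly greater than the threshold (default 0.8).
BH q-values over the jackstraw p-values are reported alongside but never
drive selection.

## Enrichment summary

Selected variables are grouped by (cluster × biological function). Counts
are reported at two granularities — modification events and distinct host
proteins — but the hypergeometric upper-tail test runs at the **protein**
level (universe, function set, cluster draw and overlap all as distinct
proteins), because several events on one protein are not independent
evidence. The default universe is the proteins hosting at least one
selected variable (configurable to the full annotation map). BH adjustment
runs jointly across all emitted cells; a cell is flagged at q < 0.05.
Under random label permutations the significant fraction at nominal 0.05
is ≈ 2–4% — the discrete protein-level test is conservative, never
anti-conservative.

## Synthetic study generator

The generator emulates the motivating study's design: m ≈ 1600 variables,
time points (1, 3, 5, 7, 10, 14), 4 replicates, log₂ treated/control
ratios, scattered missing cells with every row keeping ≥ 4 observations.
Five default templates mirror the temporal patterns the platform is built
to separate (continual descent, continual ascent, early descent then
plateau, late accelerating ascent, early ascent relapsing to baseline).
Each template is scaled to unit standard deviation over the time axis so
the snr parameter (template amplitude over noise sd, default 4) holds
uniformly across clusters instead of depending on a template's shape.
Noise is Gaussian on the log-ratio scale, consistent with the log
transform in the data model.

A `spike_noise_fraction` of rows (default 10%) are pure noise with no
temporal coherence. Their marginal scale is that of the signal rows,
√(amplitude² + noise_sd²): a near-constant row could not occur in the
matrices this emulates (the fold-change pre-filter would have removed it),
and at the measurement-noise scale the spikes would form a tight sixth mode
at the origin that K-means dedicates a center to, contradicting the K = 5
study design. The replicate-table generator inverts exactly: at zero
replicate noise, collapsing recovers the templates bitwise.

What the generator does *not* model: mass-spectrometry missingness
mechanisms (censoring, intensity-dependent MNAR), batch structure,
heteroscedastic noise across time points, and correlated variables within a
protein. Tests passing on this generator therefore certify the statistical
machinery under clean exchangeable noise, not robustness to instrument
artefacts.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: null
calibration at m = 500, n = 10, K = 3, s = 50, B = 100 pooled over 10
seeds; recovery at m = 1000; the study-sized emulation at m = 1600 with
s·B = 10,000 null draws. Every stochastic step takes an explicit seed
(package default 20200603) and is bitwise reproducible given it; pipeline
manifests record file checksums so a run directory certifies its own
reproduction.
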