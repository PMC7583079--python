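# temposig

Temporal clustering of omics time courses with jackstraw evaluation of
cluster membership.

`temposig` is for studies that profile a molecular system — proteomics,
post-translational modification occupancies, metabolomics — at a handful of
ordered time points during disease progression or treatment, and ask which
variables follow which temporal pattern. The motivating design is a cardiac
remodeling time course: occupancy ratios of protein oxidative modifications
(treated over control) measured on days 1, 3, 5, 7, 10 and 14, averaged over
4 replicates and log-transformed, giving a matrix of ~1600 variables by 6
time points with scattered missing cells.

Such matrices pose three linked problems that the package solves in sequence:

1. **Preprocessing** — missing cells and measurement noise. Each variable
   with at least 4 observations is fit by a cubic regression spline whose
   degrees of freedom are chosen by cross-validation (globally or per
   variable); evaluating the spline at every time point imputes and denoises
   in one step. Sparser variables fall back to iterative SVD imputation.
   A reduced-rank PCA route (SVDImpute or NIPALS completion, then
   reconstruction from the top *r* components) is the alternative.
2. **Clustering** — K-means (Lloyd, k-means++, best of *R* restarts) or
   agglomerative hierarchical clustering, under Euclidean or dynamic
   time warping distance. A WCSS scree table supports choosing K; the choice
   itself stays with the analyst.
3. **Evaluation** — the jackstraw test for cluster membership. Testing a
   variable against a cluster learned from the same data is circular; the
   jackstraw breaks it by repeatedly replacing *s* random rows with permuted
   copies of themselves, re-clustering, and pooling the F-statistics of
   those synthetic nulls into an empirical null distribution.

## The membership statistic and PIPs

For variable *y* assigned to a cluster with mean profile *c* over the *n*
time points, membership strength is the simple-regression F-statistic

    F = (TSS − RSS) / (RSS / (n − 2)),  TSS = Σ_t (y_t − ȳ)²,

with RSS from the least-squares fit y = a + b·c. Observed F values are
compared with the pooled empirical null (add-one estimator), giving
per-variable p-values

    p_i = (1 + #{F_null ≥ F_i}) / (1 + s·B).

The p-values feed a two-group mixture: the null proportion π₀ is estimated
with a Storey λ-grid estimator (smoothed, clamped), the p-value density
f(p) by a monotone histogram (pool-adjacent-violators), and the local false
discovery rate is lfdr(p) = π₀ / f(p). The **posterior inclusion
probability** PIP = 1 − lfdr is the probability that a variable genuinely
follows its cluster's temporal pattern; selection retains variables with
PIP above a threshold (0.8 by default). A hypergeometric
over-representation test at the protein level, with Benjamini–Hochberg
adjustment across all (cluster × function) cells, summarises the selected
clusters against annotated biological functions.

## Worked example

Everything is reproducible from a seed; the synthetic generator emulates
the cardiac O-PTM study design (6 time points, 5 temporal templates, noise
spikes, missing cells) with full ground truth.

```python
import temposig as ts

spec = ts.SyntheticSpec(m=300, seed=7)          # 5 clusters, snr 4, 15% missing
matrix, truth = ts.generate_clustered_timecourses(spec)

pre, qc = ts.preprocess_spline(matrix)          # dof by global cross-validation
print(f"QC: median Pearson {qc.median_pearson:.3f}, median MSD {qc.median_msd:.3f}")

clustering = ts.kmeans_cluster(pre.values, K=5)
result = ts.jackstraw_membership(matrix, pre, clustering)
report = ts.pip_filter(result, 0.8)
print(f"pi0 {result.pi0:.3f}; retained {report.n_retained}/{report.n_input} at PIP > 0.8")
```

prints

```
QC: median Pearson 0.985, median MSD 0.030
pi0 0.071; retained 266/300 at PIP > 0.8
```

The QC line compares the preprocessed matrix with the raw input over the
observed cells — correlation near 1 and a small mean squared difference mean
the smoothing preserved each variable's temporal shape. π₀ ≈ 0.07 estimates
the fraction of variables with no real cluster membership; of this
generator's 30 planted pure-noise rows, 28 fall below the PIP threshold and
are removed, while 266 of the 270 genuine members are retained.

The same pipeline runs from the shell:

```bash
temposig synth --output-prefix example --m 300 --seed 7
temposig run --input example_matrix.tsv --outdir example_run --seed 7
# load:300 -> fold_change_filter:300 -> preprocess:300 -> cluster:300 -> jackstraw:300 -> pip_filter:268
```

The output directory is self-describing: every intermediate as TSV/JSON, the
resolved configuration, a log, and a manifest with stage counts and file
checksums (bitwise reproducible under the same seed). Subcommands
`preprocess`, `scree`, `cluster`, `jackstraw`, `enrich` and `synth` expose
the stages individually.

## Layout

- `src/temposig/data.py` — matrix container, I/O, replicate collapsing, fold-change filter
- `src/temposig/preprocess.py` — splines, CV, SVDImpute, NIPALS, PCA reconstruction, QC
- `src/temposig/cluster.py` — K-means, hierarchical, DTW, scree/elbow
- `src/temposig/jackstraw.py` — membership F, jackstraw resampling, π₀/lfdr/PIP, selection
- `src/temposig/enrich.py` — annotation maps, hypergeometric test, BH, bubble table
- `src/temposig/synth.py` — seeded generators with ground truth
- `src/temposig/pipeline.py`, `cli.py` — orchestration and the `temposig` command

`docs/methods.md` documents the statistical model, parameter defaults and
the numerical design choices in detail.
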