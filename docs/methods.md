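# Methods

## Model

A tumour's cell-level phylogeny is reduced to its earliest bifurcation,
which partitions the tumour into a "left" lineage of cell fraction `f` and
a "right" lineage of fraction `1 − f`. Alterations above the split
(truncal) are present in every cell; alterations below it are sub-clonal.
If samples are independent draws from the tumour — sample `j` lands on the
left side with probability `f` — then `i` samples cover both sides with
probability

    p_f(i) = 1 − f^i − (1 − f)^i.

Only a both-sides cohort can identify the truncal set exactly: any
one-sided cohort's shared alterations include that side's lineage-specific
ones. Consequences used throughout:

- remaining uncertainty `σ(n) = f^n + (1 − f)^n = 1 − p_f(n)`;
- information gain of one extra sample
  `Δ(n) = f^n (1 − f) + (1 − f)^n f`, which decays exponentially for
  balanced trees (`2^{−n}` at `f = 0.5`) and is nearly flat (`≈ f`) for
  strongly unbalanced ones, where `p_f(n) ≈ n f`;
- the planner's sample count: smallest `n` with `σ(n) ≤ σ_target`, found
  by exact incremental search (the closed form
  `n = ⌈1 + log2(1/σ)⌉` holds only at `f = 0.5` and is kept as a
  cross-check).

Assumptions: no back-mutation; a single relevant bifurcation (deeper
structure affects which alterations are lineage-specific but not the
both-sides argument); samples equally representative of the whole tumour.
All formulas are symmetric in `f ↔ 1 − f`, so estimates are reported on
the canonical range `(0, 0.5]`.

## Empirical statistic and inference

For a cohort of `n` samples with binary alteration calls, the minimal
clonal list is the intersection of all `n` alteration sets. The
concordance profile records, for each `i`, the fraction of the `C(n, i)`
sample subsets whose intersection *equals* that minimal list (set
equality, not size equality). Subsets are enumerated exactly below a
configurable cap (default 10^6 total; real multi-region cohorts with
n ≤ 13 are always exact) and by seeded uniform sampling above it, with the
per-size draw counts recorded in the output.

To compare with theory at finite `n`, the curve is rescaled by its value
at the cohort size:

    p̃_f(i; n) = p_f(i) / p_f(n),

which is 0 at `i = 1` and exactly 1 at `i = n`, matching the profile's
endpoints. `fit_balancing` minimizes the sum of squared residuals between
profile and rescaled curve over `f ∈ [10^{−4}, 0.5]` — a dense grid
(step 10^{−3}) followed by a bounded scalar refinement inside the winning
grid cell, accepted only when it strictly improves the grid optimum. The
procedure is deterministic; exact ties resolve toward larger `f`; a
`boundary_flag` marks estimates at either end of the search range (highly
unbalanced tumours surface as `f̂` at the lower boundary and should be
read as `f < 0.01`-style bounds). All indices `i = 1..n` enter the fit:
the `i = n` residual is identically zero and the `i = 1` residual (theory
0 vs possibly positive data) is informative and retained.

`robustness_scan` repeats profile + fit on every sample subset of size
`min_size..n − 1` (exact up to a per-size cap, then seeded sampling) and
reports the per-size `f̂` distributions as quantile tables — the tabular
equivalent of violin plots.

### Estimator bias (known limitation)

A real cohort is a *fixed* split: `k` of `n` samples on one side. Its
noise-free concordance profile is the without-replacement curve
`1 − [C(k,i) + C(n−k,i)] / C(n,i)`, which rises faster than the
independent-sampling curve being fitted. The least-squares estimate is
therefore quantized and biased: at `n = 12`, a `k = 1` split produces a
profile exactly linear in `i` (the `f → 0` limit of the curve), pinning
`f̂` to the lower boundary, while `k = 4` yields `f̂ ≈ 0.43` and `k = 5`
saturates at 0.5. Mean absolute recovery errors on noise-free simulations
at `n = 12` reach ≈ 0.10–0.13 for true `f ∈ {0.1, 0.3, 0.4}` (computed by
the parameter-recovery test in `tests/test_acceptance.py`, which asserts
a 0.05 band and accordingly fails for `f ∈ {0.1, 0.3, 0.4}` — kept as an
executable record of this limit rather than loosened).
Small-subset `f̂` distributions are correspondingly multi-modal —
competing explanations (estimator quantization vs genuine spatial
structure) cannot be separated by this model. Interpret `f̂` as a
curve-shape summary: near 0.5 = balanced, at the boundary = strongly
unbalanced, intermediate values qualitative.

## Homoplasy filtering

Binary somatic characters with ancestral state 0 are consistent with a
single tree iff no pair shows all three patterns (1,1), (1,0), (0,1)
across samples (three-gamete test). `find_conflicts` runs the test on all
pairs via integer matrix products; `filter_homoplasy` greedily removes the
alteration with the most conflicts (ties: lexicographically smallest id)
until the matrix is compatible. Greedy removal is deterministic and
removes few characters when homoplasy is sparse — the false-negative-call
regime it is meant for; minimum character removal is NP-hard and not
attempted. Filtering runs before profiling when requested (`--filter-homoplasy`).

## Simulator

`simulate_tumour` emulates multi-region cohorts: a truncal set shared by
all samples, a first split into two lineages with lineage-specific sets,
optional recursive deeper splits (each node reusing the root balance), and
sample-private alterations. Two assignment modes separate the theory's
assumption from the data's reality: `bernoulli` (each sample independently
left with probability `f`; validates `p_f` by Monte-Carlo) and
`proportional` (fixed `round(n·f)` split; what an analysis of a fixed
cohort sees). Defaults — 8 samples, Poisson counts with means 20 truncal,
15 per lineage, 5 private per sample — give ~40 alterations per sample,
in the range of multi-region exome cohorts (9–76 coding mutations per
sample). Poisson counts reflect mutation accumulation as a counting
process; fixed counts are available for exact combinatorial tests.

Noise is false-negative dropout only: each true presence is independently
zeroed with probability `dropout_rate` (sequencing depth and normal
contamination produce false negatives; false positives are not modelled).
Dropout is what injects homoplasy, exercising the filter. Not emulated:
spatial sampling geometry, selection dynamics, copy-number mechanics
(events are abstract ids), sequencing reads. Passing tests therefore show
correctness of the combinatorics and estimator on tree-structured binary
data, not robustness to spatially correlated sampling.

Determinism: one `numpy` generator seeded from `config.seed` drives
structure; matrix emission derives an independent stream from the same
seed, so identical configs give byte-identical matrices.

## Numerical choices

- Powers `f^i` are computed directly in double precision; underflow to 0
  for tiny `f` is the correct limit, and results are clamped to [0, 1].
- The fit's search range excludes `f = 0` (rescaled curve undefined) and
  `(0.5, 1)` (symmetry); grid step 10^{−3} with refinement tolerance
  10^{−7} resolves `f̂` far below the estimator's intrinsic bias.
- Subset enumeration packs each sample's alteration set into an
  arbitrary-precision integer bitmask; intersections are bitwise ANDs and
  recovery a single equality test. Problem sizes used in the test suite
  (n ≤ 12 samples, ≤ 2^12 subsets per profile, 100 recovery replicates
  per balancing value) keep the whole suite in tens of seconds.
- Degenerate inputs have defined behaviour: identical samples give an
  all-ones profile and `f̂ = 0.5` with a boundary flag and warning; an
  empty global intersection is legal and reported with a warning;
  a profile from one sample, `f ∈ {0, 1}` in the rescaled curve, and
  unrepresentable proportional splits (`round(n·f) ∈ {0, n}`) raise
  errors.
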