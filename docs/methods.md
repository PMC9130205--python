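# Methods

This note documents the models and algorithms implemented in `hgadmix`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Haplogroup nomenclature

A haplogroup label is decomposed into tokens: the first token is the
maximal leading alphabetic run (so two-letter clades like `HV` and `JT` are
single depth-1 tokens), followed by alternating maximal digit and
alphabetic runs. The *phylogenetic depth* of a label is its token count:
`H` has depth 1, `H13a` depth 3, `K1a1b1a` depth 7. Case is normalized
(leading run upper-cased, later alphabetic runs lower-cased) because
published tables mix cases.

Assignment of an observed label to a fixed basis uses token-level prefix
matching, never string prefixes: `H1` is not an ancestor of `H13a` because
the token `13` is not the token `1`. The *cumulating* rule returns the
longest basis token-prefix (preserving information carried by deep
subclades); the *cutting* rule keeps only exact basis members. A query
without a match is reported with an explicit `UNASSIGNED` sentinel; only
the frequency layer decides what exclusion means, so no information is
dropped silently at the matching layer.

## Frequency matrices

The candidate basis truncates every observed label to a maximal depth
(default 3) and deduplicates. The prevalence filter keeps a candidate only
when *strictly more* than a fraction (default 0.0005) of the whole database
is assigned to it, with counts pooled over all populations and computed
under the same assignment mode used downstream (cumulating changes pooled
counts). Frequencies are normalized by default over the *classified*
individuals of a population, so usable rows sum to one; this treats a row
as a distribution over the basis, which is what both the clustering and
the admixture model assume. Normalizing by total population size is
available as a sensitivity option (rows then sum to <= 1). Populations
with no classifiable individual are flagged unusable and excluded from
downstream stages with a warning.

## Jointly propagating haplogroup selection

Haplogroups that spread together in past migrations leave rank-correlated
frequency variation across *subsets* of populations; demography since then
erodes correlation over the full set. For each haplogroup pair the package
searches for such a subset greedily: starting from all populations, while
the Spearman correlation (average ranks for ties) is below `rho_min` and
more than `min_pops` populations remain, the single population whose
removal raises the correlation most is dropped (ties broken by lowest
population index, for reproducibility). The best configuration encountered
along the path is returned, which guarantees the result is never worse
than the all-population correlation. A pair is accepted at
`rho >= rho_min` (default 0.8) with support `>= min_pops` (default 10),
and the selected basis keeps every haplogroup with at least one accepted
partner. Greedy leave-one-out is one reconstruction of an iterative
subset search; the thresholds and the accepted pair list (with supports)
are exposed so users can audit or re-run the selection under other
settings. Populations with zero frequency for a haplogroup are kept in
the rank vectors (tied at the bottom) — absence is informative for
propagation. The leave-one-out step is vectorized (one ranked-matrix
evaluation per shrink step), which keeps the all-pairs search tractable
at a few thousand pairs.

## Central-vector clustering

Populations condense around shared ancestral profiles; the clusterer finds
those condensation centers by vector quantization with a *growth*
criterion. For a candidate number of centers N it refines
(nearest-assignment + centroid update to a movement tolerance of 1e-9,
empty clusters re-seeded at the point farthest from its own center) from
`n_restarts` (default 10) random data-point initializations plus one warm
start that splits the worst cluster of the previous N at its farthest
member; the solution with the lowest total within-cluster distance wins.
N grows from `n_start` (default 2) until every multi-member cluster
satisfies

    radius(i) < ratio * delta(i),    ratio default 1/3,

where `radius(i)` is the mean member-to-center distance and `delta(i)` the
distance to the nearest other center. Singletons pass trivially. If
`max_n` is reached without satisfaction the best solution is returned with
`converged_ = False` rather than an error. Everything is deterministic
given `random_state`.

Diagnostics: per-cluster radii; a one-sided paired t-test per cluster that
members are closer to their own center than to the nearest other center
(reported as 1 − p; clusters with fewer than 3 members or zero-variance
differences are marked not computable); the binary same-cluster
("inherence") matrix; and its Pearson correlation with a population
distance matrix over the off-diagonal upper triangle. When the clustering
matches the geometry, same-cluster pairs are the close pairs, so good
correspondence appears as a *negative* correlation; the signed value is
reported and the sign convention documented here rather than hidden in an
absolute value.

On data without real cluster structure (a continuum of admixed
populations) the radius criterion keeps splitting and the method drifts
toward many small clusters; that is a property of the stopping rule, not a
bug, and `max_n` exists to cap it.

## Admixture model

A population's frequency vector `h` is modeled as `h = Σ a_i v_i + ε` with
the weights minimizing the error power `H = Σ ε_k²`; fit quality is the
normalized error `J = H / Σ h_k²` (0 perfect, 1 the null model). The
central vectors are generally not orthogonal, so weights are not
coordinates, are not normalized to one, and may exceed one; an optional
non-negativity constraint (`nonneg=True`, projected gradient / NNLS)
supports the strict admixture-proportion reading but is off by default
because nothing in the model requires it.

The reference solver is steepest descent from the all-zero weights (which
anchors `J <= 1`), with the analytic gradient `∂H/∂a_m = −2 Σ ε_k v_{m,k}`
and backtracking step control: halve the step until H decreases, grow it
by 1.2 after each accepted step, starting from `learning_rate` (0.1)
divided by the spectral norm of the Gram matrix. Stopping: for a
positive-definite Gram matrix the quadratic objective admits a certified
optimality gap, `H − H_opt <= |grad|² / (4 λ_min)`, and the solver stops
when this gap falls below `max(tol, 1e-9) · H`; a plain
relative-improvement rule stalls up to ~1e-5 short of the optimum on
ill-conditioned instances, which is why the certificate is used whenever
it is available. For rank-deficient or constrained problems the solver
falls back to the relative-improvement rule (`tol` default 1e-10), plus an
absolute floor `H <= 1e-14 · Σ h_k²` for numerically exact
representations. `max_iter` (default 1e5) bounds the search either way.
Iterations work in the N-dimensional Gram form (O(N²) per step), so a fit
at N = 35, D = 74 costs milliseconds.

A closed-form least-squares solver (`solver="exact"`, `numpy.linalg.lstsq`
/ `scipy.optimize.nnls`) is shipped as a fast path; in the test suite it
serves as the independent oracle for the gradient path, and the two are
never collapsed into one route. From the zero start the gradient path
reaches the minimum-norm solution on rank-deficient systems, matching the
pseudo-inverse residual.

## Distances, matrix correlation, Mantel test

Populations are compared by unweighted Euclidean distance of their
frequency vectors. Two distance matrices are compared by the Pearson
correlation of their off-diagonal upper triangles: the diagonal is
excluded because its structural zeros would inflate the correlation, and
the lower triangle adds no information. Labels are intersected and
reordered automatically before comparison.

The Mantel test permutes rows and columns of one matrix *jointly* (the
standard test; permuting rows alone would break symmetry) and reports the
one-sided p-value with the +1 correction,
`p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations)`, so p is never
exactly zero and the smallest attainable value is `1/(n_permutations+1)`.
Under the null this estimator is discrete-uniform, which the test suite
verifies by simulation (rejection rate at α = 0.05 and a KS check).

Graph summaries over a set of central vectors: classical (Torgerson)
metric MDS via double-centering and an eigendecomposition, truncating
negative eigenvalues with a warning for non-Euclidean input; threshold
edges strictly below a fraction (default 0.35) of the maximal distance;
and the minimum spanning tree (scipy's csgraph, with genuine zero
distances preserved as edges). Distance matrices are read and written as
labeled square CSV and as PHYLIP-style square text.

## Synthetic data

The generator plants exactly the structure the pipeline is meant to
recover. Ancestral profiles are Dirichlet draws over a generated label
tree (top-level letter clades with digit/letter subclades, depths 1–3, so
some basis labels are token-ancestors of others, as in real nomenclature).
Populations are either noisy copies of single profiles (`pure`; truncated
Gaussian noise, clipped at zero and renormalized) or convex combinations
with Dirichlet-drawn recorded weights (`admixed`). Individuals are
multinomial draws from each population's distribution; each drawn basis
label is extended level-by-level with probability `subclade_prob` into a
random deeper subclade (alternating 1–2 digit and 1–2 lowercase-letter
runs, up to 7 tokens), with the first added token chosen to avoid every
deeper basis label, so the cumulating assignment provably recovers the
drawn label. Everything is deterministic given the seed and all planted
quantities are returned for verification.

Default study conditions used by the acceptance script: 200 random solver
instances at N ∈ [5, 35], D ∈ [10, 74]; weight recovery with K = 4
profiles in D = 12 at noise σ ∈ {0, 0.001, 0.005, 0.02} with 100
replicates per level; clustering recovery with K = 5 well-separated
profiles (concentration 0.3), 20 populations per profile, noise 0.01,
over 20 seeds; Mantel calibration with 1000 replicates of 8-label matrices
at 99 permutations; and an end-to-end run with K = 5, D = 20, P = 60
populations, 500 individuals each, subclade probability 0.3. These sizes
keep every stage's behavior measurable while each planted property remains
recoverable by construction.

What the generator does not emulate: real phylogenetic dependence between
haplogroup frequencies (axes are exchangeable here), sampling biases and
small ancient-DNA sample sizes, nomenclature synonyms or versioning, and
drift/bottleneck dynamics. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration on data satisfying the model's
assumptions, not robustness to the messiness of real archaeogenetic
databases.

## Known limitations

- The iterative rank-correlation subset search is a greedy reconstruction;
  it can return a local optimum of the subset-selection problem, and its
  accepted-pair list should be read with the exposed thresholds in mind.
- The clustering's growth rule depends on restarts for stability at each
  N; with few restarts the chosen N can vary between seeds on borderline
  data (`converged_` and the criterion are always verifiable after the
  fact).
- The admixture weights are unconstrained by default, so they are a
  least-squares description of a population in the central-vector frame,
  not literal ancestry proportions.
- The spreadsheet importer expects the documented sheet layouts and fails
  loudly on anything else; it never guesses.
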