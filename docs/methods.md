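# Methods note

This note records the modelling assumptions, default parameters and
numerical choices behind the package, and where its behaviour deliberately
departs from common alternatives.

## Sloan neutral community model

**Model.** A taxon at metacommunity relative abundance `p` has, under
neutral drift with immigration, a local relative abundance distributed
`Beta(Nm·p, Nm·(1−p))`. With detection limit `d`, its predicted occurrence
frequency is `f(p) = 1 − I_d(Nm·p, Nm·(1−p))`, evaluated with
`scipy.special.betainc`.

**Estimation.** `Nm` is estimated by least squares of observed occurrence
frequencies on `f(p)`, parameterized as log10(Nm) on the interval [−2, 9].
The SSE surface is flat for extreme `Nm`, so a bounded scalar minimization
is combined with L-BFGS-B restarts from log10(Nm) ∈ {1, …, 6}; the best
local optimum wins. `p` is each taxon's mean relative abundance over the
fitted samples; taxa never detected are excluded (their `p` is 0 and the
model is undefined there).

**Detection limit.** By default `d = 1/N` with `N` the mean total reads per
sample: one read is the smallest observable abundance. `d` can be overridden
when depths are very uneven.

**Classification.** The 95% band around each predicted frequency is a
Wilson score interval at the fitted sample count
(`statsmodels proportion_confint`), which stays inside [0, 1] and behaves
sensibly at frequencies near 0 and 1 where a normal-approximation band does
not. Classification uses strict inequalities; an observation exactly on a
bound is neutral. `R² = 1 − SSE/SST` is reported descriptively; it is not a
hypothesis test of neutrality.

## Nearest taxon index

MNTD is the mean, over community members, of the patristic distance to the
closest other member (optionally abundance-weighted). The null shuffles tip
labels across the location's taxon pool — equivalently, draws random
communities of the observed richness from the pool — and
`NTI = −(MNTD_obs − mean_null)/sd_null`, so positive values mean
phylogenetic clustering. Defaults: 999 null draws; a community equal to the
entire pool (shuffle-invariant) or a zero-variance null is flagged
`undefined` rather than given a value.

Patristic distances are computed by a single tree traversal accumulating
cross-pairs of child subtrees at each internal node (each tip pair visited
once, O(n²) total); the implementation is verified against dendropy's
phylogenetic distance matrix in the test suite. For survey-scale workloads
the null MNTDs are computed with a per-pool sorted-neighbor cache: each
member scans its distance-sorted neighbor list until the first co-member,
an expected O(pool) per community instead of O(k²) per shuffle.

Per-plot inference is a two-sided one-sample t-test of the plot's NTI values
against zero.

## Core microbiome and abundance–occupancy

An OTU is retained in a location when its occurrence count there reaches the
per-domain threshold (default 10 samples for bacteria, 5 for fungi, matching
the sparsity filter conventionally applied before network inference in soil
surveys); the core is the Venn region retained in all locations. Core
abundance fractions use domain-specific denominators (core bacterial reads
over total bacterial reads, likewise for fungi). The abundance–occupancy
relation is Spearman's ρ between per-OTU mean relative abundance and
occupancy within a location.

## Association networks

Linkage density is `2E/N` (mean edges per node) and edge density
`100·E/(N(N−1)/2)` (percent of realized pairs), matching how such surveys
print them. Modules come from greedy modularity maximization (deterministic).

**Null models.** `rewire` randomizes by double edge swaps (10·E swaps),
conserving every node's degree exactly; `er` redraws edges uniformly,
conserving only node and edge counts. The **shared-association test**
randomizes all networks jointly `n` times and reports the empirical
one-sided p-value `(1 + #{null ≥ observed})/(n + 1)`, which is never zero
and attains 1.

For the ER variant of the shared-edge test, edges are redrawn *stratified by
association type* (bacterial–bacterial, bacterial–fungal, fungal–fungal
counts each preserved). An unstratified ER null scatters edges over all node
pairs; for the purely bacterial–fungal networks this test targets, that
shrinks the probability of any specific observed (B–F) edge and biases the
null shared count low, making the test miscalibrated. With stratification,
calibration runs on unplanted synthetic networks give non-extreme p-values
at the expected rate while 20 planted shared edges across four networks are
detected at p = 0.001.

## Synthetic survey generator

The generator emulates the study design: 4 locations × 10 plots × 5
subsamples (200 samples), each sample an independent local community.

- **Metacommunity:** log-normal species-abundance distribution
  (σ = 2.0, 2000 taxa), normalized.
- **Local dynamics:** a Moran urn of `J = 10,000` individuals initialized
  from the metacommunity; each event kills a uniform individual and replaces
  it with an immigrant (probability `m = 0.1`, parent drawn by metacommunity
  abundance) or a local offspring. Community size is conserved exactly.
- **Generations = 20:** with immigration rate m, composition relaxes toward
  the immigration–drift equilibrium at rate ≈ m per generation; 20
  generations is ≈ 2/m relaxation times at the default `m = 0.1`, enough to
  forget the initial draw without simulating to stationarity.
- **Reads:** multinomial at depth 10,000 (every sample survives the
  5,000-read quality filter by construction).
- **Selection:** 5% of taxa are selected-for and 5% selected-against, with
  inclusion odds multiplied/divided by 5. The baseline presence probability
  `q` is the model's own prediction at `Nm = J·m`, `d = 1/depth`; a
  selected-for taxon absent from a sample is injected with probability
  `(q′−q)/(1−q)` and a selected-against taxon present is removed with
  probability `1 − q′/q`. Flips happen **in read space** as minimal transfers
  (2 reads) against the sample's dominant taxon, so depths stay exact and
  the perturbation changes occupancy without materially moving mean
  abundance — i.e. it moves taxa *off* the neutral curve vertically rather
  than sliding them along it.
- **Trees:** a pure-birth (Yule) process grown to the requested tip count
  with exponential waiting times; ultrametric, strictly positive branch
  lengths, no root branch, tip labels matching synthetic OTU ids.

Generator defaults are the study conditions used by the validation suite;
they are not tuned to the tests.

## Pipeline

Stages run in analysis order (depth filter → core/Venn/abundance-occupancy →
per-location NCM → NTI with per-plot tests → network statistics →
shared-association test → NCM-class projection onto networks). One global
seed fans out to fixed per-stage offsets so each stage is independently
reproducible. The bundled network inferrer (CLR transform + |Pearson r| ≥
0.9) is demonstration plumbing so the pipeline runs end-to-end without
external tools; it is not a substitute for sparse-inverse-covariance
inference, and on purely neutral synthetic data it correctly finds
(almost) no edges, in which case the shared-edge stage records an explicit
skip.

## Limitations

- The NCM confidence band classifies descriptively; it is not a formal
  multiple-testing-corrected selection test.
- The NTI null treats the location pool as fixed and taxa as exchangeable;
  habitat filtering *of the pool itself* is outside the model.
- Recovery of selected-against taxa is intrinsically weaker than
  selected-for: removing a rare taxon's few presences is often
  indistinguishable from neutral absence at n = 50 samples per location.
- The Moran simulator models independent samples; it does not generate
  spatial autocorrelation between subsamples of a plot.
- Synthetic association networks are random bipartite graphs with planted
  intersections; they validate the test machinery, not ecological inference.
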