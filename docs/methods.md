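# Methods

This note records the models, conventions and numerical choices behind
`micronet`, and what the synthetic benchmark does and does not establish.

## Abundance partitioning

Taxa are classified by **mean relative abundance across the samples of the
dataset**: abundant if the mean exceeds 0.1% (strict), rare if below 0.01%
(strict), intermediate otherwise — intermediates enter neither network.
"Relative abundance" could also be read per-sample or stage-scoped; the
dataset-mean reading is the default and a `sample_ids` argument provides
stage-scoped classification. Prevalence ("present in more than 50% of
samples") is a strict inequality — a taxon present in exactly half the
samples is excluded — and is recomputed within each stage's sample set when
stage-wise networks are built, because each network only sees its own
samples. 16S and ITS tables are partitioned separately; the synthetic
generator emulates the joint (bacteria + fungi) case with a kingdom tag per
taxon.

## Diversity statistics

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)). Shannon is
reported in nats (a `base` flag gives bits); the log base is a reporting
convention with no effect on hypothesis tests. ANOSIM uses midranks for
tied distances and the plus-one permutation estimator
p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1), so p is bounded below by
1/(n_perm+1) and the test is exact-level. PCoA double-centres −½D² (Gower),
reports **all** eigenvalues including negative ones (Bray–Curtis is
non-Euclidean) but builds coordinates and proportions from positive
eigenvalues only; no Lingoes/Cailliez correction is applied, matching a
plain PCoA. The Wilcoxon/Mann–Whitney pairwise tests use the exact null
distribution for small untied samples and the tie-corrected normal
approximation otherwise; two identical constant groups return p = 1 with a
warning rather than a 0/0.

## Network construction

The correlation input is the relative-abundance sub-table of retained taxa
with a "paired-valid" fill: zeros of taxa that are non-zero in more than
half the samples are replaced by 0.01 **on the percent scale** (10⁻⁴ as a
fraction), the convention of percent-scaled molecular-ecology network
tables; both the constant and the majority rule are configurable. The
default coefficient is Pearson on these filled fractions (Spearman by
flag).

The RMT threshold scan zeroes sub-threshold similarities on the grid
0.30–1.00 (step 0.01), drops rows/columns with no surviving off-diagonal
entry, and eigendecomposes the remaining matrix. Unfolding collapses
degenerate eigenvalues (tolerance 1e−8), fits a monotone PCHIP cubic to the
empirical cumulative spectral function through ⌈n/10⌉ knots (minimum 5) and
rescales levels as eᵢ = n·G(λᵢ), giving unit-mean spacings by
construction. The NNSD goodness-of-fit uses 20 histogram bins on
[0, max spacing] plus a closed tail bin, pools bins left-to-right until
each holds expected mass ≥ 1, and compares χ² distances to the Poisson and
GOE densities; "Poisson fits" requires both χ²_P < χ²_GOE and χ²_P below
the 0.001-level critical value for the pooled degrees of freedom. The
chosen threshold is the smallest grid value whose Poisson fit persists at
every larger evaluable threshold — the GOE→Poisson transition is
one-directional, and the persistence rule suppresses single-threshold
noise flips. Matrices with fewer than 20 distinct eigenvalues are "not
evaluable" at that threshold. Both the scan-selected and a fixed
comparative cutoff (0.88) are supported; comparative runs across groups use
the fixed cutoff. Edges require |r| ≥ cutoff (a cutoff of 0 therefore
yields the complete graph); signs follow the correlation sign; isolated
taxa are dropped.

## Topology

Average path distance (GD) averages shortest paths over **connected pairs
only**; the harmonic geodesic distance is HD = P/Σ(1/d) over all
P = N(N−1)/2 pairs with disconnected pairs contributing zero reciprocal —
so HD ≤ GD on connected graphs but may exceed it on fragmented ones, which
is expected. Local clustering of degree-<2 nodes counts as 0 in avgCC.
Degree centralization is Σ(k_max−kᵢ)/((N−1)(N−2)); betweenness
centralization normalizes Σ(b_max−bᵢ) by its star-graph maximum (N−1 for
normalized betweenness). The power-law R² is OLS on log count-of-degree-k
vs log k — a descriptive fit in the molecular-ecology tradition, not a
Clauset-style maximum-likelihood estimate, and it is reported as NaN (with
a warning) in summaries when fewer than 3 distinct degrees exist. Modules
come from fast-greedy modularity maximization on the unsigned graph; the
null ensemble applies 10·L double-edge swaps per replicate (100 replicates
by default, seeded), asserting the exact degree multiset each time; graphs
admitting no swap (e.g. a triangle) yield identical copies with a warning.

## Zi–Pi roles

Zi standardizes the within-module degree with the **population** sd over
the node's module including the node itself, with Zi = 0 when the sd is 0
(the degenerate case is undefined in the role literature; 0 keeps regular
modules peripheral). Pi = 1 − Σₜ(k_it/kᵢ)². Boundary values sit with the
"≤" branch: a node at exactly (2.5, 0.62) is peripheral. Keystones =
connectors ∪ module hubs ∪ network hubs, computed on the fixed-cutoff
network.

## Drivers

Mantel/partial-Mantel tests permute the row/column order of the second
matrix, one-sided toward positive association (the ecological convention;
a two-sided flag exists), plus-one estimator, 999 permutations by default.
Environmental distances are Euclidean on standardized variables. In the
exact self-partialling limit (B ≡ C, or any perfectly collinear triple with
vanishing numerator) the partial r is 0 analytically; inconsistent
degenerate triples raise an error. Because one empirical network exists per
stage, topology–environment Pearson correlations need several networks or
stage-aggregated units; the pipeline correlates stage-level topology with
stage-mean environment, and fuller calibration uses many synthetic
replicate networks.

## Synthetic benchmark

The generator draws base relative abundances from a lognormal (sd 2.0) —
yielding ≈9% abundant and ≈60% rare taxa at 2,000 taxa, the skew typical of
soil amplicon surveys — adds per-(group, taxon) Gaussian composition shifts
(sd 0.75), embeds planted modules as equicorrelated blocks (shared factor,
ρ = 0.95 by default) in a correlated latent Gaussian scaled by τ = 0.8,
and draws counts by multinomial sampling at depth 10,065 (bacterial-scale;
8,000 emulates ITS depth). Module taxa get a fixed base abundance (0.8%
each, 4 modules × 8 taxa ≈ 26% of reads — abundant fractions of real soil
communities carry comparable mass) so the planted correlations survive
counting noise: the observable linear-scale correlation of a planted pair
is roughly ρ·[τ²/(τ²+1/(depth·p))]·[(e^{ρτ²}−1)/(e^{τ²}−1)]/ρ ≈ 0.92,
comfortably above the 0.88 cutoff at n = 30. Two deliberate defaults follow
from this arithmetic: planted modules are **all-positive** (for lognormal
abundances an anti-correlated pair's linear correlation is bounded by
(e^{−ρτ²}−1)/(e^{τ²}−1) ≈ −0.5, unrecoverable at 0.88, though signed
patterns are supported and tested on constructed similarity matrices), and
module taxa are **exempt from group shifts** (taxon-independent group noise
would attenuate the planted correlation below recoverability; a flag
restores shifts). Environmental variables are linear in the standardized
group index plus Gaussian noise (sd 0.5), with a pure-noise column as a
negative control.

What passing the benchmark shows: the pipeline's statistics are calibrated
(type-I error ≈ 5%), its network stage recovers strong planted linear
associations, and its module/keystone machinery is correct on known
structure. What it does not show: performance on real data with
zero-inflation beyond multinomial closure, phylogenetic correlation,
compositional effects at high dominance, or negative ecological
interactions at stringent cutoffs — compositional closure is accepted as a
documented property of the benchmark, not corrected.

## Problem sizes

Defaults mirror the emulated survey (30 samples, 2,000 taxa, depth 10,065,
999 permutations, 100 null replicates). The packaged test-suite pipeline
runs use a reduced configuration (400–600 taxa, 10–20 null replicates,
49–99 permutations) — the pipeline is linear in these knobs and the
full-scale settings are exercised directly by the benchmark and calibration
suites (10 replicates of the full 30 × 2,000 benchmark; 500 null
simulations × 999 permutations for calibration; 100 NNSD trials at 500
spacings).

## Known limitations

- Pearson on (filled) relative abundances inherits compositional bias; no
  SparCC/SPIEC-EASI-style correction is attempted (out of scope).
- The NNSD χ² classifier needs a few hundred spacings; small networks'
  thresholds are frequently "not evaluable", and the scan then reports
  whatever evaluable range exists.
- The RMT persistence rule can return no threshold when late-grid
  fluctuations break Poisson fits; callers fall back to the fixed cutoff.
- GraphML/edge-list exports carry signs and correlations but no layout;
  visualization is delegated to external viewers.
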