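# micronet

Analysis of **abundant and rare soil microbial communities and their
co-occurrence networks** across environmental gradients (e.g. successional
stages of a recovering forest), built for microbial ecologists working with
amplicon (16S/ITS) ASV tables.

Microbial communities are heavily right-skewed: a handful of abundant taxa
carry most reads while most taxa are rare. `micronet` partitions a
sample × taxon count table into **abundant** (mean relative abundance
> 0.1%) and **rare** (< 0.01%) fractions and then characterizes each
fraction's structure and interactions:

- **Diversity** — Chao1 (S<sub>obs</sub> + F₁(F₁−1)/(2(F₂+1))) and Shannon
  (−Σ pᵢ ln pᵢ) α-diversity, Bray–Curtis β-diversity, PCoA ordination,
  one-way ANOSIM (R = (r̄<sub>B</sub> − r̄<sub>W</sub>)/(M/2)) and pairwise
  Wilcoxon rank-sum tests, all with seeded permutations.
- **Co-occurrence networks with an RMT threshold** — zeros of prevalent taxa
  are filled with a small constant (0.01 on the percent scale), pairwise
  Pearson (or Spearman) correlations are folded to a similarity matrix
  S = |r|, and similarity thresholds 0.30…1.00 (step 0.01) are scanned.
  At each threshold the surviving matrix's eigenvalue spectrum is unfolded
  and its nearest-neighbour spacing distribution (NNSD) is tested against
  the Poisson form e^(−d) (modular, non-random structure) versus the
  Wigner–Dyson/GOE form (πd/2)e^(−πd²/4) (random-matrix noise); the chosen
  threshold is where the spectrum turns (and stays) Poisson. A fixed
  comparative cutoff (0.88) is equally supported.
- **Topology against degree-preserving nulls** — node/link/sign counts,
  power-law degree fit R², average degree 2L/N, clustering, average and
  harmonic geodesic distances, degree/betweenness centralization, density
  2L/(N(N−1)), transitivity, Krackhardt connectedness, fast-greedy
  modularity — each compared with mean ± sd over a Maslov–Sneppen
  (double-edge-swap) random ensemble.
- **Keystone taxa** — within-module degree z-score Zi and among-module
  participation Pi = 1 − Σₜ(k<sub>it</sub>/kᵢ)²; nodes with Zi > 2.5 or
  Pi > 0.62 (module hubs, connectors, network hubs) are flagged as putative
  keystones.
- **Environmental drivers** — Mantel and partial Mantel tests (999 seeded
  permutations) of community distance against environmental distance, and
  Pearson correlations of topology metrics with environmental variables.

A first-class **synthetic-data generator** emulates a 3-stage × 10-sample
survey with lognormal abundances, group-dependent composition shifts,
planted correlated taxon modules and coupled environmental covariates, so
every stage of the pipeline is testable against known ground truth without
any sequencing data.

## Worked example

```python
from micronet import synthetic_data as sd, partition as pt
from micronet import network_construction as nc, topology as tp, keystone as ks

spec = sd.SyntheticSpec(seed=42, planted_modules=sd.default_module_layout())
table, truth = sd.generate_community(spec)          # 30 samples x 2000 taxa
part = pt.classify_abundance(table)                 # 0.1% / 0.01% cutoffs
taxa = part.taxa_in_class("abundant")               # prevalent abundant taxa
net = nc.network_from_table(table, taxa, 0.88, partition=part)
nulls = tp.random_null(net, n_nets=100, seed=0)
s = tp.summarize(net, nulls, name="abundant_0.88")
rec = sd.edge_recovery(net, truth, table.taxon_ids)
```

prints (via the obvious `print` calls):

```
classes: {'rare': 1243, 'intermediate': 583, 'abundant': 174}
retained abundant taxa: 174
nodes=31 links=92 avgK=5.935 density=0.198 modularity=0.744 modules=4
null modularity: 0.280 +/- 0.019
planted-edge recovery: 82.1%  false edges: 0.0%
```

Read: of 2,000 taxa, 174 are abundant and 1,243 rare — the expected skew.
At the 0.88 cutoff the abundant-fraction network contains almost exactly
the four planted 8-taxon modules (82% of planted pairs, no false edge),
fast-greedy community detection finds the 4 modules, and the empirical
modularity (0.744) towers over its degree-preserving null (0.280 ± 0.019)
— planted structure, not degree sequence, explains the modules.

The same workflow runs from the shell:

```bash
micronet simulate --n-taxa 2000 --seed 42 \
    --out-table t.tsv --out-metadata m.tsv --out-env e.tsv
micronet run-all --seed 42 --out results/run
```

`run-all` writes partition, diversity (Chao1/Shannon/Wilcoxon/ANOSIM/PCoA),
per-stage network edge lists, a topology table (empirical + random-null
rows), keystone and Mantel reports, plus a `manifest.json`.

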