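"""Synthetic ASV tables with known ground truth.

The generator emulates the design of a three-stage successional soil
survey: 3 groups x 10 samples, a right-skewed (lognormal) taxon abundance
distribution producing few abundant and many rare taxa, group-dependent
composition shifts, planted blocks of correlated taxa that downstream
network inference should recover as modules, and environmental covariates
coupled to the group gradient.

Generative model
----------------
Base relative abundances p_j are proportional to exp(N(mu, sigma^2)).
Per sample s, latent log-abundances are

    x_sj = log p_j + delta_{g(s),j} + tau * z_sj

where delta are per-(group, taxon) composition shifts and z_s is a
correlated standard Gaussian whose correlation matrix embeds the planted
modules (equicorrelated blocks built from a shared per-module factor).
Counts are multinomial draws of the softmax of x_s at the stated depth,
so compositional (closure) artefacts are part of the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import AsvTable, EnvMatrix

STAGE_NAMES = ("grassland", "shrubland", "secondary_forest")

#: environmental variables emulated; "noise" is a pure-noise negative control
ENV_VARIABLES = ("stage", "plant_richness", "SOC", "TN", "NO3", "NH4", "TP",
                 "EC", "pH", "SM", "C:N", "C:P", "N:P", "noise")


@dataclass(frozen=True)
class PlantedModule:
    """A block of taxa with within-module latent correlation ``rho``.

    ``signs`` (one of +/-1 per taxon) flips the loading of individual taxa
    on the shared module factor; None means all positive.
    """

    taxa: tuple[int, ...]
    rho: float = 0.95
    signs: tuple[int, ...] | None = None

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValidationError("module rho must lie in (0, 1)")
        if self.signs is not None and len(self.signs) != len(self.taxa):
            raise ValidationError("signs length must match module size")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic community benchmark.

    Defaults mirror the emulated study scale: 3 successional stages x 10
    samples, bacterial sequencing depth 10,065 reads/sample, and a
    lognormal abundance distribution (sd 2.0) skewed enough that well
    under 20% of taxa are abundant (>0.1% mean relative abundance) and
    well over 40% are rare (<0.01%).
    """

    n_samples_per_group: int = 10
    n_groups: int = 3
    n_taxa: int = 2000
    base_log_mean: float = 0.0
    base_log_sd: float = 2.0
    depth: int = 10065
    latent_sd: float = 0.8
    planted_modules: list[PlantedModule] = field(default_factory=list)
    module_rel_abund: float = 0.008
    group_effect_sd: float = 0.75
    modules_respond_to_groups: bool = False
    env_coupling: float = 1.0
    env_noise_sd: float = 0.5
    frac_bacteria: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.n_samples_per_group < 1 or self.n_groups < 1:
            raise ValidationError("need at least one sample and one group")
        seen: set[int] = set()
        for m in self.planted_modules:
            for t in m.taxa:
                if not 0 <= t < self.n_taxa:
                    raise ValidationError(
                        f"module taxon index {t} out of range [0, {self.n_taxa})")
                if t in seen:
                    raise ValidationError("planted modules must be disjoint")
                seen.add(t)
        if len(seen) * self.module_rel_abund >= 0.5:
            raise ValidationError("planted modules would exceed half the community mass")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * self.n_groups


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream scoring."""

    true_class: np.ndarray            # per-taxon 'abundant'/'intermediate'/'rare'
    planted_adjacency: np.ndarray     # n_taxa x n_taxa, 0/+1/-1 (signed)
    group_shift: np.ndarray           # n_groups x n_taxa log-scale shifts
    base_rel_abund: np.ndarray        # latent p_j
    env_coefficients: dict[str, float] = field(default_factory=dict)

    def planted_edges(self, taxon_ids: list[str]) -> set[frozenset]:
        """Planted within-module pairs as sets of taxon-id pairs."""
        ii, jj = np.nonzero(np.triu(self.planted_adjacency, k=1))
        return {frozenset((taxon_ids[i], taxon_ids[j])) for i, j in zip(ii, jj)}


def default_module_layout(n_modules: int = 4, module_size: int = 8,
                          rho: float = 0.95) -> list[PlantedModule]:
    """Disjoint planted modules on the first taxon indices."""
    return [
        PlantedModule(tuple(range(k * module_size, (k + 1) * module_size)), rho)
        for k in range(n_modules)
    ]


def _module_signs(module: PlantedModule) -> np.ndarray:
    if module.signs is None:
        return np.ones(len(module.taxa))
    return np.asarray(module.signs, dtype=float)


def generate_community(spec: SyntheticSpec) -> tuple[AsvTable, GroundTruth]:
    """Draw a count table and its ground truth from ``spec``.

    Reproducible given ``spec.seed``; module taxa receive a fixed base
    relative abundance (``module_rel_abund``) so the planted correlation
    structure survives multinomial counting noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, t = spec.n_samples, spec.n_taxa

    # base abundances: lognormal for background, fixed for module taxa
    log_w = rng.normal(spec.base_log_mean, spec.base_log_sd, t)
    p = np.exp(log_w - log_w.max())
    module_taxa = np.concatenate(
        [m.taxa for m in spec.planted_modules]).astype(int) \
        if spec.planted_modules else np.empty(0, dtype=int)
    bg = np.setdiff1d(np.arange(t), module_taxa)
    module_mass = len(module_taxa) * spec.module_rel_abund
    p_full = np.empty(t)
    p_full[bg] = p[bg] / p[bg].sum() * (1.0 - module_mass)
    p_full[module_taxa] = spec.module_rel_abund

    # per-(group, taxon) composition shifts
    delta = rng.normal(0.0, spec.group_effect_sd, (spec.n_groups, t))
    if not spec.modules_respond_to_groups:
        delta[:, module_taxa] = 0.0

    # correlated latent Gaussian embedding the planted blocks
    z = rng.standard_normal((n, t))
    for m in spec.planted_modules:
        f = rng.standard_normal(n)
        s = _module_signs(m)
        idx = np.asarray(m.taxa)
        z[:, idx] = s * (np.sqrt(m.rho) * f[:, None]
                         + np.sqrt(1.0 - m.rho) * z[:, idx])

    groups = np.repeat(np.arange(spec.n_groups), spec.n_samples_per_group)
    x = np.log(p_full)[None, :] + delta[groups] + spec.latent_sd * z
    probs = np.exp(x - x.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(spec.depth, probs[i]) for i in range(n)])

    width = len(str(t))
    taxon_ids = [f"ASV_{j:0{width}d}" for j in range(t)]
    stage_of = [STAGE_NAMES[g % len(STAGE_NAMES)] for g in groups]
    sample_ids = [f"S{i + 1:02d}_{stage_of[i][:5]}" for i in range(n)]
    n_bact = int(round(spec.frac_bacteria * t))
    taxonomy = {}
    for j, tid in enumerate(taxon_ids):
        kingdom = "Bacteria" if j < n_bact else "Fungi"
        taxonomy[tid] = (f"k__{kingdom};p__Phylum{j % 12:02d};c__;o__;"
                         f"f__;g__Genus{j % 97:02d}")
    metadata = pd.DataFrame(
        {"stage": stage_of, "group_index": groups}, index=sample_ids)
    table = AsvTable(counts, sample_ids, taxon_ids, taxonomy, metadata)

    # signed planted adjacency
    adj = np.zeros((t, t))
    for m in spec.planted_modules:
        s = _module_signs(m)
        idx = np.asarray(m.taxa)
        block = np.outer(s, s)
        np.fill_diagonal(block, 0.0)
        adj[np.ix_(idx, idx)] = block

    rel = counts / counts.sum(axis=1, keepdims=True)
    mean_rel = rel.mean(axis=0)
    true_class = np.where(mean_rel > 1e-3, "abundant",
                          np.where(mean_rel < 1e-4, "rare", "intermediate"))
    return table, GroundTruth(true_class, adj, delta, p_full)


def generate_env(spec: SyntheticSpec, truth: GroundTruth) -> EnvMatrix:
    """Environmental covariates coupled to the successional gradient.

    Every variable (except the pure-noise control) is a linear function
    of the standardized group index plus Gaussian noise; the coupling
    coefficients are recorded on ``truth.env_coefficients``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    n = spec.n_samples
    groups = np.repeat(np.arange(spec.n_groups), spec.n_samples_per_group)
    g_std = (groups - groups.mean()) / (groups.std() if groups.std() else 1.0)
    cols = []
    coeffs = {}
    for var in ENV_VARIABLES:
        if var == "stage":
            cols.append(groups.astype(float) + 1.0)
            coeffs[var] = np.nan  # ordinal stage index itself
            continue
        b = 0.0 if var == "noise" else spec.env_coupling
        cols.append(b * g_std + rng.normal(0.0, spec.env_noise_sd, n))
        coeffs[var] = b
    truth.env_coefficients = coeffs
    stage_of = [STAGE_NAMES[g % len(STAGE_NAMES)] for g in groups]
    sample_ids = [f"S{i + 1:02d}_{stage_of[i][:5]}" for i in range(n)]
    return EnvMatrix(np.column_stack(cols), sample_ids, list(ENV_VARIABLES))


def edge_recovery(net, truth: GroundTruth, taxon_ids: list[str]) -> dict:
    """Score a recovered network against the planted adjacency.

    Returns recovered / planted edge counts, the fraction of planted
    edges present, and the false-edge rate (fraction of the network's
    edges that were not planted).
    """
    import networkx as nx
    planted = truth.planted_edges(taxon_ids)
    graph = getattr(net, "graph", None)
    if not isinstance(graph, nx.Graph):
        graph = net
    found = {frozenset((u, v)) for u, v in graph.edges()}
    n_hit = len(planted & found)
    n_false = len(found - planted)
    return {
        "n_planted": len(planted),
        "n_edges": len(found),
        "n_recovered": n_hit,
        "recovery": n_hit / len(planted) if planted else np.nan,
        "false_edge_rate": n_false / len(found) if found else 0.0,
    }
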