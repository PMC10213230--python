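"""End-to-end orchestration: rarefy -> partition -> diversity -> stagewise
networks -> topology + nulls -> keystones -> environmental drivers.

A single config object (loadable from YAML/JSON) carries the study
constants — rarefaction depth, abundance cutoffs (0.1% / 0.01%),
prevalence rule (>50%), fixed similarity cutoff (0.88), Zi/Pi role
thresholds (2.5 / 0.62) and 999 permutations — so a bare synthetic run
mirrors the emulated study design.  All randomness derives from one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, drivers, io_tables, keystone, network_construction, \
    partition as partition_mod, synthetic_data, topology
from .errors import EmptyNetworkError, ValidationError

log = logging.getLogger("micronet")


@dataclass
class RunConfig:
    # input: either a table/metadata path pair or a synthetic spec
    table_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    rarefaction_depth: int = 10065
    abundant_cut: float = 1e-3
    rare_cut: float = 1e-4
    prevalence_min: float = 0.5
    cutoff_mode: str = "fixed"          # 'fixed' or 'rmt'
    cutoff: float = 0.88
    correlation_method: str = "pearson"
    fill_value: float = 0.01            # percent scale
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    n_permutations: int = 999
    null_ensemble: int = 100
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.rarefaction_depth <= 0:
            problems.append("rarefaction_depth must be positive")
        if not 0 < self.rare_cut < self.abundant_cut < 1:
            problems.append("need 0 < rare_cut < abundant_cut < 1")
        if not 0 <= self.prevalence_min < 1:
            problems.append("prevalence_min must lie in [0, 1)")
        if not 0 <= self.cutoff <= 1:
            problems.append("similarity cutoff must lie in [0, 1]")
        if self.cutoff_mode not in ("fixed", "rmt"):
            problems.append("cutoff_mode must be 'fixed' or 'rmt'")
        if self.n_permutations < 1 or self.null_ensemble < 1:
            problems.append("permutations and null ensemble must be >= 1")
        if self.zi_cut <= 0 or not 0 < self.pi_cut < 1:
            problems.append("role thresholds out of range")
        if problems:
            raise ValidationError("; ".join(problems))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_inputs(config: RunConfig):
    if config.table_path:
        table = io_tables.read_asv_table(config.table_path)
        if config.metadata_path:
            table.metadata = io_tables.read_metadata(config.metadata_path)
        env = io_tables.read_env(config.env_path) if config.env_path else None
        return table, env, None
    spec_kwargs = dict(config.synthetic)
    spec_kwargs.setdefault("seed", config.seed)
    spec_kwargs.setdefault("depth", config.rarefaction_depth)
    if "planted_modules" in spec_kwargs and spec_kwargs["planted_modules"] \
            and isinstance(spec_kwargs["planted_modules"][0], dict):
        spec_kwargs["planted_modules"] = [
            synthetic_data.PlantedModule(tuple(m["taxa"]), m.get("rho", 0.95),
                                         tuple(m["signs"]) if m.get("signs") else None)
            for m in spec_kwargs["planted_modules"]]
    spec_kwargs.setdefault(
        "planted_modules", synthetic_data.default_module_layout())
    spec = synthetic_data.SyntheticSpec(**spec_kwargs)
    table, truth = synthetic_data.generate_community(spec)
    env = synthetic_data.generate_env(spec, truth)
    return table, env, truth


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Deterministic given ``config.seed``; every report is listed in
    ``manifest.json`` with the producing stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "reports": {}, "skipped": [],
                "counts": {}}

    def save(stage: str, name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, sep="\t", float_format="%.6g")
        manifest["reports"][name] = stage

    table, env, _truth = _load_inputs(config)
    # a synthetic spec that states its own depth also sets the rarefaction depth
    depth = config.synthetic.get("depth", config.rarefaction_depth) \
        if not config.table_path else config.rarefaction_depth
    table = io_tables.rarefy(table, depth, config.seed + 1)
    log.info("rarefied to depth %d: %d samples x %d taxa",
             depth, table.n_samples, table.n_taxa)

    part = partition_mod.classify_abundance(
        table, config.abundant_cut, config.rare_cut)
    counts_by_class = pd.Series(part.labels).value_counts().to_dict()
    manifest["counts"]["abundance_classes"] = counts_by_class
    log.info("abundance classes: %s", counts_by_class)
    save("partition", "partition.tsv", part.to_dataframe())

    # --- diversity ---------------------------------------------------
    div = diversity.diversity_report(table, part)
    save("diversity", "diversity.tsv", div)
    stages = table.metadata["stage"].astype(str) if table.metadata is not None \
        else pd.Series("all", index=table.sample_ids)
    wilcox_rows = []
    anosim_rows = []
    ord_frames = []
    rng = np.random.default_rng(config.seed + 2)
    for cls in ("abundant", "rare"):
        taxa = part.taxa_in_class(cls, retained_only=False)
        if len(taxa) < 2:
            manifest["skipped"].append(f"diversity:{cls} (too few taxa)")
            continue
        sub = table.subset_taxa(taxa)
        rel = partition_mod.relative_abundance(sub)
        dm = diversity.bray_curtis(rel, sub.sample_ids)
        if stages.nunique() >= 2:
            r, p = diversity.anosim(dm, stages.loc[sub.sample_ids],
                                    n_perm=config.n_permutations,
                                    seed=int(rng.integers(2 ** 31 - 1)))
            anosim_rows.append({"class": cls, "R": r, "p": p})
            dcls = div[div["class"] == cls].set_index("sample")
            for index_name in ("chao1", "shannon"):
                vals = dcls[index_name].dropna()
                gc = diversity.group_compare(vals, stages.loc[vals.index])
                gc.insert(0, "index", index_name)
                gc.insert(0, "class", cls)
                wilcox_rows.append(gc)
        ordn = diversity.pcoa(dm, n_axes=2)
        frame = pd.DataFrame(ordn.coordinates,
                             index=ordn.sample_ids,
                             columns=["axis1", "axis2"][:ordn.coordinates.shape[1]])
        frame.insert(0, "class", cls)
        ord_frames.append(frame)
    if anosim_rows:
        save("diversity", "anosim.tsv", pd.DataFrame(anosim_rows))
    if wilcox_rows:
        save("diversity", "wilcoxon.tsv", pd.concat(wilcox_rows, ignore_index=True))
    if ord_frames:
        save("diversity", "pcoa.tsv", pd.concat(ord_frames))

    # --- stagewise networks, topology, keystones ---------------------
    summaries = []
    keystone_frames = []
    stage_levels = list(dict.fromkeys(stages))
    for stage in stage_levels:
        stage_samples = [s for s in table.sample_ids if stages[s] == stage]
        for cls in ("abundant", "rare"):
            name = f"{stage}_{cls}"
            stage_part = partition_mod.prevalence_filter(
                part, table, config.prevalence_min, stage_samples)
            taxa = stage_part.taxa_in_class(cls)
            manifest["counts"][f"retained_{name}"] = len(taxa)
            log.info("%s: %d taxa retained for network", name, len(taxa))
            if len(taxa) < 4:
                manifest["skipped"].append(f"network:{name} (too few taxa)")
                continue
            stage_table = table.subset_samples(stage_samples)
            try:
                pos = {t: i for i, t in enumerate(stage_table.taxon_ids)}
                rel = partition_mod.relative_abundance(stage_table)
                rel = rel[:, [pos[t] for t in taxa]]
                filled = network_construction.fill_missing(
                    rel, fill=config.fill_value)
                sim = network_construction.correlation_matrix(
                    filled, taxa, method=config.correlation_method)
                cutoff = config.cutoff
                if config.cutoff_mode == "rmt":
                    scan = network_construction.rmt_threshold_scan(sim)
                    save("network", f"rmt_scan_{name}.tsv", scan.to_dataframe())
                    if scan.chosen_threshold is not None:
                        cutoff = scan.chosen_threshold
                net = network_construction.build_network(
                    sim, cutoff, partition=stage_part,
                    taxonomy=table.taxonomy)
            except (EmptyNetworkError, ValidationError) as exc:
                manifest["skipped"].append(f"network:{name} ({exc})")
                log.warning("skipping network %s: %s", name, exc)
                continue
            io_tables.write_network(net, out / f"network_{name}.tsv", "tsv")
            manifest["reports"][f"network_{name}.tsv"] = "network"
            nulls = topology.random_null(
                net, n_nets=config.null_ensemble,
                seed=int(rng.integers(2 ** 31 - 1)))
            summaries.append(topology.summarize(net, nulls, name=name))
            mods = topology.detect_modules(net)
            roles = keystone.classify_roles(
                keystone.zi_pi(net, mods), config.zi_cut, config.pi_cut)
            ktab = keystone.keystone_table(roles, table.taxonomy)
            ktab.insert(0, "network", name)
            keystone_frames.append(ktab)
    if summaries:
        save("topology", "topology.tsv", topology.topology_report(summaries))
    if keystone_frames:
        save("keystone", "keystone.tsv",
             pd.concat(keystone_frames, ignore_index=True))

    # --- drivers -----------------------------------------------------
    if env is not None:
        for cls in ("abundant", "rare"):
            taxa = part.taxa_in_class(cls, retained_only=False)
            if len(taxa) < 2:
                continue
            sub = table.subset_taxa(taxa)
            rel = partition_mod.relative_abundance(sub)
            dm = diversity.bray_curtis(rel, sub.sample_ids)
            rep = drivers.mantel_report(
                dm, env, n_perm=config.n_permutations,
                seed=int(rng.integers(2 ** 31 - 1)))
            save("drivers", f"mantel_{cls}.tsv", rep)
        if len(summaries) >= 3:
            env_df = env.to_dataframe()
            stage_mean = env_df.groupby(
                stages.loc[env.sample_ids].to_numpy()).mean()
            metr = pd.DataFrame({s.name: s.to_series() for s in summaries}).T
            metr["stage"] = [n.rsplit("_", 1)[0] for n in metr.index]
            merged_env = stage_mean.loc[metr["stage"]].set_index(metr.index)
            corr = drivers.env_topology_correlation(
                merged_env, metr.drop(columns=["stage", "cutoff"]))
            save("drivers", "env_topology.tsv", corr)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
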