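"""End-to-end orchestration of the community analysis.

Stage order:

1. read (or synthesize) the OTU table, drop organelle OTUs;
2. branch A (abundance): rarefy, then distances (Bray-Curtis, Jaccard,
   optionally weighted UniFrac), NMDS, PERMANOVA and variance partitioning —
   on the full community and on the keystone / methanogen / methanotroph
   subsets;
3. branch B (networks): prefilter un-rarefied counts, split into groups,
   estimate SparCC correlations with bootstrap p-values per group, build
   networks, compute centralities and keystones, and cluster the groups by
   abundance-weighted vs importance-weighted profiles.

Every stage writes plain-text outputs (TSV / newick / GraphML / JSON) under
the output directory, and a manifest records all seeds and thresholds; a
re-run with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance as dist_mod
from . import network as net_mod
from . import otu as otu_mod
from . import synthetic as syn_mod
from .sparcc import sparcc as run_sparcc
from .varpart import varpart as run_varpart, variance_table

logger = logging.getLogger("otunet")


@dataclasses.dataclass
class PipelineConfig:
    """Everything the full analysis needs; one input source (files XOR synthetic)."""

    counts_path: str | None = None
    meta_path: str | None = None
    tax_path: str | None = None
    tree_path: str | None = None
    synthetic: syn_mod.SyntheticConfig | None = None
    rarefaction_depth: int = 1000
    min_total: int = 10
    min_samples: int = 3
    sparcc_n_iter: int = 20
    sparcc_n_boot: int = 100
    alpha: float = 0.05
    keystone_percentile: float = 99.0
    network_groups: tuple = ("habitat", "compartment")
    varpart_factors: tuple = ("habitat", "plant", "compartment", "month")
    n_perm: int = 999
    run_unifrac: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.counts_path is not None
        have_syn = self.synthetic is not None
        if have_files == have_syn:
            raise ValueError("exactly one input source: file paths XOR synthetic config")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.keystone_percentile < 100:
            raise ValueError("keystone_percentile must be in (0, 100)")


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from YAML (synthetic block optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", None)
    if syn is not None:
        for key in ("habitats", "compartments", "months", "sequencing_depth_range"):
            if key in syn:
                syn[key] = tuple(syn[key])
        if "plant_habitats" in syn:
            syn["plant_habitats"] = {k: tuple(v) for k, v in syn["plant_habitats"].items()}
        syn = syn_mod.SyntheticConfig(**syn)
    for key in ("network_groups", "varpart_factors"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(synthetic=syn, **raw)


def _seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ("synthetic", "rarefy", "sparcc", "nmds", "varpart", "tree")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _group_label(key: tuple) -> str:
    return "|".join(str(k) for k in key)


def run_full_analysis(config: PipelineConfig, outdir) -> dict:
    """Run both branches and write all artefacts; returns a result bundle.

    The returned dict holds in-memory results (tables, metrics, keystone
    sets, variance partitions) plus the manifest written to disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": {
            "rarefaction_depth": config.rarefaction_depth,
            "min_total": config.min_total,
            "min_samples": config.min_samples,
            "alpha": config.alpha,
            "keystone_percentile": config.keystone_percentile,
            "sparcc_n_iter": config.sparcc_n_iter,
            "sparcc_n_boot": config.sparcc_n_boot,
            "n_perm": config.n_perm,
        },
        "stages": [],
    }

    def stage(name: str) -> None:
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    # -- input ------------------------------------------------------------
    tree = None
    if config.synthetic is not None:
        stage("synthesize")
        syn_cfg = dataclasses.replace(config.synthetic, seed=seeds["synthetic"])
        table, truth = syn_mod.generate_community(syn_cfg)
        otu_mod.write_otu_table(
            table, outdir / "counts.tsv", outdir / "metadata.tsv", outdir / "taxonomy.tsv"
        )
        syn_mod.write_ground_truth(truth, outdir / "ground_truth.json")
        manifest["synthetic_config"] = syn_mod.config_to_dict(syn_cfg)
        if config.run_unifrac:
            tree = syn_mod.generate_tree(table.otu_ids, seed=seeds["tree"])
            tree.write(str(outdir / "tree.nwk"))
    else:
        stage("read")
        table = otu_mod.read_otu_table(config.counts_path, config.meta_path, config.tax_path)
        if config.run_unifrac and config.tree_path:
            from skbio import TreeNode

            tree = TreeNode.read(str(config.tree_path))

    stage("remove_organelles")
    table = otu_mod.remove_organelles(table)
    functional = otu_mod.assign_functional_groups(table)

    results: dict = {"table": table, "manifest": manifest, "functional_labels": functional}

    # -- branch B: networks on un-rarefied counts --------------------------
    stage("filter_for_networks")
    net_table = otu_mod.filter_for_networks(table, config.min_total, config.min_samples)
    stage("split_by_group")
    grouped = otu_mod.split_by_group(net_table, list(config.network_groups))
    grouped.group_means.to_csv(outdir / "group_mean_abundance.tsv", sep="\t")

    rng = np.random.default_rng(seeds["sparcc"])
    networks, metrics_by_group, keystones_by_group = {}, {}, {}
    for key, sub in grouped.tables.items():
        label = _group_label(key)
        sub_f = otu_mod.filter_for_networks(sub, config.min_total, config.min_samples)
        if sub_f.n_otus < 4 or sub_f.n_samples < 3:
            logger.warning("group %s too small for networks (%d OTUs, %d samples); skipped",
                           label, sub_f.n_otus, sub_f.n_samples)
            continue
        corr = run_sparcc(
            sub_f,
            n_iter=config.sparcc_n_iter,
            n_boot=config.sparcc_n_boot,
            seed=int(rng.integers(2**31)),
        )
        mean_ab = sub_f.relative_abundance().mean(axis=1)
        net = net_mod.build_network(corr.rho, corr.pvals, config.alpha, node_abundance=mean_ab)
        metrics = net_mod.centralities(net)
        ks = net_mod.identify_keystones(metrics["pagerank"], config.keystone_percentile)
        networks[label] = net
        metrics_by_group[label] = metrics
        keystones_by_group[label] = ks
        safe = label.replace("|", "_")
        net_mod.write_network(net, outdir / f"edges_{safe}.tsv", outdir / f"network_{safe}.graphml")
        net_mod.node_metrics_table(metrics, ks).to_csv(outdir / f"nodes_{safe}.tsv", sep="\t")
    stage("networks")
    results.update(networks=networks, metrics=metrics_by_group, keystones=keystones_by_group)

    keystone_union = sorted({o for ks in keystones_by_group.values() for o in ks.otu_ids})
    keystone_census = {
        "n_networks": len(keystones_by_group),
        "n_unique_keystones": len(keystone_union),
        "per_network_counts": {g: len(ks.otu_ids) for g, ks in keystones_by_group.items()},
    }
    with open(outdir / "keystones.json", "w") as fh:
        json.dump({"union": keystone_union, **keystone_census}, fh, indent=1, sort_keys=True)
    results["keystone_census"] = keystone_census

    # abundance- vs importance-weighted clustering of groups
    if len(metrics_by_group) >= 2:
        stage("profile_clustering")
        imp = dist_mod.importance_profiles(metrics_by_group)
        ab = dist_mod.abundance_profiles(grouped.group_means.loc[list(imp.index)])
        for name, prof in (("importance", imp), ("abundance", ab)):
            for metric, fn in (("braycurtis", dist_mod.bray_curtis), ("jaccard", dist_mod.jaccard)):
                dmat = fn(prof)
                dend = dist_mod.hierarchical_cluster(dmat)
                (outdir / f"dendrogram_{name}_{metric}.nwk").write_text(dend.to_newick() + "\n")
            prof.to_csv(outdir / f"profiles_{name}.tsv", sep="\t")

    # -- branch A: rarefied distances + variance partitioning -------------
    stage("rarefy")
    rare = otu_mod.rarefy(table, depth=config.rarefaction_depth, seed=seeds["rarefy"])

    subsets = {"all_otus": rare.otu_ids}
    if keystone_union:
        subsets["keystone_otus"] = [o for o in keystone_union if o in set(rare.otu_ids)]
    rare_functional = functional.loc[rare.otu_ids]
    for group in ("methanogen", "methanotroph"):
        subsets[group + "s"] = list(rare_functional.index[rare_functional == group])

    vp_rng = np.random.default_rng(seeds["varpart"])
    usable_factors = []
    for f in config.varpart_factors:
        if rare.sample_meta[f].nunique() >= 2:
            usable_factors.append(f)
        else:
            logger.warning("factor %s has a single level; dropped from varpart", f)
    factor_groups = {f: [f] for f in usable_factors}
    partitions, stress_by_subset = {}, {}
    for name, otus in subsets.items():
        if len(otus) < 2:
            logger.warning("subset %s has %d OTUs; variance partitioning skipped", name, len(otus))
            continue
        sub = rare.subset_otus(otus)
        nonzero = sub.counts.sum(axis=0) > 0
        sub = sub.subset_samples(list(nonzero.index[nonzero]))
        if len(factor_groups) < 2 or sub.n_samples < len(factor_groups) + 3:
            logger.warning("subset %s has too few non-empty samples; skipped", name)
            continue
        bc = dist_mod.bray_curtis(sub)
        partitions[name] = run_varpart(
            bc, sub.sample_meta, factor_groups,
            n_perm=config.n_perm, seed=int(vp_rng.integers(2**31)),
        )
        partitions[name].table.to_csv(outdir / f"varpart_{name}_braycurtis.tsv", sep="\t")
        if name == "all_otus":
            coords, stress = dist_mod.nmds(bc, k=2, n_starts=10, seed=seeds["nmds"])
            coords.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
            stress_by_subset[name] = stress
            if tree is not None:
                wu = dist_mod.weighted_unifrac(sub, tree)
                partitions["all_otus_unifrac"] = run_varpart(
                    wu, sub.sample_meta, factor_groups,
                    n_perm=config.n_perm, seed=int(vp_rng.integers(2**31)),
                )
                partitions["all_otus_unifrac"].table.to_csv(
                    outdir / "varpart_all_otus_unifrac.tsv", sep="\t"
                )
    stage("variance_partitioning")
    results.update(partitions=partitions, nmds_stress=stress_by_subset)

    report = variance_table(partitions, alpha=config.alpha)
    report.to_csv(outdir / "variance_table.tsv", sep="\t")
    results["variance_table"] = report
    manifest["nmds_stress"] = stress_by_subset
    manifest["keystone_census"] = keystone_census
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
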