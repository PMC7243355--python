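"""Synthetic plant-microbiome communities with known ground truth.

Emulates a permafrost-thaw-gradient sampling design: three habitats (palsa,
bog, fen) x three compartments (phyllosphere, rhizosphere, bulk peat) x six
plant species (each species occurring only in the habitats where it grows),
sampled at three locations over three months.

Generative model, per sample s and OTU k:

    z[s, k] = mu_k + b_habitat[h(s), k] + b_plant[p(s), k]
            + b_compartment[c(s), k] + b_month[m(s), k] + eps[s, k]

where mu_k ~ N(0, basis_sd^2) is the OTU's log basis abundance, each factor
effect is N(0, sd_factor^2) per level, and eps is unit-variance Gaussian
sample noise. Correlation structure is planted in eps *before* compositional
closure:

* planted pairs (i, j) share a latent factor scaled so corr(eps_i, eps_j) =
  planted_rho — the ground truth a compositionality-robust correlation
  method should recover and naive Pearson-on-proportions should distort;
* hub OTUs split their latent variance equally over ``hub_degree`` partner
  OTUs, giving hub-partner correlation planted_rho/sqrt(hub_degree) while
  partners stay mutually uncorrelated — so a hub has many moderate edges
  (high degree) rather than membership in one clique.

Counts are a multinomial draw of each sample's depth (uniform over
``sequencing_depth_range``) from the softmax of z[s, :]: the compositional
closure that SparCC-style estimators are built to undo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otu import (
    METHANOGEN_ORDERS,
    METHANOTROPH_FAMILIES,
    METHANOTROPH_ORDERS,
    OtuTable,
)

#: Habitat membership of the six plant species along the thaw gradient.
DEFAULT_PLANT_HABITATS = {
    "R.chamaemorus": ("palsa",),
    "A.polifolia": ("palsa", "bog"),
    "E.vaginatum": ("palsa", "bog"),
    "Sphagnum": ("palsa", "bog"),
    "C.rotundata": ("bog", "fen"),
    "E.angustifolium": ("fen",),
}

DEFAULT_MONTHS = ("June", "July", "September")

_GENERIC_PHYLA = (
    "Proteobacteria",
    "Acidobacteria",
    "Bacteroidetes",
    "Verrucomicrobia",
    "Actinobacteria",
    "Planctomycetes",
)


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for the community generator."""

    n_locations: int = 3
    habitats: tuple = ("palsa", "bog", "fen")
    compartments: tuple = ("phyllosphere", "rhizosphere", "peat")
    plant_habitats: dict = field(default_factory=lambda: dict(DEFAULT_PLANT_HABITATS))
    months: tuple = DEFAULT_MONTHS
    n_otus: int = 150
    sequencing_depth_range: tuple = (2000, 20000)
    habitat_sd: float = 0.8
    plant_sd: float = 0.5
    compartment_sd: float = 0.5
    month_sd: float = 0.1
    basis_sd: float = 1.5
    n_planted_pairs: int = 5
    planted_rho: float = 0.8
    n_hub_otus: int = 2
    hub_degree: int = 10
    frac_methanogen: float = 0.05
    frac_methanotroph: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sequencing_depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("sequencing_depth_range must be positive and ordered")
        for name in ("frac_methanogen", "frac_methanotroph"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1 < self.planted_rho < 1:
            raise ValueError("planted_rho must lie strictly inside (-1, 1)")
        for name in ("habitat_sd", "plant_sd", "compartment_sd", "month_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for plant, habs in self.plant_habitats.items():
            unknown = set(habs) - set(self.habitats)
            if unknown:
                raise ValueError(f"plant {plant} placed in unknown habitats {unknown}")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    basis_means: pd.DataFrame  # OTU x factor-level log-abundance means
    planted_pairs: list  # (otu_i, otu_j, rho)
    hub_otus: list  # OTU ids
    hub_partners: dict  # hub OTU -> list of partner OTU ids
    functional_labels: pd.Series  # OTU -> methanogen/methanotroph/other
    latent: pd.DataFrame  # samples x OTUs log basis abundances (pre-closure)


def _plant_correlation_structure(rng, n_samples, n_otus, planted_pairs, hubs, rho):
    """Draw eps (n_samples x n_otus, unit marginal variance) with the planted
    pair and hub correlation structure."""
    eps = rng.standard_normal((n_samples, n_otus))
    a = np.sqrt(abs(rho))
    for i, j in planted_pairs:
        u = rng.standard_normal(n_samples)
        eps[:, i] = a * u + np.sqrt(1 - abs(rho)) * eps[:, i]
        eps[:, j] = np.sign(rho) * a * u + np.sqrt(1 - abs(rho)) * eps[:, j]
    for hub, partners in hubs.items():
        d = len(partners)
        v = rng.standard_normal((n_samples, d))
        # hub = equal-variance mix of the d partner factors
        eps[:, hub] = v.sum(axis=1) / np.sqrt(d)
        b = abs(rho)  # partner loading on its own factor
        for col, p in enumerate(partners):
            eps[:, p] = b * v[:, col] + np.sqrt(1 - b**2) * eps[:, p]
    return eps


def _make_taxonomy(rng, otu_ids, frac_methanogen, frac_methanotroph):
    """Greengenes-style 7-rank strings; methane-cyclers first, disjointly."""
    n = len(otu_ids)
    n_mg = int(round(frac_methanogen * n))
    n_mt = int(round(frac_methanotroph * n))
    order = rng.permutation(n)
    mg_idx = order[:n_mg]
    mt_idx = order[n_mg : n_mg + n_mt]
    lineages = {}
    for pos, idx in enumerate(mg_idx):
        o = METHANOGEN_ORDERS[pos % len(METHANOGEN_ORDERS)]
        lineages[otu_ids[idx]] = (
            f"k__Archaea;p__Euryarchaeota;c__Methanomicrobia;o__{o};"
            f"f__{o}_fam;g__;s__"
        )
    mt_lineage_pool = [("o", o) for o in METHANOTROPH_ORDERS] + [
        ("f", f) for f in METHANOTROPH_FAMILIES
    ]
    for pos, idx in enumerate(mt_idx):
        kind, name = mt_lineage_pool[pos % len(mt_lineage_pool)]
        if kind == "o":
            lineages[otu_ids[idx]] = (
                f"k__Bacteria;p__Verrucomicrobia;c__Methylacidiphilae;o__{name};"
                f"f__;g__;s__"
            )
        else:
            lineages[otu_ids[idx]] = (
                f"k__Bacteria;p__Proteobacteria;c__Alphaproteobacteria;"
                f"o__Rhizobiales;f__{name};g__;s__"
            )
    for idx in order[n_mg + n_mt :]:
        phylum = _GENERIC_PHYLA[int(rng.integers(len(_GENERIC_PHYLA)))]
        lineages[otu_ids[idx]] = (
            f"k__Bacteria;p__{phylum};c__{phylum}_cl;o__{phylum}_ord;"
            f"f__{phylum}_fam;g__;s__"
        )
    return pd.Series({o: lineages[o] for o in otu_ids}, name="taxonomy")


def _place_structure(rng, n_otus, n_planted_pairs, n_hub_otus, hub_degree):
    """Choose disjoint OTU indices for pairs, hubs, and hub partners."""
    needed = 2 * n_planted_pairs + n_hub_otus * (1 + hub_degree)
    if needed > n_otus:
        raise ValueError(
            f"cannot place {n_planted_pairs} pairs and {n_hub_otus} hubs of "
            f"degree {hub_degree} among {n_otus} OTUs ({needed} slots needed)"
        )
    chosen = rng.choice(n_otus, size=needed, replace=False)
    pairs = [(int(chosen[2 * p]), int(chosen[2 * p + 1])) for p in range(n_planted_pairs)]
    hubs = {}
    off = 2 * n_planted_pairs
    for h in range(n_hub_otus):
        block = chosen[off + h * (1 + hub_degree) : off + (h + 1) * (1 + hub_degree)]
        hubs[int(block[0])] = [int(x) for x in block[1:]]
    return pairs, hubs


def _counts_from_latent(rng, latent, depth_range):
    """Multinomial closure: counts[s] ~ Multinomial(depth_s, softmax(z_s))."""
    n_samples = latent.shape[0]
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=n_samples)
    z = latent - latent.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    counts = np.empty_like(latent, dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(depths[s], p[s])
    return counts


def generate_community(config: SyntheticConfig) -> tuple[OtuTable, GroundTruth]:
    """Generate an OTU table over the factorial field design.

    One sample per (month, location, habitat, plant-in-habitat, compartment);
    bulk peat is sampled adjacent to each plant so every sample, including
    peat, carries a plant label. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    otu_ids = [f"OTU_{k}" for k in range(config.n_otus)]

    # sample roster
    rows = []
    for month in config.months:
        for loc in range(1, config.n_locations + 1):
            for habitat in config.habitats:
                for plant, habs in config.plant_habitats.items():
                    if habitat not in habs:
                        continue
                    for comp in config.compartments:
                        rows.append(
                            {
                                "habitat": habitat,
                                "compartment": comp,
                                "plant": plant,
                                "month": month,
                                "location": f"L{loc}",
                                "replicate_type": "distributed",
                            }
                        )
    meta = pd.DataFrame(rows)
    meta.index = [f"S{i:04d}" for i in range(len(meta))]
    meta.index.name = "sample_id"

    # factor-level effects
    D = config.n_otus
    mu = rng.normal(0.0, config.basis_sd, size=D)
    factor_sds = {
        "habitat": config.habitat_sd,
        "plant": config.plant_sd,
        "compartment": config.compartment_sd,
        "month": config.month_sd,
    }
    effects = {}
    basis_cols = {"mu": mu}
    for factor, sd in factor_sds.items():
        for level in sorted(meta[factor].unique()):
            eff = rng.normal(0.0, sd, size=D)
            effects[(factor, level)] = eff
            basis_cols[f"{factor}:{level}"] = eff

    pairs, hubs = _place_structure(
        rng, D, config.n_planted_pairs, config.n_hub_otus, config.hub_degree
    )
    eps = _plant_correlation_structure(
        rng, len(meta), D, pairs, hubs, config.planted_rho
    )

    latent = np.tile(mu, (len(meta), 1)) + eps
    for factor in factor_sds:
        levels = meta[factor].to_numpy()
        for level in np.unique(levels):
            latent[levels == level] += effects[(factor, level)]

    counts = _counts_from_latent(rng, latent, config.sequencing_depth_range)
    taxonomy = _make_taxonomy(
        rng, otu_ids, config.frac_methanogen, config.frac_methanotroph
    )
    counts_df = pd.DataFrame(counts.T, index=otu_ids, columns=meta.index)
    table = OtuTable(counts_df, meta, taxonomy)

    from .otu import assign_functional_groups

    truth = GroundTruth(
        basis_means=pd.DataFrame(basis_cols, index=otu_ids),
        planted_pairs=[(otu_ids[i], otu_ids[j], config.planted_rho) for i, j in pairs],
        hub_otus=[otu_ids[h] for h in hubs],
        hub_partners={otu_ids[h]: [otu_ids[p] for p in ps] for h, ps in hubs.items()},
        functional_labels=assign_functional_groups(table),
        latent=pd.DataFrame(latent, index=meta.index, columns=otu_ids),
    )
    return table, truth


def generate_basis_table(
    n_samples: int,
    n_otus: int,
    *,
    n_planted_pairs: int = 0,
    planted_rho: float = 0.8,
    n_hub_otus: int = 0,
    hub_degree: int = 10,
    basis_sd: float = 1.5,
    depth_range: tuple = (2000, 20000),
    dominant_otu_shift: float = 0.0,
    group_labels: list | None = None,
    group_sd: float = 0.0,
    frac_methanogen: float = 0.0,
    frac_methanotroph: float = 0.0,
    seed: int = 0,
) -> tuple[OtuTable, GroundTruth]:
    """Design-free community: ``n_samples`` exchangeable samples.

    Used for null-calibration and correlation-recovery studies where a flat
    sample count (e.g. 100 or 200 samples) is specified instead of the field
    design. ``dominant_otu_shift`` adds a log-scale offset to OTU 0 to force
    compositional dominance; ``group_labels`` + ``group_sd`` optionally add a
    single grouping factor (stored as ``habitat``-column metadata).
    """
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{k}" for k in range(n_otus)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    mu = rng.normal(0.0, basis_sd, size=n_otus)
    mu[0] += dominant_otu_shift
    pairs, hubs = _place_structure(rng, n_otus, n_planted_pairs, n_hub_otus, hub_degree)
    eps = _plant_correlation_structure(rng, n_samples, n_otus, pairs, hubs, planted_rho)
    latent = np.tile(mu, (n_samples, 1)) + eps

    if group_labels is not None:
        if len(group_labels) != n_samples:
            raise ValueError("group_labels must have one entry per sample")
        groups = np.asarray(group_labels)
        basis_cols = {"mu": mu}
        for level in np.unique(groups):
            eff = rng.normal(0.0, group_sd, size=n_otus)
            latent[groups == level] += eff
            basis_cols[f"group:{level}"] = eff
        habitat = groups
    else:
        basis_cols = {"mu": mu}
        habitat = np.repeat("bog", n_samples)

    counts = _counts_from_latent(rng, latent, depth_range)
    meta = pd.DataFrame(
        {
            "habitat": habitat,
            "compartment": "peat",
            "plant": "none",
            "month": "July",
            "location": "L1",
            "replicate_type": "distributed",
        },
        index=sample_ids,
    )
    meta.index.name = "sample_id"
    taxonomy = _make_taxonomy(rng, otu_ids, frac_methanogen, frac_methanotroph)
    table = OtuTable(pd.DataFrame(counts.T, index=otu_ids, columns=sample_ids), meta, taxonomy)

    from .otu import assign_functional_groups

    truth = GroundTruth(
        basis_means=pd.DataFrame(basis_cols, index=otu_ids),
        planted_pairs=[(otu_ids[i], otu_ids[j], planted_rho) for i, j in pairs],
        hub_otus=[otu_ids[h] for h in hubs],
        hub_partners={otu_ids[h]: [otu_ids[p] for p in ps] for h, ps in hubs.items()},
        functional_labels=assign_functional_groups(table),
        latent=pd.DataFrame(latent, index=sample_ids, columns=otu_ids),
    )
    return table, truth


# -- phylogeny -------------------------------------------------------------


def generate_tree(otu_ids: list, seed: int = 0) -> TreeNode:
    """Random rooted bifurcating tree over ``otu_ids``.

    Coalescent-style: repeatedly join two uniformly chosen lineages under a
    new internal node; branch lengths are exponential draws (mean 0.1) plus a
    small floor so every branch is strictly positive. Deterministic given
    ``seed``.
    """
    if len(otu_ids) < 2:
        raise ValueError("need at least two OTU ids")
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=str(o)) for o in otu_ids]
    for n in nodes:
        n.length = float(rng.exponential(0.1) + 1e-3)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.exponential(0.1) + 1e-3)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


# -- serialization ---------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_pairs": [[i, j, r] for i, j, r in truth.planted_pairs],
        "hub_otus": truth.hub_otus,
        "hub_partners": truth.hub_partners,
        "functional_labels": truth.functional_labels.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["habitats"] = list(d["habitats"])
    d["compartments"] = list(d["compartments"])
    d["months"] = list(d["months"])
    d["sequencing_depth_range"] = list(d["sequencing_depth_range"])
    d["plant_habitats"] = {k: list(v) for k, v in d["plant_habitats"].items()}
    return d
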