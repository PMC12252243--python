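"""Synthetic community datasets with the structure the analyses assume.

The generator emulates a 3-cultivation-mode (greenhouse, hilly-
converted, paddy-converted) × 2-growth-stage (flowering, fruiting)
soil survey of protistan ASV communities:

* a random ultrametric phylogeny of the ASVs;
* phylogenetically conserved niche optima (Brownian motion along the
  tree), so that environmental filtering leaves a detectable
  phylogenetic signature;
* a nitrogen-like environmental gradient whose mode-dependent mean
  (greenhouse lowest) imposes selection in the ``selection`` scenario,
  while the ``neutral`` scenario replaces filtering with per-sample
  compositional drift;
* mode/stage-dependent soil chemistry (15 named variables) and fruit
  quality (12 parameters) tables, the latter with a planted per-mode
  effect that puts greenhouse fruit lowest;
* PR2-style lineages spread over clades that cover all three trophic
  groups, plus a few non-protist contaminant ASVs (fungi, metazoans,
  land plants) so the taxon-exclusion filter has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .dataset import CommunityDataset, CULTIVATION_MODES, GROWTH_STAGES

# relative position of each cultivation mode on the nitrogen-like
# gradient (greenhouse lowest, matching the survey's direction)
MODE_SCORE = {"greenhouse": -1.0, "hilly": 0.0, "paddy": 1.0}
STAGE_SCORE = {"flowering": -1.0, "fruiting": 1.0}

#: soil variable -> (baseline, mode coefficient, stage coefficient, noise sd)
SOIL_MODEL: dict[str, tuple[float, float, float, float]] = {
    "pH": (6.9, 0.40, 0.15, 0.20),
    "moisture": (21.0, 1.20, 0.80, 1.50),
    "TN": (2.0, 0.60, 0.10, 0.20),
    "TP": (0.9, 0.20, 0.02, 0.08),
    "TK": (14.0, 2.50, 0.30, 1.00),
    "AP": (35.0, 8.00, 1.50, 4.00),
    "AK": (120.0, 25.0, 5.00, 12.0),
    "ammonia": (5.0, 1.50, 0.30, 0.50),
    "nitrate": (10.0, 0.50, 2.50, 0.80),
    "nitrite": (0.8, 0.20, 0.05, 0.08),
    "DOC": (150.0, 30.0, 8.00, 15.0),
    "ALP": (40.0, 8.00, 2.00, 4.00),
    "beta-Glu": (25.0, 4.00, 2.00, 3.00),
    "urease": (18.0, 3.00, 1.00, 2.00),
    "cellulase": (12.0, 2.00, 1.00, 1.50),
}

#: quality parameter -> (baseline, natural sd); the planted mode effect
#: shifts means by quality_effect x sd (greenhouse down, open field up)
QUALITY_MODEL: dict[str, tuple[float, float]] = {
    "fruit_weight": (150.0, 12.0),
    "fruit_width": (62.0, 3.0),
    "fruit_height": (85.0, 4.0),
    "fruit_shape_index": (1.37, 0.05),
    "pericarp_thickness": (5.5, 0.5),
    "pericarp_weight": (38.0, 3.5),
    "valve_number": (9.5, 0.8),
    "valve_weight": (11.0, 1.0),
    "seed_number": (12.0, 2.5),
    "seed_weight": (3.2, 0.5),
    "solid_rate": (0.38, 0.03),
    "edible_rate": (0.66, 0.03),
}

# lineage templates used to spread the tree's clades over the three
# trophic groups; {i} receives the tip label. Ordered so that, once
# clades are ranked by niche optimum, phototrophs land on the
# low-nitrogen end (enriched in greenhouse soils) and consumers on the
# high-nitrogen end (enriched in the converted open-field farmlands).
_LINEAGE_TEMPLATES = [
    "domain:Eukaryota;supergroup:Archaeplastida;division:Chlorophyta;"
    "class:Chlorophyceae;order:Sphaeropleales;family:Scenedesmaceae;"
    "genus:Scenedesmus;species:Scenedesmus_{i}",
    "domain:Eukaryota;supergroup:Archaeplastida;division:Chlorophyta;"
    "class:Trebouxiophyceae;order:Chlorellales;family:Chlorellaceae;"
    "genus:Chlorella_like;species:Chlorella_{i}",
    "domain:Eukaryota;supergroup:TSAR;division:Stramenopiles;"
    "class:Peronosporomycetes;order:Peronosporales;family:Pythiaceae;"
    "genus:Pythium;species:Pythium_{i}",
    "domain:Eukaryota;supergroup:TSAR;division:Alveolata;class:Apicomplexa;"
    "order:Eugregarinorida;family:Gregarinidae;genus:Gregarina;species:Gregarina_{i}",
    "domain:Eukaryota;supergroup:TSAR;division:Alveolata;class:Ciliophora;"
    "order:Hypotrichia;family:Oxytrichidae;genus:Oxytricha;species:Oxytricha_{i}",
    "domain:Eukaryota;supergroup:TSAR;division:Rhizaria;class:Cercozoa;"
    "order:Cercomonadida;family:Cercomonadidae;genus:Cercomonas;species:Cercomonas_{i}",
]

_CONTAMINANT_TEMPLATES = [
    "domain:Eukaryota;supergroup:Opisthokonta;division:Fungi;class:Ascomycota;"
    "order:Hypocreales;family:Nectriaceae;genus:Fusarium;species:Fusarium_{i}",
    "domain:Eukaryota;supergroup:Opisthokonta;division:Metazoa;class:Nematoda;"
    "order:Rhabditida;family:Rhabditidae;genus:Rhabditis;species:Rhabditis_{i}",
    "domain:Eukaryota;supergroup:Archaeplastida;division:Embryophyta;"
    "class:Magnoliopsida;order:Sapindales;family:Rutaceae;genus:Citrus;"
    "species:Citrus_{i}",
]


@dataclass
class ScenarioSpec:
    """Parameters of one simulated survey.

    ``assembly_mode`` selects environmental filtering ("selection") or
    mode-independent drift ("neutral"); ``niche_breadth`` is the
    Gaussian niche width on the (unitless) environmental axis;
    ``gradient_strength`` scales the between-mode spread of the
    environment relative to the ~unit spread of Brownian niche optima;
    ``depth_mean`` is the Poisson mean sequencing depth per sample.
    """

    n_taxa: int = 40
    n_samples_per_cell: int = 6
    modes: tuple[str, ...] = CULTIVATION_MODES
    stages: tuple[str, ...] = GROWTH_STAGES
    assembly_mode: str = "selection"
    niche_breadth: float = 0.4
    gradient_strength: float = 2.0
    depth_mean: int = 20000
    quality_effect: float = 1.0
    seed: int = 0
    n_contaminants: int = 3
    contaminant_fraction: float = 0.03  # of reads, before taxon exclusion
    env_noise: float = 1.5  # within-cell sd of the environmental value
    stage_coef: float = 0.5  # stage offset relative to the mode spacing
    drift_sd: float = 0.75
    abundance_sigma: float = 0.5
    niche_conservatism: float = 12.0  # early-burst decay rate of niche evolution

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_samples_per_cell < 1:
            raise ValueError("n_samples_per_cell must be >= 1")
        if self.assembly_mode not in ("selection", "neutral"):
            raise ValueError("assembly_mode must be 'selection' or 'neutral'")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth (sigma) must be > 0")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.n_contaminants < 0:
            raise ValueError("n_contaminants must be >= 0")


def scenario(name: str, **overrides) -> ScenarioSpec:
    """Named presets: 'selection', 'neutral', 'greenhouse_vs_openfield'."""
    presets = {
        "selection": {"assembly_mode": "selection"},
        # without filtering, sample sparsity must come from the abundance
        # distribution itself: a strongly skewed lognormal puts rare taxa
        # at the detection edge (as in real ASV tables), while mild drift
        # keeps observed turnover within the Raup-Crick null's reach so
        # stochastic pairs read as drift, not spurious dispersal
        "neutral": {"assembly_mode": "neutral", "drift_sd": 0.5, "abundance_sigma": 3.0},
        # the quality-focused preset: same selective assembly, planted
        # lower-quality greenhouse fruit
        "greenhouse_vs_openfield": {"assembly_mode": "selection", "quality_effect": 1.0},
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    kw = dict(presets[name])
    kw.update(overrides)
    return ScenarioSpec(**kw)


# ---------------------------------------------------------------------------
# Tree and niche simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_taxa: int, seed: int | None = None) -> TreeNode:
    """Random rooted ultrametric tree with unit depth.

    Lineages merge pairwise at exponentially spaced times (a simple
    coalescent construction), then all node heights are rescaled so
    every root-to-tip path has length exactly 1. Tips are labelled
    ``ASV_1 .. ASV_n``.
    """
    if n_taxa < 3:
        raise ValueError("simulate_tree needs n_taxa >= 3")
    rng = np.random.default_rng(seed)

    class _Node:
        __slots__ = ("birth", "children")

        def __init__(self, birth: float) -> None:
            self.birth = birth
            self.children: list["_Node"] = []

    root = _Node(0.0)
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.children = [_Node(t), _Node(t)]
        active.extend(node.children)
    depth = t + rng.exponential(1.0 / n_taxa)  # stretch to just before the next birth
    # normalise by the span from the root's split so tip depths equal 1
    t_root = root.children[0].birth
    span = depth - t_root

    labels = iter(f"ASV_{i + 1}" for i in range(n_taxa))

    def newick(node: _Node) -> str:
        end = node.children[0].birth if node.children else depth
        bl = (end - node.birth) / span
        if node.children:
            inner = ",".join(newick(c) for c in node.children)
            return f"({inner}):{bl:.10f}"
        return f"{next(labels)}:{bl:.10f}"

    inner = ",".join(newick(c) for c in root.children)
    return TreeNode.read([f"({inner});"], convert_underscores=False)


def simulate_niche(
    tree: TreeNode,
    sigma: float,
    seed: int | None = None,
    conservatism: float = 0.0,
) -> pd.Series:
    """Gaussian niche optima evolved along the tree (root value 0).

    ``conservatism=0`` gives plain Brownian motion: each branch adds a
    Gaussian increment with variance sigma² per unit branch length, so
    close relatives end up with similar optima. A positive
    ``conservatism`` is an early-burst decay rate: the variance density
    at height h from the root is sigma²·exp(-conservatism·h), which
    concentrates niche divergence on the deep splits and keeps recent
    relatives tightly clustered — strong phylogenetic niche
    conservatism, the regime that makes betaNTI responsive to
    environmental filtering.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    heights: dict[int, float] = {id(tree): 0.0}
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        h0 = heights[id(node.parent)]
        heights[id(node)] = h0 + bl
        if bl <= 0:
            step = 0.0
        elif conservatism > 0:
            var = (
                sigma**2
                * (np.exp(-conservatism * h0) - np.exp(-conservatism * (h0 + bl)))
                / conservatism
            )
            step = rng.normal(0.0, np.sqrt(var))
        else:
            step = rng.normal(0.0, sigma * np.sqrt(bl))
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series(
        {tip.name: values[id(tip)] for tip in tree.tips()}, name="niche_optimum"
    )


# ---------------------------------------------------------------------------
# Full dataset simulation
# ---------------------------------------------------------------------------


def _taxonomy_for(
    tree: TreeNode, n_protist: int, n_contaminant: int, optima: pd.Series
) -> pd.Series:
    """PR2-style lineages for the simulated tips.

    Protist tips are chunked over clade templates in tree order (so
    lineage groups are phylogenetically coherent); chunks are then
    matched to templates by their mean niche optimum, placing the
    phototroph templates on the low-nitrogen end of the gradient and
    the consumer templates on the high end, as observed in the field.
    Contaminant tips get fungal/metazoan/land-plant lineages.
    """
    tip_order = [t.name for t in tree.tips()]
    protist_tips = [t for t in tip_order if int(t.split("_")[1]) <= n_protist]
    contaminant_tips = [t for t in tip_order if int(t.split("_")[1]) > n_protist]
    lineages: dict[str, str] = {}
    k = len(_LINEAGE_TEMPLATES)
    chunk = max(1, int(np.ceil(len(protist_tips) / k)))
    chunks = [protist_tips[i * chunk : (i + 1) * chunk] for i in range(k)]
    chunks = [c for c in chunks if c]
    order = np.argsort([optima.loc[c].mean() for c in chunks])
    for rank, chunk_idx in enumerate(order):
        template = _LINEAGE_TEMPLATES[min(rank * k // len(chunks), k - 1)]
        for tip in chunks[chunk_idx]:
            lineages[tip] = template.format(i=tip)
    for pos, tip in enumerate(contaminant_tips):
        template = _CONTAMINANT_TEMPLATES[pos % len(_CONTAMINANT_TEMPLATES)]
        lineages[tip] = template.format(i=tip)
    return pd.Series(lineages, name="lineage")


def simulate_dataset(spec: ScenarioSpec) -> CommunityDataset:
    """Generate a complete :class:`CommunityDataset` for a scenario."""
    root_seq = np.random.SeedSequence(spec.seed)
    s_tree, s_niche, s_comm, s_soil, s_qual = root_seq.generate_state(5)

    n_total = spec.n_taxa + spec.n_contaminants
    tree = simulate_tree(n_total, seed=int(s_tree))
    optima = simulate_niche(
        tree, sigma=1.0, seed=int(s_niche), conservatism=spec.niche_conservatism
    )
    # standardize so gradient units are comparable across realizations
    optima = (optima - optima.mean()) / optima.std(ddof=0)
    taxa = [f"ASV_{i + 1}" for i in range(n_total)]
    opt = optima.loc[taxa].to_numpy()

    rng = np.random.default_rng(int(s_comm))
    log_base = rng.normal(0.0, spec.abundance_sigma, size=n_total)
    protist = np.arange(n_total) < spec.n_taxa

    samples: list[str] = []
    cells: list[tuple[str, str]] = []
    for mode in spec.modes:
        for stage_name in spec.stages:
            for i in range(spec.n_samples_per_cell):
                samples.append(f"{mode}_{stage_name}_{i + 1}")
                cells.append((mode, stage_name))

    count_rows = np.zeros((len(samples), n_total), dtype=np.int64)
    env_values = np.zeros(len(samples))
    for s, (mode, stage_name) in enumerate(cells):
        # within-cell environmental heterogeneity: sampling points in one
        # farmland still differ in microhabitat, so replicate samples are
        # exposed to (heterogeneous) selection too
        env = spec.gradient_strength * (
            MODE_SCORE[mode] + spec.stage_coef * STAGE_SCORE[stage_name]
        ) + rng.normal(0.0, spec.env_noise)
        env_values[s] = env
        drift = rng.normal(0.0, spec.drift_sd, size=n_total)
        if spec.assembly_mode == "selection":
            # soft environmental filtering plus per-sample drift, so
            # replicate samples turn over among close relatives rather
            # than being mere multinomial resamples of one community
            log_w = (
                log_base
                - ((opt - env) ** 2) / (2.0 * spec.niche_breadth**2)
                + drift
            )
        else:
            log_w = log_base + drift
        # log-space normalisation keeps extreme filtering from underflowing
        w = np.zeros(n_total)
        lw_p = log_w[protist]
        w[protist] = np.exp(lw_p - lw_p.max())
        # contaminants (fungi/metazoa/land plants) are a modest background
        # fraction of reads outside the protist niche model
        if spec.n_contaminants and spec.contaminant_fraction > 0:
            lw_c = (log_base + drift)[~protist]
            w_cont = np.exp(lw_c - lw_c.max())
            w[~protist] = (
                w_cont
                / w_cont.sum()
                * w[protist].sum()
                * spec.contaminant_fraction
                / (1.0 - spec.contaminant_fraction)
            )
        depth = max(1, int(rng.poisson(spec.depth_mean)))
        count_rows[s] = rng.multinomial(depth, w / w.sum())

    counts = pd.DataFrame(count_rows, index=samples, columns=taxa)
    metadata = pd.DataFrame(
        {
            "cultivation_mode": [m for m, _ in cells],
            "growth_stage": [st for _, st in cells],
            "environment": env_values,
        },
        index=samples,
    )

    soil_rng = np.random.default_rng(int(s_soil))
    soil = pd.DataFrame(index=samples, columns=list(SOIL_MODEL), dtype=float)
    for var, (base, mode_c, stage_c, sd) in SOIL_MODEL.items():
        for s, (mode, stage_name) in enumerate(cells):
            mean = base + mode_c * MODE_SCORE[mode] + stage_c * STAGE_SCORE[stage_name]
            soil.iloc[s, soil.columns.get_loc(var)] = soil_rng.normal(mean, sd)

    qual_rng = np.random.default_rng(int(s_qual))
    quality = pd.DataFrame(index=samples, columns=list(QUALITY_MODEL), dtype=float)
    for par, (base, sd) in QUALITY_MODEL.items():
        for s, (mode, _) in enumerate(cells):
            shift = -spec.quality_effect if mode == "greenhouse" else 0.5 * spec.quality_effect
            quality.iloc[s, quality.columns.get_loc(par)] = qual_rng.normal(
                base + shift * sd, sd
            )

    return CommunityDataset(
        counts=counts,
        taxonomy=_taxonomy_for(tree, spec.n_taxa, spec.n_contaminants, optima),
        metadata=metadata,
        tree=tree,
        soil=soil,
        quality=quality,
    )
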