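"""Reading, writing, and table preparation for community datasets.

File formats are deliberately plain: tab-delimited UTF-8 tables with a
header row and IDs in the first column, plus newick for the phylogeny.
Preparation steps mirror standard post-denoising practice for soil 18S
surveys: drop ASVs assigned to non-protist lineages (fungi, metazoans,
land plants), discard singletons (ASVs whose total read count across
all samples is 1), and rarefy every sample to a common depth.
"""

from __future__ import annotations

import os
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .dataset import CommunityDataset, parse_lineage, warn


class NewickParseError(ValueError):
    pass


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_tree(path: str | os.PathLike) -> TreeNode:
    """Parse a rooted newick tree, naming the offending token on failure."""
    text = Path(path).read_text().strip()
    try:
        tree = TreeNode.read([text], convert_underscores=False)
    except Exception as exc:  # skbio raises several parse exception types
        raise NewickParseError(f"malformed newick in {path}: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise NewickParseError(f"duplicate tip labels in {path}: {dups}")
    return tree


def read_community_data(
    counts_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    tree_path: str | os.PathLike | None = None,
    soil_path: str | os.PathLike | None = None,
    quality_path: str | os.PathLike | None = None,
    orientation: str = "samples_by_asvs",
) -> CommunityDataset:
    """Load and validate a :class:`CommunityDataset` from TSV/newick files.

    ``orientation`` declares the counts-table layout explicitly
    (``samples_by_asvs`` or ``asvs_by_samples``); it is never guessed,
    so a transposed table fails validation loudly rather than silently.
    """
    counts = _read_table(counts_path)
    if orientation == "asvs_by_samples":
        counts = counts.T
    elif orientation != "samples_by_asvs":
        raise ValueError(
            f"orientation must be 'samples_by_asvs' or 'asvs_by_samples', got {orientation!r}"
        )
    counts.columns = counts.columns.astype(str)

    tax_df = _read_table(taxonomy_path)
    if "lineage" not in tax_df.columns:
        raise ValueError(f"taxonomy table {taxonomy_path} lacks a 'lineage' column")
    taxonomy = tax_df["lineage"].astype(str)
    metadata = _read_table(metadata_path)
    tree = None if tree_path is None else read_tree(tree_path)
    soil = None if soil_path is None else _read_table(soil_path)
    quality = None if quality_path is None else _read_table(quality_path)
    return CommunityDataset(
        counts=counts,
        taxonomy=taxonomy,
        metadata=metadata,
        tree=tree,
        soil=soil,
        quality=quality,
    )


def write_community_data(dataset: CommunityDataset, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write all tables of a dataset as TSV (+ newick) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _w(name: str, df: pd.DataFrame, index_label: str) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index_label=index_label)
        paths[name] = p

    _w("counts", dataset.counts, "sample_id")
    _w("taxonomy", dataset.taxonomy.to_frame("lineage"), "asv_id")
    _w("metadata", dataset.metadata, "sample_id")
    if dataset.soil is not None:
        _w("soil", dataset.soil, "sample_id")
    if dataset.quality is not None:
        _w("quality", dataset.quality, "sample_id")
    if dataset.tree is not None:
        p = out / "tree.nwk"
        dataset.tree.write(str(p))
        paths["tree"] = p
    return paths


def load_dataset_dir(dir_path: str | os.PathLike) -> CommunityDataset:
    """Load a dataset previously written by :func:`write_community_data`."""
    d = Path(dir_path)
    return read_community_data(
        counts_path=d / "counts.tsv",
        taxonomy_path=d / "taxonomy.tsv",
        metadata_path=d / "metadata.tsv",
        tree_path=(d / "tree.nwk") if (d / "tree.nwk").exists() else None,
        soil_path=(d / "soil.tsv") if (d / "soil.tsv").exists() else None,
        quality_path=(d / "quality.tsv") if (d / "quality.tsv").exists() else None,
    )


# ---------------------------------------------------------------------------
# Table preparation
# ---------------------------------------------------------------------------


def filter_taxa(
    dataset: CommunityDataset, exclude_lineages: set[str] | frozenset[str]
) -> CommunityDataset:
    """Drop ASVs whose lineage contains any excluded taxon name.

    Matching is exact and case-sensitive against the name at any rank
    (no substring matching), so excluding ``Fungi`` cannot accidentally
    remove, say, a genus whose name merely contains that string.
    """
    exclude = set(exclude_lineages)
    if not exclude:
        return dataset
    keep = []
    for asv in dataset.asv_ids:
        names = {name for _, name in parse_lineage(dataset.taxonomy.loc[asv])}
        if not (names & exclude):
            keep.append(asv)
    if not keep:
        warn("filter_taxa removed every ASV; the resulting table is empty")
    return dataset.subset_asvs(keep)


def remove_singletons(dataset: CommunityDataset) -> CommunityDataset:
    """Drop ASVs whose total read count across all samples equals 1."""
    totals = dataset.counts.sum(axis=0)
    keep = totals.index[totals != 1]
    return dataset.subset_asvs(keep)


def rarefy(dataset: CommunityDataset, depth: int, seed: int | None = None) -> CommunityDataset:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each retained sample's counts are a multivariate-hypergeometric draw
    from its observed counts (uniform subsampling of reads without
    replacement). Samples whose total is below ``depth`` are dropped with
    a warning so that all downstream row sums stay comparable. A fixed
    seed makes the draw bit-reproducible.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = dataset.counts.sum(axis=1)
    kept_rows: dict[str, np.ndarray] = {}
    dropped = []
    for sample in dataset.sample_ids:
        row = dataset.counts.loc[sample].to_numpy()
        if totals.loc[sample] < depth:
            dropped.append(sample)
            continue
        kept_rows[sample] = rng.multivariate_hypergeometric(row, depth)
    if dropped:
        warn(
            f"rarefy dropped {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    if not kept_rows:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    new_counts = pd.DataFrame.from_dict(kept_rows, orient="index", dtype=np.int64)
    new_counts.columns = dataset.counts.columns
    sub = dataset.subset_samples(kept_rows)
    return replace(sub, counts=new_counts.loc[sub.sample_ids])


def prepare(
    dataset: CommunityDataset,
    exclude_lineages: set[str] | frozenset[str] = frozenset(
        {"Fungi", "Metazoa", "Embryophyta"}
    ),
    depth: int = 18907,
    seed: int | None = None,
) -> CommunityDataset:
    """Taxon exclusion, singleton removal, then rarefaction, in that order."""
    out = filter_taxa(dataset, exclude_lineages)
    out = remove_singletons(out)
    return rarefy(out, depth=depth, seed=seed)
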