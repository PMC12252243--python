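"""Central data container for amplicon community analyses.

A :class:`CommunityDataset` bundles the five tables a marker-gene soil
survey produces once reads have been denoised into ASVs (amplicon
sequence variants): the sample-by-ASV count table, per-ASV taxonomic
lineages, a rooted phylogeny of the ASVs, per-sample design metadata
(cultivation mode and crop growth stage), and optional per-sample soil
chemistry and fruit-quality tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

CULTIVATION_MODES = ("greenhouse", "hilly", "paddy")
GROWTH_STAGES = ("flowering", "fruiting")

#: PR2-style rank hierarchy, least to most specific.
RANKS = (
    "domain",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class ValidationError(ValueError):
    """A dataset table violates a structural invariant."""


def parse_lineage(lineage: str) -> list[tuple[str, str]]:
    """Split a ``rank:Name;rank:Name`` lineage string into (rank, name) pairs.

    Entries without an explicit ``rank:`` prefix are assigned ranks
    positionally following :data:`RANKS`.
    """
    out: list[tuple[str, str]] = []
    if not lineage or not lineage.strip():
        return out
    for i, tok in enumerate(lineage.strip().strip(";").split(";")):
        tok = tok.strip()
        if not tok:
            continue
        if ":" in tok:
            rank, name = tok.split(":", 1)
            out.append((rank.strip(), name.strip()))
        else:
            rank = RANKS[i] if i < len(RANKS) else f"rank{i}"
            out.append((rank, tok))
    return out


@dataclass
class CommunityDataset:
    """Counts + taxonomy + phylogeny + metadata for one community survey.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples (rows) by ASVs (columns), non-negative integers.
    taxonomy : pandas.Series
        Per-ASV lineage string (``rank:Name;...``), indexed by ASV id.
    tree : skbio.TreeNode, optional
        Rooted phylogeny with non-negative branch lengths. Its tip set
        must cover every ASV used by phylogenetic operations; coverage
        is checked lazily at those operations, not at construction.
    metadata : pandas.DataFrame
        Per-sample ``cultivation_mode`` and ``growth_stage``.
    soil : pandas.DataFrame, optional
        Per-sample named real-valued soil variables.
    quality : pandas.DataFrame, optional
        Per-sample named real-valued fruit-quality parameters.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame
    tree: TreeNode | None = None
    soil: pd.DataFrame | None = None
    quality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs in counts: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV IDs in counts: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
        if arr.size and (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

        missing_meta = [s for s in c.index if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                f"samples present in counts but absent from metadata: {missing_meta}"
            )
        for col in ("cultivation_mode", "growth_stage"):
            if col not in self.metadata.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
        bad_mode = set(self.metadata["cultivation_mode"]) - set(CULTIVATION_MODES)
        if bad_mode:
            raise ValidationError(f"unknown cultivation_mode values: {sorted(bad_mode)}")
        bad_stage = set(self.metadata["growth_stage"]) - set(GROWTH_STAGES)
        if bad_stage:
            raise ValidationError(f"unknown growth_stage values: {sorted(bad_stage)}")

        missing_tax = [a for a in c.columns if a not in self.taxonomy.index]
        if missing_tax:
            raise ValidationError(
                f"ASVs present in counts but absent from taxonomy: {missing_tax}"
            )
        for name, table in (("soil", self.soil), ("quality", self.quality)):
            if table is None:
                continue
            miss = [s for s in c.index if s not in table.index]
            if miss:
                raise ValidationError(
                    f"samples present in counts but absent from {name}: {miss}"
                )
        if self.tree is not None:
            for node in self.tree.traverse(include_self=False):
                if node.length is not None and node.length < 0:
                    raise ValidationError(
                        f"negative branch length on tree node {node.name!r}"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised counts; rows must have positive totals."""
        totals = self.counts.sum(axis=1)
        zero = totals[totals == 0].index.tolist()
        if zero:
            raise ValidationError(f"samples with zero total count: {zero}")
        return self.counts.div(totals, axis=0)

    def lineages(self) -> dict[str, list[tuple[str, str]]]:
        return {a: parse_lineage(self.taxonomy.loc[a]) for a in self.asv_ids}

    def subset_asvs(self, keep: Iterable[str]) -> "CommunityDataset":
        keep = [a for a in self.asv_ids if a in set(keep)]
        return replace(
            self,
            counts=self.counts[keep].copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
        )

    def subset_samples(self, keep: Iterable[str]) -> "CommunityDataset":
        keep = [s for s in self.sample_ids if s in set(keep)]
        return replace(
            self,
            counts=self.counts.loc[keep].copy(),
            metadata=self.metadata.loc[keep].copy(),
            soil=None if self.soil is None else self.soil.loc[keep].copy(),
            quality=None if self.quality is None else self.quality.loc[keep].copy(),
        )

    def groups(self, by: str = "cell") -> pd.Series:
        """Per-sample group labels: 'mode', 'stage', or 'cell' (mode×stage)."""
        md = self.metadata.loc[self.sample_ids]
        if by == "mode":
            return md["cultivation_mode"]
        if by == "stage":
            return md["growth_stage"]
        if by == "cell":
            return md["cultivation_mode"] + "/" + md["growth_stage"]
        raise ValueError(f"unknown grouping {by!r}; use 'mode', 'stage' or 'cell'")

    def __eq__(self, other: object) -> bool:  # round-trip identity checks
        if not isinstance(other, CommunityDataset):
            return NotImplemented
        if not self.counts.equals(other.counts):
            return False
        if not self.taxonomy.equals(other.taxonomy):
            return False
        if not self.metadata.equals(other.metadata):
            return False
        for a, b in ((self.soil, other.soil), (self.quality, other.quality)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.allclose(a.to_numpy(), b.to_numpy()):
                return False
        ta = None if self.tree is None else str(self.tree)
        tb = None if other.tree is None else str(other.tree)
        return ta == tb


@dataclass
class PipelineConfig:
    """Knobs shared across pipeline stages.

    Defaults follow common amplicon practice for this survey design:
    rarefaction to 18,907 reads, exclusion of the non-protist lineages
    co-amplified by general 18S primers, |betaNTI| > 2 and |RC| > 0.95
    as the deterministic/dispersal thresholds, and 999 randomisations
    for null models and permutation tests.
    """

    rarefaction_depth: int = 18907
    exclude_lineages: frozenset[str] = frozenset({"Fungi", "Metazoa", "Embryophyta"})
    n_null: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be a positive integer")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        self.exclude_lineages = frozenset(self.exclude_lineages)


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
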