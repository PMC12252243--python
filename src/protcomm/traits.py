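"""Trophic functional groups of protists.

Soil protists are conventionally partitioned into three trophic modes
by taxonomic affiliation: consumers (bacterivores and predators, e.g.
ciliates and cercozoans), phototrophs (algal primary producers, mostly
Archaeplastida), and parasites (e.g. apicomplexans and oomycetes such
as *Pythium*). The packaged lookup table is a small curated subset
keyed mostly at higher ranks — enough for common soil clades and the
synthetic generator; a full published matching table can be supplied
as a TSV with columns ``taxon, rank, trait`` and replaces the default
wholesale.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import CommunityDataset, RANKS, parse_lineage

TRAITS = ("consumer", "phototrophic", "parasitic")
UNASSIGNED = "unassigned"

# rank specificity for most-specific-rank-wins resolution
_RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}


class TraitMap:
    """Taxon-name → trophic-trait lookup with rank-specificity resolution."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"taxon", "rank", "trait"}
        if not required.issubset(table.columns):
            raise ValueError(f"trait map needs columns {sorted(required)}")
        bad = set(table["trait"]) - set(TRAITS)
        if bad:
            raise ValueError(f"unknown trait labels: {sorted(bad)}; allowed: {TRAITS}")
        dup = table["taxon"][table["taxon"].duplicated()]
        if not dup.empty:
            conflicts = []
            for t in dup.unique():
                traits = set(table.loc[table["taxon"] == t, "trait"])
                if len(traits) > 1:
                    conflicts.append(t)
            if conflicts:
                raise ValueError(f"conflicting duplicate trait-map keys: {conflicts}")
            table = table.drop_duplicates("taxon")
        self._entries = {
            row.taxon: (row.rank, row.trait) for row in table.itertuples()
        }

    @classmethod
    def default(cls) -> "TraitMap":
        with resources.files("protcomm.data").joinpath("trait_map.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t"))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitMap":
        return cls(pd.read_csv(path, sep="\t"))

    def lookup(self, lineage: list[tuple[str, str]]) -> str:
        """Trait of the most specific matching rank; UNASSIGNED if none."""
        best_level, best_trait = -1, UNASSIGNED
        for rank, name in lineage:
            if name in self._entries:
                level = _RANK_LEVEL.get(rank, len(RANKS))
                if level > best_level:
                    best_level, best_trait = level, self._entries[name][1]
        return best_trait


def assign_traits(
    taxonomy: pd.Series, trait_map: TraitMap | None = None
) -> pd.Series:
    """Per-ASV trophic group from its lineage (most specific rank wins)."""
    tm = trait_map or TraitMap.default()
    return pd.Series(
        {asv: tm.lookup(parse_lineage(lin)) for asv, lin in taxonomy.items()},
        name="trait",
    )


def trait_composition(
    dataset: CommunityDataset, assignment: pd.Series | None = None
) -> pd.DataFrame:
    """Per-sample relative abundance of each trophic group.

    Columns are the three trait groups plus ``unassigned``; each row
    sums to 1 (total relative abundance is conserved).
    """
    if assignment is None:
        assignment = assign_traits(dataset.taxonomy)
    rel = dataset.relative_abundance()
    out = pd.DataFrame(
        0.0, index=rel.index, columns=list(TRAITS) + [UNASSIGNED]
    )
    for group in out.columns:
        members = assignment.index[assignment == group]
        cols = [a for a in rel.columns if a in set(members)]
        if cols:
            out[group] = rel[cols].sum(axis=1)
    return out


def trait_subset(dataset: CommunityDataset, trait: str) -> CommunityDataset:
    """Dataset restricted to the ASVs of one trophic group.

    Useful for per-group ordination/PERMANOVA of a single trait's
    community composition.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; choose from {TRAITS}")
    assignment = assign_traits(dataset.taxonomy)
    return dataset.subset_asvs(assignment.index[assignment == trait])
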