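"""Phylogenetic null-model analysis of community assembly.

The framework quantifies, for every pair of communities, how far their
phylogenetic turnover departs from a random expectation, and reads the
departure as the signature of an ecological process:

* betaMNTD — between-community mean nearest taxon distance: for each
  taxon in one community, the patristic distance to its closest
  relative in the other community, averaged with relative-abundance
  weights (unweighted variant: equal weights over the taxa present).
* betaNTI — the standardized effect size of betaMNTD against a null
  distribution obtained by shuffling tip labels across the whole
  phylogeny while leaving the community matrix untouched.
  betaNTI > +2 indicates heterogeneous selection, betaNTI < -2
  homogeneous selection.
* RCbray — the abundance-based Raup–Crick metric: observed Bray–Curtis
  compared with null community pairs that preserve each sample's
  richness and total count, rescaled to [-1, 1]. Among phylogenetically
  stochastic pairs (|betaNTI| <= 2), RC > +0.95 indicates dispersal
  limitation, RC < -0.95 homogenizing dispersal, |RC| <= 0.95 drift.

:class:`CommunityAssembly` bundles the whole analysis as a model fitted
to a :class:`~protcomm.dataset.CommunityDataset`; its
:meth:`~CommunityAssembly.fit` returns an :class:`AssemblyResults` with
the per-pair matrices, the per-pair process classification, and
per-group process fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .dataset import CommunityDataset

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)
UNDEFINED = "undefined"


# ---------------------------------------------------------------------------
# Patristic distances and betaMNTD
# ---------------------------------------------------------------------------


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix of a tree."""
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dups}")
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def beta_mntd(
    counts: pd.DataFrame, pd_matrix: pd.DataFrame, weighted: bool = True
) -> DistanceMatrix:
    """Between-community mean nearest taxon distance for all sample pairs.

    For samples A, B with relative abundances f:
    betaMNTD(A, B) = 1/2 [ sum_{i in A} f_i min_{j in B} d(i, j)
                         + sum_{j in B} f_j min_{i in A} d(j, i) ].
    A taxon shared by both samples contributes 0 (it is its own nearest
    neighbour). ``weighted=False`` replaces f by 1/richness.
    """
    taxa = [a for a in counts.columns if (counts[a] > 0).any()]
    missing = [a for a in taxa if a not in pd_matrix.index]
    if missing:
        raise ValueError(f"taxa absent from the patristic matrix: {missing}")
    x = counts[taxa].to_numpy(dtype=float)
    empty = np.flatnonzero(x.sum(axis=1) == 0)
    if empty.size:
        bad = [counts.index[i] for i in empty]
        raise ValueError(f"empty sample(s): {bad}")
    d = pd_matrix.loc[taxa, taxa].to_numpy()
    return DistanceMatrix(
        _beta_mntd_core(x, d, weighted), ids=list(counts.index)
    )


def _beta_mntd_core(x: np.ndarray, d: np.ndarray, weighted: bool) -> np.ndarray:
    """Vectorised betaMNTD on a counts array and matching distance matrix."""
    present = x > 0
    if weighted:
        f = x / x.sum(axis=1, keepdims=True)
    else:
        f = present / present.sum(axis=1, keepdims=True)
    n_samples = x.shape[0]
    # nearest[i, s] = distance from taxon i to its closest taxon present in s
    nearest = np.empty((x.shape[1], n_samples))
    for s in range(n_samples):
        nearest[:, s] = d[:, present[s]].min(axis=1)
    g = f @ nearest  # g[A, B] = sum_{i in A} f_iA * min_{j in B} d(i, j)
    out = 0.5 * (g + g.T)
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------


@dataclass
class BetaNTIResult:
    """betaMNTD with its tip-shuffle null distribution summary."""

    beta_mntd: DistanceMatrix
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    beta_nti: pd.DataFrame  # NaN where the null sd is 0 (undefined)


def beta_nti(
    counts: pd.DataFrame,
    pd_matrix: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
    weighted: bool = True,
) -> BetaNTIResult:
    """Standardized effect size of betaMNTD under tip-label shuffling.

    The null keeps the community matrix fixed and permutes tip labels
    across the whole phylogeny ``n_null`` times; betaNTI is
    (observed - null mean) / null sd per pair, with sd taken over the
    null replicates (ddof=1). Pairs whose null sd is 0 (for example on
    a star phylogeny, where shuffling changes nothing) are returned as
    NaN rather than an arbitrary number.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    taxa = [a for a in counts.columns if (counts[a] > 0).any()]
    missing = [a for a in taxa if a not in pd_matrix.index]
    if missing:
        raise ValueError(f"taxa absent from the patristic matrix: {missing}")
    x = counts[taxa].to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        bad = list(counts.index[x.sum(axis=1) == 0])
        raise ValueError(f"empty sample(s): {bad}")
    d = pd_matrix.loc[taxa, taxa].to_numpy()
    weighted = bool(weighted)

    obs = _beta_mntd_core(x, d, weighted)
    rng = np.random.default_rng(seed)
    n_taxa = len(taxa)
    nulls = np.empty((n_null, *obs.shape))
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[k] = _beta_mntd_core(x, d[np.ix_(perm, perm)], weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1) if n_null > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / sd, np.nan)
    np.fill_diagonal(bnti, np.nan)
    ids = list(counts.index)
    return BetaNTIResult(
        beta_mntd=DistanceMatrix(obs, ids=ids),
        null_mean=pd.DataFrame(mean, index=ids, columns=ids),
        null_sd=pd.DataFrame(sd, index=ids, columns=ids),
        beta_nti=pd.DataFrame(bnti, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# Abundance-based Raup-Crick (RCbray)
# ---------------------------------------------------------------------------


def _bray_curtis_pair(a: np.ndarray, b: np.ndarray) -> float:
    return 1.0 - 2.0 * np.minimum(a, b).sum() / (a.sum() + b.sum())


def raup_crick(
    counts: pd.DataFrame, n_null: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Abundance-based Raup–Crick (RCbray) for all sample pairs.

    For each pair, ``n_null`` null community pairs are assembled: each
    null sample keeps its observed richness and total count; its taxa
    are drawn without replacement with probability proportional to
    occurrence frequency across samples; each drawn taxon receives one
    individual (so richness is preserved exactly) and the remaining
    individuals are assigned multinomially with probability
    proportional to the taxa's total relative abundance. With
    RC_raw = (#{null BC < obs BC} + 1/2 #{null BC = obs BC}) / n_null,
    the metric is RC = 2 (RC_raw - 1/2), bounded in [-1, 1].
    """
    if counts.shape[0] < 2:
        raise ValueError("raup_crick needs at least 2 samples")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    x = counts.to_numpy(dtype=float)
    occ = (x > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occ > 0)
    p_occ = occ[pool] / occ[pool].sum()
    abund = x.sum(axis=0)[pool]
    rng = np.random.default_rng(seed)

    n = x.shape[0]
    richness = (x > 0).sum(axis=1)
    totals = x.sum(axis=1).astype(int)

    def null_sample(s: int) -> np.ndarray:
        r, tot = int(richness[s]), int(totals[s])
        drawn = rng.choice(len(pool), size=min(r, len(pool)), replace=False, p=p_occ)
        w = abund[drawn]
        comm = np.ones(len(drawn))
        extra = tot - len(drawn)
        if extra > 0:
            comm += rng.multinomial(extra, w / w.sum())
        full = np.zeros(x.shape[1])
        full[pool[drawn]] = comm
        return full

    rc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs_bc = _bray_curtis_pair(x[i], x[j])
            less = equal = 0
            for _ in range(n_null):
                bc = _bray_curtis_pair(null_sample(i), null_sample(j))
                if bc < obs_bc - 1e-12:
                    less += 1
                elif abs(bc - obs_bc) <= 1e-12:
                    equal += 1
            rc_raw = (less + 0.5 * equal) / n_null
            rc[i, j] = rc[j, i] = 2.0 * (rc_raw - 0.5)
    ids = list(counts.index)
    out = pd.DataFrame(rc, index=ids, columns=ids)
    np.fill_diagonal(out.values, np.nan)
    return out


# ---------------------------------------------------------------------------
# Process classification and partition
# ---------------------------------------------------------------------------


def classify_pair(
    bnti: float, rc: float, bnti_threshold: float = 2.0, rc_threshold: float = 0.95
) -> str:
    if np.isnan(bnti):
        return UNDEFINED
    if bnti > bnti_threshold:
        return "heterogeneous_selection"
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if rc > rc_threshold:
        return "dispersal_limitation"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def within_group_pairs(labels: pd.Series) -> dict[str, list[tuple[str, str]]]:
    """All unordered within-group sample pairs, per group label."""
    out: dict[str, list[tuple[str, str]]] = {}
    for g in labels.unique():
        members = list(labels.index[labels == g])
        out[str(g)] = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    return out


def partition_processes(
    beta_nti: pd.DataFrame,
    raup_crick: pd.DataFrame,
    pair_sets: dict[str, list[tuple[str, str]]],
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Fractions of the five assembly processes per named pair set.

    Per pair: betaNTI > +t selects heterogeneous selection, < -t
    homogeneous selection; otherwise RC > +r is dispersal limitation,
    RC < -r homogenizing dispersal, |RC| <= r drift. Pairs with an
    undefined betaNTI (null sd of 0) are excluded from the fractions
    but reported in an ``n_undefined`` column rather than silently
    dropped. Fractions over the defined pairs of each set sum to 1.
    """
    rows = []
    for group, pairs in pair_sets.items():
        if not pairs:
            raise ValueError(f"empty pair set for group {group!r}")
        tally = {p: 0 for p in PROCESSES}
        undefined = 0
        for s1, s2 in pairs:
            label = classify_pair(
                float(beta_nti.loc[s1, s2]),
                float(raup_crick.loc[s1, s2]),
                bnti_threshold,
                rc_threshold,
            )
            if label == UNDEFINED:
                undefined += 1
            else:
                tally[label] += 1
        defined = sum(tally.values())
        row = {"group": group, "n_pairs": len(pairs), "n_undefined": undefined}
        for p in PROCESSES:
            row[p] = tally[p] / defined if defined else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


class CommunityAssembly:
    """Null-model assembly analysis of a community dataset.

    Parameters
    ----------
    dataset : CommunityDataset
        Must carry a rooted tree covering all ASVs with nonzero counts.
    weighted : bool
        Relative-abundance weighting of betaMNTD (default) or equal
        weights over present taxa.
    bnti_threshold, rc_threshold : float
        Classification thresholds, |betaNTI| > 2 and |RC| > 0.95 by
        convention.

    Examples
    --------
    >>> res = CommunityAssembly(dataset).fit(n_null=199, seed=0)
    >>> res.fractions.loc["greenhouse/flowering", "heterogeneous_selection"]
    """

    def __init__(
        self,
        dataset: CommunityDataset,
        weighted: bool = True,
        bnti_threshold: float = 2.0,
        rc_threshold: float = 0.95,
    ) -> None:
        if dataset.tree is None:
            raise ValueError("CommunityAssembly requires a dataset with a tree")
        self.dataset = dataset
        self.weighted = weighted
        self.bnti_threshold = bnti_threshold
        self.rc_threshold = rc_threshold
        self.pd_matrix = patristic_distances(dataset.tree)

    def fit(
        self, n_null: int = 999, seed: int | None = None, groupby: str = "cell"
    ) -> "AssemblyResults":
        seeds = np.random.SeedSequence(seed).generate_state(2)
        nti = beta_nti(
            self.dataset.counts,
            self.pd_matrix,
            n_null=n_null,
            seed=int(seeds[0]),
            weighted=self.weighted,
        )
        rc = raup_crick(self.dataset.counts, n_null=n_null, seed=int(seeds[1]))
        pair_sets = within_group_pairs(self.dataset.groups(groupby))
        fractions = partition_processes(
            nti.beta_nti, rc, pair_sets, self.bnti_threshold, self.rc_threshold
        )
        ids = self.dataset.sample_ids
        rows = []
        for i, s1 in enumerate(ids):
            for s2 in ids[i + 1 :]:
                b = float(nti.beta_nti.loc[s1, s2])
                r = float(rc.loc[s1, s2])
                rows.append(
                    {
                        "sample_1": s1,
                        "sample_2": s2,
                        "beta_mntd": float(nti.beta_mntd[s1, s2]),
                        "beta_nti": b,
                        "raup_crick": r,
                        "process": classify_pair(
                            b, r, self.bnti_threshold, self.rc_threshold
                        ),
                    }
                )
        return AssemblyResults(
            model=self,
            beta_mntd=nti.beta_mntd,
            null_mean=nti.null_mean,
            null_sd=nti.null_sd,
            beta_nti=nti.beta_nti,
            raup_crick=rc,
            classification=pd.DataFrame(rows),
            fractions=fractions,
            n_null=n_null,
            seed=seed,
        )


@dataclass
class AssemblyResults:
    """Fitted null-model assembly analysis.

    Attributes
    ----------
    beta_mntd : skbio.DistanceMatrix
    null_mean, null_sd, beta_nti, raup_crick : pandas.DataFrame
        Square per-pair matrices (NaN diagonal for betaNTI/RC).
    classification : pandas.DataFrame
        One row per unordered sample pair with its process label.
    fractions : pandas.DataFrame
        Per-group process fractions over defined pairs (rows sum to 1)
        plus the count of undefined pairs.
    """

    model: CommunityAssembly
    beta_mntd: DistanceMatrix
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    beta_nti: pd.DataFrame
    raup_crick: pd.DataFrame
    classification: pd.DataFrame
    fractions: pd.DataFrame
    n_null: int
    seed: int | None = None

    @property
    def selection_fraction(self) -> float:
        """Fraction of defined pairs under selection (|betaNTI| > threshold)."""
        defined = self.classification[self.classification["process"] != UNDEFINED]
        if defined.empty:
            return np.nan
        sel = defined["process"].isin(
            ["heterogeneous_selection", "homogeneous_selection"]
        )
        return float(sel.mean())

    @property
    def mean_beta_nti(self) -> float:
        vals = self.beta_nti.to_numpy()
        iu = np.triu_indices(vals.shape[0], 1)
        return float(np.nanmean(vals[iu]))

    def summary(self) -> str:
        lines = [
            "Community assembly null-model analysis",
            f"  samples: {len(self.beta_nti)}   pairs: {len(self.classification)}"
            f"   null replicates: {self.n_null}",
            f"  mean betaNTI: {self.mean_beta_nti:+.3f}"
            f"   selection fraction: {self.selection_fraction:.3f}",
            "",
            "  Process fractions over defined within-group pairs:",
        ]
        with pd.option_context("display.width", 120):
            lines.append(
                self.fractions.round(4).to_string().replace("\n", "\n  ")
            )
        return "\n".join(lines)
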