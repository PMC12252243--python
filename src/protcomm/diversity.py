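"""Alpha and beta diversity, ordination, and group comparisons.

Alpha indices cover the four facets usually reported for soil protist
surveys: Chao1 (richness), Faith's phylogenetic diversity (evolutionary
breadth), Shannon entropy (diversity, natural log), and Pielou's J
(evenness). Beta diversity is Bray–Curtis on counts, summarised by
principal coordinate analysis and tested by PERMANOVA; univariate group
contrasts use Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha as skbio_alpha
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.stats.distance import permanova as skbio_permanova
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dataset import CommunityDataset, warn

ALPHA_METRICS = ("chao1", "shannon", "pielou", "faith_pd")


def alpha_diversity(dataset: CommunityDataset, metric: str) -> pd.Series:
    """Per-sample alpha diversity.

    Shannon uses the natural log on relative abundances of the nonzero
    taxa; Pielou's J is Shannon / ln(richness), undefined (NaN, with a
    warning) when a sample holds at most one taxon; Chao1 is the
    bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)); Faith PD is the
    total branch length of the minimal rooted subtree spanning the
    sample's taxa and the root.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")
    counts = dataset.counts
    if metric == "faith_pd":
        if dataset.tree is None:
            raise ValueError("faith_pd requires the dataset to carry a tree")
        tips = {t.name for t in dataset.tree.tips()}
        present = counts.columns[(counts > 0).any(axis=0)]
        missing = [a for a in present if a not in tips]
        if missing:
            raise ValueError(
                f"ASVs present in counts but absent from the tree: {missing}"
            )
        vals = {
            s: skbio_faith_pd(
                counts.loc[s].to_numpy(), counts.columns, dataset.tree, validate=False
            )
            for s in counts.index
        }
        return pd.Series(vals, name="faith_pd")

    out = {}
    low_richness = []
    for s in counts.index:
        row = counts.loc[s].to_numpy()
        if metric == "chao1":
            out[s] = skbio_alpha.chao1(row, bias_corrected=True)
        elif metric == "shannon":
            out[s] = skbio_alpha.shannon(row, base=np.e)
        else:  # pielou
            richness = int((row > 0).sum())
            if richness <= 1:
                low_richness.append(s)
                out[s] = np.nan
            else:
                out[s] = skbio_alpha.shannon(row, base=np.e) / np.log(richness)
    if low_richness:
        warn(f"pielou undefined (richness <= 1) for samples: {low_richness}")
    return pd.Series(out, name=metric)


def alpha_table(dataset: CommunityDataset) -> pd.DataFrame:
    """All four alpha indices as one samples × metrics table."""
    metrics = list(ALPHA_METRICS) if dataset.tree is not None else [
        m for m in ALPHA_METRICS if m != "faith_pd"
    ]
    return pd.DataFrame({m: alpha_diversity(dataset, m) for m in metrics})


def bray_curtis(dataset: CommunityDataset) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity on counts.

    BC(x, y) = 1 - 2 * sum_k min(x_k, y_k) / (sum x + sum y).
    """
    counts = dataset.counts
    if counts.shape[0] < 2:
        raise ValueError("bray_curtis needs at least 2 samples")
    totals = counts.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    x = counts.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[i], x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (x[i].sum() + x[i + 1 :].sum(axis=1))
    d = d + d.T
    return DistanceMatrix(d, ids=list(counts.index))


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds only positive-eigenvalue axes, scaled by the
    square root of their eigenvalues; negative eigenvalues are reported
    in ``eigenvalues`` but contribute no axis. ``proportion_explained``
    is each retained axis's eigenvalue over the sum of positive
    eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling via Gower centering."""
    d = dm.data
    n = d.shape[0]
    if n < 2:
        raise ValueError("pcoa needs at least 2 samples")
    a = -0.5 * d**2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigvals, eigvecs = scipy.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # tiny negative rounding noise around zero is squashed, genuine
    # non-Euclidean negatives are kept and reported
    eigvals[np.abs(eigvals) < 1e-10 * max(1.0, np.abs(eigvals).max())] = 0.0
    if (eigvals < 0).any():
        warn(
            f"pcoa: {(eigvals < 0).sum()} negative eigenvalue(s) reported, "
            "axes omitted from coordinates (no Lingoes/Cailliez correction)"
        )
    pos = eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=list(dm.ids), columns=cols)
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=coordinates, eigenvalues=eigvals, proportion_explained=prop
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int

    def __repr__(self) -> str:  # compact, vegan-adonis-style line
        return (
            f"PERMANOVA: pseudo-F={self.pseudo_F:.4g} R2={self.R2:.4f} "
            f"p={self.p_value:.4g} ({self.n_perm} permutations)"
        )


def _permanova_ss(dm: DistanceMatrix, labels: pd.Series) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson 2001)."""
    d2 = dm.data**2
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    ids = np.asarray(dm.ids)
    for g in labels.unique():
        idx = np.flatnonzero(np.isin(ids, labels.index[labels == g]))
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dm: DistanceMatrix,
    labels: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with unrestricted seeded label permutations.

    The pseudo-F and permutation p-value come from scikit-bio's
    implementation; R² (SS_among / SS_total) is added here from the same
    distance partition.
    """
    labels = labels.loc[list(dm.ids)]
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("permanova needs at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    res = skbio_permanova(dm, labels.to_numpy(), permutations=n_perm, seed=seed)
    ss_total, ss_within = _permanova_ss(dm, labels)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        pseudo_F=float(res["test statistic"]),
        R2=float(r2),
        p_value=float(res["p-value"]),
        n_perm=int(res["number of permutations"]),
    )


def tukey_groups(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise Tukey–Kramer HSD comparisons of group means.

    Returns a table with columns ``group1, group2, difference, p_adj``.
    When every group has zero within-group variance and all means are
    equal the studentized range is degenerate; those comparisons are
    reported with p_adj = 1 and a warning.
    """
    values = values.dropna()
    labels = labels.loc[values.index]
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("tukey_groups needs at least 2 groups")
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 observations: {small}")

    mse = sum(
        ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
        for g in sizes.index
    ) / (len(values) - len(sizes))
    if mse == 0:
        warn("tukey_groups: zero within-group variance in every group")
        pairs = []
        groups = sorted(sizes.index)
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1 :]:
                diff = values[labels == g2].mean() - values[labels == g1].mean()
                pairs.append((g1, g2, diff, 1.0 if diff == 0 else 0.0))
        return pd.DataFrame(pairs, columns=["group1", "group2", "difference", "p_adj"])

    res = pairwise_tukeyhsd(values.to_numpy(), labels.to_numpy())
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c.strip() for c in res.summary().data[0]]
    )
    out = frame[["group1", "group2", "meandiff", "p-adj"]].rename(
        columns={"meandiff": "difference", "p-adj": "p_adj"}
    )
    out["p_adj"] = res.pvalues  # full precision, not the rounded summary
    out["difference"] = res.meandiffs
    return out


def within_group_distances(
    dm: DistanceMatrix, labels: pd.Series
) -> dict[str, np.ndarray]:
    """All within-group off-diagonal distances, per group.

    Groups of size 1 contribute no pairs and are excluded with a warning.
    The result feeds directly into :func:`tukey_groups` (values = pooled
    distances, labels = group of each pair).
    """
    labels = labels.loc[list(dm.ids)]
    out: dict[str, np.ndarray] = {}
    singletons = []
    ids = np.asarray(dm.ids)
    for g in labels.unique():
        idx = np.flatnonzero(np.isin(ids, labels.index[labels == g]))
        if len(idx) < 2:
            singletons.append(g)
            continue
        sub = dm.data[np.ix_(idx, idx)]
        out[str(g)] = sub[np.triu_indices(len(idx), 1)]
    if singletons:
        warn(f"groups of size 1 excluded from within-group distances: {singletons}")
    return out
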