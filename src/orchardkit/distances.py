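"""Distance matrices, clustering trees, and the Mantel congruence test.

Phenotypic side: Mahalanobis dissimilarity between clones on standardized
genotypic values, and average-linkage (UPGMA) clustering on 1 - Pearson
profile correlation.  Molecular side: Nei (1972) standard distance between
populations, shared-allele dissimilarity between individuals, and
neighbor-joining trees.  Congruence between the two data layers is tested
with a one-sided permutation Mantel test.

``skbio.DistanceMatrix`` is the distance container throughout, and trees are
``skbio.TreeNode`` objects (so Newick export is free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .genotypes import GenotypeTable

__all__ = [
    "mahalanobis_matrix",
    "pearson_upgma",
    "cut_tree",
    "nei_distance",
    "nei_distance_matrix",
    "individual_distance",
    "neighbor_joining",
    "mantel",
    "MantelResult",
    "Upgma",
    "top_fraction",
]


# ---------------------------------------------------------------------------
# Phenotypic distances
# ---------------------------------------------------------------------------

def mahalanobis_matrix(z: pd.DataFrame, ridge: float = 1e-8) -> DistanceMatrix:
    """Pairwise Mahalanobis distances between clone rows of a z-score matrix.

    d(i, j) = sqrt((xi - xj)' S^-1 (xi - xj)) with S the trait covariance of
    the standardized clonal values.  When S is singular (fewer clones than
    traits, or collinear traits) a ridge-regularized pseudo-inverse is used.
    """
    x = z.to_numpy(float)
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least two clones")
    s = np.cov(x, rowvar=False)
    if p == 1:
        s = np.array([[float(s)]])
    try:
        if n <= p:
            raise np.linalg.LinAlgError("fewer clones than traits")
        vi = np.linalg.inv(s)
    except np.linalg.LinAlgError:
        vi = np.linalg.pinv(s + ridge * np.eye(p))
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, vi, diff)
    d2 = np.clip((d2 + d2.T) / 2.0, 0.0, None)
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(np.sqrt(d2), ids=[str(i) for i in z.index])


@dataclass
class Upgma:
    """Average-linkage dendrogram: scipy linkage plus labels and Newick export."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        """Group membership (1..k) from cutting the dendrogram into k clusters."""
        memb = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(memb, index=self.labels, name="group")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_tree(self) -> TreeNode:
        root = hierarchy.to_tree(self.linkage)

        def build(node) -> TreeNode:
            if node.is_leaf():
                return TreeNode(name=self.labels[node.id], length=node.dist / 2.0)
            t = TreeNode(children=[build(node.left), build(node.right)])
            # ultrametric: edge length = parent height/2 - child height/2
            for child, src in zip(t.children, (node.left, node.right)):
                child.length = (node.dist - src.dist) / 2.0
            return t

        tree = build(root)
        tree.length = None
        return tree

    def newick(self) -> str:
        return str(self.to_tree()).strip()


def pearson_upgma(profiles: pd.DataFrame) -> Upgma:
    """UPGMA dendrogram on 1 - Pearson correlation of clone trait profiles.

    Each clone's profile is its row of (typically standardized) trait values;
    two clones with identical profiles merge at height 0.  Zero-variance
    profiles have no defined correlation and are rejected.
    """
    x = profiles.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("need at least two clones")
    if (x.std(axis=1) <= 0).any():
        raise ValueError("zero-variance clone profile: Pearson similarity undefined")
    d = 1.0 - np.corrcoef(x)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Upgma(linkage=link, labels=[str(i) for i in profiles.index])


def cut_tree(dendrogram: Upgma, k: int) -> pd.Series:
    return dendrogram.cut(k)


def top_fraction(clone_values: pd.DataFrame, traits: list[str], frac: float = 0.10) -> list[str]:
    """Highest-performing clones by mean rank over the given traits.

    Ranking helper for shortlisting breeding material (e.g. the top 10% by
    stem volume or seed weight genotypic value).
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    ranks = clone_values[traits].rank(ascending=False).mean(axis=1)
    k = max(1, int(round(frac * len(clone_values))))
    return ranks.nsmallest(k).index.tolist()


# ---------------------------------------------------------------------------
# Molecular distances
# ---------------------------------------------------------------------------

def nei_distance(p_freqs: dict[str, dict[int, float]],
                 q_freqs: dict[str, dict[int, float]]) -> float:
    """Nei (1972) standard genetic distance between two populations.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with identities summed over all loci:
    Jxy = sum_l sum_a p_la q_la, Jx = sum_l sum_a p_la^2, Jy likewise.  With
    no shared alleles at any locus the identity is zero and D is infinite
    (returned as ``inf``).
    """
    loci = sorted(set(p_freqs) & set(q_freqs))
    if not loci:
        raise ValueError("no shared loci")
    jxy = jx = jy = 0.0
    for locus in loci:
        p, q = p_freqs[locus], q_freqs[locus]
        alleles = set(p) | set(q)
        for a in alleles:
            pa, qa = p.get(a, 0.0), q.get(a, 0.0)
            jxy += pa * qa
            jx += pa * pa
            jy += qa * qa
    if jxy <= 0:
        return float("inf")
    return float(-math.log(jxy / math.sqrt(jx * jy)))


def nei_distance_matrix(af) -> DistanceMatrix:
    """Pairwise Nei distances among all groups of an :class:`AlleleFrequencies`."""
    groups = af.groups
    n = len(groups)
    d = np.zeros((n, n))
    per_group = [
        {locus: af.freqs[(g, locus)] for locus in af.loci if (g, locus) in af.freqs}
        for g in groups
    ]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(per_group[i], per_group[j])
    return DistanceMatrix(d, ids=groups)


def individual_distance(table: GenotypeTable) -> DistanceMatrix:
    """Shared-allele dissimilarity between individuals.

    d(i, j) = 1 - mean over loci of (shared alleles at the locus) / 2, where
    the shared-allele count between two diploid genotypes is the size of the
    multiset intersection of their allele pairs (0, 1 or 2).  Loci missing in
    either individual are skipped for that pair.
    """
    n = table.n_individuals
    # allele count vectors per locus for multiset intersections
    share = np.zeros((n, n))
    denom = np.zeros((n, n))
    for l in range(table.n_loci):
        ok = ~table.missing[:, l]
        alleles = np.unique(table.calls[ok, l, :]) if ok.any() else np.array([], int)
        if alleles.size == 0:
            continue
        idx = {a: k for k, a in enumerate(alleles.tolist())}
        y = np.zeros((n, alleles.size))
        for i in np.where(ok)[0]:
            y[i, idx[int(table.calls[i, l, 0])]] += 1
            y[i, idx[int(table.calls[i, l, 1])]] += 1
        # multiset intersection size = sum_a min(y_i, y_j)
        mins = np.minimum(y[:, None, :], y[None, :, :]).sum(axis=2)
        pair_ok = np.outer(ok, ok)
        share += np.where(pair_ok, mins, 0.0)
        denom += np.where(pair_ok, 2.0, 0.0)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(denom > 0, share / denom, 1.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(table.individuals))


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining on a labeled distance matrix.

    Standard Q-criterion agglomeration; ties broken by the first (lowest
    index) pair so output is deterministic.  Negative branch lengths are
    clamped to zero and the deficit moved to the sister edge, preserving the
    pairwise path length of the joined pair.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    active = list(range(n))
    d = d.copy()
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives; keep li + lj = dij
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    i, j = active
    nodes[i].length = None
    nodes[j].length = float(max(d[i, j], 0.0))
    root = nodes[i]
    root.append(nodes[j])
    return root


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    permutations: int
    p_value: float
    seed: int | None
    alternative: str = "greater"


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, alternative: str = "greater") -> MantelResult:
    """Permutation Mantel test of correlation between two distance matrices.

    r is the Pearson correlation of the upper off-diagonal triangles; the null
    distribution permutes the labels of the second matrix.  The one-sided
    ``greater`` alternative (positive congruence) is the default; p uses the
    add-one rule (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share identical label order")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("bad alternative")
    a = np.asarray(d1.data, float)
    b = np.asarray(d2.data, float)
    iu = np.triu_indices(a.shape[0], k=1)
    x = a[iu]

    def corr(mat: np.ndarray) -> float:
        yv = mat[iu]
        return float(np.corrcoef(x, yv)[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs
        elif alternative == "less":
            hits += r_p <= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, permutations=n_perm, p_value=float(p),
                        seed=seed, alternative=alternative)
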