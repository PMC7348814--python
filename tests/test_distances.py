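"""Distance matrices, UPGMA/NJ trees, and the Mantel permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from orchardkit.distances import (individual_distance, mahalanobis_matrix,
                                  mantel, nei_distance, neighbor_joining,
                                  pearson_upgma, top_fraction)
from orchardkit.genotypes import GenotypeTable
from orchardkit.quantgen import fit_rcb, standardize_clonal_values
from orchardkit.simulate import OrchardSimSpec, simulate_orchard
from conftest import random_table


# ----------------------------------------------------------------- Mahalanobis

def test_mahalanobis_reduces_to_euclidean_for_identity_covariance(rng):
    # columns with unit sample covariance: d equals the Euclidean distance
    x = rng.normal(size=(40, 3))
    # decorrelate exactly
    x = (x - x.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(x, rowvar=False))).T
    df = pd.DataFrame(x, index=[f"c{i}" for i in range(40)])
    dm = mahalanobis_matrix(df)
    d_euc = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    assert np.allclose(dm.data, d_euc, atol=1e-8)


def test_mahalanobis_duplicate_profile_zero_distance(rng):
    x = rng.normal(size=(6, 2))
    x[3] = x[0]
    dm = mahalanobis_matrix(pd.DataFrame(x))
    assert dm.data[0, 3] == pytest.approx(0.0, abs=1e-10)


def test_mahalanobis_matches_hand_computation():
    x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [1.0, 2.0]])
    dm = mahalanobis_matrix(pd.DataFrame(x))
    vi = np.linalg.inv(np.cov(x, rowvar=False))
    for i, j in itertools.combinations(range(4), 2):
        d = x[i] - x[j]
        assert dm.data[i, j] == pytest.approx(math.sqrt(d @ vi @ d), rel=1e-9)


# ----------------------------------------------------------------------- UPGMA

def naive_average_linkage(d: np.ndarray):
    """O(n^3) UPGMA oracle returning sorted merge heights."""
    clusters = {i: [i] for i in range(d.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights


def test_upgma_identical_profiles_merge_at_zero(rng):
    x = rng.normal(size=(5, 6))
    x[1] = x[0]
    tree = pearson_upgma(pd.DataFrame(x))
    assert tree.heights.min() == pytest.approx(0.0, abs=1e-12)


def test_upgma_matches_naive_agglomeration(rng):
    x = rng.normal(size=(7, 10))
    tree = pearson_upgma(pd.DataFrame(x))
    d = 1 - np.corrcoef(x)
    np.fill_diagonal(d, 0)
    assert np.allclose(sorted(tree.heights), naive_average_linkage(d), atol=1e-9)


def test_upgma_tree_is_ultrametric(rng):
    x = rng.normal(size=(8, 5))
    tree = pearson_upgma(pd.DataFrame(x, index=[f"c{i}" for i in range(8)])).to_tree()
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    assert np.allclose(depths, depths[0], atol=1e-9)


def test_upgma_zero_variance_profile_rejected():
    x = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 2.0, 1.0]])
    with pytest.raises(ValueError, match="variance"):
        pearson_upgma(x)


def test_upgma_recovers_simulated_clusters():
    # three well-separated latent groups of clones (shift 6 genetic sd)
    spec = OrchardSimSpec(n_clones=60, n_blocks=6, site_sizes=(40, 20),
                          n_clone_groups=3, group_shift_sd=6.0)
    rec = simulate_orchard(spec, seed=42)
    cm = pd.DataFrame({t: fit_rcb(rec, t).clone_means
                       for t in rec["trait"].unique()})
    groups = rec.drop_duplicates("clone").set_index("clone")["group"]
    cut = pearson_upgma(standardize_clonal_values(cm)).cut(3)
    # adjusted-for-chance agreement via pair counting (Rand index)
    same_true = groups.values[:, None] == groups.values[None, :]
    same_est = cut.values[:, None] == cut.values[None, :]
    iu = np.triu_indices(len(groups), 1)
    rand = (same_true[iu] == same_est[iu]).mean()
    assert rand > 0.95


# ------------------------------------------------------------------------- Nei

def test_nei_identical_frequencies_zero():
    f = {"L1": {1: 0.3, 2: 0.7}, "L2": {1: 1.0}}
    assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)


def test_nei_disjoint_alleles_infinite():
    assert math.isinf(nei_distance({"L1": {1: 1.0}}, {"L1": {2: 1.0}}))


def test_nei_two_locus_hand_value():
    p = {"L1": {1: 0.8, 2: 0.2}, "L2": {1: 0.5, 2: 0.5}}
    q = {"L1": {1: 0.4, 2: 0.6}, "L2": {1: 0.9, 2: 0.1}}
    jxy = (0.8 * 0.4 + 0.2 * 0.6) + (0.5 * 0.9 + 0.5 * 0.1)
    jx = (0.64 + 0.04) + (0.25 + 0.25)
    jy = (0.16 + 0.36) + (0.81 + 0.01)
    assert nei_distance(p, q) == pytest.approx(-math.log(jxy / math.sqrt(jx * jy)))


# ---------------------------------------------------------- individual distance

def test_individual_distance_identical_and_disjoint():
    t = GenotypeTable(
        ["a", "b", "c"], ["L1", "L2"], ["P1"] * 3,
        np.array([
            [[100, 102], [200, 200]],
            [[100, 102], [200, 200]],
            [[104, 106], [202, 204]],
        ]))
    dm = individual_distance(t)
    assert dm["a", "b"] == pytest.approx(0.0)
    assert dm["a", "c"] == pytest.approx(1.0)


def test_individual_distance_matches_brute_force(rng):
    t = random_table(rng, n=12, loci=5, missing_rate=0.1)
    dm = individual_distance(t)
    for a, b in itertools.combinations(t.individuals, 2):
        shares, used = [], 0
        for locus in t.loci:
            ca, cb = t.call(a, locus), t.call(b, locus)
            if ca is None or cb is None:
                continue
            used += 1
            cb_list = list(cb)
            s = 0
            for allele in ca:
                if allele in cb_list:
                    cb_list.remove(allele)
                    s += 1
            shares.append(s / 2)
        expect = 1 - np.mean(shares) if used else 1.0
        assert dm[a, b] == pytest.approx(expect, abs=1e-12)


# -------------------------------------------------------------------------- NJ

def tree_dists(tree, ids):
    td = tree.tip_tip_distances(ids)
    return np.asarray(td.data)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distance matrix
    d = np.array([
        [0, 3, 5, 3],
        [3, 0, 6, 4],
        [5, 6, 0, 4],
        [3, 4, 4, 0],
    ], dtype=float)
    dm = DistanceMatrix(d, ids=list("ABCD"))
    tree = neighbor_joining(dm)
    got = tree_dists(tree, list("ABCD"))
    assert np.allclose(got, d, atol=1e-9)
    # AB vs CD split recovered
    ab = tree.lca(["A", "B"])
    assert {t.name for t in ab.tips()} in ({"A", "B"}, {"C", "D"})


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(d, ids=list("XYZ")))
    # star lengths: x = (3+4-5)/2 = 1, y = 2, z = 3
    lengths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
    assert lengths["X"] + lengths["Y"] == pytest.approx(3)
    assert lengths["X"] + lengths["Z"] == pytest.approx(4)
    assert lengths["Y"] + lengths["Z"] == pytest.approx(5)


def test_nj_matches_skbio_on_random_matrix(rng):
    x = rng.normal(size=(7, 4))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    ids = [f"t{i}" for i in range(7)]
    dm = DistanceMatrix(d, ids=ids)
    ours = neighbor_joining(dm)
    ref = skbio_nj(dm)
    assert ours.compare_rfd(ref) == 0.0


def test_nj_label_order_invariance(rng):
    x = rng.normal(size=(6, 3))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    ids = [f"t{i}" for i in range(6)]
    t1 = neighbor_joining(DistanceMatrix(d, ids=ids))
    perm = rng.permutation(6)
    t2 = neighbor_joining(DistanceMatrix(d[np.ix_(perm, perm)],
                                         ids=[ids[i] for i in perm]))
    total1 = sum(n.length or 0 for n in t1.traverse())
    total2 = sum(n.length or 0 for n in t2.traverse())
    assert total1 == pytest.approx(total2, rel=1e-9)
    assert t1.compare_rfd(t2) == 0.0


def test_nj_rejects_asymmetric_input():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(Exception):
        neighbor_joining(DistanceMatrix(d, ids=list("abc")))


def test_nj_agrees_with_upgma_on_ultrametric(rng):
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform
    x = rng.normal(size=(6, 4))
    d = squareform(np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1)), checks=False)
    link = hierarchy.linkage(d, "average")
    coph = squareform(hierarchy.cophenet(link))
    ids = [f"t{i}" for i in range(6)]
    njt = neighbor_joining(DistanceMatrix(coph, ids=ids))
    upg = pearson_upgma  # topology check only, via cluster splits
    # NJ on an ultrametric matrix recovers the UPGMA topology
    tree2 = skbio_nj(DistanceMatrix(coph, ids=ids))
    assert njt.compare_rfd(tree2) == 0.0


# ---------------------------------------------------------------------- Mantel

def test_mantel_self_correlation(rng):
    x = rng.normal(size=(8, 3))
    d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    dm = DistanceMatrix(d, ids=[f"i{k}" for k in range(8)])
    res = mantel(dm, dm, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_p_matches_exhaustive_enumeration(rng):
    n = 5
    x, y = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
    da = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
    db = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
    np.fill_diagonal(da, 0), np.fill_diagonal(db, 0)
    ids = list("abcde")
    res = mantel(DistanceMatrix(da, ids=ids), DistanceMatrix(db, ids=ids),
                 n_perm=4999, seed=1)
    iu = np.triu_indices(n, 1)
    robs = np.corrcoef(da[iu], db[iu])[0, 1]
    exact = np.mean([
        np.corrcoef(da[iu], db[np.ix_(p, p)][iu])[0, 1] >= robs - 1e-12
        for p in itertools.permutations(range(n))])
    assert res.r == pytest.approx(robs)
    # Monte-Carlo p within binomial error of the exhaustive p
    se = math.sqrt(exact * (1 - exact) / 5000)
    assert res.p_value == pytest.approx(exact, abs=4 * se + 1e-3)


def test_mantel_type_one_error(rng):
    # under independence, rejection rate at alpha = 0.05 stays near 0.05
    n = 10
    rejections = 0
    sims = 400
    for _ in range(sims):
        x, y = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
        da = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        db = np.sqrt(((y[:, None] - y[None, :]) ** 2).sum(-1))
        np.fill_diagonal(da, 0), np.fill_diagonal(db, 0)
        ids = [str(i) for i in range(n)]
        res = mantel(DistanceMatrix(da, ids=ids), DistanceMatrix(db, ids=ids),
                     n_perm=99, seed=int(rng.integers(2 ** 31)))
        rejections += res.p_value <= 0.05
    assert rejections / sims == pytest.approx(0.05, abs=0.02)


def test_mantel_label_mismatch_rejected(rng):
    d = np.array([[0, 1.0], [1.0, 0]])
    with pytest.raises(ValueError, match="label"):
        mantel(DistanceMatrix(d, ids=["a", "b"]),
               DistanceMatrix(d, ids=["b", "a"]), n_perm=99)


def test_top_fraction_ranking():
    cv = pd.DataFrame({"vol": [5.0, 1.0, 3.0, 4.0, 2.0]},
                      index=list("abcde"))
    assert top_fraction(cv, ["vol"], frac=0.4) == ["a", "d"]
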