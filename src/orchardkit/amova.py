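"""Two-level analysis of molecular variance (AMOVA) on codominant genotypes.

Sums of squares follow the Excoffier squared-distance formulation: with
pairwise squared genetic distances d2(i, j) between individuals,
SS_total = sum_{i<j} d2 / n and SS_within = sum_g sum_{i<j in g} d2 / n_g,
SS_among = SS_total - SS_within.  The genetic distance is the codominant
allele-count distance d2 = 1/2 * ||y_i - y_j||^2 on per-locus allele count
vectors (0 for identical genotypes, 1 for one shared allele of a
heterozygote, up to 4 for opposite homozygotes), the GenAlEx default.

Degrees of freedom default to the gene-copy level: (G-1, 2N-G, 2N-1) for N
diploids in G groups, with the unequal-size EMS coefficient n0 computed on
gene-copy counts.  The individual level (G-1, N-G, N-1) is available via
``level="individual"``.  Significance of Phi_ST comes from random permutation
of individuals across groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = ["AmovaTable", "amova_two_level", "amova_report", "squared_distance_matrix"]


def squared_distance_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise codominant squared distances (allele-count metric) between individuals.

    Loci missing in either member of a pair are excluded from that pair's sum
    (no rescaling).
    """
    n = table.n_individuals
    d2 = np.zeros((n, n))
    for l in range(table.n_loci):
        ok = ~table.missing[:, l]
        if not ok.any():
            continue
        alleles = np.unique(table.calls[ok, l, :])
        idx = {int(a): k for k, a in enumerate(alleles.tolist())}
        y = np.zeros((n, alleles.size))
        for i in np.where(ok)[0]:
            y[i, idx[int(table.calls[i, l, 0])]] += 1
            y[i, idx[int(table.calls[i, l, 1])]] += 1
        diff = y[:, None, :] - y[None, :, :]
        contrib = 0.5 * (diff ** 2).sum(axis=2)
        pair_ok = np.outer(ok, ok)
        d2 += np.where(pair_ok, contrib, 0.0)
    return d2


@dataclass
class AmovaTable:
    """AMOVA partition: rows among/within/total with df, SS, MS, components, %."""

    table: pd.DataFrame
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    level: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.table.to_string()}\n"
            f"Phi_ST = {self.phi_st:.4f}  (p = {self.p_value:.4g}, "
            f"{self.n_permutations} permutations)"
        )


def _partition(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray,
               copies_per_unit: int):
    """SS partition and variance components for one labelling."""
    n = d2.shape[0]
    tot = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g, ng in enumerate(sizes):
        rows = np.where(codes == g)[0]
        sub = d2[np.ix_(rows, rows)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = tot - ss_within
    k = sizes.size
    units = sizes * copies_per_unit  # gene copies (or individuals) per group
    n_units = units.sum()
    df_among = k - 1
    df_within = n_units - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_units - (units ** 2).sum() / n_units) / df_among
    s2_within = ms_within
    s2_among = (ms_among - ms_within) / n0
    return tot, ss_among, ss_within, df_among, df_within, ms_among, ms_within, s2_among, s2_within


def amova_two_level(table: GenotypeTable, level: str = "gene-copy",
                    n_perm: int = 999, seed: int | None = None) -> AmovaTable:
    """Two-level AMOVA (among groups / within groups) with permutation p.

    ``level`` chooses the degrees-of-freedom convention: ``"gene-copy"``
    treats each diploid as two gene copies (df within = 2N - G), the GenAlEx
    codominant default; ``"individual"`` uses N - G.  Negative among-group
    components are truncated to zero before percentages are formed.  The
    p-value tests Phi_ST by randomly permuting individuals across groups.
    """
    if level not in ("gene-copy", "individual"):
        raise ValueError("level must be 'gene-copy' or 'individual'")
    labels = np.asarray(table.populations)
    groups, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if groups.size < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 individuals")
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value")
    cpu = 2 if level == "gene-copy" else 1
    d2 = squared_distance_matrix(table)

    (ss_total, ss_among, ss_within, df_among, df_within,
     ms_among, ms_within, s2_among, s2_within) = _partition(d2, codes, sizes, cpu)
    truncated = s2_among < 0
    s2_among_t = max(s2_among, 0.0)
    total_var = s2_among_t + s2_within
    pct_among = 100.0 * s2_among_t / total_var if total_var > 0 else float("nan")
    phi = s2_among_t / total_var if total_var > 0 else float("nan")
    if truncated:
        warnings.warn("negative among-group variance component truncated to 0")

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(max(n_perm, 0)):
        perm = rng.permutation(codes)
        *_, pa, pw = _partition(d2, perm, sizes, cpu)
        tv = max(pa, 0.0) + pw
        phi_p = max(pa, 0.0) / tv if tv > 0 else 0.0
        if phi_p >= phi:
            hits += 1
    p = (1 + hits) / (n_perm + 1) if n_perm > 0 else float("nan")

    df = pd.DataFrame(
        {
            "df": [df_among, df_within, df_among + df_within],
            "ss": [ss_among, ss_within, ss_total],
            "ms": [ms_among, ms_within, np.nan],
            "est_var": [s2_among_t, s2_within, total_var],
            "pct": [pct_among, 100.0 - pct_among, 100.0],
        },
        index=["among_groups", "within_groups", "total"],
    )
    return AmovaTable(table=df, phi_st=float(phi), p_value=float(p),
                      n_permutations=n_perm, seed=seed, level=level)


def amova_report(result: AmovaTable, path=None) -> pd.DataFrame:
    """AMOVA report (Source, df, SS, MS, Est. Var., %), optionally to CSV.

    MS is recomputed as SS/df and cross-checked against the stored values.
    """
    t = result.table
    out = pd.DataFrame(
        {
            "Source": ["Among collection sites", "Within collection sites", "Total"],
            "df": t["df"].to_numpy(),
            "SS": t["ss"].round(3).to_numpy(),
            "MS": [round(t.loc[r, "ss"] / t.loc[r, "df"], 3)
                   for r in ("among_groups", "within_groups")] + [np.nan],
            "Est. Var.": t["est_var"].round(3).to_numpy(),
            "%": t["pct"].round(0).astype(int).astype(str) + "%",
        }
    )
    for r in ("among_groups", "within_groups"):
        assert np.isclose(t.loc[r, "ss"] / t.loc[r, "df"], t.loc[r, "ms"])
    if path is not None:
        out.to_csv(path, index=False)
    return out
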