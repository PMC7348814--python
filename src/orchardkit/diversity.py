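"""Per-locus SSR diversity statistics: Na, Ne, I, Ho, He, uHe, F, Fst, PIC.

All statistics follow the GenAlEx codominant definitions: Ne = 1/sum(pi^2),
Shannon I = -sum(pi ln pi), He = 1 - sum(pi^2), uHe = (2N/(2N-1)) He,
F = (He - Ho)/He, and Fst = (Ht - mean He)/Ht with Ht the gene diversity of
the pooled allele frequencies.  PIC uses the Botstein et al. (1980) formula
1 - sum(pi^2) - sum_{i<j} 2 pi^2 pj^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, GenotypeTable, allele_frequencies

__all__ = [
    "shannon_index",
    "effective_alleles",
    "heterozygosities",
    "fst_per_locus",
    "pic",
    "diversity_table",
    "LocusDiversity",
]


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency set")
    if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    if (p <= 0).any():
        raise ValueError("frequencies must be strictly positive")
    return p


def shannon_index(freqs) -> float:
    """Shannon's information index I = -sum(pi ln pi); 0 for a monomorphic locus."""
    p = _check_freqs(freqs)
    return float(-(p * np.log(p)).sum())


def effective_alleles(freqs) -> float:
    """Effective number of alleles Ne = 1 / sum(pi^2)."""
    p = _check_freqs(freqs)
    return float(1.0 / (p ** 2).sum())


def expected_heterozygosity(freqs) -> float:
    """Nei gene diversity He = 1 - sum(pi^2)."""
    p = _check_freqs(freqs)
    return float(1.0 - (p ** 2).sum())


def pic(freqs) -> float:
    """Botstein polymorphic information content.

    PIC = 1 - sum(pi^2) - sum_{i<j} 2 pi^2 pj^2, always <= He.
    """
    p = _check_freqs(freqs)
    s2 = (p ** 2).sum()
    # sum_{i<j} pi^2 pj^2 = ((sum pi^2)^2 - sum pi^4) / 2
    cross = (s2 ** 2 - (p ** 4).sum()) / 2.0
    return float(1.0 - s2 - 2.0 * cross)


def heterozygosities(table: GenotypeTable, group: str, locus: str):
    """Observed/expected heterozygosity and fixation index at one (group, locus).

    Returns ``(Ho, He, uHe, F)`` where N is the number of non-missing
    individuals of the group at the locus, Ho the heterozygote fraction,
    He = 1 - sum(pi^2), uHe = (2N/(2N-1)) He, and F = (He - Ho)/He.
    F is ``nan`` (flagged undefined) when He = 0.
    """
    i_rows = [i for i, p in enumerate(table.populations) if p == group]
    if not i_rows:
        raise ValueError(f"unknown group {group!r}")
    l = table.loci.index(locus)
    rows = [i for i in i_rows if not table.missing[i, l]]
    if not rows:
        raise ValueError(f"all genotypes missing for group {group!r} at {locus!r}")
    n = len(rows)
    het = sum(1 for i in rows if table.calls[i, l, 0] != table.calls[i, l, 1])
    ho = het / n
    copies = table.calls[rows, l, :].ravel()
    _, counts = np.unique(copies, return_counts=True)
    p = counts / counts.sum()
    he = float(1.0 - (p ** 2).sum())
    uhe = he * (2 * n) / (2 * n - 1) if n > 1 else float("nan")
    f = (he - ho) / he if he > 0 else float("nan")
    return ho, he, uhe, f


def fst_per_locus(group_freqs: dict[str, dict[int, float]],
                  n_copies: dict[str, int] | None = None,
                  weight_pooling: bool = True) -> float:
    """Fst = (Ht - mean He)/Ht for one locus across >= 2 groups.

    ``mean He`` is the unweighted mean of per-group gene diversities.  Ht is
    computed from pooled frequencies: gene-copy weighted when
    ``weight_pooling`` and ``n_copies`` are given (GenAlEx-like), otherwise the
    unweighted mean of group frequencies.  Returns ``nan`` when Ht = 0.
    """
    if len(group_freqs) < 2:
        raise ValueError("Fst needs at least two groups with data")
    hes = []
    alleles = sorted({a for f in group_freqs.values() for a in f})
    mat = np.zeros((len(group_freqs), len(alleles)))
    w = np.ones(len(group_freqs))
    for gi, (g, f) in enumerate(group_freqs.items()):
        p = np.array([f.get(a, 0.0) for a in alleles])
        mat[gi] = p
        hes.append(1.0 - (p ** 2).sum())
        if weight_pooling and n_copies is not None:
            w[gi] = n_copies[g]
    tpi = (w[:, None] * mat).sum(axis=0) / w.sum()
    ht = 1.0 - (tpi ** 2).sum()
    if ht <= 0:
        return float("nan")
    return float((ht - np.mean(hes)) / ht)


@dataclass
class LocusDiversity:
    """Mean-over-group diversity summary for one locus (report row)."""

    locus: str
    na: float
    ne: float
    i: float
    ho: float
    he: float
    uhe: float
    f: float
    fst: float
    ht: float
    pic: float
    pi_min: float
    pi_max: float


def _sem(values: list[float]) -> float:
    v = np.asarray([x for x in values if not math.isnan(x)], dtype=float)
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / math.sqrt(v.size))


def diversity_table(table: GenotypeTable, min_group_n: int = 2) -> pd.DataFrame:
    """Per-locus diversity statistics plus a mean row, as a tidy DataFrame.

    Per-locus rows report the unweighted mean over population groups of Na,
    Ne, I, Ho, He, uHe and F, with the standard error over groups in the
    matching ``*_se`` column; Fst, Ht, PIC and the allele-frequency range come
    from the pooled/between-group frequencies and have no group dispersion.
    The ``Mean`` row is the unweighted mean over loci, with standard errors
    taken over loci.  Groups with fewer than ``min_group_n`` non-missing
    individuals at a locus are skipped (flagged by a reduced group count).
    """
    af = allele_frequencies(table, "population")
    rows: list[dict] = []
    for locus in table.loci:
        per_group: dict[str, list[float]] = {k: [] for k in
                                             ("na", "ne", "i", "ho", "he", "uhe", "f")}
        gf: dict[str, dict[int, float]] = {}
        nc: dict[str, int] = {}
        for g in af.groups:
            key = (g, locus)
            if key not in af.freqs:
                continue
            if af.n_copies[key] < 2 * min_group_n:
                continue
            f = af.freqs[key]
            gf[g] = f
            nc[g] = af.n_copies[key]
            ho, he, uhe, fix = heterozygosities(table, g, locus)
            per_group["na"].append(len(f))
            per_group["ne"].append(effective_alleles(f))
            per_group["i"].append(shannon_index(f))
            per_group["ho"].append(ho)
            per_group["he"].append(he)
            per_group["uhe"].append(uhe)
            per_group["f"].append(fix)
        if not gf:
            continue
        pooled = af.pooled[locus]
        tpi = np.array(list(pooled.values()))
        ht = float(1.0 - (tpi ** 2).sum())
        fst = fst_per_locus(gf, nc) if len(gf) >= 2 else float("nan")
        row = {"locus": locus}
        for k, vals in per_group.items():
            clean = [v for v in vals if not math.isnan(v)]
            row[k] = float(np.mean(clean)) if clean else float("nan")
            row[k + "_se"] = _sem(vals)
        row.update(fst=fst, ht=ht, pic=pic(pooled),
                   pi_min=float(tpi.min()), pi_max=float(tpi.max()),
                   n_groups=len(gf))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no locus had sufficient data")
    mean = {"locus": "Mean"}
    for col in df.columns:
        if col in ("locus", "n_groups") or col.endswith("_se"):
            continue
        vals = df[col].dropna().tolist()
        mean[col] = float(np.mean(vals)) if vals else float("nan")
        mean[col + "_se"] = _sem(df[col].tolist())
    mean["n_groups"] = df["n_groups"].max()
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
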