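"""Synthetic data generators for the two layers of a clonal orchard trial.

The phenotype generator emulates a balanced randomized-complete-block design
with single-tree plots: Y_ij = mu + beta_i + a_j + eps_ij with clone effects
drawn multivariate normal across traits (target genetic correlations), site
mean shifts calibrated to a per-trait QST target, fixed block effects, and
independent residuals.  Defaults mirror the trial layout: 110 clones in 10
blocks, clones originating from two selection sites in a 90/20 split.

The genotype generator uses the Balding-Nichols model: per locus an ancestral
frequency vector p ~ Dirichlet(1), per population frequencies
p_g ~ Dirichlet(p (1 - theta)/theta) so that E[Fst] ~ theta, and diploid
genotypes by random union of gametes.  The default locus panel is 16 SSRs
with 2-9 alleles and theta = 0.03, the regime of the orchard's markers.

Both generators are fully determined by (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .quantgen import TRAIT_CATALOG

__all__ = [
    "OrchardSimSpec",
    "SsrSimSpec",
    "simulate_orchard",
    "simulate_ssr",
    "simulate_trial",
    "DEFAULT_ALLELE_COUNTS",
]

#: Allele counts of the default 16-locus SSR panel (2-9 alleles per locus).
DEFAULT_ALLELE_COUNTS: tuple[int, ...] = (7, 3, 8, 3, 2, 4, 4, 9, 9, 3, 5, 5, 2, 4, 4, 3)


def _default_traits() -> pd.DataFrame:
    return pd.DataFrame(TRAIT_CATALOG, columns=["trait", "unit", "mean", "pcv", "h2", "qst"])


@dataclass
class OrchardSimSpec:
    """Design and genetic parameters of the simulated orchard.

    ``traits`` needs columns trait/mean/pcv/h2/qst (the bundled catalog of 28
    orchard traits by default, with per-trait PCV in percent).  ``site_sizes``
    assigns clones to origin sites in order (default 90/20).
    ``block_sd_frac`` scales fixed block effects relative to sqrt(sigma2_Y).
    ``genetic_corr`` is an optional trait x trait genetic correlation matrix
    (identity if omitted).  ``n_clone_groups``/``group_shift_sd`` optionally
    overlay a latent clone clustering: clone effects are shifted by a
    group-specific vector of length ``group_shift_sd`` (in units of the
    genetic standard deviation), which makes phenotype-based clustering
    recoverable — used for end-to-end clustering checks.
    """

    n_clones: int = 110
    n_blocks: int = 10
    site_sizes: tuple[int, ...] = (90, 20)
    traits: pd.DataFrame = field(default_factory=_default_traits)
    genetic_corr: np.ndarray | None = None
    block_sd_frac: float = 0.5
    missing_rate: float = 0.0
    n_clone_groups: int = 1
    group_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        if sum(self.site_sizes) != self.n_clones:
            raise ValueError("site sizes must sum to n_clones")
        t = self.traits
        if ((t["h2"] < 0) | (t["h2"] > 1)).any():
            raise ValueError("H2 targets must lie in [0, 1]")
        if ((t["qst"] < 0) | (t["qst"] >= 1)).any():
            raise ValueError("QST targets must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate in [0, 1) required")
        if self.genetic_corr is not None:
            r = np.asarray(self.genetic_corr, float)
            if r.shape != (len(t), len(t)):
                raise ValueError("genetic_corr shape mismatch")
            if not np.allclose(r, r.T):
                raise ValueError("genetic_corr must be symmetric")
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise ValueError("genetic_corr must be positive semi-definite")


def _site_shifts(sizes: np.ndarray, s2_between: float) -> np.ndarray:
    """Fixed site deviations with weighted mean 0 whose one-way EMS component is s2_between.

    For G sites of sizes n_g the moment estimator recovers
    sum n_g delta_g^2 / (G - 1) / n0; shifts are spread along the contrast
    (1, -n_1/n_2, ...) for two sites, or scaled orthogonal deviations
    generally.
    """
    g = sizes.size
    n = sizes.sum()
    if s2_between <= 0 or g < 2:
        return np.zeros(g)
    n0 = (n - (sizes ** 2).sum() / n) / (g - 1)
    # base pattern: alternate +/- deviations, then center to weighted mean 0
    base = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(g)])
    base -= (sizes * base).sum() / n
    scale2 = (sizes * base ** 2).sum()
    t = np.sqrt((g - 1) * n0 * s2_between / scale2)
    return base * t


def simulate_orchard(spec: OrchardSimSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate ramet-level phenotype records for all traits of the spec.

    Returns a long-form DataFrame with columns clone, block, site, group,
    trait, value.  Clone effects are correlated across traits via the spec's
    genetic correlation matrix; each trait t has total variance
    sigma2_Y = (pcv/100 * mean)^2 split as h2 * sigma2_Y genetic and the rest
    residual; sites receive fixed shifts calibrated so the expected QST
    estimate matches the target.
    """
    rng = np.random.default_rng(seed)
    t = spec.traits.reset_index(drop=True)
    nt = len(t)
    mu = t["mean"].to_numpy(float)
    s2y = (t["pcv"].to_numpy(float) / 100.0 * mu) ** 2
    s2a = t["h2"].to_numpy(float) * s2y
    s2e = s2y - s2a
    corr = np.eye(nt) if spec.genetic_corr is None else np.asarray(spec.genetic_corr, float)
    cov_a = corr * np.sqrt(np.outer(s2a, s2a))

    clones = [f"C{i + 1:03d}" for i in range(spec.n_clones)]
    sites = np.repeat([f"S{i + 1}" for i in range(len(spec.site_sizes))],
                      spec.site_sizes)
    site_idx = np.repeat(np.arange(len(spec.site_sizes)), spec.site_sizes)
    groups = (np.arange(spec.n_clones) * spec.n_clone_groups) // spec.n_clones

    a = rng.multivariate_normal(np.zeros(nt), cov_a, size=spec.n_clones,
                                method="eigh")
    sizes = np.asarray(spec.site_sizes)
    for j in range(nt):
        qst_t = float(t.loc[j, "qst"])
        if qst_t > 0:
            s2_between = 2.0 * qst_t * s2a[j] / (1.0 - qst_t)
            a[:, j] += _site_shifts(sizes, s2_between)[site_idx]
    if spec.n_clone_groups > 1 and spec.group_shift_sd > 0:
        shift_dir = rng.standard_normal((spec.n_clone_groups, nt))
        shift_dir /= np.linalg.norm(shift_dir, axis=1, keepdims=True)
        a += spec.group_shift_sd * np.sqrt(s2a)[None, :] * shift_dir[groups]

    beta = rng.standard_normal((spec.n_blocks, nt)) * spec.block_sd_frac * np.sqrt(s2y)
    beta -= beta.mean(axis=0)

    rows = []
    eps = rng.standard_normal((spec.n_clones, spec.n_blocks, nt)) * np.sqrt(s2e)
    keep = rng.random((spec.n_clones, spec.n_blocks)) >= spec.missing_rate
    for ci, clone in enumerate(clones):
        for b in range(spec.n_blocks):
            if not keep[ci, b]:
                continue
            y = mu + beta[b] + a[ci] + eps[ci, b]
            for j in range(nt):
                rows.append((clone, f"B{b + 1:02d}", sites[ci], int(groups[ci]) + 1,
                             t.loc[j, "trait"], y[j]))
    return pd.DataFrame(rows, columns=["clone", "block", "site", "group",
                                       "trait", "value"])


@dataclass
class SsrSimSpec:
    """Balding-Nichols genotype simulation parameters.

    ``pop_sizes`` are individuals per population; ``allele_counts`` the
    alleles per locus of the SSR panel; ``fst`` the differentiation target
    theta; ``admixture_q`` an optional individuals x populations matrix of
    ancestry proportions used to mix gamete pools.
    """

    pop_sizes: tuple[int, ...] = (90, 20)
    allele_counts: tuple[int, ...] = DEFAULT_ALLELE_COUNTS
    fst: float = 0.03
    admixture_q: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if any(c < 2 for c in self.allele_counts):
            raise ValueError("each locus needs >= 2 alleles")
        if self.admixture_q is not None:
            q = np.asarray(self.admixture_q, float)
            if q.shape != (sum(self.pop_sizes), len(self.pop_sizes)):
                raise ValueError("admixture_q shape mismatch")
            if not np.allclose(q.sum(axis=1), 1.0):
                raise ValueError("admixture_q rows must sum to 1")


def simulate_ssr(spec: SsrSimSpec, seed: int | None = None,
                 individuals: list[str] | None = None) -> GenotypeTable:
    """Simulate a codominant SSR genotype table under the Balding-Nichols model.

    Ancestral frequencies are uniform-Dirichlet per locus; population
    frequencies are Dirichlet(p (1-theta)/theta) around them (exact copies at
    theta = 0).  Gametes are drawn from the individual's population pool, or
    from a mixture of pools when admixture proportions are given.  Allele
    codes mimic SSR fragment sizes (100 + 2 * allele index per locus offset).
    """
    rng = np.random.default_rng(seed)
    n_pops = len(spec.pop_sizes)
    n = sum(spec.pop_sizes)
    n_loci = len(spec.allele_counts)
    pop_of = np.repeat(np.arange(n_pops), spec.pop_sizes)
    if individuals is None:
        individuals = [f"I{i + 1:03d}" for i in range(n)]
    elif len(individuals) != n:
        raise ValueError("individual ID count mismatch")

    calls = np.zeros((n, n_loci, 2), dtype=int)
    for l, na in enumerate(spec.allele_counts):
        anc = rng.dirichlet(np.ones(na))
        if spec.fst > 0:
            conc = anc * (1.0 - spec.fst) / spec.fst
            pops = rng.dirichlet(np.maximum(conc, 1e-9), size=n_pops)
        else:
            pops = np.tile(anc, (n_pops, 1))
        sizes = 100 + 10 * l + 2 * np.arange(na)
        for i in range(n):
            if spec.admixture_q is not None:
                origins = rng.choice(n_pops, size=2, p=spec.admixture_q[i])
            else:
                origins = (pop_of[i], pop_of[i])
            g = [rng.choice(na, p=pops[o]) for o in origins]
            calls[i, l] = sizes[g]
    return GenotypeTable(
        individuals=list(individuals),
        loci=[f"SSR{l + 1:02d}" for l in range(n_loci)],
        populations=[f"P{p + 1}" for p in pop_of],
        calls=calls,
    )


def simulate_trial(orchard: OrchardSimSpec, ssr: SsrSimSpec, seed: int | None = None):
    """Joint phenotype + genotype simulation over a shared clone set.

    The SSR population of each clone is its origin site when the population
    count matches the site count, otherwise its latent clone group (so
    molecular and phenotypic clusterings can be made congruent).  Returns
    ``(trait_records, genotype_table)`` with genotype individuals named after
    clones.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    records = simulate_orchard(orchard, seed=s1)
    meta = records.drop_duplicates("clone")[["clone", "site", "group"]]
    if len(ssr.pop_sizes) == len(orchard.site_sizes) and \
            tuple(ssr.pop_sizes) == tuple(orchard.site_sizes):
        labels = meta["site"].tolist()
    else:
        counts = meta["group"].value_counts().sort_index()
        if len(counts) != len(ssr.pop_sizes) or tuple(counts) != tuple(ssr.pop_sizes):
            raise ValueError("SSR pop sizes match neither site sizes nor clone groups")
        labels = [f"P{g}" for g in meta["group"]]
    order = np.argsort(np.unique(labels, return_inverse=True)[1], kind="stable")
    clones = meta["clone"].to_numpy()[order]
    table = simulate_ssr(ssr, seed=s2, individuals=clones.tolist())
    # keep the clones' own ordering and label by their true stratum
    lab_by_clone = dict(zip(meta["clone"], labels))
    table = table.subset(meta["clone"].tolist())
    table.populations = [lab_by_clone[c] for c in table.individuals]
    return records, table
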