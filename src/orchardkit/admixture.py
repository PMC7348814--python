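"""Bayesian model-based clustering of multilocus genotypes (Gibbs sampler).

This is the classic admixture model for unlinked codominant markers: each
gene copy of individual n at locus l originates from one of K clusters
(Z), each cluster k carries allele frequencies P_k,l ~ Dirichlet(lambda),
and each individual has membership proportions Q_n ~ Dirichlet(alpha).  The
Gibbs sampler alternates conjugate updates

    P | Z  ~ Dirichlet(lambda + allele counts per cluster)
    Q | Z  ~ Dirichlet(alpha + origin counts per individual)
    Z | P,Q  per gene copy, multinomial with weight Q_nk * P_k,l,allele

(in the no-admixture variant Z is sampled once per individual).  The data
log-probability is estimated from the recorded log-likelihood trace as
mean(L) - var(L)/2, and the number of clusters is chosen with the Evanno
delta-K statistic on replicate runs across K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "AdmixtureRun",
    "DeltaKTable",
    "run_mcmc",
    "run_k_range",
    "delta_k",
    "align_runs",
]


@dataclass
class AdmixtureRun:
    k: int
    seed: int | None
    burnin: int
    reps: int
    q: np.ndarray                 # (n, K) posterior mean memberships
    p: list[np.ndarray]           # per locus: (K, n_alleles) posterior mean freqs
    loglik_trace: np.ndarray      # recorded sweeps
    ln_prob_data: float
    individuals: list[str]
    loci: list[str]
    alleles: list[np.ndarray]     # allele size per index, per locus
    model: str = "admixture"

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.individuals,
                            columns=[f"cluster_{k + 1}" for k in range(self.k)])


def _encode(table: GenotypeTable):
    """Recode calls to per-locus 0-based allele indices with a missing mask."""
    n, nl = table.n_individuals, table.n_loci
    alleles = [np.asarray(table.alleles_at(locus), dtype=int) for locus in table.loci]
    counts = [a.size for a in alleles]
    amax = max(counts)
    x = np.zeros((n, nl, 2), dtype=np.int64)
    for l in range(nl):
        lut = {int(a): i for i, a in enumerate(alleles[l].tolist())}
        ok = ~table.missing[:, l]
        for i in np.where(ok)[0]:
            x[i, l, 0] = lut[int(table.calls[i, l, 0])]
            x[i, l, 1] = lut[int(table.calls[i, l, 1])]
    obs = ~np.repeat(table.missing[:, :, None], 2, axis=2)
    valid = np.zeros((nl, amax), dtype=bool)
    for l, c in enumerate(counts):
        valid[l, :c] = True
    return x, obs, valid, alleles


def run_mcmc(table: GenotypeTable, k: int, burnin: int = 5000, reps: int = 5000,
             seed: int | None = None, model: str = "admixture",
             alpha: float = 1.0, lam: float = 1.0) -> AdmixtureRun:
    """Run the Gibbs sampler for one K and one seed.

    ``burnin`` sweeps are discarded, ``reps`` sweeps are recorded.  ``alpha``
    is the (fixed) Dirichlet parameter of individual memberships and ``lam``
    the uniform allele-frequency prior.  Missing genotypes contribute neither
    to the likelihood nor to the count updates.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if burnin < 0 or reps < 100:
        raise ValueError("need non-negative burn-in and >= 100 recorded sweeps")
    if model not in ("admixture", "no-admixture"):
        raise ValueError("model must be 'admixture' or 'no-admixture'")
    rng = np.random.default_rng(seed)
    x, obs, valid, alleles = _encode(table)
    n, nl, _ = x.shape
    amax = valid.shape[1]
    lidx = np.broadcast_to(np.arange(nl)[None, :, None], x.shape)
    karr = np.arange(k)

    z = rng.integers(0, k, size=x.shape)
    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, nl, amax))
    logliks = []

    xo, lo = x[obs], lidx[obs]
    for sweep in range(burnin + reps):
        # P | Z
        cp = np.zeros((k, nl, amax))
        np.add.at(cp, (z[obs], lo, xo), 1.0)
        p = rng.standard_gamma(lam + cp)
        p *= valid[None, :, :]
        p /= p.sum(axis=2, keepdims=True)
        # Q | Z
        cq = ((z[:, :, :, None] == karr) & obs[:, :, :, None]).sum(axis=(1, 2))
        q = rng.standard_gamma(alpha + cq)
        q /= q.sum(axis=1, keepdims=True)
        # Z | P, Q
        w = p[:, lidx, x]                      # (K, n, L, 2)
        if model == "admixture":
            probs = q.T[:, :, None, None] * w
            cum = np.cumsum(probs, axis=0)
            tot = cum[-1]
            u = rng.random(x.shape) * np.where(tot > 0, tot, 1.0)
            z = (cum < u[None, ...]).sum(axis=0).astype(np.int64)
            np.clip(z, 0, k - 1, out=z)
        else:
            with np.errstate(divide="ignore"):
                lw = np.where(obs[None, ...], np.log(np.maximum(w, 1e-300)), 0.0)
            ll_nk = lw.sum(axis=(2, 3)) + np.log(np.maximum(q.T, 1e-300))
            ll_nk -= ll_nk.max(axis=0, keepdims=True)
            pr = np.exp(ll_nk)
            pr /= pr.sum(axis=0, keepdims=True)
            cum = np.cumsum(pr, axis=0)
            u = rng.random(n)
            zi = (cum < u[None, :]).sum(axis=0)
            z = np.broadcast_to(zi[:, None, None], x.shape).copy()
        # log-likelihood of the data given current (P, Q)
        s = np.einsum("nk,knlc->nlc", q, w)
        ll = float(np.log(np.maximum(s[obs], 1e-300)).sum())
        if sweep >= burnin:
            q_sum += q
            p_sum += p
            logliks.append(ll)

    trace = np.asarray(logliks)
    ln_pd = float(trace.mean() - trace.var(ddof=1) / 2.0) if trace.size > 1 else float(trace.mean())
    q_mean = q_sum / reps
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    p_mean = p_sum / reps
    p_out = []
    for l, a in enumerate(alleles):
        pl = p_mean[:, l, :a.size]
        p_out.append(pl / pl.sum(axis=1, keepdims=True))
    return AdmixtureRun(k=k, seed=seed, burnin=burnin, reps=reps, q=q_mean,
                        p=p_out, loglik_trace=trace, ln_prob_data=ln_pd,
                        individuals=list(table.individuals), loci=list(table.loci),
                        alleles=alleles, model=model)


def run_k_range(table: GenotypeTable, k_values, n_reps: int = 10,
                burnin: int = 5000, reps: int = 5000,
                seed: int | None = None, model: str = "admixture") -> list[AdmixtureRun]:
    """Replicate runs over a K range with independent child seeds."""
    ss = np.random.SeedSequence(seed)
    runs = []
    for k in k_values:
        for child in ss.spawn(n_reps):
            child_seed = int(child.generate_state(1)[0] % (2 ** 31))
            runs.append(run_mcmc(table, k, burnin=burnin, reps=reps,
                                 seed=child_seed, model=model))
    return runs


@dataclass
class DeltaKTable:
    table: pd.DataFrame           # K, n_runs, mean_lnp, sd_lnp, delta_k
    selected_k: int | None
    ambiguous: bool = False


def delta_k(runs: list[AdmixtureRun]) -> DeltaKTable:
    """Evanno delta-K model choice over replicate runs.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K), defined
    for interior K with positive replicate spread; the selected K is the
    argmax.  Requires >= 3 consecutive K values with >= 2 replicates each.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.ln_prob_data)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(by_k[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicate runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = num / sd[k] if sd[k] > 0 else np.nan
        rows.append({"K": k, "n_runs": len(by_k[k]), "mean_lnp": mean[k],
                     "sd_lnp": sd[k], "delta_k": dk})
    df = pd.DataFrame(rows)
    finite = df.dropna(subset=["delta_k"])
    if finite.empty or (finite["delta_k"] == 0).all():
        return DeltaKTable(table=df, selected_k=None, ambiguous=True)
    sel = int(finite.loc[finite["delta_k"].idxmax(), "K"])
    return DeltaKTable(table=df, selected_k=sel)


def align_runs(runs: list[AdmixtureRun]):
    """Align cluster labels across replicate runs at the same K.

    Greedy matching of Q columns to the first run by correlation (label
    switching is a gauge freedom of the model).  Returns the per-run column
    permutations and the averaged Q matrix, whose rows still sum to 1.
    """
    if not runs:
        raise ValueError("no runs to align")
    k = runs[0].k
    if any(r.k != k for r in runs):
        raise ValueError("all runs must share the same K")
    ref = runs[0].q
    perms: list[list[int]] = []
    q_acc = np.zeros_like(ref)
    for r in runs:
        if k == 1:
            perm = [0]
        else:
            c = np.corrcoef(ref.T, r.q.T)[:k, k:]
            c = np.nan_to_num(c, nan=-1.0)
            perm = [-1] * k
            used: set[int] = set()
            for _ in range(k):
                flat = np.argmax(np.where(np.isfinite(c), c, -np.inf))
                i, j = np.unravel_index(flat, c.shape)
                perm[i] = int(j)
                used.add(int(j))
                c[i, :] = -np.inf
                c[:, j] = -np.inf
        perms.append(perm)
        q_acc += r.q[:, perm]
    q_mean = q_acc / len(runs)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    return perms, q_mean
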