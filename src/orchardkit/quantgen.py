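"""Quantitative genetics of a clonal randomized-complete-block trial.

The model for a single trait is the additive two-way layout

    Y_ij = mu + beta_i + a_ij + eps_ij

with ``beta_i`` the fixed effect of block i, ``a_ij`` the random clonal
(genotypic) value of clone j, and ``eps_ij`` the within-plot residual.  With
single-tree plots there is no clone-by-block interaction term.  Variance
components come from the expected-mean-squares method of moments:
``sigma2_e = MS_resid`` and ``sigma2_a = (MS_clone - MS_resid)/b`` with ``b``
the (harmonic-mean, for unbalanced data) number of ramets per clone.

Derived quantities: clonal repeatability H2 = sigma2_a / (sigma2_a + sigma2_e)
(a broad-sense heritability analogue), the phenotypic coefficient of
variation PCV = 100 * sqrt(sigma2_Y) / mean, QST between clone-origin sites
QST = s2_between / (s2_between + 2 * s2_within) computed from clone genotypic
values, and broad-sense genetic correlations between traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRAIT_CATALOG",
    "VarianceComponents",
    "QstEstimate",
    "apply_trait_transform",
    "fit_rcb",
    "repeatability",
    "pcv",
    "qst",
    "genetic_correlation",
    "stem_volume",
    "standardize_clonal_values",
    "significance_stars",
    "trait_report",
]

#: Trait catalog: (name, unit, nominal mean, PCV %, H2, QST) for the 28 traits
#: measured on the orchard — 11 growth, 3 wood, 14 cone/seed/nut traits.
#: Means are nominal working values for simulation; PCV/H2/QST are the trial's
#: reported variation parameters and drive the synthetic generator defaults.
TRAIT_CATALOG: list[tuple[str, str, float, float, float, float]] = [
    ("tree_height",          "m",      15.0,   8.36, 0.663, 0.0236),
    ("basal_diameter",       "cm",     32.0,   9.05, 0.749, 0.0761),
    ("dbh",                  "cm",     26.0,   9.30, 0.765, 0.0036),
    ("diameter_3m",          "cm",     23.0,   9.55, 0.729, 0.0258),
    ("stem_volume",          "m3",      0.45, 23.54, 0.777, 0.0003),
    ("bark_thickness",       "mm",     11.0,  12.20, 0.494, 0.0122),
    ("stem_straightness",    "score",   3.5,   4.44, 0.020, 0.0001),
    ("branch_angle",         "deg",    50.0,   9.18, 0.515, 0.6407),
    ("crown_breadth",        "m",       4.5,   8.03, 0.539, 0.0003),
    ("crown_height",         "m",      11.0,  10.69, 0.633, 0.0076),
    ("branch_number",        "count",   5.0,  13.01, 0.313, 0.0034),
    ("wood_density",         "g/cm3",   0.42, 13.20, 0.498, 2.0e-05),
    ("fiber_length",         "um",   3100.0,  11.13, 0.786, 0.0992),
    ("fiber_width",          "um",     41.0,   5.71, 0.570, 0.1901),
    ("cone_number",          "count",  16.0,  17.98, 0.457, 0.0183),
    ("cone_length",          "mm",    132.0,   8.91, 0.927, 0.0869),
    ("cone_width",           "mm",     82.0,  13.25, 0.977, 0.4178),
    ("cone_weight",          "g",     185.0,  16.04, 0.907, 0.9809),
    ("layer_number",         "count",  15.0,  11.16, 0.906, 0.2264),
    ("seed_number_per_cone", "count", 112.0,   9.73, 0.830, 0.4171),
    ("seed_length",          "mm",     14.5,   5.86, 0.908, 0.0388),
    ("seed_width",           "mm",      9.2,   6.28, 0.829, 0.0059),
    ("seed_weight",          "g",       0.55, 15.66, 0.939, 0.0002),
    ("nut_length",           "mm",     11.5,   6.51, 0.918, 0.0188),
    ("nut_width",            "mm",      7.3,   5.84, 0.822, 0.0004),
    ("nut_weight",           "g",       0.26, 17.17, 0.851, 3.0e-05),
    ("seed_coat_thickness",  "mm",      0.72,  6.97, 0.801, 2.0e-06),
    ("thousand_seed_weight", "g",     540.0,  13.37, 0.913, 0.9958),
]


def apply_trait_transform(records: pd.DataFrame, trait: str,
                          transform: str = "square") -> pd.DataFrame:
    """Pre-analysis transform of one trait's values (currently ``square``).

    Ordinal scores such as the stem-straightness degree are squared before
    the variance analysis; other traits pass through untouched.
    """
    if transform != "square":
        raise ValueError(f"unknown transform {transform!r}")
    out = records.copy()
    mask = out["trait"] == trait
    if not mask.any():
        raise ValueError(f"trait {trait!r} not present")
    out.loc[mask, "value"] = out.loc[mask, "value"] ** 2
    return out


def significance_stars(p: float) -> str:
    """Report-style significance flag: *** (p<=0.001), ** (p<=0.01), * (p<=0.05), NS."""
    if math.isnan(p):
        return "NS"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


@dataclass
class VarianceComponents:
    trait: str
    grand_mean: float
    block_effects: pd.Series          # beta_i, indexed by block
    clonal_values: pd.DataFrame       # columns clone, block, value (a_ij)
    clone_means: pd.Series            # mean a_ij per clone
    anova: pd.DataFrame               # rows clone/block/residual: ss, df, ms, F, p
    sigma2_a: float
    sigma2_e: float
    truncated: bool = False           # sigma2_a clipped at zero
    replication: float = 1.0          # harmonic-mean ramets per clone

    @property
    def sigma2_y(self) -> float:
        return self.sigma2_a + self.sigma2_e

    @property
    def h2(self) -> float:
        return repeatability(self)

    @property
    def pcv(self) -> float:
        return pcv(self)


def _anova_two_way(df: pd.DataFrame) -> pd.DataFrame:
    """Additive two-way ANOVA (clone + block) on possibly unbalanced data.

    Balanced data use the closed-form orthogonal decomposition; unbalanced
    data use sequential least squares with clone adjusted for block (type-I
    with block first), which coincides with the balanced formulas when the
    layout is complete.
    """
    y = df["value"].to_numpy(float)
    n = y.size
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    counts = df.groupby(["clone", "block"], observed=True).size()
    balanced = (counts == 1).all() and (
        df.groupby("clone", observed=True).size().nunique() == 1
        and df.groupby("block", observed=True).size().nunique() == 1
    )
    cl = df.groupby("clone", observed=True)["value"]
    bl = df.groupby("block", observed=True)["value"]
    df_clone = cl.ngroups - 1
    df_block = bl.ngroups - 1
    df_resid = n - 1 - df_clone - df_block
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    if balanced:
        ss_clone = (cl.size() * (cl.mean() - gm) ** 2).sum()
        ss_block = (bl.size() * (bl.mean() - gm) ** 2).sum()
        ss_resid = ss_total - ss_clone - ss_block
    else:
        # sequential fit via dummy least squares
        def _design(labels: pd.Series) -> np.ndarray:
            cats = pd.Categorical(labels)
            m = np.zeros((len(labels), len(cats.categories) - 1))
            codes = cats.codes
            for j in range(1, len(cats.categories)):
                m[codes == j, j - 1] = 1.0
            return m
        ones = np.ones((n, 1))
        xb = np.hstack([ones, _design(df["block"])])
        xcb = np.hstack([xb, _design(df["clone"])])

        def _rss(x: np.ndarray) -> float:
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return float(r @ r)
        rss_b = _rss(xb)
        rss_cb = _rss(xcb)
        ss_block = ss_total - rss_b
        ss_clone = rss_b - rss_cb
        ss_resid = rss_cb
    ms_clone = ss_clone / df_clone
    ms_block = ss_block / df_block
    ms_resid = ss_resid / df_resid
    f_clone = ms_clone / ms_resid
    f_block = ms_block / ms_resid
    return pd.DataFrame(
        {
            "ss": [ss_clone, ss_block, ss_resid, ss_total],
            "df": [df_clone, df_block, df_resid, n - 1],
            "ms": [ms_clone, ms_block, ms_resid, np.nan],
            "F": [f_clone, f_block, np.nan, np.nan],
            "p": [
                stats.f.sf(f_clone, df_clone, df_resid),
                stats.f.sf(f_block, df_block, df_resid),
                np.nan,
                np.nan,
            ],
        },
        index=["clone", "block", "residual", "total"],
    )


def fit_rcb(records: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Fit the randomized-complete-block clonal model for one trait.

    ``records`` needs columns ``clone``, ``block``, ``value`` (plus optionally
    ``trait`` to select with the ``trait`` argument).  Clones observed in
    fewer than one block are dropped with a warning; at least two clones and
    two blocks are required.  Returns moment estimates of the clone and
    residual variance components with the full ANOVA table.
    """
    df = records
    if trait is not None:
        df = df[df["trait"] == trait]
    df = df.dropna(subset=["value"]).copy()
    name = trait or (df["trait"].iloc[0] if "trait" in df and len(df) else "trait")
    if df.groupby(["clone", "block"], observed=True).size().max() > 1:
        raise ValueError("more than one record per (clone, block): not single-tree plots")
    counts = df.groupby("clone", observed=True).size()
    bad = counts[counts < 1].index
    if len(bad):
        warnings.warn(f"dropping clones with no observations: {list(bad)}")
        df = df[~df["clone"].isin(bad)]
    if df["block"].nunique() < 2 or df["clone"].nunique() < 2:
        raise ValueError("need >= 2 blocks and >= 2 clones")

    gm = df["value"].mean()
    beta = df.groupby("block", observed=True)["value"].mean() - gm
    a = df["value"].to_numpy(float) - gm - beta.loc[df["block"]].to_numpy(float)
    clonal = df[["clone", "block"]].copy()
    clonal["value"] = a
    clone_means = clonal.groupby("clone", observed=True)["value"].mean()

    anova = _anova_two_way(df)
    reps = df.groupby("clone", observed=True).size().to_numpy(float)
    b_harm = len(reps) / (1.0 / reps).sum()
    s2e = float(anova.loc["residual", "ms"])
    s2a = (float(anova.loc["clone", "ms"]) - s2e) / b_harm
    truncated = s2a < 0
    if truncated:
        warnings.warn(f"{name}: negative clone variance estimate truncated to 0")
        s2a = 0.0
    return VarianceComponents(
        trait=str(name), grand_mean=float(gm), block_effects=beta,
        clonal_values=clonal, clone_means=clone_means, anova=anova,
        sigma2_a=float(s2a), sigma2_e=s2e, truncated=truncated,
        replication=float(b_harm),
    )


def repeatability(vc: VarianceComponents) -> float:
    """Clonal repeatability H2 = sigma2_a / (sigma2_a + sigma2_e); nan if sigma2_Y = 0."""
    if vc.sigma2_y <= 0:
        return float("nan")
    return vc.sigma2_a / vc.sigma2_y


def pcv(vc: VarianceComponents, mean: float | None = None) -> float:
    """Phenotypic coefficient of variation 100*sqrt(sigma2_Y)/mean, in percent."""
    mu = vc.grand_mean if mean is None else mean
    if mu <= 0:
        raise ValueError("PCV needs a positive trait mean")
    return 100.0 * math.sqrt(vc.sigma2_y) / mu


@dataclass
class QstEstimate:
    trait: str
    sigma2_between: float
    sigma2_within: float
    qst: float
    truncated: bool = False


def qst(clone_values: pd.Series, sites: pd.Series, trait: str = "trait") -> QstEstimate:
    """Quantitative differentiation QST between clone-origin sites.

    ``clone_values`` are clone genotypic values (e.g. ``VarianceComponents.
    clone_means``) indexed by clone; ``sites`` maps the same clones to origin
    sites.  A one-way moment decomposition by site gives the between-site and
    within-site genotypic variances, and QST = s2_B / (s2_B + 2 s2_W) clipped
    into [0, 1].
    """
    sites = sites.loc[clone_values.index]
    if sites.nunique() < 2:
        raise ValueError("QST needs clones from >= 2 origin sites")
    y = clone_values.to_numpy(float)
    groups = [y[(sites == s).to_numpy()] for s in sites.unique()]
    k = len(groups)
    n = y.size
    gm = y.mean()
    ssb = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - sum(g.size ** 2 for g in groups) / n) / (k - 1)
    s2b = (msb - msw) / n0
    truncated = s2b < 0
    s2b = max(s2b, 0.0)
    s2w = msw
    denom = s2b + 2 * s2w
    q = s2b / denom if denom > 0 else 0.0
    return QstEstimate(trait=trait, sigma2_between=float(s2b),
                       sigma2_within=float(s2w), qst=float(min(max(q, 0.0), 1.0)),
                       truncated=truncated)


def genetic_correlation(clone_values: pd.DataFrame, convention: str = "product") -> pd.DataFrame:
    """Broad-sense genetic correlation matrix from clone genotypic values.

    ``clone_values`` is a clone x trait matrix of genotypic values.  The
    default ``product`` convention is the standard
    ``cov(x, y) / sqrt(var(x) var(y))`` (unit diagonal, symmetric); the
    ``sum`` convention ``cov(x, y) / sqrt(var(x) + var(y))`` is also offered
    because some field reports normalise by the summed variances.  Traits with
    zero clonal variance yield ``nan`` entries.
    """
    if convention not in ("product", "sum"):
        raise ValueError("convention must be 'product' or 'sum'")
    x = clone_values.to_numpy(float)
    cov = np.cov(x, rowvar=False)
    var = np.diag(cov).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if convention == "product":
            denom = np.sqrt(np.outer(var, var))
        else:
            denom = np.sqrt(var[:, None] + var[None, :])
        r = np.where(denom > 0, cov / denom, np.nan)
    return pd.DataFrame(r, index=clone_values.columns, columns=clone_values.columns)


def stem_volume(dbh_cm, height_m):
    """Stem volume (m^3) from DBH (cm) and height (m) for coniferous stems.

    Vol = DBH^2 * Ht * pi * fc / 40000 with pi = 3.14 and fc = 0.41, the
    conifer form coefficient; the rounded pi is kept deliberately so reported
    volumes are bit-compatible with the trial's published convention.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    ht = np.asarray(height_m, dtype=float)
    if (dbh <= 0).any() or (ht <= 0).any():
        raise ValueError("DBH and height must be positive")
    out = dbh ** 2 * ht * 3.14 * 0.41 / 40000.0
    return float(out) if out.ndim == 0 else out


def standardize_clonal_values(clone_values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait column (mean 0, sd 1); constant columns are an error."""
    sd = clone_values.std(ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"constant trait column(s): {bad}")
    return (clone_values - clone_values.mean()) / sd


def trait_report(records: pd.DataFrame, sites: pd.Series | None = None) -> pd.DataFrame:
    """Per-trait variation summary: ANOVA, PCV, H2, QST.

    ``records`` holds all traits in long form (clone, block, trait, value,
    optionally site); ``sites`` maps clone -> origin site for QST (taken from
    a ``site`` column when present).
    """
    if sites is None and "site" in records:
        sites = records.drop_duplicates("clone").set_index("clone")["site"]
    rows = []
    for trait_name, _ in records.groupby("trait", observed=True):
        vc = fit_rcb(records, trait_name)
        row = {
            "trait": trait_name,
            "ss_clone": vc.anova.loc["clone", "ss"],
            "df_clone": vc.anova.loc["clone", "df"],
            "ms_clone": vc.anova.loc["clone", "ms"],
            "F_clone": vc.anova.loc["clone", "F"],
            "sig_clone": significance_stars(vc.anova.loc["clone", "p"]),
            "ss_block": vc.anova.loc["block", "ss"],
            "df_block": vc.anova.loc["block", "df"],
            "ms_block": vc.anova.loc["block", "ms"],
            "F_block": vc.anova.loc["block", "F"],
            "sig_block": significance_stars(vc.anova.loc["block", "p"]),
            "pcv": vc.pcv,
            "h2": vc.h2,
        }
        if sites is not None:
            row["qst"] = qst(vc.clone_means, sites, trait_name).qst
        rows.append(row)
    return pd.DataFrame(rows)
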