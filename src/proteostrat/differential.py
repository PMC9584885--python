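"""Moderated differential abundance and mRNA~protein correlation structure.

Implements the empirical-Bayes moderated t workflow for log2 abundance
matrices with arbitrary design matrices: per-feature least squares with
casewise deletion of missing values, a scaled inverse-chi-square prior
fitted to the residual variances by method of moments (Smyth 2004), and
Benjamini-Hochberg adjustment across features.  Around it sit the
standard characterization tools: hit calling at fold-change/FDR cuts,
LOWESS gene-dosage profiles along a chromosome, per-gene Spearman
mRNA~protein correlations with class-wise summaries, two-sample KS
comparison of correlation distributions, the scaled interaction linear
model, one-sided Fisher over-representation, and chromosome-12-based
trisomy inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix

__all__ = [
    "bh_adjust",
    "design_matrix",
    "two_group_design",
    "moderated_fit",
    "call_hits",
    "dosage_profile",
    "mrna_protein_spearman",
    "correlation_cdf_compare",
    "scaled_interaction_lm",
    "fisher_overrepresentation",
    "fisher_overrepresentation_table",
    "infer_trisomy12",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design matrices

def design_matrix(annotation: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Build a design matrix from ``+``-separated annotation columns.

    ``"IGHV_mutated + trisomy12 + IGHV_mutated:trisomy12"`` yields an
    intercept column plus one column per term; ``a:b`` terms are
    elementwise products.  Columns must be numeric (0/1 indicators or
    continuous covariates).
    """
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    design = pd.DataFrame({"(Intercept)": 1.0}, index=annotation.index)
    for term in terms:
        if ":" in term:
            a, b = (x.strip() for x in term.split(":", 1))
            for col in (a, b):
                if col not in annotation.columns:
                    raise KeyError(f"unknown annotation column {col!r}")
            design[term] = (annotation[a].astype(float)
                            * annotation[b].astype(float))
        else:
            if term not in annotation.columns:
                raise KeyError(f"unknown annotation column {term!r}")
            design[term] = annotation[term].astype(float)
    return design


def two_group_design(labels: pd.Series, positive) -> pd.DataFrame:
    """Intercept + indicator design for a group-vs-rest contrast."""
    ind = (labels == positive).astype(float)
    return pd.DataFrame({"(Intercept)": 1.0, "group": ind},
                        index=labels.index)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation

def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value, good for the relevant range
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior.

    Matches the first two moments of log(s2) to those implied by the
    prior (d0, s0^2); returns ``(d0, s0_squared)`` with ``d0 = inf``
    when the observed variances are underdispersed relative to pure
    chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return math.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s02 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        # no detectable variance heterogeneity: the prior collapses onto
        # the common value (geometric mean), so s2_post == s2 when all
        # features share one variance
        d0 = math.inf
        s02 = math.exp(float(np.mean(z)))
    return d0, s02


@dataclass
class ModeratedResult:
    """Per-feature moderated statistics plus the fitted prior."""

    table: pd.DataFrame
    d0: float
    s02: float
    coefficient: str


def moderated_fit(matrix: OmicsMatrix, design: pd.DataFrame,
                  coefficient: str, d0_override: float | None = None
                  ) -> ModeratedResult:
    """Per-feature least squares + empirical-Bayes moderated t.

    Missing values are handled per feature by casewise deletion;
    features whose residual df drops below 1 (or whose reduced design
    loses rank) are dropped with a warning.  ``d0_override`` forces the
    prior df (0 disables shrinkage entirely; used for limit checks).
    """
    if coefficient not in design.columns:
        raise KeyError(f"coefficient {coefficient!r} not in design")
    X_full = design.loc[matrix.sample_ids].to_numpy(dtype=float)
    p = X_full.shape[1]
    if np.linalg.matrix_rank(X_full) < p:
        raise ValueError("design matrix is rank deficient")
    j = design.columns.get_loc(coefficient)
    Y = matrix.values.to_numpy(dtype=float)

    n_feat = Y.shape[0]
    beta = np.full(n_feat, np.nan)
    stdev_unscaled = np.full(n_feat, np.nan)
    s2 = np.full(n_feat, np.nan)
    df_resid = np.zeros(n_feat)
    dropped = 0
    for i in range(n_feat):
        y = Y[i]
        obs = np.isfinite(y)
        n_obs = int(obs.sum())
        if n_obs < p + 1:
            dropped += 1
            continue
        X = X_full[obs]
        if np.linalg.matrix_rank(X) < p:
            dropped += 1
            continue
        coef, rss, _, _ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ coef
        rss = float(resid @ resid)
        dfr = n_obs - p
        xtx_inv = np.linalg.inv(X.T @ X)
        beta[i] = coef[j]
        stdev_unscaled[i] = math.sqrt(xtx_inv[j, j])
        s2[i] = rss / dfr
        df_resid[i] = dfr
    if dropped:
        warnings.warn(f"{dropped} feature(s) dropped "
                      "(insufficient observations or reduced-rank design)")

    ok = df_resid > 0
    if d0_override is not None:
        d0 = float(d0_override)
        s02 = float(np.median(s2[ok])) if ok.any() else 1.0
    else:
        d0, s02 = fit_variance_prior(s2[ok], df_resid[ok])

    s2_post = np.full(n_feat, np.nan)
    if math.isinf(d0):
        s2_post[ok] = s02
        df_total = np.full(n_feat, np.inf)
    elif d0 == 0:
        s2_post[ok] = s2[ok]
        df_total = df_resid.astype(float)
    else:
        s2_post[ok] = (d0 * s02 + df_resid[ok] * s2[ok]) / (d0 + df_resid[ok])
        df_total = d0 + df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / (np.sqrt(s2_post) * stdev_unscaled)
    pvals = np.full(n_feat, np.nan)
    finite = np.isfinite(t)
    if np.isinf(d0):
        pvals[finite] = 2.0 * stats.norm.sf(np.abs(t[finite]))
    else:
        pvals[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total[finite])

    table = pd.DataFrame({
        "log2FC": beta, "s2": s2, "s2_post": s2_post,
        "df_resid": df_resid, "t": t, "p": pvals,
    }, index=matrix.values.index)
    table = table[np.isfinite(table["p"])]
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return ModeratedResult(table=table, d0=d0, s02=s02,
                           coefficient=coefficient)


def call_hits(result: ModeratedResult | pd.DataFrame,
              lfc_cut: float = 0.5, fdr_cut: float = 0.001) -> pd.DataFrame:
    """Features with adjusted p < fdr_cut and \\|log2FC\\| > lfc_cut."""
    if lfc_cut < 0 or fdr_cut < 0:
        raise ValueError("thresholds must be non-negative")
    table = result.table if isinstance(result, ModeratedResult) else result
    hit = (table["p_adj"] < fdr_cut) & (table["log2FC"].abs() > lfc_cut)
    out = table.copy()
    out["hit"] = hit
    return out


# ---------------------------------------------------------------------------
# gene-dosage profiles

def dosage_profile(matrix: OmicsMatrix, chromosome: str,
                   group: pd.Series, frac: float = 0.3) -> pd.DataFrame:
    """Per-group LOWESS curves of abundance along a chromosome.

    Each sample's feature-median-centred abundances for features on
    ``chromosome`` (matrices arrive normalized, so only the per-feature
    baseline is removed) are smoothed against genomic position (span
    ``frac``), then averaged within the carrier / non-carrier groups
    defined by the boolean ``group``.  Returns a DataFrame indexed by
    position with columns ``carrier`` and ``noncarrier``.
    """
    meta = matrix.feature_meta
    if meta is None:
        raise ValueError("dosage_profile requires feature metadata")
    on = meta["chromosome"].astype(str) == str(chromosome)
    if not on.any():
        raise ValueError(f"no features on chromosome {chromosome!r}")
    sub = matrix.values.loc[on.to_numpy()]
    sub = sub.sub(sub.median(axis=1), axis=0)  # remove feature baselines
    pos = meta.loc[on.to_numpy(), "start"].to_numpy(dtype=float)
    order = np.argsort(pos)
    pos_sorted = pos[order]
    curves = {}
    for sample in matrix.sample_ids:
        y = sub[sample].to_numpy()[order]
        obs = np.isfinite(y)
        smoothed = sm_lowess(y[obs], pos_sorted[obs], frac=frac,
                             xvals=pos_sorted)
        curves[sample] = smoothed
    df = pd.DataFrame(curves, index=pos_sorted)
    grp = group.loc[matrix.sample_ids].astype(bool)
    return pd.DataFrame({
        "carrier": df.loc[:, grp.to_numpy()].mean(axis=1),
        "noncarrier": df.loc[:, (~grp).to_numpy()].mean(axis=1),
    })


def off_chromosome_fraction(hits: list[str], meta: pd.DataFrame,
                            chromosome: str) -> float:
    """Fraction of hit features whose gene lies off ``chromosome``."""
    if not len(hits):
        raise ValueError("empty hit list")
    chroms = meta.loc[list(hits), "chromosome"].astype(str)
    return float((chroms != str(chromosome)).mean())


# ---------------------------------------------------------------------------
# mRNA ~ protein correlation

def mrna_protein_spearman(prot: OmicsMatrix, rna: OmicsMatrix,
                          min_pairs: int = 3) -> pd.DataFrame:
    """Per-gene Spearman correlation between protein and mRNA profiles.

    Genes are matched by shared feature id over shared samples; pairs
    with fewer than ``min_pairs`` complete observations are skipped with
    a warning.  Returns a table with ``rho, p, p_adj, feature_class``;
    summaries are available via :func:`correlation_summaries`.
    """
    shared_samples = [s for s in prot.sample_ids if s in set(rna.sample_ids)]
    if len(shared_samples) < min_pairs:
        raise ValueError("fewer than min_pairs shared samples")
    shared_genes = [g for g in prot.feature_ids
                    if g in set(rna.feature_ids)]
    P = prot.values.loc[shared_genes, shared_samples].to_numpy()
    R = rna.values.loc[shared_genes, shared_samples].to_numpy()
    rho = np.full(len(shared_genes), np.nan)
    pval = np.full(len(shared_genes), np.nan)
    skipped = 0
    for i in range(len(shared_genes)):
        obs = np.isfinite(P[i]) & np.isfinite(R[i])
        if obs.sum() < min_pairs:
            skipped += 1
            continue
        res = stats.spearmanr(P[i, obs], R[i, obs])
        rho[i], pval[i] = res.statistic, res.pvalue
    if skipped:
        warnings.warn(f"{skipped} gene(s) skipped (<{min_pairs} paired samples)")
    table = pd.DataFrame({"rho": rho, "p": pval},
                         index=pd.Index(shared_genes, name="feature_id"))
    table = table[np.isfinite(table["p"])]
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    if prot.feature_meta is not None and "feature_class" in prot.feature_meta:
        table["feature_class"] = prot.feature_meta.loc[table.index,
                                                       "feature_class"]
    else:
        table["feature_class"] = "background"
    return table


def correlation_summaries(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Median rho overall/per class and the significant-positive fraction."""
    out = {
        "median_rho": float(table["rho"].median()),
        "frac_significant_positive": float(
            ((table["p_adj"] < alpha) & (table["rho"] > 0)).mean()),
        "median_rho_by_class": {
            cls: float(sub["rho"].median())
            for cls, sub in table.groupby("feature_class")
        },
    }
    return out


def correlation_cdf_compare(rho_class: np.ndarray,
                            rho_other: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p."""
    a = np.asarray(rho_class, dtype=float)
    b = np.asarray(rho_other, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty correlation vector")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def scaled_interaction_lm(prot_gene, rna_gene, ighv, tris12) -> float:
    """OLS of scaled mRNA on scaled protein + IGHV + trisomy12 + interaction.

    Returns the coefficient of the scaled protein term, i.e. the
    mRNA~protein association after adjusting for the two genotype main
    effects and their interaction.
    """
    y = np.asarray(rna_gene, dtype=float)
    x = np.asarray(prot_gene, dtype=float)
    g1 = np.asarray(ighv, dtype=float)
    g2 = np.asarray(tris12, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 samples")

    def zscore(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("constant input vector")
        return (v - v.mean()) / sd

    X = np.column_stack([np.ones_like(y), zscore(x), g1, g2, g1 * g2])
    # drop collinear genotype columns (e.g. constant or duplicated)
    keep = [0, 1]
    for k in range(2, X.shape[1]):
        trial = X[:, keep + [k]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(k)
    X = X[:, keep]
    coef, _, _, _ = np.linalg.lstsq(X, zscore(y), rcond=None)
    return float(coef[1])


# ---------------------------------------------------------------------------
# over-representation

def fisher_overrepresentation(hits: set, universe: set, gene_set: set) -> float:
    """One-sided (enrichment) hypergeometric tail probability.

    P(overlap >= observed) drawing ``len(hits)`` features from
    ``universe`` where ``len(gene_set & universe)`` are marked.
    """
    hits, universe = set(hits), set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    K = len(set(gene_set) & universe)
    n, N = len(hits), len(universe)
    k = len(hits & set(gene_set))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_overrepresentation_table(hits: set, universe: set,
                                    collection) -> pd.DataFrame:
    """One-sided Fisher p per set with BH adjustment across sets."""
    names = collection.names()
    rows = []
    for name in names:
        members = set(collection[name])
        p = fisher_overrepresentation(hits, universe, members)
        rows.append({"set": name,
                     "overlap": len(set(hits) & members & set(universe)),
                     "set_size": len(members & set(universe)), "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# trisomy-12 inference from chromosome-12 abundance

def infer_trisomy12(matrix: OmicsMatrix, chr12_set: list[str],
                    quantile: float = 0.8) -> pd.Series:
    """Flag the samples above the ``quantile`` of mean chr12 abundance.

    The top ``ceil((1 - quantile) * n)`` samples by mean chromosome-12
    abundance are flagged positive; ties (and the fully degenerate case
    of identical samples) are broken deterministically by sample id.
    """
    chr12_set = list(chr12_set)
    if not chr12_set:
        raise ValueError("empty chromosome-12 feature set")
    sub = matrix.values.loc[[f for f in chr12_set
                             if f in matrix.values.index]]
    if sub.empty:
        raise ValueError("no chromosome-12 features present in matrix")
    means = sub.mean(axis=0, skipna=True)
    n = len(means)
    m = math.ceil((1.0 - quantile) * n)
    flags = pd.Series(False, index=means.index, name="trisomy12_inferred")
    if m <= 0:
        return flags
    if means.nunique() == 1:
        warnings.warn("all samples have identical chr12 means; "
                      "flagging by sample-id tie-break")
    ranked = means.sort_values(ascending=False, kind="mergesort")
    # stable sort on value; equal values keep sample-id order
    order = sorted(means.index, key=lambda s: (-means[s], s))
    flags[order[:m]] = True
    return flags
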