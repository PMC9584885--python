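"""PSI quantification and differential exon-skipping statistics.

PSI (percent spliced-in) follows the length-normalized junction-count
convention: PSI = (I/lI) / (I/lI + S/lS), missing when both counts are
zero.  Differential splicing between a group of interest and the rest
uses a two-sided rank-sum test on per-sample PSI with three filters —
BH-adjusted p below an FDR cut, absolute difference of groupwise mean
PSI above a cut, and mean raw inclusion counts strictly above a
coverage floor.  The significance of the *number* of passing events,
N_e, is assessed by a label-permutation null that redraws the group of
interest uniformly without replacement and reruns the full pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, moderated_fit, two_group_design
from .io import OmicsMatrix

__all__ = [
    "compute_psi",
    "top_variable_events",
    "mean_psi",
    "differential_psi",
    "PermutationResult",
    "permutation_null",
    "spliceosome_psi_correlation",
    "diffsplice_exons",
    "event_samples",
]


def event_samples(events: pd.DataFrame) -> list[str]:
    """Ordered sample ids encoded in an event table's count columns."""
    return [c[5:] for c in events.columns if c.startswith("incl:")]


def _counts(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = event_samples(events)
    incl = events[[f"incl:{s}" for s in samples]].to_numpy(dtype=float)
    skip = events[[f"skip:{s}" for s in samples]].to_numpy(dtype=float)
    return incl, skip, samples


def compute_psi(events: pd.DataFrame) -> pd.DataFrame:
    """Length-normalized PSI per event and sample (NaN when I + S = 0)."""
    incl, skip, samples = _counts(events)
    if (incl < 0).any() or (skip < 0).any():
        raise ValueError("negative junction counts")
    li = events["incl_len"].to_numpy(dtype=float)[:, None]
    ls = events["skip_len"].to_numpy(dtype=float)[:, None]
    if (li <= 0).any() or (ls <= 0).any():
        raise ValueError("effective lengths must be positive")
    ni = incl / li
    ns = skip / ls
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = ni / (ni + ns)
    psi[(incl + skip) == 0] = np.nan
    return pd.DataFrame(psi, index=events.index, columns=samples)


def top_variable_events(psi: pd.DataFrame, events: pd.DataFrame,
                        category: str, n: int = 1000) -> pd.DataFrame:
    """The n events of one category with the largest across-sample variance.

    Missing-aware; exact ties (including the all-zero-variance case) are
    broken by event id, and a zero-variance selection is flagged with a
    warning.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    in_cat = events.index[events["category"] == category]
    if in_cat.empty:
        raise ValueError(f"no events of category {category!r}")
    sub = psi.loc[in_cat]
    var = sub.var(axis=1, skipna=True).fillna(0.0)
    if n >= len(var):
        return sub.sort_index()
    order = sorted(var.index, key=lambda e: (-var[e], e))
    chosen = pd.Index(order[:n])
    if var.loc[chosen].max() == 0.0:
        warnings.warn("selected events all have zero PSI variance")
    return sub.loc[chosen]


def mean_psi(psi_subset: pd.DataFrame) -> pd.Series:
    """Missing-aware per-sample mean PSI over an event subset."""
    if psi_subset.shape[0] < 1:
        raise ValueError("need at least one event")
    out = psi_subset.mean(axis=0, skipna=True)
    if out.isna().any():
        warnings.warn(f"{int(out.isna().sum())} sample(s) have all-missing PSI")
    return out


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p (tie-corrected normal
    approximation with continuity correction, missing-aware).

    Vectorized re-implementation of the asymptotic Mann-Whitney test:
    scipy's axis-aware path dominates the permutation-null runtime.
    """
    vals = np.concatenate([a, b], axis=1)
    finite = np.isfinite(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranks = stats.rankdata(vals, axis=1, nan_policy="omit")
    n1 = finite[:, :a.shape[1]].sum(axis=1).astype(float)
    n2 = finite[:, a.shape[1]:].sum(axis=1).astype(float)
    ntot = n1 + n2
    r1 = np.nansum(ranks[:, :a.shape[1]], axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # per-row tie term sum(t^3 - t)
    tie = np.zeros(len(vals))
    for i in range(len(vals)):
        row = vals[i][finite[i]]
        if row.size:
            _, counts = np.unique(row, return_counts=True)
            tie[i] = float((counts.astype(float) ** 3 - counts).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (n1 * n2 / 12.0) * ((ntot + 1.0)
                                  - tie / (ntot * (ntot - 1.0)))
        z = (np.abs(u - mu) - 0.5) / np.sqrt(var)
    z = np.clip(z, 0.0, None)
    p = 2.0 * stats.norm.sf(z)
    p = np.where((n1 >= 1) & (n2 >= 1) & np.isfinite(p), p, 1.0)
    return np.minimum(p, 1.0)


def differential_psi(events: pd.DataFrame, labels: pd.Series,
                     group, fdr: float = 0.01, min_dpsi: float = 0.1,
                     min_mean_incl: float = 20.0,
                     category: str | None = "SE") -> pd.DataFrame:
    """Group-vs-rest rank-sum test on PSI with the three event filters.

    An event is significant when its BH-adjusted two-sided rank-sum p is
    below ``fdr``, the absolute difference of groupwise mean PSI exceeds
    ``min_dpsi``, and its mean raw inclusion count across all samples is
    strictly greater than ``min_mean_incl`` (events at or below the
    floor are excluded regardless of p).  Returns the full per-event
    table with a ``significant`` flag.
    """
    if category is not None:
        events = events[events["category"] == category]
    samples = event_samples(events)
    lab = labels.loc[samples]
    in_grp = (lab == group).to_numpy()
    if in_grp.sum() < 3 or (~in_grp).sum() < 3:
        raise ValueError("both groups need at least 3 samples")
    psi = compute_psi(events).to_numpy()
    incl, _, _ = _counts(events)
    mean_incl = incl.mean(axis=1)

    a = psi[:, in_grp]
    b = psi[:, ~in_grp]
    p = _ranksum_p(a, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dpsi = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    dpsi = np.where(np.isfinite(dpsi), dpsi, 0.0)
    table = pd.DataFrame({
        "dpsi": dpsi, "p": p, "mean_incl": mean_incl,
    }, index=events.index)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = (
        (table["p_adj"] < fdr)
        & (table["dpsi"].abs() > min_dpsi)
        & (table["mean_incl"] > min_mean_incl)
    )
    return table


@dataclass
class PermutationResult:
    """Observed N_e against its label-permutation null."""

    observed: int
    null: np.ndarray
    p: float
    n_perm: int
    seed: int


def permutation_null(events: pd.DataFrame, labels: pd.Series, group,
                     n_perm: int = 200, seed: int = 0,
                     fdr: float = 0.01, min_dpsi: float = 0.1,
                     min_mean_incl: float = 20.0,
                     category: str | None = "SE") -> PermutationResult:
    """Permutation test for the number of significant events N_e.

    Each permutation redraws the group-of-interest members uniformly
    without replacement, preserving the group size, and reruns the full
    differential pipeline.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    samples = event_samples(events)
    lab = labels.loc[samples]
    n_grp = int((lab == group).sum())
    observed = int(differential_psi(
        events, lab, group, fdr, min_dpsi, min_mean_incl, category
    )["significant"].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    others = "__rest__"
    for b in range(n_perm):
        chosen = rng.choice(len(samples), size=n_grp, replace=False)
        perm = pd.Series(others, index=samples)
        perm.iloc[chosen] = group
        null[b] = int(differential_psi(
            events, perm, group, fdr, min_dpsi, min_mean_incl, category
        )["significant"].sum())
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null=null, p=p,
                             n_perm=n_perm, seed=seed)


def spliceosome_psi_correlation(protein: OmicsMatrix,
                                spliceosome_set: list[str],
                                mean_psi_by_category: dict[str, pd.Series]
                                ) -> pd.DataFrame:
    """Spearman of mean spliceosomal abundance vs per-category mean PSI."""
    members = [f for f in spliceosome_set if f in protein.values.index]
    if not members:
        raise ValueError("empty spliceosome set after matching")
    spl = protein.values.loc[members].mean(axis=0, skipna=True)
    rows = []
    for cat, mp in mean_psi_by_category.items():
        shared = [s for s in spl.index if s in mp.index]
        x = spl.loc[shared].to_numpy()
        y = mp.loc[shared].to_numpy()
        obs = np.isfinite(x) & np.isfinite(y)
        res = stats.spearmanr(x[obs], y[obs])
        rows.append({"category": cat, "rho": float(res.statistic),
                     "p": float(res.pvalue), "n": int(obs.sum())})
    return pd.DataFrame(rows).set_index("category")


def diffsplice_exons(exon_quant: OmicsMatrix, gene_map: pd.Series,
                     labels: pd.Series, group,
                     min_presence: int = 2,
                     batch: pd.Series | None = None,
                     fdr: float = 0.01, lfc_cut: float = 0.5
                     ) -> pd.DataFrame:
    """Exon-level relative-usage test (this-exon-vs-the-rest).

    Each exon's deviation profile (exon value minus the per-sample mean
    of its gene's exons) is tested for a group-vs-rest shift with the
    moderated t machinery; an exon is significant at BH-adjusted
    p < ``fdr`` and |deviation log2FC| > ``lfc_cut``.  Exons must be
    present in more than ``min_presence`` batches (per-sample ``batch``
    labels; without batch labels a batch is a single sample).
    Single-exon genes are skipped with a warning.
    """
    values = exon_quant.values
    genes = gene_map.loc[values.index]
    multi = genes.map(genes.value_counts()) >= 2
    if (~multi).any():
        warnings.warn(f"{int((~multi).sum())} single-exon gene exon(s) skipped")
        values = values.loc[multi.to_numpy()]
        genes = genes.loc[multi.to_numpy()]

    present = values.notna()
    if batch is not None:
        batches = batch.loc[values.columns]
        n_batches = present.T.groupby(batches).any().sum(axis=0)
    else:
        n_batches = present.sum(axis=1)
    keep = n_batches > min_presence
    if (~keep).any():
        values = values.loc[keep.to_numpy()]
        genes = genes.loc[keep.to_numpy()]

    gene_mean = values.groupby(genes).transform("mean")
    deviation = values - gene_mean
    dev_matrix = OmicsMatrix(deviation)
    design = two_group_design(labels.loc[values.columns], group)
    fit = moderated_fit(dev_matrix, design, "group")
    table = fit.table.copy()
    table["gene_id"] = genes.loc[table.index]
    table["significant"] = ((table["p_adj"] < fdr)
                            & (table["log2FC"].abs() > lfc_cut))
    return table
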