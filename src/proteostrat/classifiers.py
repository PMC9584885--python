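"""Rank-based k-TSP and PLS-DA subtype classifiers.

The k-TSP classifier votes over k disjoint feature pairs using only the
within-sample order of the two abundances, which makes it invariant to
any monotone per-sample normalization and therefore portable across
acquisition technologies.  Training restricts candidates to a feature
panel (B-cell receptor + spliceosome sets by default in this workflow),
scores all pairs by the difference of within-class order frequencies,
selects disjoint pairs greedily, and tunes k by repeated Monte-Carlo
cross-validation on balanced accuracy.  Prediction applies the
documented missing-pair rule: a pair whose feature is absent for a
sample is dropped and the vote threshold is lowered by one (floor 1).

PLS-DA regresses a {0,1} class coding on z-scored predictors with
NIPALS-fitted partial-least-squares components; the component count is
chosen by leave-one-out AUROC and the decision cutoff is the midpoint
of the class mean scores.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "TspModel",
    "PlsdaModel",
    "tsp_pair_scores",
    "tsp_select",
    "tsp_train_mccv",
    "tsp_predict",
    "plsda_train",
    "plsda_predict",
    "roc_auc",
]


def roc_auc(scores, y) -> float:
    """AUROC via the Mann-Whitney rank statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# k-TSP

@dataclass
class TspModel:
    """Ordered pairs [(a, b)] voting for ``positive`` when a < b."""

    pairs: list[tuple[str, str]]
    positive: str
    negative: str
    vote_threshold: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        feats = [f for p in self.pairs for f in p]
        if len(set(feats)) != len(feats):
            raise ValueError("pairs must be disjoint and features distinct")
        if not 1 <= self.vote_threshold <= max(len(self.pairs), 1):
            raise ValueError("vote_threshold outside [1, k]")

    @property
    def k(self) -> int:
        return len(self.pairs)

    def to_json(self) -> str:
        return json.dumps({
            "type": "ktsp",
            "classes": [self.positive, self.negative],
            "pairs": [{"a": a, "b": b, "vote": self.positive}
                      for a, b in self.pairs],
            "k": self.k,
            "threshold": self.vote_threshold,
            "provenance": self.provenance,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TspModel":
        obj = json.loads(text)
        if obj.get("type") != "ktsp":
            raise ValueError("not a k-TSP model JSON")
        return cls(
            pairs=[(p["a"], p["b"]) for p in obj["pairs"]],
            positive=obj["classes"][0], negative=obj["classes"][1],
            vote_threshold=obj["threshold"],
            provenance=obj.get("provenance", {}),
        )


def tsp_pair_scores(X: pd.DataFrame, y: pd.Series, positive,
                    candidate_features: list[str] | None = None
                    ) -> pd.DataFrame:
    """Score all feature pairs by the TSP order-frequency statistic.

    For a pair (i, j), Delta = |P(Xi < Xj | positive) - P(Xi < Xj |
    rest)| estimated by within-class frequencies over samples where
    both features are observed.  The secondary score is the absolute
    between-class difference of mean within-sample rank differences.
    ``X`` is features x samples.
    """
    if candidate_features is not None:
        missing = [f for f in candidate_features if f not in X.index]
        if missing:
            raise KeyError(f"candidate features absent: {missing[:5]}")
        X = X.loc[list(candidate_features)]
    y = y.loc[X.columns]
    pos = (y == positive).to_numpy()
    if pos.sum() < 3 or (~pos).sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    V = X.to_numpy(dtype=float)
    m = V.shape[0]
    finite = np.isfinite(V)
    less = V[:, None, :] < V[None, :, :]          # (i, j, sample)
    valid = finite[:, None, :] & finite[None, :, :]

    def freq(mask):
        cnt = (less & valid & mask).sum(axis=2)
        tot = (valid & mask).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, cnt / np.maximum(tot, 1), 0.0)

    p_pos = freq(pos[None, None, :])
    p_neg = freq(~pos[None, None, :])
    delta = p_pos - p_neg

    # within-sample ranks over the candidate panel (NaN-aware)
    ranks = np.full_like(V, np.nan)
    for s in range(V.shape[1]):
        obs = finite[:, s]
        if obs.any():
            ranks[obs, s] = rankdata(V[obs, s])
    rd = ranks[:, None, :] - ranks[None, :, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_pos = np.nanmean(np.where(pos[None, None, :], rd, np.nan), axis=2)
        mean_neg = np.nanmean(np.where(~pos[None, None, :], rd, np.nan), axis=2)
    secondary = np.abs(np.nan_to_num(mean_pos) - np.nan_to_num(mean_neg))

    iu = np.triu_indices(m, k=1)
    feats = X.index.to_numpy()
    rows = pd.DataFrame({
        "a": feats[iu[0]], "b": feats[iu[1]],
        "delta": np.abs(delta[iu]),
        "secondary": secondary[iu],
        # orientation: vote positive when a < b iff that order is the
        # more frequent one in the positive class
        "flip": delta[iu] < 0,
    })
    a = np.where(rows["flip"], rows["b"], rows["a"])
    b = np.where(rows["flip"], rows["a"], rows["b"])
    rows["a"], rows["b"] = a, b
    return rows.drop(columns="flip").sort_values(
        ["delta", "secondary", "a", "b"],
        ascending=[False, False, True, True]).reset_index(drop=True)


def tsp_select(scores: pd.DataFrame, k: int) -> list[tuple[str, str]]:
    """Greedy disjoint selection of the k best-scoring pairs.

    Pairs sharing a feature with an already-chosen pair are skipped;
    ties are broken by the secondary score then lexicographically.  If
    fewer than k disjoint pairs exist the maximum achievable is
    returned with a warning.
    """
    used: set[str] = set()
    chosen: list[tuple[str, str]] = []
    ordered = scores.sort_values(["delta", "secondary", "a", "b"],
                                 ascending=[False, False, True, True])
    for _, row in ordered.iterrows():
        if row["a"] in used or row["b"] in used:
            continue
        chosen.append((row["a"], row["b"]))
        used.update((row["a"], row["b"]))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        warnings.warn(f"only {len(chosen)} disjoint pairs available "
                      f"(requested {k})")
    return chosen


def tsp_predict(model: TspModel, X: pd.DataFrame
                ) -> tuple[pd.Series, pd.Series]:
    """Apply a k-TSP model with the missing-pair threshold rule.

    Per sample, every evaluable pair votes via the indicator a < b;
    pairs with either feature absent from the matrix or missing for
    that sample are dropped and the vote threshold is lowered by one
    per dropped pair (floor 1).  Samples with no evaluable pair get a
    missing label with a warning.  Returns (labels, votes).
    """
    labels = pd.Series(index=X.columns, dtype=object, name="label")
    votes = pd.Series(0, index=X.columns, name="votes")
    absent_pairs = [(a, b) for a, b in model.pairs
                    if a not in X.index or b not in X.index]
    if absent_pairs:
        warnings.warn(f"{len(absent_pairs)} pair(s) unavailable in matrix; "
                      "threshold lowered accordingly")
    usable = [(a, b) for a, b in model.pairs
              if a in X.index and b in X.index]
    n_missing_any = 0
    for sample in X.columns:
        col = X[sample]
        n_votes = 0
        n_eval = 0
        for a, b in usable:
            va, vb = col[a], col[b]
            if not (np.isfinite(va) and np.isfinite(vb)):
                continue
            n_eval += 1
            if va < vb:
                n_votes += 1
        dropped = model.k - n_eval
        if n_eval == 0:
            labels[sample] = None
            n_missing_any += 1
            continue
        threshold = max(model.vote_threshold - dropped, 1)
        votes[sample] = n_votes
        labels[sample] = (model.positive if n_votes >= threshold
                          else model.negative)
    if n_missing_any:
        warnings.warn(f"{n_missing_any} sample(s) had no evaluable pair")
    return labels, votes


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true
    tpr = (y_pred & pos).sum() / max(pos.sum(), 1)
    tnr = (~y_pred & ~pos).sum() / max((~pos).sum(), 1)
    return float((tpr + tnr) / 2.0)


def tsp_train_mccv(X: pd.DataFrame, y: pd.Series, positive,
                   panel: list[str], k_grid=(3, 5, 7, 9, 11),
                   n_splits: int = 100, holdout_frac: float = 0.25,
                   seed: int = 0) -> TspModel:
    """Train a k-TSP model with Monte-Carlo cross-validated pair count.

    For each k in ``k_grid`` the mean balanced accuracy over
    ``n_splits`` stratified random holdouts is computed from a single
    greedy selection per split (prefixes of the disjoint-pair list);
    the best k (smallest on ties) is refit on all data with vote
    threshold ceil(k / 2).
    """
    panel = [f for f in panel if f in X.index]
    if not panel:
        raise ValueError("empty panel intersection with matrix features")
    k_grid = sorted(set(int(k) for k in k_grid))
    kmax = k_grid[-1]
    Xp = X.loc[panel]
    y = y.loc[Xp.columns]
    pos_mask = (y == positive).to_numpy()
    pos_idx = np.where(pos_mask)[0]
    neg_idx = np.where(~pos_mask)[0]
    rng = np.random.default_rng(seed)
    acc = {k: [] for k in k_grid}
    negative = "other"
    for _ in range(n_splits):
        n_pos_hold = max(1, int(round(holdout_frac * len(pos_idx))))
        n_neg_hold = max(1, int(round(holdout_frac * len(neg_idx))))
        hold = np.concatenate([
            rng.choice(pos_idx, n_pos_hold, replace=False),
            rng.choice(neg_idx, n_neg_hold, replace=False),
        ])
        train = np.setdiff1d(np.arange(len(y)), hold)
        scores = tsp_pair_scores(Xp.iloc[:, train], y.iloc[train], positive)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs_all = tsp_select(scores, kmax)
        y_hold = pos_mask[hold]
        for k in k_grid:
            pairs = pairs_all[:k]
            if not pairs:
                acc[k].append(0.5)
                continue
            sub = TspModel(pairs=pairs, positive=positive,
                           negative=negative,
                           vote_threshold=math.ceil(len(pairs) / 2))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred, _ = tsp_predict(sub, Xp.iloc[:, hold])
            acc[k].append(_balanced_accuracy(
                y_hold, (pred == positive).to_numpy()))
    mean_acc = {k: float(np.mean(acc[k])) for k in k_grid}
    best_k = min((k for k in k_grid),
                 key=lambda k: (-round(mean_acc[k], 12), k))
    scores = tsp_pair_scores(Xp, y, positive)
    pairs = tsp_select(scores, best_k)
    model = TspModel(
        pairs=pairs, positive=positive, negative=negative,
        vote_threshold=math.ceil(len(pairs) / 2),
        provenance={"panel_size": len(panel), "k_grid": list(k_grid),
                    "n_splits": n_splits, "holdout_frac": holdout_frac,
                    "seed": seed, "cv_balanced_accuracy": mean_acc},
    )
    return model


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PlsdaModel:
    """NIPALS PLS-DA with z-scored predictors and a score cutoff."""

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coefs: np.ndarray
    intercept: float
    weights: np.ndarray       # columns = component weight vectors
    n_components: int
    cutoff: float
    positive: str
    negative: str
    loo_auroc: float = float("nan")

    def to_json(self) -> str:
        return json.dumps({
            "type": "plsda",
            "classes": [self.positive, self.negative],
            "features": self.features,
            "mean": self.mean.tolist(), "sd": self.sd.tolist(),
            "ncomp": self.n_components,
            "weights": self.weights.T.tolist(),
            "coefs": self.coefs.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "loo_auroc": self.loo_auroc,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PlsdaModel":
        obj = json.loads(text)
        if obj.get("type") != "plsda":
            raise ValueError("not a PLS-DA model JSON")
        return cls(
            features=obj["features"],
            mean=np.asarray(obj["mean"]), sd=np.asarray(obj["sd"]),
            coefs=np.asarray(obj["coefs"]), intercept=obj["intercept"],
            weights=np.asarray(obj["weights"]).T,
            n_components=obj["ncomp"], cutoff=obj["cutoff"],
            positive=obj["classes"][0], negative=obj["classes"][1],
            loo_auroc=obj.get("loo_auroc", float("nan")),
        )


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_comp: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS partial least squares for a single response.

    Returns (W, P, q): weight vectors, loadings, and per-component
    regression scalars on centered inputs.
    """
    Xd = X.copy()
    yd = y.copy()
    p = X.shape[1]
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    for a in range(n_comp):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
    return W, P, q


def _pls_coefs(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def plsda_train(X: pd.DataFrame, y: pd.Series, positive,
                max_comp: int = 5) -> PlsdaModel:
    """Fit PLS-DA (samples x features) with LOO-AUROC component choice.

    Predictors are centered and scaled; constant features are dropped
    with a warning.  For each candidate component count the
    leave-one-out AUROC of the held-out scores is computed and the
    maximizing count kept (smallest on ties).  The decision cutoff is
    the midpoint of the two class mean fitted scores.
    """
    y = y.loc[X.index]
    pos = (y == positive).to_numpy().astype(float)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 samples")
    if pos.sum() == 0 or pos.sum() == n:
        raise ValueError("both classes must be present")
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) dropped")
        X = X.loc[:, ~constant]
    features = X.columns.tolist()
    mu = X.mean(axis=0).to_numpy()
    sdv = X.std(axis=0, ddof=1).to_numpy()
    Z = (X.to_numpy(dtype=float) - mu) / sdv
    if np.isnan(Z).any():
        Z = np.nan_to_num(Z)  # missing predictors imputed at 0 after scaling
    yc = pos - pos.mean()
    max_comp = min(max_comp, n - 2, Z.shape[1])

    loo_scores = np.zeros((n, max_comp))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Zi = Z[mask] - Z[mask].mean(axis=0)
        yi = pos[mask] - pos[mask].mean()
        W, P, q = _nipals_pls1(Zi, yi, max_comp)
        for c in range(1, max_comp + 1):
            cc = min(c, W.shape[1])
            B = _pls_coefs(W[:, :cc], P[:, :cc], q[:cc])
            loo_scores[i, c - 1] = float(
                (Z[i] - Z[mask].mean(axis=0)) @ B + pos[mask].mean())
    aurocs = [roc_auc(loo_scores[:, c], pos.astype(bool))
              for c in range(max_comp)]
    best = int(np.argmin([-round(a, 12) for a in aurocs]))
    n_comp = best + 1

    W, P, q = _nipals_pls1(Z.copy(), yc.copy(), n_comp)
    B = _pls_coefs(W, P, q)
    intercept = float(pos.mean())
    fitted = Z @ B + intercept
    cutoff = float((fitted[pos.astype(bool)].mean()
                    + fitted[~pos.astype(bool)].mean()) / 2.0)
    return PlsdaModel(
        features=features, mean=mu, sd=sdv, coefs=B, intercept=intercept,
        weights=W, n_components=n_comp, cutoff=cutoff,
        positive=positive, negative="other",
        loo_auroc=float(aurocs[best]),
    )


def plsda_predict(model: PlsdaModel, X: pd.DataFrame
                  ) -> tuple[pd.Series, pd.Series]:
    """Project samples (rows) onto the PLS score and threshold at cutoff.

    Features absent from ``X`` are imputed at 0 after scaling (with a
    warning); a sample with no observed model feature gets a missing
    label.
    """
    present = [f for f in model.features if f in X.columns]
    if not present:
        raise ValueError("no overlapping features with the model")
    if len(present) < len(model.features):
        warnings.warn(f"{len(model.features) - len(present)} model feature(s) "
                      "absent; imputed at 0 after scaling")
    Z = np.zeros((X.shape[0], len(model.features)))
    feat_pos = {f: i for i, f in enumerate(model.features)}
    observed_any = np.zeros(X.shape[0], dtype=bool)
    for f in present:
        i = feat_pos[f]
        col = X[f].to_numpy(dtype=float)
        obs = np.isfinite(col)
        Z[obs, i] = (col[obs] - model.mean[i]) / model.sd[i]
        observed_any |= obs
    scores = Z @ model.coefs + model.intercept
    labels = pd.Series(
        np.where(scores >= model.cutoff, model.positive, model.negative),
        index=X.index, dtype=object, name="label")
    if not observed_any.all():
        warnings.warn(f"{int((~observed_any).sum())} sample(s) have no "
                      "observed model feature; label set to missing")
        labels[~observed_any] = None
    return labels, pd.Series(scores, index=X.index, name="score")
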