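import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from proteostrat.classifiers import (
    PlsdaModel,
    TspModel,
    plsda_predict,
    plsda_train,
    roc_auc,
    tsp_pair_scores,
    tsp_predict,
    tsp_select,
    tsp_train_mccv,
)


def brute_force_tsp_scores(X: pd.DataFrame, y: pd.Series, positive):
    """Independent oracle: explicit loops over pairs and samples."""
    out = {}
    pos_samples = [s for s in X.columns if y[s] == positive]
    neg_samples = [s for s in X.columns if y[s] != positive]
    for fa, fb in itertools.combinations(X.index, 2):
        def freq(samples):
            n, cnt = 0, 0
            for s in samples:
                va, vb = X.loc[fa, s], X.loc[fb, s]
                if np.isfinite(va) and np.isfinite(vb):
                    n += 1
                    if va < vb:
                        cnt += 1
            return cnt / n if n else 0.0
        out[(fa, fb)] = abs(freq(pos_samples) - freq(neg_samples))
    return out


class TestPairScores:
    def test_perfect_pair_delta_one(self):
        X = pd.DataFrame({
            "s1": [1, 2], "s2": [1, 3], "s3": [2, 1],
            "s4": [3, 1], "s5": [1, 2], "s6": [4, 2],
        }, index=["fa", "fb"], dtype=float)
        y = pd.Series(["p", "p", "n", "n", "p", "n"], index=X.columns)
        scores = tsp_pair_scores(X, y, "p")
        assert scores["delta"].iloc[0] == 1.0
        assert (scores["a"].iloc[0], scores["b"].iloc[0]) == ("fa", "fb")

    def test_identical_distribution_near_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(2, 200)), index=["fa", "fb"],
                         columns=[f"s{i}" for i in range(200)])
        y = pd.Series(["p"] * 100 + ["n"] * 100, index=X.columns)
        scores = tsp_pair_scores(X, y, "p")
        assert scores["delta"].iloc[0] < 0.2

    def test_matches_brute_force_enumeration(self):
        """Exact agreement with the loop oracle on 50 random toys."""
        rng = np.random.default_rng(1)
        for trial in range(50):
            n_feat = int(rng.integers(4, 10))
            n = int(rng.integers(8, 14))
            X = pd.DataFrame(
                rng.normal(size=(n_feat, n)),
                index=[f"f{i}" for i in range(n_feat)],
                columns=[f"s{i}" for i in range(n)])
            if rng.random() < 0.3:
                mask = rng.random(X.shape) < 0.1
                X = X.mask(pd.DataFrame(mask, index=X.index,
                                        columns=X.columns))
            y = pd.Series(["p"] * (n // 2) + ["n"] * (n - n // 2),
                          index=X.columns)
            scores = tsp_pair_scores(X, y, "p")
            oracle = brute_force_tsp_scores(X, y, "p")
            for _, row in scores.iterrows():
                key = ((row["a"], row["b"]) if (row["a"], row["b"]) in oracle
                       else (row["b"], row["a"]))
                assert row["delta"] == pytest.approx(oracle[key], abs=1e-12)

    def test_small_class_rejected(self):
        X = pd.DataFrame(np.zeros((2, 5)), index=["fa", "fb"],
                         columns=[f"s{i}" for i in range(5)])
        y = pd.Series(["p", "p", "n", "n", "n"], index=X.columns)
        with pytest.raises(ValueError):
            tsp_pair_scores(X, y, "p")


class TestSelect:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["a", "b", "delta", "secondary"])

    def test_shared_feature_skipped(self):
        scores = self._scores([
            ("f1", "f2", 0.9, 1.0),
            ("f1", "f3", 0.8, 1.0),
            ("f4", "f5", 0.7, 1.0),
        ])
        pairs = tsp_select(scores, 2)
        assert pairs == [("f1", "f2"), ("f4", "f5")]

    def test_k_one_best_pair(self):
        scores = self._scores([("f1", "f2", 0.9, 1.0), ("f3", "f4", 0.5, 1.0)])
        assert tsp_select(scores, 1) == [("f1", "f2")]

    def test_tie_break_lexicographic(self):
        scores = self._scores([
            ("f9", "f8", 0.8, 0.5),
            ("f1", "f2", 0.8, 0.5),
        ])
        assert tsp_select(scores, 1) == [("f1", "f2")]

    def test_insufficient_pairs_warns(self):
        scores = self._scores([("f1", "f2", 0.9, 1.0), ("f2", "f3", 0.8, 1.0)])
        with pytest.warns(UserWarning, match="disjoint"):
            pairs = tsp_select(scores, 2)
        assert len(pairs) == 1


class TestPredict:
    def _clean_model_and_matrix(self, k=8):
        pairs = [(f"a{i}", f"b{i}") for i in range(k)]
        model = TspModel(pairs=pairs, positive="ASB", negative="other",
                         vote_threshold=(k + 1) // 2)
        rows, data = [], []
        for a, b in pairs:
            rows += [a, b]
            data += [[1.0, 5.0], [2.0, 4.0]]  # s1: a<b (vote); s2: a>b
        X = pd.DataFrame(data, index=rows, columns=["s1", "s2"])
        return model, X

    def test_all_pairs_vote_positive(self):
        model, X = self._clean_model_and_matrix()
        labels, votes = tsp_predict(model, X)
        assert labels["s1"] == "ASB" and votes["s1"] == 8
        assert labels["s2"] == "other" and votes["s2"] == 0

    def test_missing_pair_lowers_threshold(self):
        model, X = self._clean_model_and_matrix()
        with pytest.warns(UserWarning, match="pair"):
            labels2, _ = tsp_predict(model, X.drop(index=["a0"]))
        labels, _ = tsp_predict(model, X)
        assert (labels2 == labels).all()

    def test_votes_exactly_at_threshold_positive(self):
        model, X = self._clean_model_and_matrix(k=4)  # threshold 2
        Xv = X.copy()
        # flip two of four pairs for s1 -> exactly 2 votes
        Xv.loc["a0", "s1"], Xv.loc["b0", "s1"] = 5.0, 1.0
        Xv.loc["a1", "s1"], Xv.loc["b1", "s1"] = 5.0, 1.0
        labels, votes = tsp_predict(model, Xv)
        assert votes["s1"] == 2 and labels["s1"] == "ASB"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        model, X = self._clean_model_and_matrix()
        noise = pd.DataFrame(rng.normal(10, 3, (len(X), 4)),
                             index=X.index,
                             columns=[f"s{i}" for i in range(4)])
        labels, _ = tsp_predict(model, noise)
        transformed = noise.apply(lambda col: np.exp(col / 2) + 7)
        labels2, _ = tsp_predict(model, transformed)
        assert (labels == labels2).all()

    def test_all_pairs_unevaluable_missing_label(self):
        model, X = self._clean_model_and_matrix()
        Xna = X.copy()
        Xna["s1"] = np.nan
        with pytest.warns(UserWarning, match="no evaluable"):
            labels, _ = tsp_predict(model, Xna)
        assert labels["s1"] is None

    def test_model_json_roundtrip(self):
        model, _ = self._clean_model_and_matrix()
        back = TspModel.from_json(model.to_json())
        assert back.pairs == model.pairs
        assert back.vote_threshold == model.vote_threshold


class TestTrainMccv:
    def test_planted_asb_high_holdout_accuracy(self, default_bundle):
        panel = (default_bundle.gene_sets["BCR"]
                 + default_bundle.gene_sets["SPLICEOSOME"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = tsp_train_mccv(
                default_bundle.protein.values, default_bundle.truth, "ASB",
                panel, k_grid=(3, 5, 7, 9), n_splits=40, seed=0)
        best = model.provenance["cv_balanced_accuracy"][model.k]
        assert best >= 0.9

    def test_shuffled_labels_chance_level(self, default_bundle):
        rng = np.random.default_rng(0)
        truth = default_bundle.truth
        shuffled = pd.Series(rng.permutation(truth.to_numpy()),
                             index=truth.index)
        panel = default_bundle.gene_sets["BCR"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = tsp_train_mccv(
                default_bundle.protein.values, shuffled, "ASB", panel,
                k_grid=(3, 5), n_splits=30, seed=0)
        accs = model.provenance["cv_balanced_accuracy"]
        assert all(abs(a - 0.5) < 0.12 for a in accs.values())

    def test_clean_separable_chooses_smallest_k(self):
        rng = np.random.default_rng(0)
        n = 40
        y = pd.Series(["p"] * 12 + ["n"] * 28,
                      index=[f"s{i}" for i in range(n)])
        # 20 features; f0<f1 in class p, reversed in class n, clean
        data = {}
        for i in range(0, 20, 2):
            lo = rng.normal(10, 0.1, n)
            data[f"f{i}"] = np.where(y == "p", lo, lo + 2)
            data[f"f{i+1}"] = lo + 1
        X = pd.DataFrame(data).T
        X.columns = y.index
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = tsp_train_mccv(X, y, "p", list(X.index),
                                   k_grid=(3, 5, 7, 9), n_splits=20, seed=0)
        assert model.k == 3
        assert model.vote_threshold == 2

    def test_empty_panel_rejected(self, default_bundle):
        with pytest.raises(ValueError):
            tsp_train_mccv(default_bundle.protein.values,
                           default_bundle.truth, "ASB", ["NOPE"])


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5

    def test_pairwise_win_counting_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_equals_u_statistic_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], n)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            # oracle: explicit pairwise wins with half-credit ties
            wins = 0.0
            for i in range(n):
                for j in range(n):
                    if y[i] == 1 and y[j] == 0:
                        wins += (1.0 if scores[i] > scores[j]
                                 else 0.5 if scores[i] == scores[j] else 0.0)
            oracle = wins / (y.sum() * (n - y.sum()))
            assert roc_auc(scores, y) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestPlsda:
    def _separable(self, n=30, p=12, gap=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series(["p"] * (n // 3) + ["n"] * (n - n // 3),
                      index=[f"s{i}" for i in range(n)])
        X = rng.normal(size=(n, p))
        X[:n // 3, :3] += gap
        return pd.DataFrame(X, index=y.index,
                            columns=[f"f{i}" for i in range(p)]), y

    def test_separable_loo_auroc_one(self):
        X, y = self._separable()
        model = plsda_train(X, y, "p")
        assert model.loo_auroc == 1.0

    def test_independent_labels_chance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         index=[f"s{i}" for i in range(40)],
                         columns=[f"f{i}" for i in range(10)])
        y = pd.Series(rng.choice(["p", "n"], 40), index=X.index)
        model = plsda_train(X, y, "p")
        assert abs(model.loo_auroc - 0.5) < 0.25

    def test_first_component_closed_form(self):
        """w1 is proportional to X^T y on centered, scaled data."""
        X, y = self._separable(seed=5)
        model = plsda_train(X, y, "p", max_comp=1)
        Z = (X - X.mean()) / X.std(ddof=1)
        yc = (y == "p").astype(float)
        yc = yc - yc.mean()
        w_ref = Z.T @ yc
        w_ref = w_ref / np.linalg.norm(w_ref)
        cos = abs(float(np.dot(model.weights[:, 0], w_ref)))
        assert cos >= 1 - 1e-8

    def test_training_data_repredicted_consistently(self):
        X, y = self._separable()
        model = plsda_train(X, y, "p")
        labels, scores = plsda_predict(model, X)
        assert (labels == y.map({"p": "p", "n": "other"})).all()

    def test_constant_feature_dropped_with_warning(self):
        X, y = self._separable()
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = plsda_train(X, y, "p")
        assert "const" not in model.features

    def test_all_missing_sample_gets_missing_label(self):
        X, y = self._separable()
        model = plsda_train(X, y, "p")
        Xa = X.copy()
        Xa.iloc[0, :] = np.nan
        with pytest.warns(UserWarning, match="no observed"):
            labels, _ = plsda_predict(model, Xa)
        assert labels.iloc[0] is None

    def test_matches_sklearn_pls_scores(self):
        """Cross-check fitted scores against sklearn PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = self._separable(seed=9)
        model = plsda_train(X, y, "p", max_comp=2)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        yc = (y == "p").astype(float).to_numpy()
        skl = PLSRegression(n_components=model.n_components, scale=False)
        skl.fit(Z, yc - yc.mean())
        ref = skl.predict(Z).ravel() + yc.mean()
        mine = Z @ model.coefs + model.intercept
        assert np.allclose(mine, ref, atol=1e-8)

    def test_model_json_roundtrip(self):
        X, y = self._separable()
        model = plsda_train(X, y, "p")
        back = PlsdaModel.from_json(model.to_json())
        _, s1 = plsda_predict(model, X)
        _, s2 = plsda_predict(back, X)
        assert np.allclose(s1, s2, atol=1e-12)


class TestCrossTechnologyTransfer:
    def test_renoised_rescaled_copy_agreement(self, default_bundle):
        """Rank-based prediction survives a simulated platform change."""
        rng = np.random.default_rng(0)
        panel = (default_bundle.gene_sets["BCR"]
                 + default_bundle.gene_sets["SPLICEOSOME"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = tsp_train_mccv(
                default_bundle.protein.values, default_bundle.truth, "ASB",
                panel, k_grid=(5, 7, 9), n_splits=30, seed=0)
            orig, _ = tsp_predict(model, default_bundle.protein.values)
            # simulate re-acquisition: per-sample affine rescale + noise
            replica = (default_bundle.protein.values * 1.7 + 3.0
                       + rng.normal(0, 0.15,
                                    default_bundle.protein.values.shape))
            renoised, _ = tsp_predict(model, replica)
        both = orig.notna() & renoised.notna()
        agreement = (orig[both] == renoised[both]).mean()
        assert agreement >= 0.9
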