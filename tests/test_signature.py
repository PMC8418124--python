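"""SVM-RFE ranking, signature-size selection, gene clustering, PC1 fits,
score formula and model serialization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmescore import (
    PC1Fit,
    SurvivalData,
    TMEScoreError,
    TMEScoreModel,
    assign_direction_sets,
    cluster_signature_genes,
    cyt_score,
    fit_pc1,
    gep_score,
    select_signature,
    svm_rfe_rank,
    tme_score,
)
from tmescore.containers import ExpressionMatrix


class TestSVMRFE:
    def test_separating_gene_ranked_first(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = rng.normal(size=(60, 51))
            X[:, 0] = y * 4 + rng.normal(0, 0.3, 60)  # near-perfect separator
            frame = pd.DataFrame(X, columns=[f"g{i}" for i in range(51)])
            ranked = svm_rfe_rank(frame, y, seed=seed)
            wins += ranked[0] == "g0"
        assert wins >= 9

    def test_single_gene_trivial(self, rng):
        frame = pd.DataFrame({"only": rng.normal(size=10)})
        assert svm_rfe_rank(frame, np.repeat([0, 1], 5)) == ["only"]

    def test_returns_full_permutation(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 12)), columns=[f"g{i}" for i in range(12)])
        ranked = svm_rfe_rank(frame, np.repeat([0, 1], 15))
        assert sorted(ranked) == sorted(frame.columns)

    def test_single_class_errors(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(TMEScoreError, match="two classes"):
            svm_rfe_rank(frame, np.zeros(10))


class TestSelectSignature:
    def _separable(self, rng, n=80, n_genes=80, n_inform=20):
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, n_genes))
        X[:, :n_inform] += y[:, None] * 2.0
        return pd.DataFrame(X, columns=[f"g{i}" for i in range(n_genes)]), y

    def test_tie_goes_to_smaller_size(self, rng):
        X, y = self._separable(rng)
        ranked = svm_rfe_rank(X, y)
        genes, table = select_signature(ranked, X, y, candidate_sizes=[40, 60])
        # both sizes separate perfectly -> the smaller wins
        assert table["cv_accuracy"].iloc[0] == table["cv_accuracy"].iloc[1] == 1.0
        assert len(genes) == 40

    def test_full_list_candidate(self, rng):
        X, y = self._separable(rng, n_genes=30)
        ranked = svm_rfe_rank(X, y)
        genes, _ = select_signature(ranked, X, y, candidate_sizes=[len(ranked)])
        assert genes == ranked

    def test_recovers_informative_genes(self, rng):
        # weak individual effects: accuracy genuinely grows with size, so
        # the accuracy-maximising prefix must gather most planted genes
        y = np.repeat([0, 1], 75)
        X = rng.normal(size=(150, 100))
        X[:, :20] += y[:, None] * 0.8
        X = pd.DataFrame(X, columns=[f"g{i}" for i in range(100)])
        ranked = svm_rfe_rank(X, y, seed=1)
        genes, table = select_signature(ranked, X, y, candidate_sizes=[5, 10, 20, 30, 50], seed=1)
        planted = {f"g{i}" for i in range(20)}
        assert len(set(genes) & planted) / 20 >= 0.8
        assert table["cv_accuracy"].max() >= 0.9

    def test_out_of_range_size_errors(self, rng):
        X, y = self._separable(rng, n_genes=20)
        with pytest.raises(TMEScoreError, match="candidate sizes"):
            select_signature(list(X.columns), X, y, candidate_sizes=[50])


class TestGeneClusters:
    def test_two_correlated_blocks_recovered(self, rng):
        base1, base2 = rng.normal(size=(2, 100))
        genes = np.vstack(
            [base1 + rng.normal(0, 0.3, (6, 100)), base2 + rng.normal(0, 0.3, (6, 100))]
        )
        expr = pd.DataFrame(genes, index=[f"g{i}" for i in range(12)])
        labels, res = cluster_signature_genes(expr, k_values=(2,), n_resamples=20, seed=0)
        truth = np.repeat([0, 1], 6)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_single_cluster_forced(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 40)), index=[f"g{i}" for i in range(5)])
        labels, res = cluster_signature_genes(expr, k_values=(1,), n_resamples=5, seed=0)
        assert labels.nunique() == 1

    def test_anticorrelated_pair_split(self, rng):
        x = rng.normal(size=50)
        expr = pd.DataFrame([x, -x], index=["up", "down"])
        labels, _ = cluster_signature_genes(expr, k_values=(2,), n_resamples=5, seed=0)
        assert labels["up"] != labels["down"]


class TestFitPC1:
    def test_matches_eigendecomposition(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 40)), index=[f"g{i}" for i in range(6)])
        fit = fit_pc1(expr)
        Z = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).to_numpy()
        evals, evecs = np.linalg.eigh(Z.T @ Z / (Z.shape[0] - 1))
        lead = evecs[:, -1]
        agreement = abs(float(np.dot(lead, fit.loadings)))
        assert agreement == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(fit.loadings) == pytest.approx(1.0, abs=1e-12)

    def test_orientation_positive_with_cluster_mean(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(r.normal(size=(8, 30)))
            fit = fit_pc1(expr)
            score = fit.score(expr, standardize="train")
            meanz = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).mean(axis=1)
            assert np.corrcoef(score, meanz)[0, 1] > 0

    def test_rank_one_structure(self, rng):
        shared = rng.normal(size=30)
        expr = pd.DataFrame(np.outer([1.0, 2.0, 0.5], shared) + 5.0)
        fit = fit_pc1(expr)
        assert fit.explained_ratio >= 0.999

    def test_zero_variance_gene_dropped(self, rng):
        expr = pd.DataFrame(
            np.vstack([np.ones(20), rng.normal(size=(3, 20))]), index=["flat", "a", "b", "c"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_pc1(expr)
        assert fit.genes == ["a", "b", "c"]

    def test_single_gene_cluster(self, rng):
        expr = pd.DataFrame(rng.normal(size=(1, 25)), index=["solo"])
        fit = fit_pc1(expr)
        assert fit.loadings.tolist() == [1.0]
        score = fit.score(expr, standardize="train")
        np.testing.assert_allclose(
            score, (expr.iloc[0] - expr.iloc[0].mean()) / expr.iloc[0].std(ddof=1)
        )


class TestDirections:
    def test_hazardous_cluster_gets_i(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            latent = rng.normal(size=n)
            up = pd.DataFrame(latent + rng.normal(0, 0.4, (4, n)), index=[f"u{i}" for i in range(4)])
            down = pd.DataFrame(-latent + rng.normal(0, 0.4, (4, n)), index=[f"d{i}" for i in range(4)])
            expr = pd.concat([up, down])
            rate = 0.01 * np.exp(np.log(2) * latent)
            surv = SurvivalData(rng.exponential(1 / rate), np.ones(n, int))
            labels = pd.Series([0] * 4 + [1] * 4, index=expr.index)
            directions, pc1, table = assign_direction_sets(labels, expr, surv)
            hits += directions["0"] == "i" and directions["1"] == "j"
        assert hits >= 9


def _toy_model(rng, n_genes=6, cutoff=None):
    genes = [f"g{i}" for i in range(n_genes)]
    half = n_genes // 2
    model = TMEScoreModel(
        signature_genes=genes,
        gene_clusters={"a": genes[:half], "b": genes[half:]},
        direction={"a": "i", "b": "j"},
        pc1={
            "a": PC1Fit(genes[:half], np.full(half, 1 / np.sqrt(half)),
                        np.zeros(half), np.ones(half), 1.0),
            "b": PC1Fit(genes[half:], np.full(half, 1 / np.sqrt(half)),
                        np.zeros(half), np.ones(half), 1.0),
        },
        cutoff=cutoff,
    )
    return model, genes


class TestTMEScore:
    def test_empty_j_set_is_plain_sum(self, rng):
        model, genes = _toy_model(rng)
        model.direction = {"a": "i", "b": "i"}
        expr = pd.DataFrame(rng.normal(size=(6, 20)), index=genes)
        res = tme_score(expr, model, standardize="train")
        np.testing.assert_allclose(res["tme_score"], res["PC1_a"] + res["PC1_b"], atol=1e-12)

    def test_i_minus_j(self, rng):
        model, genes = _toy_model(rng)
        expr = pd.DataFrame(rng.normal(size=(6, 20)), index=genes)
        res = tme_score(expr, model, standardize="train")
        np.testing.assert_allclose(res["tme_score"], res["PC1_a"] - res["PC1_b"], atol=1e-12)

    def test_invariant_to_non_signature_genes(self, rng):
        model, genes = _toy_model(rng)
        expr = pd.DataFrame(rng.normal(size=(6, 20)), index=genes)
        extra = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"x{i}" for i in range(10)],
                             columns=expr.columns)
        a = tme_score(expr, model)
        b = tme_score(pd.concat([extra, expr]), model)
        np.testing.assert_array_equal(a["tme_score"], b["tme_score"])

    def test_sample_permutation_equivariance(self, rng):
        model, genes = _toy_model(rng)
        expr = pd.DataFrame(rng.normal(size=(6, 20)), index=genes)
        perm = rng.permutation(expr.columns)
        a = tme_score(expr, model, standardize="train")
        b = tme_score(expr[perm], model, standardize="train")
        np.testing.assert_array_equal(a.loc[perm, "tme_score"], b["tme_score"])

    def test_low_coverage_errors(self, rng):
        model, genes = _toy_model(rng, n_genes=10)
        expr = pd.DataFrame(rng.normal(size=(6, 5)), index=genes[:6])
        with pytest.raises(TMEScoreError, match="coverage"):
            tme_score(expr, model)

    def test_grouping_against_cutoff(self, rng):
        model, genes = _toy_model(rng, cutoff=0.0)
        expr = pd.DataFrame(rng.normal(size=(6, 30)), index=genes)
        res = tme_score(expr, model, standardize="train")
        assert ((res["group"] == "high") == (res["tme_score"] > 0)).all()


class TestModelSerialization:
    def test_round_trip_scores_bitwise(self, rng):
        model, genes = _toy_model(rng, cutoff=0.3)
        expr = pd.DataFrame(rng.normal(size=(6, 15)), index=genes)
        clone = TMEScoreModel.from_json(model.to_json())
        a = tme_score(expr, model)
        b = tme_score(expr, clone)
        assert np.array_equal(a["tme_score"].to_numpy(), b["tme_score"].to_numpy())

    def test_file_round_trip(self, rng, tmp_path):
        model, _ = _toy_model(rng, cutoff=1.5)
        model.to_json(tmp_path / "m.json")
        clone = TMEScoreModel.from_json(tmp_path / "m.json")
        assert clone.to_json() == model.to_json()

    def test_partition_validated(self, rng):
        model, genes = _toy_model(rng)
        with pytest.raises(TMEScoreError, match="partition"):
            TMEScoreModel(
                signature_genes=genes + ["orphan"],
                gene_clusters=model.gene_clusters,
                direction=model.direction,
                pc1=model.pc1,
            )


class TestImmuneReadouts:
    def _linear(self, data, genes):
        return ExpressionMatrix(pd.DataFrame(data, index=genes), scale="linear")

    def test_cyt_geometric_mean(self):
        em = self._linear([[4.0], [9.0]], ["GZMA", "PRF1"])
        assert cyt_score(em)["CYT"].iloc[0] == pytest.approx(6.0, abs=0.02)

    def test_cyt_zero_floor(self):
        em = self._linear([[0.0], [0.0]], ["GZMA", "PRF1"])
        assert cyt_score(em)["CYT"].iloc[0] == pytest.approx(0.01)

    def test_cyt_equal_markers(self):
        em = self._linear([[7.0], [7.0]], ["GZMA", "PRF1"])
        assert cyt_score(em)["CYT"].iloc[0] == pytest.approx(7.01)

    def test_cyt_missing_marker_named(self):
        em = self._linear([[4.0]], ["GZMA"])
        with pytest.raises(TMEScoreError, match="PRF1"):
            cyt_score(em)

    def test_gep_mean_and_linearity(self, rng):
        genes = [f"gep{i}" for i in range(18)]
        em = ExpressionMatrix(pd.DataFrame(np.full((18, 1), 2.5), index=genes), scale="log2")
        assert gep_score(em, genes)["GEP"].iloc[0] == pytest.approx(2.5)
        X = rng.normal(size=(18, 3))
        a = gep_score(ExpressionMatrix(pd.DataFrame(X, index=genes), scale="log2"), genes)
        b = gep_score(ExpressionMatrix(pd.DataFrame(X + 1, index=genes), scale="log2"), genes)
        np.testing.assert_allclose(b["GEP"], a["GEP"] + 1)

    def test_gep_missing_genes_counted(self, rng):
        genes = [f"gep{i}" for i in range(18)]
        em = ExpressionMatrix(pd.DataFrame(rng.normal(size=(17, 2)), index=genes[:17]), scale="log2")
        with pytest.raises(TMEScoreError, match="1 of 18"):
            gep_score(em, genes)
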