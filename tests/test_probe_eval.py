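"""Linear probing protocol, 2-D projections, transportability, class filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from fundusfm.embed_store import EmbeddingMatrix
from fundusfm.probe_eval import (EvalProtocol, cosine_affinity, fit_linear_probe,
                                 fit_projection, probe_2d,
                                 select_nontrivial_classes, transport_evaluate)
from fundusfm.synthetic import generate_embedding_blobs


def _split(emb, labels, frac=0.8, seed=0):
    rng = np.random.default_rng(seed)
    n = emb.n
    order = rng.permutation(n)
    k = int(frac * n)
    tr, te = order[:k], order[k:]
    return (EmbeddingMatrix(emb.values[tr], [emb.ids[i] for i in tr]), labels[tr],
            EmbeddingMatrix(emb.values[te], [emb.ids[i] for i in te]), labels[te])


@pytest.fixture(scope="module")
def blobs():
    emb, labels = generate_embedding_blobs(250, d=384, separation=10.0, seed=0)
    return _split(emb, labels)


class TestLinearProbe:
    def test_binary_probe_parameter_count(self, blobs):
        xtr, ytr, _, _ = blobs
        probe = fit_linear_probe(xtr, ytr)
        assert probe.n_parameters == 385  # 384 weights + intercept

    def test_separable_blobs_high_auc(self, blobs):
        xtr, ytr, xte, yte = blobs
        probe = fit_linear_probe(xtr, ytr)
        assert probe.auc(xte, yte) > 0.99

    def test_permuted_labels_chance_auc(self, blobs):
        """Permutation null: averaging over a few label permutations, the
        probe scores at chance."""
        xtr, ytr, xte, yte = blobs
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(5):
            probe = fit_linear_probe(xtr, rng.permutation(ytr))
            aucs.append(probe.auc(xte, rng.permutation(yte)))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_single_class_rejected(self, blobs):
        xtr, ytr, _, _ = blobs
        with pytest.raises(ValueError, match="severity"):
            fit_linear_probe(xtr, np.zeros_like(ytr), target="severity")

    def test_multiclass_target_multinomial_per_class_auc(self):
        rng = np.random.default_rng(0)
        centers = np.zeros((3, 20))
        centers[1, 0] = 6
        centers[2, 1] = 6
        x = np.vstack([rng.normal(size=(60, 20)) + centers[g] for g in range(3)])
        y = np.repeat([0, 1, 2], 60)
        emb = EmbeddingMatrix(x.astype(np.float32), [f"i{i}" for i in range(180)])
        xtr, ytr, xte, yte = _split(emb, y)
        probe = fit_linear_probe(xtr, ytr, target="grade")
        aucs = probe.auc(xte, yte)
        assert set(aucs) == {0, 1, 2}
        assert all(a > 0.95 for a in aucs.values())

    def test_train_only_standardisation_matches_leakage_oracle(self, blobs):
        """Pipeline equals a hand-built train-only-scaler oracle; fitting the
        scaler on train+test gives a different fitted model."""
        from sklearn.preprocessing import StandardScaler

        xtr, ytr, xte, yte = blobs
        probe = fit_linear_probe(xtr, ytr)
        xtr64 = xtr.values.astype(np.float64)
        scaler = StandardScaler().fit(xtr64)
        oracle = LogisticRegression(max_iter=20_000).fit(scaler.transform(xtr64), ytr)
        assert np.allclose(probe.clf.coef_, oracle.coef_, rtol=1e-4, atol=1e-6)
        leaky_scaler = StandardScaler().fit(np.vstack([xtr.values, xte.values]))
        assert not np.allclose(scaler.mean_, leaky_scaler.mean_)

    def test_probe_deterministic(self, blobs):
        xtr, ytr, xte, yte = blobs
        a1 = fit_linear_probe(xtr, ytr).auc(xte, yte)
        a2 = fit_linear_probe(xtr, ytr).auc(xte, yte)
        assert a1 == a2


class TestCosineAffinity:
    def test_reference_values(self):
        assert cosine_affinity([1, 0], [1, 0]) == pytest.approx(1.0)
        assert cosine_affinity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_affinity([1, 0], [1, 1]) == pytest.approx(0.70711, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_affinity([0, 0], [1, 0])


class TestProjections:
    def test_pca_matches_eigendecomposition(self):
        """PCA coordinates equal a brute-force eigendecomposition of the
        covariance matrix up to per-component sign."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 8))
        proj = fit_projection(x, method="pca", metric="euclidean", seed=0)
        coords = proj.transform(x)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T, bias=False))
        top2 = evecs[:, np.argsort(evals)[::-1][:2]]
        brute = xc @ top2
        for j in range(2):
            assert (np.allclose(coords[:, j], brute[:, j], atol=1e-8)
                    or np.allclose(coords[:, j], -brute[:, j], atol=1e-8))

    def test_pca_explained_variance_ordered(self, blobs):
        xtr, _, _, _ = blobs
        proj = fit_projection(xtr, method="pca", metric="euclidean", seed=0)
        ev = proj.steps[0].explained_variance_
        assert ev[0] >= ev[1]

    def test_pca_warns_on_metric(self, blobs):
        with pytest.warns(UserWarning, match="metric"):
            fit_projection(blobs[0], method="pca", metric="cosine", seed=0)

    def test_umap_deterministic_given_seed(self):
        emb, _ = generate_embedding_blobs(60, d=20, separation=6.0, seed=3)
        c1 = fit_projection(emb, method="umap", metric="cosine", seed=0).transform(emb)
        c2 = fit_projection(emb, method="umap", metric="cosine", seed=0).transform(emb)
        assert np.array_equal(c1, c2)

    def test_pca100_umap_variant_runs(self):
        emb, _ = generate_embedding_blobs(40, d=30, separation=6.0, seed=4)
        proj = fit_projection(emb, method="pca100+umap", metric="euclidean", seed=0)
        assert proj.transform(emb).shape == (80, 2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_projection(np.zeros((5, 4)), method="pca", metric="euclidean")


class TestProbe2D:
    def test_separated_blobs_both_probes_high(self):
        emb, labels = generate_embedding_blobs(100, d=2, separation=8.0, seed=0)
        xtr, ytr, xte, yte = _split(emb, labels)
        aucs = probe_2d(xtr.values, ytr, xte.values, yte)
        assert aucs["logistic"] > 0.99 and aucs["knn"] > 0.99

    def test_permuted_labels_chance(self):
        emb, labels = generate_embedding_blobs(200, d=2, separation=8.0, seed=0)
        rng = np.random.default_rng(5)
        labels = rng.permutation(labels)
        xtr, ytr, xte, yte = _split(emb, labels)
        aucs = probe_2d(xtr.values, ytr, xte.values, yte)
        assert 0.35 < aucs["logistic"] < 0.65
        assert 0.35 < aucs["knn"] < 0.65

    def test_knn_beats_logistic_on_nonlinear_clusters(self):
        """Positive class split into two opposite clusters: no single linear
        direction separates it, but neighbourhoods do."""
        rng = np.random.default_rng(0)
        neg = rng.normal(scale=0.5, size=(150, 2))
        pos = np.vstack([rng.normal(loc=(+4, 0), scale=0.5, size=(75, 2)),
                         rng.normal(loc=(-4, 0), scale=0.5, size=(75, 2))])
        x = np.vstack([neg, pos])
        y = np.repeat([0, 1], 150)
        emb = EmbeddingMatrix(x.astype(np.float32), [f"i{i}" for i in range(300)])
        xtr, ytr, xte, yte = _split(emb, y)
        aucs = probe_2d(xtr.values, ytr, xte.values, yte)
        assert aucs["knn"] > aucs["logistic"]

    def test_single_class_test_flagged(self):
        x = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="lacks"):
            probe_2d(x, np.repeat([0, 1], 10), x[:5], np.zeros(5))


class TestTransport:
    def test_transport_equals_within_dataset_result(self, blobs):
        xtr, ytr, xte, yte = blobs
        probe = fit_linear_probe(xtr, ytr)
        assert transport_evaluate(probe, xte, yte) == probe.auc(xte, yte)

    def test_transport_deterministic_without_refit(self, blobs):
        xtr, ytr, xte, yte = blobs
        probe = fit_linear_probe(xtr, ytr)
        coef = probe.clf.coef_.copy()
        shifted = EmbeddingMatrix(xte.values + 3.0, xte.ids)
        a1 = transport_evaluate(probe, shifted, yte)
        a2 = transport_evaluate(probe, shifted, yte)
        assert a1 == a2
        assert np.array_equal(probe.clf.coef_, coef)  # no refitting happened

    def test_site_shift_degradation_measured(self, blobs):
        """Same class means but inflated covariance at site B: the frozen
        pipeline runs and reports a (typically lower) AUC."""
        xtr, ytr, xte, yte = blobs
        probe = fit_linear_probe(xtr, ytr)
        rng = np.random.default_rng(2)
        site_b = EmbeddingMatrix(
            (xte.values + rng.normal(scale=8.0, size=xte.values.shape)).astype(np.float32),
            xte.ids)
        auc_b = transport_evaluate(probe, site_b, yte)
        assert 0.0 <= auc_b <= 1.0
        assert auc_b < probe.auc(xte, yte)

    def test_dimension_mismatch_rejected(self, blobs):
        xtr, ytr, _, _ = blobs
        probe = fit_linear_probe(xtr, ytr)
        bad = EmbeddingMatrix(np.zeros((4, 10), np.float32), list("abcd"))
        with pytest.raises(ValueError, match="dimension"):
            transport_evaluate(probe, bad, [0, 1, 0, 1])


class TestNontrivialClassFilter:
    def test_threshold_rule(self):
        table = pd.DataFrame(
            {"m1": [1.0, 0.94, 0.95], "m2": [1.0, 1.0, 0.95], "m3": [1.0, 1.0, 0.95]},
            index=["trivial", "kept", "boundary"])
        kept = select_nontrivial_classes(table, threshold=0.95)
        assert kept == ["kept"]  # all-perfect dropped; exactly 0.95 dropped

    def test_mapping_input(self):
        kept = select_nontrivial_classes({"a": [0.99, 0.93], "b": [0.99, 0.98]})
        assert kept == ["a"]
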