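"""MC-dropout intervals, embedding search and PCA projection."""

import numpy as np
import pytest

from micropka.chemgraph import MoleculeRecord, build_graph
from micropka.model import ModelConfig, init_model
from micropka.synthetic import generate_set
from micropka.training import NoSiteError
from micropka.uncertainty import (
    EmbeddingIndex,
    build_embedding_index,
    mc_dropout_predict,
    project_embeddings,
    similar_molecules,
)


@pytest.fixture(scope="module")
def drop_state():
    return init_model(ModelConfig(n_layers=2, hidden_dim=12, head_hidden_dims=(8,),
                                  dropout_rate=0.3, mode="acidic", seed=21))


@pytest.fixture(scope="module")
def nodrop_state():
    return init_model(ModelConfig(n_layers=2, hidden_dim=12, head_hidden_dims=(8,),
                                  dropout_rate=0.0, mode="acidic", seed=21))


GLYCOLIC = "OCC(=O)O"


class TestMcDropout:
    def test_zero_dropout_degenerate_interval(self, nodrop_state):
        g = build_graph(GLYCOLIC)
        with pytest.warns(UserWarning):
            u = mc_dropout_predict(nodrop_state, g, n_samples=10, seed=0)
        assert u.ci_low == u.macro_mean == u.ci_high

    def test_single_sample_collapses(self, drop_state):
        g = build_graph(GLYCOLIC)
        u = mc_dropout_predict(drop_state, g, n_samples=1, seed=3)
        assert u.ci_low == u.macro_mean == u.ci_high

    def test_seeded_reproducibility(self, drop_state):
        g = build_graph(GLYCOLIC)
        a = mc_dropout_predict(drop_state, g, n_samples=50, seed=7)
        b = mc_dropout_predict(drop_state, g, n_samples=50, seed=7)
        assert (a.macro_mean, a.ci_low, a.ci_high) == (b.macro_mean, b.ci_low, b.ci_high)

    def test_interval_orders_and_brackets_mean(self, drop_state):
        g = build_graph(GLYCOLIC)
        u = mc_dropout_predict(drop_state, g, n_samples=100, seed=1, keep_samples=True)
        assert u.ci_low <= u.macro_mean <= u.ci_high
        assert u.ci_low < u.ci_high  # dropout active: genuine spread
        assert u.n_samples == len(u.samples) == 100

    def test_interval_from_empirical_percentiles(self, drop_state):
        g = build_graph(GLYCOLIC)
        u = mc_dropout_predict(drop_state, g, n_samples=200, seed=5, keep_samples=True)
        assert u.ci_low == pytest.approx(np.percentile(u.samples, 2.5))
        assert u.ci_high == pytest.approx(np.percentile(u.samples, 97.5))

    def test_no_site_molecule_rejected(self, drop_state):
        with pytest.raises(NoSiteError):
            mc_dropout_predict(drop_state, build_graph("CC"))

    def test_ci_width_grows_with_dropout_rate(self):
        """Stochastic: averaged over 10 seeds per rate."""
        g = build_graph(GLYCOLIC)
        widths = []
        for rate in (0.05, 0.5):
            cfg = ModelConfig(n_layers=2, hidden_dim=12, head_hidden_dims=(8,),
                              dropout_rate=rate, mode="acidic", seed=21)
            st = init_model(cfg)
            w = [mc_dropout_predict(st, g, n_samples=40, seed=s).ci_high
                 - mc_dropout_predict(st, g, n_samples=40, seed=s).ci_low
                 for s in range(10)]
            widths.append(np.mean(w))
        assert widths[1] > widths[0]


@pytest.fixture(scope="module")
def ref_set(nodrop_state):
    s = generate_set(12, "acidic", 0.0, seed=31)
    return s.records


class TestEmbeddingIndex:
    def test_cardinality(self, nodrop_state, ref_set):
        idx = build_embedding_index(nodrop_state, ref_set)
        assert len(idx) == len(ref_set)
        assert idx.embeddings.shape == (len(ref_set), nodrop_state.config.hidden_dim)

    def test_no_site_records_skipped(self, nodrop_state, ref_set, caplog):
        import logging

        bad = MoleculeRecord("nosite", "CC", "CC", acidic_label=1.0)
        with caplog.at_level(logging.WARNING, logger="micropka.uncertainty"):
            idx = build_embedding_index(nodrop_state, list(ref_set) + [bad])
        assert len(idx) == len(ref_set)
        assert any("nosite" in r.message for r in caplog.records)

    def test_serialization_roundtrip_bit_identical(self, nodrop_state, ref_set, tmp_path):
        idx = build_embedding_index(nodrop_state, ref_set)
        p = str(tmp_path / "ref.npz")
        idx.save(p)
        idx2 = EmbeddingIndex.load(p)
        assert np.array_equal(idx.embeddings, idx2.embeddings)
        assert idx.record_ids == idx2.record_ids
        assert idx.model_fingerprint == idx2.model_fingerprint


class TestSimilarMolecules:
    def test_self_match_first_with_zero_distance(self, nodrop_state, ref_set):
        idx = build_embedding_index(nodrop_state, ref_set)
        g = build_graph(ref_set[0].standardized_smiles)
        hits = similar_molecules(idx, nodrop_state, g)
        assert hits and hits[0]["distance"] == 0.0
        assert hits[0]["record_id"] == ref_set[0].record_id

    def test_stale_index_rejected(self, nodrop_state, drop_state, ref_set):
        idx = build_embedding_index(nodrop_state, ref_set)
        g = build_graph(ref_set[0].standardized_smiles)
        with pytest.raises(ValueError, match="stale"):
            similar_molecules(idx, drop_state, g)

    def test_threshold_and_truncation_match_brute_force(self, nodrop_state):
        """1000-entry index: result equals an all-pairs distance scan."""
        from micropka.uncertainty import _dominant_embedding

        g = build_graph(GLYCOLIC)
        _, qvec = _dominant_embedding(nodrop_state, g, "acidic")
        rng = np.random.default_rng(99)
        emb = qvec[None, :] + rng.normal(scale=0.012, size=(1000, qvec.size))
        idx = EmbeddingIndex(
            record_ids=[f"r{i}" for i in range(1000)],
            atom_indices=np.zeros(1000, dtype=np.int64),
            embeddings=emb,
            experimental_pka=rng.uniform(0, 12, 1000),
            mode="acidic",
            model_fingerprint=nodrop_state.fingerprint(),
        )
        hits = similar_molecules(idx, nodrop_state, g)
        d = np.linalg.norm(emb - qvec[None, :], axis=1)
        under = np.where(d < 0.05)[0]
        expected = under[np.argsort(d[under])][:4]
        assert len(under) > 4  # exercise the truncation branch
        assert [h["record_id"] for h in hits] == [f"r{i}" for i in expected]
        assert [h["distance"] for h in hits] == sorted(h["distance"] for h in hits)

    def test_all_far_gives_empty_result(self, nodrop_state):
        g = build_graph(GLYCOLIC)
        from micropka.uncertainty import _dominant_embedding

        _, qvec = _dominant_embedding(nodrop_state, g, "acidic")
        idx = EmbeddingIndex(
            record_ids=["far"],
            atom_indices=np.zeros(1, dtype=np.int64),
            embeddings=qvec[None, :] + 10.0,
            experimental_pka=np.array([5.0]),
            mode="acidic",
            model_fingerprint=nodrop_state.fingerprint(),
        )
        assert similar_molecules(idx, nodrop_state, g) == []


class TestProjection:
    def test_collinear_points_have_zero_second_component(self):
        t = np.linspace(0, 1, 7)[:, None]
        X = t @ np.array([[1.0, 2.0, -1.0]])
        coords, frac = project_embeddings(X)
        assert frac[0] == pytest.approx(1.0)
        assert frac[1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(coords[:, 1], 0.0, atol=1e-9)

    def test_explained_variance_fractions_sum_le_one(self):
        X = np.random.default_rng(3).normal(size=(20, 6))
        _, frac = project_embeddings(X)
        assert 0 < frac.sum() <= 1.0 + 1e-12

    def test_matches_eigendecomposition_oracle(self):
        """5-point toy set vs a spectral decomposition of the covariance."""
        X = np.random.default_rng(11).normal(size=(5, 4))
        coords, frac = project_embeddings(X)
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for j in range(2):
            v = evecs[:, order[j]]
            proj = Xc @ v
            # sign-insensitive comparison against the oracle
            assert min(np.abs(coords[:, j] - proj).max(),
                       np.abs(coords[:, j] + proj).max()) < 1e-9
        np.testing.assert_allclose(frac, evals[order[:2]] / evals.sum(), atol=1e-12)

    def test_sign_convention_deterministic(self):
        X = np.random.default_rng(4).normal(size=(10, 3))
        c1, _ = project_embeddings(X)
        c2, _ = project_embeddings(X.copy())
        np.testing.assert_array_equal(c1, c2)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            project_embeddings(np.ones((5, 3)))
        with pytest.raises(ValueError):
            project_embeddings(np.ones((1, 3)))
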