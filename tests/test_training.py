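"""Splitting, training behavior, metrics and consistency machinery."""

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from micropka.chemgraph import MoleculeRecord, build_graph
from micropka.model import ModelConfig, init_model, predict_micro
from micropka.synthetic import generate_set
from micropka.training import (
    DominantSiteAssignment,
    NoSiteError,
    TrainRunConfig,
    aggregate_runs,
    compute_regression_metrics,
    consistency_rate,
    difference_value,
    dominant_sites,
    max_similarity_bins,
    split_dataset,
    train,
)


def _records(n):
    return [MoleculeRecord(f"r{i}", "C", "C") for i in range(n)]


class TestSplit:
    def test_100_records_70_15_15(self):
        s = split_dataset(_records(100), seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == (70, 15, 15)

    def test_deterministic_membership(self):
        a = split_dataset(_records(50), seed=3)
        b = split_dataset(_records(50), seed=3)
        assert [r.record_id for r in a.train] == [r.record_id for r in b.train]
        assert [r.record_id for r in a.test] == [r.record_id for r in b.test]

    def test_partition_property(self):
        recs = _records(37)
        s = split_dataset(recs, seed=9)
        ids = [r.record_id for r in s.train + s.validation + s.test]
        assert sorted(ids) == sorted(r.record_id for r in recs)

    def test_largest_remainder_rounding(self):
        # 10 records at 70:15:15 -> quotas 7.0/1.5/1.5; the two leftover
        # fractions tie and resolve in subset order: 7/2/1
        s = split_dataset(_records(10), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (7, 2, 1)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_records(10), ratios=(0.5, 0.2, 0.2))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_records(2))


@pytest.fixture(scope="module")
def tiny_synth_split():
    s = generate_set(90, "acidic", 0.1, seed=7)
    from micropka.training import split_dataset

    return s, split_dataset(s.records, seed=1)


class TestTrain:
    def test_beats_mean_baseline(self, tiny_synth_split):
        s, split = tiny_synth_split
        cfg = ModelConfig(n_layers=3, hidden_dim=24, head_hidden_dims=(16,),
                          dropout_rate=0.0, seed=0)
        state = init_model(cfg)
        rc = TrainRunConfig(max_epochs=15, patience=15, seed=0,
                            batch_size=64, learning_rate=5e-3)
        state, hist = train(state, split, rc)
        labels_tr = np.array([r.acidic_label for r in split.train])
        labels_va = np.array([r.acidic_label for r in split.validation])
        baseline = np.mean(np.abs(labels_va - labels_tr.mean()))
        assert min(hist["val_mae"]) < baseline

    def test_zero_learning_rate_constant_loss(self, tiny_synth_split):
        _, split = tiny_synth_split
        cfg = ModelConfig(n_layers=2, hidden_dim=8, head_hidden_dims=(8,),
                          dropout_rate=0.0, seed=0)
        state = init_model(cfg)
        rc = TrainRunConfig(max_epochs=4, patience=10, seed=0,
                            batch_size=10_000, learning_rate=0.0)
        _, hist = train(state, split, rc)
        assert np.ptp(hist["train_loss"]) < 1e-10

    def test_reproducible_loss_history(self, tiny_synth_split):
        _, split = tiny_synth_split
        cfg = ModelConfig(n_layers=2, hidden_dim=8, head_hidden_dims=(8,),
                          dropout_rate=0.1, seed=4)
        rc = TrainRunConfig(max_epochs=3, patience=10, seed=4, batch_size=32)
        _, h1 = train(init_model(cfg), split, rc)
        _, h2 = train(init_model(cfg), split, rc)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_mae"] == h2["val_mae"]

    def test_empty_training_set_raises(self):
        recs = [MoleculeRecord(f"e{i}", "CC", "CC", acidic_label=None) for i in range(5)]
        split = split_dataset(recs, seed=0)
        state = init_model(ModelConfig(n_layers=1, hidden_dim=4))
        with pytest.raises(ValueError):
            train(state, split, TrainRunConfig(max_epochs=1))

    def test_no_site_records_excluded_with_warning(self, caplog):
        import logging

        good = generate_set(6, "acidic", 0.0, seed=2).records
        bad = [MoleculeRecord("nosite", "CC", "CC", acidic_label=3.0)]
        from micropka.training import _prepare
        from micropka.chemgraph import FeatureConfig

        with caplog.at_level(logging.WARNING, logger="micropka.training"):
            prep = _prepare(good + bad, "acidic", FeatureConfig())
        assert len(prep.graphs) == 6
        assert any("nosite" in r.message for r in caplog.records)


class TestMetrics:
    def test_perfect_fit(self):
        r = compute_regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mae, r.rmse, r.r2) == (0.0, 0.0, 1.0)

    def test_hand_computed_constant_truths(self):
        r = compute_regression_metrics([1, 2, 3], [2, 2, 2])
        assert r.mae == pytest.approx(2 / 3)
        assert r.rmse == pytest.approx(np.sqrt(2 / 3))
        assert r.r2 is None and r.r2_undefined

    def test_mean_predictor_r2_zero(self):
        t = np.array([1.0, 2.0, 4.0, 5.0])
        r = compute_regression_metrics(np.full_like(t, t.mean()), t)
        assert r.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=50), rng.normal(size=50)
        r = compute_regression_metrics(p, t)
        assert r.rmse >= r.mae >= 0

    def test_aggregate_runs_mean_std(self):
        reps = [compute_regression_metrics([1, 2], [1, 3]),
                compute_regression_metrics([1, 2], [2, 2])]
        agg = aggregate_runs(reps)
        maes = [r.mae for r in reps]
        assert agg["mae"]["mean"] == pytest.approx(np.mean(maes))
        assert agg["mae"]["std"] == pytest.approx(np.std(maes, ddof=1))


class TestSimilarityBins:
    def _recs(self, smis):
        return [MoleculeRecord(f"m{i}", s, s) for i, s in enumerate(smis)]

    def test_self_similarity_top_bin(self):
        train = self._recs(["CCO", "c1ccccc1", "CC(=O)O"])
        test = self._recs(["CCO"])
        sims, table = max_similarity_bins(test, train)
        assert sims[0] == 1.0
        assert table[-1]["n"] == 1

    def test_disjoint_fingerprints_bottom_bin(self):
        train = self._recs(["c1ccncc1"])
        test = self._recs(["C"])
        sims, table = max_similarity_bins(test, train)
        assert sims[0] == 0.0 and table[0]["n"] == 1

    def test_matches_brute_force_tanimoto(self):
        train = self._recs(["CCO", "CCCO", "c1ccccc1"])
        test = self._recs(["CCCCO", "Cc1ccccc1", "CC(=O)O"])
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        expected = []
        for t in test:
            fp = gen.GetFingerprint(Chem.MolFromSmiles(t.standardized_smiles))
            best = max(
                DataStructs.TanimotoSimilarity(
                    fp, gen.GetFingerprint(Chem.MolFromSmiles(r.standardized_smiles))
                )
                for r in train
            )
            expected.append(best)
        sims, _ = max_similarity_bins(test, train)
        np.testing.assert_allclose(sims, expected, atol=1e-12)

    def test_bin_counts_sum_and_stability_under_reordering(self):
        train = self._recs(["CCO", "CCCO", "c1ccccc1", "CC(=O)O"])
        test = self._recs(["CCCCO", "Cc1ccccc1", "C", "CCN"])
        preds, truths = [1.0, 2.0, 3.0, 4.0], [1.5, 2.0, 2.5, 4.5]
        _, t1 = max_similarity_bins(test, train, predictions=preds, truths=truths)
        _, t2 = max_similarity_bins(test, train[::-1], predictions=preds, truths=truths)
        assert sum(r["n"] for r in t1) == len(test)
        assert [r["n"] for r in t1] == [r["n"] for r in t2]

    def test_empty_train_set_rejected(self):
        with pytest.raises(ValueError):
            max_similarity_bins(self._recs(["C"]), [])


@pytest.fixture(scope="module")
def site_state():
    return init_model(ModelConfig(n_layers=2, hidden_dim=12, head_hidden_dims=(8,),
                                  dropout_rate=0.0, seed=5))


class TestDominantSites:
    def _assign(self, micro, eps=0.1, mode="acidic"):
        extreme = min(micro.values()) if mode == "acidic" else max(micro.values())
        G = frozenset(k for k, v in micro.items() if abs(v - extreme) <= eps)
        return DominantSiteAssignment("m", mode, G, eps, extreme, micro)

    def test_unique_minimum(self, site_state):
        g = build_graph("OCC(=O)O")  # two acidic oxygens, distinct environments
        a = dominant_sites(site_state, g, "acidic", epsilon=1e-9)
        assert a.G <= set(a.site_micro)
        assert a.extreme_value == min(a.site_micro.values())
        for s in a.G:
            assert abs(a.site_micro[s] - a.extreme_value) <= 1e-9

    def test_near_tie_within_epsilon(self):
        a = self._assign({0: 4.00, 1: 4.05}, eps=0.1)
        assert a.G == {0, 1}

    def test_separation_beyond_epsilon(self):
        a = self._assign({0: 4.0, 1: 4.5}, eps=0.1)
        assert a.G == {0}

    def test_no_site_raises(self, site_state):
        with pytest.raises(NoSiteError):
            dominant_sites(site_state, build_graph("CC"), "acidic")

    def test_consistency_rate_counts(self):
        assigns = [self._assign({0: 4.0, 1: 6.0}) for _ in range(10)]
        experts = [0] * 9 + [1]
        rep = consistency_rate(assigns, experts)
        assert rep.consistency_rate == pytest.approx(0.9)
        assert rep.n == 10
        assert len(rep.difference_values) == 1
        assert rep.difference_values[0] == pytest.approx(2.0)

    def test_full_agreement_and_disagreement(self):
        assigns = [self._assign({0: 4.0, 1: 6.0}) for _ in range(5)]
        assert consistency_rate(assigns, [0] * 5).consistency_rate == 1.0
        assert consistency_rate(assigns, [1] * 5).consistency_rate == 0.0

    def test_worst_case_difference_with_multi_site_G(self):
        a = self._assign({0: 4.0, 1: 4.05, 2: 7.0}, eps=0.1)
        rep = consistency_rate([a], [2])
        assert rep.difference_values[0] == pytest.approx(abs(4.0 - 7.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consistency_rate([], [1])

    def test_difference_value_symmetric_and_zero_on_identity(self, site_state):
        g = build_graph("OCC(=O)O")
        from micropka.chemgraph import enumerate_acidic_sites

        sites = sorted(enumerate_acidic_sites(g))
        i, j = sites[0], sites[1]
        dv = difference_value(site_state, g, i, j)
        assert dv == difference_value(site_state, g, j, i) >= 0
        assert difference_value(site_state, g, i, i) == 0.0
        micro = predict_micro(site_state, g)
        assert dv == pytest.approx(abs(micro[i] - micro[j]))

    def test_difference_value_non_site_rejected(self, site_state):
        g = build_graph("OCC(=O)O")
        with pytest.raises(ValueError):
            difference_value(site_state, g, 0, 1)  # atom 1 is a carbon
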