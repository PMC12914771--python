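"""Ensemble MLP regression: splits, weighting, training, Pearson, grid search."""

import itertools

import numpy as np
import pytest

from timpdesign import (
    ARCHITECTURES,
    DEFAULT_GRID,
    HyperParams,
    TrainingExample,
    evaluate,
    grid_search,
    pearson,
    sample_weight,
    split_by_depth,
    train_ensemble,
)
from timpdesign.model import (
    DivergenceError,
    ZeroVarianceError,
    _design_matrices,
    grid_combinations,
    train_member,
)
from timpdesign.variant_space import one_hot_batch


def make_examples(n, seed=0, sig_len=3, alphabet="ACDW"):
    rng = np.random.default_rng(seed)
    sigs = ["".join(rng.choice(list(alphabet), sig_len)) for _ in range(n)]
    return [
        TrainingExample(signature=s, label=float(rng.normal()), weight_raw=int(rng.integers(2, 300)))
        for s in sigs
    ]


class TestSplitByDepth:
    def test_floor_rule_at_published_size(self):
        split = split_by_depth(make_examples(4882))
        assert len(split.test) == 488
        assert len(split.val) == 488
        assert len(split.train) == 3906

    def test_minimum_size(self):
        split = split_by_depth(make_examples(10))
        assert (len(split.test), len(split.val), len(split.train)) == (1, 1, 8)
        with pytest.raises(ValueError):
            split_by_depth(make_examples(9))

    def test_partition_and_depth_ordering(self):
        examples = make_examples(100, seed=3)
        split = split_by_depth(examples)
        recombined = split.test + split.val + split.train
        assert len(recombined) == 100
        assert sorted(map(id, recombined)) == sorted(map(id, examples))
        # read depth dominates: test >= val >= train everywhere
        assert min(e.weight_raw for e in split.test) >= max(e.weight_raw for e in split.val)
        assert min(e.weight_raw for e in split.val) >= max(e.weight_raw for e in split.train)

    def test_deterministic_tie_break(self):
        examples = [
            TrainingExample("AAA", 0.0, 10),
            TrainingExample("CCC", 1.0, 10),
        ] + make_examples(18, seed=4)
        a = split_by_depth(examples)
        b = split_by_depth(list(reversed(examples)))
        assert [e.signature for e in a.test] == [e.signature for e in b.test]
        assert [e.signature for e in a.train] == [e.signature for e in b.train]


class TestSampleWeight:
    @pytest.mark.parametrize("raw, expected", [(128, 7.0), (2, 1.0), (1, 0.0)])
    def test_log2(self, raw, expected):
        assert sample_weight(TrainingExample("AAA", 0.0, raw)) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sample_weight(TrainingExample("AAA", 0.0, 0))


class TestArchitectures:
    def test_parameter_counts_on_140_inputs(self):
        # 140->32->4->1 and 140->8->2->1, weights + biases.
        assert ARCHITECTURES["Lib"].n_parameters(140) == 4649
        assert ARCHITECTURES["Ala"].n_parameters(140) == 1149

    def test_declared_dropout_rates(self):
        lib, ala = ARCHITECTURES["Lib"], ARCHITECTURES["Ala"]
        assert (lib.fcl1_units, lib.dropout1, lib.fcl2_units, lib.dropout2) == (32, 0.20, 4, 0.10)
        assert (ala.fcl1_units, ala.dropout1, ala.fcl2_units, ala.dropout2) == (8, 0.00, 2, 0.30)


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            assert abs(pearson(x, y) - np.corrcoef(x, y)[0, 1]) < 1e-12

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestTrainMember:
    def overfit_task(self, reduced_scheme):
        sigs = ["ACD", "WCD", "AWD", "ACW", "WWD", "WCW", "AWW", "WWW"]
        examples = [TrainingExample(s, float(s.count("W")), 16) for s in sigs]
        hp = HyperParams(batch_size=8, epochs=2000, learning_rate=1e-2, architecture="Lib")
        X, y, w = _design_matrices(examples, reduced_scheme, hp)
        return X, y, w, hp

    def test_overfits_tiny_noiseless_task(self, reduced_scheme):
        X, y, w, hp = self.overfit_task(reduced_scheme)
        net, _curve = train_member(X, y, w, hp, seed=0)
        # Final MSE with dropout off (inference mode), on the training inputs.
        assert float(np.mean((net.predict(X) - y) ** 2)) < 1e-2
        assert np.allclose(net.predict(X), y, atol=0.2)

    def test_same_seed_bitwise_identical(self, reduced_scheme):
        X, y, w, hp = self.overfit_task(reduced_scheme)
        hp = HyperParams(batch_size=4, epochs=20, learning_rate=5e-3)
        a, _ = train_member(X, y, w, hp, seed=5)
        b, _ = train_member(X, y, w, hp, seed=5)
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_different_seed_differs(self, reduced_scheme):
        X, y, w, hp = self.overfit_task(reduced_scheme)
        hp = HyperParams(batch_size=4, epochs=20, learning_rate=5e-3)
        a, _ = train_member(X, y, w, hp, seed=5)
        b, _ = train_member(X, y, w, hp, seed=6)
        assert not np.array_equal(a.predict(X), b.predict(X))

    def test_divergence_detected(self, reduced_scheme):
        X, y, w, hp = self.overfit_task(reduced_scheme)
        bad = HyperParams(batch_size=2, epochs=30, learning_rate=1e18)
        with pytest.raises(DivergenceError):
            train_member(X, y, w, bad, seed=0)

    def test_weighting_pulls_prediction_toward_heavy_example(self, reduced_scheme):
        # Two contradictory labels for the same input: the weighted fit must
        # sit closer to the heavily sampled one.
        examples = [
            TrainingExample("WCD", 1.0, 1024),
            TrainingExample("WCD", -1.0, 2),
        ]
        hp_w = HyperParams(batch_size=2, epochs=300, learning_rate=1e-2,
                           architecture="Ala", sample_weighting="with-weight")
        hp_u = HyperParams(batch_size=2, epochs=300, learning_rate=1e-2,
                           architecture="Ala", sample_weighting="no-weight")
        probe = one_hot_batch(["WCD"], reduced_scheme)
        Xw, yw, ww = _design_matrices(examples, reduced_scheme, hp_w)
        Xu, yu, wu = _design_matrices(examples, reduced_scheme, hp_u)
        net_w, _ = train_member(Xw, yw, ww, hp_w, seed=0)
        net_u, _ = train_member(Xu, yu, wu, hp_u, seed=0)
        # Weighted optimum: (1024*1 + 2*(-1))/1026 via log2 weights (10 vs 1)
        assert net_w.predict(probe)[0] > net_u.predict(probe)[0]


class TestEnsemble:
    def test_degenerate_labels_give_near_zero_predictions(self, reduced_scheme):
        examples = [TrainingExample(s, 0.0, 8) for s in ("ACD", "WCD", "AWD", "ACW")]
        hp = HyperParams(batch_size=4, epochs=100, learning_rate=5e-3)
        model = train_ensemble(examples, hp, reduced_scheme, n_members=10)
        preds = model.predict_signatures(["WWW", "ACD", "DWD"])
        assert np.all(np.abs(preds) < 0.1)

    def test_prediction_is_exact_member_mean(self, small_trained_ensemble, reduced_scheme):
        model, _, _ = small_trained_ensemble
        probe = ["ACD", "WWW", "DCW"]
        X = one_hot_batch(probe, reduced_scheme)
        member_mean = np.mean([m.predict(X) for m in model.members], axis=0)
        assert np.array_equal(model.predict_signatures(probe), member_mean)

    def test_member_seeds_are_consecutive(self, small_trained_ensemble):
        model, _, _ = small_trained_ensemble
        base = model.hyperparams.base_seed
        assert model.member_seeds == [base + i for i in range(len(model.members))]

    def test_empty_prediction(self, small_trained_ensemble):
        model, _, _ = small_trained_ensemble
        assert model.predict_signatures([]).shape == (0,)

    def test_ensemble_mean_varies_less_than_single_members(self, reduced_scheme):
        # Averaging reduces seed-to-seed variance on a noisy synthetic task.
        examples = make_examples(40, seed=9)
        hp = HyperParams(batch_size=8, epochs=30, learning_rate=5e-3, architecture="Ala")
        probe = ["ACD", "WWW"]
        single_preds, ensemble_preds = [], []
        for rep in range(10):
            hp_rep = HyperParams(batch_size=8, epochs=30, learning_rate=5e-3,
                                 architecture="Ala", base_seed=rep * 50)
            model = train_ensemble(examples, hp_rep, reduced_scheme, n_members=5)
            X = one_hot_batch(probe, reduced_scheme)
            single_preds.append(model.members[0].predict(X))
            ensemble_preds.append(model.predict_matrix(X))
        assert np.var(ensemble_preds, axis=0).mean() < np.var(single_preds, axis=0).mean()

    def test_save_load_roundtrip(self, small_trained_ensemble, tmp_path):
        from timpdesign import EnsembleModel

        model, _, _ = small_trained_ensemble
        model.save(tmp_path / "m")
        loaded = EnsembleModel.load(tmp_path / "m")
        probe = ["ACD", "WWW", "DCW"]
        assert np.array_equal(
            loaded.predict_signatures(probe), model.predict_signatures(probe)
        )
        assert loaded.hyperparams == model.hyperparams


class TestGridSearch:
    def test_declared_grid_size(self):
        assert len(grid_combinations(DEFAULT_GRID)) == 6 * 5 * 6 * 2 * 2 == 720

    def test_degenerate_grid_picks_survivor(self, reduced_scheme):
        examples = make_examples(30, seed=2)
        grid = {
            "batch_size": (8,),
            "epochs": (20,),
            "learning_rate": (5e-3, 1e18),
            "architecture": ("Ala",),
            "sample_weighting": ("no-weight",),
        }
        best_hp, _, leaderboard = grid_search(
            examples, reduced_scheme, grid=grid, n_members=2
        )
        assert best_hp.learning_rate == 5e-3
        assert (leaderboard["status"] == "diverged").sum() >= 1

    def test_best_val_is_argmax_and_test_scored_once(self, reduced_scheme):
        examples = make_examples(40, seed=6)
        grid = {
            "batch_size": (8, 16),
            "epochs": (15,),
            "learning_rate": (5e-3,),
            "architecture": ("Ala",),
            "sample_weighting": ("no-weight",),
        }
        best_hp, model, leaderboard = grid_search(
            examples, reduced_scheme, grid=grid, n_members=2
        )
        best_val = leaderboard["val_pearson"].max()
        winner = leaderboard[leaderboard["test_pearson"].notna()]
        assert len(winner) == 1
        assert winner["val_pearson"].iloc[0] == best_val
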