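"""Losses, gradients, the checkpointed training loop, sweep and transfer."""

import numpy as np
import pandas as pd
import pytest

from panelcast import (
    ModelConfig,
    TrainConfig,
    WindowSpec,
    init_model,
    loss_onestep,
    loss_stacked,
    make_onestep,
    train,
)
from panelcast.training import AdamOptimizer, loss_and_grads, standardized_pairs
from panelcast.windowing import WindowDataset

from conftest import make_series


def toy_pairs(n=40, T=2, d=3, seed=0):
    x = np.random.default_rng(seed).standard_normal((n, d))
    ds = make_onestep(x, T)
    return ds


class TestLosses:
    def test_perfect_prediction_zero(self):
        p = np.random.default_rng(0).normal(size=(5, 9))
        assert loss_onestep(p, p) == 0.0
        q = np.random.default_rng(0).normal(size=(4, 3, 9))
        assert loss_stacked(q, q) == 0.0

    def test_unit_vector_residual_oracle(self):
        # single pair off by a unit vector: squared norm 1 over 9 entries
        pred = np.zeros((1, 9))
        target = np.zeros((1, 9))
        pred[0, 0] = 1.0
        assert loss_onestep(pred, target) == pytest.approx(1.0 / 9.0)

    def test_stacked_unit_vector_oracle(self):
        # N=1, T=2, one step off by a unit vector: 1 / (9*2)
        pred = np.zeros((1, 2, 9))
        target = np.zeros((1, 2, 9))
        pred[0, 1, 3] = 1.0
        assert loss_stacked(pred, target, T=2) == pytest.approx(1.0 / 18.0)

    def test_batch_order_invariance(self):
        rng = np.random.default_rng(1)
        pred, target = rng.normal(size=(8, 9)), rng.normal(size=(8, 9))
        perm = rng.permutation(8)
        assert loss_onestep(pred, target) == pytest.approx(
            loss_onestep(pred[perm], target[perm])
        )

    def test_stacked_reduces_to_onestep_at_single_step(self):
        rng = np.random.default_rng(2)
        pred, target = rng.normal(size=(6, 9)), rng.normal(size=(6, 9))
        assert loss_stacked(pred[:, None, :], target[:, None, :], T=1) == pytest.approx(
            loss_onestep(pred, target)
        )

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        pred, target = rng.normal(size=(7, 9)), rng.normal(size=(7, 9))
        manual = sum(np.sum((pred[i] - target[i]) ** 2) / 9 for i in range(7)) / 7
        assert loss_onestep(pred, target) == pytest.approx(manual)
        p3, t3 = rng.normal(size=(4, 3, 9)), rng.normal(size=(4, 3, 9))
        manual3 = sum(
            np.sum((p3[i, t] - t3[i, t]) ** 2) / (9 * 3) for i in range(4) for t in range(3)
        ) / 4
        assert loss_stacked(p3, t3, T=3) == pytest.approx(manual3)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss_onestep(np.zeros((0, 9)), np.zeros((0, 9)))
        with pytest.raises(ValueError):
            loss_stacked(np.zeros((0, 2, 9)), np.zeros((0, 2, 9)))


class TestGradients:
    @pytest.mark.parametrize(
        "seq_out,d_out,head", [(False, 9, ()), (False, 18, ()), (True, 9, (6,))]
    )
    def test_backprop_matches_central_differences(self, seq_out, d_out, head):
        cfg = ModelConfig(
            d_in=5, d_out=d_out, hidden=4, n_cells=2, head_layers=head,
            sequence_output=seq_out, seed=3,
        )
        m = init_model(cfg)
        rng = np.random.default_rng(0)
        B, T = 3, 4
        x = rng.standard_normal((B, T, 5))
        y = rng.standard_normal((B, T, d_out) if seq_out else (B, d_out))
        _, grads = loss_and_grads(m, x, y)

        def total_loss():
            p = m.forward(x)
            return loss_stacked(p, y) if seq_out else loss_onestep(p, y)

        pick = np.random.default_rng(1)
        for name, P in m.params.items():
            for flat in pick.choice(P.size, size=min(6, P.size), replace=False):
                ix = np.unravel_index(flat, P.shape)
                orig = P[ix]
                eps = 1e-6
                P[ix] = orig + eps
                lp = total_loss()
                P[ix] = orig - eps
                lm = total_loss()
                P[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, abs=1e-7)


class TestTrainLoop:
    def small_setup(self, epochs=5, lr=0.001, epsilon=0.01, seed=0):
        ds = toy_pairs(n=60, T=2, d=3)
        train_ds = ds.subset(np.arange(40))
        test_ds = ds.subset(np.arange(40, len(ds)))
        model = init_model(ModelConfig(d_in=3, d_out=3, hidden=8, seed=seed))
        cfg = TrainConfig(batch_size=8, learning_rate=lr, epsilon=epsilon,
                          epochs=epochs, seed=seed)
        return model, train_ds, test_ds, cfg

    def test_zero_learning_rate_is_inert(self):
        model, tr, te, cfg = self.small_setup(lr=0.0)
        result = train(model, tr, te, cfg)
        for k in model.params:
            np.testing.assert_array_equal(result.model.params[k], model.params[k])
        assert result.history["train_loss"].nunique() == 1

    def test_seeded_determinism(self):
        a = train(*self.small_setup())
        b = train(*self.small_setup())
        pd.testing.assert_frame_equal(a.history, b.history)
        for k in a.model.params:
            np.testing.assert_array_equal(a.model.params[k], b.model.params[k])

    def test_tolerance_never_reached_warns_not_raises(self, caplog):
        model, tr, te, cfg = self.small_setup(epochs=2, epsilon=1e-9)
        with caplog.at_level("WARNING"):
            result = train(model, tr, te, cfg)
        assert not result.tolerance_reached
        assert result.selected_epoch is None
        assert result.epochs_to_tolerance is None

    def test_checkpoint_has_minimal_test_loss(self):
        # loose tolerance so every epoch checkpoints
        model, tr, te, cfg = self.small_setup(epochs=15, epsilon=1e3)
        result = train(model, tr, te, cfg)
        evaluated = result.history["test_loss"].dropna()
        assert result.checkpoints_evaluated == len(evaluated)
        from panelcast.training import dataset_loss

        assert dataset_loss(result.model, te) == pytest.approx(evaluated.min())
        assert result.selected_epoch == int(
            result.history.loc[evaluated.idxmin(), "epoch"]
        )

    def test_test_set_contributes_no_gradients(self):
        # swapping the test targets must not change the training trajectory
        model, tr, te, cfg = self.small_setup(epochs=6)
        te_other = WindowDataset(
            inputs=te.inputs.copy(),
            targets=te.targets + 42.0,
            spec=te.spec,
            origin_offsets=te.origin_offsets,
        )
        a = train(model, tr, te, cfg)
        b = train(model, tr, te_other, cfg)
        pd.testing.assert_series_equal(a.history["train_loss"], b.history["train_loss"])

    def test_batch_size_larger_than_dataset_rejected(self):
        model, tr, te, cfg = self.small_setup()
        with pytest.raises(ValueError):
            train(model, tr.subset(np.arange(4)), te, cfg)


class TestSweepAndTransfer:
    def make_split(self, seed=0, n=80):
        # smooth multi-sine series: easy to forecast, so short training
        # budgets reach the loss tolerance and the tests stay fast
        from panelcast import sequential_split

        rng = np.random.default_rng(seed)
        t = np.arange(n)[:, None]
        freq = rng.uniform(0.05, 0.15, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        vals = np.sin(2 * np.pi * freq * t + phase) * np.array([5.0, 2.0, 1.0])
        vals += np.array([50.0, 100.0, 20.0])
        return sequential_split(make_series(vals))

    def test_single_T_sweep_schema_and_selection(self):
        from panelcast import sweep_time_step

        split = self.make_split()
        cfg = TrainConfig(batch_size=8, epochs=3, epsilon=1e3, seed=1)
        table, selected = sweep_time_step(split, [3], cfg)
        assert selected == 3
        assert list(table["T"]) == [3]
        assert {"rel_l1", "rel_linf"} <= set(table.columns)
        assert table[["rel_l1", "rel_linf"]].notna().all().all()

    def test_sweep_deterministic_under_seed(self):
        from panelcast import sweep_time_step

        split = self.make_split()
        cfg = TrainConfig(batch_size=8, epochs=3, epsilon=1e3, seed=2)
        t1, s1 = sweep_time_step(split, [1, 2], cfg)
        t2, s2 = sweep_time_step(split, [1, 2], cfg)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)

    def test_transfer_preserves_architecture_and_checks_widths(self):
        from panelcast import fit_design, fit_standardizer, transfer

        split = self.make_split(seed=3)
        stats = fit_standardizer(split.train)
        cfg = TrainConfig(batch_size=8, epochs=3, epsilon=1e3, seed=3)
        master = fit_design(split, stats, WindowSpec(T=2), cfg)
        split2 = self.make_split(seed=4)
        result = transfer(master.model, split2, cfg, spec=WindowSpec(T=2))
        assert result.model.config == master.model.config
        # width mismatch rejected
        bad = init_model(ModelConfig(d_in=5, d_out=5, hidden=4, seed=0))
        with pytest.raises(ValueError, match="incompatible"):
            transfer(bad, split2, cfg, spec=WindowSpec(T=2))

    def test_transfer_to_own_series_not_slower(self):
        # retraining on the very series the master saw reaches tolerance at
        # least as fast as the original cold start did
        from panelcast import fit_design, fit_standardizer, transfer

        split = self.make_split(seed=5)
        stats = fit_standardizer(split.train)
        cfg = TrainConfig(batch_size=8, epochs=40, epsilon=0.05, seed=5)
        master = fit_design(split, stats, WindowSpec(T=2), cfg)
        assert master.tolerance_reached
        again = transfer(master.model, split, cfg, spec=WindowSpec(T=2))
        assert again.epochs_to_tolerance is not None
        assert again.epochs_to_tolerance <= master.epochs_to_tolerance
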