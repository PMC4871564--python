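import json

import numpy as np
import pandas as pd
import pytest

from imitatebci.analysis import (
    RegretCurve,
    best_in_hindsight,
    empirical_regret,
    encoding_recovery,
    plateau_trial,
    regret_growth_exponent,
    run_experiment_preset,
    summarize_sessions,
    trial_mse,
    trial_sse,
    trials_to_recover,
)
from imitatebci.closed_loop import TrialRecord, cursor_preset, run_session
from imitatebci.decoder import init_decoder
from imitatebci.effector import Goal
from imitatebci.updates import Dataset, UpdateSpec, ftl_update, surrogate_loss

from conftest import random_dataset


def make_record(decoded, oracle):
    decoded = np.asarray(decoded, float)
    T, D = decoded.shape
    return TrialRecord(
        k=1,
        goal=Goal(kind="cursor_point", positions=np.zeros((1, 3))),
        poses=np.zeros((T, D)),
        velocities=np.zeros((T, D)),
        neural=np.zeros((T, 2)),
        oracle=np.asarray(oracle, float),
        decoded=decoded,
        executed=decoded,
        success=True,
        final_distance=0.0,
    )


class TestTrialLoss:
    def test_perfect_decoder_zero(self):
        rec = make_record(np.ones((4, 3)), np.ones((4, 3)))
        assert trial_sse(rec) == 0.0

    def test_two_steps_sse_and_mse(self):
        rec = make_record([[1.0, 0.0], [1.0, np.sqrt(2)]], [[0.0, 0.0], [0.0, 0.0]])
        assert trial_sse(rec) == pytest.approx(4.0)
        assert trial_mse(rec) == pytest.approx(2.0)

    def test_matches_step_loop(self, rng):
        dec, orc = rng.standard_normal((2, 7, 3))
        rec = make_record(dec, orc)
        loop = sum(float(np.sum((dec[t] - orc[t]) ** 2)) for t in range(7))
        assert trial_sse(rec) == pytest.approx(loop)


class TestBestInHindsight:
    def test_equals_ftl_on_full_data(self, rng):
        ds = random_dataset(rng)
        flat = best_in_hindsight(ds, ridge=0.9)
        ftl = ftl_update(ds, UpdateSpec(rule="ftl", ridge=0.9))
        assert np.allclose(flat.as_weights(), ftl.as_weights())

    def test_beats_history_on_aggregate(self, rng):
        ds = random_dataset(rng)
        flat = best_in_hindsight(ds, ridge=0.0)
        total = surrogate_loss(flat, ds)
        for seed in range(5):
            other = init_decoder(6, 3, np.random.default_rng(seed), scale=0.5)
            assert total <= surrogate_loss(other, ds) + 1e-9

    def test_beats_random_perturbations(self, rng):
        ds = random_dataset(rng, trials=(10,))
        flat = best_in_hindsight(ds, ridge=0.2)
        mask = np.ones(6 + 1 + 3)
        mask[6] = 0.0
        Z, O = ds.regressors(), ds.targets()

        def reg_loss(W):
            return np.sum((Z @ W.T - O) ** 2) + 0.2 * np.sum((W * mask) ** 2)

        base = reg_loss(flat.as_weights())
        W0 = flat.as_weights()
        for _ in range(10_000):
            W = W0 + 1e-2 * rng.standard_normal(W0.shape)
            assert reg_loss(W) >= base


class TestEmpiricalRegret:
    def test_zero_when_history_is_hindsight_optimum(self, rng):
        ds = random_dataset(rng, trials=(6, 6))
        flat = best_in_hindsight(ds, ridge=0.5)
        curve = empirical_regret([flat, flat], ds, ridge=0.5)
        assert np.allclose(curve.regret, 0.0, atol=1e-9)

    def test_three_trial_hand_assembly(self, rng):
        ds = random_dataset(rng, trials=(4, 5, 6))
        hist = [init_decoder(6, 3, np.random.default_rng(s), scale=0.4) for s in range(3)]
        curve = empirical_regret(hist, ds, ridge=0.3)
        flat = best_in_hindsight(ds, ridge=0.3)
        expected = []
        acc = 0.0
        for k in range(3):
            Zk, Ok = ds.trial_arrays(k)
            acc += surrogate_loss(hist[k], (Zk, Ok)) - surrogate_loss(flat, (Zk, Ok))
            expected.append(acc)
        assert np.allclose(curve.regret, expected)
        assert np.allclose(curve.regret, np.cumsum(curve.losses - curve.best_losses))

    def test_history_length_checked(self, rng):
        ds = random_dataset(rng, trials=(4, 5))
        with pytest.raises(ValueError):
            empirical_regret([init_decoder(6, 3, rng)], ds)


class TestRegretGrowthExponent:
    def test_linear_curve(self):
        ks = np.arange(1, 501, dtype=float)
        assert regret_growth_exponent(ks, (50, 500)) == pytest.approx(1.0, abs=0.01)

    def test_sqrt_curve(self):
        ks = np.sqrt(np.arange(1, 501, dtype=float))
        assert regret_growth_exponent(ks, (50, 500)) == pytest.approx(0.5, abs=0.01)

    def test_log_curve_flat(self):
        ks = np.log(np.arange(1, 501, dtype=float) + 1)
        assert regret_growth_exponent(ks, (50, 500)) < 0.3

    def test_nonpositive_regret_rejected(self):
        curve = np.concatenate([[-1.0], np.arange(1, 100, dtype=float)])
        with pytest.raises(ValueError, match="positive"):
            regret_growth_exponent(curve, (1, 50))


class TestEncodingRecovery:
    def test_noiseless_full_excitation_perfect(self, rng):
        N, D = 8, 3
        A = rng.standard_normal((N, D))
        ds = Dataset(N, D)
        O = rng.standard_normal((30, D))
        ds.append_trial(np.zeros((30, D)), np.zeros((30, D)), O @ A.T, O)
        curve = encoding_recovery(ds, A)
        assert np.all(curve.correlations[-1] > 1 - 1e-6)

    def test_underdetermined_prefix_flagged_not_errored(self, rng):
        N, D = 5, 3
        A = rng.standard_normal((N, D))
        ds = Dataset(N, D)
        ds.append_trial(np.zeros((2, D)), np.zeros((2, D)), rng.standard_normal((2, N)), rng.standard_normal((2, D)))
        curve = encoding_recovery(ds, A)
        assert np.all(np.isnan(curve.correlations[0]))

    def test_correlation_invariant_to_column_rescaling(self, rng):
        # Pearson correlation ignores positive rescaling of estimated columns
        N, D = 8, 3
        A = rng.standard_normal((N, D))
        ds = Dataset(N, D)
        O = rng.standard_normal((40, D))
        noise = 0.1 * rng.standard_normal((40, N))
        ds.append_trial(np.zeros((40, D)), np.zeros((40, D)), O @ A.T + noise, O)
        c1 = encoding_recovery(ds, A).correlations[-1]
        c2 = encoding_recovery(ds, 2.5 * A).correlations[-1]
        assert np.allclose(c1, c2, atol=1e-10)

    def test_matches_dense_normal_equations(self, rng):
        N, D = 6, 3
        A = rng.standard_normal((N, D))
        ds = Dataset(N, D)
        O = rng.standard_normal((20, D))
        Nmat = O @ A.T + 0.2 * rng.standard_normal((20, N))
        ds.append_trial(np.zeros((20, D)), np.zeros((20, D)), Nmat, O)
        ridge = 1e-8
        A_hat = np.linalg.solve(O.T @ O + ridge * np.eye(D), O.T @ Nmat).T
        curve = encoding_recovery(ds, A, ridge=ridge)
        expected = [np.corrcoef(A_hat[:, d], A[:, d])[0, 1] for d in range(D)]
        assert np.allclose(curve.correlations[-1], expected)

    def test_trials_to_recover_past_end_when_never(self):
        curve_corr = np.full((5, 2), 0.5)
        from imitatebci.analysis import RecoveryCurve

        assert trials_to_recover(RecoveryCurve(curve_corr), 0) == 6


class TestPlateauTrial:
    def test_step_curve(self):
        curve = np.concatenate([np.full(5, 100.0), np.full(95, 1.0)])
        assert plateau_trial(curve) == 6

    def test_already_flat(self):
        assert plateau_trial(np.ones(100)) == 1

    def test_dip_below_reference_is_inside_band(self):
        curve = np.concatenate([np.full(3, 50.0), np.full(97, 1.0)])
        curve[10] = 0.2  # favourable dip must not delay the plateau
        assert plateau_trial(curve) == 4


class TestExperimentPresets:
    def test_unknown_preset_lists_options(self, tmp_path):
        with pytest.raises(ValueError, match="cursor_compare"):
            run_experiment_preset("nope", tmp_path)

    def test_cursor_smoke_emits_three_algorithms(self, tmp_path):
        out = run_experiment_preset("cursor_compare", tmp_path, repeats=2, reaches=8, seed=1)
        df = pd.read_csv(out / "summary.csv")
        assert set(df["algorithm"]) == {"ftl", "ogd", "ma"}
        assert df["trial"].max() == 8
        curves = pd.read_csv(out / "curves.csv")
        assert {"mean", "lo", "hi"} <= set(curves.columns)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["preset"] == "cursor_compare"

    def test_arc_at_zero_matches_plain_ftl_bitwise(self, tmp_path):
        # neutral mismatch is the identity: shared seeds give identical runs
        from imitatebci.analysis import run_sessions, summarize_sessions

        spec = UpdateSpec(rule="ftl", K=10)
        base = run_sessions(cursor_preset(K=10, update=spec), 2, 3)
        from imitatebci.oracle import MismatchSpec

        arc0 = run_sessions(
            cursor_preset(K=10, update=spec, mismatch=MismatchSpec(kind="arc", phi_max=0.0)), 2, 3
        )
        for a, b in zip(base, arc0):
            assert np.array_equal(a.final_params.as_weights(), b.final_params.as_weights())


class TestHindsightCompetitiveness:
    def test_ftl_and_tuned_ogd_track_best_in_hindsight(self):
        """At the end of training, the per-trial surrogate loss of the FTL and
        tuned-OGD decoders (mean over repeats, final 20% of trials) stays
        within twice the loss of the best decoder in hindsight."""
        from imitatebci.analysis import run_sessions

        for rule in ("ftl", "ogd"):
            runs = run_sessions(cursor_preset(update=UpdateSpec(rule=rule, K=100)), 6, 7)
            ratios = []
            for res in runs:
                curve = empirical_regret(res.params_history, res.dataset, ridge=10.0)
                ratios.append(curve.losses[80:].sum() / curve.best_losses[80:].sum())
            assert np.mean(ratios) <= 2.0


def test_summarize_sessions_schema():
    res = run_session(cursor_preset(K=3, seed=1))
    df = summarize_sessions([res], algorithm="ftl")
    assert list(df.columns) == ["repeat", "trial", "sse", "mse", "T_k", "success", "algorithm"]
    assert len(df) == 3
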