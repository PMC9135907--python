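"""Elastic-net clock fitting, prediction contracts and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from panclock.clock import (
    ClockModel,
    ClockSpec,
    evaluate_transfer,
    fit_elastic_net,
    lambda_grid,
    longitudinal_ordering,
    loocv,
    predict_age,
    train_clock,
)
from panclock.datamodel import BetaMatrix, SampleSheet, ValidationError
from panclock.simulate import SimConfig, simulate
from panclock.transforms import TransformSpec

from conftest import random_design
from oracles import enet_coordinate_descent, enet_objective


def _identity_spec(**kw):
    return ClockSpec(transform=TransformSpec("identity"), **kw)


class TestFitElasticNet:
    def test_zero_penalty_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X, y = random_design(rng, 10, 3)
        model = fit_elastic_net(X, y, _identity_spec(), lam=0.0)
        A = np.column_stack([np.ones(10), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        coef = np.array([model.coef.get(c, 0.0) for c in X.columns])
        np.testing.assert_allclose(coef, ols[1:], atol=1e-6)
        assert model.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_above_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(1)
        X, y = random_design(rng, 20, 8)
        Xs = (X.to_numpy() - X.to_numpy().mean(0)) / X.to_numpy().std(0)
        lam_max = lambda_grid(Xs, y, 0.5, 2, 0.5)[0]
        model = fit_elastic_net(X, y, _identity_spec(), lam=lam_max * 1.01)
        assert model.coef == {}
        assert model.intercept == pytest.approx(y.mean(), abs=1e-8)

    def test_objective_matches_coordinate_descent_oracle(self):
        # the dual-route check: library-backed fit vs a from-scratch
        # coordinate-descent solver, compared on the standardized objective
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(12, 41))
            p = int(rng.integers(3, 31))
            X, y = random_design(rng, n, p)
            lam = float(10 ** rng.uniform(-3, 0))
            model = fit_elastic_net(X, y, _identity_spec(), lam=lam, tol=1e-12)
            arr = X.to_numpy()
            keep = arr.std(0) > 0
            mu, sd = arr[:, keep].mean(0), arr[:, keep].std(0)
            Xs = (arr[:, keep] - mu) / sd
            yc = y - y.mean()
            b_impl = np.array([model.coef.get(c, 0.0) for c in X.columns[keep]]) * sd
            _, b_oracle = enet_coordinate_descent(Xs, y, lam, 0.5)
            obj_impl = enet_objective(Xs, yc, 0.0, b_impl, lam, 0.5)
            obj_oracle = enet_objective(Xs, yc, 0.0, b_oracle, lam, 0.5)
            worst = max(worst, abs(obj_impl - obj_oracle))
        assert worst < 1e-8

    def test_constant_target_rejected(self):
        rng = np.random.default_rng(3)
        X, _ = random_design(rng, 12, 4)
        with pytest.raises(ValidationError, match="constant"):
            fit_elastic_net(X, np.full(12, 5.0), _identity_spec())

    def test_fewer_samples_than_folds_rejected(self):
        rng = np.random.default_rng(4)
        X, y = random_design(rng, 8, 4)
        with pytest.raises(ValidationError, match="folds"):
            fit_elastic_net(X, y, _identity_spec())

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(5)
        X, y = random_design(rng, 12, 4)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_elastic_net(X, y, _identity_spec(), lam=0.1)


def _as_bm(X: pd.DataFrame) -> BetaMatrix:
    bm = X.T.copy()
    bm.columns = [f"s{i:03d}" for i in range(bm.shape[1])]
    return BetaMatrix(bm)


def _sheet_for(bm: BetaMatrix, ages) -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": list(bm.sample_ids), "species": "vervet",
        "tissue": "blood", "sex": "F", "age": ages,
    }))


class TestPredict:
    def test_zero_coefficient_model_predicts_untransformed_intercept(self, tiny):
        model = ClockModel(intercept=7.5, coef={}, transform=TransformSpec("identity"))
        pred = predict_age(model, tiny.beta, tiny.sheet)
        assert (pred == 7.5).all()

    def test_missing_model_probes_error(self, tiny):
        model = ClockModel(intercept=0.0, coef={"not_a_probe": 1.0},
                           transform=TransformSpec("identity"))
        with pytest.raises(ValidationError, match="not_a_probe"):
            predict_age(model, tiny.beta, tiny.sheet)

    def test_prediction_depends_only_on_model_probes(self, tiny):
        model = ClockModel(intercept=1.0, coef={"cg000000": 4.0},
                           transform=TransformSpec("identity"))
        perturbed = tiny.beta.values.copy()
        perturbed.loc["cg000010"] = 0.5  # not a model probe
        pred_a = predict_age(model, tiny.beta, tiny.sheet)
        pred_b = predict_age(model, BetaMatrix(perturbed), tiny.sheet)
        pd.testing.assert_series_equal(pred_a, pred_b)

    def test_invariant_to_probe_and_sample_order(self, tiny):
        spec = _identity_spec(seed=1)
        model = train_clock(tiny.beta, tiny.sheet, spec)
        pred = predict_age(model, tiny.beta, tiny.sheet)
        shuffled = BetaMatrix(tiny.beta.values.iloc[::-1, ::-1])
        pred_shuffled = predict_age(model, shuffled, tiny.sheet)
        pd.testing.assert_series_equal(pred, pred_shuffled)

    def test_noise_free_training_fit_is_perfect(self):
        cfg = SimConfig(n_samples_per_tissue=40, tissues=("blood",), n_probes=300,
                        n_age_probes_shared=60, n_age_probes_per_tissue=0,
                        noise_sd=0.0, animal_sd=0.0, seed=11)
        bm, sheet, _, _ = simulate(cfg)
        model = train_clock(bm, sheet, _identity_spec(seed=1))
        ev = evaluate_transfer(model, bm, sheet)
        assert ev.r > 0.999


class TestLoocv:
    def test_exactly_n_refits_each_on_n_minus_1(self, monkeypatch):
        rng = np.random.default_rng(6)
        X, y = random_design(rng, 10, 5)
        bm = _as_bm(X)
        sheet = _sheet_for(bm, np.linspace(1, 20, 10))
        calls = []
        import panclock.clock as clock_mod
        original = clock_mod.fit_elastic_net

        def spy(X, y, spec, **kw):
            calls.append(X.shape[0])
            return original(X, y, spec, **kw)

        monkeypatch.setattr(clock_mod, "fit_elastic_net", spy)
        spec = _identity_spec(n_folds_internal=5, seed=0)
        loocv(bm, sheet, spec)
        assert calls == [9] * 10

    def test_too_few_samples_rejected(self, tiny):
        few = tiny.sheet.subset(list(tiny.sheet.sample_ids[:5]))
        with pytest.raises(ValidationError, match=">= 10"):
            loocv(tiny.beta, few, _identity_spec())

    def test_recovers_planted_signal_on_tiny_fixture(self, tiny):
        ev = loocv(tiny.beta, tiny.sheet, _identity_spec(seed=0))
        assert ev.r > 0.9
        age_range = np.ptp(tiny.sheet.ages)
        assert ev.mae < 0.1 * age_range


class TestTransferAndLongitudinal:
    def test_transfer_on_training_scope_matches_resubstitution(self, tiny):
        spec = _identity_spec(seed=2)
        model = train_clock(tiny.beta, tiny.sheet, spec)
        ev1 = evaluate_transfer(model, tiny.beta, tiny.sheet)
        ev2 = evaluate_transfer(model, tiny.beta, tiny.sheet)
        assert ev1.r == ev2.r and ev1.mae == ev2.mae

    def test_group_metrics_only_for_groups_of_three_plus(self, tiny):
        spec = _identity_spec(seed=2)
        model = train_clock(tiny.beta, tiny.sheet, spec)
        ev = evaluate_transfer(model, tiny.beta, tiny.sheet)
        assert (ev.by_tissue["n"] >= 3).all()

    def test_longitudinal_pairs_ordered_and_sign_flip_reverses(self):
        from panclock.simulate import make_fixture

        bundle = make_fixture("longitudinal")
        spec = _identity_spec(seed=0)
        model = train_clock(bundle.beta, bundle.sheet, spec)
        verdicts = longitudinal_ordering(model, bundle.beta, bundle.sheet)
        assert len(verdicts) == 14
        assert verdicts["correct"].all()
        # negating the clock's weights must reverse every verdict
        anti = ClockModel(intercept=model.intercept,
                          coef={p: -w for p, w in model.coef.items()},
                          transform=model.transform)
        anti_verdicts = longitudinal_ordering(anti, bundle.beta, bundle.sheet)
        assert not anti_verdicts["correct"].any()

    def test_zero_gap_pair_skipped_with_warning(self, tiny):
        sheet_df = tiny.sheet.df.copy()
        sheet_df.loc[0, "replicate_group"] = "dup"
        sheet_df.loc[1, "replicate_group"] = "dup"
        sheet_df.loc[1, "age"] = sheet_df.loc[0, "age"]
        sheet = SampleSheet(sheet_df)
        model = ClockModel(intercept=1.0, coef={}, transform=TransformSpec("identity"))
        with pytest.warns(UserWarning, match="zero age gap"):
            verdicts = longitudinal_ordering(model, tiny.beta, sheet)
        assert len(verdicts) == 0
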