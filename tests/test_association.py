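import datetime

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from psycourse.association import (
    SeparationError,
    build_covariates,
    compare_group_pgs,
    fit_binary_endpoint,
    fit_burden_model,
    fit_progression_cox,
    pgs_strata,
    standardize_pgs,
)


class TestStandardize:
    def test_population_sd_convention(self):
        out = standardize_pgs([1.0, 2.0, 3.0])
        assert out == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_idempotent_and_location_invariant(self):
        z = standardize_pgs(np.arange(7.0))
        assert standardize_pgs(z) == pytest.approx(z)
        assert standardize_pgs(np.arange(7.0) + 100.0) == pytest.approx(z)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize_pgs([2.0, 2.0, 2.0])


def test_pgs_strata_partition():
    z = np.linspace(-2, 2, 100)
    strata = pgs_strata(z)
    # percentile 10 → low, 50 → middle, 90 → high
    assert strata[9] == "low" and strata[49] == "middle" and strata[90] == "high"
    counts = pd.Series(strata).value_counts()
    assert counts["low"] == 20 and counts["middle"] == 60 and counts["high"] == 20
    assert set(strata) == {"low", "middle", "high"}


class TestLinearFit:
    def test_matches_normal_equations_on_five_rows(self):
        y = pd.Series([1.0, 3.0, 2.0, 5.0, 4.0])
        x = pd.Series([0.1, 0.9, 0.4, 1.2, 0.8])
        c = pd.DataFrame({"c1": [1.0, 0.0, 1.0, 0.0, 1.0]})
        res = fit_burden_model(y, x, c)
        X = np.column_stack([np.ones(5), x, c["c1"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert res.estimate == pytest.approx(beta[1], abs=1e-8)
        assert res.n == 5 and res.model == "linear" and res.effect is None

    def test_sign_flip_negates_estimate(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=50))
        y = pd.Series(0.3 * x + rng.normal(size=50))
        a = fit_burden_model(y, x)
        b = fit_burden_model(y, -x)
        assert a.estimate == pytest.approx(-b.estimate)
        assert a.p == pytest.approx(b.p)

    def test_rank_deficiency_reported_with_column(self):
        y = pd.Series(np.arange(6.0))
        x = pd.Series(np.arange(6.0) * 2)
        c = pd.DataFrame({"dup": np.arange(6.0) * 3})
        with pytest.raises(ValueError, match="dup"):
            fit_burden_model(y, x, c)


class TestLogisticFit:
    def test_collapsed_two_by_two_equals_cross_product_ratio(self):
        # 2x2 table: exposed cases 30, exposed controls 10, unexposed 20/40
        rows = [(1, 1)] * 30 + [(1, 0)] * 10 + [(0, 1)] * 20 + [(0, 0)] * 40
        x = pd.Series([r[0] for r in rows], dtype=float)
        y = pd.Series([r[1] for r in rows], dtype=float)
        res = fit_binary_endpoint(y, x)
        assert res.effect == pytest.approx((30 * 40) / (10 * 20), rel=1e-6)

    def test_matches_maximum_likelihood_oracle_on_ten_rows(self):
        y = pd.Series([0, 0, 1, 0, 1, 1, 0, 1, 1, 0], dtype=float)
        x = pd.Series([-1.2, -0.8, 0.3, -0.5, 1.1, 0.9, 0.2, 1.4, -0.1, -1.0])

        def nll(b):
            eta = b[0] + b[1] * x.to_numpy()
            return float(np.sum(np.log1p(np.exp(eta)) - y.to_numpy() * eta))

        oracle = minimize(nll, [0.0, 0.0], method="BFGS", tol=1e-12).x
        res = fit_binary_endpoint(y, x)
        assert res.estimate == pytest.approx(oracle[1], abs=1e-6)

    def test_null_predictor_gives_or_near_one(self):
        rng = np.random.default_rng(11)
        y = pd.Series((rng.random(2000) < 0.3).astype(float))
        x = pd.Series(rng.normal(size=2000))
        res = fit_binary_endpoint(y, x)
        assert res.effect == pytest.approx(1.0, abs=0.15)
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_perfect_separation_raises(self):
        x = pd.Series(np.arange(10.0))
        y = pd.Series((x > 4.5).astype(float))
        with pytest.raises((SeparationError, Exception)):
            fit_binary_endpoint(y, x)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_binary_endpoint(pd.Series([1.0] * 5), pd.Series(np.arange(5.0)))


class TestCoxFit:
    def test_matches_partial_likelihood_grid_oracle(self):
        # four subjects, distinct event/censor times → Efron == exact
        T = pd.Series([2.0, 5.0, 8.0, 11.0])
        E = pd.Series([1, 1, 0, 1])
        x = pd.Series([0.5, -0.2, 0.9, -1.1])

        def neg_pl(b):
            risk = np.exp(b * x.to_numpy())
            order = np.argsort(T.to_numpy())
            ll = 0.0
            for i in order:
                if E[i]:
                    at_risk = T.to_numpy() >= T[i]
                    ll += b * x[i] - np.log(risk[at_risk].sum())
            return -ll

        oracle = minimize_scalar(neg_pl, bounds=(-4, 4), method="bounded",
                                 options={"xatol": 1e-10}).x
        res = fit_progression_cox(T, E, x)
        assert res.estimate == pytest.approx(oracle, abs=1e-5)
        assert res.model == "cox" and res.effect == pytest.approx(np.exp(oracle), abs=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            fit_progression_cox(
                pd.Series([1.0, 2.0]), pd.Series([0, 0]), pd.Series([0.1, -0.1])
            )


class TestGroupContrast:
    def test_covariate_free_equals_difference_of_means(self):
        z = pd.Series(
            [0.1, 0.5, 0.3, -0.2, -0.6, -0.1],
            index=[f"p{i}" for i in range(6)],
        )
        a_ids, b_ids = z.index[:3], z.index[3:]
        res = compare_group_pgs(a_ids, b_ids, z)
        assert res.estimate == pytest.approx(z[b_ids].mean() - z[a_ids].mean(), abs=1e-10)

    def test_identical_distributions_give_near_zero(self):
        rng = np.random.default_rng(3)
        z = pd.Series(rng.normal(size=400), index=[f"p{i}" for i in range(400)])
        res = compare_group_pgs(z.index[:200], z.index[200:], z)
        assert abs(res.estimate) < 3 * (res.ci95[1] - res.estimate) / 1.96

    def test_overlapping_groups_rejected(self):
        z = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        with pytest.raises(ValueError, match="overlap"):
            compare_group_pgs(pd.Index(["a", "b"]), pd.Index(["b", "c"]), z)


def test_group_pgs_shift_recovered_from_generator():
    """A −0.10 SD generator-side shift of the progressed group's SZ-PGS is
    recovered by the covariate-adjusted contrast within 3 MC SE."""
    from psycourse.analyses import _frames
    from psycourse.hierarchy import progression_cohort
    from psycourse.simulate import preset_paper_defaults, simulate_cohort

    ests = []
    for r in range(4):
        preset = preset_paper_defaults("progression-logistic-sex", n_persons=8000, seed=300 + r)
        preset = preset.model_copy(update={"progressed_pgs_shift": -0.10})
        bundle, _ = simulate_cohort(preset)
        traj, covs, pgs = _frames(bundle)
        labelled, _ = progression_cohort(traj)
        labelled = labelled.set_index("person_id")
        direct = labelled.index[labelled["progression_group"] == "direct_sz"]
        prog = labelled.index[labelled["progression_group"] == "progressed_to_sz"]
        ests.append(compare_group_pgs(direct, prog, pgs["sz"], covs).estimate)
    mean = np.mean(ests)
    mc_se = np.std(ests, ddof=1) / 2
    assert abs(mean - (-0.10)) < max(3 * mc_se, 0.01)


def test_null_calibration_across_seeds():
    """Zero-effect cohorts: the PGS-burden estimate stays within 3 SE of zero
    in at least 99% of 200 seeded replicates."""
    from psycourse.analyses import burden_pgs_fit
    from psycourse.simulate import preset_paper_defaults, simulate_cohort, zero_effect

    base = zero_effect(preset_paper_defaults("burden-pgs", n_persons=2000))
    hits = 0
    for s in range(200):
        bundle, _ = simulate_cohort(base.model_copy(update={"seed": 1000 + s}))
        res = burden_pgs_fit(bundle)
        se = (res.ci95[1] - res.ci95[0]) / (2 * 1.959964)
        if abs(res.estimate) < 3 * se:
            hits += 1
    assert hits >= 198
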