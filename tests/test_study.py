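"""Tests of the metrics, CV tuning, method dispatch, and study driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from clinms.study import (
    METHODS,
    StudyConfig,
    cbar,
    cv_error,
    fit_method,
    mcr,
    run_study,
    tp_fp,
    tune_by_cv,
)
from clinms.synthetic import Dataset, SimulationConfig, simulate_dataset


class TestMCR:
    def test_identical_vectors_zero(self):
        assert mcr(np.array([0, 1, 1]), np.array([0, 1, 1])) == 0.0

    def test_complemented_vectors_hundred(self):
        assert mcr(np.array([0, 1, 0]), np.array([1, 0, 1])) == 100.0

    def test_one_in_four(self):
        assert mcr(np.array([0, 1, 1, 0]), np.array([0, 1, 1, 1])) == 25.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mcr(np.array([0, 1]), np.array([0, 1, 1]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mcr(np.array([]), np.array([]))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounds_property(self, bits):
        y = np.array(bits)
        rate = mcr(y, 1 - y[::-1] if len(y) > 1 else 1 - y)
        assert 0.0 <= rate <= 100.0


class TestTPFP:
    def test_perfect_selection(self):
        tp, fp = tp_fp(range(20), range(20))
        assert (tp, fp) == (20, 0)

    def test_disjoint_selection(self):
        tp, fp = tp_fp([30, 31, 32], range(20))
        assert (tp, fp) == (0, 3)

    def test_random_sets_match_bruteforce(self, rng):
        selected = rng.choice(500, 30, replace=False)
        active = rng.choice(500, 20, replace=False)
        tp, fp = tp_fp(selected, active)
        tp_naive = sum(1 for j in selected if j in set(active))
        fp_naive = sum(1 for j in selected if j not in set(active))
        assert (tp, fp) == (tp_naive, fp_naive)


class TestCbar:
    def test_eta_in_clinical_span_gives_zero(self, rng):
        Z = rng.standard_normal((40, 4))
        eta = 2.0 + Z @ rng.normal(size=4)
        assert cbar(eta, Z) == pytest.approx(0.0, abs=1e-10)

    def test_eta_orthogonal_to_span_gives_one(self, rng):
        Z = rng.standard_normal((40, 4))
        D = np.column_stack([np.ones(40), Z])
        eta = rng.standard_normal(40)
        Q, _ = np.linalg.qr(D)
        eta -= Q @ (Q.T @ eta)
        assert cbar(eta, Z) == pytest.approx(1.0, abs=1e-10)

    def test_matches_explicit_dense_projection(self, rng):
        Z = rng.standard_normal((50, 5))
        eta = rng.standard_normal(50)
        D = np.column_stack([np.ones(50), Z])
        # oracle: explicit projector from an orthonormal basis, applied densely
        U, s, _ = np.linalg.svd(D, full_matrices=False)
        basis = U[:, s > 1e-12]
        P = basis @ basis.T
        expected = np.linalg.norm((np.eye(50) - P) @ eta) / np.linalg.norm(eta)
        assert cbar(eta, Z) == pytest.approx(expected, abs=1e-10)

    def test_zero_eta_rejected(self, rng):
        with pytest.raises(ValueError, match="zero norm"):
            cbar(np.zeros(10), rng.standard_normal((10, 2)))


def _clinical_dataset(n=150, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, 3))
    X = rng.standard_normal((n, 12))
    eta = Z @ np.array([1.2, -0.8, 1.0]) + 1.5 * X[:, 0]
    y = rng.binomial(1, expit(eta))
    if y.sum() in (0, n):
        y[0] = 1 - y[0]
    return Dataset(X=X, Z=Z, y=y)


class TestTuning:
    def test_single_point_grid_returned_directly(self):
        ds = _clinical_dataset()
        point = {"lam": 100.0, "r": 2}
        assert tune_by_cv("RPLS", ds, grid=[point]) == point

    def test_empty_grid_methods_return_no_params(self):
        ds = _clinical_dataset()
        assert tune_by_cv("Clin", ds) == {}
        assert tune_by_cv("Boost", ds) == {}

    def test_picks_grid_point_with_lower_cv_error(self):
        # one strong feature: keeping a single active variable (large delta,
        # r=1) should beat an extreme near-zero-threshold fit on this data
        ds = _clinical_dataset(seed=3)
        grid = ({"r": 1, "delta": 0.9}, {"r": 5, "delta": 0.05})
        errs = [
            cv_error("SGPLS", ds, dict(g), folds=5, seed=11) for g in grid
        ]
        choice = tune_by_cv("SGPLS", ds, folds=5, seed=11, grid=grid)
        assert choice == dict(grid[int(np.argmin(errs))])
        assert errs[0] != errs[1]  # the comparison is informative

    def test_deterministic_under_seed(self):
        ds = _clinical_dataset(seed=5)
        grid = ({"r": 1, "delta": 0.3}, {"r": 2, "delta": 0.6})
        a = tune_by_cv("SGPLS", ds, seed=9, grid=grid)
        b = tune_by_cv("SGPLS", ds, seed=9, grid=grid)
        assert a == b

    def test_tie_breaks_to_first_grid_point(self):
        ds = _clinical_dataset(seed=7)
        point = {"lam": 120.0, "r": 1}
        # identical grid points tie exactly; the first must win
        choice = tune_by_cv("RPLS", ds, seed=1, grid=(point, dict(point)))
        assert choice == point


class TestFitMethod:
    def test_registry_names(self):
        assert set(METHODS) == {
            "Clin", "Boost", "BoostOffClin", "ClinOffBoost", "SGPLS",
            "SGPLSOffClin", "ClinOffSGPLS", "RPLS", "RPLSOffClin",
            "ClinOffRPLS", "Oracle",
        }

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            fit_method("Lasso", _clinical_dataset())

    def test_oracle_requires_ground_truth(self):
        ds = _clinical_dataset()
        with pytest.raises(ValueError, match="ground-truth"):
            fit_method("Oracle", ds)

    def test_boostoffclin_with_zero_clinical_equals_boost(self):
        # balanced y + all-zero Z: the clinical predictor is identically 0,
        # so offset boosting must coincide with plain boosting
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 10))
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        ds = Dataset(X=X, Z=np.zeros((60, 2)), y=y)
        opts = {"nu": 0.1, "h_max": 50}
        plain = fit_method("Boost", ds, boost_opts=opts)
        offc = fit_method("BoostOffClin", ds, boost_opts=opts)
        Xn = rng.standard_normal((15, 10))
        assert np.allclose(
            plain.predict_proba(Xn),
            offc.predict_proba(Xn, np.zeros((15, 2))),
            atol=1e-10,
        )

    def test_clinical_regime_favors_clin_over_boost(self):
        # mu=0: y depends on Z only, so the clinical model should beat
        # feature-only boosting on most replicates
        wins = 0
        reps = 20
        for seed in range(reps):
            ds = simulate_dataset(
                SimulationConfig(n=200, p=100, mu=0.0, seed=300 + seed)
            )
            from clinms.synthetic import make_split

            plan = make_split(200, 0.8, seed=seed)
            tr, te = ds.subset(plan.train_indices), ds.subset(plan.test_indices)
            opts = {"nu": 0.1, "h_max": 300}
            clin = fit_method("Clin", tr)
            boost = fit_method("Boost", tr, boost_opts=opts)
            m_clin = mcr(clin.predict(te.X, te.Z), te.y)
            m_boost = mcr(boost.predict(te.X, te.Z), te.y)
            wins += m_clin < m_boost
        assert wins >= 0.8 * reps

    def test_clinoffboost_predicts_from_both_blocks(self):
        ds = _clinical_dataset(seed=11)
        fit = fit_method("ClinOffBoost", ds, boost_opts={"h_max": 50})
        eta = fit.linear_predictor(ds.X, ds.Z)
        assert eta.shape == (ds.n,)
        assert np.all(np.isfinite(eta))


class TestRunStudy:
    def test_bookkeeping_single_replicate(self):
        cfg = StudyConfig(
            n_values=(80,),
            p=30,
            mu_values=(0.5,),
            replicates=1,
            methods=("Clin",),
            seed=1,
        )
        res = run_study(cfg)
        assert len(res.records) == 1
        row = res.records.iloc[0]
        assert row["method"] == "Clin" and row["n"] == 80
        assert 0.0 <= row["mcr"] <= 100.0
        assert res.failures.empty

    def test_aggregate_reproducible_from_records(self):
        cfg = StudyConfig(
            n_values=(60, 100),
            p=25,
            mu_values=(2.0,),
            replicates=4,
            methods=("Clin", "Oracle"),
            seed=2,
        )
        res = run_study(cfg)
        agg = res.aggregate()
        for _, row in agg.iterrows():
            sub = res.records[
                (res.records["method"] == row["method"])
                & (res.records["n"] == row["n"])
            ]["mcr"]
            assert row["mcr_mean"] == pytest.approx(sub.mean())
            assert row["mcr_sd"] == pytest.approx(sub.std())

    def test_selection_and_cbar_recorded(self):
        cfg = StudyConfig(
            n_values=(80,),
            p=30,
            p_star=5,
            mu_values=(2.0,),
            replicates=2,
            methods=("Boost", "BoostOffClin"),
            seed=3,
            boost_h_max=150,
        )
        res = run_study(cfg)
        boost_rows = res.records[res.records["method"] == "Boost"]
        assert boost_rows["tp"].notna().all()
        assert (boost_rows["tp"] <= 5).all()
        comb = res.records[res.records["method"] == "BoostOffClin"]
        assert comb["cbar"].between(0.0, 1.0).all()
        # feature-only methods get no cbar (no clinical block in the model)
        assert boost_rows["cbar"].isna().all()

    def test_deterministic_under_master_seed(self):
        cfg = StudyConfig(
            n_values=(60,),
            p=20,
            mu_values=(0.5,),
            replicates=2,
            methods=("Clin",),
            seed=4,
        )
        a, b = run_study(cfg), run_study(cfg)
        assert a.records["mcr"].tolist() == b.records["mcr"].tolist()
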