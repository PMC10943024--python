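import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pondscape as ps
from pondscape.metrics import TERM_NAMES, SweepConfig, aicc, effect_tables, run_sweep
from pondscape.simulate import Trajectory


def make_traj(intervals, richness, biomass, active, gamma, n_S, mainland=0):
    intervals = np.asarray(intervals, dtype=float)
    return Trajectory(
        horizon=float(intervals[-1, 1]),
        n_S=n_S,
        mainland=mainland,
        intervals=intervals,
        richness=np.asarray(richness),
        site_biomass=np.asarray(biomass, dtype=float),
        active=np.asarray(active, dtype=bool),
        gamma_richness=np.asarray(gamma),
    )


class TestInstantaneous:
    def test_full_occupancy(self):
        present = np.ones((3, 10), dtype=bool)
        active = np.array([True, True, True])
        assert ps.instantaneous_persistence(present, active, 0, "alpha") == 1.0
        assert ps.instantaneous_persistence(present, active, 0, "gamma") == 1.0

    def test_disjoint_halves(self):
        present = np.zeros((3, 10), dtype=bool)
        present[0] = True  # mainland
        present[1, :5] = True
        present[2, 5:] = True
        active = np.ones(3, dtype=bool)
        assert ps.instantaneous_persistence(present, active, 0, "alpha") == 0.5
        assert ps.instantaneous_persistence(present, active, 0, "gamma") == 1.0

    def test_no_active_sites_is_missing(self):
        present = np.zeros((2, 4), dtype=bool)
        present[0] = True
        assert np.isnan(
            ps.instantaneous_persistence(present, np.array([True, False]), 0, "alpha")
        )

    def test_matches_set_oracle_on_random_occupancy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            present = rng.random((6, 12)) < 0.4
            active = rng.random(6) < 0.7
            active[0] = True
            alpha = ps.instantaneous_persistence(present, active, 0, "alpha")
            gamma = ps.instantaneous_persistence(present, active, 0, "gamma")
            sites = [p for p in range(1, 6) if active[p]]
            if sites:
                assert alpha == pytest.approx(
                    np.mean([present[p].sum() / 12 for p in sites])
                )
            union = set()
            for p in range(1, 6):
                union |= set(np.flatnonzero(present[p]))
            assert gamma == pytest.approx(len(union) / 12)

    def test_biomass_cv(self):
        bm = np.array([9.9, 2.0, 2.0, 2.0])
        act = np.ones(4, bool)
        assert ps.instantaneous_biomass(bm, act, 0, "beta") == 0.0
        bm2 = np.array([9.9, 1.0, 3.0])
        assert ps.instantaneous_biomass(bm2, np.ones(3, bool), 0, "beta") == pytest.approx(0.5)
        assert ps.instantaneous_biomass(bm2, np.ones(3, bool), 0, "gamma") == pytest.approx(4.0)

    def test_biomass_cv_missing_cases(self):
        bm = np.array([5.0, 1.0, 1.0])
        act = np.array([True, True, False])
        assert np.isnan(ps.instantaneous_biomass(bm, act, 0, "beta"))  # one site
        zero = np.zeros(3)
        assert np.isnan(ps.instantaneous_biomass(zero, np.ones(3, bool), 0, "beta"))


class TestPowerMean:
    def test_arithmetic_two_intervals(self):
        assert ps.power_mean([2, 4], [3, 3], p=1) == pytest.approx(3.0)

    def test_harmonic_two_intervals(self):
        assert ps.power_mean([2, 4], [3, 3], p=-1) == pytest.approx(8 / 3)

    def test_geometric_limit(self):
        assert ps.power_mean([2, 8], [1, 1], p=0) == pytest.approx(4.0)

    def test_missing_intervals_excluded(self):
        assert ps.power_mean([np.nan, 4, 2], [5, 1, 1], p=1) == pytest.approx(3.0)

    def test_all_missing_is_missing(self):
        assert np.isnan(ps.power_mean([np.nan], [1.0], p=1))

    @settings(derandomize=True, max_examples=40)
    @given(
        c=st.floats(0.01, 100),
        p=st.floats(-3, 3),
        n=st.integers(1, 6),
    )
    def test_constant_series_identity(self, c, p, n):
        w = np.arange(1, n + 1, dtype=float)
        assert ps.power_mean([c] * n, w, p=p) == pytest.approx(c, rel=1e-9)


class TestSummarizeRun:
    def test_three_interval_hand_oracle(self):
        # 2 temporary sites + mainland (site 0); richness and biomass vary
        traj = make_traj(
            intervals=[[0, 1], [1, 2], [2, 4]],
            richness=[[4, 2, 0], [4, 4, 2], [4, 0, 0]],
            biomass=[[9.0, 1.0, 0.0], [9.0, 3.0, 1.0], [9.0, 0.0, 0.0]],
            active=[[True, True, False], [True, True, True], [True, False, False]],
            gamma=[2, 4, 0],
            n_S=4,
        )
        r = ps.summarize_run(traj)
        # alpha: (2/4)*1 + mean(4,2)/4*1 + missing(2) -> (0.5 + 0.75)/2
        assert r.P_alpha == pytest.approx(0.625)
        # gamma: (2/4 + 4/4 + 0*2)/4
        assert r.P_gamma == pytest.approx(0.375)
        assert r.P_beta == pytest.approx(0.375 / 0.625)
        # B_gamma: (1 + 4 + 0*2)/4
        assert r.B_gamma == pytest.approx(1.25)
        # B_beta defined only on [1,2]: sites (3,1), CV = 1/2
        assert r.B_beta == pytest.approx(0.5)

    def test_identity_on_simulated_runs(self, star_setup):
        L, web, dyn = star_setup
        for seed in range(3):
            sched = ps.sample_activation_schedule(L, 0.4, 3, seed=seed)
            traj = ps.simulate_run(L, sched, web, dyn, 400.0, 3.0, seed=seed)
            r = ps.summarize_run(traj)
            if not np.isnan(r.P_beta):
                assert r.P_beta * r.P_alpha == pytest.approx(r.P_gamma, abs=1e-12)


class TestSensitivity:
    def test_referential_values(self):
        assert ps.sensitivity(0.8, 0.6) == pytest.approx(-0.4)
        assert ps.sensitivity(0.3, 0.3) == 0.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            ps.sensitivity(0.1, 0.2, 0.5, 0.5)

    @settings(derandomize=True, max_examples=40)
    @given(
        x_L=st.floats(-5, 5),
        x_H=st.floats(-5, 5),
    )
    def test_linearity_and_sign(self, x_L, x_H):
        s = ps.sensitivity(x_L, x_H)
        assert s == pytest.approx(2 * (x_H - x_L), rel=1e-12, abs=1e-12)
        assert np.sign(s) == np.sign(x_H - x_L)


def synthetic_design(n, seed, noise=0.0, coefs=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "T": rng.uniform(0, 1.2, n),
            "lam": rng.uniform(1 / 3, 1.0, n),
            "ahat": rng.uniform(np.log10(30), np.log10(3000), n),
        }
    )
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    zT, zl, za = z(df["T"]), z(df["lam"]), z(df["ahat"])
    terms = [zT, zl, za, zT * zl, zT * za, zl * za, zT**2, zl**2, za**2]
    coefs = coefs if coefs is not None else np.zeros(9)
    df["S"] = sum(c * t for c, t in zip(coefs, terms)) + rng.normal(0, noise, n)
    return df


class TestEffectSizes:
    def test_noiseless_exact_recovery_and_subset_selection(self):
        coefs = np.array([2.0, -1.0, 0, 0, 0, 0, 0, 0, 0])
        df = synthetic_design(200, seed=0, noise=0.0, coefs=coefs)
        tab = ps.effect_sizes(df)
        np.testing.assert_allclose(tab.coef.values, coefs, atol=1e-10)
        assert tab.best_terms == ("T", "lam")
        assert not tab.full_model_best

    def test_noisy_recovery_within_tolerance(self):
        coefs = np.array([2.0, -1.0, 0, 0, 0.5, 0, 0, 0, 0])
        df = synthetic_design(500, seed=1, noise=0.1, coefs=coefs)
        tab = ps.effect_sizes(df)
        assert np.max(np.abs(tab.coef.values - coefs)) < 0.05

    def test_aicc_matches_hand_formula(self):
        df = synthetic_design(20, seed=2, noise=0.3, coefs=np.array([1.0] + [0.0] * 8))
        tab = ps.effect_sizes(df)
        # recompute AICc for the {T}-only model by hand
        z = (df["T"] - df["T"].mean()) / df["T"].std(ddof=0)
        X = np.column_stack([np.ones(20), z])
        beta, *_ = np.linalg.lstsq(X, df["S"].values, rcond=None)
        rss = float(np.sum((df["S"].values - X @ beta) ** 2))
        k = 2
        expected = 20 * np.log(rss / 20) + 2 * k + 2 * k * (k + 1) / (20 - k - 1)
        row = tab.aicc[tab.aicc["terms"].apply(lambda t: t == ("T",))]
        assert row["aicc"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_row_permutation_invariance(self):
        df = synthetic_design(100, seed=3, noise=0.2, coefs=np.arange(9) / 10)
        tab1 = ps.effect_sizes(df)
        tab2 = ps.effect_sizes(df.sample(frac=1.0, random_state=0))
        np.testing.assert_allclose(tab1.coef.values, tab2.coef.values, atol=1e-10)

    def test_predictor_rescaling_invariance(self):
        df = synthetic_design(100, seed=4, noise=0.2, coefs=np.arange(9) / 10)
        df2 = df.copy()
        df2["T"] = df2["T"] * 37.0  # z-scoring absorbs any positive rescaling
        np.testing.assert_allclose(
            ps.effect_sizes(df).coef.values, ps.effect_sizes(df2).coef.values, atol=1e-10
        )

    def test_rank_deficient_design_rejected(self):
        df = synthetic_design(50, seed=5, noise=0.1, coefs=np.zeros(9))
        df["lam"] = df["T"]  # perfectly collinear mains
        with pytest.raises(np.linalg.LinAlgError):
            ps.effect_sizes(df)

    def test_too_few_rows_rejected(self):
        df = synthetic_design(10, seed=6)
        with pytest.raises(ValueError):
            ps.effect_sizes(df)


@pytest.fixture(scope="module")
def tiny_results():
    cfg = SweepConfig(
        T_values=(0.1, 0.5),
        lam_values=(0.8,),
        a_values=(300.0,),
        replicates=2,
        years=2,
        n_S=8,
        C=0.2,
        n_P=6,
        F=5.0,
        seed=123,
    )
    return cfg, run_sweep(cfg)


class TestSweep:
    def test_shape_and_columns(self, tiny_results):
        cfg, res = tiny_results
        assert len(res) == 2 * 1 * 1 * 2 * len(ps.RESPONSES)
        assert set(res["response"]) == set(ps.RESPONSES)
        # paired identity holds row-wise where defined
        pa = res[res.response == "P_alpha"].set_index(["T", "replicate"])
        pg = res[res.response == "P_gamma"].set_index(["T", "replicate"])
        pb = res[res.response == "P_beta"].set_index(["T", "replicate"])
        for key in pa.index:
            for col in ("x_low", "x_high"):
                if pa.loc[key, col] > 0:
                    assert pb.loc[key, col] * pa.loc[key, col] == pytest.approx(
                        pg.loc[key, col], abs=1e-9
                    )

    def test_sensitivity_consistent_with_endpoints(self, tiny_results):
        _, res = tiny_results
        ok = res.dropna(subset=["S"])
        np.testing.assert_allclose(ok["S"], 2 * (ok["x_high"] - ok["x_low"]), atol=1e-12)

    def test_deterministic_replay(self, tiny_results):
        cfg, res = tiny_results
        res2 = run_sweep(cfg)
        pd.testing.assert_frame_equal(res, res2)


def test_assembly_persistence_bounds():
    p = ps.assembly_persistence(10, 2, 18, 0.1, 1.0, seed=0)
    assert 0.0 <= p <= 1.0
    # failed assembly (impossible topology budget never accepted) gives zero
    assert ps.assembly_persistence(3, 1, 5, 0.0, 1.0, seed=0, max_tries=2) == 0.0
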