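"""Mixed-model engine checks against dense brute-force oracles, classical
limits, and the estimable-function machinery (LSMeans, BLUPs, Type-3,
slices)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

import strawtrack as st
from strawtrack.lmm import (
    MovementLMM,
    VarianceComponents,
    build_design,
    icc,
    neg2_reml,
)

from _oracles import (
    anova_two_way_f,
    dense_gls_beta,
    dense_neg2_reml,
    henderson_blups,
)

THETAS = [
    (15_000.0, 39_000.0, 0.19),
    (0.0, 500.0, 0.0),
    (200.0, 100.0, -0.5),
    (50.0, 300.0, 0.85),
]


class TestIcc:
    def test_printed_variance_components(self):
        val = icc(15_773.0, 38_884.0)
        assert val == pytest.approx(0.2886, abs=5e-4)
        assert round(val, 2) == 0.29

    def test_boundaries(self):
        assert icc(0.0, 123.0) == 0.0
        assert icc(123.0, 1e-12) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hst.floats(0.0, 1e6),
        hst.floats(1e-3, 1e6),
        hst.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, s2p, s2r, c):
        """Multiplying the response by c scales both components by c^2 and
        leaves the ICC unchanged."""
        assert icc(s2p * c**2, s2r * c**2) == pytest.approx(
            icc(s2p, s2r), abs=1e-12
        )

    def test_variance_components_validation(self):
        with pytest.raises(ValueError):
            VarianceComponents(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            VarianceComponents(1.0, 1.0, 1.0)


class TestBuildDesign:
    def test_toy_column_count(self):
        df = pd.DataFrame(
            {
                "pig_id": ["A", "A", "B", "B"] * 2,
                "day": [1, 1, 1, 1, 2, 2, 2, 2],
                "hour": [0, 1, 0, 1, 0, 1, 0, 1],
                "dist_cm_per_h": np.arange(8.0),
            }
        )
        d = build_design(df)
        assert d.rank_X == 4  # 2 x 2 observed cells
        assert d.rank_additive == 3
        assert d.interaction_rank == 1

    def test_row_permutation_invariance(self, tiny_gappy):
        fit1 = MovementLMM(n_starts=1).fit(tiny_gappy)
        shuffled = tiny_gappy.sample(frac=1.0, random_state=5)
        fit2 = MovementLMM(n_starts=1).fit(shuffled)
        assert fit1.reml_value_ == pytest.approx(fit2.reml_value_, abs=1e-8)
        pd.testing.assert_series_equal(fit1.beta_, fit2.beta_, rtol=1e-9)

    def test_empty_cell_reduces_interaction_rank(self, small_hourly):
        d_full = build_design(small_hourly)
        drop = (small_hourly["day"] == 2) & (small_hourly["hour"] == 5)
        d_holed = build_design(small_hourly[~drop])
        assert d_full.interaction_rank - d_holed.interaction_rank == 1

    def test_unknown_values_rejected(self):
        df = pd.DataFrame(
            {"pig_id": ["A", "B"], "day": [1, 1], "hour": [0, 25],
             "dist_cm_per_h": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="hour"):
            build_design(df)


class TestRemlObjective:
    @pytest.mark.parametrize("theta", THETAS)
    def test_matches_dense_oracle(self, tiny_gappy, theta):
        d = build_design(tiny_gappy)
        mine = neg2_reml(VarianceComponents(*theta), d)
        oracle = dense_neg2_reml(tiny_gappy, list(d.cells), *theta)
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_iid_closed_form_limit(self, tiny_gappy):
        """sigma2_pig = 0, rho = 0: REML is the iid-Gaussian closed form."""
        d = build_design(tiny_gappy)
        s2 = 123.4
        mine = neg2_reml(VarianceComponents(0.0, s2, 0.0), d)
        df = tiny_gappy.sort_values(["pig_id", "day", "hour"])
        y = df["dist_cm_per_h"].to_numpy()
        cell_codes = d.ar1.cell
        means = np.bincount(cell_codes, y) / np.bincount(cell_codes)
        rss = float(((y - means[cell_codes]) ** 2).sum())
        n, p = d.n_obs, d.rank_X
        counts = np.bincount(cell_codes)
        closed = (
            (n - p) * np.log(s2)
            + np.sum(np.log(counts))
            + rss / s2
            + (n - p) * np.log(2 * np.pi)
        )
        assert mine == pytest.approx(closed, abs=1e-8)

    def test_pig_relabeling_invariance(self, tiny_gappy):
        relabeled = tiny_gappy.assign(
            pig_id=tiny_gappy["pig_id"].map({"A": "Z9", "B": "A0"})
        )
        d1, d2 = build_design(tiny_gappy), build_design(relabeled)
        vc = VarianceComponents(300.0, 900.0, 0.3)
        assert neg2_reml(vc, d1) == pytest.approx(neg2_reml(vc, d2), abs=1e-8)


class TestFit:
    @pytest.mark.parametrize("theta", THETAS[:2])
    def test_gls_beta_matches_dense_oracle(self, tiny_gappy, theta):
        from strawtrack.reml import ar1_neg2_reml

        d = build_design(tiny_gappy)
        _, aux = ar1_neg2_reml(*theta, d.ar1, want_aux=True)
        oracle = dense_gls_beta(tiny_gappy, list(d.cells), *theta)
        np.testing.assert_allclose(aux["beta"], oracle, atol=1e-6)

    def test_blups_match_henderson_oracle(self, tiny_gappy):
        fit = MovementLMM(n_starts=1).fit(tiny_gappy)
        vc = fit.vc_
        pigs, b_oracle = henderson_blups(
            tiny_gappy, list(fit.design_.cells),
            vc.sigma2_pig, vc.sigma2_res, vc.rho,
        )
        table = fit.blups()
        assert list(table["pig_id"]) == pigs
        np.testing.assert_allclose(table["deviation"], b_oracle, atol=1e-6)

    def test_ols_limit(self, small_hourly):
        """With both rho and the pig variance pinned at zero the GLS fit
        collapses to ordinary least squares (cell means)."""
        fit = MovementLMM(fix_sigma2_pig=0.0, fix_rho=0.0).fit(small_hourly)
        ols = small_hourly.groupby(["day", "hour"])["dist_cm_per_h"].mean()
        np.testing.assert_allclose(fit.beta_.to_numpy(), ols.to_numpy(), atol=1e-8)
        # REML residual variance equals RSS / (n - p)
        resid = small_hourly["dist_cm_per_h"] - ols.loc[
            list(zip(small_hourly["day"], small_hourly["hour"]))
        ].to_numpy()
        s2_hat = float((resid**2).sum()) / (fit.n_obs_ - fit.rank_X_)
        assert fit.vc_.sigma2_res == pytest.approx(s2_hat, rel=1e-5)

    def test_zero_pig_variance_boundary_recovery(self):
        """sigma2_pig = 0 simulations should give near-zero estimated ICC."""
        hits = 0
        for rep in range(10):
            truth = st.default_truth(
                seed=rep, n_days=3, sigma2_pig=0.0, sigma2_res=38_884.0, rho=0.19
            )
            df = st.simulate_hourly(truth, 8, 3, rng=100 + rep)
            fit = MovementLMM(n_starts=1).fit(df)
            hits += fit.icc_ < 0.05
        assert hits >= 9

    def test_rho_unidentifiable_fixed_at_zero(self, caplog):
        df = pd.DataFrame(
            {
                "pig_id": ["A", "A", "B", "B"],
                "day": [1, 2, 1, 2],
                "hour": [3, 4, 5, 6],
                "dist_cm_per_h": [700.0, 800.0, 650.0, 900.0],
            }
        )
        # one observation per pig-day: no information about rho
        df = df.assign(day=[1, 2, 1, 2])
        with caplog.at_level("WARNING"):
            fit = MovementLMM(n_starts=1).fit(df)
        assert fit.vc_.rho == 0.0


class TestLsMeans:
    def test_balanced_equals_arithmetic_cell_means(self, small_hourly):
        fit = MovementLMM(n_starts=1).fit(small_hourly)
        ls = fit.lsmeans("hour")
        arithmetic = small_hourly.groupby("hour")["dist_cm_per_h"].mean()
        np.testing.assert_allclose(
            ls["estimate"], arithmetic.to_numpy(), atol=1e-6
        )
        assert ls["estimable"].all()
        assert ((ls["ci_lo"] <= ls["estimate"]) & (ls["estimate"] <= ls["ci_hi"])).all()

    def test_halving_data_inflates_ses(self, small_hourly):
        full = MovementLMM(n_starts=1).fit(small_hourly)
        half = small_hourly[small_hourly["day"] <= 2]
        reduced = MovementLMM(n_starts=1).fit(half)
        se_full = full.lsmeans("hour")["se"].to_numpy()
        se_half = reduced.lsmeans("hour")["se"].to_numpy()
        assert np.all(se_half > se_full)

    def test_missing_cell_flags_inestimable_level(self, small_hourly):
        drop = (small_hourly["day"] == 1) & (small_hourly["hour"] == 7)
        fit = MovementLMM(n_starts=1).fit(small_hourly[~drop])
        ls = fit.lsmeans("hour")
        row = ls[ls["level"] == 7].iloc[0]
        assert not row["estimable"]
        assert np.isnan(row["estimate"])
        assert ls[ls["level"] != 7]["estimable"].all()


class TestType3AndSlices:
    def test_num_df_on_full_grid(self, small_hourly):
        fit = MovementLMM(n_starts=1).fit(small_hourly)
        t3 = fit.type3().set_index("effect")
        assert t3.loc["hour", "num_df"] == 23
        assert t3.loc["day", "num_df"] == 3
        assert t3.loc["day x hour", "num_df"] == 3 * 23

    def test_containment_den_df(self, small_hourly):
        fit = MovementLMM(n_starts=1).fit(small_hourly)
        # n - (observed cells + pigs - 1 connected component)
        expected = fit.n_obs_ - (fit.rank_X_ + 4 - 1)
        assert fit.den_df_ == expected

    def test_balanced_anova_equivalence(self):
        """At rho = 0 and sigma2_pig = 0, Wald Type-3 F equals the classical
        sums-of-squares two-way ANOVA F on a balanced design."""
        truth = st.default_truth(seed=9, n_days=3, sigma2_pig=0.0,
                                 sigma2_res=5_000.0, rho=0.0)
        df = st.simulate_hourly(truth, 4, 3, rng=31)
        fit = MovementLMM(fix_sigma2_pig=0.0, fix_rho=0.0).fit(df)
        t3 = fit.type3().set_index("effect")
        oracle = anova_two_way_f(df)
        assert t3.loc["day", "F"] == pytest.approx(oracle["day"], rel=1e-6)
        assert t3.loc["hour", "F"] == pytest.approx(oracle["hour"], rel=1e-6)
        assert t3.loc["day x hour", "F"] == pytest.approx(
            oracle["day x hour"], rel=1e-6
        )

    def test_slice_num_df_is_observed_hours_minus_one(self, small_hourly):
        drop = (small_hourly["day"] == 3) & (small_hourly["hour"].isin([2, 3]))
        fit = MovementLMM(n_starts=1).fit(small_hourly[~drop])
        sl = fit.slice_tests().set_index("day")
        assert sl.loc[3, "num_df"] == 21
        assert sl.loc[1, "num_df"] == 23

    def test_strong_diurnal_signal_detected_in_every_slice(self, small_hourly):
        # 4 pigs x 4 days: far less power than the study grid, so the
        # within-day hour differences are required at 0.01, not 1e-4
        fit = MovementLMM(n_starts=1).fit(small_hourly)
        sl = fit.slice_tests()
        assert len(sl) == 4
        assert (sl["p"] < 0.01).all()


class TestBlupContracts:
    def test_full_shrinkage_as_pig_variance_vanishes(self, small_hourly):
        fit = MovementLMM(fix_sigma2_pig=1e-8, n_starts=1).fit(small_hourly)
        assert np.all(np.abs(fit.blups()["deviation"]) < 1e-3)

    def test_sparse_pig_shrinks_more_with_wider_ci(self, paper_truth):
        df = st.simulate_hourly(paper_truth, 6, 4, rng=77)
        # keep only 4 observations for one pig
        sparse_pig = "ET00001"
        keep = (df["pig_id"] != sparse_pig) | (
            (df["day"] == 1) & (df["hour"] < 4)
        )
        fit = MovementLMM(n_starts=1).fit(df[keep])
        b = fit.blups().set_index("pig_id")
        assert b.loc[sparse_pig, "n_obs_pig"] == 4
        widths = b["ci_hi"] - b["ci_lo"]
        assert widths.loc[sparse_pig] == widths.max()
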