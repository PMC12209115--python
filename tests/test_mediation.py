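"""Stacked 1-1-1 mediation: stacking, estimation, Monte-Carlo inference."""

import numpy as np
import pandas as pd
import pytest

from emovar.design import StudyDesign, SyntheticTruth
from emovar.mediation import (
    MediationResult,
    co_moderation,
    fit_1m,
    monte_carlo_indirect,
    stack_for_mediation,
)
from emovar.multilevel import ModelSpec, fit_crosslag
from emovar.preprocess import add_centered, align_lags


def prepared(truth, n=150, missing=0.0):
    tab, _ = gen(truth, n, missing)
    return tab


def gen(truth, n=150, missing=0.0):
    from emovar.synth import gen_index_level

    tab, truth = gen_index_level(
        StudyDesign("s", n, 10, 7, 4, 5, 5, missing_rate=missing), truth
    )
    tab = tab[~tab["missing"]].copy()
    tab = add_centered(tab, ["ed", "erv", "intensity"])
    tab = align_lags(tab, ["ed_w"])
    return tab, truth


def stack(tab):
    return stack_for_mediation(tab, predictor="ed_w_lag", mediator="erv",
                               outcome="intensity", mediator_within="erv_w")


class TestStacking:
    def test_two_rows_per_complete_row_with_exclusive_selectors(self, analysis_table):
        tab, _ = analysis_table
        st = stack(tab)
        n_complete = tab.dropna(subset=["ed_w_lag", "erv", "intensity",
                                        "erv_w"]).shape[0]
        assert len(st) == 2 * n_complete
        assert ((st["s_m"] + st["s_y"]) == 1.0).all()
        assert set(zip(st["s_m"], st["s_y"])) == {(1.0, 0.0), (0.0, 1.0)}
        # response carries mediator on s_m rows, outcome on s_y rows
        assert (st.loc[st.s_m == 1, "z"] == st.loc[st.s_m == 1, "erv"]).all()
        assert (st.loc[st.s_y == 1, "z"]
                == st.loc[st.s_y == 1, "intensity"]).all()

    def test_round_trip_recovers_original(self, analysis_table):
        tab, _ = analysis_table
        st = stack(tab)
        cc = tab.dropna(subset=["ed_w_lag", "erv", "intensity", "erv_w"])
        unstacked = st[st["s_m"] == 1].drop(columns=["z", "s_m", "s_y"])
        pd.testing.assert_frame_equal(
            unstacked.reset_index(drop=True),
            cc.reset_index(drop=True),
        )

    def test_missing_column_rejected(self, analysis_table):
        tab, _ = analysis_table
        with pytest.raises(ValueError, match="missing required column"):
            stack_for_mediation(tab, predictor="nope", mediator="erv",
                                outcome="intensity", mediator_within="erv_w")


class TestFit1M:
    def test_path_recovery_and_indirect_identity(self, analysis_table):
        tab, truth = analysis_table
        med = fit_1m(stack(tab))
        assert med.converged
        assert med.a == pytest.approx(truth.a_true, abs=4 * med.se_a)
        assert med.b == pytest.approx(truth.b_true, abs=4 * med.se_b)
        assert med.cprime == pytest.approx(truth.cprime_true,
                                           abs=4 * med.se_cprime)
        true_cov = truth.rho_ab * truth.sd_a * truth.sd_b
        assert med.sigma_ab == pytest.approx(true_cov,
                                             abs=4 * med.se_sigma_ab)
        # exact identity, not approximation
        assert med.indirect == med.a * med.b + med.sigma_ab

    def test_offsetting_covariance_kills_indirect(self):
        """cov(a_i, b_i) = -a*b makes the indirect effect vanish."""
        a, b = -0.3, 0.4
        sd_a = sd_b = 0.35   # need sd_a*sd_b >= |a*b| for a valid rho
        rho = -a * b / (sd_a * sd_b)
        truth = SyntheticTruth(a_true=a, b_true=b, sd_a=sd_a, sd_b=sd_b,
                               rho_ab=rho, seed=31)
        assert truth.indirect_true == pytest.approx(0.0, abs=1e-12)
        tab, _ = gen(truth, n=300)
        med = fit_1m(stack(tab))
        ci = monte_carlo_indirect(med, seed=3)
        assert med.indirect == pytest.approx(0.0, abs=0.02)
        assert ci.lower < 0 < ci.upper

    def test_b_zero_design(self):
        truth = SyntheticTruth(a_true=-0.3, b_true=0.0, cprime_true=0.2,
                               rho_ab=0.0, seed=37)
        tab, _ = gen(truth, n=200)
        med = fit_1m(stack(tab))
        assert med.cprime == pytest.approx(0.2, abs=4 * med.se_cprime)
        assert abs(med.b) < 4 * med.se_b
        assert med.indirect == pytest.approx(med.sigma_ab + med.a * med.b)

    def test_consistency_with_crosslag_a_path(self, analysis_table):
        """The stacked a-path matches a direct mediator-only fit."""
        tab, _ = analysis_table
        med = fit_1m(stack(tab), random_intercepts=True)
        direct = fit_crosslag(
            tab, ModelSpec(outcome="erv", within=("ed_w_lag",),
                           dataset_effect="none")
        )
        a_direct = direct.params.loc["ed_w_lag"]
        assert med.a == pytest.approx(a_direct["estimate"],
                                      abs=0.25 * a_direct["se"])


class TestMonteCarlo:
    def degenerate(self, a, b, sigma_ab, var=0.0):
        params = pd.DataFrame({"estimate": [a, b]},
                              index=pd.Index(["a", "b"], name="term"))
        return MediationResult(
            a=a, b=b, cprime=0.0, se_a=0.0, se_b=0.0, se_cprime=0.0,
            cov_fe_ab=np.eye(2) * var, sigma_ab=sigma_ab,
            se_sigma_ab=0.0, var_a_re=1.0, var_b_re=1.0,
            indirect=a * b + sigma_ab, params=params,
            cov_re=pd.DataFrame(), n_obs=0, n_persons=0, converged=True,
            sigma_ab_estimable=True,
        )

    def test_all_zero_inputs_give_point_ci(self):
        ci = monte_carlo_indirect(self.degenerate(0, 0, 0), seed=1)
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_exact_offset_gives_zero_ci(self):
        ci = monte_carlo_indirect(self.degenerate(0.5, 0.5, -0.25), seed=1)
        assert ci.point == pytest.approx(0.0, abs=1e-15)
        assert (ci.lower, ci.upper) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_seeded_and_reproducible(self, analysis_table):
        tab, _ = analysis_table
        med = fit_1m(stack(tab))
        c1 = monte_carlo_indirect(med, seed=9)
        c2 = monte_carlo_indirect(med, seed=9)
        c3 = monte_carlo_indirect(med, seed=10)
        assert (c1.lower, c1.upper) == (c2.lower, c2.upper)
        assert (c1.lower, c1.upper) != (c3.lower, c3.upper)

    def test_non_psd_covariance_rejected(self):
        bad = self.degenerate(0.1, 0.1, 0.0)
        bad.cov_fe_ab = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="not positive semidefinite"):
            monte_carlo_indirect(bad, seed=1)

    def test_clipping_counted_under_tight_psd_bound(self):
        res = self.degenerate(0.1, 0.1, 0.0)
        res.se_sigma_ab = 1.0
        res.var_a_re = res.var_b_re = 1e-6
        ci = monte_carlo_indirect(res, n_draws=2000, seed=2)
        assert ci.n_clipped > 1800          # almost every draw hits the bound


class TestCoModeration:
    def test_zero_moderator_reduces_to_fit_1m(self, analysis_table):
        tab, _ = analysis_table
        df = tab.copy()
        df["mod0"] = 0.0
        base = fit_1m(stack(df))
        # constant-zero moderator columns are degenerate: the interaction
        # design is all zero, so estimates must match the unmoderated fit
        st = stack(df)
        mod = co_moderation(st, "mod0")
        assert mod.a == pytest.approx(base.a, abs=1e-8)
        assert mod.b == pytest.approx(base.b, abs=1e-8)

    def test_trait_dependent_a_path_recovered(self):
        truth = SyntheticTruth(a_true=-0.25, a_mod=0.12, sd_a=0.05, seed=41)
        tab, _ = gen(truth, n=250)
        st = stack(tab)
        mod = co_moderation(st, "trait")
        inter = mod.params.loc["mod:a"]
        assert inter["estimate"] == pytest.approx(0.12, abs=4 * inter["se"])
        assert inter["ci95_lower"] > 0
        # b-path interaction is null in this design
        inter_b = mod.params.loc["mod:b"]
        assert abs(inter_b["estimate"]) < 4 * inter_b["se"]
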