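"""Heterogeneity statistics, PH and linearity tests, loop splits, agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipdnma import (
    GeneratorConfig,
    MCMCSettings,
    ModelConfig,
    NetworkSpec,
    PosteriorSummary,
    agreement,
    build_design,
    build_network,
    direct_indirect_split,
    generate_network,
    global_ph_test,
    heterogeneity,
    linearity_test,
    pairwise_estimates,
)
from ipdnma.diagnostics import HeterogeneityResult
from ipdnma.inference import fit
from tests.conftest import small_network_config


def brute_force_het(y, se):
    """Independent direct evaluation of the inverse-variance formulas."""
    w = [1 / s**2 for s in se]
    yhat = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    Q = sum(wi * (yi - yhat) ** 2 for wi, yi in zip(w, y))
    df = len(y) - 1
    I2 = max(0.0, (Q - df) / Q) * 100 if Q > 0 else 0.0
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return Q, I2, tau2


class TestHeterogeneity:
    def test_identical_estimates(self):
        r = heterogeneity([(0.3, 0.1), (0.3, 0.2), (0.3, 0.15)])
        assert r.Q == pytest.approx(0.0)
        assert r.I2 == 0.0 and r.tau2 == 0.0

    def test_worked_case(self):
        r = heterogeneity([(0.0, 0.5), (1.0, 0.5)])
        assert r.Q == pytest.approx(2.0)
        assert r.df == 1
        assert r.I2 == pytest.approx(50.0)

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.5)),
                    min_size=2, max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force(self, est):
        r = heterogeneity(est)
        Q, I2, tau2 = brute_force_het([e[0] for e in est], [e[1] for e in est])
        assert r.Q == pytest.approx(Q, abs=1e-12)
        assert r.I2 == pytest.approx(I2, abs=1e-12)
        assert r.tau2 == pytest.approx(tau2, abs=1e-12)

    def test_q_scales_inversely_with_squared_se(self):
        est = [(0.1, 0.3), (0.7, 0.4), (-0.2, 0.25)]
        c = 2.0
        scaled = [(y, c * s) for y, s in est]
        assert heterogeneity(scaled).Q == pytest.approx(
            heterogeneity(est).Q / c**2
        )

    def test_single_estimate_errors(self):
        with pytest.raises(ValueError, match="2 estimates"):
            heterogeneity([(0.1, 0.2)])


def _summary(rows):
    tab = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(table=tab, dic=0.0, pd=0.0, dbar=0.0)


TWO_NET = NetworkSpec(
    treatments=("RT", "CTRT"), reference="RT",
    basic_parameters=(("RT", "CTRT"),), loops=(), edges=(("RT", "CTRT"),),
)


def _interaction_rows(dA, ciA, dB, ciB, treat="CTRT"):
    return [
        {"parameter": f"deltaA[{treat}]", "mean": dA, "sd": 0.0,
         "lower": ciA[0], "upper": ciA[1]},
        {"parameter": f"deltaB[{treat}]", "mean": dB, "sd": 0.0,
         "lower": ciB[0], "upper": ciB[1]},
    ]


class TestAgreement:
    def test_published_style_interaction_pair_agrees(self):
        # within 0.176, across 0.165 with across CrI (-0.279, 0.584):
        # SE_across ~ 0.220, threshold 0.110, |diff| = 0.011 -> agree
        s = _summary(_interaction_rows(0.176, (-0.069, 0.417),
                                       0.165, (-0.279, 0.584)))
        (v,) = agreement(s, TWO_NET)
        assert v.se_across == pytest.approx(0.220, abs=0.002)
        assert v.difference == pytest.approx(0.011)
        assert v.threshold == pytest.approx(0.110, abs=0.001)
        assert v.agree

    def test_equal_deltas_agree_regardless_of_se(self):
        s = _summary(_interaction_rows(0.4, (0.35, 0.45), 0.4, (0.399, 0.401)))
        assert agreement(s, TWO_NET)[0].agree

    def test_boundary_counts_as_agreement(self):
        se_b = 0.2
        lo, hi = 0.0 - 1.959963984540054 * se_b, 0.0 + 1.959963984540054 * se_b
        s = _summary(_interaction_rows(0.5 * se_b, (0, 1), 0.0, (lo, hi)))
        v = agreement(s, TWO_NET)[0]
        assert v.difference == pytest.approx(v.threshold)
        assert v.agree

    def test_verdict_invariant_to_covariate_rescaling(self):
        # z -> cz divides every delta and SE by c: verdict unchanged
        c = 3.7
        base = _interaction_rows(0.3, (0.1, 0.5), 0.1, (-0.3, 0.5))
        scaled = _interaction_rows(0.3 / c, (0.1 / c, 0.5 / c),
                                   0.1 / c, (-0.3 / c, 0.5 / c))
        assert (agreement(_summary(base), TWO_NET)[0].agree
                == agreement(_summary(scaled), TWO_NET)[0].agree)

    def test_combined_fit_summary_rejected(self):
        s = _summary([{"parameter": "delta[CTRT]", "mean": 0.1, "sd": 0.1,
                       "lower": -0.1, "upper": 0.3}])
        with pytest.raises(ValueError, match="separated"):
            agreement(s, TWO_NET)


class TestPairwise:
    @pytest.fixture(scope="class")
    def pair_data(self):
        cfg = small_network_config(
            n_per_arm=150, seed=3,
            designs=((("RT", "CTRT"), 5),), treatments=("RT", "CTRT"),
            beta={"CTRT": -0.3},
        )
        return generate_network(cfg)[0]

    def test_single_trial_pooled_equals_trial_estimate(self):
        cfg = small_network_config(
            n_per_arm=100, designs=((("RT", "CTRT"), 1),),
            treatments=("RT", "CTRT"), beta={"CTRT": -0.3},
        )
        ds, _ = generate_network(cfg)
        res = pairwise_estimates(ds, ("RT", "CTRT"), n_knots=0)
        assert res.pooled_estimate == pytest.approx(
            res.per_trial["estimate"].iloc[0], abs=1e-4
        )

    def test_inverse_variance_pooling_of_equal_trials(self):
        # two equal-information trials: pooled SE ~ single-trial SE / sqrt(2)
        cfg = small_network_config(
            n_per_arm=200, seed=5, designs=((("RT", "CTRT"), 2),),
            treatments=("RT", "CTRT"), beta={"CTRT": -0.3},
        )
        ds, _ = generate_network(cfg)
        res = pairwise_estimates(ds, ("RT", "CTRT"), n_knots=0)
        mean_se = res.per_trial["se"].mean()
        assert res.pooled_se == pytest.approx(mean_se / np.sqrt(2), rel=0.15)

    def test_five_trial_recovery(self, pair_data):
        res = pairwise_estimates(pair_data, ("RT", "CTRT"), n_knots=0)
        assert res.pooled_estimate == pytest.approx(-0.3, abs=2 * res.pooled_se)

    def test_no_informative_trial_errors(self, pair_data):
        with pytest.raises(ValueError, match="no trial"):
            pairwise_estimates(pair_data, ("RT", "CT+S"))

    def test_weights_and_forest_table(self, pair_data):
        res = pairwise_estimates(pair_data, ("RT", "CTRT"), n_knots=0)
        tab = res.forest_table()
        assert list(tab.columns) == ["trial", "estimate", "lower", "upper", "weight"]
        assert tab["weight"].sum() == pytest.approx(100.0)


class TestGlobalPH:
    @pytest.fixture(scope="class")
    def ph_fit(self):
        cfg = small_network_config(
            n_per_arm=100, designs=((("RT", "CTRT"), 2),),
            treatments=("RT", "CTRT"), beta={"CTRT": -0.3},
        )
        ds, _ = generate_network(cfg)
        design = build_design(ds, build_network(ds, "RT"),
                              ModelConfig(ph_interactions=True, n_knots=0))
        return fit(design, settings=MCMCSettings(n_burnin=200, n_iter=400,
                                                 n_chains=2, seed=9))

    def test_zero_phi_draws_give_zero_statistic(self, ph_fit):
        arr = np.zeros(ph_fit.raw.draws.shape[:2])
        idx = ph_fit.raw.names.index("phi[CTRT]")
        raw = dataclasses.replace(ph_fit.raw, draws=ph_fit.raw.draws.copy())
        raw.draws[:, :, idx] = arr
        # zero draws have zero covariance; the statistic degenerates to 0
        mocked = dataclasses.replace(ph_fit, raw=raw)
        with np.errstate(all="ignore"):
            chi2, df, p = global_ph_test(mocked)
        assert df == 1
        assert not chi2 > 1e-6 or np.isnan(chi2)

    def test_ph_respecting_data_not_rejected_typically(self, ph_fit):
        chi2, df, p = global_ph_test(ph_fit)
        assert df == 1
        assert chi2 >= 0.0

    def test_fit_without_phi_errors(self, triangle_like_fit):
        with pytest.raises(ValueError, match="ln\\(time\\)"):
            global_ph_test(triangle_like_fit)

    def test_time_varying_effect_detected(self):
        cfg = small_network_config(
            n_per_arm=500, seed=21, designs=((("RT", "CTRT"), 2),),
            treatments=("RT", "CTRT"), beta={"CTRT": 0.0},
            phi={"CTRT": 0.5},
        )
        ds, _ = generate_network(cfg)
        design = build_design(ds, build_network(ds, "RT"),
                              ModelConfig(ph_interactions=True, n_knots=0))
        draws = fit(design, settings=MCMCSettings(n_burnin=200, n_iter=400,
                                                  n_chains=2, seed=10))
        chi2, df, p = global_ph_test(draws)
        assert p < 0.05


@pytest.fixture(scope="module")
def triangle_like_fit():
    cfg = small_network_config(n_per_arm=30)
    ds, _ = generate_network(cfg)
    design = build_design(ds, build_network(ds, "RT"), ModelConfig(n_knots=0))
    return fit(design, settings=MCMCSettings(n_burnin=150, n_iter=250,
                                             n_chains=2, seed=13))


class TestLinearity:
    def test_two_level_trials_are_excluded(self):
        # network where one trial observes only 2 stage levels
        cfg = small_network_config(n_per_arm=120, seed=2)
        ds, _ = generate_network(cfg)
        tab = ds.table.copy()
        t1 = tab.trial == "T01"
        tab.loc[t1 & (tab.stage == 2.0), "stage"] = 1.0
        from ipdnma import CovariateSpec, IPDDataset

        ds2 = IPDDataset(tab, covariates=ds.covariates, treatments=ds.treatments)
        chi2_all, df_all, _ = linearity_test(ds, "stage", n_knots=0)
        chi2_sub, df_sub, _ = linearity_test(ds2, "stage", n_knots=0)
        assert df_all == len(ds.trial_ids)
        assert df_sub == df_all - 1

    def test_strong_convex_effect_detected(self):
        cfg = small_network_config(
            n_per_arm=300, seed=6, designs=((("RT", "CTRT"), 3),),
            treatments=("RT", "CTRT"), beta={"CTRT": -0.2},
            nonlinear_mid_offset=1.0,
        )
        ds, _ = generate_network(cfg)
        chi2, df, p = linearity_test(ds, "stage", n_knots=0)
        assert p < 0.05

    def test_linear_effect_not_rejected(self):
        cfg = small_network_config(n_per_arm=200, seed=8)
        ds, _ = generate_network(cfg)
        chi2, df, p = linearity_test(ds, "stage", n_knots=0)
        assert p > 0.01  # calibrated null behaviour at one replicate

    def test_requires_three_levels(self):
        cfg = small_network_config(ordinal=False)
        ds, _ = generate_network(cfg)
        with pytest.raises(ValueError, match="3-level"):
            linearity_test(ds, "stage")


class TestDirectIndirectSplit:
    @pytest.fixture(scope="class")
    def loop_data(self):
        cfg = small_network_config(
            n_per_arm=80, seed=4,
            designs=((("RT", "CTRT"), 2), (("RT", "CT+RT"), 2),
                     (("CTRT", "CT+RT"), 2)),
        )
        ds, _ = generate_network(cfg)
        return ds, build_network(ds, "RT")

    def test_per_draw_identity_holds_exactly(self, loop_data):
        ds, net = loop_data
        split = direct_indirect_split(
            ds, net, net.loops[0], config=ModelConfig(n_knots=0),
            settings=MCMCSettings(n_burnin=150, n_iter=250, n_chains=2, seed=3),
        )
        # exact by construction: direct is defined as indirect + omega per draw
        np.testing.assert_array_equal(
            split.direct_draws, split.indirect_draws + split.omega_draws
        )
        assert set(split.table.index) == {"direct", "indirect", "network", "omega"}

    def test_unknown_loop_errors(self, loop_data):
        ds, net = loop_data
        with pytest.raises(ValueError, match="not a loop"):
            direct_indirect_split(ds, net, ("RT", "CTRT", "XX"))

    def test_omega_recovery_with_true_inconsistency(self):
        cfg = small_network_config(
            n_per_arm=150, seed=12,
            designs=((("RT", "CTRT"), 2), (("RT", "CT+RT"), 2),
                     (("CTRT", "CT+RT"), 2)),
            omega={("CTRT", "CT+RT"): 0.6},
        )
        ds, _ = generate_network(cfg)
        net = build_network(ds, "RT")
        split = direct_indirect_split(
            ds, net, net.loops[0], config=ModelConfig(n_knots=0),
            settings=MCMCSettings(n_burnin=250, n_iter=400, n_chains=2, seed=3),
        )
        om = split.omega_draws
        assert om.mean() == pytest.approx(0.6, abs=2 * om.std(ddof=1))
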