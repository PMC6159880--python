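"""Model designs: column layout, consistency coding, centering, imputation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ipdnma import (
    CovariateSpec,
    IPDDataset,
    ModelConfig,
    PriorSpec,
    attach_imputation,
    build_design,
    build_network,
    effective_trial_means,
)


def network_dataset(stage_missing=(), trial_means=(0.5, 1.0, 1.5)):
    """Three trials: RT-B, RT-C, B-C; 4 patients each, stage attached."""
    rows = []
    trials = [("T1", "RT", "B"), ("T2", "RT", "C"), ("T3", "B", "C")]
    k = 0
    for (tid, a, b), zbar in zip(trials, trial_means):
        for i in range(4):
            stage = zbar + (0.5 if i % 2 else -0.5)
            rows.append(
                [tid, a if i < 2 else b, 1.0 + 0.3 * i + 0.1 * k, 1,
                 None if k in stage_missing else stage]
            )
            k += 1
    df = pd.DataFrame(rows, columns=["trial", "treatment", "time", "event", "stage"])
    return IPDDataset(df, covariates=[CovariateSpec("stage", bounds=(-1, 3))],
                      treatments=["RT", "B", "C"])


@pytest.fixture
def net():
    return build_network(network_dataset(), "RT")


class TestConfig:
    def test_interaction_requires_covariate(self):
        with pytest.raises(ValueError, match="covariate"):
            ModelConfig(interaction_mode="combined")

    def test_text_round_trip(self):
        cfg = ModelConfig(
            covariate="stage", covariate_mode="fixed_trial",
            interaction_mode="separated", ph_interactions=True,
            inconsistency=(("RT", "B", "C"),), n_knots=1,
        )
        again = ModelConfig.from_text(cfg.to_text())
        for f in ("covariate", "covariate_mode", "interaction_mode",
                  "ph_interactions", "inconsistency", "n_knots"):
            assert getattr(again, f) == getattr(cfg, f)


class TestColumnLayout:
    def test_column_count_audit(self, net):
        ds = network_dataset()
        J, q = 3, 2
        cases = {
            ("common", "none"): 1,
            ("fixed_trial", "none"): J,
            ("fixed_trial", "separated"): J + 2 * q,
            ("fixed_trial", "combined"): J + q,
        }
        for (cmode, imode), extra in cases.items():
            cfg = ModelConfig(covariate="stage", covariate_mode=cmode,
                              interaction_mode=imode, n_knots=0)
            design = build_design(ds, net, cfg)
            n_spline = 2 * J  # K=0: intercept + linear per trial
            assert design.n_cols == n_spline + q + extra

    def test_btoc_trial_gets_consistency_pattern(self, net):
        ds = network_dataset()
        design = build_design(ds, net, ModelConfig(n_knots=0))
        t3 = ds.table["trial"] == "T3"
        on_c = t3 & (ds.table["treatment"] == "C")
        on_b = t3 & (ds.table["treatment"] == "B")
        bcol = design.X0[:, design.col("beta[B]")]
        ccol = design.X0[:, design.col("beta[C]")]
        # records on C in the B-vs-C trial carry the pattern beta_C - beta_B
        assert np.all(bcol[on_c] == -1.0) and np.all(ccol[on_c] == 1.0)
        assert np.all(bcol[on_b] == 0.0) and np.all(ccol[on_b] == 0.0)

    def test_separated_centering_arithmetic(self, net):
        ds = network_dataset(trial_means=(1.4, 1.4, 1.4))
        cfg = ModelConfig(covariate="stage", covariate_mode="common",
                          interaction_mode="separated", n_knots=0)
        design = build_design(ds, net, cfg)
        i = ds.table.index[(ds.table["trial"] == "T1")
                           & (ds.table["treatment"] == "B")][1]
        z = ds.table.loc[i, "stage"]  # 1.9 in a trial with mean 1.4
        k = design.col("deltaA[B]")
        within = design.X0[i, k] + z * design.M[i, k]
        across = design.X0[i, design.col("deltaB[B]")]
        assert within == pytest.approx(z - 1.4)
        assert across == pytest.approx(1.4)

    def test_centering_identity_when_trial_means_zero(self, net):
        ds = network_dataset()
        means = {t: 0.0 for t in ds.trial_ids}
        sep = build_design(ds, net, ModelConfig(
            covariate="stage", covariate_mode="fixed_trial",
            interaction_mode="separated", trial_means=means, n_knots=0))
        comb = build_design(ds, net, ModelConfig(
            covariate="stage", covariate_mode="fixed_trial",
            interaction_mode="combined", trial_means=means, n_knots=0))
        shared = [n for n in comb.colnames]
        for name in shared:
            sname = name.replace("delta[", "deltaA[")
            i, j = comb.col(name), sep.col(sname)
            assert np.array_equal(comb.X0[:, i], sep.X0[:, j])
            assert np.array_equal(comb.M[:, i], sep.M[:, j])
            assert np.array_equal(comb.Xd[:, i], sep.Xd[:, j])
        for name in sep.colnames:
            if name.startswith("deltaB["):
                assert not np.any(sep.X0[:, sep.col(name)])

    def test_contrast_column_consistency(self, net):
        # any contrast pattern equals the difference of basic patterns
        ds = network_dataset()
        design = build_design(ds, net, ModelConfig(n_knots=0))
        cb = design.X0[:, design.col("beta[B]")]
        cc = design.X0[:, design.col("beta[C]")]
        for i, pat in enumerate(zip(cb, cc)):
            coefs = net.contrast_coefficients(
                "RT", ds.table["treatment"].iloc[i]
            )
            base = net.contrast_coefficients(
                "RT", {"T1": "RT", "T2": "RT", "T3": "B"}[ds.table["trial"].iloc[i]]
            )
            expect = np.zeros(2)
            for k, v in coefs.items():
                expect[k] += v
            for k, v in base.items():
                expect[k] -= v
            np.testing.assert_allclose(pat, expect)

    def test_ph_columns_carry_log_time(self, net):
        ds = network_dataset()
        design = build_design(ds, net, ModelConfig(ph_interactions=True, n_knots=0))
        k = design.col("phi[B]")
        on_b_t1 = (ds.table["trial"] == "T1") & (ds.table["treatment"] == "B")
        i = ds.table.index[on_b_t1][0]
        assert design.X0[i, k] == pytest.approx(np.log(ds.table.loc[i, "time"]))
        assert design.Xd[i, k] == 1.0

    def test_inconsistency_column_on_closing_edge(self, net):
        ds = network_dataset()
        cfg = ModelConfig(inconsistency=(("RT", "B", "C"),), n_knots=0)
        design = build_design(ds, net, cfg)
        loop = ("RT", "B", "C")
        assert design.closing_edge_of[loop] == ("B", "C")  # fewest trials
        col = design.X0[:, design.omega_cols[loop]]
        on_c_t3 = ((ds.table["trial"] == "T3")
                   & (ds.table["treatment"] == "C")).to_numpy()
        assert np.all(col[on_c_t3] == 1.0)
        assert np.all(col[~on_c_t3] == 0.0)

    def test_missing_covariate_without_imputation_errors(self, net):
        ds = network_dataset(stage_missing=(0,))
        cfg = ModelConfig(covariate="stage", covariate_mode="common")
        with pytest.raises(ValueError, match="imputation"):
            build_design(ds, net, cfg)

    def test_separated_all_missing_trial_instructs_two_pass(self, net):
        ds = network_dataset(stage_missing=(0, 1, 2, 3))
        cfg = ModelConfig(covariate="stage", covariate_mode="common",
                          interaction_mode="separated",
                          imputation="truncated_normal")
        with pytest.raises(ValueError, match="two-pass"):
            build_design(ds, net, cfg)


class TestImputation:
    def test_no_missing_is_identity(self, net):
        ds = network_dataset()
        cfg = ModelConfig(covariate="stage", covariate_mode="common")
        design = build_design(ds, net, cfg)
        assert attach_imputation(design, ds, (-1, 3)) is design

    def test_one_missing_adds_one_latent(self, net):
        ds = network_dataset(stage_missing=(5,))
        cfg = ModelConfig(covariate="stage", covariate_mode="common",
                          imputation="truncated_normal")
        design = build_design(ds, net, cfg)
        assert design.n_latent == 1
        assert design.imputation.missing_idx.tolist() == [5]
        assert design.imputation.bounds == (-1.0, 3.0)

    def test_undeclared_bounds_error(self, net):
        ds = IPDDataset(network_dataset(stage_missing=(5,)).table,
                        covariates=[CovariateSpec("stage")])
        net2 = build_network(ds, "RT")
        cfg = ModelConfig(covariate="stage", covariate_mode="common",
                          imputation="truncated_normal")
        with pytest.raises(ValueError, match="bounds"):
            build_design(ds, net2, cfg)


class TestEffectiveTrialMeans:
    def test_weighted_average(self):
        rows = [["T1", "A" if i % 2 else "B", 1.0 + i, 1,
                 1.0 if i < 80 else None] for i in range(100)]
        df = pd.DataFrame(rows, columns=["trial", "treatment", "time", "event", "z"])
        ds = IPDDataset(df, covariates=[CovariateSpec("z", bounds=(0, 3))])
        imputed = {i: 1.5 for i in range(80, 100)}
        means = effective_trial_means(ds, "z", imputed)
        assert means["T1"] == pytest.approx((80 * 1.0 + 20 * 1.5) / 100)

    def test_fully_observed_unchanged(self):
        ds = network_dataset()
        means = effective_trial_means(ds, "stage", {})
        for t, s in zip(ds.trial_ids, (0.5, 1.0, 1.5)):
            assert means[t] == pytest.approx(s)

    def test_fully_missing_uses_imputed_only(self):
        rows = [["T1", "A" if i % 2 else "B", 1.0 + i, 1, None] for i in range(2)]
        df = pd.DataFrame(rows, columns=["trial", "treatment", "time", "event", "z"])
        ds = IPDDataset(df, covariates=[CovariateSpec("z", bounds=(0, 3))])
        means = effective_trial_means(ds, "z", {0: 1.2, 1: 0.8})
        assert means["T1"] == pytest.approx(1.0)


class TestDesignLikelihood:
    def test_matches_record_level_reference_path(self, net):
        """The matrix likelihood equals the readable per-record formulation."""
        from ipdnma import LinearPredictorParts, log_likelihood

        ds = network_dataset()
        cfg = ModelConfig(covariate="stage", covariate_mode="fixed_trial",
                          interaction_mode="separated", n_knots=0)
        design = build_design(ds, net, cfg)
        rng = np.random.default_rng(2)
        theta = rng.normal(scale=0.2, size=design.n_cols)
        for t in ds.trial_ids:
            theta[design.col(f"gamma[{t},1]")] = abs(theta[design.col(f"gamma[{t},1]")]) + 0.5

        means = design.trial_means
        baseline = {"T1": "RT", "T2": "RT", "T3": "B"}
        beta = {}
        for treat in ("B", "C"):
            beta[treat] = theta[design.col(f"beta[{treat}]")]
        parts = LinearPredictorParts(
            knots=design.knots,
            gamma={t: np.array([theta[design.col(f"gamma[{t},0]")],
                                theta[design.col(f"gamma[{t},1]")]])
                   for t in ds.trial_ids},
            alpha={t: theta[design.col(f"alpha[{t}]")] for t in ds.trial_ids},
            trial_means=means,
            center_covariate=True,
        )
        # translate trial-baseline coding into per-record effects by hand
        eta_ref = []
        from ipdnma.survival import log_likelihood_arrays

        table = ds.table
        for i, row in enumerate(table.itertuples(index=False)):
            coefs = net.contrast_coefficients(baseline[row.trial], row.treatment)
            eff = sum(v * theta[design.col(f"beta[{net.basic_parameters[k][1]}]")]
                      for k, v in coefs.items())
            effA = sum(v * theta[design.col(f"deltaA[{net.basic_parameters[k][1]}]")]
                       for k, v in coefs.items())
            effB = sum(v * theta[design.col(f"deltaB[{net.basic_parameters[k][1]}]")]
                       for k, v in coefs.items())
            z = row.stage
            x = np.log(row.time)
            eta = (parts.gamma[row.trial][0] + parts.gamma[row.trial][1] * x
                   + eff
                   + parts.alpha[row.trial] * (z - means[row.trial])
                   + effA * (z - means[row.trial]) + effB * means[row.trial])
            eta_ref.append(eta)
        deta = design.Xd @ theta
        ref = log_likelihood_arrays(design.d, np.array(eta_ref), deta, design.x)
        got = design.log_likelihood(theta)
        assert got.value == pytest.approx(ref.value, abs=1e-10)

    def test_audit_table_shape(self, net):
        ds = network_dataset()
        design = build_design(ds, net, ModelConfig(n_knots=0))
        audit = design.audit_table()
        assert audit.shape == (len(ds), design.n_cols)
        assert list(audit.columns) == design.colnames
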