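"""Clock training, PD normalization, application, dual-set rule, summary."""

import numpy as np
import pandas as pd
import pytest

import pmdclock as pc

from conftest import WORLD_SEED


def _toy_model(intercept=10.0, coefs=None, means=None):
    coefs = coefs or {"cg1": -5.0}
    means = means or {k: 0.5 for k in coefs}
    return pc.ClockModel(
        intercept=intercept,
        coefficients=pd.Series(coefs),
        training_means=pd.Series(means),
    )


class TestApplyClock:
    def test_linear_predictor_arithmetic(self):
        model = _toy_model()
        beta = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        out = pc.apply_clock(model, beta)
        assert out.loc["s1", "estimate"] == pytest.approx(7.5)

    def test_missing_probe_hard_error_lists_probes(self):
        model = _toy_model(coefs={"cg1": -5.0, "cg2": 1.0})
        beta = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        with pytest.raises(ValueError, match="cg2"):
            pc.apply_clock(model, beta)

    def test_imputation_uses_training_means_and_counts(self):
        model = _toy_model(
            coefs={"cg1": -5.0, "cg2": 2.0}, means={"cg1": 0.5, "cg2": 0.25}
        )
        beta = pd.DataFrame({"s1": [0.5]}, index=["cg1"])
        out = pc.apply_clock(model, beta, impute=True)
        assert out.loc["s1", "estimate"] == pytest.approx(10 - 2.5 + 0.5)
        assert out.loc["s1", "n_imputed"] == 1

    def test_all_training_mean_sample_scores_closed_form(self):
        model = _toy_model(
            coefs={"cg1": -5.0, "cg2": 2.0}, means={"cg1": 0.7, "cg2": 0.2}
        )
        beta = pd.DataFrame(
            {"s1": model.training_means.loc[model.probes]},
        )
        out = pc.apply_clock(model, beta)
        expected = model.intercept + float(
            (model.coefficients * model.training_means).sum()
        )
        assert out.loc["s1", "estimate"] == pytest.approx(expected)


class TestReferenceModel:
    def test_holdout_rmse_small_on_simulated_reference(self, sim_config):
        """40-sample reference culture: held-out prediction RMSE under 10%
        of the PD range."""
        scenario = pc.CultureScenario(
            lineages=[
                pc.Lineage("ref", 5.0, [(4.0, 7.0)] * 39),
            ]
        )
        beta, sheet, _ = pc.simulate_culture(sim_config, scenario)
        sheet = sheet.set_index("sample_id")
        train = sheet.index[::2]
        test = sheet.index[1::2]
        model = pc.train_reference_model(
            beta[train], sheet.loc[train, "cum_pd"], seed=1
        )
        pred = pc.apply_clock(model, beta[test], impute=True)["estimate"]
        rmse = np.sqrt(((pred - sheet.loc[test, "cum_pd"]) ** 2).mean())
        pd_range = sheet["cum_pd"].max() - sheet["cum_pd"].min()
        assert rmse < 0.10 * pd_range

    def test_deterministic_given_seed(self, default_culture):
        beta, sheet, _ = default_culture
        sheet_i = sheet.set_index("sample_id")
        cols = sheet_i.index[sheet_i["lineage"] == "line1"]
        m1 = pc.train_reference_model(beta[cols], sheet_i.loc[cols, "cum_pd"], seed=7)
        m2 = pc.train_reference_model(beta[cols], sheet_i.loc[cols, "cum_pd"], seed=7)
        assert m1.intercept == m2.intercept
        pd.testing.assert_series_equal(m1.coefficients, m2.coefficients)

    def test_shift_equivariance(self, default_culture):
        """Adding a constant to all training PDs shifts the intercept by
        that constant and leaves coefficients unchanged."""
        beta, sheet, _ = default_culture
        sheet_i = sheet.set_index("sample_id")
        cols = sheet_i.index[sheet_i["lineage"] == "line2"]
        pds = sheet_i.loc[cols, "cum_pd"]
        m1 = pc.train_reference_model(beta[cols], pds, seed=3)
        m2 = pc.train_reference_model(beta[cols], pds + 100.0, seed=3)
        assert m2.intercept - m1.intercept == pytest.approx(100.0, abs=1e-6)
        pd.testing.assert_series_equal(
            m1.coefficients, m2.coefficients, atol=1e-8
        )

    def test_duplicated_training_set_equivalent_at_fixed_penalty(
        self, default_culture
    ):
        beta, sheet, _ = default_culture
        sheet_i = sheet.set_index("sample_id")
        cols = sheet_i.index[sheet_i["lineage"] == "line0"]
        pds = sheet_i.loc[cols, "cum_pd"]
        m1 = pc.train_reference_model(beta[cols], pds, seed=1, penalty=0.05)
        dup = beta[cols].copy()
        dup.columns = [f"{c}_dup" for c in dup.columns]
        beta2 = pd.concat([beta[cols], dup], axis=1)
        pds2 = pd.Series(
            np.concatenate([pds.to_numpy()] * 2), index=beta2.columns
        )
        m2 = pc.train_reference_model(beta2, pds2, seed=1, penalty=0.05)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-4)
        common = m1.coefficients.index.union(m2.coefficients.index)
        np.testing.assert_allclose(
            m1.coefficients.reindex(common, fill_value=0.0),
            m2.coefficients.reindex(common, fill_value=0.0),
            atol=1e-4,
        )

    def test_single_dominant_probe_recovered(self):
        rng = np.random.default_rng(0)
        pds = pd.Series(np.arange(0.0, 60.0, 2.0))
        pds.index = [f"s{i}" for i in range(len(pds))]
        beta = pd.DataFrame(
            rng.uniform(0.3, 0.7, (30, len(pds))),
            index=[f"noise{i}" for i in range(30)],
            columns=pds.index,
        )
        beta.loc["signal"] = 0.9 - 0.01 * pds.to_numpy()
        model = pc.train_reference_model(beta, pds, seed=1)
        assert "signal" in model.probes

    def test_constant_pds_rejected(self):
        beta = pd.DataFrame(
            np.full((3, 8), 0.5), columns=[f"s{i}" for i in range(8)]
        )
        with pytest.raises(ValueError, match="constant"):
            pc.train_reference_model(beta, pd.Series(5.0, index=beta.columns))


class TestNormalizePds:
    def test_forced_rule_example(self):
        """Lineage observed at PDs {5, 8} whose start is predicted at 30
        normalizes to {30, 33}."""
        model = _toy_model(intercept=30.0, coefs={"cg1": 2.0})
        beta = pd.DataFrame({"a1": [0.0], "a2": [0.9]}, index=["cg1"])
        sheet = pd.DataFrame(
            {
                "sample_id": ["a1", "a2"],
                "lineage": ["A", "A"],
                "cum_pd": [5.0, 8.0],
            }
        )
        norm = pc.normalize_pds(model, sheet, beta)
        assert norm["normalized_pd"].tolist() == pytest.approx([30.0, 33.0])
        assert norm["predicted_start"].tolist() == pytest.approx([30.0, 30.0])

    def test_reference_lineage_keeps_observed(self):
        model = _toy_model(intercept=30.0, coefs={"cg1": 2.0})
        beta = pd.DataFrame({"r1": [0.5], "r2": [0.4]}, index=["cg1"])
        sheet = pd.DataFrame(
            {
                "sample_id": ["r1", "r2"],
                "lineage": ["ref", "ref"],
                "cum_pd": [2.0, 6.0],
            }
        )
        norm = pc.normalize_pds(model, sheet, beta, reference_lineage="ref")
        assert norm["normalized_pd"].tolist() == [2.0, 6.0]

    def test_recovers_relative_offsets_on_simulation(
        self, trained_clock, default_culture, sim_config
    ):
        """Predicted lineage starting PDs reproduce the simulated in-vivo
        offsets up to a common shift, within a few PD."""
        _, sheet, truth = default_culture
        norm = trained_clock["normalized"]
        sheet_i = sheet.set_index("sample_id")
        starts = norm.groupby(sheet_i["lineage"])["predicted_start"].first()
        true_offsets = truth["samples"].groupby("lineage")["true_total_pd"].min()
        rel_pred = starts - starts["line0"]
        rel_true = true_offsets - true_offsets["line0"]
        assert (rel_pred - rel_true).abs().max() < 5.0


class TestTrainReplitali:
    def test_training_is_deterministic(self, default_culture, trained_clock):
        beta, sheet, truth = default_culture
        norm = trained_clock["normalized"]
        m2, _ = pc.train_replitali(
            beta, norm["normalized_pd"], truth["probes"], seed=WORLD_SEED
        )
        pd.testing.assert_series_equal(
            trained_clock["model"].coefficients, m2.coefficients
        )

    def test_model_restricted_to_pmd_probes(self, default_culture, trained_clock):
        _, _, truth = default_culture
        panel = truth["probes"]
        pmd = set(panel.index[panel["domain"] == "commonPMD"])
        assert set(trained_clock["model"].probes) <= pmd

    def test_empty_pmd_pool_rejected(self, default_culture):
        beta, sheet, truth = default_culture
        ann = truth["probes"].copy()
        ann["domain"] = "neither"
        with pytest.raises(ValueError, match="common-PMD"):
            pc.train_replitali(
                beta, sheet.set_index("sample_id")["cum_pd"], ann, seed=0
            )

    def test_fitted_values_reproducible_at_application(
        self, default_culture, trained_clock
    ):
        """Applying the model to its own training samples reproduces the
        training-time linear predictor."""
        beta, _, _ = default_culture
        model = trained_clock["model"]
        train_ids = model.metadata["training_samples"]
        est1 = pc.apply_clock(model, beta[train_ids])["estimate"]
        est2 = model.intercept + beta[train_ids].reindex(model.probes).mul(
            model.coefficients, axis=0
        ).sum(axis=0)
        np.testing.assert_allclose(est1, est2)


class TestDualClock:
    def test_max_rule(self):
        clock = pc.DualSetClock(
            hyper_probes=pd.Index(["h1"]),
            hyper_intercept=0.0,
            hyper_slope=10.0,
            hypo_probes=pd.Index(["l1"]),
            hypo_intercept=10.0,
            hypo_slope=-10.0,
        )
        beta = pd.DataFrame({"s1": [0.3, 0.5]}, index=["h1", "l1"])
        out = pc.apply_dual_clock(clock, beta)
        assert out.loc["s1", "score_hyper"] == pytest.approx(3.0)
        assert out.loc["s1", "score_hypo"] == pytest.approx(5.0)
        assert out.loc["s1", "estimate"] == pytest.approx(5.0)
        assert out.loc["s1", "selected"] == "hypo"

    def test_tie_flagged(self):
        clock = pc.DualSetClock(
            pd.Index(["h1"]), 0.0, 10.0, pd.Index(["l1"]), 0.0, 10.0
        )
        beta = pd.DataFrame({"s1": [0.4, 0.4]}, index=["h1", "l1"])
        out = pc.apply_dual_clock(clock, beta)
        assert out.loc["s1", "selected"] == "tie"
        assert out.loc["s1", "estimate"] == pytest.approx(4.0)

    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            pc.DualSetClock(
                pd.Index(["x"]), 0.0, 1.0, pd.Index(["x"]), 0.0, 1.0
            )

    def test_missing_set_rejected_at_application(self):
        clock = pc.DualSetClock(
            pd.Index(["h1"]), 0.0, 1.0, pd.Index(["l1"]), 0.0, 1.0
        )
        beta = pd.DataFrame({"s1": [0.4]}, index=["h1"])
        with pytest.raises(ValueError, match="hypomethylation"):
            pc.apply_dual_clock(clock, beta)

    def test_hypo_component_dominates_under_erosion(self, default_culture):
        """With hypomethylation-driven dynamics, the losing probe set is
        selected for nearly all late-PD samples.

        The hypo score is calibrated on this cell type; the hyper score is
        calibrated as if its probe set gained methylation with divisions
        (the situation of a gain-set clock ported from another tissue), so
        in a culture where that set stays flat the hyper score cannot keep
        up with accumulating divisions.
        """
        beta, sheet, truth = default_culture
        panel = truth["probes"]
        sheet_i = sheet.set_index("sample_id")
        pds = sheet_i["cum_pd"]
        hypo = panel.index[panel["class"] == "soloWCGW_PMD"]
        hyper = panel.index[panel["class"] == "social_nonPMD"]
        hypo_cal = pc.fit_dual_clock(beta, pds, hyper, hypo)
        early = pds.index[pds <= pds.quantile(0.1)]
        hyper_mean_early = beta.loc[hyper, early].mean().mean()
        hyper_slope = 50.0  # expected gain per unit beta, from elsewhere
        clock = pc.DualSetClock(
            hyper_probes=hyper,
            hyper_intercept=float(
                pds[early].mean() - hyper_slope * hyper_mean_early
            ),
            hyper_slope=hyper_slope,
            hypo_probes=hypo,
            hypo_intercept=hypo_cal.hypo_intercept,
            hypo_slope=hypo_cal.hypo_slope,
        )
        out = pc.apply_dual_clock(clock, beta)
        late = sheet_i.index[sheet_i["cum_pd"] > sheet_i["cum_pd"].median()]
        frac_hypo = (out.loc[late, "selected"] == "hypo").mean()
        assert frac_hypo >= 0.95


class TestSummarizeModel:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {
                "flank_class": ["WCGW", "WCGW", "SCGS"],
                "solo": [True, True, False],
                "domain": ["commonPMD", "commonPMD", "commonPMD"],
                "in_cgi": [False, False, False],
            },
            index=["cgA", "cgB", "cgC"],
        )

    def test_toy_composition_arithmetic(self, annotation):
        model = _toy_model(
            coefs={"cgA": -4.0, "cgB": -2.0, "cgC": -1.0},
            means={"cgA": 0.5, "cgB": 0.5, "cgC": 0.5},
        )
        report = pc.summarize_model(model, annotation)
        assert report.loc["all", "n_probes"] == 3
        assert report.loc["all", "mean_coefficient"] == pytest.approx(-7 / 3)
        assert report.loc["soloWCGW_PMD", "n_probes"] == 2
        assert report.loc["soloWCGW_PMD", "mean_coefficient"] == pytest.approx(-3.0)
        assert report.loc["soloWCGW_PMD", "fraction"] == pytest.approx(2 / 3)

    def test_empty_class_reported_with_nan_mean(self, annotation):
        model = _toy_model(coefs={"cgC": -1.0}, means={"cgC": 0.5})
        report = pc.summarize_model(model, annotation)
        assert report.loc["soloWCGW_PMD", "n_probes"] == 0
        assert np.isnan(report.loc["soloWCGW_PMD", "mean_coefficient"])

    def test_unannotated_probe_warned_and_excluded_from_classes(self, annotation):
        model = _toy_model(
            coefs={"cgA": -4.0, "cgZ": -9.0}, means={"cgA": 0.5, "cgZ": 0.5}
        )
        with pytest.warns(UserWarning, match="cgZ"):
            report = pc.summarize_model(model, annotation)
        assert report.loc["all", "n_probes"] == 2
        assert report.loc["all", "mean_coefficient"] == pytest.approx(-6.5)
        assert report.loc["soloWCGW_PMD", "mean_coefficient"] == pytest.approx(-4.0)
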