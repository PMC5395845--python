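"""Experiment drivers: develop-everywhere, the validation matrix,
and the correlation sweeps."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import casemixsim as cm


class TestSeeds:
    def test_population_seeds_distinct_and_bounded(self):
        seeds = {
            cm.population_seed(1, pid, app)
            for pid in "ABCDEFGHIJKLMNOP"
            for app in (1, 2)
        }
        assert len(seeds) == 32
        assert all(0 <= s < 2**31 for s in seeds)

    def test_population_seed_deterministic(self):
        assert cm.population_seed(5, "A", 1) == cm.population_seed(5, "A", 1)
        assert cm.population_seed(5, "A", 1) != cm.population_seed(6, "A", 1)


class TestDevelopAll:
    def test_empty_spec_list(self):
        result = cm.develop_all([], 1)
        assert result.cohorts == {} and result.models == {} and result.reports == {}

    def test_duplicate_ids_rejected(self, table1_specs):
        with pytest.raises(ValueError, match="unique"):
            cm.develop_all([table1_specs["A"], table1_specs["A"]], 1)

    def test_one_artifact_per_population(self, dev_a1, dev_a2):
        assert len(dev_a1.models) == 16 and len(dev_a2.models) == 9
        assert dev_a1.population_ids == list("ABCDEFGHIJKLMNOP")

    def test_table1_population_p_auc(self, dev_a1):
        assert dev_a1.reports["P"].auc == pytest.approx(0.810, abs=0.01)

    def test_table2_population_f_auc(self, dev_a2):
        assert dev_a2.reports["F"].auc == pytest.approx(0.858, abs=0.01)


class TestCrossValidate:
    def test_diagonal_equals_development_auc(self, dev_a1, xval_a1):
        for pid in dev_a1.population_ids:
            assert xval_a1.auc.loc[pid, pid] == pytest.approx(dev_a1.reports[pid].auc)

    def test_model_g_transported_to_p(self, xval_a1):
        assert xval_a1.auc.loc["P", "G"] == pytest.approx(0.810, abs=0.01)

    def test_mismatched_id_sets_rejected(self, dev_a1):
        models = dict(dev_a1.models)
        models.pop("A")
        with pytest.raises(ValueError, match="same population ids"):
            cm.cross_validate(models, dev_a1.cohorts)

    def test_identical_populations_are_exchangeable(self, table1_specs):
        # two fresh draws of the same spec: off-diagonal ~ diagonal
        import dataclasses

        spec1 = table1_specs["A"]
        spec2 = dataclasses.replace(spec1, id="A2")
        result = cm.develop_all([spec1, spec2], 99)
        matrix = cm.cross_validate(result.models, result.cohorts)
        diag = matrix.diagonal()
        assert matrix.auc.loc["A", "A2"] == pytest.approx(diag["A"], abs=0.01)
        assert matrix.auc.loc["A2", "A"] == pytest.approx(diag["A2"], abs=0.01)

    def test_transported_auc_depends_only_on_coefficient_direction(self, dev_a1):
        # scaling a model's coefficient vector leaves every validation
        # AUC unchanged exactly (ranks are invariant)
        model = dev_a1.models["A"]
        scaled = model.scaled(3.7)
        for pid in ("E", "H", "P"):
            cohort = dev_a1.cohorts[pid]
            a1, _ = cm.auc_mann_whitney(model.linear_predictor(cohort.x), cohort.y, "auto")
            a2, _ = cm.auc_mann_whitney(scaled.linear_predictor(cohort.x), cohort.y, "auto")
            assert a1 == a2

    def test_models_with_proportional_coefficients_validate_identically(
        self, dev_a1
    ):
        # populations A and E share adjusted ORs (1.5, 1.5); their fitted
        # coefficient vectors are near-proportional, so their transported
        # AUCs agree in any fixed cohort
        cohort = dev_a1.cohorts["P"]
        auc_a, _ = cm.auc_mann_whitney(
            dev_a1.models["A"].linear_predictor(cohort.x), cohort.y, "auto"
        )
        auc_e, _ = cm.auc_mann_whitney(
            dev_a1.models["E"].linear_predictor(cohort.x), cohort.y, "auto"
        )
        assert auc_a == pytest.approx(auc_e, abs=0.002)


class TestCorrelationSweepA1:
    def test_single_point_grid_reproduces_population_a(self, table1_specs):
        sweep = cm.correlation_sweep_a1(table1_specs["A"], [0.2], "same", seed=3)
        assert sweep.grid.tolist() == [0.2]
        assert sweep.auc[0] == pytest.approx(0.663, abs=0.01)

    def test_invalid_grids_rejected(self, table1_specs):
        with pytest.raises(ValueError):
            cm.correlation_sweep_a1(table1_specs["A"], [0.2, 0.1], "same", seed=0)
        with pytest.raises(ValueError):
            cm.correlation_sweep_a1(table1_specs["A"], [0.2, 1.0], "same", seed=0)

    def test_sweep_frame_round_trip(self, sweep_same):
        df = sweep_same.to_frame()
        assert list(df.columns) == ["rho", "auc", "sd_lp", "scenario"]
        assert len(df) == len(sweep_same.grid)


class TestCorrelationSweepA2:
    def test_degenerate_single_point_curve(self):
        base = cm.fig3_scenario_specs(n=20_000)["a"]
        curves = cm.correlation_sweep_a2(base, [0.2], [0.2], seed=5)
        assert len(curves) == 1 and curves[0].grid.tolist() == [0.2]

    def test_one_curve_per_case_level(self):
        base = cm.fig3_scenario_specs(n=10_000)["a"]
        curves = cm.correlation_sweep_a2(base, [-0.2, 0.2], [-0.2, 0.0, 0.2], seed=5)
        assert len(curves) == 2
        assert all(len(c.auc) == 3 for c in curves)

    def test_scenario_specs_cover_four_layouts(self):
        specs = cm.fig3_scenario_specs()
        assert sorted(specs) == ["a", "b", "c", "d"]
        assert specs["b"].case.mu == (1.0, 3.0)
        assert specs["d"].case.sigma == (2.0, 1.0)
        assert all(s.control.mu == (0.0, 0.0) for s in specs.values())

    def test_negative_case_correlation_improves_auc(self, table2_specs):
        """Scenario (a): increasingly negative case correlation raises the
        AUC (population E, shared rho -0.1, beats population A, shared 0.2)."""
        base = cm.fig3_scenario_specs()["a"]
        levels = [-0.3, -0.1, 0.1, 0.3]
        curves = cm.correlation_sweep_a2(base, levels, [0.2], seed=13)
        aucs = [c.auc[0] for c in curves]
        diffs = np.diff(aucs)
        assert (diffs <= 0.005).all(), aucs  # decreasing in rho_case

    def test_equal_strong_positive_correlation_boosts_auc(self):
        """Equal case/control correlation near +1 discriminates better than
        at +0.4: predictors 'move together', so the LP distributions of
        cases and controls separate."""
        base = cm.fig3_scenario_specs()["a"]
        aucs = {}
        for rho in (0.4, 0.95):
            spec = base.with_correlations(rho, rho)
            cohort = cm.simulate_population_a2(spec, 17)
            report = cm.evaluate(cm.fit_logistic(cohort), cohort)
            aucs[rho] = report.auc
        assert aucs[0.95] > aucs[0.4] + 0.02


class TestFig2LegendValues:
    def test_population_e_beats_population_a(self, dev_a2):
        assert dev_a2.reports["E"].auc == pytest.approx(0.795, abs=0.01)
        assert dev_a2.reports["A"].auc == pytest.approx(0.770, abs=0.01)
        assert dev_a2.reports["E"].auc > dev_a2.reports["A"].auc


class TestHeterogeneityDiscriminationLink:
    def test_sd_lp_and_auc_share_rank_order(self, sweep_same):
        rho, _ = spearmanr(sweep_same.sd_lp, sweep_same.auc)
        assert rho >= 0.99
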