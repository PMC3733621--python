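"""Mechanism-of-action ranking, tolerance metrics, dose-response, sweeps."""

import math

import numpy as np
import pytest

from gemkin import (
    ExpressionVector,
    FixtureSpec,
    RateParameters,
    assemble_model,
    dose_response,
    inhibition_schedule,
    make_toy_network,
    normalized_sse_fluxes,
    ntc,
    nuc,
    pearson_correlation,
    rank_targets,
    sensitivity_sweep,
    solve_steady_state,
    sse_log_concentrations,
    tolerance_inhibition,
    tolerance_woa,
)
from gemkin.analyses import MetricError
from gemkin.fixtures import toy_inhibition_family, toy_woa_family


class TestSseMetrics:
    def test_zero_for_perfect_prediction(self):
        assert sse_log_concentrations({"a": 2.0}, {"a": 2.0}) == 0.0

    def test_single_twofold_error(self):
        assert sse_log_concentrations({"a": 2.0}, {"a": 1.0}) == pytest.approx(
            math.log(2.0) ** 2
        )

    def test_disjoint_ids_rejected(self):
        with pytest.raises(MetricError):
            sse_log_concentrations({"a": 1.0}, {"b": 1.0})

    def test_normalized_flux_sse_anchors(self):
        treated = {"f1": 2.0, "f2": 4.0}
        reference = {"f1": 1.0, "f2": 2.0}
        assert normalized_sse_fluxes(treated, treated, reference) == 0.0
        assert normalized_sse_fluxes(reference, treated, reference) == 1.0
        midway = {"f1": 1.5, "f2": 3.0}
        assert normalized_sse_fluxes(midway, treated, reference) == pytest.approx(0.25)

    def test_zero_denominator_rejected(self):
        with pytest.raises(MetricError):
            normalized_sse_fluxes({"f": 1.0}, {"f": 2.0}, {"f": 2.0})


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_printed_triple(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981, abs=1e-3)

    def test_log_scale(self):
        x = [1.0, 10.0, 100.0]
        y = [2.0, 20.0, 200.0]
        assert pearson_correlation(x, y, log_scale=True) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(MetricError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestInhibitionSchedule:
    def test_printed_anchor_points(self):
        assert inhibition_schedule(1.0) == pytest.approx(1.0)
        assert inhibition_schedule(0.487) == pytest.approx(0.0227, abs=1e-12)

    def test_midpoint_interpolation(self):
        assert inhibition_schedule(0.7435) == pytest.approx(0.51135, abs=1e-10)

    def test_clipped_at_positive_floor(self):
        assert inhibition_schedule(0.1) == pytest.approx(1e-6)


class TestRankTargets:
    def make_model(self, seed=0):
        spec = FixtureSpec(topology="chain", n=5, fraction_reversible=0.3,
                           n_drains=1, seed=seed)
        net, ref = make_toy_network(spec)
        return net, assemble_model(net, ref)

    def test_planted_perturbation_recovered(self):
        net, model = self.make_model(seed=0)
        direction = "forward" if net.reaction("step2").reversible else "whole"
        pert = model.with_rate_scaling("step2", 0.3, direction)
        truth = solve_steady_state(pert)
        results = rank_targets(model, truth.c)
        top = results[0]
        assert top.reaction_id == "step2"
        assert top.optimal_factor == pytest.approx(0.3, rel=0.02)
        assert top.normalized_sse < 0.05

    def test_baseline_data_leaves_factors_at_one(self):
        net, model = self.make_model(seed=1)
        baseline = solve_steady_state(model)
        results = rank_targets(model, baseline.c)
        for res in results:
            assert res.optimal_factor == pytest.approx(1.0, abs=0.02)
            assert res.normalized_sse == pytest.approx(1.0)

    def test_normalized_sse_never_exceeds_one(self):
        net, model = self.make_model(seed=2)
        pert = model.with_rate_scaling("step3", 2.0, "whole")
        truth = solve_steady_state(pert)
        for res in rank_targets(model, truth.c):
            assert res.normalized_sse <= 1.0 + 1e-9

    def test_deterministic_ordering(self):
        net, model = self.make_model(seed=3)
        pert = model.with_rate_scaling("step1", 5.0, "whole")
        truth = solve_steady_state(pert)
        a = rank_targets(model, truth.c)
        b = rank_targets(model, truth.c)
        assert [(r.reaction_id, r.direction) for r in a] == [
            (r.reaction_id, r.direction) for r in b
        ]


class TestToleranceContributions:
    def test_single_dominant_reaction_gets_full_credit(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_inhibition_family(model)
        g = ExpressionVector(g={"cat": 2.0})
        tol_g = tolerance_inhibition(build, g, setup)
        tol_0 = tolerance_inhibition(build, ExpressionVector(), setup)
        assert tol_g > tol_0  # the up-regulated step buys tolerance
        assert ntc(build, g, ["cat"], setup, tol_ged=tol_g, tol_noged=tol_0) == pytest.approx(1.0)

    def test_unchanged_reaction_scores_zero(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_inhibition_family(model)
        g = ExpressionVector(g={"cat": 2.0})
        assert ntc(build, g, ["up"], setup) == 0.0

    def test_full_subset_scores_unity(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_inhibition_family(model)
        g = ExpressionVector(g={"cat": 1.7, "up": 1.2})
        assert ntc(build, g, ["cat", "up"], setup) == pytest.approx(1.0, abs=1e-9)

    def test_zero_reference_flux_reaction_is_uncoupled(self, yeast_kinetic_model):
        # pdh carries no flux in the fermentative reference state, so even
        # complete inhibition cannot wash the culture out
        from gemkin.fixtures import reference_chemostat

        base = yeast_kinetic_model.with_params(yeast_kinetic_model.params.replace())
        assert base.reference.v["pdh"] == 0.0
        model, setup = reference_chemostat(base)

        def build(k, expression):
            k = min(max(k, 1e-9), 1.0)
            return model.with_params(
                model.params.replace(inhibition={"pdh": k})
            ).with_expression(expression)

        depth = tolerance_inhibition(build, ExpressionVector(), setup)
        assert depth == pytest.approx(1.0)

    def test_undefined_when_expression_has_no_effect(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_inhibition_family(model)
        with pytest.raises(MetricError):
            ntc(build, ExpressionVector(), ["cat"], setup)

    def test_nuc_mirrors_ntc_algebra(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_woa_family(model)
        g = ExpressionVector(g={"up": 2.0})
        wur_g = tolerance_woa(build, g, setup)
        wur_0 = tolerance_woa(build, ExpressionVector(), setup)
        assert wur_g > wur_0
        assert nuc(build, g, ["up"], setup, wur_ged=wur_g, wur_noged=wur_0) == pytest.approx(1.0)
        assert nuc(build, g, ["cat"], setup, wur_ged=wur_g, wur_noged=wur_0) == 0.0

    def test_biomass_fraction_one_gives_zero_tolerance(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_woa_family(model)
        with pytest.raises(MetricError):
            tolerance_woa(build, ExpressionVector(), setup, biomass_fraction=1.0)

    def test_doubling_atp_cost_halves_tolerated_uptake(self, chemostat_toy_model):
        model, setup = chemostat_toy_model

        def family(atp_per_woa):
            def build(woa, expression):
                return model.with_params(
                    model.params.replace(
                        woa_uptake=float(woa), atp_per_woa=atp_per_woa
                    )
                ).with_expression(expression)

            return build

        w1 = tolerance_woa(family(2.0), ExpressionVector(), setup)
        w2 = tolerance_woa(family(4.0), ExpressionVector(), setup)
        assert w2 == pytest.approx(w1 / 2.0, rel=0.01)


class TestDoseResponse:
    def test_scenarios_and_monotonicity(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_woa_family(model)
        g = ExpressionVector(g={"up": 1.5, "cat": 1.3})
        grid = [0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 64.0, 80.0]
        curve = dose_response(build, g, grid, setup)
        frame = curve.to_frame()
        assert set(frame.columns) == {"GED", "NoGED", "extrapolated"}
        for name in frame.columns:
            values = frame[name].to_numpy()
            peak = int(np.argmax(values))
            assert all(a >= b - 1e-9 for a, b in zip(values[peak:], values[peak + 1 :]))
        # washout is encoded as exactly zero at the extreme dose
        assert frame["NoGED"].iloc[-1] == 0.0

    def test_no_ged_peaks_at_reference_point(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_woa_family(model)
        grid = [0.0, 0.5, 1.0, 2.0]
        curve = dose_response(build, ExpressionVector(), grid, setup)
        values = curve.biomass["NoGED"]
        assert values[0] == max(values)

    def test_extrapolated_outlasts_measured_expression(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        build = toy_woa_family(model)
        g = ExpressionVector(g={"up": 1.5})
        w_ged = tolerance_woa(build, g, setup)
        from gemkin import extrapolate_expression

        w_ext = tolerance_woa(build, extrapolate_expression(g, 2.0), setup)
        assert w_ext > w_ged

    def test_decreasing_grid_rejected(self, chemostat_toy_model):
        model, setup = chemostat_toy_model
        with pytest.raises(MetricError):
            dose_response(
                toy_woa_family(model), ExpressionVector(), [1.0, 0.5], setup
            )


class TestSensitivitySweep:
    def test_metric_stable_without_reversible_cycles(self):
        spec = FixtureSpec(topology="chain", n=4, fraction_reversible=0.5,
                           n_drains=1, seed=21)
        net, ref = make_toy_network(spec)
        truth = solve_steady_state(assemble_model(net, ref, {"step2": 1.8}))

        def build(beta):
            return assemble_model(
                net, ref, {"step2": 1.8}, RateParameters(beta_global=beta)
            )

        def metric(model):
            sol = solve_steady_state(model)
            return sse_log_concentrations(sol.c, truth.c)

        table = sensitivity_sweep(build, {"beta": [2.0, 10.0, 30.0, 100.0]}, metric)
        assert table["converged"].all()
        # the expression-change response barely depends on the split depth
        assert table["metric"].max() - table["metric"].min() < 0.05

    def test_alpha_zero_limit_matches_fixed_drains(self):
        spec = FixtureSpec(topology="chain", n=4, n_drains=1, seed=22)
        net, ref = make_toy_network(spec)

        def build(alpha):
            return assemble_model(net, ref, {"step2": 1.5},
                                  RateParameters(alpha=alpha))

        sol_tiny = solve_steady_state(build(1e-9))
        drains = [r.id for r in net.reactions if r.id.startswith("drain")]
        for d in drains:
            assert sol_tiny.r[d] == pytest.approx(ref.v[d], rel=1e-6)

    def test_duplicate_grid_points_identical_rows(self, chemostat_toy_model):
        model, setup = chemostat_toy_model

        def build(alpha):
            return model.with_params(model.params.replace(alpha=alpha))

        def metric(m):
            return solve_steady_state(m).residual_norm

        table = sensitivity_sweep(build, {"alpha": [0.1, 0.1]}, metric)
        assert table.iloc[0]["metric"] == table.iloc[1]["metric"]
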