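"""Fcirc arithmetic, enrichment model, network fitting and bootstrap CIs."""

import dataclasses

import numpy as np
import pytest

from gngflux import (
    FluxNetwork,
    InfusionExperiment,
    compute_fcirc,
    confidence_intervals,
    contribution_ratio,
    fit_network,
    predict_enrichments,
    simulate_invivo,
)
from gngflux.invivo import NODE_CARBONS, _enrichments_from_params
from gngflux.synthetic import InVivoGroundTruth, default_invivo_network


def make_experiment(tracer="glycerol", rate=0.375, enrichments=None):
    return InfusionExperiment(
        tracer=tracer,
        infusion_rate=rate,
        body_mass=25.0,
        steady_state_enrichments=enrichments or {"glycerol": 0.15},
    )


class TestFcirc:
    def test_equal_dilution_returns_infusion_rate(self):
        exp = make_experiment(enrichments={"glycerol": 0.5})
        assert compute_fcirc(exp).fcirc == pytest.approx(exp.infusion_rate)

    def test_standard_glycerol_infusion(self):
        # 150 mM at 0.1 ul/g/min = 15 nmol/g/min tracee; 15% enrichment
        exp = InfusionExperiment(
            tracer="glycerol",
            infusion_rate=15.0,  # nmol/g/min
            body_mass=25.0,
            steady_state_enrichments={"glycerol": 0.15},
        )
        assert compute_fcirc(exp).fcirc == pytest.approx(85.0)

    def test_vanishes_as_fraction_approaches_one(self):
        exp = make_experiment(enrichments={"glycerol": 1 - 1e-9})
        assert compute_fcirc(exp).fcirc == pytest.approx(0.0, abs=1e-6)

    def test_strictly_decreasing_in_fraction(self):
        values = [
            compute_fcirc(make_experiment(enrichments={"glycerol": f})).fcirc
            for f in np.linspace(0.05, 0.95, 25)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_per_gram_normalization(self):
        exp = make_experiment(enrichments={"glycerol": 0.5})
        assert compute_fcirc(exp, per_gram=True).fcirc == pytest.approx(
            exp.infusion_rate / exp.body_mass
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            InfusionExperiment(
                tracer="glycerol",
                infusion_rate=1.0,
                body_mass=25.0,
                steady_state_enrichments={"glycerol": 1.2},
            )


class TestContributionRatio:
    def test_sole_precursor(self):
        assert contribution_ratio(0.2, 0.2) == 1.0

    def test_glycerol_to_glucose_share(self):
        assert contribution_ratio(0.15, 0.09) == pytest.approx(0.60)

    def test_unlabeled_recipient(self):
        assert contribution_ratio(0.15, 0.0) == 0.0

    def test_noisy_exceedance_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            assert contribution_ratio(0.10, 0.11) == 1.0

    def test_zero_donor_rejected(self):
        with pytest.raises(ValueError):
            contribution_ratio(0.0, 0.1)


class TestEnrichmentModel:
    def test_closed_form_matches_linear_solver(self, rng):
        # oracle: assemble and solve the 3x3 steady-state balance directly
        for _ in range(50):
            f_lip, f_groglc_frac, f_lacglc, f_glclac_extra = rng.uniform(0.5, 10, 4)
            f_groglc = f_groglc_frac * f_lip / 10.0
            loss = rng.uniform(0, 1)
            f_glclac = f_lacglc + f_glclac_extra  # keep lactate sink >= 0
            params = np.array([f_lip, f_groglc, f_lacglc, f_glclac, loss])
            rates = [0.0, 0.0, 0.0]
            rates[int(rng.integers(3))] = rng.uniform(0.1, 3.0)
            r_gro, r_glc, r_lac = rates
            amat = np.array(
                [
                    [f_lip + r_gro, 0.0, 0.0],
                    [-f_groglc, f_groglc + f_lacglc + r_glc, -f_lacglc * (1 - loss)],
                    [0.0, -f_glclac, f_glclac + r_lac],
                ]
            )
            expected = np.linalg.solve(amat, np.array([r_gro, r_glc, r_lac]))
            np.testing.assert_allclose(
                _enrichments_from_params(params, tuple(rates)), expected, atol=1e-10
            )

    def test_network_balance_enforced(self):
        with pytest.raises(ValueError, match="imbalance"):
            FluxNetwork(
                lipolysis_to_glycerol=5.0,
                glycerol_to_glucose=5.4,
                glycerol_to_sink=1.0,
                lactate_to_glucose=8.0,
                glucose_to_lactate=12.0,
                glucose_to_sink=1.4,
                lactate_to_sink=4.0,
            )

    def test_lossless_glycerol_route(self):
        # all glucose from glycerol, no Cori return: e_glc = e_gro
        network = FluxNetwork.from_free_params(5.0, 5.0, 0.0, 0.0, 0.0)
        enriched = predict_enrichments(network, "glycerol", 1.0)
        assert enriched["glucose"] == pytest.approx(enriched["glycerol"])


class TestFitNetwork:
    def fit_noise_free(self, seed=3):
        gt = InVivoGroundTruth(noise_cv=0.0)
        experiments, _ = simulate_invivo(gt, 1)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        return gt, fit_network(experiments, fcircs, seed=seed)

    def test_noise_free_recovery_within_one_percent(self):
        gt, fit = self.fit_noise_free()
        for edge, truth in gt.network.edge_fluxes().items():
            estimate = fit.best_fit.edge_fluxes()[edge]
            assert estimate == pytest.approx(truth, rel=0.01, abs=0.01 * gt.network.lipolysis_to_glycerol)
        assert fit.best_fit.tca_loss == pytest.approx(gt.network.tca_loss, abs=0.01)

    def test_fitted_network_satisfies_node_balance(self):
        _, fit = self.fit_noise_free()
        net = fit.best_fit
        assert net.lipolysis_to_glycerol == pytest.approx(
            net.glycerol_to_glucose + net.glycerol_to_sink, rel=1e-6
        )
        assert net.glycerol_to_glucose + net.lactate_to_glucose == pytest.approx(
            net.glucose_to_lactate + net.glucose_to_sink, rel=1e-6
        )

    def test_invariant_to_experiment_ordering(self):
        gt = InVivoGroundTruth()
        experiments, _ = simulate_invivo(gt, 5)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        forward = fit_network(experiments, fcircs, seed=2, popsize=12, maxiter=80)
        backward = fit_network(list(reversed(experiments)), fcircs, seed=2, popsize=12, maxiter=80)
        np.testing.assert_allclose(
            forward.best_fit.free_params(), backward.best_fit.free_params(), rtol=1e-9
        )

    def test_units_rescaling_scales_fluxes_linearly(self):
        gt = InVivoGroundTruth(noise_cv=0.0)
        experiments, _ = simulate_invivo(gt, 1)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        fit_one = fit_network(experiments, fcircs, seed=2, popsize=12, maxiter=80)
        scale = 1000.0  # umol -> nmol
        scaled_exps = [
            dataclasses.replace(e, infusion_rate=e.infusion_rate * scale) for e in experiments
        ]
        scaled_fcircs = {e.infused_node: compute_fcirc(e) for e in scaled_exps}
        fit_two = fit_network(scaled_exps, scaled_fcircs, seed=2, popsize=12, maxiter=80)
        np.testing.assert_allclose(
            fit_two.best_fit.free_params()[:4], scale * fit_one.best_fit.free_params()[:4], rtol=1e-3
        )

    def test_wrong_experiment_set_rejected(self):
        gt = InVivoGroundTruth()
        experiments, _ = simulate_invivo(gt, 5)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        with pytest.raises(ValueError):
            fit_network(experiments[:2], fcircs, seed=1)


class TestConfidenceIntervals:
    def test_noise_free_intervals_are_degenerate(self):
        gt = InVivoGroundTruth(noise_cv=0.0)
        experiments, _ = simulate_invivo(gt, 1)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        fit = fit_network(experiments, fcircs, seed=3, popsize=12, maxiter=80)
        fit = confidence_intervals(fit, n_boot=60, seed=4)
        for edge, value in fit.best_fit.edge_fluxes().items():
            if value > 0.1:
                width = fit.ci_upper[edge] - fit.ci_lower[edge]
                assert width < 0.01 * value

    def test_bounds_bracket_best_fit(self):
        gt = InVivoGroundTruth()
        experiments, _ = simulate_invivo(gt, 9)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        fit = fit_network(experiments, fcircs, seed=3, popsize=12, maxiter=80)
        fit = confidence_intervals(fit, n_boot=60, seed=4, noise_cv=0.05)
        for edge, value in fit.estimates().items():
            assert fit.ci_lower[edge] <= value <= fit.ci_upper[edge]

    def test_null_glycerol_to_glucose_edge_ci_includes_zero(self):
        # gro->glc truly 0; balance then forces lac->glc == glc->lac
        network = FluxNetwork.from_free_params(4.0, 0.0, 6.0, 6.0, 0.3)
        gt = InVivoGroundTruth(network=network, noise_cv=0.02)
        experiments, _ = simulate_invivo(gt, 11)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        fit = fit_network(experiments, fcircs, seed=5, popsize=12, maxiter=80)
        fit = confidence_intervals(fit, n_boot=60, seed=6, noise_cv=0.02)
        assert fit.ci_lower["glycerol_to_glucose"] <= 0.05 * network.lipolysis_to_glycerol

    def test_small_n_boot_warns(self):
        gt = InVivoGroundTruth(noise_cv=0.0)
        experiments, _ = simulate_invivo(gt, 1)
        fcircs = {e.infused_node: compute_fcirc(e) for e in experiments}
        fit = fit_network(experiments, fcircs, seed=3, popsize=12, maxiter=80)
        with pytest.warns(UserWarning, match="n_boot"):
            confidence_intervals(fit, n_boot=10, seed=4)
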