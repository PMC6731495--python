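"""Fitting objectives and per-cell parameter recovery.

The full four-parameter stage-one recovery lives in the acceptance suite;
here the objectives are checked against self-matches and perturbations, and
the cheap one/two-parameter per-cell fits against their generating values.
"""

import numpy as np
import pytest

import ornsim as o
from ornsim.fitting import AveragePulseProtocol, average_targets_from_recordings


@pytest.fixture(scope="module")
def targets():
    """Model-generated dose-resolved average pulse responses at defaults."""
    return o.simulate_average_responses()


@pytest.fixture(scope="module")
def delta_tau_cell():
    """Synthetic cell generated with (delta, tau) = (0.5, 1.2) mV.s / s."""
    thr = o.ThresholdParams(delta=0.5, tau=1.2)
    return o.generate_recording(thr, dose_pg=100, bin_s=0.05, seed=11, cell_id=0)


TRUTH = {"n": 0.056, "gamma": 99.27, "tau": 0.58, "delta": 0.77}


class TestIseAverage:
    def test_self_match_is_zero(self, targets):
        assert o.ise_average(TRUTH, targets) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("param,factor", [("gamma", 1.1), ("tau", 0.8),
                                              ("delta", 1.3), ("n", 1.2)])
    def test_perturbation_increases_objective(self, targets, param, factor):
        perturbed = {**TRUTH, param: TRUTH[param] * factor}
        assert o.ise_average(perturbed, targets) > 1.0

    def test_single_dose_sums_one_term(self, targets):
        one = {1e-5: targets[1e-5]}
        full = o.ise_average({**TRUTH, "gamma": 110.0}, targets)
        single = o.ise_average({**TRUTH, "gamma": 110.0}, one)
        parts = sum(
            o.ise_average({**TRUTH, "gamma": 110.0}, {L: targets[L]})
            for L in targets
        )
        assert single < full
        assert parts == pytest.approx(full, rel=1e-9)


class TestIseIndividual:
    def test_self_match_near_zero(self, delta_tau_cell):
        rec = delta_tau_cell
        grid = o.rate_grid(1.0, 11.0, 0.001)
        data = o.kernel_rate(rec.spikes, grid)
        e = o.ise_individual(
            {"delta": 0.5, "tau": 1.2}, rec.stimulus, data, (1.0, 11.0)
        )
        # burn-in covers [0, 1] exactly, so the self-match is exact
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_increases_objective(self, delta_tau_cell):
        rec = delta_tau_cell
        grid = o.rate_grid(1.0, 11.0, 0.001)
        data = o.kernel_rate(rec.spikes, grid)
        e = o.ise_individual(
            {"delta": 0.75, "tau": 1.2}, rec.stimulus, data, (1.0, 11.0)
        )
        assert e > 10.0

    def test_zero_length_window(self, delta_tau_cell):
        rec = delta_tau_cell
        grid = o.rate_grid(1.0, 11.0, 0.001)
        data = o.kernel_rate(rec.spikes, grid)
        assert o.ise_individual({}, rec.stimulus, data, (5.0, 5.0)) == 0.0


class TestFitCell:
    def test_delta_tau_recovery(self, delta_tau_cell):
        rec = delta_tau_cell
        fit = o.fit_cell(rec.stimulus, rec.spikes, "delta_tau")
        assert fit.params["delta"] == pytest.approx(0.5, rel=0.10)
        assert fit.params["tau"] == pytest.approx(1.2, rel=0.10)

    def test_gamma_recovery(self):
        mem = o.MembraneParams(gamma=120.0)
        rec = o.generate_recording(
            o.ThresholdParams(), dose_pg=100, bin_s=0.05, seed=12, mem=mem
        )
        fit = o.fit_cell(rec.stimulus, rec.spikes, "gamma")
        assert fit.params["gamma"] == pytest.approx(120.0, rel=0.10)

    def test_homogeneous_equals_objective_at_defaults(self, delta_tau_cell):
        rec = delta_tau_cell
        fit = o.fit_cell(rec.stimulus, rec.spikes, "homogeneous")
        grid = o.rate_grid(1.0, 11.0, 0.001)
        data = o.kernel_rate(rec.spikes, grid)
        direct = o.ise_individual({}, rec.stimulus, data, (1.0, 11.0))
        assert fit.params == {}
        assert fit.objective == pytest.approx(direct, rel=1e-9)

    def test_scheme_nesting(self, delta_tau_cell):
        # richer schemes fit at least as well, up to optimizer tolerance
        rec = delta_tau_cell
        e_hom = o.fit_cell(rec.stimulus, rec.spikes, "homogeneous").objective
        e_dt = o.fit_cell(rec.stimulus, rec.spikes, "delta_tau").objective
        e_gdt = o.fit_cell(rec.stimulus, rec.spikes, "gamma_delta_tau").objective
        assert e_dt <= e_hom * 1.001
        assert e_gdt <= e_dt * 1.05 + 1.0

    def test_unknown_scheme_rejected(self, delta_tau_cell):
        rec = delta_tau_cell
        with pytest.raises(ValueError, match="scheme"):
            o.fit_cell(rec.stimulus, rec.spikes, "everything")


class TestEvaluatePrediction:
    def test_generator_scores_near_one(self, delta_tau_cell):
        rec = delta_tau_cell
        truth_fit = o.FitResult(
            "delta_tau", {"delta": 0.5, "tau": 1.2},
            {"kin": o.KineticParams(), "mem": o.MembraneParams(),
             "thr": o.ThresholdParams()}, 0.0,
        )
        r2 = o.evaluate_prediction(rec.stimulus, rec.spikes, truth_fit)
        assert r2 > 0.9

    def test_wrong_parameters_score_worse(self, delta_tau_cell):
        rec = delta_tau_cell
        fixed = {"kin": o.KineticParams(), "mem": o.MembraneParams(),
                 "thr": o.ThresholdParams()}
        good = o.FitResult("delta_tau", {"delta": 0.5, "tau": 1.2}, fixed, 0.0)
        bad = o.FitResult("delta_tau", {"delta": 1.5, "tau": 0.3}, fixed, 0.0)
        r2_good = o.evaluate_prediction(rec.stimulus, rec.spikes, good)
        r2_bad = o.evaluate_prediction(rec.stimulus, rec.spikes, bad)
        assert r2_bad < r2_good


class TestPopulationSummary:
    def _fit(self, delta, tau, e=1.0):
        return o.FitResult("delta_tau", {"delta": delta, "tau": tau}, {}, e)

    def test_hand_built_table(self):
        fits = [self._fit(0.4, 1.0), self._fit(0.6, 1.4),
                self._fit(0.5, 1.2), self._fit(0.3, 1.6)]
        r2 = [0.5, 0.7, 0.9, 0.6]
        s = o.population_summary(fits, r2)
        d = np.array([0.4, 0.6, 0.5, 0.3])
        t = np.array([1.0, 1.4, 1.2, 1.6])
        assert s.mean["delta"] == pytest.approx(d.mean())
        assert s.sd["tau"] == pytest.approx(t.std(ddof=1))
        assert s.corr_delta_tau == pytest.approx(np.corrcoef(d, t)[0, 1])
        assert s.r2_median == pytest.approx(0.65)
        assert s.r2_iqr[0] == pytest.approx(np.percentile(r2, 25))

    def test_identical_cells_flagged(self):
        fits = [self._fit(0.5, 1.2), self._fit(0.5, 1.2)]
        s = o.population_summary(fits, [0.8, 0.8])
        assert s.sd["delta"] == 0.0
        assert np.isnan(s.corr_delta_tau)

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            o.population_summary([self._fit(0.5, 1.2)], [0.9])


class TestAverageTargets:
    def test_targets_from_pulse_like_recordings(self):
        # a recording whose valve pattern contains qualifying puffs yields
        # a target trace per dose, on the protocol grid
        cells = [
            o.generate_recording(o.ThresholdParams(), dose_pg=dose,
                                 bin_s=0.1, seed=20 + i, cell_id=i)
            for i, dose in enumerate([100, 100, 1000])
        ]
        proto = AveragePulseProtocol(post_s=0.0)
        targets = average_targets_from_recordings(cells, proto)
        assert set(targets) <= {1e-5, 1e-4}
        for tr in targets.values():
            assert tr.time.shape == proto.grid().shape
            assert tr.rate.max() > 0
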