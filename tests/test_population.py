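import numpy as np
import pytest

from nfkbpulse import (ModelParameters, parse_protocol, simulate_cell)
from nfkbpulse.population import (CellSpec, DistributedParam, NoiseMode,
                                  PopulationSpec, calibrate_ikkk_distribution,
                                  discordant_fraction,
                                  equilibrated_pulse_experiment,
                                  response_threshold, run_population,
                                  sample_population, simulate_cell_intrinsic)
from nfkbpulse.protocols import two_pulse
from nfkbpulse.traces import classify_responder_model


class TestSampling:
    def test_zero_sd_gives_identical_cells(self, nominal):
        spec = PopulationSpec(n_cells=5, distributed_params={
            "IKKKtott_T": DistributedParam(1e6, 0.0)}, rng_seed=1)
        cells = sample_population(spec, nominal)
        assert all(c.overrides["IKKKtott_T"] == 1e6 for c in cells)

    def test_truncated_normal_moments(self, nominal):
        # sd small relative to mean: truncation negligible, moments recovered
        spec = PopulationSpec(n_cells=100_000, distributed_params={
            "IKKKtott_T": DistributedParam(1e6, 3e5)}, rng_seed=2)
        draws = np.array([c.overrides["IKKKtott_T"]
                          for c in sample_population(spec, nominal)])
        assert abs(draws.mean() - 1e6) / 1e6 < 0.01
        assert abs(draws.std() - 3e5) / 3e5 < 0.02
        assert draws.min() > 0

    def test_lognormal_support_positive(self, nominal):
        spec = PopulationSpec(n_cells=5000, distributed_params={
            "c1a": DistributedParam(1.0, 0.5, family="lognormal")}, rng_seed=3)
        draws = np.array([c.overrides["c1a"] for c in sample_population(spec, nominal)])
        assert np.all(draws > 0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            PopulationSpec(n_cells=2, distributed_params={
                "not_a_rate": DistributedParam(1.0, 0.1)})

    def test_reproducible_given_seed(self, nominal):
        spec = PopulationSpec(n_cells=10, distributed_params={
            "IKKKtott_T": DistributedParam(1e6, 2e5)}, rng_seed=7)
        a = sample_population(spec, nominal)
        b = sample_population(spec, nominal)
        assert [c.overrides for c in a] == [c.overrides for c in b]


class TestRunPopulation:
    def test_degenerate_population_matches_single_cell(self, nominal):
        proto = parse_protocol("T@0", t_end=150.0)
        cells = [CellSpec("c0", {}, seed=0)]
        [traj] = run_population(cells, proto, base=nominal)
        ref = simulate_cell(nominal, proto)
        np.testing.assert_allclose(traj.y, ref.y, rtol=1e-6, atol=1e-3)

    def test_extrinsic_mode_deterministic(self, nominal):
        proto = two_pulse(70.0, tail=60.0)
        spec = PopulationSpec(n_cells=8, distributed_params={
            "IKKKtott_T": DistributedParam(1e6, 3e5)}, rng_seed=5)
        cells = sample_population(spec, nominal)
        calls1 = [classify_responder_model(t, 70.0)[0]
                  for t in run_population(cells, proto, base=nominal)]
        calls2 = [classify_responder_model(t, 70.0)[0]
                  for t in run_population(cells, proto, base=nominal)]
        assert calls1 == calls2

    def test_empty_population_rejected(self, nominal):
        with pytest.raises(ValueError):
            run_population([], two_pulse(60.0), base=nominal)

    def test_failure_reports_cell_id(self, nominal):
        cells = [CellSpec("badcell", {"IKKKtott_T": float("nan")}, seed=0)]
        with pytest.raises(RuntimeError, match="badcell"):
            run_population(cells, two_pulse(60.0), base=nominal)


class TestThresholdAndCalibration:
    def test_threshold_between_responding_and_refractory(self, nominal):
        """Cells above θ(Δ) respond to the second pulse, cells below do not."""
        theta = response_threshold(70.0, nominal)
        proto = two_pulse(70.0, tail=60.0)
        hi = simulate_cell(nominal.replace(IKKKtott_T=1.3 * theta), proto)
        lo = simulate_cell(nominal.replace(IKKKtott_T=0.7 * theta), proto)
        assert classify_responder_model(hi, 70.0)[0]
        assert not classify_responder_model(lo, 70.0)[0]

    def test_threshold_decreases_with_interval(self, nominal):
        """Longer recovery time means smaller IKKK pools suffice."""
        t60 = response_threshold(60.0, nominal)
        t100 = response_threshold(100.0, nominal)
        assert t100 < t60

    def test_median_threshold_maps_to_half_fraction(self, nominal):
        """Quantile oracle: a fraction of 1/2 at some interval puts θ at the
        distribution median, i.e. ≈ μ for a mildly truncated normal."""
        cal = calibrate_ikkk_distribution({60.0: 0.30, 70.0: 0.70}, nominal)
        theta_mid = np.interp(0.5, [0.30, 0.70],
                              [cal.thresholds[60.0], cal.thresholds[70.0]])
        assert abs(theta_mid - cal.mu) < 0.25 * cal.mu

    def test_sigma_matches_closed_form_quantiles(self, nominal):
        """Construct fractions analytically from known thresholds: the fitted
        σ must recover the generating σ (brute-force grid agrees with the
        optimizer to 1%)."""
        from scipy.stats import norm
        cal = calibrate_ikkk_distribution(
            {50.0: 0.05, 60.0: 0.30, 70.0: 0.70, 100.0: 0.93}, nominal)
        # regenerate fractions exactly from the fitted normal, re-fit
        fr = {d: cal.fraction_above(th) for d, th in cal.thresholds.items()}
        cal2 = calibrate_ikkk_distribution(fr, nominal)
        assert cal2.sigma == pytest.approx(cal.sigma, rel=0.01)
        # independent brute-force grid on sigma
        sig_grid = np.linspace(0.5 * cal.sigma, 2 * cal.sigma, 400)
        def sse(s):
            z0 = norm.cdf(-cal.mu / s)
            return sum(((1 - norm.cdf((cal.thresholds[d] - cal.mu) / s)) / (1 - z0)
                        - fr[d]) ** 2 for d in fr)
        best = sig_grid[np.argmin([sse(s) for s in sig_grid])]
        assert best == pytest.approx(cal.sigma, rel=0.01)

    def test_non_monotone_fractions_rejected(self, nominal):
        with pytest.raises(ValueError, match="non-decreasing"):
            calibrate_ikkk_distribution({50.0: 0.5, 60.0: 0.3}, nominal)

    def test_all_responding_is_degenerate(self, nominal):
        cal = calibrate_ikkk_distribution({60.0: 1.0, 70.0: 1.0}, nominal)
        assert cal.degenerate
        assert np.isinf(cal.sigma)


class TestIntrinsicNoise:
    def test_reproducible_per_seed(self, nominal):
        proto = two_pulse(70.0, tail=50.0)
        cell = CellSpec("c0", {}, seed=42, noise_mode=NoiseMode.intrinsic)
        a = simulate_cell_intrinsic(cell, proto, base=nominal)
        b = simulate_cell_intrinsic(cell, proto, base=nominal)
        np.testing.assert_array_equal(a.y, b.y)

    def test_bad_rates_rejected(self, nominal):
        cell = CellSpec("c0", {}, seed=0, noise_mode=NoiseMode.intrinsic)
        with pytest.raises(ValueError):
            simulate_cell_intrinsic(cell, two_pulse(70.0), base=nominal,
                                    switch_on=0.0)

    def test_fast_switching_approaches_deterministic(self, nominal):
        """With very fast gene switching the telegraph average converges to
        the deterministic trajectory."""
        proto = parse_protocol("T@0", t_end=150.0)
        cell = CellSpec("c0", {}, seed=3, noise_mode=NoiseMode.intrinsic)
        fast = simulate_cell_intrinsic(cell, proto, base=nominal,
                                       switch_on=50.0, switch_off=25.0)
        det = simulate_cell(nominal, proto)
        nf_f, nf_d = fast.nfkb_nuclear_fraction, det.nfkb_nuclear_fraction
        assert np.max(np.abs(nf_f - nf_d)) < 0.1

    def test_runs_differ_between_seeds(self, nominal):
        proto = two_pulse(70.0, tail=50.0)
        a = simulate_cell_intrinsic(CellSpec("c0", {}, 1, NoiseMode.intrinsic),
                                    proto, base=nominal)
        b = simulate_cell_intrinsic(CellSpec("c0", {}, 2, NoiseMode.intrinsic),
                                    proto, base=nominal)
        assert not np.allclose(a.y, b.y)


class TestEquilibratedPulses:
    def test_extrinsic_calls_identical_across_pairs(self, nominal):
        spec = PopulationSpec(n_cells=6, distributed_params={
            "IKKKtott_T": DistributedParam(1e6, 2.5e5)}, rng_seed=9)
        cells = sample_population(spec, nominal)
        calls = equilibrated_pulse_experiment(cells, delta=70.0, gap=480.0,
                                              base=nominal)
        assert discordant_fraction(calls) == 0.0

    def test_short_gap_rejected(self, nominal):
        cells = [CellSpec("c0", {}, seed=0)]
        with pytest.raises(ValueError, match="gap"):
            equilibrated_pulse_experiment(cells, delta=70.0, gap=120.0,
                                          base=nominal)
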