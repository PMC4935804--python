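import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nfkbpulse.traces import (RefractoryDistribution, ResponseTable, TraceTable,
                              amplitude_ratio, auc_nuclear,
                              classify_responder_model, classify_responder_trace,
                              cluster_responders, dominant_period,
                              fraction_responding, pair_concordance,
                              pca_subtrajectories, peak_to_peak,
                              refractory_distribution)


def synth_table(n_cells=6, t_end=400.0, dt=1.0, period=100.0, dip_at=None,
                dip_depth=0.4, seed=0):
    """Small analytic trace table: cosine IκBα oscillation, optional extra
    dip (degradation response) after ``dip_at`` for the first half of cells."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    ik, nt = {}, {}
    for i in range(n_cells):
        y = 1.0 + 0.3 * np.cos(2 * np.pi * t / period)
        if dip_at is not None and i < n_cells // 2:
            y = y - dip_depth * np.exp(-0.5 * ((t - dip_at - 28.0) / 10.0) ** 2)
        ik[f"c{i}"] = y
        nt[f"c{i}"] = 0.3 + 0.25 * np.sin(2 * np.pi * t / period)
    return TraceTable(t, pd.DataFrame(ik), pd.DataFrame(nt))


class TestResponderRules:
    def test_flat_trajectory_is_nonresponder(self, nominal):
        from nfkbpulse import simulate_cell
        from nfkbpulse.protocols import StimulationProtocol
        traj = simulate_cell(nominal, StimulationProtocol((), t_end=400.0))
        resp, net = classify_responder_model(traj, 100.0)
        assert not resp and net == pytest.approx(0.0, abs=1e-3)

    def test_threshold_is_strict(self, nominal):
        # a net amplitude of exactly 15% must NOT qualify (rule is strict >)
        from nfkbpulse.model import N_STATE, Trajectory
        from nfkbpulse.protocols import parse_protocol
        t = np.arange(0.0, 100.0, 1.0)
        y = np.zeros((len(t), N_STATE))
        y[:, 7] = np.where(t >= 20.0, 0.15 * nominal.nfkbtot, 0.0)
        traj = Trajectory(t=t, y=y, params=nominal,
                          protocol=parse_protocol("T@0", t_end=100.0))
        resp, net = classify_responder_model(traj, 0.0)
        assert net == pytest.approx(0.15, abs=1e-12)
        assert not resp

    def test_first_pulse_always_responds(self, single_pulse_traj):
        resp, net = classify_responder_model(single_pulse_traj, 0.0)
        assert resp and net > 0.3

    def test_window_must_be_covered(self, single_pulse_traj):
        with pytest.raises(ValueError):
            classify_responder_model(single_pulse_traj, 400.0)

    def test_rescaling_invariance(self, nominal):
        """The model rule works on fractions of total NF-κB, so uniformly
        rescaling the molecule unit must not change the call."""
        from nfkbpulse import parse_protocol, simulate_cell
        scale = 2.5
        p2 = nominal.replace(
            IKKKtott_T=nominal.IKKKtott_T * scale,
            IKKKtott_I=nominal.IKKKtott_I * scale,
            IKKtot=nominal.IKKtot * scale, nfkbtot=nominal.nfkbtot * scale,
            sIKKK=nominal.sIKKK * scale, kA20_T=nominal.kA20_T * scale,
            kA20_I=nominal.kA20_I * scale, k_nfkb_half=nominal.k_nfkb_half * scale,
            k_assoc=nominal.k_assoc / scale, k_ikk_deg=nominal.k_ikk_deg / scale,
            k_ikk_deg_c=nominal.k_ikk_deg_c / scale,
            c1=nominal.c1 * scale, c1a=nominal.c1a * scale)
        proto = parse_protocol("T@0,T@60", t_end=200.0)
        t1 = simulate_cell(nominal, proto)
        t2 = simulate_cell(p2, proto)
        for pt in (0.0, 60.0):
            r1, n1 = classify_responder_model(t1, pt)
            r2, n2 = classify_responder_model(t2, pt)
            assert r1 == r2
            assert n1 == pytest.approx(n2, rel=5e-2)

    def test_gradient_rule_rising_trace_is_nonresponder(self):
        t = np.arange(0.0, 200.0, 1.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": 1.0 + 0.002 * t}))
        assert not classify_responder_trace(tbl, 60.0, cell_id="c0")

    def test_gradient_rule_recovers_synthetic_dips(self):
        tbl = synth_table(n_cells=10, dip_at=60.0)
        calls = classify_responder_trace(tbl, 60.0)
        assert calls[:5].all() and not calls[5:].any()

    def test_gradient_rule_needs_enough_samples(self):
        t = np.arange(0.0, 200.0, 15.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}))
        with pytest.raises(ValueError, match="3 samples"):
            classify_responder_trace(tbl, 60.0, cell_id="c0")


class TestFractionsAndRefractory:
    def test_fraction_all_true(self):
        rt = ResponseTable.from_calls([("a", 2, True, 0.3, 80.0),
                                       ("b", 2, True, 0.2, 82.0)])
        assert fraction_responding(rt, 2) == (1.0, 2)

    def test_empty_table_rejected(self):
        rt = ResponseTable.from_calls([])
        with pytest.raises(ValueError):
            fraction_responding(rt, 2)

    def test_printed_fraction_curve_masses(self):
        """The measured fraction curve implies 40% of cells refractory
        between 60 and 70 min, 25% between 50 and 60, 5% below 50."""
        dist = refractory_distribution({50: 0.05, 60: 0.30, 70: 0.70, 100: 0.93})
        s = dist.as_series()
        assert s["[60,70)"] == pytest.approx(0.40)
        assert s["[50,60)"] == pytest.approx(0.25)
        assert s["[70,100)"] == pytest.approx(0.23)
        assert s["<50"] == pytest.approx(0.05)
        assert s[">=100"] == pytest.approx(0.07)

    def test_all_responding_mass_below_smallest(self):
        dist = refractory_distribution({50: 1.0, 60: 1.0})
        assert dist.as_series()["<50"] == pytest.approx(1.0)

    def test_noisy_nonmonotone_clipped_and_renormalized(self):
        with pytest.warns(UserWarning, match="clipped"):
            dist = refractory_distribution({50: 0.40, 60: 0.35, 70: 0.80})
        assert dist.mass.min() >= 0.0
        assert dist.mass.sum() == pytest.approx(1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_masses_sum_to_one_and_invert_to_fractions(self, raw):
        fr = dict(zip(np.arange(50.0, 50.0 + 10 * len(raw), 10.0), sorted(raw)))
        dist = refractory_distribution(fr)
        assert dist.mass.sum() == pytest.approx(1.0)
        # cumulative masses reproduce the input fractions
        cum = np.cumsum(dist.mass)
        for i, d in enumerate(sorted(fr)):
            assert cum[i] == pytest.approx(fr[d], abs=1e-9)


class TestAmplitudeAndAUC:
    def test_identical_responses_give_unit_ratio(self):
        t = np.arange(0.0, 200.0, 1.0)
        bump = lambda c: 0.2 + 0.4 * np.exp(-0.5 * ((t - c) / 6.0) ** 2)
        nt = bump(25.0) + bump(125.0) - 0.2
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}),
                         pd.DataFrame({"c0": np.clip(nt, 0, 1)}))
        r = amplitude_ratio(tbl, [0.0, 100.0], cell_id="c0")
        assert r == pytest.approx(1.0, abs=0.05)

    def test_zero_first_amplitude_rejected(self):
        t = np.arange(0.0, 200.0, 1.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}),
                         pd.DataFrame({"c0": np.full_like(t, 0.2)}))
        with pytest.raises(ValueError):
            amplitude_ratio(tbl, [0.0, 100.0], cell_id="c0")

    def test_auc_zero_trace(self):
        t = np.arange(0.0, 100.0, 1.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}),
                         pd.DataFrame({"c0": np.zeros_like(t)}))
        assert auc_nuclear(tbl, cell_id="c0") == 0.0

    def test_auc_rectangular_bump_equals_width(self):
        t = np.arange(0.0, 100.0, 1.0)
        nt = np.where((t >= 20) & (t < 50), 0.5, 0.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}),
                         pd.DataFrame({"c0": nt}))
        # unit-height normalized bump of width 30 -> area 30 (trapezoid edges)
        assert auc_nuclear(tbl, cell_id="c0") == pytest.approx(30.0, abs=1.5)


class TestPeriods:
    def test_sinusoid_trough_spacing(self):
        tbl = synth_table(n_cells=1, period=100.0)
        gaps = peak_to_peak(tbl, cell_id="c0")
        assert np.allclose(gaps, 100.0, atol=2.0)

    def test_two_troughs_single_interval(self):
        t = np.arange(0.0, 200.0, 1.0)
        y = 1.0 - 0.4 * (np.exp(-0.5 * ((t - 35) / 6) ** 2)
                         + np.exp(-0.5 * ((t - 140) / 6) ** 2))
        tbl = TraceTable(t, pd.DataFrame({"c0": y}))
        gaps = peak_to_peak(tbl, cell_id="c0")
        assert list(gaps) == [pytest.approx(105.0, abs=1.0)]

    def test_too_few_troughs_empty(self):
        t = np.arange(0.0, 100.0, 1.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": 1.0 + 0.001 * t}))
        assert len(peak_to_peak(tbl, cell_id="c0")) == 0

    def test_dominant_period_pure_sinusoid(self):
        t = np.arange(0.0, 800.0, 5.0)
        y = 1.0 + 0.3 * np.cos(2 * np.pi * t / 100.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": y}))
        assert dominant_period(tbl, cell_id="c0") == pytest.approx(100.0, rel=0.05)

    def test_dominant_component_wins(self):
        t = np.arange(0.0, 800.0, 5.0)
        y = 1.0 + 0.3 * np.cos(2 * np.pi * t / 100.0) + 0.05 * np.cos(2 * np.pi * t / 50.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": y}))
        assert dominant_period(tbl, cell_id="c0") == pytest.approx(100.0, rel=0.05)

    def test_constant_trace_rejected(self):
        t = np.arange(0.0, 800.0, 5.0)
        tbl = TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}))
        with pytest.raises(ValueError):
            dominant_period(tbl, cell_id="c0")

    def test_agrees_with_trough_spacing_on_clean_oscillation(self):
        tbl = synth_table(n_cells=1, t_end=800.0, period=110.0)
        p1 = dominant_period(tbl, cell_id="c0")
        p2 = peak_to_peak(tbl, cell_id="c0").mean()
        assert abs(p1 - p2) / p2 < 0.1


class TestClusteringAndPairs:
    def test_well_separated_groups_recovered(self):
        tbl = synth_table(n_cells=12, dip_at=60.0, dip_depth=0.5)
        labels = cluster_responders(tbl, 60.0)
        assert labels[:6].all() and not labels[6:].any()

    def test_single_cell_rejected(self):
        tbl = synth_table(n_cells=1)
        with pytest.raises(ValueError):
            cluster_responders(tbl, 60.0)

    def test_cluster_agrees_with_gradient_rule(self):
        tbl = synth_table(n_cells=20, dip_at=60.0, dip_depth=0.5)
        km = cluster_responders(tbl, 60.0)
        grad = classify_responder_trace(tbl, 60.0)
        assert (km == grad).mean() >= 0.95

    def test_pca_identical_cells_coincide(self):
        tbl = synth_table(n_cells=4, seed=1)
        emb = pca_subtrajectories(tbl, [(0.0, 140.0), (200.0, 340.0)])
        for w in (0, 1):
            pts = emb.xs(w, level="window").to_numpy()
            assert np.allclose(pts, pts[0], atol=1e-8)

    def test_pca_separates_and_keeps_cells_together(self):
        tbl = synth_table(n_cells=12, dip_at=60.0, dip_depth=0.6, t_end=500.0)
        emb = pca_subtrajectories(tbl, [(0.0, 140.0), (0.0, 140.0)])
        ev = emb.attrs["explained_variance"]
        assert ev[0] >= ev[1]
        # responders and non-responders separate on PC1
        pc1 = emb.xs(0, level="window")["pc1"]
        a, b = pc1.iloc[:6].mean(), pc1.iloc[6:].mean()
        gap = abs(a - b)
        spread = max(pc1.iloc[:6].std(), pc1.iloc[6:].std())
        assert gap > 3 * spread

    def test_pair_concordance_identical_twins(self):
        rt = ResponseTable.from_calls([(f"c{i}", 2, i % 2 == 0, 0.2, 80.0)
                                       for i in range(6)])
        pairs = [("c0", "c2"), ("c1", "c3")]   # same parity -> same call
        assert pair_concordance(rt, pairs, 2) == 1.0

    def test_pair_concordance_random_calls_near_half(self):
        rng = np.random.default_rng(0)
        calls = rng.random(2000) < 0.5
        rt = ResponseTable.from_calls([(f"c{i}", 2, bool(calls[i]), 0.2, 80.0)
                                       for i in range(2000)])
        pairs = [(f"c{2*i}", f"c{2*i+1}") for i in range(1000)]
        assert pair_concordance(rt, pairs, 2) == pytest.approx(0.5, abs=0.05)

    def test_unmatched_pair_rejected(self):
        rt = ResponseTable.from_calls([("a", 2, True, 0.2, 80.0)])
        with pytest.raises(ValueError):
            pair_concordance(rt, [("a", "missing")], 2)


class TestTraceTableIO:
    def test_long_format_roundtrip(self, tmp_path):
        tbl = synth_table(n_cells=3)
        f = tmp_path / "traces.tsv"
        tbl.save(f)
        back = TraceTable.load(f)
        np.testing.assert_allclose(back.time, tbl.time)
        # loader re-normalizes to t=0; original is already normalized there
        np.testing.assert_allclose(back.ikba.to_numpy(),
                                   tbl.normalized().ikba.to_numpy(), rtol=1e-9)

    def test_nt_ratio_bounds_enforced(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(ValueError, match="N/T"):
            TraceTable(t, pd.DataFrame({"c0": np.ones_like(t)}),
                       pd.DataFrame({"c0": np.full_like(t, 1.5)}))
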