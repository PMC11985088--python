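"""Gating simulator: dwell statistics, acquisition physics, growth model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats
from scipy.integrate import solve_ivp

from singlechan.gatingsim import (
    AcquisitionConfig,
    GatingModel,
    GrowthModel,
    PanelEntry,
    VoltageProtocol,
    bessel_lowpass,
    default_panel,
    make_panel,
    render_trace,
    sample_dwells,
    simulate_growth,
    simulate_recording,
    slow_gate_model,
    wildtype_model,
)


def pinned_fast(**kw):
    """Model with the flicker gate pinned open."""
    return GatingModel(fast_open_rate0=1.0, fast_close_rate0=0.0, **kw)


class TestSampleDwells:
    def test_symmetric_rates_give_half_open(self):
        m = pinned_fast(genotype_label="sym", g_true=100.0,
                        slow_open_rate0=2.0, slow_close_rate0=2.0)
        fracs = [sample_dwells(m, 0.0, 100.0, s).conducting_fraction
                 for s in range(20)]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_stationary_fraction_low_po(self):
        # closed-form stationary open fraction k_open/(k_open+k_close) = 0.1
        m = pinned_fast(genotype_label="p01", g_true=100.0,
                        slow_open_rate0=1.0, slow_close_rate0=9.0)
        fracs = [sample_dwells(m, 0.0, 500.0, s).conducting_fraction
                 for s in range(50)]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.1) < 3 * se

    def test_absorbing_open_state(self):
        # both close rates zero and stationary start -> permanently conducting
        m = GatingModel("open", g_true=100.0, slow_open_rate0=5.0,
                        slow_close_rate0=0.0, fast_open_rate0=5.0,
                        fast_close_rate0=0.0)
        d = sample_dwells(m, 0.0, 10.0, 0)
        assert d.states.size == 1
        assert bool(d.states[0]) is True
        assert d.durations[0] == pytest.approx(10.0)

    def test_determinism(self):
        m = wildtype_model()
        a = sample_dwells(m, -140.0, 5.0, 123)
        b = sample_dwells(m, -140.0, 5.0, 123)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.durations, b.durations)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            sample_dwells(wildtype_model(), 0.0, 0.0, 0)

    def test_rate_overflow_names_rate(self):
        m = GatingModel("hot", g_true=100.0, slow_open_rate0=1.0,
                        slow_close_rate0=1.0, slow_z_open=50.0)
        with pytest.raises(ValueError, match="slow_open"):
            sample_dwells(m, 160.0, 1.0, 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        k_open=st.floats(0.5, 200.0),
        k_close=st.floats(0.5, 200.0),
        duration=st.floats(0.5, 5.0),
        seed=st.integers(0, 2**20),
    )
    def test_conservation_and_alternation(self, k_open, k_close, duration, seed):
        m = pinned_fast(genotype_label="h", g_true=10.0,
                        slow_open_rate0=k_open, slow_close_rate0=k_close)
        d = sample_dwells(m, 0.0, duration, seed)
        assert d.durations.sum() == pytest.approx(duration, rel=1e-9)
        assert not np.any(d.states[1:] == d.states[:-1])
        assert np.all(d.durations > 0)


class TestRenderTrace:
    def test_constant_conducting_level(self):
        # i = g * V: 174 pS at +100 mV -> 17.4 pA
        m = GatingModel("wt-level", g_true=174.0, slow_open_rate0=1.0,
                        slow_close_rate0=0.0, fast_open_rate0=1.0,
                        fast_close_rate0=0.0)
        d = sample_dwells(m, 100.0, 1.0, 0)
        acq = AcquisitionConfig(noise_sd=0.0, duration=1.0)
        tr = render_trace(d, m, 100.0, acq, 0)
        settled = tr.samples[100:]  # skip the causal filter transient
        assert np.allclose(settled, 17.4, atol=1e-6)

    def test_reversal_potential_gives_zero(self):
        m = wildtype_model()
        d = sample_dwells(m, m.e_rev, 1.0, 1)
        acq = AcquisitionConfig(noise_sd=0.0, duration=1.0)
        tr = render_trace(d, m, m.e_rev, acq, 1)
        assert np.allclose(tr.samples, 0.0)

    def test_fast_gating_apparent_amplitude(self):
        # analytic fast-gating limit: apparent level = i_true * ko/(ko+kc)
        m = GatingModel("flicker", g_true=174.0, slow_open_rate0=1.0,
                        slow_close_rate0=0.0, fast_open_rate0=50000.0,
                        fast_close_rate0=50000.0)
        d = sample_dwells(m, -160.0, 2.0, 3)
        acq = AcquisitionConfig(noise_sd=0.0, duration=2.0)
        tr = render_trace(d, m, -160.0, acq, 3)
        apparent = tr.samples[5000:].mean()
        assert apparent == pytest.approx(0.5 * m.i_true(-160.0), rel=0.05)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            AcquisitionConfig(fs=5000.0, filter_cutoff=2600.0)
        with pytest.raises(ValueError, match="cutoff"):
            AcquisitionConfig(fs=5000.0, filter_cutoff=2500.0)


class TestBessel:
    def test_dc_gain_unity(self):
        y = bessel_lowpass(np.full(5000, 3.7), 50000.0, 1000.0, 4)
        assert y[-1] == pytest.approx(3.7, rel=1e-9)
        assert np.all(np.isfinite(y))

    def test_minus_3db_at_cutoff(self):
        # independent filter-design oracle: frequency response at cutoff
        fs, fc = 50000.0, 1000.0
        b, a = signal.bessel(4, fc, "low", norm="mag", fs=fs)
        _, h = signal.freqz(b, a, worN=[fc], fs=fs)
        assert abs(h[0]) == pytest.approx(1 / np.sqrt(2), rel=1e-6)
        t = np.arange(int(fs * 0.5)) / fs
        y = bessel_lowpass(np.sin(2 * np.pi * fc * t), fs, fc, 4)
        amp = np.abs(y[int(fs * 0.2):]).max()
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_step_overshoot_below_one_percent(self):
        y = bessel_lowpass(np.ones(5000), 50000.0, 1000.0, 4)
        assert y.max() < 1.01

    @pytest.mark.parametrize("cutoff,order", [(0.0, 4), (30000.0, 4), (500.0, 0)])
    def test_invalid_parameters(self, cutoff, order):
        with pytest.raises(ValueError):
            bessel_lowpass(np.zeros(10), 50000.0, cutoff, order)


class TestSimulateRecording:
    def test_default_protocol_trace_count(self, wt_model, fast_acq):
        protocol = VoltageProtocol(per_voltage_duration=0.5)
        assert len(protocol.voltages) == 17
        rec = simulate_recording(wt_model, protocol, fast_acq(0.4, 0.5), 0)
        assert len(rec.traces) == 17
        assert rec.voltages[0] == 160.0 and rec.voltages[-1] == -160.0

    def test_same_seed_bit_identical(self, wt_model, fast_acq):
        protocol = VoltageProtocol(voltages=(100.0, -140.0), per_voltage_duration=0.5)
        acq = fast_acq(0.4, 0.5)
        a = simulate_recording(wt_model, protocol, acq, 7)
        b = simulate_recording(wt_model, protocol, acq, 7)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.samples, tb.samples)

    def test_truth_fraction_ratio_across_voltages(self, fast_acq):
        # WT slow gate is configured 6.8-fold more open at -160 than +160
        m = wildtype_model(flicker=False)
        expected = m.p_slow(-160.0) / m.p_slow(160.0)
        protocol = VoltageProtocol(voltages=(160.0, -160.0), per_voltage_duration=300.0)
        acq = fast_acq(0.0, 300.0, oversample=1)
        neg, pos = 0.0, 0.0
        for seed in range(5):
            rec = simulate_recording(m, protocol, acq, seed)
            pos += rec.truth_at(160.0).conducting_fraction
            neg += rec.truth_at(-160.0).conducting_fraction
        assert neg / pos == pytest.approx(expected, rel=0.15)


class TestGrowth:
    def test_zero_activity_zero_baseline_no_growth(self):
        gm = GrowthModel(baseline_rate=0.0, noise_sd=0.0)
        records = simulate_growth(0.0, gm, 0, n_replicates=2)
        od0 = {r.replicate: r.od600 for r in records if r.time == 0.0}
        for r in records:
            assert r.od600 == pytest.approx(od0[r.replicate])

    def test_fold_change_monotone_in_activity(self):
        gm = GrowthModel(noise_sd=0.0)
        folds = []
        for activity in (0.1, 0.5, 2.0, 10.0):
            records = simulate_growth(activity, gm, 0, n_replicates=1)
            od = {r.time: r.od600 for r in records}
            folds.append(od[48.0] / od[0.0])
        assert all(a < b for a, b in zip(folds, folds[1:]))
        # saturating: approaches carrying capacity at large activity
        gm_fast = GrowthModel(noise_sd=0.0, max_rate=0.3)
        records = simulate_growth(1e4, gm_fast, 0, n_replicates=1)
        od = {r.time: r.od600 for r in records}
        assert od[72.0] == pytest.approx(gm_fast.carrying_capacity, rel=0.01)

    def test_logistic_matches_ode_oracle(self):
        # independent oracle: integrate dOD/dt = r OD (1 - OD/K)
        gm = GrowthModel(noise_sd=0.0)
        rate = gm.rate_for(1.7)
        sol = solve_ivp(
            lambda t, y: rate * y * (1 - y / gm.carrying_capacity),
            (0.0, 72.0), [gm.od0], t_eval=[0.0, 6.0, 24.0, 48.0, 72.0],
            rtol=1e-10, atol=1e-12,
        )
        for t, od_oracle in zip(sol.t, sol.y[0]):
            assert gm.od_at(rate, t) == pytest.approx(od_oracle, rel=1e-7)

    def test_noise_is_reproducible(self):
        gm = GrowthModel(noise_sd=0.1)
        a = simulate_growth(1.0, gm, 5)
        b = simulate_growth(1.0, gm, 5)
        assert [r.od600 for r in a] == [r.od600 for r in b]


class TestMakePanel:
    @pytest.fixture
    def tiny_protocol(self):
        return VoltageProtocol(voltages=(100.0, -140.0), per_voltage_duration=0.2)

    def test_counts_and_wt(self, tiny_protocol, fast_acq):
        panel = default_panel()
        assert len(panel) == 20
        result = make_panel(panel, tiny_protocol, fast_acq(0.4, 0.2),
                            GrowthModel(), seed=0)
        assert len(result.recordings) == 20
        assert result.growth["genotype"].nunique() == 20
        assert result.wt_label == "WT"
        assert "WT" in result.recordings

    def test_missing_wt_flag_rejected(self, tiny_protocol, fast_acq):
        panel = [PanelEntry(wildtype_model(), is_wt=False)]
        with pytest.raises(ValueError, match="WT"):
            make_panel(panel, tiny_protocol, fast_acq(0.4, 0.2), GrowthModel(), 0)

    def test_rank_agreement_without_hidden_variance(self, tiny_protocol, fast_acq):
        # expression factors 1, zero noise -> growth rank == |activity| rank
        panel = default_panel()
        gm = GrowthModel(noise_sd=0.0)
        result = make_panel(panel, tiny_protocol, fast_acq(0.4, 0.2), gm, seed=3)
        labels = sorted(result.truth_activity)
        acts = [abs(result.truth_activity[g]) for g in labels]
        folds = []
        for g in labels:
            sub = result.growth[result.growth["genotype"] == g]
            od = dict(zip(sub["time_h"], sub["od600"]))
            folds.append(od[48.0] / od[0.0])
        rho = stats.spearmanr(acts, folds).statistic
        assert rho == pytest.approx(1.0)


class TestModelFactories:
    def test_slow_gate_hits_targets(self):
        m = slow_gate_model("x", 174.0, p_neg=0.034, p_pos=0.005)
        assert m.p_slow(-160.0) == pytest.approx(0.034, rel=1e-9)
        assert m.p_slow(160.0) == pytest.approx(0.005, rel=1e-9)

    def test_wildtype_printed_values(self):
        m = wildtype_model()
        assert m.g_true == 174.0
        assert m.i_true(100.0) == pytest.approx(17.4)
        assert m.p_conducting(-160.0) <= m.p_slow(-160.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GatingModel("bad", g_true=-1.0)
        with pytest.raises(ValueError):
            GatingModel("bad", g_true=1.0, slow_open_rate0=0.0, slow_close_rate0=0.0)
        with pytest.raises(ValueError):
            AcquisitionConfig(fs=5000.0, filter_cutoff=3000.0)
        with pytest.raises(ValueError):
            VoltageProtocol(voltages=(100.0, 100.0))
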