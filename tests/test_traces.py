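"""Strain-coupling assay: unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardionuc import traces as T
from conftest import make_series


@pytest.mark.parametrize("baseline,strain,include,reason", [
    (1.65, 0.12, False, "baseline"),
    (1.80, 0.12, True, ""),
    (1.80, 0.08, False, "strain"),
    (1.60, 0.05, False, "baseline+strain"),
    (1.80, -0.12, True, ""),          # magnitude counts, not sign
])
def test_qc_filter_gates(baseline, strain, include, reason):
    ok, why = T.qc_filter(baseline, strain)
    assert ok == include
    assert why == reason


def test_qc_filter_rejects_nonfinite():
    with pytest.raises(T.TraceValidationError):
        T.qc_filter(np.nan, 0.1)


def _periodic_trace(n_beats=5, rate=250.0, period=1.0, noise=0.0, rng=None,
                    pre=0.5):
    t = np.arange(0.0, pre + n_beats * period, 1.0 / rate)
    stim = pre + period * np.arange(n_beats)
    beat = np.zeros_like(t)
    for s in stim:
        phase = t - s
        m = (phase >= 0) & (phase < 0.4)
        beat[m] += -0.1 * np.sin(np.pi * phase[m] / 0.4)
    v = 1.85 * (1 + beat)
    if noise:
        v = v + rng.normal(0, noise, size=len(t))
    return T.RawTrace(time=t, value=v, sampling_rate=rate, stim_times=stim,
                      channel="sarcomere_length")


class TestBeatAverage:
    def test_identical_beats_recovered(self):
        tr = _periodic_trace()
        beat = T.beat_average(tr, 5)
        # the averaged beat equals any single beat of the periodic trace
        ref = np.interp(tr.stim_times[0] + beat.time, tr.time, tr.value)
        assert np.allclose(beat.value, ref, atol=1e-12)
        assert beat.time[-1] < 1.0                 # one cycle duration

    def test_noise_reduced_by_sqrt_n(self):
        # Monte-Carlo: the residual after averaging 5 noisy beats shrinks
        # by ~sqrt(5) relative to a single beat's noise
        sd_single, sd_avg = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            clean = _periodic_trace()
            noisy = _periodic_trace(noise=0.01, rng=rng)
            ref = T.beat_average(clean, 5)
            avg = T.beat_average(noisy, 5)
            sd_avg.append(np.std(avg.value - ref.value))
        ratio = 0.01 / np.mean(sd_avg)
        assert ratio == pytest.approx(np.sqrt(5), rel=0.15)

    def test_too_few_stimuli(self):
        tr = _periodic_trace(n_beats=2)
        with pytest.raises(T.TraceValidationError, match="2 stimuli"):
            T.beat_average(tr, 3)

    def test_irregular_spacing_names_beat(self):
        tr = _periodic_trace()
        stim = tr.stim_times.copy()
        stim[3] += 0.3
        bad = T.RawTrace(time=tr.time, value=tr.value, sampling_rate=250.0,
                         stim_times=stim, channel="sarcomere_length")
        with pytest.raises(T.TraceValidationError, match="beat"):
            T.beat_average(bad, 5)


class TestResample:
    def test_identity_at_target_rate(self):
        t = np.arange(0, 1, 1 / 91.0)
        tr = T.RawTrace(time=t, value=1.8 + 0.1 * t, sampling_rate=91.0,
                        stim_times=[0.0], channel="sarcomere_length")
        out = T.resample_to(tr, 91.0)
        assert np.allclose(out.value, tr.value, atol=1e-12)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 1, 1 / 250.0)
        tr = T.RawTrace(time=t, value=2.0 + 0.5 * t, sampling_rate=250.0,
                        stim_times=[0.0], channel="sarcomere_length")
        out = T.resample_to(tr, 91.0)
        assert np.allclose(out.value, 2.0 + 0.5 * out.time, atol=1e-12)

    def test_sine_within_tolerance(self):
        t = np.arange(0, 2, 1e-3)
        tr = T.RawTrace(time=t, value=2 + np.sin(2 * np.pi * t),
                        sampling_rate=1000.0, stim_times=[0.0],
                        channel="sarcomere_length")
        out = T.resample_to(tr, 91.0)
        exact = 2 + np.sin(2 * np.pi * out.time)
        assert np.max(np.abs(out.value - exact) / np.abs(exact)) < 1e-3

    def test_invalid_rate(self):
        tr = _periodic_trace()
        with pytest.raises(T.TraceValidationError):
            T.resample_to(tr, 0.0)


class TestStrain:
    def test_constant_trace_zero_strain(self):
        t = np.arange(0, 2, 0.01)
        tr = T.RawTrace(time=t, value=np.full_like(t, 1.9),
                        sampling_rate=100.0, stim_times=[0.5],
                        channel="sarcomere_length")
        assert np.allclose(T.compute_strain(tr), 0.0)

    def test_strain_arithmetic(self):
        t = np.arange(0, 1, 0.01)
        v = np.full_like(t, 1.80)
        v[60] = 1.60
        tr = T.RawTrace(time=t, value=v, sampling_rate=100.0,
                        stim_times=[0.5], channel="sarcomere_length")
        eps = T.compute_strain(tr)
        assert eps[60] == pytest.approx(-0.1111, abs=1e-4)

    def test_baseline_window_must_contain_samples(self):
        t = np.arange(0, 1, 0.01)
        tr = T.RawTrace(time=t, value=np.full_like(t, 1.8),
                        sampling_rate=100.0, stim_times=[0.0],
                        channel="sarcomere_length")
        with pytest.raises(T.TraceValidationError):
            T.compute_strain(tr)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_strain_invariant_to_unit_rescaling(self, scale):
        t = np.arange(0, 2, 0.01)
        v = 1.8 + 0.1 * np.sin(2 * np.pi * np.maximum(t - 0.5, 0))
        tr1 = T.RawTrace(time=t, value=v, sampling_rate=100.0,
                         stim_times=[0.5], channel="sarcomere_length")
        tr2 = T.RawTrace(time=t, value=v * scale, sampling_rate=100.0,
                         stim_times=[0.5], channel="sarcomere_length")
        assert np.allclose(T.compute_strain(tr1), T.compute_strain(tr2),
                           atol=1e-12)


def _twitch_series(gain=1.0, n=201, peak=0.10, hold_nucleus=False):
    """Triangular compression transient and (possibly lagged) nucleus."""
    t = np.linspace(0, 1, n)
    up = t <= 0.5
    eps_s = -peak * np.where(up, t / 0.5, (1 - t) / 0.5)
    eps_n = gain * eps_s
    if hold_nucleus:
        eps_n = np.where(up, gain * eps_s, gain * eps_s[n // 2])
    return make_series(t, eps_s, eps_n)


class TestCouplingCurve:
    def test_identity_coupling_on_diagonal(self):
        c = T.build_coupling_curve(_twitch_series(gain=1.0))
        assert np.allclose(c.eps_s, c.eps_n, atol=1e-12)

    def test_single_phase_switch(self):
        c = T.build_coupling_curve(_twitch_series())
        ph = c.phase
        switches = np.sum(ph[:-1] != ph[1:])
        assert switches == 1
        assert ph[c.peak_index] == "systolic"
        assert c.eps_s[c.peak_index] == c.eps_s.max()

    def test_flat_trace_rejected(self):
        s = make_series([0, 0.5, 1], [0, 0, 0], [0, 0, 0])
        with pytest.raises(T.TraceValidationError):
            T.build_coupling_curve(s)

    def test_lagged_relaxation_gives_positive_hysteresis(self):
        # nuclear relaxation lags the sarcomere: diastolic curve sits
        # above the end-systolic reference -> positive D_dia
        t = np.linspace(0, 1, 400)
        up = t <= 0.3
        eps_s = -0.1 * np.where(up, t / 0.3, np.exp(-(t - 0.3) / 0.1))
        lag = 0.06
        eps_n = 0.6 * np.interp(t - lag, t, eps_s, left=0.0)
        c = T.build_coupling_curve(make_series(t, eps_s, eps_n))
        assert T.diastolic_dampening(c) > 0


class TestDampening:
    def test_identity_coupling_zero_areas(self):
        c = T.build_coupling_curve(_twitch_series(gain=1.0))
        assert T.systolic_dampening(c) == pytest.approx(0.0, abs=1e-15)
        assert T.diastolic_dampening(c) == pytest.approx(0.0, abs=1e-15)

    def test_rigid_nucleus_triangle(self):
        # eps_n = 0, peak |eps_s| = 0.1: area under the 1:1 line is the
        # triangle (1/2)(0.1)(0.1) = 0.005
        c = T.build_coupling_curve(_twitch_series(gain=0.0))
        assert T.systolic_dampening(c) == pytest.approx(0.005, abs=1e-6)

    def test_half_gain_against_dense_trapezoid(self):
        c = T.build_coupling_curve(_twitch_series(gain=0.5, n=4001))
        # independent oracle: D = int (x - 0.5 x) dx over x in [0, 0.1]
        x = np.linspace(0, 0.1, 100001)
        oracle = np.trapezoid(x - 0.5 * x, x)
        assert T.systolic_dampening(c) == pytest.approx(oracle, abs=1e-6)
        assert oracle == pytest.approx(0.0025, abs=1e-9)

    def test_held_nucleus_diastolic_area(self):
        # nucleus frozen at end-systole (|eps_n| = 0.066) while the
        # sarcomere relaxes from 0.10: area between the unit-slope
        # reference and the horizontal path is (1/2)(0.1)^2 = 0.005
        c = T.build_coupling_curve(
            _twitch_series(gain=0.66, n=2001, hold_nucleus=True))
        assert T.diastolic_dampening(c) == pytest.approx(0.005, abs=1e-5)

    @pytest.mark.parametrize("gains", [(1.0, 0.7, 0.4, 0.1)])
    def test_monotone_in_dampening_factor(self, gains):
        d = [T.systolic_dampening(T.build_coupling_curve(
            _twitch_series(gain=g))) for g in gains]
        assert np.all(np.diff(d) > 0)


class TestIntegratedStrain:
    def test_zero_strain_zero_integral(self):
        s = make_series([0, 0.5, 1], [0, -0.1, 0], [0, 0, 0])
        assert T.integrated_nuclear_strain(s) == 0.0

    def test_triangle_area(self):
        # |eps_nL| triangular, peak 0.066, base 0.4 s -> 0.0132 strain*s
        t = np.linspace(0, 0.4, 2001)
        eps_n = -0.066 * (1 - np.abs(t - 0.2) / 0.2)
        s = make_series(t, eps_n, eps_n)
        assert T.integrated_nuclear_strain(s) == pytest.approx(0.0132,
                                                               abs=1e-6)

    def test_additive_over_concatenated_cycles(self):
        t = np.linspace(0, 0.4, 801)
        eps = -0.05 * np.sin(np.pi * t / 0.4) ** 2
        one = T.integrated_nuclear_strain(make_series(t, eps, eps))
        t2 = np.linspace(0, 0.8, 1601)
        eps2 = -0.05 * np.sin(np.pi * t2 / 0.4) ** 2
        two = T.integrated_nuclear_strain(make_series(t2, eps2, eps2))
        assert two == pytest.approx(2 * one, rel=1e-3)

    @given(c=st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_linear_in_strain_scale(self, c):
        t = np.linspace(0, 1, 201)
        eps = -0.05 * np.sin(np.pi * t) ** 2
        s1 = T.integrated_nuclear_strain(make_series(t, eps, eps))
        s2 = T.integrated_nuclear_strain(make_series(t, eps, c * eps))
        assert s2 == pytest.approx(c * s1, rel=1e-9)


def test_pipeline_recovers_generator_peaks():
    """beat_average -> resample -> strain on noise-free synthetic traces
    recovers the planted peak strains to < 0.5% relative error."""
    from cardionuc import synthetic as S
    p = S.TraceGenParams(seed=9, n_cells=3, noise_sd_um=0.0,
                         nuc_noise_sd_um=0.0, peak_sarc_strain_sd=0.0,
                         coupling_gain_sd=0.0)
    for cell in S.gen_traces(p, preset="WT"):
        series = T.pair_series(cell["sarcomere_length"],
                               cell["nuclear_length"],
                               cell["nuclear_width"])
        m = T.coupling_metrics(series)
        assert m.peak_eps_s == pytest.approx(
            cell["truth"]["peak_eps_s"], rel=5e-3)
        assert m.peak_eps_nL == pytest.approx(
            cell["truth"]["peak_eps_nL"], rel=1.5e-2)


def test_csv_round_trip(tmp_path):
    import pandas as pd
    t = np.arange(0, 2, 0.01)
    rows = []
    for ch, L0 in [("sarcomere_length", 1.85), ("nuclear_length", 12.0)]:
        for ti, vi in zip(t, L0 * (1 + 0.0 * t)):
            rows.append({"time_s": ti, "channel": ch, "value_um": vi})
    rows.append({"time_s": 0.5, "channel": "stim", "value_um": 0})
    path = tmp_path / "cell.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    traces = T.read_cell_csv(path)
    assert set(traces) == {"sarcomere_length", "nuclear_length"}
    assert traces["sarcomere_length"].stim_times.tolist() == [0.5]
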