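"""Presynaptic QC, failure-inclusive averaging and EPSP measurement."""

import numpy as np
import pytest

from stpkit import (
    EPSPKinetics,
    QCConfig,
    ReleaseModelParams,
    StimProtocol,
    average_response,
    exclude_polysynaptic,
    extract_connection,
    measure_epsp,
    qc_presynaptic_spikes,
    render_sweeps,
    simulate_connection,
)
from stpkit.sweeps import SweepSet

PROTOCOL = StimProtocol(frequency=20.0, n_sweeps=4)
NOISELESS = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01, A=2.0)


def rendered(params=NOISELESS, protocol=PROTOCOL, seed=0, **kin):
    amps = np.full(protocol.n_pulses, 2.0)
    return render_sweeps(amps, EPSPKinetics(**kin), protocol, params, seed=seed)


class TestPresynapticQC:
    def test_intact_spikes_all_pass(self):
        sw, _ = rendered()
        passed, peaks = qc_presynaptic_spikes(sw)
        assert passed.all()
        np.testing.assert_allclose(
            peaks[0], sw.stim_times + 0.6e-3, atol=1.0 / sw.sampling_rate
        )

    def test_removed_spike_fails_only_that_pulse(self):
        sw, _ = rendered()
        sr = sw.sampling_rate
        i0 = int(sw.stim_times[3] * sr)
        sw.v_pre[0, i0 : i0 + int(0.005 * sr)] = -70.0
        passed, _ = qc_presynaptic_spikes(sw)
        assert not passed[0, 3]
        assert passed[0, :3].all() and passed[0, 4:].all() and passed[1:].all()

    def test_threshold_above_template_slope_flags_connection(self):
        sw, _ = rendered()
        passed, _ = qc_presynaptic_spikes(sw, QCConfig(dvdt_threshold=1e6))
        assert not passed.any()
        rec = extract_connection(sw, qc=QCConfig(dvdt_threshold=1e6))
        assert "qc-failed" in rec.flags
        assert np.isnan(rec.amplitudes).all()


class TestAveraging:
    def test_identical_noiseless_sweeps_average_to_single_sweep(self):
        sw, gt = rendered()
        passed, peaks = qc_presynaptic_spikes(sw)
        segs, t0 = average_response(sw, passed, peaks)
        segs2, _ = average_response(
            SweepSet(sw.time, sw.v_pre[:1], sw.v_post[:1], sw.stim_times,
                     sw.protocol, sw.sampling_rate),
            passed[:1], peaks[:1],
        )
        np.testing.assert_allclose(segs, segs2, atol=1e-12)

    def test_failures_included_in_average(self):
        # 2 success sweeps (2 mV) stacked with 2 total-failure sweeps -> 1 mV
        sw_ok, _ = rendered()
        sw_fail, _ = rendered(
            ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01, A=2.0,
                               p_fail=0.999999)
        )
        merged = SweepSet(
            sw_ok.time,
            np.vstack([sw_ok.v_pre[:2], sw_fail.v_pre[:2]]),
            np.vstack([sw_ok.v_post[:2], sw_fail.v_post[:2]]),
            sw_ok.stim_times, sw_ok.protocol, sw_ok.sampling_rate,
        )
        rec = extract_connection(merged)
        assert rec.amplitudes[0] == pytest.approx(1.0, rel=0.02)

    def test_baseline_noise_attenuates_as_sqrt_n(self):
        protocol = StimProtocol(frequency=20.0, n_sweeps=50)
        params = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01, A=2.0,
                                    noise_sd=0.2)
        sw, _ = rendered(params, protocol, seed=4)
        passed, peaks = qc_presynaptic_spikes(sw)
        segs, t0 = average_response(sw, passed, peaks)
        nb = int(t0 * sw.sampling_rate)
        baseline_sd = segs[0, :nb].std()
        assert baseline_sd == pytest.approx(0.2 / np.sqrt(50), rel=0.35)

    def test_average_is_permutation_invariant(self):
        sw, _ = rendered(ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01,
                                            A=2.0, noise_sd=0.1), seed=5)
        passed, peaks = qc_presynaptic_spikes(sw)
        segs, _ = average_response(sw, passed, peaks)
        perm = [2, 0, 3, 1]
        sw_p = SweepSet(sw.time, sw.v_pre[perm], sw.v_post[perm], sw.stim_times,
                        sw.protocol, sw.sampling_rate)
        segs_p, _ = average_response(sw_p, passed[perm], peaks[perm])
        np.testing.assert_allclose(segs, segs_p, atol=1e-12)

    def test_zero_passing_sweeps_is_an_error(self):
        sw, _ = rendered()
        passed, peaks = qc_presynaptic_spikes(sw)
        with pytest.raises(ValueError):
            average_response(sw, np.zeros_like(passed), peaks)


class TestMeasureEPSP:
    def test_recovers_generator_kinetics(self):
        sw, gt = rendered(tau_rise=2.0, tau_decay=20.0, onset_delay=1.5)
        rec = extract_connection(sw)
        f = rec.first_epsp
        assert f.amplitude == pytest.approx(2.0, rel=0.01)
        assert f.decay_tau == pytest.approx(20.0, rel=0.05)
        assert f.onset_delay == pytest.approx(1.5, abs=0.2)

    def test_flat_trace_is_flagged(self):
        sr = 20_000.0
        flat = np.zeros(int(0.1 * sr))
        f = measure_epsp(flat, sr, 0.02)
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)
        assert "no-onset" in f.flags
        assert np.isnan(f.onset_delay)

    def test_amplitude_linearity_preserves_kinetics(self):
        sw1, _ = rendered()
        amps2 = np.full(PROTOCOL.n_pulses, 4.0)
        sw2, _ = render_sweeps(amps2, EPSPKinetics(), PROTOCOL, NOISELESS, seed=0)
        f1 = extract_connection(sw1).first_epsp
        f2 = extract_connection(sw2).first_epsp
        assert f2.amplitude == pytest.approx(2.0 * f1.amplitude, rel=1e-3)
        assert f2.rise_time == pytest.approx(f1.rise_time, abs=0.1)
        assert f2.decay_tau == pytest.approx(f1.decay_tau, rel=0.01)


class TestPolysynapticExclusion:
    def make_records(self, delays):
        recs = []
        for i, d in enumerate(delays):
            sw, _ = rendered(seed=i, onset_delay=d)
            recs.append(extract_connection(sw, connection_id=f"c{i}"))
        return recs

    def test_cutoff_filters_long_latencies(self):
        recs = self.make_records([1.2, 2.0, 6.0])
        kept = exclude_polysynaptic(recs, max_onset_delay=4.0)
        assert [r.connection_id for r in kept] == ["c0", "c1"]

    def test_infinite_cutoff_is_identity(self):
        recs = self.make_records([1.2, 2.0, 6.0])
        assert len(exclude_polysynaptic(recs, max_onset_delay=np.inf)) == 3

    def test_all_excluded_warns(self):
        recs = self.make_records([6.0, 7.0])
        with pytest.warns(UserWarning):
            kept = exclude_polysynaptic(recs, max_onset_delay=1.0)
        assert kept == []


def test_failure_inclusive_mean_tracks_release_probability():
    protocol = StimProtocol(frequency=20.0, n_sweeps=40)
    params = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01, A=2.0,
                                p_fail=0.4, noise_sd=0.05)
    sw, gt = simulate_connection(params, protocol, seed=8)
    rec = extract_connection(sw)
    expected = (1 - 0.4) * gt.mean_amplitudes[0]
    mc_se = gt.mean_amplitudes[0] * np.sqrt(0.4 * 0.6 / 40)
    assert abs(rec.amplitudes[0] - expected) < 3 * mc_se
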