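"""STP metrics, heatmaps, recovery curves and frequency comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stpkit import (
    ConnectionRecord,
    ReleaseModelParams,
    StimProtocol,
    build_heatmap,
    compute_metrics,
    frequency_comparison,
    ppr_vs_div,
    recovery_curve,
    simulate_release_train,
)


def record(amps, cid="c0", freq=50.0, delay=0.25, **kw):
    return ConnectionRecord(cid, np.asarray(amps, float), freq, delay, **kw)


def release_record(params, freq=50.0, delay=0.25, cid="c0", **kw):
    prot = StimProtocol(frequency=freq, recovery_delay=delay)
    amps = simulate_release_train(params, prot.pulse_times())
    return record(amps, cid=cid, freq=freq, delay=delay, **kw)


class TestComputeMetrics:
    def test_direct_arithmetic(self):
        amps = [1.0, 0.8, 0.6, 0.5, 0.45, 0.4, 0.4, 0.4, 0.6, 0.5, 0.45, 0.42]
        m = compute_metrics(record(amps))
        assert m.ppr == pytest.approx(0.8)
        assert m.ratio_1_8 == pytest.approx(0.4)
        assert m.ratio_1_6_8 == pytest.approx(0.4)
        assert m.dynamics_call == "depressing"
        assert m.normalized_train[0] == 1.0
        assert m.early_recovery == pytest.approx(0.6)

    def test_tie_called_depressing(self):
        m = compute_metrics(record(np.ones(12)))
        assert m.ppr == 1.0
        assert m.dynamics_call == "depressing"

    def test_facilitating_release_params(self):
        m = compute_metrics(
            release_record(ReleaseModelParams(U=0.1, tau_rec=0.05, tau_facil=0.5))
        )
        assert m.ppr == pytest.approx(1.7397, abs=5e-4)
        assert m.dynamics_call == "facilitating"

    def test_zero_first_pulse_flagged(self):
        m = compute_metrics(record([0.0] + [1.0] * 11))
        assert m.flagged
        assert np.isnan(m.ppr)

    @given(scale=st.floats(0.01, 100.0))
    def test_metrics_are_scale_invariant(self, scale):
        amps = np.array([2.0, 1.4, 1.0, 0.8, 0.7, 0.65, 0.6, 0.6, 1.1, 0.9, 0.8, 0.7])
        m1 = compute_metrics(record(amps))
        m2 = compute_metrics(record(amps * scale))
        assert m2.ppr == pytest.approx(m1.ppr, rel=1e-9)
        assert m2.ratio_1_6_8 == pytest.approx(m1.ratio_1_6_8, rel=1e-9)
        np.testing.assert_allclose(m2.normalized_train, m1.normalized_train, rtol=1e-9)
        assert m2.dynamics_call == m1.dynamics_call


class TestRecoveryCurve:
    DELAYS = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

    def depressing_records(self):
        p = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01)
        return [release_record(p, delay=d) for d in self.DELAYS]

    def test_depression_recovery_is_monotone_in_delay(self):
        rc = recovery_curve(self.depressing_records())
        assert np.all(np.diff(rc.delays_ms) > 0)
        assert np.all(np.diff(rc.recovery) >= -1e-12)

    def test_four_second_delay_recovers_fully(self):
        rc = recovery_curve(self.depressing_records())
        assert rc.recovery[-1] == pytest.approx(1.0, abs=0.02)

    def test_single_delay_curve(self):
        rc = recovery_curve(self.depressing_records()[:1])
        assert rc.delays_ms.size == 1


class TestHeatmap:
    def test_rows_sorted_by_first_amplitude_descending(self):
        recs = [
            record(np.full(12, 0.5), cid="a"),
            record(np.full(12, 3.0), cid="b"),
            record(np.full(12, 1.0), cid="c"),
        ]
        hm = build_heatmap(recs, frequency=50.0)
        assert hm.connection_ids == ["b", "c", "a"]
        np.testing.assert_allclose(hm.first_amplitudes, [3.0, 1.0, 0.5])
        np.testing.assert_allclose(hm.matrix, 1.0)  # normalised trains

    def test_tie_broken_by_connection_id(self):
        recs = [record(np.full(12, 2.0), cid="z"), record(np.full(12, 2.0), cid="a")]
        hm = build_heatmap(recs, frequency=50.0)
        assert hm.connection_ids == ["a", "z"]

    def test_single_connection_and_rescaling_invariance(self):
        recs = [record(np.linspace(2, 1, 12), cid="solo")]
        hm = build_heatmap(recs, frequency=50.0)
        assert hm.matrix.shape[0] == 1
        scaled = [record(r.amplitudes * 7.0, cid=r.connection_id) for r in recs]
        hm2 = build_heatmap(scaled, frequency=50.0)
        assert hm2.connection_ids == hm.connection_ids
        np.testing.assert_allclose(hm2.matrix, hm.matrix, rtol=1e-12)


class TestFrequencyComparison:
    def test_deeper_depression_at_higher_frequency(self):
        p = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01)
        recs = [release_record(p, freq=f, cid=f"c{f}") for f in (20.0, 50.0)]
        df = frequency_comparison(recs)
        dep = df[df.dynamics == "depressing"]
        p8 = dep[dep.pulse == 8].set_index("frequency")["mean"]
        assert p8[50.0] < p8[20.0]

    def test_identical_trains_identical_summaries(self):
        amps = np.linspace(1.0, 0.4, 12)
        recs = [record(amps, cid="a", freq=20.0), record(amps, cid="a", freq=50.0)]
        df = frequency_comparison(recs)
        means = df.pivot_table(index="pulse", columns="frequency", values="mean")
        np.testing.assert_allclose(means[20.0], means[50.0])

    def test_empty_class_warns_and_is_omitted(self):
        p = ReleaseModelParams(U=0.5, tau_rec=0.5, tau_facil=0.01)
        recs = [release_record(p, freq=50.0)]
        with pytest.warns(UserWarning):
            df = frequency_comparison(recs, frequencies=(50.0,))
        assert set(df.dynamics) == {"depressing"}


class TestPPRvsDIV:
    def test_exact_linear_relation(self):
        recs = []
        for i, div in enumerate([3.0, 5.0, 7.0, 9.0]):
            ppr = 0.1 * div
            amps = np.concatenate([[1.0, ppr], np.full(10, 0.5)])
            recs.append(record(amps, cid=f"c{i}", prep="culture", div=div))
        res = ppr_vs_div(recs)
        assert res.slope == pytest.approx(0.1)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_records_is_an_error(self):
        recs = [
            record(np.ones(12), cid=f"c{i}", prep="culture", div=3.0 + i)
            for i in range(2)
        ]
        with pytest.raises(ValueError):
            ppr_vs_div(recs)


def test_cohort_classification_recovers_generating_regime(small_cohort):
    calls = [compute_metrics(r).dynamics_call for r in small_cohort.records]
    truth = small_cohort.truth["regime"].tolist()
    assert np.mean([c == t for c, t in zip(calls, truth)]) >= 0.95
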