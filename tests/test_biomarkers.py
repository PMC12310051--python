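"""Biomarker extraction against closed-form synthetic waveforms, dense-grid
brute-force oracles, and the regime-classification decision rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apsens.biomarkers import (
    DegenerateTransientError, NoAPError, classify_response,
    extract_ap_biomarkers, extract_ca_biomarkers, pacing_convergence,
    restitution_curve,
)
from apsens.shannon import PacingProtocol, ScalingVector
from apsens.trace import Trace

from conftest import make_beat_train


def _trace(t, V, ca=None, bcl=500.0):
    return Trace(t=t, V=V, Cai=ca, stimulus_onsets=np.array([0.0]), bcl=bcl)


class TestAPExtraction:
    def test_square_pulse_bulk_is_amplitude_times_duration(self):
        # V = Vrest + A on [10, 110], Vrest elsewhere; B = A * d exactly
        rest, A, d = -80.0, 100.0, 100.0
        eps = 1e-9
        t = np.concatenate([
            [0.0, 10.0 - eps], np.linspace(10.0, 110.0, 201),
            [110.0 + eps, 500.0],
        ])
        V = np.where((t >= 10.0) & (t <= 110.0), rest + A, rest)
        bm = extract_ap_biomarkers(_trace(t, V), 0)
        assert bm.B == pytest.approx(A * d, rel=1e-6)
        assert bm.Vmax == rest + A
        assert bm.Vrest == rest

    def test_triangular_pulse_matches_closed_form_crossings(self):
        # rise to 40 mV at 1 ms, linear to -80 mV at 400 ms, then flat
        t = np.arange(0.0, 500.0 + 0.05, 0.1)
        V = np.where(
            t <= 1.0, -80.0 + 120.0 * t,
            np.where(t <= 400.0, 40.0 - 120.0 * (t - 1.0) / 399.0, -80.0),
        )
        bm = extract_ap_biomarkers(_trace(t, V), 0)
        # closed-form crossing times of the -68 mV (90%) and 4 mV (30%) levels
        a90_exact = 1.0 + 108.0 * 399.0 / 120.0
        a30_exact = 1.0 + 36.0 * 399.0 / 120.0
        assert bm.A90 == pytest.approx(a90_exact, rel=1e-6)
        assert bm.A30 == pytest.approx(a30_exact, rel=1e-6)
        vplt_exact = 40.0 - 120.0 * (a90_exact / 2.0 - 1.0) / 399.0
        assert bm.Vplt == pytest.approx(vplt_exact, rel=1e-6)
        assert bm.A30 <= bm.A90

    def test_dense_grid_oracle_agreement(self):
        # brute-force oracle: first sub-sample below the level on a 1000x
        # finer grid; interpolation-based extraction must agree to < 0.1%
        tr_coarse = make_beat_train([250.0], dt=0.5)
        bm = extract_ap_biomarkers(tr_coarse, 0)
        t = np.arange(0.0, 500.0 + 5e-4, 5e-4)
        tau = (250.0 - 1.0) / np.log(10.0) ** 0.25
        V = np.where(t <= 1.0, -85.0 + 125.0 * t,
                     -85.0 + 125.0 * np.exp(-((t - 1.0) / tau) ** 4))
        lvl90 = V.max() - 0.9 * (V.max() - V[-1])
        ipk = V.argmax()
        a90_oracle = t[ipk + np.argmax(V[ipk:] <= lvl90)]
        assert bm.A90 == pytest.approx(a90_oracle, rel=1e-3)

    def test_constant_trace_raises_no_ap(self):
        t = np.linspace(0.0, 500.0, 100)
        with pytest.raises(NoAPError):
            extract_ap_biomarkers(_trace(t, np.full(100, -80.0)), 0)

    def test_unrepolarized_beat_raises_no_ap(self):
        t = np.linspace(0.0, 500.0, 100)
        V = np.where(t < 5.0, -80.0, 20.0)  # depolarizes, never comes back
        with pytest.raises(NoAPError):
            extract_ap_biomarkers(_trace(t, V), 0)

    def test_bulk_invariant_under_voltage_offset(self):
        tr = make_beat_train([200.0])
        b0 = extract_ap_biomarkers(tr, 0).B
        tr_shift = Trace(t=tr.t, V=tr.V + 17.0, Cai=None,
                         stimulus_onsets=tr.stimulus_onsets, bcl=tr.bcl)
        assert extract_ap_biomarkers(tr_shift, 0).B == pytest.approx(b0, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a90=st.floats(min_value=50.0, max_value=380.0))
    def test_a30_never_exceeds_a90(self, a90):
        bm = extract_ap_biomarkers(make_beat_train([a90], dt=0.1), 0)
        assert bm.A30 <= bm.A90
        assert bm.A90 == pytest.approx(a90, rel=5e-3)


class TestCaExtraction:
    def test_square_ca_pulse_d50_is_width(self):
        base, amp, w = 1e-4, 5e-4, 120.0
        eps = 1e-9
        t = np.concatenate([
            [0.0, 20.0 - eps], np.linspace(20.0, 20.0 + w, 200),
            [20.0 + w + eps, 500.0],
        ])
        ca = np.where((t >= 20.0) & (t <= 20.0 + w), base + amp, base)
        V = np.full(t.size, -80.0)
        bm = extract_ca_biomarkers(_trace(t, V, ca), 0)
        assert bm.D50 == pytest.approx(w, rel=1e-6)
        assert bm.PSV == base + amp
        assert bm.ED == base

    def test_biexponential_matches_closed_form_peak(self):
        tr_, td_ = 20.0, 150.0
        tpeak = np.log(td_ / tr_) / (1.0 / tr_ - 1.0 / td_)
        gpeak = np.exp(-tpeak / td_) - np.exp(-tpeak / tr_)
        t = np.arange(0.0, 500.0 + 0.05, 0.1)
        ca = 1e-4 + 4e-4 / gpeak * (np.exp(-t / td_) - np.exp(-t / tr_))
        bm = extract_ca_biomarkers(_trace(t, np.full(t.size, -80.0), ca), 0)
        assert bm.PSV == pytest.approx(1e-4 + 4e-4, rel=1e-4)
        assert bm.Tpeak == pytest.approx(tpeak, abs=0.11)

    def test_monotone_decreasing_raises_degenerate(self):
        t = np.linspace(0.0, 500.0, 200)
        ca = np.linspace(5e-4, 1e-4, 200)
        with pytest.raises(DegenerateTransientError):
            extract_ca_biomarkers(_trace(t, np.full(200, -80.0), ca), 0)

    def test_flat_ca_raises_degenerate(self):
        t = np.linspace(0.0, 500.0, 200)
        with pytest.raises(DegenerateTransientError):
            extract_ca_biomarkers(
                _trace(t, np.full(200, -80.0), np.full(200, 1e-4)), 0)


class TestClassification:
    def test_stable_detected_beats_are_normal(self):
        tr = make_beat_train([200.0] * 40)
        assert classify_response(tr).regime == "normal_1_1"

    def test_alternating_a90_is_alternans(self):
        tr = make_beat_train([200.0, 150.0] * 20)
        assert classify_response(tr).regime == "alternans_2_2"

    def test_ap_no_ap_alternation_is_2_1_block(self):
        tr = make_beat_train([200.0, None] * 20)
        assert classify_response(tr).regime == "block_2_1"

    def test_runs_of_aps_and_failures_are_intermittent(self):
        tr = make_beat_train(([200.0] * 10 + [None] * 10) * 3)
        label = classify_response(tr)
        assert label.regime == "intermittent"
        assert label.Q == pytest.approx(10.0, abs=2.0)

    def test_no_aps_is_non_excitable(self):
        tr = make_beat_train([None] * 40)
        assert classify_response(tr).regime == "non_excitable"

    def test_too_few_beats_raises(self):
        tr = make_beat_train([200.0] * 10)
        with pytest.raises(ValueError, match="recorded beats"):
            classify_response(tr)

    def test_classification_invariant_to_time_translation(self):
        tr = make_beat_train([200.0, 150.0] * 20)
        assert (classify_response(tr.shifted(1234.5)).regime
                == classify_response(tr).regime)


class TestDiagnostics:
    def test_restitution_single_entry_matches_direct_composition(self):
        # injectable toy simulator: A90 proportional to BCL
        def toy(p, proto):
            return make_beat_train([0.4 * proto.bcl] * proto.record_last,
                                   bcl=proto.bcl)

        proto = PacingProtocol(n_beats=100, record_last=40)
        pts = restitution_curve(ScalingVector(), [500.0], proto, simulate=toy)
        assert len(pts) == 1
        direct = extract_ap_biomarkers(toy(None, proto), -1).A90
        assert pts[0]["A90"] == pytest.approx(direct)
        assert pts[0]["regime"] == "normal_1_1"

    def test_restitution_flags_non_one_to_one_points(self):
        def toy(p, proto):
            if proto.bcl < 250.0:
                return make_beat_train([150.0, None] * (proto.record_last // 2),
                                       bcl=proto.bcl)
            return make_beat_train([0.4 * proto.bcl] * proto.record_last,
                                   bcl=proto.bcl)

        proto = PacingProtocol(n_beats=100, record_last=40)
        pts = restitution_curve(ScalingVector(), [200.0, 400.0, 800.0], proto,
                                simulate=toy)
        regimes = {p["bcl"]: p["regime"] for p in pts}
        assert regimes[200.0] == "block_2_1"
        assert regimes[400.0] == regimes[800.0] == "normal_1_1"
        a90 = {p["bcl"]: p["A90"] for p in pts}
        assert a90[400.0] <= a90[800.0]  # restitution: A90 non-decreasing in BCL

    def test_restitution_continues_past_failing_points(self):
        def toy(p, proto):
            if proto.bcl == 300.0:
                raise RuntimeError("boom")
            return make_beat_train([200.0] * proto.record_last, bcl=proto.bcl)

        proto = PacingProtocol(n_beats=100, record_last=40)
        pts = restitution_curve(ScalingVector(), [300.0, 500.0], proto, simulate=toy)
        assert pts[0]["error"] is not None and np.isnan(pts[0]["A90"])
        assert pts[1]["error"] is None and np.isfinite(pts[1]["A90"])

    def test_pacing_convergence_zero_at_reference_and_for_constant_stream(self):
        def toy(p, proto):
            return make_beat_train([200.0] * proto.record_last, bcl=proto.bcl,
                                   with_ca=False)

        proto = PacingProtocol(n_beats=10, record_last=10)
        rows = pacing_convergence(ScalingVector(), proto, n_ref=10,
                                  simulate=toy, include_ca=False)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in rows[10].values())
        for b in rows:
            for v in rows[b].values():
                assert v == pytest.approx(0.0, abs=1e-6)
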