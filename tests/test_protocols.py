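"""Cell-protocol tests: biomarkers, pacing, threshold, restitution, I-V."""

import numpy as np
import pytest

from genodt import ionic, protocols
from genodt.protocols import (
    ProtocolError, RestitutionCurve, StimulusSpec,
    find_diastolic_threshold, iv_curve_INa, max_restitution_slope,
    measure_ap_biomarkers, measure_cat_biomarkers, pace_to_steady_state,
)


class TestAPBiomarkers:
    def test_analytic_triangle(self):
        """Instant rise -85 -> +35 mV then linear fall over 300 ms: the 90%
        level (-73 mV) is crossed at 270 ms."""
        t = np.concatenate([[-5.0, -0.001], np.linspace(0.0, 300.0, 30001)])
        V = np.concatenate([[-85.0, -85.0],
                            35.0 + (-120.0 / 300.0) * np.linspace(0, 300, 30001)])
        bm = measure_ap_biomarkers((t, V))
        assert bm.APD90 == pytest.approx(270.0, abs=0.1)
        assert bm.RMP == -85.0
        assert bm.V_peak == 35.0
        assert bm.amplitude == 120.0

    def test_flat_trace_raises(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(ProtocolError, match="upstroke"):
            measure_ap_biomarkers((t, np.full_like(t, -85.0)))

    def test_steady_state_rmp_matches_fixed_point(self, ge, ge_rest,
                                                  ge_steady):
        trace, _ = ge_steady
        bm = measure_ap_biomarkers(trace)
        assert abs(bm.RMP - ge_rest.V) < 1.0

    def test_sampling_rate_stability(self, ge_steady):
        trace, _ = ge_steady
        bm_fine = measure_ap_biomarkers(trace)
        coarse = (trace.t[::2], trace.V[::2])
        bm_coarse = measure_ap_biomarkers(coarse)
        assert abs(bm_fine.APD90 - bm_coarse.APD90) < 1.0


class TestCaTBiomarkers:
    def test_analytic_pulse(self):
        """Linear rise 1e-4 -> 1.1e-3 mM over 30 ms then linear fall over
        300 ms: time to peak 30 ms, 90% return 270 ms."""
        t1 = np.linspace(0, 30, 301)
        t2 = np.linspace(30, 330, 3001)[1:]
        t = np.concatenate([[-1.0], t1, t2])
        ca = np.concatenate([[1e-4], 1e-4 + (1e-3 / 30.0) * t1,
                             1.1e-3 - (1e-3 / 300.0) * (t2 - 30.0)])
        bm = measure_cat_biomarkers((t, ca), stim_onset=0.0)
        assert bm.time_to_peak == pytest.approx(30.0, abs=0.1)
        assert bm.t90_return == pytest.approx(270.0, abs=0.2)

    def test_monotone_trace_raises(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(ProtocolError):
            measure_cat_biomarkers((t, np.linspace(1e-4, 2e-4, 101)))

    def test_sampling_rate_stability(self, ge_steady):
        trace, _ = ge_steady
        fine = measure_cat_biomarkers(trace)
        coarse = measure_cat_biomarkers((trace.t[::2], trace.Cai[::2]))
        assert abs(fine.time_to_peak - coarse.time_to_peak) < 1.0
        assert abs(fine.t90_return - coarse.t90_return) < 1.0


class TestPacing:
    def test_periodicity_at_20_beats(self, ge_steady):
        trace, _ = ge_steady
        assert trace.periodic is True

    def test_single_beat(self, ge):
        trace, _ = pace_to_steady_state(ge, n_beats=1)
        assert trace.periodic is None
        assert trace.V.max() > 0

    def test_zero_amplitude_no_capture(self, ge):
        with pytest.raises(ProtocolError, match="capture"):
            pace_to_steady_state(ge, n_beats=1,
                                 stim=StimulusSpec(amplitude=0.0))


class TestThreshold:
    def test_bisection_consistency(self, ge, ge_rest):
        thr = find_diastolic_threshold(ge, rest_state=ge_rest)
        from genodt.ionic import run_cell

        tr_lo, _ = run_cell(ge_rest.copy(), ge, 51.0, [(0.0, 1.0, -0.99 * thr)],
                            dt=0.02)
        tr_hi, _ = run_cell(ge_rest.copy(), ge, 51.0, [(0.0, 1.0, -1.01 * thr)],
                            dt=0.02)
        assert tr_lo.V.max() < 0.0
        assert tr_hi.V.max() > 0.0


class TestRestitution:
    def test_synthetic_linear_slope(self):
        di = np.array([300.0, 200.0, 100.0])
        curve = RestitutionCurve(di=di, apd90=200.0 + 0.5 * di,
                                 captured=np.ones(3, dtype=bool))
        assert max_restitution_slope(curve) == pytest.approx(0.5)

    def test_slope_needs_two_captured(self):
        curve = RestitutionCurve(di=np.array([100.0]),
                                 apd90=np.array([180.0]),
                                 captured=np.array([True]))
        with pytest.raises(ProtocolError):
            max_restitution_slope(curve)

    def test_sample_count_without_extension(self, ge):
        # protocol arithmetic: 1000 -> 50 ms by 25 ms = 39 DIs
        dis = np.arange(1000.0, 49.0, -25.0)
        assert len(dis) == 39

    def test_di_strictly_decreasing(self, ge_restitution):
        assert np.all(np.diff(ge_restitution.di) < 0)

    def test_restitution_divergence_at_fast_pacing(self, ge_restitution,
                                                   pkp2_restitution):
        """PKP2 repolarizes slower than GE at every captured DI <= 160 ms."""
        for di, apd, cap in zip(pkp2_restitution.di, pkp2_restitution.apd90,
                                pkp2_restitution.captured):
            if not cap or di > 160.0:
                continue
            j = np.where(ge_restitution.di == di)[0]
            if len(j) and ge_restitution.captured[j[0]]:
                assert apd > ge_restitution.apd90[j[0]]

    def test_rate_adaptation_and_slope_ordering(self, ge_restitution,
                                                pkp2_restitution):
        ge_c = ge_restitution
        assert ge_c.apd90[0] > ge_c.min_captured_APD90
        assert pkp2_restitution.max_slope < ge_restitution.max_slope


class TestIVCurve:
    def test_zero_at_reversal_potential(self, ge):
        from genodt.protocols import ClampSpec
        import math

        ena = ionic.RTONF * math.log(ge["Na_o"] / 8.604)
        iv = iv_curve_INa(ge, ClampSpec(v_tests=(ena,)))
        assert iv[0][1] == pytest.approx(0.0, abs=1e-9)

    def test_peak_location_near_minus_36(self, ge):
        iv = iv_curve_INa(ge)
        v_at_peak = min(iv, key=lambda kv: kv[1])[0]
        assert -45.0 <= v_at_peak <= -25.0

    def test_pkp2_scaling_is_pure_conductance(self, ge, pkp2):
        """Identical clamp: peak ratio = 0.30 at every test potential."""
        iv_ge = dict(iv_curve_INa(ge))
        iv_pk = dict(iv_curve_INa(pkp2))
        for v, ina in iv_ge.items():
            if abs(ina) > 1e-6:
                assert iv_pk[v] / ina == pytest.approx(0.30, rel=1e-9)
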