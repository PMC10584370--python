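"""Ionic model unit tests: parameter handling, variants, currents, stepping."""

import json
import math

import numpy as np
import pytest

from genodt import ionic
from genodt.ionic import (
    BASELINE_PARAMS, CellState, ParameterError, VariantParameterSet,
    compute_currents, load_baseline, make_variant, run_cell, step,
)


@pytest.fixture()
def baseline_file(tmp_path):
    p = tmp_path / "ge.json"
    ionic.baseline_ge().to_file(p)
    return p


class TestParameterIO:
    def test_roundtrip_and_published_constants(self, baseline_file):
        p = load_baseline(baseline_file)
        assert p["g_Na"] == pytest.approx(14.838)
        assert p["K_bufsr"] == pytest.approx(0.3)
        assert p["V_rel"] == pytest.approx(0.102)
        assert p.values == ionic.baseline_ge().values

    def test_missing_constant_is_named(self, tmp_path):
        raw = dict(BASELINE_PARAMS)
        del raw["g_CaL"]
        f = tmp_path / "bad.json"
        f.write_text(json.dumps(raw))
        with pytest.raises(ParameterError, match="g_CaL"):
            load_baseline(f)

    def test_nan_constant_rejected(self, tmp_path):
        raw = dict(BASELINE_PARAMS)
        raw["g_Kr"] = float("nan")
        f = tmp_path / "bad.json"
        f.write_text(json.dumps(raw).replace("NaN", "\"nan\""))
        with pytest.raises(ParameterError, match="g_Kr"):
            load_baseline(f)

    def test_unknown_key_rejected(self, tmp_path):
        raw = dict(BASELINE_PARAMS)
        raw["g_Mystery"] = 1.0
        f = tmp_path / "bad.json"
        f.write_text(json.dumps(raw))
        with pytest.raises(ParameterError, match="g_Mystery"):
            load_baseline(f)


class TestVariants:
    def test_pkp2_scalings_exact(self, ge, pkp2):
        assert pkp2["g_Na"] == pytest.approx(0.30 * ge["g_Na"], rel=1e-12)
        assert pkp2["g_Na"] == pytest.approx(4.4514)
        assert pkp2["g_CaL"] == pytest.approx(0.50 * ge["g_CaL"], rel=1e-12)
        assert pkp2["g_bCa"] == pytest.approx(5.0 * ge["g_bCa"], rel=1e-12)
        assert pkp2["k_NaCa"] == pytest.approx(0.80 * ge["k_NaCa"], rel=1e-12)
        assert pkp2["V_rel"] == pytest.approx(0.0816)
        assert pkp2["V_leak"] == pytest.approx(2.88e-4)
        assert pkp2["K_bufsr"] == pytest.approx(0.18)

    def test_fibrosis_scalings_exact(self, ge, fibrosis):
        expected = {"g_NaL": 2.07, "g_CaL": 1.19, "g_Kr": 0.66, "g_Ks": 0.73,
                    "g_to": 0.15, "g_K1": 0.85, "k_NaCa": 1.34,
                    "V_maxup": 0.57}
        for k, s in expected.items():
            assert fibrosis[k] == pytest.approx(s * ge[k], rel=1e-12), k

    def test_ge_variant_is_identity(self, ge):
        assert make_variant(ge, "GE").values == ge.values

    def test_unknown_variant(self, ge):
        with pytest.raises(ParameterError):
            make_variant(ge, "DSP")

    def test_negative_parameter_rejected(self, ge):
        with pytest.raises(ParameterError):
            ge.with_overrides(g_Na=-1.0)


class TestCurrents:
    def test_closed_sodium_channel(self, ge):
        s = CellState.initial()
        for name in ("m", "h", "j"):
            s.values[ionic.STATE_NAMES.index(name)] = 0.0
        assert compute_currents(s, ge).I_Na == 0.0

    @pytest.mark.parametrize("gname,iname", [
        ("g_Na", "I_Na"), ("g_CaL", "I_CaL"), ("g_Kr", "I_Kr"),
        ("g_Ks", "I_Ks"), ("g_to", "I_to"), ("g_K1", "I_K1"),
        ("g_bCa", "I_bCa"), ("g_NaL", "I_NaL"),
    ])
    def test_conductance_linearity(self, ge, gname, iname):
        """Every gated/Ohmic current scales exactly with its conductance."""
        s = CellState.initial()
        s.values[0] = -20.0  # depolarized clamp point so currents flow
        full = compute_currents(s, ge).values[iname]
        half = compute_currents(s, ge.with_overrides(
            **{gname: 0.5 * ge[gname]})).values[iname]
        assert half == pytest.approx(0.5 * full, rel=1e-12, abs=1e-15)

    def test_resting_fixed_point_balance(self, ge, ge_rest):
        cur = compute_currents(ge_rest, ge)
        assert abs(cur.I_total) < 1e-3

    def test_nonfinite_state_identified(self, ge):
        s = CellState.initial()
        s.values[ionic.STATE_NAMES.index("Cai")] = float("nan")
        with pytest.raises(ValueError, match="Cai"):
            compute_currents(s, ge)


class TestStepping:
    def test_dt_validation(self, ge):
        with pytest.raises(ValueError):
            step(CellState.initial(), ge, dt=0.1)
        with pytest.raises(ValueError):
            step(CellState.initial(), ge, dt=0.0)

    def test_rest_is_stationary(self, ge, ge_rest):
        trace, final = run_cell(ge_rest.copy(), ge, 20.0, [], dt=0.02)
        assert abs(final.V - ge_rest.V) < 0.01

    def test_threshold_stimulus_elicits_upstroke(self, ge, ge_rest):
        trace, _ = run_cell(ge_rest.copy(), ge, 50.0, [(0.0, 1.0, -52.0)],
                            dt=0.02)
        assert trace.V.max() > 0.0

    def test_gates_stay_in_bounds(self, ge, ge_rest):
        _, final = run_cell(ge_rest.copy(), ge, 400.0, [(0.0, 1.0, -52.0)],
                            dt=0.02)
        final.validate()  # checks gates in [0,1], concentrations > 0

    def test_dt_convergence_of_apd90(self, ge):
        """Halving dt changes the paced APD90 by < 1 ms."""
        from genodt import protocols

        apds = []
        for dt in (0.02, 0.01):
            tr, _ = protocols.pace_to_steady_state(ge, n_beats=5, dt=dt)
            apds.append(protocols.measure_ap_biomarkers(tr).APD90)
        assert abs(apds[0] - apds[1]) < 1.0

    def test_concentrations_positive_under_pacing(self, ge, pkp2, fibrosis):
        """Minute-scale 1 Hz pacing keeps all concentrations positive.

        Run is shortened to 20 beats; the slow ionic drifts are monotone in
        this regime so positivity over the conditioning run is the binding
        check.
        """
        for p in (ge, pkp2, fibrosis):
            _, final = run_cell(CellState.initial(), p, 20_000.0,
                                [(i * 1000.0, 1.0, -52.0) for i in range(20)],
                                dt=0.02, sample_every=50.0)
            assert np.all(final.values[16:21] > 0)
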