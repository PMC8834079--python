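import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ojipsuite import errors
from ojipsuite import synthetic as syn
from ojipsuite.io_formats import Channel, KineticTrace
from ojipsuite.jip import (OjipMarkers, analyze_transient, extract_markers,
                           jip_table, phenomenological_fluxes, quantum_yields,
                           specific_fluxes)

# Hand-evaluated worked example: F_o=500, F_K=900, F_J=1500, F_I=2100, F_m=2500
HAND_MARKERS = OjipMarkers(F_o=500.0, F_K=900.0, F_J=1500.0, F_I=2100.0, F_m=2500.0,
                           t_Fm_us=300000.0, F_v=2000.0, V_J=0.5, V_I=0.8, M_o=0.8)


class TestExtractMarkers:
    def test_generator_anchors_recovered(self, clean_pf_trace):
        m = extract_markers(clean_pf_trace)
        assert (m.F_o, m.F_J, m.F_I, m.F_m) == (500.0, 1500.0, 2100.0, 2500.0)
        assert m.V_J == pytest.approx(0.5) and m.V_I == pytest.approx(0.8)

    def test_constant_trace_is_degenerate(self):
        t = np.geomspace(20, 3e5, 100)
        trace = KineticTrace(Channel.PF, t, np.full(100, 1000.0))
        with pytest.raises(errors.DegenerateTransientError):
            extract_markers(trace)

    def test_mo_hand_value(self):
        spec = syn.PfSpec(f_o=500.0, f_m=2500.0, v_K=0.2, v_J=0.5, v_I=0.8)
        m = extract_markers(syn.make_pf_trace(spec))
        assert m.M_o == pytest.approx(4 * 0.2, rel=1e-9)  # 0.8 per ms

    def test_trace_not_covering_20us_is_coverage_error(self, clean_pf_spec):
        t = np.geomspace(100, 3e5, 100)
        trace = KineticTrace(Channel.PF, t, np.linspace(500, 2500, 100))
        with pytest.raises(errors.CoverageError):
            extract_markers(trace)

    def test_wrong_channel_rejected(self, mr_valley_spec):
        with pytest.raises(errors.ValidationError):
            extract_markers(syn.make_mr_trace(mr_valley_spec))

    def test_fm_tie_break_takes_earliest_time(self):
        t = np.geomspace(20, 3e5, 100)
        v = np.linspace(500, 2500, 100)
        v[60:] = 2500.0  # plateau
        m = extract_markers(KineticTrace(Channel.PF, t, v))
        assert m.t_Fm_us == pytest.approx(t[60])

    def test_interpolation_matches_dense_grid_oracle(self, clean_pf_spec):
        """Log-linear marker interpolation vs nearest-point lookup on a dense
        generator grid: within 0.1% at >= 500 points."""
        tr = syn.make_pf_trace(clean_pf_spec, syn.LogGrid(n=500))
        dense = syn.make_pf_trace(clean_pf_spec, syn.LogGrid(n=50_000))
        m = extract_markers(tr)
        for t_us, got in ((300.0, m.F_K), (2000.0, m.F_J), (30000.0, m.F_I)):
            oracle = dense.values[np.argmin(np.abs(dense.times - t_us))]
            assert got == pytest.approx(oracle, rel=1e-3)


class TestQuantumYields:
    def test_wt_identity_phi_eo(self):
        """phi_Eo = phi_Po * psi_o: 0.82 * 0.70 = 0.574, printing as 0.57."""
        y = quantum_yields(HAND_MARKERS)
        assert y.phi_Eo == pytest.approx(y.phi_Po * y.psi_o, abs=1e-12)
        assert 0.82 * 0.70 == pytest.approx(0.574)

    def test_delta_ro_is_ratio_of_yields(self):
        y = quantum_yields(HAND_MARKERS)
        assert y.delta_Ro == pytest.approx(y.phi_Ro / y.phi_Eo, rel=1e-12)
        assert 0.20 / 0.57 == pytest.approx(0.3509, abs=1e-4)

    def test_no_closure_limit(self):
        m = OjipMarkers(F_o=500, F_K=900, F_J=500, F_I=500, F_m=2500, t_Fm_us=3e5,
                        F_v=2000, V_J=0.0, V_I=0.0, M_o=0.8)
        y = quantum_yields(m)
        assert y.psi_o == 1.0 and y.delta_Ro == 1.0
        assert y.phi_Eo == y.phi_Po == y.phi_Ro

    def test_vj_one_is_undefined_delta_ro(self):
        m = OjipMarkers(F_o=500, F_K=900, F_J=2500, F_I=2500, F_m=2500, t_Fm_us=3e5,
                        F_v=2000, V_J=1.0, V_I=1.0, M_o=0.8)
        with pytest.raises(errors.DegenerateTransientError):
            quantum_yields(m)


class TestSpecificFluxes:
    def test_hand_evaluated_example(self):
        s = specific_fluxes(HAND_MARKERS)
        assert s.TR0_RC == pytest.approx(1.6)
        assert s.ABS_RC == pytest.approx(2.0)
        assert s.DI0_RC == pytest.approx(0.4)
        assert s.ET0_RC == pytest.approx(0.8)
        assert s.RE0_RC == pytest.approx(0.32)

    def test_abs_equals_tr_plus_di_exactly(self):
        s = specific_fluxes(HAND_MARKERS)
        assert s.ABS_RC - s.TR0_RC - s.DI0_RC == 0.0

    def test_gamma_rc_half_when_abs_rc_is_one(self):
        # ABS_RC = (M_o/V_J)/phi_Po = 1 for M_o=0.4, V_J=0.5, phi_Po=0.8
        m = OjipMarkers(F_o=500, F_K=700, F_J=1500, F_I=2100, F_m=2500, t_Fm_us=3e5,
                        F_v=2000, V_J=0.5, V_I=0.8, M_o=0.4)
        assert specific_fluxes(m).ABS_RC == pytest.approx(1.0)
        assert quantum_yields(m).gamma_RC == pytest.approx(0.5)

    def test_vj_zero_is_undefined(self):
        m = OjipMarkers(F_o=500, F_K=900, F_J=500, F_I=2100, F_m=2500, t_Fm_us=3e5,
                        F_v=2000, V_J=0.0, V_I=0.8, M_o=0.8)
        with pytest.raises(errors.DegenerateTransientError):
            specific_fluxes(m)


class TestPhenomenologicalFluxes:
    def test_hand_evaluated_example(self):
        p = phenomenological_fluxes(HAND_MARKERS)
        assert p.ABS_CSM == pytest.approx(2500.0)
        assert p.TR0_CSM == pytest.approx(2000.0)
        assert p.ET0_CSM == pytest.approx(1000.0)
        assert p.RE0_CSM == pytest.approx(400.0)
        assert p.DI0_CSM == pytest.approx(500.0)
        assert p.RC_CSM == pytest.approx(1250.0)

    def test_rc_density_ratio_equals_fm_over_fo(self):
        p = phenomenological_fluxes(HAND_MARKERS)
        assert p.RC_CSM / p.RC_CSo == pytest.approx(HAND_MARKERS.F_m / HAND_MARKERS.F_o,
                                                    rel=1e-12)

    def test_output_units_follow_input_trace_scale(self):
        """Doubling the trace counts doubles every per-CS flux."""
        spec = syn.PfSpec(f_o=1000.0, f_m=5000.0, v_J=0.5, v_I=0.8)
        p1 = analyze_transient(syn.make_pf_trace(syn.PfSpec(f_o=500, f_m=2500,
                                                            v_J=0.5, v_I=0.8))).phenomenological
        p2 = analyze_transient(syn.make_pf_trace(spec)).phenomenological
        assert p2.ABS_CSM == pytest.approx(2 * p1.ABS_CSM, rel=1e-9)
        assert p2.RC_CSM == pytest.approx(2 * p1.RC_CSM, rel=1e-9)


class TestJipTable:
    def test_two_groups_three_replicates(self):
        traces, _ = syn.make_dataset(syn.default_group_specs(), 3, seed=0)
        pf = [t for t in traces if t.channel is Channel.PF]
        table, failures = jip_table(pf)
        assert len(table) == 6 and not failures
        assert set(table["group"]) == {"WT", "MT"}

    def test_degenerate_replicate_reported_not_dropped(self, clean_pf_spec):
        good = [syn.make_pf_trace(clean_pf_spec, replicate_id=str(i)) for i in range(5)]
        t = np.geomspace(20, 3e5, 100)
        bad = KineticTrace(Channel.PF, t, np.full(100, 7.0), "WT", "bad")
        table, failures = jip_table(good + [bad])
        assert len(table) == 5
        assert len(failures) == 1 and failures[0]["replicate"] == "bad"

    def test_noise_free_rows_reproduce_spec_phi_po(self, clean_pf_spec):
        table, _ = jip_table([syn.make_pf_trace(clean_pf_spec)])
        truth = 1 - clean_pf_spec.f_o / clean_pf_spec.f_m
        assert table.loc[0, "phi_Po"] == pytest.approx(truth, abs=1e-12)


@given(
    f_o=st.floats(200, 2000),
    span=st.floats(500, 8000),
    v_k_frac=st.floats(0.1, 0.8),
    v_j=st.floats(0.15, 0.85),
    dv=st.floats(0.02, 0.14),
)
@settings(max_examples=40, deadline=None)
def test_identity_suite_holds_for_any_valid_transient(f_o, span, v_k_frac, v_j, dv):
    """JIP internal identities hold to 1e-9 whatever the transient shape."""
    spec = syn.PfSpec(f_o=f_o, f_m=f_o + span, v_K=v_k_frac * v_j, v_J=v_j, v_I=v_j + dv)
    a = analyze_transient(syn.make_pf_trace(spec))
    y, s, p, m = a.yields, a.specific, a.phenomenological, a.markers
    assert y.phi_Po + y.phi_Do == pytest.approx(1.0, abs=1e-9)
    assert y.phi_Eo == pytest.approx(y.phi_Po * (1 - m.V_J), abs=1e-9)
    assert y.phi_Ro == pytest.approx(y.phi_Eo * y.delta_Ro, abs=1e-9)
    assert s.ABS_RC == pytest.approx(s.TR0_RC + s.DI0_RC, rel=1e-9)
    assert p.ET0_CSM == pytest.approx(y.phi_Eo * p.ABS_CSM, rel=1e-9)
    assert p.RC_CSM * m.M_o == pytest.approx(y.phi_Po * m.V_J * m.F_m, rel=1e-9)


def test_increasing_vj_strictly_decreases_psi_o_and_phi_eo():
    results = []
    for v_j in (0.3, 0.45, 0.6, 0.75):
        spec = syn.PfSpec(v_J=v_j, v_I=0.9)
        results.append(analyze_transient(syn.make_pf_trace(spec)).yields)
    psi = [y.psi_o for y in results]
    eo = [y.phi_Eo for y in results]
    assert all(a > b for a, b in zip(psi, psi[1:]))
    assert all(a > b for a, b in zip(eo, eo[1:]))
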