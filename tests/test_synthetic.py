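import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ojipsuite import errors
from ojipsuite import synthetic as syn
from ojipsuite.jip import extract_markers
from ojipsuite.pigments import pigment_concentrations


class TestMakePfTrace:
    def test_anchor_values_interpolated_exactly(self, clean_pf_trace):
        f_at = lambda t: np.interp(t, clean_pf_trace.times, clean_pf_trace.values)
        assert f_at(2000.0) == pytest.approx(1500.0, abs=1e-9)
        assert f_at(30000.0) == pytest.approx(2100.0, abs=1e-9)

    def test_seeded_noise_is_reproducible(self):
        spec = syn.PfSpec(noise_sd=25.0, seed=7)
        a, b = syn.make_pf_trace(spec), syn.make_pf_trace(spec)
        np.testing.assert_array_equal(a.values, b.values)
        c = syn.make_pf_trace(syn.PfSpec(noise_sd=25.0, seed=8))
        assert not np.array_equal(a.values, c.values)

    def test_noise_free_curve_is_non_decreasing(self, clean_pf_spec):
        tr = syn.make_pf_trace(clean_pf_spec, syn.LogGrid(n=10_000))
        assert np.all(np.diff(tr.values) >= -1e-12)

    def test_grid_not_covering_anchors_is_configuration_error(self, clean_pf_spec):
        with pytest.raises(errors.ConfigurationError):
            syn.make_pf_trace(clean_pf_spec, syn.LogGrid(t_min_us=100.0))

    @pytest.mark.parametrize("bad", [dict(f_o=0), dict(f_o=3000), dict(v_J=0.9, v_I=0.8)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(errors.ConfigurationError):
            syn.PfSpec(**bad)

    @given(
        f_o=st.floats(100, 1000),
        span=st.floats(500, 5000),
        v_j=st.floats(0.2, 0.7),
        dv=st.floats(0.05, 0.25),
    )
    @settings(max_examples=25, deadline=None)
    def test_marker_recovery_is_exact_for_any_valid_spec(self, f_o, span, v_j, dv):
        """Analyzer-recovered fiducials equal generator truth to 1e-9 relative."""
        spec = syn.PfSpec(f_o=f_o, f_m=f_o + span, v_J=v_j, v_I=v_j + dv)
        m = extract_markers(syn.make_pf_trace(spec))
        assert m.F_o == pytest.approx(spec.f_o, rel=1e-9)
        assert m.F_m == pytest.approx(spec.f_m, rel=1e-9)
        assert m.V_J == pytest.approx(spec.v_J, rel=1e-9)
        assert m.V_I == pytest.approx(spec.v_I, rel=1e-9)


class TestMakeMrTrace:
    def test_minimum_matches_closed_form_inside_reported_window(self, mr_valley_spec):
        tr = syn.make_mr_trace(mr_valley_spec, syn.LogGrid(700.0, 300_000.0, 5000))
        t_min_dense = tr.times[np.argmin(tr.values)] / 1000.0
        closed = syn.mr_model_tmin(8.0, 70.0)
        assert closed == pytest.approx(8.0 * np.log(78.0 / 8.0))
        assert t_min_dense == pytest.approx(closed, rel=2e-3)
        assert 15.0 <= closed <= 20.0

    def test_zero_amplitude_gives_constant_unit_curve(self):
        tr = syn.make_mr_trace(syn.MrSpec(amplitude=0.0, gain=3.0))
        np.testing.assert_allclose(tr.values / 3.0, 1.0)

    def test_amplitude_at_least_one_rejected(self):
        with pytest.raises(errors.ConfigurationError):
            syn.MrSpec(amplitude=1.0)

    def test_gain_scales_signal_linearly(self, mr_valley_spec):
        from dataclasses import replace
        a = syn.make_mr_trace(replace(mr_valley_spec, gain=1.0))
        b = syn.make_mr_trace(replace(mr_valley_spec, gain=3.7))
        np.testing.assert_allclose(b.values, 3.7 * a.values, rtol=1e-12)


class TestMakeDfTraces:
    def test_induction_maxima_at_specified_peaks(self):
        spec = syn.DfSpec(peak1_time_us=7000.0, peak2_time_us=60000.0, bump_width=0.25)
        ind, _ = syn.make_df_traces(spec, syn.LogGrid(100.0, 300_000.0, 2000))
        v = ind.values
        locs = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
        step = np.diff(np.log10(ind.times)).max()
        peak_logs = np.log10(ind.times[locs])
        assert any(abs(pl - np.log10(7000)) <= step for pl in peak_logs)
        assert any(abs(pl - np.log10(60000)) <= step for pl in peak_logs)

    def test_zero_second_amplitude_leaves_single_interior_maximum(self):
        spec = syn.DfSpec(peak2_amp=0.0, baseline_amp=0.0)
        ind, _ = syn.make_df_traces(spec)
        v = ind.values
        assert ((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])).sum() == 1

    def test_decay_value_at_zero_is_sum_of_weights(self):
        _, dec = syn.make_df_traces(syn.DfSpec(decay_amps=(60.0, 40.0)))
        assert dec.times[0] == 0.0
        assert dec.values[0] == pytest.approx(100.0)

    def test_merged_bumps_warn_not_error(self):
        with pytest.warns(UserWarning):
            syn.make_df_traces(syn.DfSpec(peak1_time_us=7000.0, peak2_time_us=8000.0,
                                          bump_width=0.5))


class TestMakeDataset:
    def test_counts_for_two_groups_three_replicates(self):
        traces, records = syn.make_dataset(syn.default_group_specs(), 3, seed=0)
        by_channel = {}
        for t in traces:
            by_channel.setdefault(t.channel.value, []).append(t)
        assert len(by_channel["PF"]) == 6
        assert len(by_channel["MR"]) == 6
        assert len(by_channel["DF"]) == 12  # induction + decay per replicate
        assert len(records) == 6

    def test_same_master_seed_reproduces_dataset(self):
        t1, r1 = syn.make_dataset(syn.default_group_specs(), 2, seed=42)
        t2, r2 = syn.make_dataset(syn.default_group_specs(), 2, seed=42)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)
        assert r1 == r2

    def test_duplicate_group_labels_impossible_but_n1_rejected(self):
        with pytest.raises(errors.ConfigurationError):
            syn.make_dataset(syn.default_group_specs(), 1, seed=0)

    def test_pigment_truth_round_trips_through_absorbance_inversion(self):
        truth = syn.PigmentTruth(chl_a=0.38, chl_b=0.09, carotenoids=0.14, noise_cv=0.0)
        rec = syn.make_absorbance_record(truth, seed=0, group_label="WT")
        res = pigment_concentrations(rec, "acetone80")
        assert res.chl_a == pytest.approx(0.38, abs=1e-9)
        assert res.chl_b == pytest.approx(0.09, abs=1e-9)
        assert res.carotenoids == pytest.approx(0.14, abs=1e-9)

    def test_per_trace_seeds_differ_across_replicates(self):
        s1 = syn.derive_seed(0, "WT", "1", "PF")
        s2 = syn.derive_seed(0, "WT", "2", "PF")
        s3 = syn.derive_seed(0, "MT", "1", "PF")
        assert len({s1, s2, s3}) == 3 and all(0 <= s < 2**31 for s in (s1, s2, s3))
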