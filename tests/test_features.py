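"""Audiogram summaries, temporal column summaries, and dataset assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from schwannoma.cohort import (
    ACTIVE,
    AUDIO_FREQS_KHZ,
    BASIC_FREQS_KHZ,
    Cohort,
    PatientHistory,
)
from schwannoma.features import (
    DEFAULT_PDA_BASE,
    build_cbr_dataset,
    build_pda_dataset,
    cbr_columns,
    cbr_feature_vector,
    column_summary,
    pta_average,
    pta_linfit,
)

from conftest import flat_audiogram, make_checkup


def normal_equations(x, y):
    """Closed-form OLS oracle for (slope, intercept)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestPtaAverage:
    def test_constant_audiogram(self):
        assert pta_average(flat_audiogram(40.0), "full") == 40.0

    def test_basic_range_mean(self):
        gram = dict(zip(BASIC_FREQS_KHZ, (10, 10, 20, 20, 30, 30)))
        gram.update({6.0: 99.0, 8.0: 99.0})  # outside the basic range
        assert pta_average(gram, "basic") == 20.0

    def test_missing_threshold_propagates(self):
        gram = flat_audiogram(40.0)
        gram[2.0] = None
        assert pta_average(gram, "basic") is None
        assert pta_average(gram, "full") is None

    def test_missing_outside_range_ignored(self):
        gram = flat_audiogram(40.0)
        gram[8.0] = None
        assert pta_average(gram, "basic") == 40.0

    def test_unknown_range_rejected(self):
        with pytest.raises(ValueError):
            pta_average(flat_audiogram(40.0), "extended")


class TestPtaLinfit:
    def test_flat_audiogram(self):
        slope, intercept = pta_linfit(flat_audiogram(55.0), "full")
        assert abs(slope) < 1e-9
        assert abs(intercept - 55.0) < 1e-9

    def test_exact_line_in_khz(self):
        gram = {f: 5.0 + 10.0 * f for f in AUDIO_FREQS_KHZ}
        slope, intercept = pta_linfit(gram, "full")
        assert abs(slope - 10.0) < 1e-9
        assert abs(intercept - 5.0) < 1e-9

    def test_matches_normal_equations_oracle(self):
        # non-collinear audiogram, frozen values
        levels = (15.0, 20.0, 10.0, 35.0, 40.0, 55.0, 45.0, 70.0)
        gram = dict(zip(AUDIO_FREQS_KHZ, levels))
        for range_id, freqs in (("basic", BASIC_FREQS_KHZ), ("full", AUDIO_FREQS_KHZ)):
            want = normal_equations(freqs, [gram[f] for f in freqs])
            got = pta_linfit(gram, range_id)
            assert got == pytest.approx(want, abs=1e-9)

    def test_alternative_abscissae(self):
        levels = (15.0, 20.0, 10.0, 35.0, 40.0, 55.0, 45.0, 70.0)
        gram = dict(zip(AUDIO_FREQS_KHZ, levels))
        want_log = normal_equations(np.log2(AUDIO_FREQS_KHZ), levels)
        assert pta_linfit(gram, "full", abscissa="log2khz") == pytest.approx(want_log, abs=1e-9)
        want_idx = normal_equations(range(8), levels)
        assert pta_linfit(gram, "full", abscissa="index") == pytest.approx(want_idx, abs=1e-9)

    @given(st.permutations(list(AUDIO_FREQS_KHZ)))
    def test_invariant_to_map_iteration_order(self, order):
        levels = dict(zip(AUDIO_FREQS_KHZ, (15, 20, 10, 35, 40, 55, 45, 70)))
        gram = {f: float(levels[f]) for f in order}
        assert pta_linfit(gram, "full") == pta_linfit(levels, "full")
        assert pta_average(gram, "basic") == pta_average(levels, "basic")


class TestCbrVector:
    def test_derived_fields_match_primitive_ops(self):
        levels = dict(zip(AUDIO_FREQS_KHZ, (15.0, 20.0, 10.0, 35.0, 40.0, 55.0, 45.0, 70.0)))
        rec = make_checkup(pta_vs=levels, pta_h=flat_audiogram(10.0))
        v = cbr_feature_vector(rec)
        assert v["PTA_VS_AR8"] == pta_average(levels, "full")
        assert v["PTA_VS_SR4"] == pta_linfit(levels, "basic")[0]
        assert v["PTA_H_IR8"] == pta_linfit(flat_audiogram(10.0), "full")[1]
        assert v["PTA_D_AR4"] == pytest.approx(v["PTA_VS_AR4"] - v["PTA_H_AR4"])

    def test_ear_swap_negates_interaural_difference(self):
        a = dict(zip(AUDIO_FREQS_KHZ, (15.0, 20.0, 10.0, 35.0, 40.0, 55.0, 45.0, 70.0)))
        b = flat_audiogram(20.0)
        v_ab = cbr_feature_vector(make_checkup(pta_vs=a, pta_h=b))
        v_ba = cbr_feature_vector(make_checkup(pta_vs=b, pta_h=a))
        for n in ("4", "8"):
            assert v_ab[f"PTA_D_AR{n}"] == pytest.approx(-v_ba[f"PTA_D_AR{n}"])

    def test_dataset_shape_and_target(self, small_cohort):
        df = build_cbr_dataset(small_cohort)
        assert len(df) == small_cohort.n_checkups
        assert list(df.columns) == cbr_columns() + ["decision"]
        assert df["decision"].tolist() == ["WaS", "WaS", "WaS", "WaS", "Active"]

    def test_empty_cohort_gives_empty_frame(self):
        assert len(build_cbr_dataset(Cohort(()))) == 0


class TestColumnSummary:
    def test_exact_line(self):
        s = column_summary([(0.0, 10.0), (100.0, 11.0), (200.0, 12.0)])
        assert s.ac == pytest.approx(11.0)
        assert s.sc == pytest.approx(0.01, abs=1e-12)
        assert s.ic == pytest.approx(10.0, abs=1e-9)
        assert s.ld == pytest.approx(1.0)
        assert s.td == pytest.approx(2.0)

    def test_single_point_degenerates(self):
        s = column_summary([(0.0, 3.0)])
        assert (s.ac, s.ic, s.td) == (3.0, 3.0, 0.0)
        assert s.sc is None and s.ld is None

    def test_matches_normal_equations_oracle(self, rng):
        t = np.sort(rng.uniform(0, 2000, 6))
        v = rng.normal(20, 8, 6)
        s = column_summary(list(zip(t, v)))
        slope, intercept = normal_equations(t, v)
        assert s.sc == pytest.approx(slope, abs=1e-9)
        assert s.ic == pytest.approx(intercept, abs=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            column_summary([])

    @given(st.floats(-5000, 5000))
    def test_time_shift_moves_only_intercept(self, shift):
        pts = [(0.0, 10.0), (300.0, 18.0), (650.0, 13.0), (900.0, 25.0)]
        s0 = column_summary(pts)
        s1 = column_summary([(t + shift, v) for t, v in pts])
        assert s1.sc == pytest.approx(s0.sc, rel=1e-9, abs=1e-12)
        assert s1.ic == pytest.approx(s0.ic - shift * s0.sc, rel=1e-6, abs=1e-6)
        assert s1.ld == s0.ld and s1.td == s0.td and s1.ac == s0.ac

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=8))
    def test_total_difference_telescopes(self, values):
        pts = [(float(i * 100), v) for i, v in enumerate(values)]
        s = column_summary(pts)
        assert s.td == pytest.approx(sum(b - a for a, b in zip(values, values[1:])), abs=1e-9)


class TestPdaDataset:
    def test_koos_steps(self):
        hist = PatientHistory("P", (
            make_checkup("P", 0.0, koos=2),
            make_checkup("P", 300.0, koos=2),
            make_checkup("P", 600.0, koos=3, decision=ACTIVE),
        ))
        df = build_pda_dataset(Cohort((hist,)))
        assert df.loc["P", "Koos_LD"] == 1.0
        assert df.loc["P", "Koos_TD"] == 1.0
        assert df.loc["P", "outcome"] == "Active"

    def test_constant_size_series(self):
        hist = PatientHistory("P", tuple(
            make_checkup("P", float(i * 300), size_mm=9.0) for i in range(4)
        ))
        df = build_pda_dataset(Cohort((hist,)))
        assert df.loc["P", "Size_SC"] == 0.0
        assert df.loc["P", "Size_LD"] == 0.0
        assert df.loc["P", "Size_TD"] == 0.0

    def test_one_vector_per_patient(self, small_cohort):
        df = build_pda_dataset(small_cohort)
        assert len(df) == small_cohort.n_patients
        assert set(df.index) == {"P1", "P2"}

    def test_single_checkup_patient_has_missing_slopes(self, caplog):
        hist = PatientHistory("P", (make_checkup("P", 0.0),))
        with caplog.at_level("WARNING"):
            df = build_pda_dataset(Cohort((hist,)))
        assert "single checkup" in caplog.text
        assert np.isnan(df.loc["P", "Size_SC"])
        assert np.isnan(df.loc["P", "Size_LD"])
        assert df.loc["P", "Size_AC"] == df.loc["P", "Size_IC"]

    def test_series_skip_missing_values(self):
        hist = PatientHistory("P", (
            make_checkup("P", 0.0, srt=30.0),
            make_checkup("P", 300.0, srt=None),
            make_checkup("P", 600.0, srt=40.0),
        ))
        df = build_pda_dataset(Cohort((hist,)))
        # series is (0, 30), (600, 40): LD spans the gap
        assert df.loc["P", "SRT_LD"] == pytest.approx(10.0)
        assert df.loc["P", "SRT_AC"] == pytest.approx(35.0)
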