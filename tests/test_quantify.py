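import io
import math

import numpy as np
import pytest

from wbscan.quantify import (
    AmplificationRecord,
    CurveFitConfig,
    DilutionSeries,
    NormalizedValue,
    StandardCurve,
    apply_noise_filters,
    cross_reactivity_matrix,
    fit_standard_curve,
    make_default_dilution_series,
    model_ct,
    normalize_to_reference,
    percent_of_max,
    quantify,
    read_plate_csv,
    write_plate_csv,
)
from wbscan.simulate import AssayModel, simulate_dilution_series

PERFECT_SLOPE = -3.3219280948873623


class TestDilutionSeries:
    def test_default_ladder_14_points(self):
        concs = make_default_dilution_series()
        assert len(concs) == 14
        assert concs[0] == 10.0
        assert concs[-1] == pytest.approx(1e-12)  # 1 zg/ul
        ratios = [a / b for a, b in zip(concs, concs[1:])]
        assert all(r == pytest.approx(10.0) for r in ratios)

    def test_amo_protocol_ladder(self):
        # 8 ng/ul down to 0.8 zg/ul, 10-fold
        concs = make_default_dilution_series(8.0, 0.8e-12)
        assert len(concs) == 14
        assert concs[0] == 8.0
        assert concs[-1] == pytest.approx(0.8e-12)

    def test_degenerate_single_point(self):
        assert make_default_dilution_series(5.0, 5.0) == [5.0]

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            make_default_dilution_series(1.0, 2.0)
        with pytest.raises(ValueError):
            make_default_dilution_series(1.0, 0.1, fold=1.0)

    def test_concentrations_must_decrease(self):
        with pytest.raises(ValueError):
            DilutionSeries([1.0, 2.0], [[20.0], [19.0]])


class TestStandardCurve:
    def test_noiseless_fit_is_exact(self):
        model = AssayModel("a", noise_sd=0.0)
        concs = make_default_dilution_series(10.0, 1e-6)
        series = simulate_dilution_series(model, concs, replicates=3, seed=0)
        curve = fit_standard_curve(series)
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.linear_range == (pytest.approx(1e-6), 10.0)

    def test_censored_bottom_excluded_and_lod(self):
        # default model censors below 1e-9 (Ct 50 at intercept 20)
        model = AssayModel("a", noise_sd=0.0)
        concs = make_default_dilution_series()  # down to 1e-12
        series = simulate_dilution_series(model, concs, replicates=3, seed=0)
        assert series.detection_fraction(len(concs) - 1) == 0.0
        curve = fit_standard_curve(series)
        assert curve.linear_range[0] == pytest.approx(1e-9)
        assert curve.lod == pytest.approx(1e-9)

    def test_too_few_points(self):
        model = AssayModel("a", noise_sd=0.0)
        series = simulate_dilution_series(model, [10.0, 1.0, 0.1], replicates=2, seed=0)
        with pytest.raises(ValueError, match="usable"):
            fit_standard_curve(series)

    def test_parameter_recovery_under_noise(self):
        """Slope within 0.1 and efficiency within 5 points over 50 seeded
        repetitions (sigma = 0.2 Ct, 3 replicates, 10 points)."""
        model = AssayModel("a", noise_sd=0.2)
        concs = make_default_dilution_series(10.0, 1e-8)
        assert len(concs) == 10
        for rep in range(50):
            series = simulate_dilution_series(model, concs, replicates=3, seed=rep)
            curve = fit_standard_curve(series)
            assert abs(curve.slope - PERFECT_SLOPE) < 0.1
            assert abs(curve.efficiency - 1.0) < 0.05

    def test_quantify_inverse(self):
        curve = StandardCurve(PERFECT_SLOPE, 20.0, 1.0, 1.0, (1e-9, 10.0), 1e-9)
        assert quantify(20.0, curve) == pytest.approx(1.0)
        assert quantify(20.0 + curve.slope, curve) == pytest.approx(10.0)
        for c in (1e-8, 3.7e-5, 2.0):
            assert quantify(model_ct(c, curve), curve) == pytest.approx(c, rel=1e-9)
        with pytest.raises(ValueError):
            quantify(None, curve)


class TestNoiseFilters:
    def _curve(self):
        return StandardCurve(PERFECT_SLOPE, 20.0, 1.0, 1.0, (1e-9, 10.0), 1e-9, "m")

    def test_taqman_boundary(self):
        recs = [
            AmplificationRecord("A1", "g", "taqman", 35.0),
            AmplificationRecord("A2", "g", "taqman", 35.5),
            AmplificationRecord("A3", "g", "taqman", None),
        ]
        out = apply_noise_filters(recs)
        assert not out[0].noise          # Ct 35.0 retained
        assert out[1].noise              # strictly greater than 35
        assert out[2].noise              # censored

    def test_linear_range_rule(self):
        curve = self._curve()
        ct_out = model_ct(100.0, curve)   # above range high -> noise
        ct_in = model_ct(1e-5, curve)
        recs = [
            AmplificationRecord("A1", "m", "smallrna", ct_in),
            AmplificationRecord("A2", "m", "smallrna", ct_out),
            AmplificationRecord("A3", "m", "smallrna", None),
        ]
        out = apply_noise_filters(recs, {"m": curve})
        assert [r.noise for r in out] == [False, True, True]
        assert "linear range" in out[1].noise_reason

    def test_missing_curve_raises(self):
        recs = [AmplificationRecord("A1", "m", "smallrna", 30.0)]
        with pytest.raises(ValueError, match="standard curve"):
            apply_noise_filters(recs)

    def test_idempotent(self):
        curve = self._curve()
        recs = [
            AmplificationRecord("A1", "m", "smallrna", model_ct(1e-5, curve)),
            AmplificationRecord("A2", "g", "taqman", 36.0),
        ]
        once = apply_noise_filters(recs, {"m": curve})
        twice = apply_noise_filters(once, {"m": curve})
        assert [(r.noise, r.noise_reason) for r in once] == [
            (r.noise, r.noise_reason) for r in twice
        ]


class TestNormalization:
    def _curve(self, assay):
        return StandardCurve(PERFECT_SLOPE, 20.0, 1.0, 1.0, (1e-9, 10.0), 1e-9, assay)

    def _recs(self, assay, chem, cts):
        return [
            AmplificationRecord(f"A{i+1}", assay, chem, ct) for i, ct in enumerate(cts)
        ]

    def test_identity_and_scale_invariance(self):
        curves = {"t": self._curve("t"), "r": self._curve("r")}
        cts = [25.0, 28.0, 31.0]
        target = self._recs("t", "smallrna", cts)
        ref = self._recs("r", "smallrna", cts)
        out = normalize_to_reference(target, ref, curves)
        assert all(v.ratio == pytest.approx(1.0) for v in out.values())
        # scaling both assays by k leaves ratios unchanged
        shift = PERFECT_SLOPE  # one log10 step in quantity
        target2 = self._recs("t", "smallrna", [c + shift for c in cts])
        ref2 = self._recs("r", "smallrna", [c + shift for c in cts])
        out2 = normalize_to_reference(target2, ref2, curves)
        for w in out:
            assert out2[w].ratio == pytest.approx(out[w].ratio)

    def test_reference_noise_invalidates_only_that_well(self):
        curves = {"t": self._curve("t"), "r": self._curve("r")}
        target = self._recs("t", "smallrna", [25.0, 25.0])
        ref = self._recs("r", "smallrna", [25.0, 25.0])
        ref[1].noise = True
        out = normalize_to_reference(target, ref, curves)
        assert out["A1"].valid and not out["A2"].valid

    def test_ddct_fallback(self):
        target = self._recs("t", "smallrna", [26.0])
        ref = self._recs("r", "smallrna", [23.0])
        out = normalize_to_reference(target, ref, method="ddct")
        assert out["A1"].ratio == pytest.approx(2.0 ** -3)

    def test_no_overlap_raises(self):
        t = [AmplificationRecord("A1", "t", "smallrna", 25.0)]
        r = [AmplificationRecord("B1", "r", "smallrna", 25.0)]
        with pytest.raises(ValueError):
            normalize_to_reference(t, r, method="ddct")


class TestProfiles:
    def test_percent_of_max(self):
        out = percent_of_max({"a": 2.0, "b": 4.0, "c": 8.0})
        assert out == {"a": 25.0, "b": 50.0, "c": 100.0}

    def test_all_equal(self):
        out = percent_of_max({"a": 3.0, "b": 3.0})
        assert set(out.values()) == {100.0}

    def test_bounds_and_invalid_passthrough(self):
        out = percent_of_max({"a": 1.0, "b": None, "c": 5.0})
        assert out["b"] is None
        vals = [v for v in out.values() if v is not None]
        assert max(vals) == 100.0 and min(vals) >= 0.0

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            percent_of_max({})
        with pytest.raises(ValueError):
            percent_of_max({"a": None})


class TestCrossReactivity:
    def test_diagonal_is_100(self):
        panel = {("p", "p"): 4.2, ("p", "q"): 0.0, ("q", "q"): 1.0, ("q", "p"): 0.0}
        mat = cross_reactivity_matrix(panel, {"p": "p", "q": "q"})
        assert mat.loc["p", "p"] == 100.0
        assert mat.loc["q", "q"] == 100.0

    def test_off_diagonal_fraction(self):
        panel = {("p", "p"): 2.0, ("p", "q"): 0.06, ("q", "q"): 1.0, ("q", "p"): 0.0}
        mat = cross_reactivity_matrix(panel, {"p": "p", "q": "q"})
        assert mat.loc["p", "q"] == pytest.approx(3.0)

    def test_absent_template_zero(self):
        panel = {("p", "p"): 2.0, ("p", "q"): float("nan")}
        mat = cross_reactivity_matrix(panel, {"p": "p"})
        assert mat.loc["p", "q"] == 0.0

    def test_missing_matched_pair_raises(self):
        with pytest.raises(ValueError):
            cross_reactivity_matrix({("p", "q"): 1.0}, {"p": "p"})


class TestPlateCsv:
    def test_round_trip_with_preamble(self, tmp_path):
        recs = [
            AmplificationRecord("A1", "miR-16", "smallrna", 27.25),
            AmplificationRecord("B1", "miR-16", "smallrna", None),
            AmplificationRecord("A1", "18S", "genomic", 18.5),
        ]
        p = tmp_path / "plate.csv"
        write_plate_csv(recs, p, preamble="SDS 2.4\nexported 2013-01-01")
        back = read_plate_csv(p)
        assert len(back) == 3
        assert back[0].ct == pytest.approx(27.25)
        assert back[1].censored
        assert back[2].chemistry == "genomic" and back[2].cycle_max == 40.0

    def test_sds_dialect_preamble_skipped(self):
        text = (
            "SDS 2.4 RQ Results\nPlate,whatever\n\n"
            "Well,Detector,Ct\nA1,18S,17.9\nA2,18S,Undetermined\n"
        )
        recs = read_plate_csv(io.StringIO(text), assay_info={"18S": ("genomic", 40.0)})
        assert len(recs) == 2
        assert recs[1].censored

    def test_missing_chemistry_raises(self):
        text = "Well,Detector,Ct\nA1,x,20.0\n"
        with pytest.raises(ValueError, match="chemistry"):
            read_plate_csv(io.StringIO(text))


def test_ct_above_cycle_max_rejected():
    with pytest.raises(ValueError):
        AmplificationRecord("A1", "g", "taqman", 41.0)
    with pytest.raises(ValueError):
        AmplificationRecord("A1", "m", "smallrna", 50.5)
    # 50 cycles allowed for small-RNA chemistry
    AmplificationRecord("A1", "m", "smallrna", 49.9)
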