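"""Trace-level measurement procedures and tracer quantification."""

import numpy as np
import pandas as pd
import pytest

from peptiport.assay_analysis import (
    AssayTrace,
    TraceEvent,
    acid_current_ratio,
    acidification_slope,
    current_to_flux,
    evoked_current,
    pyranine_normalized_ratio,
    tracer_quantify,
    uptake_rate_percent_of_reference,
)


def step_trace(amplitude=-300.0, start=30.0, end=90.0, total=120.0, dt=0.1):
    t = np.arange(0, total, dt)
    current = np.where((t >= start) & (t < end), amplitude, 0.0)
    return AssayTrace(
        t, {"current_nA": current},
        events=[TraceEvent("sub", start, end), TraceEvent("base", 0.0, start)],
    )


class TestEvokedCurrent:
    def test_clean_step(self):
        assert evoked_current(step_trace(), "sub", "base") == pytest.approx(-300.0)

    def test_zero_response_near_zero(self):
        rng = np.random.default_rng(0)
        trace = step_trace(0.0)
        trace.channels["current_nA"] += rng.normal(0, 5, trace.time_s.shape)
        assert evoked_current(trace, "sub", "base") == pytest.approx(0.0, abs=2.0)

    def test_overlapping_windows_rejected(self):
        trace = step_trace()
        with pytest.raises(ValueError, match="overlap"):
            evoked_current(trace, TraceEvent("a", 20, 60), TraceEvent("b", 50, 80))

    def test_short_window_rejected(self):
        trace = step_trace()
        with pytest.raises(ValueError, match="2 s"):
            evoked_current(trace, TraceEvent("a", 30, 31), "base")


class TestAcidificationSlope:
    def test_hand_calculation(self):
        """5.9 mV fall over 100 s at −59 mV/pH reads as +1e−3 pH/s acidification."""
        t = np.arange(0, 100.5, 0.5)
        trace = AssayTrace(t, {"electrode_mV": -0.059 * t})
        rate, raw = acidification_slope(trace, (0, 100), -59.0)
        assert raw == pytest.approx(-0.059, rel=1e-9)
        assert rate == pytest.approx(1e-3, rel=1e-9)

    def test_flat_trace_zero(self):
        t = np.arange(0, 100, 0.5)
        trace = AssayTrace(t, {"electrode_mV": np.full_like(t, -3.0)})
        rate, _ = acidification_slope(trace, (0, 99))
        assert rate == 0.0

    def test_calibration_scaling(self):
        t = np.arange(0, 100, 0.5)
        trace = AssayTrace(t, {"electrode_mV": -0.059 * t})
        r1, _ = acidification_slope(trace, (0, 99), -59.0)
        r2, _ = acidification_slope(trace, (0, 99), -118.0)
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_calibration_rejected(self):
        t = np.arange(0, 100, 0.5)
        trace = AssayTrace(t, {"electrode_mV": t})
        with pytest.raises(ValueError, match="nonzero"):
            acidification_slope(trace, (0, 99), 0.0)

    def test_short_window_rejected(self):
        t = np.arange(0, 100, 0.5)
        trace = AssayTrace(t, {"electrode_mV": t})
        with pytest.raises(ValueError, match="10 s"):
            acidification_slope(trace, (0, 5))


class TestAcidCurrentRatio:
    CELL = {
        "His-Ala": (-380.0, 1.2e-3),
        "His-Ser": (-350.0, 1.1e-3),
        "Lys-Ala": (-380.0, 0.0),
        "His-Glu": (-300.0, 1.9e-3),
    }

    def test_reference_maps_to_unity(self):
        stats = {s.substrate: s for s in acid_current_ratio(self.CELL, "His-Ala")}
        assert stats["His-Ala"].ratio == pytest.approx(1.0)

    def test_ratios_reflect_stoichiometry(self):
        stats = {s.substrate: s for s in acid_current_ratio(self.CELL, "His-Ala")}
        assert stats["Lys-Ala"].ratio == pytest.approx(0.0, abs=1e-12)
        assert stats["His-Glu"].ratio == pytest.approx(
            (1.9e-3 / 1.2e-3) / (300.0 / 380.0))

    def test_subthreshold_reference_invalidates_cell(self):
        cell = {k: (v[0] / 10, v[1]) for k, v in self.CELL.items()}
        stats = acid_current_ratio(cell, "His-Ala")
        assert all(not s.valid for s in stats)
        assert all(s.ratio is None for s in stats)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            acid_current_ratio(self.CELL, "Ala-Ala")

    def test_invariant_to_common_acid_rescaling(self):
        """Buffering-capacity rescaling of the acid channel cancels in r̂."""
        scaled = {k: (i, 3.7 * a) for k, (i, a) in self.CELL.items()}
        base = {s.substrate: s.ratio for s in acid_current_ratio(self.CELL, "His-Ala")}
        resc = {s.substrate: s.ratio for s in acid_current_ratio(scaled, "His-Ala")}
        for sub in base:
            assert resc[sub] == pytest.approx(base[sub], rel=1e-12)


class TestCurrentToFlux:
    def test_printed_conversion(self):
        """−300 nA of unit-charge transport is 3.11 pmol/s of substrate."""
        assert current_to_flux(-300.0, +1) == pytest.approx(3.11, abs=0.005)

    def test_definitional_value(self):
        assert current_to_flux(-96.485332, +1) == pytest.approx(1.0, rel=1e-6)

    def test_divalent_halves_flux(self):
        assert current_to_flux(-300.0, +2) == pytest.approx(
            current_to_flux(-300.0, +1) / 2)

    def test_electroneutral_rejected(self):
        with pytest.raises(ValueError, match="z = 0"):
            current_to_flux(-300.0, 0)

    def test_round_trip_with_flux_to_current(self):
        flux = current_to_flux(-300.0, +1)
        implied_current = flux * 1e-12 * 96485.332 * 1e9
        assert implied_current == pytest.approx(300.0, rel=1e-9)


class TestPyranine:
    def make_trace(self, decline=0.0):
        t = np.arange(0, 300, 1.0)
        ratio = 1.2 * (1.0 + np.where(t > 60, -decline * (t - 60), 0.0))
        f460 = np.full_like(t, 1000.0)
        return AssayTrace(
            t, {"F415": ratio * f460, "F460": f460},
            events=[TraceEvent("peptide", 10.0, 11.0)],
        )

    def test_constant_channels_give_unity(self):
        fnorm = pyranine_normalized_ratio(self.make_trace(), "peptide")
        assert np.allclose(fnorm, 1.0)

    def test_normalization_window_mean_exactly_one(self):
        trace = self.make_trace(decline=1e-3)
        fnorm = pyranine_normalized_ratio(trace, "peptide")
        mask = (trace.time_s >= 10.0) & (trace.time_s <= 35.0)
        assert fnorm[mask].mean() == pytest.approx(1.0, abs=1e-15)

    def test_zero_denominator_rejected(self):
        trace = self.make_trace()
        trace.channels["F460"][5] = 0.0
        with pytest.raises(ValueError, match="denominator"):
            pyranine_normalized_ratio(trace, "peptide")


class TestPercentOfReference:
    def test_reference_is_100(self):
        out = uptake_rate_percent_of_reference({"His-Ser": -2e-3, "x": -1e-3}, "His-Ser")
        assert out["His-Ser"] == 100.0
        assert out["x"] == pytest.approx(50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            uptake_rate_percent_of_reference({"a": 0.0}, "a")


class TestTracerQuantify:
    def exact_tables(self):
        amounts = np.array([1.0, 5.0, 20.0, 50.0])
        standards = pd.DataFrame({
            "analyte": "Ala", "amount_pmol": amounts, "area": 100.0 + 50.0 * amounts})
        samples = pd.DataFrame({
            "analyte": ["Ala"], "sample_id": ["s1"], "area": [100.0 + 50.0 * 10.5]})
        return samples, standards

    def test_exact_interpolation(self):
        samples, standards = self.exact_tables()
        res = tracer_quantify(samples, standards, duration_s=60.0)
        assert res.amounts.iloc[0].amount_pmol == pytest.approx(10.5, rel=1e-12)
        assert not res.amounts.iloc[0].extrapolated

    def test_extrapolation_flagged(self):
        samples, standards = self.exact_tables()
        samples.loc[0, "area"] = 100.0 + 50.0 * 500.0
        res = tracer_quantify(samples, standards, duration_s=60.0)
        assert bool(res.amounts.iloc[0].extrapolated)

    def test_rate_and_scale(self):
        samples, standards = self.exact_tables()
        res = tracer_quantify(samples, standards, duration_s=60.0, scale=50.0)
        assert res.rates_pmol_s["Ala"] == pytest.approx(10.5 * 50.0 / 60.0)

    def test_too_few_standards_rejected(self):
        samples, standards = self.exact_tables()
        with pytest.raises(ValueError, match="≥4 standards"):
            tracer_quantify(samples, standards.head(3), duration_s=60.0)

    def test_nonpositive_duration_rejected(self):
        samples, standards = self.exact_tables()
        with pytest.raises(ValueError, match="duration"):
            tracer_quantify(samples, standards, duration_s=0.0)


class TestTraceContainer:
    def test_event_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside the time span"):
            AssayTrace(np.arange(10.0), {"c": np.zeros(10)},
                       events=[TraceEvent("x", 5.0, 20.0)])

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            AssayTrace(np.arange(10.0), {"c": np.zeros(5)})
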