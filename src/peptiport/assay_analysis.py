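"""Measurement procedures on trace and table inputs.

Covers the dual voltage-clamp / intracellular-pH workflow (evoked currents,
acidification slopes, the per-cell normalized acidification/current ratio),
current→flux conversion via the Faraday constant, pyranine two-channel
ratio processing with initial-rate normalisation, and absolute tracer
quantification against calibration standards.

Sign conventions: inward currents are negative at the trace level. The
acidification rate is reported positive for falling cytosolic pH; it is
obtained as (electrode-voltage slope)/(calibration slope), so a falling
electrode trace with the default −59 mV/pH calibration reads as positive
acidification. Because the ratio statistic normalizes both channels to a
reference substrate in the same cell, the calibration constant and the
cell's buffering capacity cancel out of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CURRENT_THRESHOLD_NA, ELECTRODE_SLOPE_MV_PER_PH, FARADAY

__all__ = [
    "TraceEvent",
    "AssayTrace",
    "RatioStatistic",
    "evoked_current",
    "acidification_slope",
    "acid_current_ratio",
    "current_to_flux",
    "pyranine_normalized_ratio",
    "uptake_rate_percent_of_reference",
    "tracer_quantify",
    "TracerResult",
    "analyze_tevc_cell",
]


@dataclass(frozen=True)
class TraceEvent:
    """A labelled time window (substrate application, baseline, ...)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"event {self.label!r}: end must exceed start")


@dataclass
class AssayTrace:
    """Uniform time-series container for current/electrode/fluorescence channels."""

    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    events: list[TraceEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.time_s.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = values
        t0, t1 = self.time_s[0], self.time_s[-1]
        for ev in self.events:
            if ev.start_s < t0 or ev.end_s > t1:
                raise ValueError(f"event {ev.label!r} outside the time span")

    def event(self, label: str) -> TraceEvent:
        for ev in self.events:
            if ev.label == label:
                return ev
        raise KeyError(f"no event labelled {label!r}")

    def window(self, channel: str, start_s: float, end_s: float) -> tuple[np.ndarray, np.ndarray]:
        # half-open [start, end): an epoch boundary sample belongs to the
        # epoch that starts there, never to the one that ends there
        mask = (self.time_s >= start_s) & (self.time_s < end_s)
        return self.time_s[mask], self.channels[channel][mask]


@dataclass
class RatioStatistic:
    """Normalized acidification/current ratio for one substrate in one cell."""

    substrate: str
    normalized_current: float
    normalized_acidification: float
    ratio: float | None
    valid: bool


def evoked_current(
    trace: AssayTrace,
    substrate_event: TraceEvent | str,
    baseline_event: TraceEvent | str,
    channel: str = "current_nA",
) -> float:
    """Substrate-evoked current: mean(plateau) − mean(baseline), nA.

    Inward currents come out negative. The two windows must not overlap and
    must each span at least 2 s.
    """
    sub = trace.event(substrate_event) if isinstance(substrate_event, str) else substrate_event
    base = trace.event(baseline_event) if isinstance(baseline_event, str) else baseline_event
    if sub.start_s < base.end_s and base.start_s < sub.end_s:
        raise ValueError("substrate and baseline windows overlap")
    for ev in (sub, base):
        if ev.end_s - ev.start_s < 2.0:
            raise ValueError(f"window {ev.label!r} shorter than 2 s")
    _, plateau = trace.window(channel, sub.start_s, sub.end_s)
    _, baseline = trace.window(channel, base.start_s, base.end_s)
    return float(plateau.mean() - baseline.mean())


def acidification_slope(
    trace: AssayTrace,
    window: TraceEvent | tuple[float, float],
    electrode_slope_mV_per_pH: float = ELECTRODE_SLOPE_MV_PER_PH,
    channel: str = "electrode_mV",
) -> tuple[float, float]:
    """Acidification rate over a window: (pH·s⁻¹, raw mV·s⁻¹).

    The electrode-voltage slope (ordinary least squares) is divided by the
    calibration slope; with the −59 mV/pH default, a falling trace gives a
    positive acidification rate (pH falling). The window must span ≥10 s.
    """
    if electrode_slope_mV_per_pH == 0:
        raise ValueError("electrode calibration slope must be nonzero")
    if isinstance(window, TraceEvent):
        start, end = window.start_s, window.end_s
    else:
        start, end = window
    if end - start < 10.0:
        raise ValueError("acidification window must span ≥10 s")
    t, v = trace.window(channel, start, end)
    slope_mv = float(stats.linregress(t, v).slope)
    return slope_mv / electrode_slope_mV_per_pH, slope_mv


def acid_current_ratio(
    cell_results: dict[str, tuple[float, float]],
    reference: str,
    threshold_nA: float = CURRENT_THRESHOLD_NA,
) -> list[RatioStatistic]:
    """Per-substrate acidification/current ratios, normalized within one cell.

    ``cell_results`` maps substrate → (evoked current nA, acidification rate
    pH·s⁻¹), all measured in the same cell. Each substrate's current and
    acidification are normalized to the reference substrate's, and

        r̂(X) = (acid_X / acid_ref) / (I_X / I_ref)

    estimates the protons released per translocated elementary charge.
    Results are flagged invalid when the reference current magnitude is
    below the proportionality threshold (~100 nA). The reference maps to
    r̂ = 1 by construction. Signs are carried through, so a substrate with
    slightly alkalinising noise can yield a slightly negative r̂.
    """
    if reference not in cell_results:
        raise ValueError(f"reference substrate {reference!r} missing from cell results")
    i_ref, acid_ref = cell_results[reference]
    valid = abs(i_ref) >= threshold_nA
    out = []
    for substrate, (current, acid) in cell_results.items():
        norm_i = current / i_ref
        norm_a = acid / acid_ref
        ratio = norm_a / norm_i if (valid and norm_i != 0.0) else None
        out.append(RatioStatistic(substrate, norm_i, norm_a, ratio, valid))
    return out


def current_to_flux(I_nA: float, z: float) -> float:
    """Convert a transport current to substrate flux, pmol·s⁻¹.

    flux = |I| / (|z|·F); −300 nA at z = +1 gives 3.11 pmol·s⁻¹.
    Electroneutral transport (z = 0) carries no current and is rejected.
    """
    if z == 0:
        raise ValueError("z = 0: electroneutral transport carries no current")
    return abs(I_nA) * 1e-9 / (abs(z) * FARADAY) * 1e12


def pyranine_normalized_ratio(
    trace: AssayTrace,
    peptide_event: TraceEvent | str,
    norm_window_s: float = 25.0,
    channel_num: str = "F415",
    channel_den: str = "F460",
) -> np.ndarray:
    """Normalized pyranine excitation ratio F415/F460 over the whole trace.

    The raw ratio is divided by its mean over the first ``norm_window_s``
    seconds after peptide addition, so that window averages exactly 1.
    """
    ev = trace.event(peptide_event) if isinstance(peptide_event, str) else peptide_event
    if trace.time_s[-1] < ev.start_s + norm_window_s:
        raise ValueError(f"trace ends before {norm_window_s} s after the peptide event")
    den = trace.channels[channel_den]
    if np.any(den == 0):
        raise ValueError("zero samples in the denominator fluorescence channel")
    ratio = trace.channels[channel_num] / den
    mask = (trace.time_s >= ev.start_s) & (trace.time_s < ev.start_s + norm_window_s)
    return ratio / ratio[mask].mean()


def uptake_rate_percent_of_reference(
    rates: dict[str, float], reference: str
) -> dict[str, float]:
    """Express initial uptake rates as a percentage of the reference substrate's."""
    if reference not in rates:
        raise ValueError(f"reference {reference!r} missing")
    ref = rates[reference]
    if ref == 0:
        raise ValueError("reference rate must be nonzero")
    return {name: 100.0 * rate / ref for name, rate in rates.items()}


@dataclass
class TracerResult:
    """Absolute tracer quantification output."""

    amounts: pd.DataFrame          # analyte, sample_id, amount_pmol, extrapolated
    rates_pmol_s: dict[str, float]  # analyte → mean uptake rate per sample
    product_ratio: float | None     # e.g. Ala / Leu(d3)
    calibration: pd.DataFrame       # analyte, slope, intercept, r2


def tracer_quantify(
    sample_areas: pd.DataFrame,
    standards: pd.DataFrame,
    duration_s: float,
    product_pair: tuple[str, str] | None = None,
    scale: float = 1.0,
) -> TracerResult:
    """Absolute quantification of peak areas against calibration standards.

    ``sample_areas`` has columns (analyte, sample_id, area); ``standards``
    has (analyte, amount_pmol, area) with ≥4 points per analyte. A straight
    calibration line with fitted intercept (blank signal) converts areas to
    pmol; samples outside the standard amount range are flagged as
    extrapolated. ``scale`` maps the injected amount back to the biological
    compartment (dilution/aliquot factor). Rates are amount/duration.
    ``product_pair=(num, den)`` reports the released-product molar ratio.
    """
    if duration_s <= 0:
        raise ValueError("incubation duration must be positive")
    cal_rows, amount_rows = [], []
    for analyte, grp in standards.groupby("analyte"):
        if len(grp) < 4:
            raise ValueError(f"analyte {analyte!r}: need ≥4 standards, got {len(grp)}")
        res = stats.linregress(grp["amount_pmol"], grp["area"])
        cal_rows.append({"analyte": analyte, "slope": res.slope,
                         "intercept": res.intercept, "r2": res.rvalue**2})
        lo, hi = grp["amount_pmol"].min(), grp["amount_pmol"].max()
        sel = sample_areas[sample_areas["analyte"] == analyte]
        for _, row in sel.iterrows():
            pmol = (row["area"] - res.intercept) / res.slope
            amount_rows.append({
                "analyte": analyte,
                "sample_id": row["sample_id"],
                "amount_pmol": pmol * scale,
                "extrapolated": not (lo <= pmol <= hi),
            })
    amounts = pd.DataFrame(amount_rows)
    rates = {
        analyte: float(grp["amount_pmol"].mean()) / duration_s
        for analyte, grp in amounts.groupby("analyte")
    }
    ratio = None
    if product_pair is not None:
        num, den = product_pair
        a = amounts[amounts["analyte"] == num].set_index("sample_id")["amount_pmol"]
        b = amounts[amounts["analyte"] == den].set_index("sample_id")["amount_pmol"]
        paired = pd.concat([a, b], axis=1, keys=["num", "den"]).dropna()
        if len(paired):
            ratio = float((paired["num"] / paired["den"]).mean())
    return TracerResult(amounts, rates, ratio, pd.DataFrame(cal_rows))


def analyze_tevc_cell(
    trace: AssayTrace,
    substrates: list[str],
    reference: str,
    acid_window_s: float = 30.0,
    electrode_slope_mV_per_pH: float = ELECTRODE_SLOPE_MV_PER_PH,
    threshold_nA: float = CURRENT_THRESHOLD_NA,
) -> tuple[list[RatioStatistic], dict[str, tuple[float, float]]]:
    """End-to-end analysis of one dual-recording trace.

    Expects, for every substrate name, events ``<name>`` (application) and
    ``<name>/baseline``. The evoked current uses the full application
    window vs. its baseline; the acidification slope uses the first
    ``acid_window_s`` seconds of the application. Returns the ratio
    statistics plus the per-substrate raw (current, acidification rate).
    """
    cell: dict[str, tuple[float, float]] = {}
    for name in substrates:
        app = trace.event(name)
        base = trace.event(f"{name}/baseline")
        current = evoked_current(trace, app, base)
        acid, _ = acidification_slope(
            trace, (app.start_s, min(app.start_s + acid_window_s, app.end_s)),
            electrode_slope_mV_per_pH,
        )
        cell[name] = (current, acid)
    return acid_current_ratio(cell, reference, threshold_nA), cell
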