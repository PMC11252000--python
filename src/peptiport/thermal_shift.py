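"""Thermal-shift (nanoDSF-style) analysis: melt curves, T_m, ΔT_m, K_D.

The melt model is a two-state unfolding equilibrium with sloped linear
baselines. With ΔCp neglected, the unfolding free energy is
ΔG(T) = ΔH·(1 − T/T_m), giving an unfolded population

    f_u(T) = K/(1+K),   K(T) = exp(−ΔH·(1 − T/T_m)/(R·T)),

and a fluorescence ratio signal
(1 − f_u)·(native baseline) + f_u·(unfolded baseline) + noise.

Ligand binding stabilises the fold; the ligand-concentration dependence of
the melting-temperature shift is fitted with the saturation model

    ΔT_m(L) = ΔT_m_max · L / (K_D + L),

a deliberate simplification of full thermodynamic-coupling treatments that
is identifiable from (L, T_m) pairs alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .constants import GAS_CONSTANT

__all__ = [
    "MeltCurve",
    "MeltFit",
    "BindingFit",
    "simulate_melt_curve",
    "extract_tm",
    "fit_kd_from_shifts",
    "delta_tm_screen",
]

#: Default melt-curve noise (sd of the fluorescence ratio); intrinsic
#: fluorescence ratios are low-noise signals, a few 1e-3 at these settings.
DEFAULT_NOISE_SD = 0.002

#: Derivative smoothing: centred moving window of 5 grid points (fixed).
_SMOOTH_WINDOW = 5


@dataclass
class MeltCurve:
    """One thermal unfolding trace across a uniform temperature grid."""

    temperature_C: np.ndarray
    signal: np.ndarray
    ligand: str = "apo"
    concentration_M: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature_C.shape != self.signal.shape:
            raise ValueError("temperature and signal must align")
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class MeltFit:
    """Extracted melting temperature (°C) and, in model mode, ΔH."""

    T_m: float | None
    method: str
    enthalpy_kJ_mol: float | None = None
    baselines: dict | None = None
    ok: bool = False
    message: str = ""


@dataclass
class BindingFit:
    """K_D and maximal stabilisation from a ΔT_m titration."""

    K_D: float | None
    dTm_max: float | None
    K_D_stderr: float | None = None
    dTm_max_stderr: float | None = None
    converged: bool = False
    non_binder: bool = False
    warnings: list[str] = field(default_factory=list)


def _two_state_signal(T_C, tm_C, dh_J, bn0, bn1, bu0, bu1):
    T = np.asarray(T_C, dtype=float) + 273.15
    tm = tm_C + 273.15
    K = np.exp(-dh_J * (1.0 - T / tm) / (GAS_CONSTANT * T))
    fu = K / (1.0 + K)
    native = bn0 + bn1 * np.asarray(T_C)
    unfolded = bu0 + bu1 * np.asarray(T_C)
    return (1.0 - fu) * native + fu * unfolded


def simulate_melt_curve(
    T_m: float,
    enthalpy_kJ_mol: float = 400.0,
    baselines: tuple[float, float, float, float] = (0.50, -2e-4, 0.92, -4e-4),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = 0,
    grid: tuple[float, float, float] = (20.0, 95.0, 0.25),
    ligand: str = "apo",
    concentration_M: float = 0.0,
    replicate: int = 0,
) -> MeltCurve:
    """Simulate a two-state melt trace on a uniform °C grid, seeded.

    ``baselines`` is (native intercept, native slope, unfolded intercept,
    unfolded slope) of the ratio signal. Deterministic per seed.
    """
    start, stop, step = grid
    temps = np.arange(start, stop + step / 2, step)
    if not (temps[0] < T_m < temps[-1]):
        raise ValueError(f"T_m={T_m} outside the temperature grid {start}–{stop}")
    if enthalpy_kJ_mol <= 0:
        raise ValueError("unfolding enthalpy must be positive")
    signal = _two_state_signal(temps, T_m, enthalpy_kJ_mol * 1e3, *baselines)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return MeltCurve(temps, signal, ligand, concentration_M, replicate)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def extract_tm(curve: MeltCurve, method: str = "derivative") -> MeltFit:
    """Extract T_m by smoothed-derivative peak or by a two-state model fit.

    The derivative method smooths the trace (5-point centred window),
    locates the first-derivative maximum and refines it with a local
    quadratic fit. A monotone, featureless trace — where the derivative
    peak does not stand out of the derivative noise — is flagged with no
    T_m rather than returning a spurious value.
    """
    temps, y = curve.temperature_C, curve.signal
    if len(temps) < 50:
        raise ValueError("need ≥50 points for T_m extraction")

    ys = _smooth(y, _SMOOTH_WINDOW)
    deriv = np.gradient(ys, temps)
    # the peak-location step works on a further-smoothed derivative; the
    # transition is several °C wide, so a ~2 °C kernel cannot shift the peak
    deriv = _smooth(deriv, 9)
    margin = _SMOOTH_WINDOW
    interior = slice(margin, len(deriv) - margin)
    i = margin + int(np.argmax(deriv[interior]))

    # Featureless check: peak height above the median derivative must exceed
    # the robust derivative scatter by a wide margin.
    med = float(np.median(deriv))
    mad = float(np.median(np.abs(deriv - med))) * 1.4826
    if mad == 0.0:
        mad = 1e-12
    if (deriv[i] - med) < 6.0 * mad:
        return MeltFit(None, method, ok=False,
                       message="no characteristic unfolding transition detected")

    if method == "derivative":
        # quadratic refinement of the derivative peak over ±3 °C
        step = temps[1] - temps[0]
        k = max(2, int(round(3.0 / step)))
        lo, hi = max(0, i - k), min(len(temps), i + k + 1)
        coeff = np.polyfit(temps[lo:hi], deriv[lo:hi], 2)
        if coeff[0] >= 0:
            tm = float(temps[i])
        else:
            tm = float(-coeff[1] / (2 * coeff[0]))
            tm = min(max(tm, temps[lo]), temps[hi - 1])
        return MeltFit(tm, "derivative", ok=True)

    if method == "two_state_fit":
        model = Model(_two_state_signal, independent_vars=["T_C"])
        n3 = len(temps) // 3
        bn1 = float(np.polyfit(temps[:n3], y[:n3], 1)[0])
        bu1 = float(np.polyfit(temps[-n3:], y[-n3:], 1)[0])
        params = model.make_params(
            tm_C=float(temps[i]), dh_J=4e5,
            bn0=float(y[0] - bn1 * temps[0]), bn1=bn1,
            bu0=float(y[-1] - bu1 * temps[-1]), bu1=bu1,
        )
        params["tm_C"].set(min=float(temps[0]), max=float(temps[-1]))
        params["dh_J"].set(min=1e4, max=5e6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(y, params, T_C=temps)
        if not result.success:
            return MeltFit(None, method, ok=False, message="model fit did not converge")
        p = result.params
        return MeltFit(
            float(p["tm_C"].value), "two_state_fit",
            enthalpy_kJ_mol=float(p["dh_J"].value) / 1e3,
            baselines={k: float(p[k].value) for k in ("bn0", "bn1", "bu0", "bu1")},
            ok=True,
        )

    raise ValueError(f"unknown method {method!r}")


def fit_kd_from_shifts(
    titration: list[tuple[float, float]],
    stabilization_floor_C: float = 0.5,
) -> BindingFit:
    """Fit ΔT_m(L) = ΔT_m_max·L/(K_D + L) to a (concentration, T_m) titration.

    The titration must contain an apo point (L = 0), at least five
    concentrations, and span at least two orders of magnitude. A ligand
    whose largest shift stays below ``stabilization_floor_C`` (instrument
    repeatability scale) is flagged as a non-binder. A warning is recorded
    when the fitted K_D falls outside the sampled concentration range.
    """
    fit = BindingFit(K_D=None, dTm_max=None)
    conc = np.array([c for c, _ in titration], dtype=float)
    tm = np.array([t for _, t in titration], dtype=float)
    if np.all(conc != 0.0):
        raise ValueError("titration must include an apo (L = 0) point")
    if len(conc) < 5:
        raise ValueError("need ≥5 titration points")
    pos = conc[conc > 0]
    if pos.max() / pos.min() < 100.0:
        fit.warnings.append("concentrations span < 2 orders of magnitude")

    tm_apo = float(np.mean(tm[conc == 0.0]))
    shifts = tm - tm_apo
    if np.max(shifts) <= stabilization_floor_C:
        fit.non_binder = True
        return fit

    model = Model(lambda L, kd, dmax: dmax * L / (kd + L))
    params = model.make_params(kd=float(np.median(pos)), dmax=float(np.max(shifts)))
    params["kd"].set(min=pos.min() / 1e3, max=pos.max() * 1e3)
    params["dmax"].set(min=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(shifts, params, L=conc)
    if not result.success:
        fit.warnings.append("optimizer did not converge")
        return fit
    fit.K_D = float(result.params["kd"].value)
    fit.dTm_max = float(result.params["dmax"].value)
    if result.params["kd"].stderr is not None:
        fit.K_D_stderr = float(result.params["kd"].stderr)
        fit.dTm_max_stderr = float(result.params["dmax"].stderr)
    fit.converged = True
    if not (pos.min() <= fit.K_D <= pos.max()):
        fit.warnings.append("fitted K_D lies outside the sampled range")
    return fit


def delta_tm_screen(curves: list[MeltCurve], method: str = "derivative"):
    """Screening report: ligand → mean ΔT_m ± sd relative to the apo mean."""
    import pandas as pd

    tms: dict[str, list[float]] = {}
    for curve in curves:
        res = extract_tm(curve, method=method)
        if res.ok:
            tms.setdefault(curve.ligand, []).append(res.T_m)
    if "apo" not in tms:
        raise ValueError("screen requires apo curves")
    apo = float(np.mean(tms["apo"]))
    rows = []
    for ligand, values in tms.items():
        if ligand == "apo":
            continue
        arr = np.array(values)
        rows.append({
            "ligand": ligand,
            "mean_dTm_C": float(arr.mean() - apo),
            "sd_dTm_C": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
            "n": len(arr),
        })
    return pd.DataFrame(rows)
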