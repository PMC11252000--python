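"""Michaelis–Menten / competitive-inhibition models and rate extraction.

Dose–response data keep their native sign (inward currents are negative);
fitting operates on magnitudes internally and the sign is restored on
output. Fits use unweighted nonlinear least squares (lmfit) with a single
deterministic start: v_max initialised at the largest response magnitude,
K_M at the dose closest to half of it, K_M bounded to
[min positive dose / 10, max dose × 10].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy import stats

__all__ = [
    "DoseResponseSet",
    "KineticsFit",
    "mm_velocity",
    "fit_michaelis_menten",
    "inhibition_velocity",
    "ki_from_fractional_inhibition",
    "initial_rate",
]


@dataclass
class DoseResponseSet:
    """Substrate dose–response points (concentrations in mol·L⁻¹)."""

    substrate: str
    concentrations: np.ndarray
    responses: np.ndarray
    unit: str = "nA"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be unique")


@dataclass
class KineticsFit:
    """Michaelis–Menten parameter estimates with uncertainties."""

    K_M: float | None
    v_max: float | None
    K_M_stderr: float | None = None
    v_max_stderr: float | None = None
    residual_rms: float | None = None
    converged: bool = False
    warnings: list[str] = field(default_factory=list)


def mm_velocity(S: float, K_M: float, v_max: float):
    """Michaelis–Menten velocity v_max·S/(K_M + S). Vectorised over S."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    if K_M <= 0:
        raise ValueError("K_M must be positive")
    out = v_max * S / (K_M + S)
    return float(out) if out.ndim == 0 else out


def inhibition_velocity(S: float, I: float, K_M: float, K_I: float, v_max: float) -> float:
    """Competitive-inhibition velocity v_max·S/(K_M·(1 + I/K_I) + S)."""
    if S < 0 or I < 0:
        raise ValueError("concentrations must be non-negative")
    if K_M <= 0 or K_I <= 0:
        raise ValueError("K_M and K_I must be positive")
    return v_max * S / (K_M * (1.0 + I / K_I) + S)


def ki_from_fractional_inhibition(phi: float, S: float, I: float, K_M: float) -> tuple[float, bool]:
    """Invert the competitive model for K_I given fractional inhibition ``phi``.

    phi = 1 − v_inhibited/v_control. Returns (K_I, lower_bound_flag); complete
    inhibition (phi = 1) yields the documented lower bound 0 with the flag
    set. Exact algebraic inversion: K_I = K_M·I·(1−phi) / ((K_M+S)·phi).
    """
    if not (0.0 < phi <= 1.0):
        raise ValueError("phi must lie in (0, 1]")
    if S < 0 or I <= 0 or K_M <= 0:
        raise ValueError("require S ≥ 0, I > 0, K_M > 0")
    if phi == 1.0:
        return 0.0, True
    return K_M * I * (1.0 - phi) / ((K_M + S) * phi), False


def fit_michaelis_menten(data: DoseResponseSet) -> KineticsFit:
    """Fit K_M and v_max to a dose–response set by nonlinear least squares.

    Requires ≥4 points; warns (and flags) when the doses do not straddle the
    fitted K_M, since the estimate is then poorly constrained.
    """
    fit = KineticsFit(K_M=None, v_max=None)
    n = len(data.concentrations)
    if n < 4:
        fit.warnings.append(f"under-determined: {n} points, need ≥4")
        return fit

    sign = -1.0 if np.sum(data.responses) < 0 else 1.0
    mag = np.abs(data.responses)
    conc = data.concentrations

    vmax0 = float(np.max(mag))
    if vmax0 == 0.0:
        fit.warnings.append("all responses are zero")
        return fit
    km0 = float(conc[np.argmin(np.abs(mag - vmax0 / 2.0))])
    pos = conc[conc > 0]
    km_min, km_max = float(pos.min()) / 10.0, float(conc.max()) * 10.0
    km0 = min(max(km0, km_min), km_max)

    model = Model(lambda S, km, vmax: vmax * S / (km + S))
    params = model.make_params(km=km0, vmax=vmax0)
    params["km"].set(min=km_min, max=km_max)
    params["vmax"].set(min=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(mag, params, S=conc)

    if not result.success or not math.isfinite(result.params["km"].value):
        fit.warnings.append("optimizer did not converge")
        return fit

    km = float(result.params["km"].value)
    vmax = float(result.params["vmax"].value)
    fit.K_M = km
    fit.v_max = sign * vmax
    if result.params["km"].stderr is not None:
        fit.K_M_stderr = float(result.params["km"].stderr)
        fit.v_max_stderr = float(result.params["vmax"].stderr)
    fit.residual_rms = float(np.sqrt(np.mean(result.residual**2)))
    fit.converged = True
    if km < pos.min() or km > conc.max():
        fit.warnings.append("doses do not straddle the fitted K_M")
    return fit


def initial_rate(
    time_s: np.ndarray,
    response: np.ndarray,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Least-squares slope of ``response`` over the time window, with its SE.

    Returns (slope, stderr) in response units per second. Requires at least
    five samples inside the window.
    """
    time_s = np.asarray(time_s, dtype=float)
    response = np.asarray(response, dtype=float)
    start, end = window
    mask = (time_s >= start) & (time_s <= end)
    if int(mask.sum()) < 5:
        raise ValueError(f"need ≥5 samples in window {window}, got {int(mask.sum())}")
    res = stats.linregress(time_s[mask], response[mask])
    return float(res.slope), float(res.stderr)
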