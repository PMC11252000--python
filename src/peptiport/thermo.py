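"""Uniporter thermodynamics: Nernst accumulation and driving forces.

Sign convention (used everywhere in this package, property-tested):

    Δψ = ψ_cyt − ψ_lum   (volts)

A "positive-inside" lysosome (lumen positive, ψ_lum > ψ_cyt) therefore has
Δψ < 0 under this convention. Worked sign table for a cation (z = +1) at
equal concentrations:

    lumen positive  →  Δψ < 0  →  zFΔψ < 0  →  ΔG(lum→cyt) < 0  →  export
    lumen negative  →  Δψ > 0  →  zFΔψ > 0  →  ΔG(lum→cyt) > 0  →  import

Because a uniporter equilibrates each transported species' electrochemical
potential, the equilibrium concentration ratio (cytosol/lumen) for a species
of charge z is exp(−zFΔψ/RT). For a titratable substrate transported in a
subset of its protonation states, re-speciation at the local pH on each side
couples the *total* concentration ratio to the pH gradient even though the
transporter itself moves no proton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .constants import FARADAY, GAS_CONSTANT, ROOM_TEMPERATURE_K
from .peptide_chem import DipeptideSpec, SpeciesState, enumerate_species

__all__ = [
    "MembraneCondition",
    "nernst_accumulation",
    "species_driving_force",
    "total_substrate_accumulation",
]


@dataclass(frozen=True)
class MembraneCondition:
    """Bilateral pH, membrane potential and temperature.

    ``delta_psi`` is ψ_cyt − ψ_lum in volts (see module docstring).
    """

    pH_lum: float
    pH_cyt: float
    delta_psi: float
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for ph in (self.pH_lum, self.pH_cyt):
            if not (0.0 <= ph <= 14.0):
                raise ValueError(f"pH must lie in 0–14, got {ph}")
        if not math.isfinite(self.delta_psi):
            raise ValueError("delta_psi must be finite")


def nernst_accumulation(z: float, condition: MembraneCondition) -> float:
    """Equilibrium concentration ratio (cytosol/lumen) for a species of charge z.

    Returns exp(−zFΔψ/RT); equals 1 for uncharged species or Δψ = 0.
    """
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    rt = GAS_CONSTANT * condition.temperature
    return math.exp(-z * FARADAY * condition.delta_psi / rt)


def species_driving_force(
    concentration_cyt: float,
    concentration_lum: float,
    z: float,
    condition: MembraneCondition,
) -> tuple[float, str]:
    """Free energy of lumen→cytosol translocation and the flux direction.

    ΔG(lum→cyt) = RT·ln(c_cyt/c_lum) + zFΔψ, J·mol⁻¹. Direction flag is
    'export' for ΔG < 0, 'import' for ΔG > 0, 'equilibrium' at zero.
    """
    if concentration_cyt <= 0 or concentration_lum <= 0:
        raise ValueError("concentrations must be positive")
    rt = GAS_CONSTANT * condition.temperature
    dg = rt * math.log(concentration_cyt / concentration_lum) + z * FARADAY * condition.delta_psi
    if dg < 0:
        direction = "export"
    elif dg > 0:
        direction = "import"
    else:
        direction = "equilibrium"
    return dg, direction


def total_substrate_accumulation(
    peptide: DipeptideSpec,
    transported_species: Iterable[SpeciesState] | Iterable[str],
    condition: MembraneCondition,
) -> float:
    """Total-concentration equilibrium ratio (cytosol/lumen) for a peptide.

    Each transported microstate is driven toward its own Nernst equilibrium
    while speciation on each side instantly re-equilibrates at the local pH
    (fractions fixed by bulk pH). The zero-net-flux total ratio, assuming
    equal per-species transport rate constants, is

        T_cyt/T_lum = Σ_i f_i(pH_lum) / Σ_i f_i(pH_cyt)/ρ_i,

    with ρ_i = exp(−z_i·FΔψ/RT). With a single transported state this
    reduces to f_lum/f_cyt · ρ, and for a single-state peptide to the plain
    Nernst ratio.

    ``transported_species`` may hold SpeciesState objects or their canonical
    labels; it must be a non-empty subset of the peptide's state space.
    """
    dist_lum = enumerate_species(peptide, condition.pH_lum)
    dist_cyt = enumerate_species(peptide, condition.pH_cyt)

    labels = []
    for sp in transported_species:
        labels.append(sp.label if isinstance(sp, SpeciesState) else str(sp))
    if not labels:
        raise ValueError("transported_species must be non-empty")

    influx = 0.0   # per unit luminal total
    efflux = 0.0   # per unit cytosolic total
    for label in labels:
        state = dist_lum.state(label)  # KeyError if not in the state space
        rho = nernst_accumulation(state.net_side_chain_charge, condition)
        influx += dist_lum.fraction(label)
        efflux += dist_cyt.fraction(label) / rho
    return influx / efflux


def equilibrate_numerically(
    peptide: DipeptideSpec,
    transported_species: Iterable[SpeciesState] | Iterable[str],
    condition: MembraneCondition,
    t_lum: float = 1.0,
    tol: float = 1e-12,
    max_steps: int = 100_000,
) -> float:
    """Brute-force fixed-point equilibration of the total ratio.

    Relaxes dT_cyt/dt = Σ_i (f_i^lum·T_lum − f_i^cyt·T_cyt/ρ_i) to its
    fixed point by explicit iteration. Kept as an independent cross-check of
    :func:`total_substrate_accumulation`; not used by the analytic path.
    """
    dist_lum = enumerate_species(peptide, condition.pH_lum)
    dist_cyt = enumerate_species(peptide, condition.pH_cyt)
    labels = [sp.label if isinstance(sp, SpeciesState) else str(sp)
              for sp in transported_species]
    if not labels:
        raise ValueError("transported_species must be non-empty")
    f_lum = np.array([dist_lum.fraction(lb) for lb in labels])
    f_cyt = np.array([dist_cyt.fraction(lb) for lb in labels])
    rho = np.array([
        nernst_accumulation(dist_lum.state(lb).net_side_chain_charge, condition)
        for lb in labels
    ])
    relax = float(np.sum(f_cyt / rho))  # linear decay rate of the flux
    dt = 0.5 / relax
    t_cyt = 0.0
    for _ in range(max_steps):
        flux = float(np.sum(f_lum * t_lum - f_cyt * t_cyt / rho))
        t_cyt += dt * flux
        # stop once the remaining concentration correction flux/relax is
        # negligible relative to the totals
        if abs(flux) < tol * relax * max(t_lum, abs(t_cyt)):
            break
    return t_cyt / t_lum
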