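"""Charge/proton stoichiometry of dipeptide translocation.

A uniporter moves the dipeptide as a single solute; any cytosolic
acidification comes from protons carried on the substrate's own titratable
groups and released when the molecule re-equilibrates at cytosolic pH. For a
transported microstate this module computes

* ``z`` — the net charge translocated (elementary charges),
* ``h`` — protons released per transported molecule on arrival,
* ``r = h/z`` — protons released per translocated elementary charge, the
  statistic the dual voltage-clamp/pH recording estimates.

Two modes are provided. ``ideal`` counts a full proton for every group that
enters protonated and has pKa below cytosolic pH (the integer predictions 0,
1, 2 used to classify substrates). ``equilibrium`` releases the
Henderson–Hasselbalch fraction instead, and charges groups that enter
deprotonated but would protonate at cytosolic pH as negative release
(proton consumption) — a symmetric extension the ideal mode ignores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .peptide_chem import DipeptideSpec, SpeciesState, fraction_protonated

__all__ = [
    "StoichiometryResult",
    "EnsemblePrediction",
    "protons_released",
    "protons_per_charge",
    "predict_ensemble",
    "species_table",
]

_MODES = ("ideal", "equilibrium")


@dataclass(frozen=True)
class StoichiometryResult:
    """Charge, proton release and their ratio for one transported species."""

    species: SpeciesState
    charge_z: float
    protons_released_h: float
    protons_per_charge_r: float | None
    electroneutral: bool
    mode: str


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-mole current/acidification prediction for a transport-weighted mix.

    ``ratio`` is undefined (None) when the weighted current vanishes; an
    electroneutral proton-carrying species inflates the ratio above any
    single-species value, which is how ratios exceeding the dominant
    species' ``r`` arise from mixed uptake.
    """

    weights: dict[SpeciesState, float]
    current_per_mole: float
    protons_per_mole: float
    ratio: float | None
    zero_current: bool


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")


def _check_species(species: SpeciesState, peptide: DipeptideSpec) -> None:
    if len(species.protonated) != len(peptide.groups):
        raise ValueError("species does not belong to the peptide's state space")


def protons_released(
    species: SpeciesState,
    peptide: DipeptideSpec,
    pH_cyt: float,
    mode: str = "ideal",
) -> float:
    """Protons released per transported molecule at cytosolic pH.

    Ideal mode: one full proton per group entering protonated with
    pKa < pH_cyt. Equilibrium mode: fractional release
    1 − f(pKa, pH_cyt) per protonated group, minus f(pKa, pH_cyt) per
    deprotonated group (protonation on arrival consumes a proton).
    """
    _check_mode(mode)
    _check_species(species, peptide)
    if not math.isfinite(pH_cyt):
        raise ValueError("pH_cyt must be finite")
    h = 0.0
    for group, entered_protonated in zip(peptide.groups, species.protonated):
        if mode == "ideal":
            if entered_protonated and group.pKa < pH_cyt:
                h += 1.0
        else:
            f_cyt = fraction_protonated(group.pKa, pH_cyt)
            if entered_protonated:
                h += 1.0 - f_cyt
            else:
                h -= f_cyt
    return h


def protons_per_charge(
    species: SpeciesState,
    peptide: DipeptideSpec,
    pH_cyt: float,
    mode: str = "ideal",
) -> StoichiometryResult:
    """Full stoichiometry of one transported microstate.

    ``z`` is the species' net side-chain charge; positive ``r`` means
    cytosolic acidification per inward elementary charge. Electroneutral
    species (z = 0) are a valid outcome: they may still release protons,
    but carry no current, so ``r`` is not reported.
    """
    h = protons_released(species, peptide, pH_cyt, mode)
    z = float(species.net_side_chain_charge)
    electroneutral = z == 0.0
    r = None if electroneutral else h / z
    return StoichiometryResult(species, z, h, r, electroneutral, mode)


def predict_ensemble(
    weights: dict[SpeciesState, float],
    peptide: DipeptideSpec,
    pH_cyt: float,
    mode: str = "ideal",
) -> EnsemblePrediction:
    """Current, proton release and their ratio for a transport-weighted mix.

    ``weights`` assigns each transported microstate its share of transport
    events (must sum to 1).
    """
    if not weights:
        raise ValueError("weights must be non-empty")
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {total_w}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    current = 0.0
    protons = 0.0
    for species, w in weights.items():
        result = protons_per_charge(species, peptide, pH_cyt, mode)
        current += w * result.charge_z
        protons += w * result.protons_released_h
    zero_current = current == 0.0
    ratio = None if zero_current else protons / current
    return EnsemblePrediction(dict(weights), current, protons, ratio, zero_current)


def species_table(
    peptide: DipeptideSpec,
    pH_cyt: float,
    mode: str = "ideal",
) -> pd.DataFrame:
    """One row per microstate with z, h, r and the mode — tabular export."""
    from .peptide_chem import enumerate_species

    rows = []
    for species in enumerate_species(peptide, pH_cyt).states:
        res = protons_per_charge(species, peptide, pH_cyt, mode)
        rows.append(
            {
                "peptide": peptide.display_name,
                "species": species.label,
                "charge_z": res.charge_z,
                "protons_released_h": res.protons_released_h,
                "protons_per_charge_r": res.protons_per_charge_r,
                "electroneutral": res.electroneutral,
                "mode": res.mode,
            }
        )
    return pd.DataFrame(rows)
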