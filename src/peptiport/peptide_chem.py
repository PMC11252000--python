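"""Dipeptide chemistry: ionizable groups, protonation microstates, masses.

A dipeptide with *n* ionizable groups populates 2^n protonation microstates.
Treating the groups as independent titratable sites, the probability that a
given group is protonated at a given pH follows Henderson–Hasselbalch,

    f(pKa, pH) = 1 / (1 + 10^(pH − pKa)),

and each microstate's fraction is the product of its per-group probabilities.
Acidic groups carry charge 0 protonated / −1 deprotonated; basic groups +1
protonated / 0 deprotonated.

By default only side-chain groups are modelled: across the pH range relevant
to lysosomal transport (roughly 5.0–7.2) the α-amino and α-carboxyl termini
are both fully charged and net-neutral as a zwitterionic pair, so they change
neither the net charge nor the proton bookkeeping of transport. Termini can
be switched on (``include_termini=True``) for full titration curves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd
from pyteomics import mass as _ptmass

from .constants import PROTON_MASS, WATER_MASS

__all__ = [
    "IonizableGroup",
    "DipeptideSpec",
    "SpeciesState",
    "SpeciesDistribution",
    "fraction_protonated",
    "enumerate_species",
    "monoisotopic_mz",
    "mean_net_charge",
    "mz_table",
    "SIDE_CHAIN_PKA",
    "N_TERMINUS_PKA",
    "C_TERMINUS_PKA",
]

# Side-chain pKa registry. His, Glu and Lys use the values the transport
# measurements were interpreted with (6.0, 4.1, 10.5); the remaining
# ionizable side chains come from a standard biochemistry table and can be
# overridden per peptide.
SIDE_CHAIN_PKA: dict[str, float] = {
    "D": 3.9,
    "E": 4.1,
    "C": 8.3,
    "H": 6.0,
    "K": 10.5,
    "R": 12.5,
    "Y": 10.1,
}

#: Default α-amino terminus pKa (standard-table value; not peptide-specific).
N_TERMINUS_PKA = 8.0
#: Default α-carboxyl terminus pKa.
C_TERMINUS_PKA = 3.1

_ACIDIC_SIDE_CHAINS = frozenset("DECY")
_BASIC_SIDE_CHAINS = frozenset("HKR")

_KINDS = ("acid", "base")
_LOCATIONS = ("side_chain_1", "side_chain_2", "n_terminus", "c_terminus")

# Three-letter display names for species labels.
_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site of a dipeptide.

    ``kind`` fixes the charge convention: an ``acid`` is neutral when
    protonated and −1 when deprotonated; a ``base`` is +1 when protonated
    and neutral when deprotonated.
    """

    label: str
    pKa: float
    kind: str
    location: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.pKa) or not (0.0 <= self.pKa <= 14.0):
            raise ValueError(f"pKa must be finite and within 0–14, got {self.pKa!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.location not in _LOCATIONS:
            raise ValueError(f"location must be one of {_LOCATIONS}, got {self.location!r}")

    def charge(self, protonated: bool) -> int:
        """Elementary charge carried in the given protonation state."""
        if self.kind == "base":
            return 1 if protonated else 0
        return 0 if protonated else -1


@dataclass(frozen=True)
class DipeptideSpec:
    """A two-residue peptide with its ionizable groups and isotope labels.

    ``labels`` lists (residue index, mass shift in Da) pairs for heavy
    isotopes, e.g. ``((1, 3.0188),)`` for a d3-labelled first residue.
    """

    residue_1: str
    residue_2: str
    groups: tuple[IonizableGroup, ...] = ()
    labels: tuple[tuple[int, float], ...] = ()
    name: str | None = None

    def __post_init__(self) -> None:
        for res in (self.residue_1, self.residue_2):
            if len(res) != 1 or not res.isalpha():
                raise ValueError(f"residues must be one-letter codes, got {res!r}")
        locations = [g.location for g in self.groups]
        if len(set(locations)) != len(locations):
            raise ValueError("at most one ionizable group per location")
        for idx, shift in self.labels:
            if idx not in (1, 2):
                raise ValueError(f"label residue index must be 1 or 2, got {idx}")
            if not math.isfinite(shift):
                raise ValueError("label mass shift must be finite")

    @property
    def display_name(self) -> str:
        if self.name is not None:
            return self.name
        return f"{_THREE_LETTER.get(self.residue_1, self.residue_1)}–" \
               f"{_THREE_LETTER.get(self.residue_2, self.residue_2)}"

    @classmethod
    def from_residues(
        cls,
        residue_1: str,
        residue_2: str,
        include_termini: bool = False,
        pka_overrides: dict[str, float] | None = None,
        labels: tuple[tuple[int, float], ...] = (),
        name: str | None = None,
    ) -> "DipeptideSpec":
        """Build a spec from one-letter codes using the default pKa registry.

        ``pka_overrides`` maps a location name to a replacement pKa.
        """
        overrides = pka_overrides or {}
        groups: list[IonizableGroup] = []
        for res, loc in ((residue_1, "side_chain_1"), (residue_2, "side_chain_2")):
            if res in SIDE_CHAIN_PKA:
                kind = "base" if res in _BASIC_SIDE_CHAINS else "acid"
                pka = overrides.get(loc, SIDE_CHAIN_PKA[res])
                groups.append(IonizableGroup(f"{_THREE_LETTER[res]} side chain", pka, kind, loc))
        if include_termini:
            groups.append(IonizableGroup(
                "N-terminal amine", overrides.get("n_terminus", N_TERMINUS_PKA),
                "base", "n_terminus"))
            groups.append(IonizableGroup(
                "C-terminal carboxyl", overrides.get("c_terminus", C_TERMINUS_PKA),
                "acid", "c_terminus"))
        return cls(residue_1, residue_2, tuple(groups), tuple(labels), name)


@dataclass(frozen=True)
class SpeciesState:
    """One protonation microstate: a truth assignment over the groups."""

    protonated: tuple[bool, ...]
    net_side_chain_charge: int
    net_total_charge: int
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class SpeciesDistribution:
    """Microstate fractions of one peptide at one pH."""

    pH: float
    states: dict[SpeciesState, float] = field(default_factory=dict)

    @property
    def dominant(self) -> SpeciesState:
        """The microstate with the highest fraction."""
        return max(self.states, key=self.states.get)

    def fraction(self, label: str) -> float:
        """Fraction of the state with the given canonical label."""
        for state, frac in self.states.items():
            if state.label == label:
                return frac
        raise KeyError(label)

    def state(self, label: str) -> SpeciesState:
        for st in self.states:
            if st.label == label:
                return st
        raise KeyError(label)


def fraction_protonated(pKa: float, pH: float) -> float:
    """Henderson–Hasselbalch protonated fraction, 1/(1 + 10^(pH − pKa))."""
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def _charge_mark(group: IonizableGroup, protonated: bool) -> str:
    charge = group.charge(protonated)
    return {1: "+", 0: "0", -1: "-"}[charge]


def _species_label(peptide: DipeptideSpec, protonated: tuple[bool, ...]) -> str:
    """Canonical label, e.g. 'His+–Glu-'; residue 1 before residue 2.

    Residues without a modelled side-chain group carry no mark; termini
    marks, when modelled, are appended in brackets.
    """
    marks = {loc: "" for loc in _LOCATIONS}
    for group, prot in zip(peptide.groups, protonated):
        marks[group.location] = _charge_mark(group, prot)
    r1 = _THREE_LETTER.get(peptide.residue_1, peptide.residue_1)
    r2 = _THREE_LETTER.get(peptide.residue_2, peptide.residue_2)
    label = f"{r1}{marks['side_chain_1']}–{r2}{marks['side_chain_2']}"
    termini = []
    if marks["n_terminus"]:
        termini.append(f"Nt{marks['n_terminus']}")
    if marks["c_terminus"]:
        termini.append(f"Ct{marks['c_terminus']}")
    if termini:
        label += " [" + ",".join(termini) + "]"
    return label


def make_species(peptide: DipeptideSpec, protonated: tuple[bool, ...]) -> SpeciesState:
    """Construct the microstate of ``peptide`` with the given assignment."""
    if len(protonated) != len(peptide.groups):
        raise ValueError("protonation assignment length must match the group count")
    side = sum(
        g.charge(p) for g, p in zip(peptide.groups, protonated)
        if g.location in ("side_chain_1", "side_chain_2")
    )
    total = sum(g.charge(p) for g, p in zip(peptide.groups, protonated))
    return SpeciesState(tuple(protonated), side, total, _species_label(peptide, protonated))


def enumerate_species(peptide: DipeptideSpec, pH: float) -> SpeciesDistribution:
    """Enumerate all 2^n protonation microstates with their fractions at ``pH``.

    Fractions are products of independent per-group Henderson–Hasselbalch
    probabilities and sum to one by construction.
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    probs = [fraction_protonated(g.pKa, pH) for g in peptide.groups]
    dist = SpeciesDistribution(pH=pH)
    for assignment in itertools.product((True, False), repeat=len(peptide.groups)):
        frac = 1.0
        for p, assigned in zip(probs, assignment):
            frac *= p if assigned else (1.0 - p)
        dist.states[make_species(peptide, assignment)] = frac
    return dist


def mean_net_charge(peptide: DipeptideSpec, pH: float) -> float:
    """Ensemble-average net charge over all modelled groups at ``pH``."""
    dist = enumerate_species(peptide, pH)
    return sum(frac * state.net_total_charge for state, frac in dist.states.items())


def monoisotopic_mz(peptide: DipeptideSpec, adduct: str = "M+H") -> float:
    """Monoisotopic m/z of the singly protonated peptide, to 4 decimals.

    Sum of monoisotopic residue masses, water, one proton, and any isotope
    label shifts. Only the [M+H]+ adduct is supported.
    """
    if adduct != "M+H":
        raise ValueError(f"unsupported adduct {adduct!r}; only 'M+H' is implemented")
    total = WATER_MASS + PROTON_MASS
    for res in (peptide.residue_1, peptide.residue_2):
        try:
            total += _ptmass.std_aa_mass[res]
        except KeyError:
            raise ValueError(f"unknown residue code {res!r}") from None
    for _, shift in peptide.labels:
        total += shift
    return round(total, 4)


def mz_table(peptides: list[DipeptideSpec]) -> pd.DataFrame:
    """Two-column (name, m/z) table suitable for building SIM/MRM lists."""
    return pd.DataFrame(
        {
            "name": [p.display_name for p in peptides],
            "mz_M_plus_H": [monoisotopic_mz(p) for p in peptides],
        }
    )
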