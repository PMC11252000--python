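"""YAML configuration: peptide registry and scenario settings.

One structured file with optional sections:

``peptides``:
    name → {residues: "HA", include_termini: false,
            pka_overrides: {side_chain_1: 6.0}, labels: [[1, 3.0188]]}
``scenario``:
    any subset of the ScenarioConfig fields (seed, dose_M, noise levels...);
    ``substrates`` entries are {name, residues, transported, k_m_M, v_max}.
``condition``:
    pH_lum, pH_cyt, delta_psi, temperature (for thermodynamic commands).

Validation failures raise :class:`ConfigError` with a named diagnostic.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .peptide_chem import DipeptideSpec
from .synthetic_data import ScenarioConfig, SubstrateSpec
from .thermo import MembraneCondition


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def load_config(path: Path | str) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        payload = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError("top level of the config must be a mapping")
    return payload


def peptide_from_entry(name: str, entry: dict) -> DipeptideSpec:
    try:
        residues = entry["residues"]
    except (KeyError, TypeError):
        raise ConfigError(f"peptide {name!r}: missing 'residues'") from None
    if not isinstance(residues, str) or len(residues) != 2:
        raise ConfigError(f"peptide {name!r}: 'residues' must be two one-letter codes")
    try:
        return DipeptideSpec.from_residues(
            residues[0], residues[1],
            include_termini=bool(entry.get("include_termini", False)),
            pka_overrides=entry.get("pka_overrides"),
            labels=tuple(tuple(lab) for lab in entry.get("labels", [])),
            name=entry.get("display_name", name),
        )
    except ValueError as exc:
        raise ConfigError(f"peptide {name!r}: {exc}") from exc


def load_peptides(payload: dict) -> dict[str, DipeptideSpec]:
    section = payload.get("peptides", {})
    if not isinstance(section, dict):
        raise ConfigError("'peptides' section must be a mapping")
    return {name: peptide_from_entry(name, entry) for name, entry in section.items()}


def load_condition(payload: dict) -> MembraneCondition:
    section = payload.get("condition", {})
    try:
        return MembraneCondition(
            pH_lum=float(section.get("pH_lum", 5.0)),
            pH_cyt=float(section.get("pH_cyt", 7.2)),
            delta_psi=float(section.get("delta_psi", 0.0)),
            temperature=float(section.get("temperature", 293.15)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"condition section: {exc}") from exc


def load_scenario(payload: dict, seed: int | None = None) -> ScenarioConfig:
    section = dict(payload.get("scenario", {}))
    substrates = section.pop("substrates", None)
    known = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown scenario fields: {sorted(unknown)}")
    config = ScenarioConfig(**section)
    if substrates is not None:
        parsed = []
        for entry in substrates:
            try:
                peptide = DipeptideSpec.from_residues(
                    entry["residues"][0], entry["residues"][1], name=entry.get("name"))
                parsed.append(SubstrateSpec(
                    name=entry["name"],
                    peptide=peptide,
                    transported_label=entry["transported"],
                    k_m_M=float(entry["k_m_M"]),
                    v_max=float(entry["v_max"]),
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"substrate entry {entry!r}: {exc}") from exc
        config.substrates = parsed
    if seed is not None:
        config.seed = seed
    if not any(s.name == config.reference for s in config.substrates):
        raise ConfigError(
            f"reference substrate {config.reference!r} missing from scenario substrates")
    return config
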