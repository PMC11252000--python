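"""Seeded generators for every input the analysis pipelines consume.

Each generator is a pure function of (config, seed): rerunning with the same
config yields byte-identical outputs, and the returned ground truth is
sufficient to score every downstream estimate. Noise set to zero makes every
downstream pipeline exact to numerical tolerance.

The default scenario reproduces the dual voltage-clamp / pH-recording study
conditions: four substrates applied sequentially to one clamped oocyte at
extracellular pH 5.0, with His–Ala as the within-cell reference. The oocyte's
acidification response is lumped into a single coupling constant κ
(pH units per mole of protons, absorbing buffering capacity and volume);
the ratio statistic is designed to cancel κ, and the generator keeps that
cancellation testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stoichiometry
from .assay_analysis import AssayTrace, TraceEvent
from .constants import ELECTRODE_SLOPE_MV_PER_PH, FARADAY
from .kinetics import mm_velocity
from .peptide_chem import DipeptideSpec, SpeciesState, enumerate_species
from .thermal_shift import DEFAULT_NOISE_SD, MeltCurve, simulate_melt_curve

__all__ = [
    "SubstrateSpec",
    "ScenarioConfig",
    "default_tevc_substrates",
    "generate_tevc_phin_experiment",
    "generate_pyranine_experiment",
    "generate_tracer_experiment",
    "generate_melt_titration",
    "generate_tm_titration",
    "generate_genotype_table",
]


@dataclass(frozen=True)
class SubstrateSpec:
    """One substrate of a transport scenario.

    ``transported_label`` selects the protonation microstate the transporter
    carries (canonical species label); K_M and v_max set the dose–response.
    v_max is in nA for electrophysiology scenarios and ΔF_norm·s⁻¹ for
    liposome scenarios.
    """

    name: str
    peptide: DipeptideSpec
    transported_label: str
    k_m_M: float
    v_max: float

    def transported_state(self, pH: float) -> SpeciesState:
        return enumerate_species(self.peptide, pH).state(self.transported_label)


def default_tevc_substrates() -> list[SubstrateSpec]:
    """The four-substrate dual-recording roster with ideal stoichiometries
    {His–Ala: 1, His–Ser: 1, Lys–Ala: 0, His–Glu (cationic): 2}.

    Current scales are set to the robustly-evoked range (a few hundred nA);
    K_M uses the measured 2.6 mM for Lys–Ala and the same order for the
    others, a detail the normalized ratio statistic does not depend on.
    """
    return [
        SubstrateSpec("His-Ala", DipeptideSpec.from_residues("H", "A"),
                      "His+–Ala", 2.6e-3, -380.0),
        SubstrateSpec("His-Ser", DipeptideSpec.from_residues("H", "S"),
                      "His+–Ser", 2.6e-3, -350.0),
        SubstrateSpec("Lys-Ala", DipeptideSpec.from_residues("K", "A"),
                      "Lys+–Ala", 2.6e-3, -380.0),
        SubstrateSpec("His-Glu", DipeptideSpec.from_residues("H", "E"),
                      "His+–Glu0", 2.6e-3, -300.0),
    ]


@dataclass
class ScenarioConfig:
    """Study conditions for the synthetic experiments (all seeded)."""

    seed: int = 0
    substrates: list[SubstrateSpec] = field(default_factory=default_tevc_substrates)
    reference: str = "His-Ala"
    dose_M: float = 10e-3                #: applied substrate concentration
    pH_out: float = 5.0                  #: perfusion / luminal-side pH
    pH_cyt: float = 7.2                  #: cytosolic pH
    stoichiometry_mode: str = "ideal"

    # electrophysiology trace layout
    dt_s: float = 0.1
    baseline_s: float = 30.0             #: pre-application baseline per substrate
    application_s: float = 60.0
    washout_s: float = 30.0
    current_noise_nA: float = 5.0
    current_drift_nA_per_s: float = 0.02
    electrode_noise_mV: float = 0.05
    electrode_slope_mV_per_pH: float = ELECTRODE_SLOPE_MV_PER_PH
    kappa_pH_per_mol: float = 3.2e8      #: lumped oocyte buffering/volume coupling

    # pyranine liposome scenario
    liposome_dose_M: float = 2.5e-3
    liposome_k_m_M: float = 24.4e-6      #: His-Ser scale
    liposome_v_max: float = -1.731e-3    #: ΔF_norm·s⁻¹
    valinomycin_potential_mV: float = -100.0
    pyranine_tau_s: float = 600.0        #: saturation time of the uptake curve
    pyranine_noise: float = 0.002        #: relative channel noise
    pyranine_baseline_ratio: float = 1.2
    peptide_at_s: float = 30.0
    valinomycin_at_s: float = 120.0
    liposome_duration_s: float = 720.0

    # tracer scenario
    tracer_rate_pmol_s: float = 1.32
    tracer_duration_s: float = 1200.0
    cleavage_fraction: float = 1.0
    tracer_dilution: float = 0.02        #: injected fraction of the oocyte content
    tracer_noise_rel: float = 0.03
    tracer_n_oocytes: int = 4
    standard_amounts_pmol: tuple[float, ...] = (0.5, 2.0, 8.0, 16.0, 32.0, 64.0, 100.0)

    # melt titration scenario
    tm_apo_C: float = 40.0
    dtm_max_C: float = 12.0
    kd_M: float = 318e-6
    titration_concentrations_M: tuple[float, ...] = (
        0.0, 1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3, 1e-2)
    melt_noise_sd: float = DEFAULT_NOISE_SD
    tm_noise_C: float = 0.3

    # genotype abundance table
    genotype_analytes: tuple[str, ...] = ("Pro-Lys", "Arg-Pro", "anserine")
    genotype_fold_changes: tuple[float, ...] = (4.0, 4.0, 2.0)
    genotype_n_per_group: int = 5
    genotype_cv: float = 0.3


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    """Independent, deterministic random stream per generator and seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def generate_tevc_phin_experiment(config: ScenarioConfig) -> tuple[AssayTrace, dict]:
    """Synthesize one dual-recording (current + pH electrode) oocyte trace.

    The current channel holds a Michaelis–Menten plateau per substrate epoch
    plus linear drift and Gaussian noise. Proton influx r·|I|/F (r from the
    stoichiometry module on the transported microstate) is integrated into
    cytosolic acidification via κ, rendered in mV through the electrode
    calibration slope (acidification → falling trace), then noise is added.
    """
    if not any(s.name == config.reference for s in config.substrates):
        raise ValueError(f"reference substrate {config.reference!r} not in scenario")
    rng = _stream_rng(config.seed, 1)

    cycle = config.baseline_s + config.application_s + config.washout_s
    total = cycle * len(config.substrates) + config.baseline_s
    time = np.arange(0.0, total, config.dt_s)
    current = np.zeros_like(time)
    proton_flux = np.zeros_like(time)  # mol·s⁻¹
    events: list[TraceEvent] = []
    truth_substrates = {}

    for k, sub in enumerate(config.substrates):
        start = config.baseline_s + k * cycle
        end = start + config.application_s
        window = (time >= start) & (time < end)
        amplitude = mm_velocity(config.dose_M, sub.k_m_M, sub.v_max)
        current[window] += amplitude

        state = sub.transported_state(config.pH_out)
        res = stoichiometry.protons_per_charge(
            state, sub.peptide, config.pH_cyt, config.stoichiometry_mode)
        r = 0.0 if res.protons_per_charge_r is None else res.protons_per_charge_r
        flux = r * abs(amplitude) * 1e-9 / FARADAY
        proton_flux[window] += flux

        events.append(TraceEvent(sub.name, start, end))
        events.append(TraceEvent(f"{sub.name}/baseline", start - config.baseline_s, start))
        truth_substrates[sub.name] = {
            "current_nA": amplitude,
            "r": r,
            "charge_z": res.charge_z,
            "protons_h": res.protons_released_h,
            "acid_rate_pH_s": config.kappa_pH_per_mol * flux,
        }

    current = current + config.current_drift_nA_per_s * time
    if config.current_noise_nA > 0:
        current = current + rng.normal(0.0, config.current_noise_nA, size=time.shape)

    acidification = np.cumsum(config.kappa_pH_per_mol * proton_flux) * config.dt_s
    electrode = config.electrode_slope_mV_per_pH * acidification
    if config.electrode_noise_mV > 0:
        electrode = electrode + rng.normal(0.0, config.electrode_noise_mV, size=time.shape)

    trace = AssayTrace(
        time_s=time,
        channels={"current_nA": current, "electrode_mV": electrode},
        events=events,
        metadata={"holding_potential_V": -0.040, "pH_out": config.pH_out,
                  "cell_id": f"oocyte-seed{config.seed}"},
    )
    truth = {
        "substrates": truth_substrates,
        "kappa_pH_per_mol": config.kappa_pH_per_mol,
        "electrode_slope_mV_per_pH": config.electrode_slope_mV_per_pH,
        "reference": config.reference,
    }
    return trace, truth


def default_pyranine_substrates() -> list[SubstrateSpec]:
    """Liposome roster: a proton-carrying substrate (His-Ser), a cationic
    substrate with no titratable proton at cytosolic pH (Lys–Ala), and the
    protein-free control handled separately."""
    return [
        SubstrateSpec("His-Ser", DipeptideSpec.from_residues("H", "S"),
                      "His+–Ser", 24.4e-6, -1.586e-3),
        SubstrateSpec("His-Ala", DipeptideSpec.from_residues("H", "A"),
                      "His+–Ala", 119.1e-6, -1.731e-3),
        SubstrateSpec("Lys-Ala", DipeptideSpec.from_residues("K", "A"),
                      "Lys+–Ala", 2.6e-3, -1.7e-3),
    ]


def generate_pyranine_experiment(
    config: ScenarioConfig,
    substrates: list[SubstrateSpec] | None = None,
) -> tuple[dict[str, AssayTrace], dict]:
    """Synthesize two-channel pyranine traces, one liposome batch per substrate
    plus an 'empty' (protein-free) control.

    Only substrates whose transported microstate releases protons at the
    liposome-internal pH (ideal mode) acidify the lumen after valinomycin;
    the normalized excitation ratio then declines with initial slope equal
    to the configured Michaelis–Menten rate, saturating with time constant
    ``pyranine_tau_s``. Empty liposomes and proton-free substrates stay flat.
    """
    substrates = default_pyranine_substrates() if substrates is None else substrates
    traces: dict[str, AssayTrace] = {}
    truth: dict[str, dict] = {}
    time = np.arange(0.0, config.liposome_duration_s, 1.0)
    t_val = config.valinomycin_at_s
    events = [
        TraceEvent("peptide", config.peptide_at_s, config.peptide_at_s + 1.0),
        TraceEvent("valinomycin", t_val, t_val + 1.0),
    ]

    for j, entry in enumerate([*substrates, None]):
        rng = _stream_rng(config.seed, 100 + j)
        if entry is None:
            name, rate = "empty", 0.0
        else:
            name = entry.name
            state = entry.transported_state(config.pH_out)
            res = stoichiometry.protons_per_charge(
                state, entry.peptide, 7.0, "ideal")  # liposome-internal pH 7.0
            carries_proton = res.protons_released_h > 0
            rate = (
                mm_velocity(config.liposome_dose_M, entry.k_m_M, entry.v_max)
                if carries_proton else 0.0
            )
        decline = np.where(
            time >= t_val,
            rate * config.pyranine_tau_s * (1.0 - np.exp(-(time - t_val) / config.pyranine_tau_s)),
            0.0,
        )
        ratio = config.pyranine_baseline_ratio * (1.0 + decline)
        f460 = 1000.0 * (1.0 + rng.normal(0.0, config.pyranine_noise, size=time.shape))
        f415 = ratio * 1000.0 * (1.0 + rng.normal(0.0, config.pyranine_noise, size=time.shape))
        traces[name] = AssayTrace(
            time_s=time,
            channels={"F415": f415, "F460": f460},
            events=list(events),
            metadata={"liposome_id": name,
                      "valinomycin_potential_mV": config.valinomycin_potential_mV},
        )
        truth[name] = {"initial_rate_Fnorm_s": rate}
    return traces, truth


def generate_tracer_experiment(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Synthesize calibration-standard and sample peak-area tables for the
    heavy-isotope uptake experiment.

    The imported dipeptide is split into its cleaved products according to
    ``cleavage_fraction`` (1.0 = complete intracellular cleavage, giving an
    equimolar product ratio). Areas follow a per-analyte linear response
    with a blank intercept and multiplicative noise. Mock samples carry no
    import, only blank signal.
    """
    if not (0.0 <= config.cleavage_fraction <= 1.0):
        raise ValueError("cleavage_fraction must lie in [0, 1]")
    rng = _stream_rng(config.seed, 2)
    analytes = {
        "Leu(d3)-Ala": {"slope": 9.0e3, "blank": 400.0},
        "Leu(d3)": {"slope": 1.2e4, "blank": 600.0},
        "Ala": {"slope": 1.5e4, "blank": 900.0},
    }
    imported = config.tracer_rate_pmol_s * config.tracer_duration_s  # pmol/oocyte
    content = {
        "Leu(d3)-Ala": (1.0 - config.cleavage_fraction) * imported,
        "Leu(d3)": config.cleavage_fraction * imported,
        "Ala": config.cleavage_fraction * imported,
    }

    std_rows, sample_rows = [], []
    for analyte, pars in analytes.items():
        for amount in config.standard_amounts_pmol:
            area = pars["blank"] + pars["slope"] * amount
            area *= 1.0 + rng.normal(0.0, config.tracer_noise_rel)
            std_rows.append({"analyte": analyte, "amount_pmol": amount, "area": area})
        for i in range(config.tracer_n_oocytes):
            injected = content[analyte] * config.tracer_dilution
            area = pars["blank"] + pars["slope"] * injected
            area *= 1.0 + rng.normal(0.0, config.tracer_noise_rel)
            sample_rows.append({"analyte": analyte, "sample_id": f"transporter-{i}", "area": area})
        for i in range(config.tracer_n_oocytes):
            area = pars["blank"] * (1.0 + rng.normal(0.0, config.tracer_noise_rel))
            sample_rows.append({"analyte": analyte, "sample_id": f"mock-{i}", "area": area})

    truth = {
        "uptake_rate_pmol_s": config.tracer_rate_pmol_s,
        "imported_pmol": imported,
        "cleavage_fraction": config.cleavage_fraction,
        "product_ratio": 1.0 if config.cleavage_fraction > 0 else None,
        "dilution": config.tracer_dilution,
        "duration_s": config.tracer_duration_s,
    }
    return pd.DataFrame(sample_rows), pd.DataFrame(std_rows), truth


def generate_melt_titration(
    config: ScenarioConfig, ligand: str = "Pro-Arg", replicates: int = 1
) -> tuple[list[MeltCurve], dict]:
    """Simulate a melt-curve dilution series with saturating stabilisation.

    T_m(L) = T_m_apo + ΔT_m_max·L/(K_D + L); each curve is a seeded
    two-state melt trace.
    """
    curves = []
    for i, conc in enumerate(config.titration_concentrations_M):
        tm = config.tm_apo_C + config.dtm_max_C * conc / (config.kd_M + conc)
        for rep in range(replicates):
            curves.append(simulate_melt_curve(
                tm,
                noise_sd=config.melt_noise_sd,
                seed=int(np.random.SeedSequence([config.seed, 3, i, rep]).generate_state(1)[0] % (2**31)),
                ligand=ligand if conc > 0 else "apo",
                concentration_M=conc,
                replicate=rep,
            ))
    truth = {"kd_M": config.kd_M, "dtm_max_C": config.dtm_max_C,
             "tm_apo_C": config.tm_apo_C}
    return curves, truth


def generate_tm_titration(
    config: ScenarioConfig, replicates: int = 3
) -> tuple[list[tuple[float, float]], dict]:
    """Directly sample (concentration, T_m) pairs with Gaussian T_m noise.

    Lighter-weight counterpart of :func:`generate_melt_titration` for K_D
    recovery studies where the melt traces themselves are not needed.
    Defaults to triplicate measurements per concentration, the usual
    thermal-stability design.
    """
    rng = _stream_rng(config.seed, 4)
    pairs = []
    for conc in config.titration_concentrations_M:
        tm = config.tm_apo_C + config.dtm_max_C * conc / (config.kd_M + conc)
        for _ in range(replicates):
            pairs.append((conc, tm + rng.normal(0.0, config.tm_noise_C)))
    truth = {"kd_M": config.kd_M, "dtm_max_C": config.dtm_max_C,
             "tm_apo_C": config.tm_apo_C}
    return pairs, truth


def generate_genotype_table(config: ScenarioConfig) -> tuple[pd.DataFrame, dict]:
    """Two-genotype dipeptide abundance table with an internal-standard column.

    Abundances are log-normal around genotype means (knockout mean = fold
    change × wild-type mean); the labelled internal standard has the same
    distribution in both genotypes, and a per-sample global scale factor
    multiplies every analyte so that internal-standard normalization removes
    it exactly.
    """
    if len(config.genotype_fold_changes) != len(config.genotype_analytes):
        raise ValueError("one fold change per analyte required")
    rng = _stream_rng(config.seed, 5)
    sigma = np.sqrt(np.log(1.0 + config.genotype_cv**2))
    rows = []
    for genotype, fold_active in (("WT", False), ("KO", True)):
        for i in range(config.genotype_n_per_group):
            sample_scale = np.exp(rng.normal(0.0, 0.2))  # injection/extraction factor
            is_level = 1e5 * np.exp(rng.normal(-sigma**2 / 2, sigma)) * sample_scale
            row = {"genotype": genotype, "sample_id": f"{genotype}-{i}",
                   "internal_standard": is_level}
            for analyte, fold in zip(config.genotype_analytes, config.genotype_fold_changes):
                mean = 1e4 * (fold if fold_active else 1.0)
                row[analyte] = mean * np.exp(rng.normal(-sigma**2 / 2, sigma)) * sample_scale
            rows.append(row)
    truth = {"fold_changes": dict(zip(config.genotype_analytes,
                                      config.genotype_fold_changes))}
    return pd.DataFrame(rows), truth
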