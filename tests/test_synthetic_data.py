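"""Generator determinism, ground-truth fidelity and downstream recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from peptiport import kinetics
from peptiport.assay_analysis import (
    analyze_tevc_cell,
    pyranine_normalized_ratio,
    tracer_quantify,
)
from peptiport.synthetic_data import (
    ScenarioConfig,
    generate_genotype_table,
    generate_melt_titration,
    generate_pyranine_experiment,
    generate_tevc_phin_experiment,
    generate_tracer_experiment,
)
from peptiport.thermal_shift import extract_tm, fit_kd_from_shifts

SUBSTRATES = [s.name for s in ScenarioConfig().substrates]


class TestDeterminism:
    def test_tevc_reruns_identical(self):
        a, _ = generate_tevc_phin_experiment(ScenarioConfig(seed=9))
        b, _ = generate_tevc_phin_experiment(ScenarioConfig(seed=9))
        assert np.array_equal(a.channels["current_nA"], b.channels["current_nA"])
        assert np.array_equal(a.channels["electrode_mV"], b.channels["electrode_mV"])

    def test_different_seed_differs(self):
        a, _ = generate_tevc_phin_experiment(ScenarioConfig(seed=1))
        b, _ = generate_tevc_phin_experiment(ScenarioConfig(seed=2))
        assert not np.array_equal(a.channels["current_nA"], b.channels["current_nA"])

    def test_tracer_reruns_identical(self):
        s1, t1, _ = generate_tracer_experiment(ScenarioConfig(seed=4))
        s2, t2, _ = generate_tracer_experiment(ScenarioConfig(seed=4))
        assert s1.equals(s2) and t1.equals(t2)


class TestTevcScenario:
    def test_zero_noise_recovers_generator_truth_exactly(self):
        cfg = ScenarioConfig(seed=0, current_noise_nA=0.0, electrode_noise_mV=0.0,
                             current_drift_nA_per_s=0.0)
        trace, truth = generate_tevc_phin_experiment(cfg)
        stats, cell = analyze_tevc_cell(trace, SUBSTRATES, cfg.reference)
        for s in stats:
            assert s.ratio == pytest.approx(truth["substrates"][s.substrate]["r"], abs=1e-9)
            assert cell[s.substrate][0] == pytest.approx(
                truth["substrates"][s.substrate]["current_nA"], rel=1e-9)

    def test_default_noise_recovery(self):
        trace, truth = generate_tevc_phin_experiment(ScenarioConfig(seed=3))
        stats, _ = analyze_tevc_cell(trace, SUBSTRATES, "His-Ala")
        for s in stats:
            assert s.ratio == pytest.approx(truth["substrates"][s.substrate]["r"], abs=0.15)

    def test_kappa_cancels_in_ratio(self):
        """Doubling the buffering/volume coupling κ doubles the acidification
        signal but leaves r̂ unchanged."""
        base = ScenarioConfig(seed=0, current_noise_nA=0.0, electrode_noise_mV=0.0,
                              current_drift_nA_per_s=0.0)
        doubled = ScenarioConfig(seed=0, current_noise_nA=0.0, electrode_noise_mV=0.0,
                                 current_drift_nA_per_s=0.0,
                                 kappa_pH_per_mol=2 * base.kappa_pH_per_mol)
        ta, _ = generate_tevc_phin_experiment(base)
        tb, _ = generate_tevc_phin_experiment(doubled)
        sa, ca = analyze_tevc_cell(ta, SUBSTRATES, "His-Ala")
        sb, cb = analyze_tevc_cell(tb, SUBSTRATES, "His-Ala")
        for x, y in zip(sa, sb):
            assert cb[y.substrate][1] == pytest.approx(2 * ca[x.substrate][1], rel=1e-9)
            assert y.ratio == pytest.approx(x.ratio, abs=1e-9)

    def test_missing_reference_rejected(self):
        cfg = ScenarioConfig(reference="Gly-Gly")
        with pytest.raises(ValueError, match="reference"):
            generate_tevc_phin_experiment(cfg)


class TestPyranineScenario:
    def test_empty_liposomes_flat(self):
        traces, _ = generate_pyranine_experiment(ScenarioConfig(seed=1))
        fnorm = pyranine_normalized_ratio(traces["empty"], "peptide")
        assert np.abs(fnorm - 1.0).max() < 0.02

    def test_proton_free_substrate_flat_despite_transport(self):
        """A Lys–Ala-like substrate is transported but carries no titratable
        proton at the liposome-internal pH, so the dye reports nothing."""
        traces, truth = generate_pyranine_experiment(ScenarioConfig(seed=1))
        assert truth["Lys-Ala"]["initial_rate_Fnorm_s"] == 0.0
        fnorm = pyranine_normalized_ratio(traces["Lys-Ala"], "peptide")
        assert np.abs(fnorm - 1.0).max() < 0.02

    def test_his_ser_rate_recovered(self):
        cfg = ScenarioConfig(seed=2)
        traces, truth = generate_pyranine_experiment(cfg)
        trace = traces["His-Ser"]
        fnorm = pyranine_normalized_ratio(trace, "peptide")
        val = trace.event("valinomycin")
        slope, _ = kinetics.initial_rate(
            trace.time_s, fnorm, (val.start_s, val.start_s + 30.0))
        assert slope == pytest.approx(truth["His-Ser"]["initial_rate_Fnorm_s"], rel=0.10)


class TestTracerScenario:
    def test_complete_cleavage_product_ratio(self):
        cfg = ScenarioConfig(seed=0)
        samples, standards, truth = generate_tracer_experiment(cfg)
        res = tracer_quantify(
            samples[samples.sample_id.str.startswith("transporter")], standards,
            cfg.tracer_duration_s, product_pair=("Ala", "Leu(d3)"),
            scale=1.0 / cfg.tracer_dilution)
        assert res.product_ratio == pytest.approx(1.0, abs=0.1)
        assert res.rates_pmol_s["Leu(d3)"] == pytest.approx(
            truth["uptake_rate_pmol_s"], rel=0.10)

    def test_zero_cleavage_all_intact(self):
        cfg = ScenarioConfig(seed=0, cleavage_fraction=0.0, tracer_noise_rel=0.0)
        samples, standards, _ = generate_tracer_experiment(cfg)
        res = tracer_quantify(
            samples[samples.sample_id.str.startswith("transporter")], standards,
            cfg.tracer_duration_s, scale=1.0 / cfg.tracer_dilution)
        assert res.rates_pmol_s["Leu(d3)-Ala"] == pytest.approx(1.32, rel=1e-6)
        assert res.rates_pmol_s["Ala"] == pytest.approx(0.0, abs=1e-9)

    def test_mock_samples_stay_at_blank(self):
        cfg = ScenarioConfig(seed=0)
        samples, standards, _ = generate_tracer_experiment(cfg)
        res = tracer_quantify(
            samples[samples.sample_id.str.startswith("mock")], standards,
            cfg.tracer_duration_s, scale=1.0 / cfg.tracer_dilution)
        # blank-level areas quantify to ~0 pmol (well under 1% of the import)
        assert np.abs(res.amounts.amount_pmol).max() < 0.05 * 1584.0

    def test_invalid_cleavage_rejected(self):
        with pytest.raises(ValueError, match="cleavage"):
            generate_tracer_experiment(ScenarioConfig(cleavage_fraction=1.5))


class TestMeltScenario:
    def test_titration_curves_recover_kd(self):
        cfg = ScenarioConfig(seed=5)
        curves, truth = generate_melt_titration(cfg)
        pairs = [(c.concentration_M, extract_tm(c).T_m) for c in curves]
        fit = fit_kd_from_shifts(pairs)
        assert fit.converged
        assert fit.K_D == pytest.approx(truth["kd_M"], rel=0.20)

    def test_apo_replicates_shift_zero(self):
        cfg = ScenarioConfig(seed=6)
        curves, _ = generate_melt_titration(cfg, replicates=2)
        apo = [extract_tm(c).T_m for c in curves if c.ligand == "apo"]
        assert max(apo) - min(apo) < 0.4


class TestGenotypeTable:
    @staticmethod
    def normalized(df):
        out = df.copy()
        for col in ("Pro-Lys", "Arg-Pro", "anserine"):
            out[col] = out[col] / out["internal_standard"]
        return out

    def test_unit_fold_change_balanced(self):
        cfg = ScenarioConfig(seed=0, genotype_fold_changes=(1.0, 1.0, 1.0),
                             genotype_n_per_group=40)
        df, _ = generate_genotype_table(cfg)
        norm = self.normalized(df)
        wt = norm[norm.genotype == "WT"]["Arg-Pro"]
        ko = norm[norm.genotype == "KO"]["Arg-Pro"]
        assert ko.mean() / wt.mean() == pytest.approx(1.0, abs=0.25)

    def test_internal_standard_removes_global_scale(self):
        cfg = ScenarioConfig(seed=1)
        df, _ = generate_genotype_table(cfg)
        scaled = df.copy()
        for col in ("Pro-Lys", "Arg-Pro", "anserine", "internal_standard"):
            scaled[col] = scaled[col] * 7.3
        assert np.allclose(self.normalized(df)[["Pro-Lys", "Arg-Pro", "anserine"]],
                           self.normalized(scaled)[["Pro-Lys", "Arg-Pro", "anserine"]])

    def test_fourfold_increase_detected_in_most_seeds(self):
        """n = 5/group, 4-fold knockout increase: t-test on normalized values
        significant at α = 0.05 in ≥90% of seeds."""
        hits = 0
        seeds = 40
        for seed in range(seeds):
            df, _ = generate_genotype_table(ScenarioConfig(seed=seed))
            norm = self.normalized(df)
            wt = norm[norm.genotype == "WT"]["Arg-Pro"]
            ko = norm[norm.genotype == "KO"]["Arg-Pro"]
            p = sps.ttest_ind(np.log(ko), np.log(wt)).pvalue
            hits += p <= 0.05
        assert hits >= 0.9 * seeds
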