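"""MR estimators against hand arithmetic and weighted-least-squares oracles."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from metamed.errors import EstimatorError, InputError, InstrumentError
from metamed.mr import (
    HarmonizedSet,
    harmonize,
    ivw,
    ld_clump,
    mr_egger,
    run_bidirectional_mr,
    select_instruments,
    wald_ratio,
)
from metamed.simulate import (
    MRTruth,
    SimulationConfig,
    block_ld,
    generate_gwas_summaries,
    identity_ld,
)


def _gwas(snp, ea, oa, eaf, beta, se, pval):
    return pd.DataFrame(
        {
            "SNP": snp,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
        }
    )


def _harmonized(bx, by, so):
    return HarmonizedSet(
        data=pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(len(bx))],
                "beta_exp": bx,
                "se_exp": [0.01] * len(bx),
                "beta_out": by,
                "se_out": so,
                "action": ["kept"] * len(bx),
            }
        ),
        actions=pd.DataFrame(),
    )


class TestSelectInstruments:
    def test_boundary_is_strict(self):
        table = _gwas(["a", "b"], "A", "C", 0.3, 0.1, 0.01, [1e-8, 0.9e-8])
        kept = select_instruments(table, p_threshold=1e-8)
        assert list(kept["SNP"]) == ["b"]

    def test_mixed_pvalues(self):
        table = _gwas(["a", "b"], "A", "C", 0.3, 0.1, 0.01, [1e-9, 1e-7])
        assert list(select_instruments(table)["SNP"]) == ["a"]

    def test_empty_selection_raises(self):
        table = _gwas(["a"], "A", "C", 0.3, 0.1, 0.01, [0.5])
        with pytest.raises(InstrumentError):
            select_instruments(table)

    def test_strong_simulated_instruments_all_pass(self):
        cfg = SimulationConfig(seed=1, mr_truth=MRTruth(50, 0.2, 0.0, 0.0))
        exp, _, _ = generate_gwas_summaries(cfg)
        assert len(select_instruments(exp)) == 50


class TestLdClump:
    def test_identity_matrix_keeps_all(self):
        table = _gwas(list("abc"), "A", "C", 0.3, 0.1, 0.01, [1e-9, 1e-10, 1e-11])
        kept = ld_clump(table, identity_ld(list("abc")))
        assert set(kept["SNP"]) == {"a", "b", "c"}

    def test_perfect_ld_keeps_smaller_p(self):
        table = _gwas(["a", "b"], "A", "C", 0.3, 0.1, 0.01, [1e-9, 1e-12])
        ld = block_ld(["a", "b"], [["a", "b"]], r2=1.0)
        kept = ld_clump(table, ld)
        assert list(kept["SNP"]) == ["b"]

    def test_block_structure_enumeration(self):
        """{1,2,3} mutually r²=0.9, {4,5} independent → 3 survivors."""
        snps = ["s1", "s2", "s3", "s4", "s5"]
        table = _gwas(snps, "A", "C", 0.3, 0.1, 0.01, [1e-9, 1e-10, 1e-11, 1e-12, 1e-13])
        ld = block_ld(snps, [["s1", "s2", "s3"]], r2=0.9)
        kept = ld_clump(table, ld)
        # oracle: greedy by ascending p keeps s5, s4, then s3 (best of its block)
        assert list(kept["SNP"]) == ["s3", "s4", "s5"]

    def test_missing_snp_in_ld_rejected(self):
        table = _gwas(["a", "b"], "A", "C", 0.3, 0.1, 0.01, [1e-9, 1e-10])
        with pytest.raises(InputError):
            ld_clump(table, identity_ld(["a"]))


class TestHarmonize:
    def test_aligned_kept_unchanged(self):
        exp = _gwas(["a"], ["A"], ["C"], [0.3], [0.1], [0.01], [1e-9])
        out = _gwas(["a"], ["A"], ["C"], [0.31], [0.05], [0.02], [0.01])
        h = harmonize(exp, out)
        assert h.data.loc[0, "action"] == "kept"
        assert h.data.loc[0, "beta_out"] == 0.05

    def test_swapped_alleles_flip_beta(self):
        exp = _gwas(["a"], ["A"], ["C"], [0.3], [0.1], [0.01], [1e-9])
        out = _gwas(["a"], ["C"], ["A"], [0.7], [0.1], [0.02], [0.01])
        h = harmonize(exp, out)
        assert h.data.loc[0, "action"] == "flipped"
        assert h.data.loc[0, "beta_out"] == -0.1

    def test_palindromic_mid_frequency_dropped(self):
        exp = _gwas(["a"], ["A"], ["T"], [0.50], [0.1], [0.01], [1e-9])
        out = _gwas(["a"], ["A"], ["T"], [0.50], [0.1], [0.02], [0.01])
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.actions.loc[0, "action"] == "dropped-palindromic"

    def test_palindromic_clear_frequency_kept(self):
        exp = _gwas(["a"], ["C"], ["G"], [0.10], [0.1], [0.01], [1e-9])
        out = _gwas(["a"], ["C"], ["G"], [0.12], [0.1], [0.02], [0.01])
        h = harmonize(exp, out)
        assert h.n_snps == 1 and h.data.loc[0, "action"] == "kept"

    def test_palindromic_opposite_sides_dropped(self):
        exp = _gwas(["a"], ["C"], ["G"], [0.10], [0.1], [0.01], [1e-9])
        out = _gwas(["a"], ["C"], ["G"], [0.90], [0.1], [0.02], [0.01])
        assert harmonize(exp, out).n_snps == 0

    def test_irreconcilable_and_missing_dropped_with_reason(self):
        exp = _gwas(["a", "b"], ["A", "A"], ["C", "C"], 0.3, 0.1, 0.01, 1e-9)
        out = _gwas(["a"], ["A"], ["G"], [0.3], [0.1], [0.02], [0.01])
        h = harmonize(exp, out)
        acts = dict(zip(h.actions["SNP"], h.actions["action"]))
        assert acts == {"a": "dropped-irreconcilable", "b": "dropped-missing"}

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing already-aligned tables changes nothing."""
        cfg = SimulationConfig(seed=2, mr_truth=MRTruth(40, 0.2, 0.0, 0.0))
        exp, out, _ = generate_gwas_summaries(cfg)
        h1 = harmonize(exp, out)
        aligned_out = exp.copy()
        aligned_out["beta"] = h1.data.set_index("SNP").loc[
            [s for s in exp["SNP"] if s in set(h1.data["SNP"])], "beta_out"
        ].reindex(exp["SNP"]).to_numpy()
        aligned_out["se"] = 0.01
        keep = aligned_out["beta"].notna()
        h2 = harmonize(exp[keep.to_numpy()], aligned_out[keep.to_numpy()])
        assert (h2.data["action"] == "kept").all()
        np.testing.assert_allclose(
            h2.data["beta_out"].to_numpy(), h1.data["beta_out"].to_numpy()
        )


class TestWaldRatio:
    def test_hand_arithmetic(self):
        res = wald_ratio({"beta_exp": 0.1, "beta_out": 0.05, "se_out": 0.02})
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(0.2, abs=1e-12)
        assert res.estimate / res.se == pytest.approx(2.5, abs=1e-12)

    def test_zero_outcome_beta(self):
        res = wald_ratio({"beta_exp": 0.1, "beta_out": 0.0, "se_out": 0.02})
        assert res.estimate == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(EstimatorError):
            wald_ratio({"beta_exp": 0.0, "beta_out": 0.1, "se_out": 0.02})

    def test_single_strong_instrument_recovers_truth(self):
        hits = 0
        for rep in range(50):
            cfg = SimulationConfig(seed=100 + rep, mr_truth=MRTruth(1, 0.2, 0.0, 0.0))
            exp, out, _ = generate_gwas_summaries(cfg)
            h = harmonize(exp, out)
            if h.n_snps == 0:  # palindromic draw
                continue
            res = wald_ratio(h.data.iloc[0])
            hits += abs(res.estimate - 0.2) < 3 * res.se
        assert hits >= 0.9 * 50 * 0.9


class TestIvw:
    def test_two_snp_worked_example(self):
        """β_exp {1,1}, β_out {0.5,0.3}, se_out 0.1 → est 0.4, SE √(1/200), Q 2."""
        res = ivw(_harmonized([1.0, 1.0], [0.5, 0.3], [0.1, 0.1]))
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.se == pytest.approx(math.sqrt(1.0 / 200.0), abs=1e-12)
        assert res.q_stat == pytest.approx(2.0, abs=1e-10)
        assert res.q_df == 1

    def test_single_snp_reduces_to_wald(self):
        h = _harmonized([0.1], [0.05], [0.02])
        res = ivw(h)
        wald = wald_ratio(h.data.iloc[0])
        assert res.method == "Wald"
        assert res.estimate == wald.estimate and res.se == wald.se

    def test_matches_wls_through_origin(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.15, 20)
        so = rng.uniform(0.008, 0.012, 20)
        by = 0.2 * bx + rng.normal(0, so)
        res = ivw(_harmonized(bx, by, so))
        fit = sm.WLS(by, bx, weights=1.0 / so**2).fit()
        assert res.estimate == pytest.approx(fit.params[0], abs=1e-8)
        # Q from first principles
        w = bx**2 / so**2
        q = float(np.sum(w * (by / bx - res.estimate) ** 2))
        assert res.q_stat == pytest.approx(q, abs=1e-8)

    def test_random_effects_triggered_by_heterogeneity(self):
        cfg = SimulationConfig(seed=4, mr_truth=MRTruth(50, 0.2, 0.05, 0.0))
        exp, out, _ = generate_gwas_summaries(cfg)
        h = harmonize(select_instruments(exp), out)
        res = ivw(h)
        assert res.p_het < 0.05
        assert res.random_effects and res.method == "IVW-random"
        # random-effects SE = fixed SE x sqrt(Q/df)
        w = h.data["beta_exp"] ** 2 / h.data["se_out"] ** 2
        fixed_se = math.sqrt(1.0 / w.sum())
        assert res.se == pytest.approx(fixed_se * math.sqrt(res.q_stat / res.q_df), abs=1e-12)
        assert res.se > fixed_se

    def test_no_heterogeneity_keeps_fixed_effects(self):
        cfg = SimulationConfig(seed=5, mr_truth=MRTruth(50, 0.2, 0.0, 0.0))
        exp, out, _ = generate_gwas_summaries(cfg)
        res = ivw(harmonize(select_instruments(exp), out))
        assert res.method == "IVW-fixed" and not res.random_effects


class TestEgger:
    def _instance(self, seed=6, intercept=0.03):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.15, 30)
        so = rng.uniform(0.008, 0.012, 30)
        by = intercept + 0.2 * bx + rng.normal(0, 2 * so)  # overdispersed
        return bx, by, so

    def test_matches_wls_oracle(self):
        bx, by, so = self._instance()
        res = mr_egger(_harmonized(bx, by, so))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / so**2).fit()
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-8)
        assert res.estimate == pytest.approx(fit.params[1], abs=1e-8)
        # overdispersion factor > 1 here, so the SEs coincide with WLS too
        assert fit.scale > 1.0
        assert res.se == pytest.approx(fit.bse[1], abs=1e-8)
        assert res.egger_intercept_se == pytest.approx(fit.bse[0], abs=1e-8)

    def test_zero_intercept_limit_agrees_with_ivw(self):
        cfg = SimulationConfig(seed=7, mr_truth=MRTruth(50, 0.2, 0.0, 0.0))
        exp, out, _ = generate_gwas_summaries(cfg)
        h = harmonize(select_instruments(exp), out)
        e, i = mr_egger(h), ivw(h)
        assert abs(e.estimate - i.estimate) < 3 * e.se

    def test_orientation_flips_negative_exposure_betas(self):
        bx = np.array([0.1, -0.1, 0.12])
        by = np.array([0.02, -0.02, 0.024])
        res = mr_egger(_harmonized(bx, by, [0.01, 0.01, 0.01]))
        flipped = mr_egger(_harmonized(np.abs(bx), np.abs(by) * np.sign(bx * by), [0.01] * 3))
        assert res.estimate == pytest.approx(flipped.estimate, abs=1e-12)

    def test_three_snps_minimal_fit(self):
        res = mr_egger(_harmonized([0.1, 0.12, 0.14], [0.02, 0.03, 0.02], [0.01] * 3))
        assert res.n_snps == 3
        assert np.isfinite(res.p_pleio)

    def test_under_identified_rejected(self):
        with pytest.raises(EstimatorError):
            mr_egger(_harmonized([0.1, 0.12], [0.02, 0.03], [0.01, 0.01]))


class TestBidirectional:
    def test_planted_effects_recovered_both_directions(self):
        cfg1 = SimulationConfig(seed=8, mr_truth=MRTruth(50, 0.1, 0.0, 0.0))
        bmi_gwas, met_gwas, _ = generate_gwas_summaries(cfg1)
        cfg2 = SimulationConfig(seed=9, mr_truth=MRTruth(20, 0.3, 0.0, 0.0))
        met_exp, t2d_gwas, _ = generate_gwas_summaries(cfg2)
        met_exp = met_exp.assign(SNP=met_exp["SNP"] + "_m")
        t2d_gwas = t2d_gwas.assign(SNP=t2d_gwas["SNP"] + "_m")
        met_table = pd.concat([met_gwas, met_exp], ignore_index=True)
        res = run_bidirectional_mr(bmi_gwas, met_table, t2d_gwas)
        d1 = res["bmi_to_metabolite"]["primary"]
        d2 = res["metabolite_to_t2d"]["primary"]
        assert abs(d1.estimate - 0.1) < 3 * d1.se
        assert abs(d2.estimate - 0.3) < 3 * d2.se

    def test_single_instrument_direction_uses_wald_without_sensitivity(self):
        cfg1 = SimulationConfig(seed=10, mr_truth=MRTruth(40, 0.1, 0.0, 0.0))
        bmi_gwas, met_gwas, _ = generate_gwas_summaries(cfg1)
        cfg2 = SimulationConfig(
            seed=11, mr_truth=MRTruth(1, 0.3, 0.0, 0.0), mr_palindromic_fraction=0.0
        )
        met_exp, t2d_gwas, _ = generate_gwas_summaries(cfg2)
        met_exp = met_exp.assign(SNP="rs_solo")
        t2d_gwas = t2d_gwas.assign(SNP="rs_solo")
        met_table = pd.concat([met_gwas, met_exp], ignore_index=True)
        res = run_bidirectional_mr(bmi_gwas, met_table, t2d_gwas)
        d2 = res["metabolite_to_t2d"]
        assert d2["primary"].method == "Wald"
        assert d2["egger"] is None

    def test_direction_without_instruments_marked_unavailable(self):
        cfg = SimulationConfig(seed=12, mr_truth=MRTruth(30, 0.1, 0.0, 0.0))
        bmi_gwas, met_gwas, _ = generate_gwas_summaries(cfg)
        weak = met_gwas.copy()
        weak["pval"] = 0.5  # metabolite has no genome-wide-significant SNPs
        t2d = met_gwas.copy()
        res = run_bidirectional_mr(bmi_gwas, weak, t2d)
        assert res["metabolite_to_t2d"] is None
        assert res["bmi_to_metabolite"] is not None
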