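"""The planted-structure generators: determinism, truth consistency, signal."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from metsubtype import compendium as comp
from metsubtype import synthdata as sd
from conftest import hypergeom_tail


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"n_genes": 0}, "positive"),
            ({"switch_rate": 1.5}, r"\[0, 1\]"),
            ({"missing_gene_fraction": -0.1}, r"\[0, 1\]"),
            ({"k_subtypes": 10, "genes_per_subtype_module": 300, "n_genes": 2000},
             "exceed"),
            ({"ploidy_weights": {2: -1.0}}, "ploidy"),
            ({"gain_enrichment_odds": 0.0}, "positive"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            sd.SynthConfig(**kwargs)


class TestCompendiumGenerator:
    def test_same_seed_bit_identical(self, small_cfg):
        t1, a1, tr1 = sd.generate_compendium(small_cfg)
        t2, a2, tr2 = sd.generate_compendium(dataclasses.replace(small_cfg))
        for s in t1:
            pd.testing.assert_frame_equal(t1[s], t2[s])
        pd.testing.assert_frame_equal(a1, a2)
        assert tr1.sample_subtype == tr2.sample_subtype

    def test_positive_scale_and_missing_rows(self, small_world):
        cfg = small_world["cfg"]
        for table in small_world["tables"].values():
            assert (table.values > 0).all()
            expected_drop = int(round(cfg.missing_gene_fraction * cfg.n_genes))
            assert table.shape[0] == cfg.n_genes - expected_drop

    def test_truth_maps_consistent(self, small_world):
        truth = small_world["truth"]
        ann = small_world["annotations"]
        assert set(truth.sample_subtype) >= set(ann["sample_id"])
        assert set(truth.sample_subtype.values()) <= set(truth.subtype_labels)
        assert set(truth.gene_module) <= set(truth.genes)
        # modules disjoint by construction: each gene maps to one subtype
        sizes = pd.Series(truth.gene_module).value_counts()
        assert (sizes == small_world["cfg"].genes_per_subtype_module).all()

    def test_within_module_correlation_exceeds_between(self, small_world):
        """Inside a subtype's samples... across all samples, genes of the
        same module correlate more strongly than genes of different
        modules, by direct computation on the generated matrix."""
        vals = small_world["compendium"].values
        truth = small_world["truth"]
        mod1 = [g for g in truth.module_genes("s1") if g in vals.index][:20]
        mod2 = [g for g in truth.module_genes("s2") if g in vals.index][:20]
        corr = vals.loc[mod1 + mod2].T.corr(min_periods=10)
        within = corr.loc[mod1, mod1].values[np.triu_indices(len(mod1), 1)]
        between = corr.loc[mod1, mod2].values.ravel()
        assert np.nanmean(within) > np.nanmean(between) + 0.2

    def test_zero_effect_gives_no_recoverable_structure(self):
        """delta=0: consensus clustering ARI vs truth stays ~0 (|ARI|<0.05
        averaged over seeds)."""
        from metsubtype.subtyping import consensus_cluster

        aris = []
        for seed in range(4):
            cfg = sd.SynthConfig(
                n_studies=2, cancer_types_per_study=2, samples_per_study=40,
                n_genes=300, genes_per_subtype_module=20, effect_size_delta=0.0,
                missing_gene_fraction=0.0, seed=100 + seed,
            )
            tables, ann, truth = sd.generate_compendium(cfg)
            raw = [comp.RawStudyTable(study_id=s, values=v) for s, v in tables.items()]
            matrix, ann2 = comp.assemble_compendium(raw, ann)
            c = comp.center_scale_within_strata(matrix, ann2)
            res = consensus_cluster(c.values, k_range=[4], reps=15,
                                    subsample_fraction=0.8, seed=seed)
            truth_labels = pd.Series(truth.sample_subtype).reindex(c.values.columns)
            aris.append(adjusted_rand_score(truth_labels, res.assignments[4]))
        assert abs(np.mean(aris)) < 0.05


class TestPairedGenerator:
    @pytest.mark.parametrize("rate,expect", [(0.0, 1.0), (1.0, 0.0)])
    def test_extreme_switch_rates(self, small_cfg, rate, expect):
        cfg = dataclasses.replace(small_cfg, switch_rate=rate, n_pairs=30)
        _, _, truth = sd.generate_compendium(cfg)
        _, _, pairs, truth = sd.generate_paired_cohort(cfg, truth)
        conc = np.mean([p == m for p, m in truth.pair_subtypes.values()])
        assert conc == expect

    def test_switch_fraction_within_binomial_ci(self, small_cfg):
        """switch_rate=0.4 at n=300: planted switch fraction inside the
        closed-form binomial 99% CI."""
        cfg = dataclasses.replace(small_cfg, switch_rate=0.4, n_pairs=300)
        _, _, truth = sd.generate_compendium(cfg)
        _, _, _, truth = sd.generate_paired_cohort(cfg, truth)
        switched = np.mean([p != m for p, m in truth.pair_subtypes.values()])
        lo, hi = binom.ppf([0.005, 0.995], 300, 0.4) / 300
        assert lo <= switched <= hi

    def test_pairs_share_patient_and_study(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_pairs=20)
        _, _, truth = sd.generate_compendium(cfg)
        met, pri, pairs, _ = sd.generate_paired_cohort(cfg, truth)
        assert list(met.columns) == list(pairs["met_sample"])
        assert list(pri.columns) == list(pairs["primary_sample"])
        assert pairs["patient_id"].is_unique


class TestCopyNumberGenerator:
    def test_all_ploidy_four_median(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, ploidy_weights={4: 1.0},
                                  gain_baseline_rate=0.0)
        _, _, truth = sd.generate_compendium(cfg)
        cn = sd.generate_copy_number(cfg, truth)
        assert (cn.median(axis=0) == 4).all()

    def test_null_odds_gain_frequency_independent_of_subtype(self, small_cfg):
        """odds=1: chi-square p over gain-by-subtype tables behaves like a
        null (no excess of small p over 20 module genes)."""
        from metsubtype.genomics import call_gain_loss, gain_enrichment_by_subtype

        cfg = dataclasses.replace(small_cfg, gain_enrichment_odds=1.0,
                                  ploidy_weights={2: 1.0})
        _, _, truth = sd.generate_compendium(cfg)
        cn = sd.generate_copy_number(cfg, truth)
        assert truth.gain_enriched == set()
        labels = pd.Series({s: truth.sample_subtype[s] for s in cn.columns})
        genes = truth.module_genes("s1")[:20]
        enr = gain_enrichment_by_subtype(call_gain_loss(cn.loc[genes]), labels)
        frac_small = (enr["p_one_sided"] < 0.05).mean()
        assert frac_small < 0.15

    def test_planted_gains_recovered(self, small_world):
        """odds=8 module gains recovered at >=80% (p<0.01) downstream."""
        from metsubtype.genomics import (
            call_gain_loss,
            gain_enrichment_by_subtype,
            ploidy_correct,
        )

        cfg = dataclasses.replace(small_world["cfg"], samples_per_study=100)
        _, _, truth = sd.generate_compendium(cfg)
        cn = sd.generate_copy_number(cfg, truth)
        calls = call_gain_loss(ploidy_correct(cn))
        labels = pd.Series({s: truth.sample_subtype[s] for s in cn.columns})
        enr = gain_enrichment_by_subtype(calls, labels).set_index(["gene", "subtype"])
        planted = enr.reindex(sorted(truth.gain_enriched))
        assert (planted["p_one_sided"] < 0.01).mean() >= 0.8


class TestMutationGenerator:
    def test_rate_zero_all_zero(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, mutation_baseline_rate=0.0,
                                  mutation_rate_ratio=1.0)
        _, _, truth = sd.generate_compendium(cfg)
        mut = sd.generate_mutations(cfg, truth)
        assert mut.values.sum() == 0

    def test_uniform_rates_show_no_enrichment(self, small_cfg):
        from metsubtype.genomics import mutation_enrichment_by_subtype

        cfg = dataclasses.replace(small_cfg, mutation_rate_ratio=1.0)
        _, _, truth = sd.generate_compendium(cfg)
        mut = sd.generate_mutations(cfg, truth)
        assert truth.mutation_enriched == set()
        labels = pd.Series({s: truth.sample_subtype[s] for s in mut.columns})
        enr = mutation_enrichment_by_subtype(mut, labels)
        assert (enr["p_one_sided"] < 0.01).mean() < 0.05

    def test_planted_five_fold_gene_recovered(self):
        from metsubtype.genomics import mutation_enrichment_by_subtype

        cfg = sd.SynthConfig(n_studies=4, samples_per_study=150, n_genes=500,
                             genes_per_subtype_module=30, seed=21)
        _, _, truth = sd.generate_compendium(cfg)
        mut = sd.generate_mutations(cfg, truth)
        labels = pd.Series({s: truth.sample_subtype[s] for s in mut.columns})
        enr = mutation_enrichment_by_subtype(mut, labels).set_index(["gene", "subtype"])
        planted = enr.reindex(sorted(truth.mutation_enriched))
        assert (planted["p_one_sided"] < 0.01).mean() >= 0.8


class TestDrugGenerator:
    def test_same_seed_identical_table(self, small_cfg):
        _, _, truth1 = sd.generate_compendium(small_cfg)
        ic1, _, _, _ = sd.generate_drug_response(small_cfg, truth1)
        _, _, truth2 = sd.generate_compendium(dataclasses.replace(small_cfg))
        ic2, _, _, _ = sd.generate_drug_response(small_cfg, truth2)
        pd.testing.assert_frame_equal(ic1, ic2)

    def test_null_effect_type_one_rate(self):
        """drug_effect=0: associations at p<0.001 occur within 3x of the
        nominal 0.1% over >=2000 tests."""
        from metsubtype.assoc import drug_response_association

        cfg = sd.SynthConfig(n_genes=50, genes_per_subtype_module=10,
                             n_drugs=500, cell_lines_per_subtype=50,
                             drug_effect=0.0, seed=5)
        _, _, truth = sd.generate_compendium(cfg)
        ic50, _, _, truth = sd.generate_drug_response(cfg, truth)
        assert truth.sensitive == set()
        labels = pd.Series({s: truth.sample_subtype[s] for s in ic50.columns})
        table = drug_response_association(ic50, labels)
        n_tests = len(table)
        assert n_tests >= 2000
        assert (table["p"] < 0.001).sum() <= max(3 * 0.001 * n_tests, 3)

    def test_planted_shift_detected_with_analytic_power(self):
        """1.0 ln-unit shift, sigma=1, 150 vs 450 lines: closed-form
        noncentral-t power at alpha=0.001 is ~1, and every planted drug
        is detected."""
        from scipy.stats import nct, t as tdist

        from metsubtype.assoc import drug_response_association

        cfg = sd.SynthConfig(n_genes=50, genes_per_subtype_module=10,
                             cell_lines_per_subtype=150, drug_effect=1.0,
                             drug_noise_sd=1.0, seed=6)
        _, _, truth = sd.generate_compendium(cfg)
        ic50, _, _, truth = sd.generate_drug_response(cfg, truth)
        ncp = 1.0 / np.sqrt(1.0 / 150 + 1.0 / 450)
        df = 598  # pooled df bound; Welch df is close at equal variances
        crit = tdist.ppf(1 - 0.0005, df)
        power = nct.sf(crit, df, ncp)
        assert power >= 0.9
        labels = pd.Series({s: truth.sample_subtype[s] for s in ic50.columns})
        table = drug_response_association(ic50, labels).set_index(["drug", "subtype"])
        planted = table.reindex(sorted(truth.sensitive))
        detected = ((planted["p"] < 0.001) & (planted["direction"] == "sensitive")).mean()
        assert detected >= power - 0.1


class TestReferenceGenerator:
    def test_full_fidelity_tf_set_equals_module(self, small_world):
        truth = small_world["truth"]
        _, tf_sets, _ = sd.generate_references(small_world["cfg"], truth, fidelity=1.0)
        assert tf_sets["TF_s1"] == sorted(truth.module_genes("s1"))

    def test_zero_fidelity_overlap_not_significant(self, small_world):
        truth = small_world["truth"]
        _, tf_sets, _ = sd.generate_references(small_world["cfg"], truth, fidelity=0.0)
        module = set(truth.module_genes("s1"))
        overlap = len(module & set(tf_sets["TF_s1"]))
        a = overlap
        b = len(module) - a
        c = len(tf_sets["TF_s1"]) - a
        d = len(truth.genes) - a - b - c
        assert hypergeom_tail(a, b, c, d) > 0.01

    def test_partial_fidelity_hypergeometric_significance(self):
        """fidelity=0.7 on a 150-gene module in a 10,000-gene universe:
        overlap p < 1e-6 by direct hypergeometric computation."""
        cfg = sd.SynthConfig(n_genes=10000, genes_per_subtype_module=150, seed=9)
        truth = sd.GroundTruth(
            subtype_labels=[f"s{i+1}" for i in range(4)],
            genes=[f"g{i:05d}" for i in range(10000)],
        )
        rng = cfg.rng("plant")
        chosen = rng.choice(10000, size=600, replace=False)
        for k in range(4):
            for gi in chosen[k * 150:(k + 1) * 150]:
                truth.gene_module[truth.genes[gi]] = f"s{k+1}"
        _, tf_sets, _ = sd.generate_references(cfg, truth, fidelity=0.7)
        module = set(truth.module_genes("s1"))
        tf = set(tf_sets["TF_s1"])
        a = len(module & tf)
        p = hypergeom_tail(a, len(module) - a, len(tf) - a,
                           10000 - len(module | tf))
        assert p < 1e-6
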