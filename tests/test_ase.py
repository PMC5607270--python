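"""RNA variant filtering, ASE calling, meta-analysis and reference-bias
diagnostics."""

import numpy as np
import pandas as pd
import pytest

from crossase.ase import (call_ase, call_ase_meta, call_ase_within_sample,
                          cluster_sites, combined_ase_loci,
                          declare_expressed_genes, define_testable,
                          filter_rna_variants, reassign_count_errors,
                          reference_bias_report, tissue_specific_ase)
from crossase.genotypes import (filter_parental_calls, find_informative_loci,
                                reassign_het_to_hom)
from crossase.simulate import SimConfig, simulate_f1_counts, simulate_parental_vcfs


class TestClusterFilter:
    def test_three_in_thirty_five_removed(self):
        bad = cluster_sites({"1": [100, 110, 130]})
        assert bad == {("1", 100), ("1", 110), ("1", 130)}

    def test_spread_sites_kept(self):
        assert cluster_sites({"1": [100, 110, 140]}) == set()

    def test_window_is_span_inclusive(self):
        # span of 100..134 is exactly 35 bp -> a cluster
        assert len(cluster_sites({"1": [100, 117, 134]})) == 3
        # span 36 bp -> not a cluster
        assert cluster_sites({"1": [100, 117, 135]}) == set()

    def test_chromosomes_do_not_mix(self):
        assert cluster_sites({"1": [100, 110], "2": [120]}) == set()


class TestRnaFilter:
    def test_site_quality_thresholds(self, obs_builder):
        obs = obs_builder([
            {"pos": 100, "QD": 1.9, "ref_count": 30, "alt_count": 30},
            {"pos": 200, "QD": 2.0, "ref_count": 30, "alt_count": 30},
            {"pos": 300, "FS": 30.0, "ref_count": 30, "alt_count": 30},
            {"pos": 400, "FS": 30.5, "ref_count": 30, "alt_count": 30},
        ])
        kept = filter_rna_variants(obs)
        assert kept.pos.tolist() == [200, 300]

    def test_depth_and_gq_boundaries_retained(self, obs_builder):
        obs = obs_builder([
            {"pos": 100, "DP": 10, "ref_count": 5, "alt_count": 5},
            {"pos": 200, "DP": 9, "ref_count": 5, "alt_count": 4},
            {"pos": 300, "DP": 40, "GQ": 30, "ref_count": 20, "alt_count": 20},
            {"pos": 400, "DP": 40, "GQ": 29, "ref_count": 20, "alt_count": 20},
        ])
        kept = filter_rna_variants(obs)
        assert kept.pos.tolist() == [100, 300]

    def test_cluster_removed_cohort_wide(self, obs_builder):
        # the cluster sites appear in different samples; all are removed
        obs = obs_builder([
            {"pos": 100, "sample": "S1", "ref_count": 30, "alt_count": 30},
            {"pos": 110, "sample": "S2", "ref_count": 30, "alt_count": 30},
            {"pos": 130, "sample": "S3", "ref_count": 30, "alt_count": 30},
            {"pos": 500, "sample": "S1", "ref_count": 30, "alt_count": 30},
        ])
        kept = filter_rna_variants(obs)
        assert kept.pos.tolist() == [500]

    def test_missing_annotation_is_conservative(self, obs_builder):
        obs = obs_builder([
            {"pos": 100, "QD": None, "ref_count": 30, "alt_count": 30},
            {"pos": 200, "ref_count": 30, "alt_count": 30},
        ])
        assert filter_rna_variants(obs).pos.tolist() == [200]


class TestErrorReassignment:
    def test_boundary_is_strict(self, obs_builder):
        obs = obs_builder([
            {"pos": 1, "DP": 300, "ref_count": 297, "alt_count": 3},
            {"pos": 2, "DP": 300, "ref_count": 298, "alt_count": 2},
        ])
        out = reassign_count_errors(obs)
        assert out.alt_count.tolist() == [3, 0]
        assert out.ref_count.tolist() == [297, 298]

    def test_balanced_counts_untouched(self, obs_builder):
        obs = obs_builder([{"pos": 1, "DP": 50, "ref_count": 25,
                            "alt_count": 25}])
        out = reassign_count_errors(obs)
        assert out.ref_count.tolist() == [25]
        assert out.usable.all()

    def test_double_zero_flagged_unusable(self, obs_builder):
        obs = obs_builder([{"pos": 1, "DP": 600, "ref_count": 2,
                            "alt_count": 3}])
        out = reassign_count_errors(obs)
        assert out.ref_count.tolist() == [0]
        assert out.alt_count.tolist() == [0]
        assert not out.usable.any()


class TestTestable:
    def informative(self):
        return pd.DataFrame({
            "chrom": ["1", "1"], "pos": [100, 200],
            "ref": ["A", "C"], "alt": ["G", "T"],
            "fayoumi_allele": ["A", "T"], "leghorn_allele": ["G", "C"],
            "gene_ids": ["g1", "g2"]})

    def test_intersection_and_line_labels(self, obs_builder):
        obs = obs_builder([
            {"pos": 100, "ref_count": 30, "alt_count": 10},
            {"pos": 200, "ref_count": 30, "alt_count": 10},
            {"pos": 999, "ref_count": 30, "alt_count": 10},
        ])
        out = define_testable(obs, self.informative())
        assert out.pos.tolist() == [100, 200]
        # at pos 200 the Fayoumi allele is the ALT allele
        assert out.fayoumi_count.tolist() == [30, 10]
        assert out.leghorn_count.tolist() == [10, 30]

    def test_informative_locus_without_observation_absent(self, obs_builder):
        obs = obs_builder([{"pos": 100, "ref_count": 5, "alt_count": 5}])
        assert define_testable(obs, self.informative()).pos.tolist() == [100]


class TestWithinSampleAse:
    def make_testable(self, pairs):
        rows = []
        for i, (fay, leg) in enumerate(pairs):
            ref, alt = fay, leg  # Fayoumi carries the reference allele
            rows.append(dict(sample="S1", cross="FL", tissue="brain",
                             chrom="1", pos=100 + i * 50, gene_ids=f"g{i}",
                             ref_count=ref, alt_count=alt, DP=ref + alt,
                             GQ=90, QD=20.0, FS=1.0,
                             fayoumi_count=fay, leghorn_count=leg))
        return pd.DataFrame(rows)

    def test_monoallelic_is_ase_without_test(self):
        out = call_ase_within_sample(self.make_testable([(0, 57)]))
        row = out.iloc[0]
        assert row.monoallelic and row.is_ase
        assert row.allelic_ratio == 1.0
        assert row.preferred_allele == "leghorn"
        assert np.isnan(row.p_value)

    def test_balanced_locus_not_ase(self):
        out = call_ase_within_sample(self.make_testable([(26, 24)] * 5))
        assert not out.is_ase.any()
        assert out.p_value.iloc[0] == pytest.approx(0.8877, abs=2e-3)

    def test_tie_has_no_preferred_allele(self):
        out = call_ase_within_sample(self.make_testable([(20, 20)]))
        assert out.preferred_allele.tolist() == ["tied"]
        assert not out.is_ase.any()

    def test_bh_family_is_biallelic_only(self):
        # one monoallelic + strongly imbalanced biallelic loci
        out = call_ase_within_sample(
            self.make_testable([(0, 60), (55, 5), (48, 52)]))
        bi = out.loc[~out.monoallelic]
        assert bi.p_adjusted.notna().all()
        assert out.loc[out.monoallelic, "p_adjusted"].isna().all()

    def test_empty_input(self):
        out = call_ase_within_sample(self.make_testable([]))
        assert len(out) == 0


class TestMetaAse:
    def make_calls(self, rows):
        records = []
        for r in rows:
            rec = dict(sample="S1", cross="FL", tissue="brain", chrom="1",
                       pos=100, gene_ids="g1", preferred_allele="fayoumi",
                       p_value=0.05, monoallelic=False, is_ase=False)
            rec.update(r)
            records.append(rec)
        return pd.DataFrame(records)

    def test_two_samples_same_allele_combined(self):
        calls = self.make_calls([{"sample": "S1"}, {"sample": "S2"}])
        meta = call_ase_meta(calls)
        assert len(meta) == 1
        row = meta.iloc[0]
        assert row.dof == 4
        assert row.combined_p == pytest.approx(0.0174, abs=2e-4)
        assert row.sample_ids == "S1,S2"

    def test_opposite_alleles_do_not_combine(self):
        calls = self.make_calls([
            {"sample": "S1", "preferred_allele": "fayoumi"},
            {"sample": "S2", "preferred_allele": "leghorn"}])
        assert len(call_ase_meta(calls)) == 0

    def test_all_monoallelic_group_declared_ase(self):
        calls = self.make_calls([
            {"sample": "S1", "monoallelic": True, "p_value": np.nan},
            {"sample": "S2", "monoallelic": True, "p_value": np.nan}])
        meta = call_ase_meta(calls)
        assert meta.is_ase.tolist() == [True]
        assert np.isnan(meta.combined_p.iloc[0])

    def test_mixed_monoallelic_contributes_support_only(self):
        calls = self.make_calls([
            {"sample": "S1", "monoallelic": True, "p_value": np.nan},
            {"sample": "S2", "p_value": 0.05}])
        meta = call_ase_meta(calls)
        assert meta.dof.tolist() == [2]
        assert meta.combined_p.iloc[0] == pytest.approx(0.05, rel=1e-9)

    def test_combined_set_deduplicates(self):
        calls = self.make_calls([
            {"sample": "S1", "p_value": 1e-6, "p_adjusted": 1e-5,
             "is_ase": True},
            {"sample": "S2", "p_value": 1e-6, "p_adjusted": 1e-5,
             "is_ase": True}])
        meta = call_ase_meta(calls)
        combined = combined_ase_loci(calls, meta)
        assert len(combined) == 1


class TestExpressedGenes:
    def test_per_snp_rule(self, obs_builder):
        obs = obs_builder([
            {"pos": 100, "sample": "S1", "gene_ids": "g1",
             "ref_count": 5, "alt_count": 5},
            {"pos": 100, "sample": "S2", "gene_ids": "g1",
             "ref_count": 5, "alt_count": 5},
            {"pos": 200, "sample": "S1", "gene_ids": "g2",
             "ref_count": 5, "alt_count": 5},
            # g3 has two SNPs but each in a single distinct sample
            {"pos": 300, "sample": "S1", "gene_ids": "g3",
             "ref_count": 5, "alt_count": 5},
            {"pos": 350, "sample": "S2", "gene_ids": "g3",
             "ref_count": 5, "alt_count": 5},
        ])
        expressed = declare_expressed_genes(obs)
        assert expressed["brain"] == {"g1"}


def test_tissue_partition():
    a = {f"g{i}" for i in range(10)}
    b = {f"g{i}" for i in range(5, 13)}
    shared, a_only, b_only = tissue_specific_ase(a, b)
    assert (len(shared), len(a_only), len(b_only)) == (5, 5, 3)
    assert tissue_specific_ase(a, a)[1] == set()
    shared, a_only, b_only = tissue_specific_ase({"x"}, {"y"})
    assert not shared and a_only == {"x"} and b_only == {"y"}


class TestReferenceBias:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos",
                                           "ref_count", "alt_count"])

    def test_count_averaging_arithmetic(self):
        orig = self.table([("S1", "1", 100, 60, 40)])
        mask = self.table([("S1", "1", 100, 48, 52)])
        report = reference_bias_report(orig, mask)
        assert report["mean_ref_ratio_averaged"] == pytest.approx(0.54)

    def test_identical_tables_identity(self):
        t = self.table([("S1", "1", 100, 30, 20), ("S1", "1", 200, 10, 40)])
        report = reference_bias_report(t, t.copy())
        assert (report["mean_ref_ratio_averaged"]
                == pytest.approx(report["mean_ref_ratio_original"]))

    def test_unmatched_loci_counted(self):
        orig = self.table([("S1", "1", 100, 60, 40), ("S1", "1", 300, 5, 5)])
        mask = self.table([("S1", "1", 100, 48, 52)])
        report = reference_bias_report(orig, mask)
        assert report["n_shared"] == 1
        assert report["n_unmatched"] == 1

    def test_simulated_bias_shifts_original_ratio(self, cis_sim):
        cfg, sim, obs = cis_sim
        keys = ["sample", "chrom", "pos"]
        orig = obs[keys].assign(ref_count=obs.ref_count_original,
                                alt_count=obs.alt_count_original)
        mask = obs[keys + ["ref_count", "alt_count"]]
        report = reference_bias_report(orig, mask)
        assert (report["mean_ref_ratio_original"]
                > report["mean_ref_ratio_masked"])


class TestFdrOnMixedSignal:
    def test_fdp_controlled_with_true_cis_effects(self):
        cfg = SimConfig(seed=31, n_loci=2000, n_genes=400, tissues=("brain",),
                        frac_cis_ase=0.2, cis_effect=0.7, depth_mean=100.0,
                        error_rate=0.0, contaminant_rate=0.0,
                        reference_bias=0.0)
        sim = simulate_parental_vcfs(cfg)
        obs = simulate_f1_counts(cfg, sim.truth)
        informative = find_informative_loci(
            reassign_het_to_hom(filter_parental_calls(sim.fayoumi)),
            reassign_het_to_hom(filter_parental_calls(sim.leghorn)))
        testable = define_testable(
            reassign_count_errors(filter_rna_variants(obs)), informative)
        calls = call_ase(testable)
        truth_class = sim.truth.set_index(["chrom", "pos"]).class_
        called = calls.loc[calls.is_ase]
        is_false = [truth_class.loc[(c, p)] == "neutral"
                    for c, p in zip(called.chrom, called.pos)]
        fdp = np.mean(is_false)
        n = len(called)
        assert n > 100
        assert fdp <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / n)

    def test_preferred_allele_matches_simulated_direction(self):
        cfg = SimConfig(seed=33, n_loci=1000, n_genes=200, tissues=("brain",),
                        frac_cis_ase=0.3, cis_effect=0.8, depth_mean=100.0,
                        error_rate=0.0, contaminant_rate=0.0,
                        reference_bias=0.0)
        sim = simulate_parental_vcfs(cfg)
        obs = simulate_f1_counts(cfg, sim.truth)
        informative = find_informative_loci(
            reassign_het_to_hom(filter_parental_calls(sim.fayoumi)),
            reassign_het_to_hom(filter_parental_calls(sim.leghorn)))
        testable = define_testable(
            reassign_count_errors(filter_rna_variants(obs)), informative)
        calls = call_ase(testable)
        truth = sim.truth.set_index(["chrom", "pos"])
        cis_calls = calls.loc[calls.is_ase & calls.preferred_allele.isin(
            ["fayoumi", "leghorn"])]
        agree = [
            truth.loc[(c, p), "preferred_line"] == pref
            for c, p, pref in zip(cis_calls.chrom, cis_calls.pos,
                                  cis_calls.preferred_allele)
            if truth.loc[(c, p), "class_"] == "cis_ase"]
        assert np.mean(agree) > 0.99
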