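"""Genotype QC, consequence classes, VCF round-trips and gene restriction."""

import numpy as np
import pandas as pd
import pytest

from rvburden.simulate import GeneSpec, SimulationConfig, simulate_study, write_study
from rvburden.variant_io import (GenotypeCall, QCReason, QCThresholds,
                                 VariantClass, apply_genotype_qc, apply_qc,
                                 classify_consequence, read_vcf,
                                 restrict_to_genes, write_vcf)

THR = QCThresholds()


class TestGenotypeQC:
    @pytest.mark.parametrize("call,expected", [
        # het with allele balance below range fails on AB
        (GenotypeCall(1, ab=0.19, gq=99, dp=30), ("fail", QCReason.AB)),
        # inclusive boundaries: AB 0.2, GQ 20, DP 10 all pass
        (GenotypeCall(1, ab=0.20, gq=20, dp=10), ("pass", None)),
        (GenotypeCall(1, ab=0.80, gq=20, dp=10), ("pass", None)),
        # hom-alt: AB not consulted, GQ 19 fails
        (GenotypeCall(2, ab=None, gq=19, dp=30), ("fail", QCReason.GQ)),
        (GenotypeCall(2, ab=None, gq=20, dp=9), ("fail", QCReason.DP)),
        (GenotypeCall(0, ab=0.0, gq=99, dp=30), ("pass", None)),
        # missing required field is an explicit failure, never a silent pass
        (GenotypeCall(1, ab=None, gq=99, dp=30), ("fail", QCReason.MISSING_FIELD)),
        (GenotypeCall(2, ab=None, gq=None, dp=30), ("fail", QCReason.MISSING_FIELD)),
        # already-missing genotypes pass through
        (GenotypeCall(-1), ("pass", None)),
    ])
    def test_judgements(self, call, expected):
        assert apply_genotype_qc(call, THR) == expected

    def test_haploid_depth_threshold(self):
        call = GenotypeCall(1, ab=None, gq=30, dp=7, is_haploid=True)
        assert apply_genotype_qc(call, THR) == ("pass", None)
        call = GenotypeCall(1, ab=None, gq=30, dp=4, is_haploid=True)
        assert apply_genotype_qc(call, THR) == ("fail", QCReason.DP)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QCThresholds(ab_het_range=(0.8, 0.2))
        with pytest.raises(ValueError):
            QCThresholds(gq_min=-1)


class TestClassifyConsequence:
    @pytest.mark.parametrize("term,expected", [
        ("stop_gained", VariantClass.LOF),
        ("frameshift_variant", VariantClass.LOF),
        ("splice_acceptor_variant", VariantClass.LOF),
        ("splice_donor_variant", VariantClass.LOF),
        ("start_lost", VariantClass.LOF),
        ("missense_variant", VariantClass.MISSENSE),
        ("synonymous_variant", VariantClass.SYNONYMOUS),
        ("intron_variant", VariantClass.OTHER),
        ("stop_lost", VariantClass.OTHER),
    ])
    def test_terms(self, term, expected):
        assert classify_consequence(term) == expected


@pytest.fixture(scope="module")
def clean_config():
    # no QC injection, no tranche failures: every genotype survives
    return SimulationConfig(
        n_cases=40,
        genes=[GeneSpec(f"G{i}", 900, 4) for i in range(4)],
        qc_fail_fraction=0.0, tranche_fail_fraction=0.0,
        maf_range=(1e-3, 2e-2), seed=11)


@pytest.fixture(scope="module")
def clean_study(clean_config):
    return simulate_study(clean_config)


class TestVcfRoundTrip:
    def test_write_read_reproduces_fields(self, clean_study, tmp_path):
        paths = write_study(clean_study, tmp_path)
        from rvburden.variant_io import read_annotation

        ann = read_annotation(paths["annotation"])
        table = read_vcf(paths["vcf"], THR, ann)
        src = clean_study.cohort
        assert table.samples == src.samples
        np.testing.assert_array_equal(table.genotypes, src.genotypes)
        np.testing.assert_allclose(table.ab, src.ab, atol=5e-4)
        np.testing.assert_array_equal(table.gq, src.gq)
        np.testing.assert_array_equal(table.dp, src.dp)
        pd.testing.assert_frame_equal(
            table.variants[["chrom", "pos", "ref", "alt", "gene", "consequence"]],
            src.variants[["chrom", "pos", "ref", "alt", "gene", "consequence"]])
        assert len(table.audit) == 0

    def test_hom_alt_contributes_two_alleles(self, clean_study):
        table = apply_qc(clean_study.cohort)
        i, j = 0, 0
        table.genotypes[i, j] = 2
        before = table.allele_counts()[i]
        table.genotypes[i, j] = 0
        assert before == table.allele_counts()[i] + 2

    def test_empty_vcf_body(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n")
        table = read_vcf(path, THR)
        assert table.n_variants == 0
        assert table.n_individuals == 2


class TestQCOnRealisticVcf:
    def test_audit_matches_injected_failures(self, tmp_path):
        cfg = SimulationConfig(
            n_cases=60, genes=[GeneSpec(f"G{i}", 900, 4) for i in range(5)],
            qc_fail_fraction=0.02, tranche_fail_fraction=0.0,
            maf_range=(1e-3, 2e-2), seed=23)
        study = simulate_study(cfg)
        paths = write_study(study, tmp_path)
        from rvburden.variant_io import read_annotation

        table = read_vcf(paths["vcf"], THR, read_annotation(paths["annotation"]))
        expected = {(f["chrom"], f["pos"], f["sample"], f["reason"])
                    for f in study.truth.qc_failures}
        observed = {(r.chrom, r.pos, r.sample, r.reason)
                    for r in table.audit.itertuples(index=False)}
        assert observed == expected

    def test_tranche_failed_sites_dropped(self, tmp_path):
        cfg = SimulationConfig(
            n_cases=30, genes=[GeneSpec(f"G{i}", 900, 5) for i in range(8)],
            qc_fail_fraction=0.0, tranche_fail_fraction=0.2,
            maf_range=(1e-3, 2e-2), seed=29)
        study = simulate_study(cfg)
        paths = write_study(study, tmp_path)
        table = read_vcf(paths["vcf"], THR)
        kept_keys = {f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
                     for r in table.variants.itertuples(index=False)}
        assert set(study.truth.tranche_failed).isdisjoint(kept_keys)
        assert table.filter_log["tranche_dropped_sites"] == len(
            study.truth.tranche_failed)

    def test_qc_idempotent_and_conservative(self, small_study):
        once = apply_qc(small_study.cohort)
        twice = apply_qc(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        raw_counts = np.where(small_study.cohort.genotypes > 0,
                              small_study.cohort.genotypes, 0).sum(axis=1)
        raw = {small_study.cohort.variant_key(i): int(raw_counts[i])
               for i in range(small_study.cohort.n_variants)}
        qc_counts = once.allele_counts()
        for i in range(once.n_variants):
            assert qc_counts[i] <= raw[once.variant_key(i)]


class TestGeneRestriction:
    def test_exact_case_sensitive_match(self, clean_study):
        table = apply_qc(clean_study.cohort)
        kept = restrict_to_genes(table, ["G0", "G1"])
        assert set(kept.variants["gene"]) <= {"G0", "G1"}
        lower = restrict_to_genes(table, ["g0"])  # case mismatch drops all
        assert lower.n_variants == 0

    def test_empty_intersection_warns(self, clean_study):
        table = apply_qc(clean_study.cohort)
        with pytest.warns(UserWarning):
            out = restrict_to_genes(table, ["NOPE"])
        assert out.n_variants == 0
        assert out.filter_log["gene_restriction_dropped"] == table.n_variants

    def test_empty_gene_list_rejected(self, clean_study):
        with pytest.raises(ValueError):
            restrict_to_genes(apply_qc(clean_study.cohort), [])


class TestMultiallelicDecomposition:
    def test_split_into_biallelic_rows(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text("\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2",
            "chr1\t100\t.\tA\tC,G\t.\tPASS\t.\tGT:AB:GQ:DP\t"
            "0/1:0.5:99:30\t1/2:0.5:99:30",
        ]) + "\n")
        table = read_vcf(path, THR)
        assert table.n_variants == 2
        assert list(table.variants["alt"]) == ["C", "G"]
        # S1 carries one C; S2 carries one C and one G
        np.testing.assert_array_equal(table.genotypes[:, 0], [1, 0])
        np.testing.assert_array_equal(table.genotypes[:, 1], [1, 1])
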