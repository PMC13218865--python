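"""Case-cohort VCF input, genotype-level quality control, and annotation.

The QC model follows exome-pipeline convention: per-genotype filters on
allele balance (heterozygous calls only), genotype quality and depth, with
failing genotypes set to missing rather than whole sites removed, plus a
site-level VQSR-tranche filter.  Every genotype set to missing is recorded
in an audit log with its failure reason.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "GenotypeCall",
    "QCReason",
    "VariantClass",
    "CohortVariantTable",
    "apply_genotype_qc",
    "classify_consequence",
    "read_vcf",
    "write_vcf",
    "restrict_to_genes",
    "read_annotation",
    "read_gene_list",
]

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for no-call
_INT_MISSING = -2147483648  # htslib integer missing sentinel


@dataclass(frozen=True)
class QCThresholds:
    """Genotype-level QC thresholds.

    Defaults mirror a standard short-read germline pipeline: heterozygous
    allele balance within [0.2, 0.8], genotype quality >= 20, depth >= 10
    (>= 5 for haploid calls), and sites restricted to the passing VQSR
    tranche.  All boundaries are inclusive.
    """

    ab_het_range: tuple[float, float] = (0.2, 0.8)
    gq_min: int = 20
    dp_min_diploid: int = 10
    dp_min_haploid: int = 5
    tranche_label: str = "PASS"

    def __post_init__(self) -> None:
        lo, hi = self.ab_het_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("ab_het_range must satisfy 0 <= low < high <= 1")
        if self.gq_min < 0 or self.dp_min_diploid < 0 or self.dp_min_haploid < 0:
            raise ValueError("GQ/DP thresholds must be non-negative")


class QCReason(str, enum.Enum):
    AB = "AB"
    GQ = "GQ"
    DP = "DP"
    TRANCHE = "TRANCHE"
    MISSING_FIELD = "MISSING_FIELD"


@dataclass(frozen=True)
class GenotypeCall:
    """One individual's call at one site: allele count 0/1/2 (-1 = missing)."""

    allele_count: int
    ab: float | None = None
    gq: int | None = None
    dp: int | None = None
    is_haploid: bool = False

    @property
    def is_het(self) -> bool:
        return self.allele_count == 1 and not self.is_haploid


def _absent(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def apply_genotype_qc(
    genotype: GenotypeCall, thresholds: QCThresholds
) -> tuple[str, QCReason | None]:
    """Judge one genotype: ``("pass", None)`` or ``("fail", reason)``.

    A missing required field is a failure (MISSING_FIELD), never a silent
    pass.  Allele balance applies to heterozygous diploid calls only.
    Already-missing genotypes pass through untouched (QC is idempotent).
    """
    if genotype.allele_count == MISSING:
        return "pass", None
    if _absent(genotype.gq) or _absent(genotype.dp):
        return "fail", QCReason.MISSING_FIELD
    if genotype.is_het:
        if _absent(genotype.ab):
            return "fail", QCReason.MISSING_FIELD
        lo, hi = thresholds.ab_het_range
        if not lo <= genotype.ab <= hi:
            return "fail", QCReason.AB
    if genotype.gq < thresholds.gq_min:
        return "fail", QCReason.GQ
    dp_min = thresholds.dp_min_haploid if genotype.is_haploid else thresholds.dp_min_diploid
    if genotype.dp < dp_min:
        return "fail", QCReason.DP
    return "pass", None


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    LOF = "lof"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def from_term(cls, term: str) -> "VariantClass":
        return classify_consequence(term)


_LOF_TERMS = frozenset({
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
})


def classify_consequence(term: str) -> VariantClass:
    """Map a Sequence-Ontology consequence term to a burden class.

    Loss-of-function covers stop-gained, frameshift, splice-site
    (donor/acceptor) and start-lost; everything that is neither LoF,
    missense nor synonymous is ``other``.
    """
    if term in _LOF_TERMS:
        return VariantClass.LOF
    if term == "missense_variant":
        return VariantClass.MISSENSE
    if term == "synonymous_variant":
        return VariantClass.SYNONYMOUS
    return VariantClass.OTHER


_VARIANT_COLS = ["chrom", "pos", "ref", "alt", "gene", "consequence"]


@dataclass
class CohortVariantTable:
    """Per-variant, per-individual genotypes for the case cohort.

    ``genotypes`` holds alt-allele counts (0/1/2, -1 missing) with matching
    ``ab``/``gq``/``dp`` matrices, one row per variant in ``variants`` and
    one column per sample.  ``audit`` records every genotype set to missing
    by QC, and ``filter_log`` accumulates the workflow's site/variant
    filtering counts.
    """

    samples: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    ab: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "sample", "reason"]))
    filter_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_var = len(self.variants)
        for name in ("genotypes", "ab", "gq", "dp"):
            arr = getattr(self, name)
            if arr.shape != (n_var, len(self.samples)):
                raise ValueError(f"{name} shape {arr.shape} != "
                                 f"({n_var}, {len(self.samples)})")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_counts(self) -> np.ndarray:
        """Alt-allele count per variant (missing genotypes contribute 0)."""
        gt = self.genotypes
        return np.where(gt > 0, gt, 0).sum(axis=1)

    def subset(self, indices: Sequence[int]) -> "CohortVariantTable":
        idx = list(indices)
        return CohortVariantTable(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True).copy(),
            genotypes=self.genotypes[idx].copy(),
            ab=self.ab[idx].copy(),
            gq=self.gq[idx].copy(),
            dp=self.dp[idx].copy(),
            audit=self.audit.copy(),
            filter_log=dict(self.filter_log),
        )

    def variant_key(self, i: int) -> tuple[str, int, str, str]:
        row = self.variants.iloc[i]
        return (row["chrom"], int(row["pos"]), row["ref"], row["alt"])


def _qc_matrix(table: CohortVariantTable, thresholds: QCThresholds) -> None:
    """Apply genotype QC in place, filling the audit log."""
    records = []
    for i in range(table.n_variants):
        chrom, pos, ref, alt = table.variant_key(i)
        for j in range(table.n_individuals):
            call = GenotypeCall(
                allele_count=int(table.genotypes[i, j]),
                ab=float(table.ab[i, j]) if not np.isnan(table.ab[i, j]) else None,
                gq=None if table.gq[i, j] == _INT_MISSING else int(table.gq[i, j]),
                dp=None if table.dp[i, j] == _INT_MISSING else int(table.dp[i, j]),
            )
            status, reason = apply_genotype_qc(call, thresholds)
            if status == "fail":
                table.genotypes[i, j] = MISSING
                records.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                                "sample": table.samples[j], "reason": reason.value})
    if records:
        table.audit = pd.concat(
            [table.audit, pd.DataFrame(records)], ignore_index=True)


def apply_qc(
    table: CohortVariantTable, thresholds: QCThresholds = QCThresholds()
) -> CohortVariantTable:
    """Site tranche filter plus genotype QC on an in-memory table.

    Equivalent to what :func:`read_vcf` applies while parsing; used when the
    cohort never leaves memory (simulation workflows).
    """
    if "filter" in table.variants.columns:
        keep = [i for i, f in enumerate(table.variants["filter"])
                if f == thresholds.tranche_label]
    else:
        keep = list(range(table.n_variants))
    out = table.subset(keep)
    out.filter_log["tranche_dropped_sites"] = table.n_variants - len(keep)
    out.filter_log["variants_read"] = table.n_variants
    _qc_matrix(out, thresholds)
    out.filter_log["genotypes_failed_qc"] = len(out.audit)
    return out


def read_annotation(path) -> pd.DataFrame:
    """Read the consequence annotation TSV (CHROM,POS,REF,ALT,GENE,CONSEQUENCE[,CDS_POS])."""
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"CHROM": str, "REF": str, "ALT": str, "GENE": str})


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_vcf(
    path,
    thresholds: QCThresholds = QCThresholds(),
    annotation: pd.DataFrame | None = None,
) -> CohortVariantTable:
    """Read a multi-sample VCF, QC every genotype, and attach annotations.

    Multi-allelic records are decomposed into one biallelic row per ALT.
    Sites whose FILTER string differs from ``thresholds.tranche_label`` are
    dropped (tranche membership is a site property).  Gene/consequence come
    from the annotation table keyed on (CHROM,POS,REF,ALT); unannotated
    variants get empty strings.
    """
    from cyvcf2 import VCF

    ann_index: dict[tuple, tuple[str, str, float]] = {}
    if annotation is not None:
        for row in annotation.itertuples(index=False):
            key = (str(row.CHROM), int(row.POS), row.REF, row.ALT)
            cds = float(getattr(row, "CDS_POS", math.nan))
            ann_index[key] = (row.GENE, row.CONSEQUENCE, cds)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    var_rows: list[dict] = []
    gt_rows, ab_rows, gq_rows, dp_rows = [], [], [], []
    n_tranche_dropped = 0

    for line_no, v in enumerate(vcf, start=1):
        filt = v.FILTER  # None means PASS in cyvcf2
        site_pass = (filt is None and thresholds.tranche_label == "PASS") or (
            filt == thresholds.tranche_label)
        if not site_pass:
            n_tranche_dropped += len(v.ALT)
            continue
        if not v.ALT:
            raise ValueError(f"malformed VCF record (no ALT) at data line {line_no}")
        try:
            ab = v.format("AB")
            gq = v.format("GQ")
            dp = v.format("DP")
        except Exception as exc:  # pragma: no cover - format layout errors
            raise ValueError(f"unknown FORMAT layout at data line {line_no}: {exc}")
        ab = (np.full(len(samples), np.nan, dtype=np.float32)
              if ab is None else ab[:, 0].astype(np.float32))
        gq = (np.full(len(samples), _INT_MISSING, dtype=np.int64)
              if gq is None else gq[:, 0].astype(np.int64))
        dp = (np.full(len(samples), _INT_MISSING, dtype=np.int64)
              if dp is None else dp[:, 0].astype(np.int64))
        genos = v.genotypes  # [[a1, a2, phased], ...]
        for alt_i, alt in enumerate(v.ALT, start=1):
            key = (v.CHROM, v.POS, v.REF, alt)
            gene, csq, cds = ann_index.get(key, ("", "", math.nan))
            var_rows.append({"chrom": v.CHROM, "pos": v.POS, "ref": v.REF,
                             "alt": alt, "gene": gene, "consequence": csq,
                             "cds_pos": cds})
            counts = np.empty(len(samples), dtype=np.int8)
            for j, g in enumerate(genos):
                alleles = g[:-1]
                if any(a < 0 for a in alleles):
                    counts[j] = MISSING
                else:
                    counts[j] = sum(1 for a in alleles if a == alt_i)
            gt_rows.append(counts)
            ab_rows.append(ab)
            gq_rows.append(gq)
            dp_rows.append(dp)

    n_var = len(var_rows)
    table = CohortVariantTable(
        samples=samples,
        variants=pd.DataFrame(var_rows, columns=_VARIANT_COLS + ["cds_pos"]),
        genotypes=(np.vstack(gt_rows) if n_var else
                   np.empty((0, len(samples)), dtype=np.int8)),
        ab=(np.vstack(ab_rows) if n_var else
            np.empty((0, len(samples)), dtype=np.float32)),
        gq=(np.vstack(gq_rows) if n_var else
            np.empty((0, len(samples)), dtype=np.int64)),
        dp=(np.vstack(dp_rows) if n_var else
            np.empty((0, len(samples)), dtype=np.int64)),
    )
    table.filter_log["tranche_dropped_sites"] = n_tranche_dropped
    table.filter_log["variants_read"] = n_var
    _qc_matrix(table, thresholds)
    table.filter_log["genotypes_failed_qc"] = len(table.audit)
    return table


def write_vcf(table: CohortVariantTable, path) -> None:
    """Write the cohort as VCF v4.2 with GT:AB:GQ:DP, deterministically.

    Fixed float formatting (AB to 3 decimals) makes output byte-identical
    for identical tables.
    """
    chroms = list(dict.fromkeys(table.variants["chrom"]))
    lines = ["##fileformat=VCFv4.2", "##source=rvburden"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##FILTER=<ID=VQSRTrancheLow,Description="Below first VQSR tranche">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AB,Number=1,Type=Float,Description="Allele balance (alt/total depth)">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    filters = table.variants.get("filter")
    for i in range(table.n_variants):
        row = table.variants.iloc[i]
        filt = filters.iloc[i] if filters is not None else "PASS"
        fields = [row["chrom"], str(int(row["pos"])), ".", row["ref"], row["alt"],
                  ".", filt, ".", "GT:AB:GQ:DP"]
        for j in range(table.n_individuals):
            ab = table.ab[i, j]
            ab_s = "." if np.isnan(ab) else f"{ab:.3f}"
            gq = table.gq[i, j]
            gq_s = "." if gq == _INT_MISSING else str(int(gq))
            dp = table.dp[i, j]
            dp_s = "." if dp == _INT_MISSING else str(int(dp))
            fields.append(f"{gt_str[int(table.genotypes[i, j])]}:{ab_s}:{gq_s}:{dp_s}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def restrict_to_genes(
    table: CohortVariantTable, gene_list: Iterable[str]
) -> CohortVariantTable:
    """Keep only variants whose gene symbol is in the curated list.

    Matching is exact and case-sensitive; alias resolution belongs upstream
    in the annotation table.  The number of dropped records is logged.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene_list must be nonempty")
    keep = [i for i, g in enumerate(table.variants["gene"]) if g in genes]
    dropped = table.n_variants - len(keep)
    out = table.subset(keep)
    out.filter_log["gene_restriction_dropped"] = dropped
    out.filter_log["gene_restriction_kept"] = len(keep)
    if not keep:
        warnings.warn("no variants fall in the curated gene list")
    logger.info("gene restriction: kept %d, dropped %d", len(keep), dropped)
    return out
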