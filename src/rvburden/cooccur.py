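"""Per-individual co-occurrence of qualifying variants within a gene.

With unphased short-read genotypes, two variants carried by one individual
in the same gene are reported as co-occurring (possible cis haplotype or
compound heterozygosity; phase is unknowable here).  A homozygous alt call
counts as one distinct carried variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .variant_io import CohortVariantTable, VariantClass

__all__ = ["CarriedVariant", "CarrierReport", "find_multicarriers",
           "syn_mis_sharing", "carriers_to_frame"]


@dataclass(frozen=True)
class CarriedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    variant_class: VariantClass
    genotype: int  # 1 het, 2 hom-alt


@dataclass
class CarrierReport:
    individual: str
    gene: str
    variants: list[CarriedVariant] = field(default_factory=list)

    @property
    def multi_carrier(self) -> bool:
        return len(self.variants) >= 2


def _carried(table: CohortVariantTable, classes: set[VariantClass] | None):
    """Yield (sample, gene, CarriedVariant) for every carried qualifying variant."""
    for i in range(table.n_variants):
        var = table.variants.iloc[i]
        vclass = VariantClass.from_term(var["consequence"])
        if classes is not None and vclass not in classes:
            continue
        row = table.genotypes[i]
        for j in row.nonzero()[0]:
            gt = int(row[j])
            if gt <= 0:  # missing (-1) or hom-ref
                continue
            yield table.samples[j], var["gene"], CarriedVariant(
                chrom=var["chrom"], pos=int(var["pos"]), ref=var["ref"],
                alt=var["alt"], consequence=var["consequence"],
                variant_class=vclass, genotype=gt)


def find_multicarriers(
    table: CohortVariantTable,
    gene_list: Iterable[str] | None = None,
    min_variants: int = 2,
    classes: Iterable[VariantClass] = (VariantClass.MISSENSE, VariantClass.LOF),
) -> list[CarrierReport]:
    """Individuals carrying >= ``min_variants`` distinct qualifying variants in one gene.

    Output is deterministically ordered by (gene, individual).
    """
    genes = set(gene_list) if gene_list is not None else None
    class_set = set(classes) if classes is not None else None
    by_carrier: dict[tuple[str, str], CarrierReport] = {}
    for sample, gene, cv in _carried(table, class_set):
        if genes is not None and gene not in genes:
            continue
        rep = by_carrier.setdefault((gene, sample),
                                    CarrierReport(individual=sample, gene=gene))
        rep.variants.append(cv)
    out = [rep for rep in by_carrier.values() if len(rep.variants) >= min_variants]
    for rep in out:
        rep.variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    out.sort(key=lambda r: (r.gene, r.individual))
    return out


def syn_mis_sharing(
    table: CohortVariantTable,
    gene_list: Iterable[str] | None = None,
) -> list[tuple[str, str, CarriedVariant, CarriedVariant]]:
    """All (individual, gene, synonymous variant, missense variant) pairings.

    An empty list reproduces the negative finding that synonymous variants
    do not travel with the missense burden in the same individuals.
    """
    genes = set(gene_list) if gene_list is not None else None
    carried: dict[tuple[str, str], dict[VariantClass, list[CarriedVariant]]] = {}
    for sample, gene, cv in _carried(
            table, {VariantClass.SYNONYMOUS, VariantClass.MISSENSE}):
        if genes is not None and gene not in genes:
            continue
        carried.setdefault((gene, sample), {}).setdefault(cv.variant_class, []).append(cv)
    pairs = []
    for (gene, sample), by_class in sorted(carried.items()):
        for syn in sorted(by_class.get(VariantClass.SYNONYMOUS, []),
                          key=lambda v: v.pos):
            for mis in sorted(by_class.get(VariantClass.MISSENSE, []),
                              key=lambda v: v.pos):
                pairs.append((sample, gene, syn, mis))
    return pairs


def carriers_to_frame(reports: Sequence[CarrierReport]) -> pd.DataFrame:
    """Flatten carrier reports: one row per carried variant."""
    rows = []
    for rep in reports:
        for cv in rep.variants:
            rows.append({
                "individual": rep.individual, "gene": rep.gene,
                "chrom": cv.chrom, "pos": cv.pos, "ref": cv.ref, "alt": cv.alt,
                "class": cv.variant_class.value, "genotype": cv.genotype,
                "multi_carrier": rep.multi_carrier,
            })
    return pd.DataFrame(rows, columns=["individual", "gene", "chrom", "pos",
                                       "ref", "alt", "class", "genotype",
                                       "multi_carrier"])
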