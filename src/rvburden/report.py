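"""Pipeline orchestration and publication-style reporting.

Glues the stages together (QC -> gene restriction -> rarity filter ->
burden scan) while keeping an audit trail of every filtering decision, and
renders the burden / co-occurrence / constraint / splice outputs as TSVs
stamped with the run's configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .burden import (GeneBurdenResult, PrioritisationCriteria, burden_scan,
                     results_to_frame)
from .cooccur import carriers_to_frame, find_multicarriers, syn_mis_sharing
from .panels import PanelTable
from .variant_io import (CohortVariantTable, QCThresholds, VariantClass,
                         apply_qc, restrict_to_genes)

__all__ = ["PipelineResult", "run_burden_pipeline", "config_hash",
           "write_tsv", "write_manifest"]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    results: list[GeneBurdenResult]
    cohort: CohortVariantTable  # post-QC, gene-restricted, rarity-filtered
    multicarriers: list
    syn_mis_pairs: list
    filter_counts: dict = field(default_factory=dict)


def run_burden_pipeline(
    cohort_raw: CohortVariantTable,
    panels: PanelTable,
    gene_list: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
    criteria: PrioritisationCriteria = PrioritisationCriteria(),
    populations: Sequence[str] = ("NFE", "Global", "CSVS"),
    primary_panel: str = "NFE",
    default_an: dict[str, int] | None = None,
    or_method: str = "sample",
    compute_ci: bool = True,
    qc_already_applied: bool = False,
) -> PipelineResult:
    """QC, restrict, rarity-filter, scan, and detect co-occurring carriers.

    ``filter_counts`` reports the workflow's variant bookkeeping: variants
    read, sites dropped by tranche, genotypes failed per QC reason, variants
    dropped by gene restriction and rarity, and the consequence-class
    composition of the surviving (ultra-rare) variant set.
    """
    cohort = cohort_raw if qc_already_applied else apply_qc(cohort_raw, thresholds)
    cohort = restrict_to_genes(cohort, gene_list)
    from .burden import rarity_filter

    cohort = rarity_filter(cohort, panels, criteria, populations)
    results = burden_scan(
        cohort, panels, list(gene_list), criteria=criteria,
        populations=populations, primary_panel=primary_panel,
        default_an=default_an, or_method=or_method, compute_ci=compute_ci,
        apply_rarity_filter=False,
    )
    multi = find_multicarriers(cohort, gene_list)
    pairs = syn_mis_sharing(cohort, gene_list)

    counts = dict(cohort.filter_log)
    by_reason = (cohort.audit["reason"].value_counts().to_dict()
                 if len(cohort.audit) else {})
    counts["qc_failures_by_reason"] = by_reason
    class_counts: dict[str, int] = {}
    for term in cohort.variants["consequence"]:
        cls = VariantClass.from_term(term).value
        class_counts[cls] = class_counts.get(cls, 0) + 1
    counts["ultra_rare_variants"] = int(len(cohort.variants))
    counts["ultra_rare_by_class"] = class_counts
    counts["significant_genes"] = sorted({
        r.gene for r in results
        if r.significant and r.variant_class == "missense_lof"})
    return PipelineResult(results=results, cohort=cohort, multicarriers=multi,
                          syn_mis_pairs=pairs, filter_counts=counts)


def write_tsv(frame: pd.DataFrame, path, cfg_hash: str) -> None:
    """Write a TSV with the config hash on a leading comment line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_manifest(outdir, config: dict, inputs: dict[str, Path],
                   extra: dict | None = None) -> Path:
    """Run manifest: tool version, config hash, input checksums."""
    from . import __version__

    outdir = Path(outdir)
    checksums = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "tool": "rvburden",
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "input_checksums": checksums,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return path


def write_pipeline_outputs(result: PipelineResult, outdir, cfg_hash: str) -> dict[str, Path]:
    """Render the burden table, carrier report and variant evidence files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    burden_frame = results_to_frame(result.results)
    paths["burden"] = outdir / "burden.tsv"
    write_tsv(burden_frame, paths["burden"], cfg_hash)
    paths["carriers"] = outdir / "carriers.tsv"
    write_tsv(carriers_to_frame(result.multicarriers), paths["carriers"], cfg_hash)
    pairs_rows = [{
        "individual": s, "gene": g,
        "synonymous": f"{syn.chrom}:{syn.pos}:{syn.ref}:{syn.alt}",
        "missense": f"{mis.chrom}:{mis.pos}:{mis.ref}:{mis.alt}",
    } for s, g, syn, mis in result.syn_mis_pairs]
    paths["syn_mis"] = outdir / "syn_mis_pairs.tsv"
    write_tsv(pd.DataFrame(pairs_rows, columns=["individual", "gene",
                                                "synonymous", "missense"]),
              paths["syn_mis"], cfg_hash)
    paths["evidence"] = outdir / "variant_evidence.json"
    evidence = result.cohort.variants.to_dict(orient="records")
    Path(paths["evidence"]).write_text(json.dumps(
        {"config_hash": cfg_hash, "variants": evidence,
         "filter_counts": result.filter_counts}, indent=1, default=str))
    paths["audit"] = outdir / "qc_audit.tsv"
    write_tsv(result.cohort.audit, paths["audit"], cfg_hash)
    return paths
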