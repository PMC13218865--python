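"""Synthetic cohorts, reference panels and splice regions with known truth.

The generator emulates the statistical design the burden analysis assumes:
a diploid case cohort of N individuals genotyped at per-gene sets of rare
variants whose reference-panel frequencies q follow a log-uniform law, with
per-gene multiplicative enrichment factors lambda on the case allele
frequency (the synthetic stand-in for a true odds ratio), planted
multi-variant carriers, genotype-QC failures injected just outside the
thresholds, and donor/acceptor splice signals planted in ref/alt sequence
windows.  Everything planted is recorded in a :class:`SyntheticTruth`
object so downstream stages can be audited against ground truth.

Genotypes are independent per-variant binomial draws (two Bernoulli alleles
at frequency min(lambda*q, 0.5)); at these frequencies linkage is
irrelevant to aggregate allele counts.  The same seed yields byte-identical
output files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import PanelTable
from .splice import SpliceMatrix, score_site
from .variant_io import CohortVariantTable, VariantClass, classify_consequence

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "generate_panel",
    "generate_cohort",
    "generate_splice_region",
    "simulate_study",
    "write_study",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: default per-population panel allele numbers (alleles, not individuals)
DEFAULT_PANEL_AN = {"NFE": 68_058, "Global": 152_312, "CSVS": 4_208}

#: default consequence mix for simulated variants
DEFAULT_CLASS_PROBS = {
    "missense_variant": 0.60,
    "synonymous_variant": 0.25,
    "stop_gained": 0.05,
    "intron_variant": 0.10,
}


@dataclass(frozen=True)
class GeneSpec:
    name: str
    cds_length: int = 1500
    n_variants: int = 5


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic cohort + panel."""

    n_cases: int = 371
    genes: list[GeneSpec] = field(default_factory=lambda: [
        GeneSpec(f"GENE{i:02d}") for i in range(10)])
    panel_an: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PANEL_AN))
    maf_range: tuple[float, float] = (1e-6, 5e-2)  # log-uniform panel q
    enrichment: dict[str, float] = field(default_factory=dict)  # gene -> lambda
    planted_pairs: dict[str, int] = field(default_factory=dict)
    planted_syn_mis: dict[str, int] = field(default_factory=dict)
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    qc_fail_fraction: float = 0.02
    tranche_fail_fraction: float = 0.01
    panel_absent_fraction: float = 0.05
    panel_jitter_sd: float = 0.3  # lognormal sd of non-primary-pop frequency
    primary_panel: str = "NFE"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if any(lam < 0 for lam in self.enrichment.values()):
            raise ValueError("enrichment factors must be >= 0")
        if not self.genes:
            raise ValueError("need at least one gene spec")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genes"] = [asdict(g) for g in self.genes]
        return d


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed for recovery from emitted files."""

    q: dict[str, float] = field(default_factory=dict)  # "chrom:pos:ref:alt" -> NFE q
    lam: dict[str, float] = field(default_factory=dict)  # gene -> lambda
    case_af: dict[str, float] = field(default_factory=dict)  # post-clamp case freq
    co_carriers: list[dict] = field(default_factory=list)
    qc_failures: list[dict] = field(default_factory=list)
    tranche_failed: list[str] = field(default_factory=list)
    panel_absent: dict[str, list[str]] = field(default_factory=dict)
    splice_sites: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    panel: PanelTable
    panel_frame: pd.DataFrame
    annotation: pd.DataFrame
    cohort: CohortVariantTable
    truth: SyntheticTruth


def _key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def _variant_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant layout: positions, alleles, consequences, true q.

    Derived from a dedicated seed stream so panel and cohort generation can
    reproduce it independently from the same config.
    """
    rng = np.random.default_rng([config.seed % (2**31), 11])
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    lo, hi = config.maf_range
    rows = []
    for gi, gene in enumerate(config.genes):
        chrom = f"chr{(gi % 22) + 1}"
        gene_start = 1_000_000 * (gi + 1)
        cds_pos = np.sort(rng.choice(gene.cds_length,
                                     size=min(gene.n_variants, gene.cds_length),
                                     replace=False))
        for p in cds_pos:
            ref = rng.choice(_BASES)
            alt = rng.choice([b for b in _BASES if b != ref])
            csq = classes[rng.choice(len(classes), p=probs)]
            q = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append({"CHROM": chrom, "POS": int(gene_start + p),
                         "REF": str(ref), "ALT": str(alt), "GENE": gene.name,
                         "CONSEQUENCE": csq, "CDS_POS": int(p), "q": q})
    return pd.DataFrame(rows)


def generate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-population panel rows (AC = round-half-even(q*AN), AF = AC/AN).

    Variants drawn absent in a population are omitted from that
    population's rows; absence is only possible for variants whose panel
    count would round to <= 2 alleles (a panel does not miss a 1%-frequency
    variant).  AC rounding to 0 at q > 0 is logged (the novel-in-panel
    edge).  The primary population's frequency is the variant's base q;
    other populations get lognormal jitter.
    """
    layout = _variant_layout(config)
    rng = np.random.default_rng([config.seed % (2**31), 13])
    truth = SyntheticTruth()
    truth.lam = {g.name: float(config.enrichment.get(g.name, 1.0))
                 for g in config.genes}
    rows = []
    for pop, an in config.panel_an.items():
        absent_list: list[str] = []
        for var in layout.itertuples(index=False):
            key = _key(var.CHROM, var.POS, var.REF, var.ALT)
            truth.q[key] = var.q
            if pop == config.primary_panel:
                q_pop = var.q
            else:
                q_pop = min(0.5, var.q * float(np.exp(
                    rng.normal(0.0, config.panel_jitter_sd))))
            ac = round(q_pop * an)  # round-half-to-even
            if ac <= 2 and rng.random() < config.panel_absent_fraction:
                absent_list.append(key)
                continue
            if ac == 0 and q_pop > 0:
                logger.info("panel %s: %s rounds to AC=0 at q=%.3g (novel-in-panel)",
                            pop, key, q_pop)
            rows.append({"CHROM": var.CHROM, "POS": var.POS, "REF": var.REF,
                         "ALT": var.ALT, "GENE": var.GENE,
                         "CONSEQUENCE": var.CONSEQUENCE, "POP": pop,
                         "AC": int(ac), "AN": int(an), "AF": ac / an})
        truth.panel_absent[pop] = absent_list
    frame = pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT", "GENE",
                                        "CONSEQUENCE", "POP", "AC", "AN", "AF"])
    return frame, truth


def generate_cohort(
    config: SimulationConfig,
    panel_truth: SyntheticTruth | None = None,
) -> tuple[CohortVariantTable, SyntheticTruth]:
    """Simulate the case cohort against the layout implied by ``config``.

    Each genotype is the sum of two Bernoulli(min(lambda*q, 0.5)) allele
    draws.  Planted multi-variant carriers are forced to heterozygous at
    their chosen variants, a configurable fraction of genotypes receives
    AB/GQ/DP values just outside the QC thresholds, and a fraction of sites
    is marked below the passing VQSR tranche.
    """
    layout = _variant_layout(config)
    rng = np.random.default_rng([config.seed % (2**31), 17])
    truth = panel_truth if panel_truth is not None else SyntheticTruth()
    truth.lam = {g.name: float(config.enrichment.get(g.name, 1.0))
                 for g in config.genes}
    n_var, n = len(layout), config.n_cases
    samples = [f"S{i:04d}" for i in range(n)]

    p_case = np.empty(n_var)
    for i, var in enumerate(layout.itertuples(index=False)):
        key = _key(var.CHROM, var.POS, var.REF, var.ALT)
        truth.q.setdefault(key, var.q)
        lam = truth.lam[var.GENE]
        p = lam * var.q
        if p > 0.5:
            warnings.warn(f"lambda*q = {p:.3g} > 0.5 at {key}; clamped")
            p = 0.5
        p_case[i] = p
        truth.case_af[key] = p

    alleles = rng.random((n_var, n, 2)) < p_case[:, None, None]
    gt = alleles.sum(axis=2).astype(np.int8)

    # plant co-carriers (forced heterozygous at chosen qualifying variants)
    qualifying = {VariantClass.MISSENSE, VariantClass.LOF}
    by_gene: dict[str, dict[VariantClass, list[int]]] = {}
    for i, var in enumerate(layout.itertuples(index=False)):
        vc = classify_consequence(var.CONSEQUENCE)
        by_gene.setdefault(var.GENE, {}).setdefault(vc, []).append(i)

    def _plant(gene: str, count: int, class_a: set, class_b: set, kind: str):
        idx_a = [i for vc in class_a for i in by_gene.get(gene, {}).get(vc, [])]
        idx_b = [i for vc in class_b for i in by_gene.get(gene, {}).get(vc, [])]
        for _ in range(count):
            if class_a == class_b:
                if len(idx_a) < 2:
                    raise ValueError(f"gene {gene} lacks 2 qualifying variants to plant")
                va, vb = rng.choice(idx_a, size=2, replace=False)
            else:
                if not idx_a or not idx_b:
                    raise ValueError(f"gene {gene} lacks variants of both classes")
                va = rng.choice(idx_a)
                vb = rng.choice(idx_b)
            person = int(rng.integers(n))
            for v in (int(va), int(vb)):
                if gt[v, person] == 0:
                    gt[v, person] = 1
            row_a, row_b = layout.iloc[int(va)], layout.iloc[int(vb)]
            truth.co_carriers.append({
                "kind": kind, "gene": gene, "individual": samples[person],
                "variants": [_key(row_a.CHROM, row_a.POS, row_a.REF, row_a.ALT),
                             _key(row_b.CHROM, row_b.POS, row_b.REF, row_b.ALT)],
            })

    for gene, count in sorted(config.planted_pairs.items()):
        _plant(gene, count, qualifying, qualifying, "pair")
    for gene, count in sorted(config.planted_syn_mis.items()):
        _plant(gene, count, {VariantClass.SYNONYMOUS}, {VariantClass.MISSENSE},
               "syn_mis")

    # per-genotype QC fields: clean values strictly inside the thresholds
    ab = np.where(gt == 1, rng.uniform(0.30, 0.70, (n_var, n)),
                  np.where(gt == 2, rng.uniform(0.95, 1.0, (n_var, n)),
                           rng.uniform(0.0, 0.05, (n_var, n))))
    # quantised to the VCF writer's precision so write->read round-trips exactly
    ab = np.round(ab, 3).astype(np.float32)
    gq = rng.integers(30, 100, (n_var, n)).astype(np.int64)
    dp = rng.integers(15, 60, (n_var, n)).astype(np.int64)

    # inject QC failures just outside the thresholds
    n_cells = n_var * n
    n_fail = int(round(config.qc_fail_fraction * n_cells))
    fail_cells = rng.choice(n_cells, size=n_fail, replace=False)
    for cell in sorted(fail_cells):
        i, j = divmod(int(cell), n)
        choices = ["AB", "GQ", "DP"] if gt[i, j] == 1 else ["GQ", "DP"]
        reason = choices[int(rng.integers(len(choices)))]
        if reason == "AB":
            side = rng.random() < 0.5
            ab[i, j] = round(rng.uniform(0.05, 0.19) if side
                             else rng.uniform(0.81, 0.95), 3)
        elif reason == "GQ":
            gq[i, j] = int(rng.integers(0, 20))
        else:
            dp[i, j] = int(rng.integers(0, 10))
        var = layout.iloc[i]
        truth.qc_failures.append({
            "chrom": var.CHROM, "pos": int(var.POS), "ref": var.REF,
            "alt": var.ALT, "sample": samples[j], "reason": reason})

    # site-level tranche failures
    filt = np.array(["PASS"] * n_var, dtype=object)
    for i in np.flatnonzero(rng.random(n_var) < config.tranche_fail_fraction):
        filt[i] = "VQSRTrancheLow"
        var = layout.iloc[int(i)]
        truth.tranche_failed.append(_key(var.CHROM, var.POS, var.REF, var.ALT))

    variants = pd.DataFrame({
        "chrom": layout["CHROM"], "pos": layout["POS"], "ref": layout["REF"],
        "alt": layout["ALT"], "gene": layout["GENE"],
        "consequence": layout["CONSEQUENCE"], "cds_pos": layout["CDS_POS"],
        "filter": filt,
    })
    cohort = CohortVariantTable(samples=samples, variants=variants,
                                genotypes=gt, ab=ab, gq=gq, dp=dp)
    return cohort, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the panel and cohort together, sharing one truth object."""
    panel_frame, truth = generate_panel(config)
    cohort, truth = generate_cohort(config, truth)
    annotation = _variant_layout(config)[
        ["CHROM", "POS", "REF", "ALT", "GENE", "CONSEQUENCE", "CDS_POS"]]
    return SimulatedStudy(config=config, panel=PanelTable(panel_frame),
                          panel_frame=panel_frame, annotation=annotation,
                          cohort=cohort, truth=truth)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Emit VCF, panel TSV, annotation TSV, gene list and truth JSON."""
    from .variant_io import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "panel": outdir / "panel.tsv",
        "annotation": outdir / "annotation.tsv",
        "genes": outdir / "genes.txt",
        "truth": outdir / "truth.json",
    }
    write_vcf(study.cohort, paths["vcf"])
    study.panel_frame.to_csv(paths["panel"], sep="\t", index=False)
    study.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["genes"].write_text(
        "\n".join(g.name for g in study.config.genes) + "\n")
    study.truth.to_json(paths["truth"])
    return paths


def generate_splice_region(
    matrix: SpliceMatrix,
    target_score_band: tuple[float, float],
    seed: int,
    flank: int = 30,
    max_restarts: int = 200,
) -> tuple[str, str, dict]:
    """Plant a scored splice site: alt differs from ref at one base.

    The alt window's score falls inside ``target_score_band`` (found by
    greedy single-base search with random restarts; an unreachable band
    raises RuntimeError).  The ref window is the single-base change of the
    alt window with the lowest score, so a high band yields a
    cryptic-site-activation event.  Returns (ref_seq, alt_seq, planted)
    where ``planted`` records the window start, k, scores and changed base.
    """
    lo, hi = target_score_band
    if not 0.0 <= lo <= hi <= 100.0:
        raise ValueError("target_score_band must be within [0, 100]")
    rng = np.random.default_rng(seed % (2**31))
    k = matrix.k

    def _score(kmer: str) -> float:
        return score_site(kmer, matrix).score

    if lo == hi == 100.0:
        alt_kmer = matrix.consensus
    elif lo == hi == 0.0:
        alt_kmer = matrix.anti_consensus
    else:
        alt_kmer = None
        for _ in range(max_restarts):
            kmer = "".join(rng.choice(_BASES, size=k))
            for _ in range(4 * k):
                s = _score(kmer)
                if lo <= s <= hi:
                    alt_kmer = kmer
                    break
                best, best_dist = None, abs(s - np.clip(s, lo, hi))
                for pos in range(k):
                    for base in "ACGT":
                        if base == kmer[pos]:
                            continue
                        cand = kmer[:pos] + base + kmer[pos + 1:]
                        sc = _score(cand)
                        dist = max(lo - sc, sc - hi, 0.0)
                        if dist < best_dist:
                            best, best_dist = cand, dist
                if best is None:
                    break
                kmer = best
            if alt_kmer is not None:
                break
        if alt_kmer is None:
            raise RuntimeError(
                f"no {matrix.kind} {k}-mer found in score band [{lo}, {hi}]")

    # ref = single-base change of alt with the lowest score (largest drop)
    candidates = [
        (alt_kmer[:pos] + base + alt_kmer[pos + 1:], pos)
        for pos in range(k) for base in "ACGT" if base != alt_kmer[pos]
    ]
    ref_kmer, changed_offset = min(candidates, key=lambda c: (_score(c[0]), c[1]))

    left = "".join(rng.choice(_BASES, size=flank))
    right = "".join(rng.choice(_BASES, size=flank))
    ref_seq = left + ref_kmer + right
    alt_seq = left + alt_kmer + right
    planted = {
        "kind": matrix.kind, "k": k, "window_start": flank,
        "changed_pos": flank + changed_offset,
        "ref_kmer": ref_kmer, "alt_kmer": alt_kmer,
        "ref_score": _score(ref_kmer), "alt_score": _score(alt_kmer),
    }
    return ref_seq, alt_seq, planted
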