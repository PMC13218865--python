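"""Splice-site strength scoring with position weight matrices.

Donor sites are modelled as 9-mers (exonic -3..-1, intronic +1..+6 around
the GT dinucleotide) and acceptors as 14-mers (pyrimidine tract, the AG
dinucleotide, and two exonic bases).  A site's consensus-value score is the
per-position weight sum rescaled to [0, 100] so that the consensus k-mer
scores 100 and the per-position-minimal k-mer scores 0 — the normalisation
used by motif-based splice tools.  The shipped matrices are
Shapiro-Senapathy-style consensus-frequency tables; any matrix with the
declared TSV layout can be substituted.

Beyond core sites, the module scans exonic splicing enhancer/silencer
(ESE/ESS) and intronic (ISE/ISS) motif sets on a ref/alt sequence pair and
reports the motif-ratio change, created motifs and broken motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpliceMatrix",
    "SpliceSiteScore",
    "SpliceEvent",
    "RegulatoryMotifDelta",
    "load_matrix",
    "default_matrix",
    "load_motifs",
    "default_motifs",
    "score_site",
    "variation_pct",
    "scan_pair",
    "motif_ratio_delta",
    "reverse_complement",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpliceMatrix:
    """Per-position base weights for a donor (k=9) or acceptor (k=14) site."""

    kind: Literal["donor", "acceptor"]
    weights: np.ndarray  # shape (k, 4), columns in ACGT order

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("weights must be (k, 4)")
        object.__setattr__(self, "weights", w)
        if self.raw_max <= self.raw_min:
            raise ValueError("matrix max score must exceed min score")

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @property
    def raw_max(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def raw_min(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=1))

    @property
    def anti_consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmin(axis=1))

    def raw_score(self, kmer: str) -> float:
        if len(kmer) != self.k:
            raise ValueError(f"k-mer length {len(kmer)} != matrix k {self.k}")
        total = 0.0
        for pos, base in enumerate(kmer):
            if base not in _BASE_IDX:
                raise ValueError(f"ambiguous or invalid base {base!r} at position {pos}")
            total += self.weights[pos, _BASE_IDX[base]]
        return total


@dataclass(frozen=True)
class SpliceSiteScore:
    """A candidate site's 0-100 consensus-value score."""

    position: int  # 0-based start of the k-mer on the scanned (+) sequence
    strand: str
    kmer: str
    score: float


@dataclass(frozen=True)
class SpliceEvent:
    """Ref vs alt score change at one k-mer frame."""

    matrix_kind: str
    position: int
    strand: str
    wild_kmer: str
    mutant_kmer: str
    wild_score: float
    mutant_score: float
    variation_pct: float
    signal: Literal["new_donor", "new_acceptor", "broken_site", "none"]
    interpretation: str


@dataclass
class RegulatoryMotifDelta:
    """ESE/ESS/ISE/ISS motif counts in ref vs alt and the enhancer-silencer delta."""

    ref_counts: dict[str, int]
    alt_counts: dict[str, int]
    created: list[tuple[str, str, int]] = field(default_factory=list)  # (class, motif, pos)
    broken: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def delta(self) -> int:
        """(ESE - ESS) in alt minus (ESE - ESS) in ref."""
        return ((self.alt_counts.get("ESE", 0) - self.alt_counts.get("ESS", 0))
                - (self.ref_counts.get("ESE", 0) - self.ref_counts.get("ESS", 0)))


def load_matrix(path, kind: Literal["donor", "acceptor"]) -> SpliceMatrix:
    """Read a matrix TSV with columns POS,A,C,G,T (one row per position)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.sort_values("POS")
    return SpliceMatrix(kind=kind, weights=frame[list(_BASES)].to_numpy(dtype=float))


def default_matrix(kind: Literal["donor", "acceptor"]) -> SpliceMatrix:
    """The packaged donor (9-mer) or acceptor (14-mer) weight table."""
    name = {"donor": "donor_matrix.tsv", "acceptor": "acceptor_matrix.tsv"}[kind]
    with resources.as_file(resources.files("rvburden.data") / name) as p:
        return load_matrix(p, kind)


def score_site(kmer: str, matrix: SpliceMatrix,
               position: int = 0, strand: str = "+") -> SpliceSiteScore:
    """Score one k-mer: 100 * (raw - min) / (max - min)."""
    raw = matrix.raw_score(kmer.upper())
    score = 100.0 * (raw - matrix.raw_min) / (matrix.raw_max - matrix.raw_min)
    return SpliceSiteScore(position=position, strand=strand, kmer=kmer.upper(),
                           score=score)


def variation_pct(wt_score: float, mut_score: float) -> float:
    """Percent change of a site score, 100 * (mut - wt) / wt, to 2 decimals."""
    if wt_score <= 0:
        raise ValueError("variation is undefined for a wild-type score of 0")
    return round(100.0 * (mut_score - wt_score) / wt_score, 2)


def scan_pair(
    ref_seq: str,
    alt_seq: str,
    matrices: Sequence[SpliceMatrix] | None = None,
    site_threshold: float = 65.0,
    min_variation: float = 10.0,
    strand: str = "+",
) -> list[SpliceEvent]:
    """Score every k-mer frame overlapping a single substitution, ref vs alt.

    A frame is called ``new_donor``/``new_acceptor`` when the mutant score
    reaches ``site_threshold`` and rises by at least ``min_variation``
    percent, and ``broken_site`` in the mirrored case.  Reverse-strand input
    is reverse-complemented before scoring; reported positions stay in the
    input (+) coordinate frame.
    """
    ref_seq, alt_seq = ref_seq.upper(), alt_seq.upper()
    if len(ref_seq) != len(alt_seq):
        raise ValueError("ref and alt sequences must have equal length")
    diffs = [i for i, (r, a) in enumerate(zip(ref_seq, alt_seq)) if r != a]
    if len(diffs) > 1:
        raise ValueError("only single-base substitutions are supported")
    if not diffs:
        return []
    if matrices is None:
        matrices = [default_matrix("donor"), default_matrix("acceptor")]
    length = len(ref_seq)
    if strand == "-":
        scan_ref, scan_alt = reverse_complement(ref_seq), reverse_complement(alt_seq)
        pos = length - 1 - diffs[0]
    else:
        scan_ref, scan_alt = ref_seq, alt_seq
        pos = diffs[0]

    events: list[SpliceEvent] = []
    for matrix in matrices:
        k = matrix.k
        for start in range(max(0, pos - k + 1), min(pos, length - k) + 1):
            wt = score_site(scan_ref[start:start + k], matrix).score
            mut = score_site(scan_alt[start:start + k], matrix).score
            if wt > 0:
                var = variation_pct(wt, mut)
            else:
                var = math.inf if mut > 0 else 0.0
            signal: str = "none"
            interp = ""
            if mut >= site_threshold and var >= min_variation:
                signal = f"new_{matrix.kind}"
                interp = f"Activation of a cryptic {matrix.kind} site"
            elif wt >= site_threshold and var <= -min_variation:
                signal = "broken_site"
                interp = f"Alteration of the wild-type {matrix.kind} site"
            if signal == "none":
                continue
            out_pos = start if strand == "+" else length - (start + k)
            events.append(SpliceEvent(
                matrix_kind=matrix.kind, position=out_pos, strand=strand,
                wild_kmer=scan_ref[start:start + k],
                mutant_kmer=scan_alt[start:start + k],
                wild_score=round(wt, 2), mutant_score=round(mut, 2),
                variation_pct=var, signal=signal, interpretation=interp))
    events.sort(key=lambda e: (e.matrix_kind, e.position))
    return events


def load_motifs(path) -> dict[str, set[str]]:
    """Read a motif TSV (columns CLASS, MOTIF) into class -> k-mer set."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    sets: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        sets.setdefault(row.CLASS, set()).add(row.MOTIF.upper())
    return sets


def default_motifs() -> dict[str, set[str]]:
    with resources.as_file(resources.files("rvburden.data") / "splice_motifs.tsv") as p:
        return load_motifs(p)


def _motif_hits(seq: str, motif_sets: Mapping[str, set[str]]) -> set[tuple[str, str, int]]:
    hits = set()
    for cls, motifs in motif_sets.items():
        for motif in motifs:
            start = seq.find(motif)
            while start != -1:
                hits.add((cls, motif, start))
                start = seq.find(motif, start + 1)
    return hits


def motif_ratio_delta(
    ref_seq: str,
    alt_seq: str,
    motif_sets: Mapping[str, set[str]] | None = None,
) -> RegulatoryMotifDelta:
    """Exact-count motif scan of both sequences, reporting created/broken motifs."""
    if motif_sets is None:
        motif_sets = default_motifs()
    if not motif_sets or all(not m for m in motif_sets.values()):
        raise ValueError("motif sets must be non-empty")
    ref_hits = _motif_hits(ref_seq.upper(), motif_sets)
    alt_hits = _motif_hits(alt_seq.upper(), motif_sets)

    def _count(hits):
        counts: dict[str, int] = {}
        for cls, _, _ in hits:
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    return RegulatoryMotifDelta(
        ref_counts=_count(ref_hits),
        alt_counts=_count(alt_hits),
        created=sorted(alt_hits - ref_hits),
        broken=sorted(ref_hits - alt_hits),
    )
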