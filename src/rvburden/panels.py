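"""Reference-panel allele frequencies used as pseudo-controls.

Loads gnomAD-style (per-population AC/AN/AF) and CSVS-style (AF only)
frequency tables and resolves each case variant to a per-population
frequency, count, or *absence*.  Absence is a first-class outcome distinct
from AF = 0 at a known allele number: the burden workflow treats a variant
absent from every queried panel as novel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ABSENT",
    "PanelFrequency",
    "PanelLookupResult",
    "PanelTable",
    "read_panel",
    "control_counts",
    "POPULATIONS",
]

logger = logging.getLogger(__name__)

#: population tag vocabulary (gnomAD super-populations plus CSVS)
POPULATIONS = ("NFE", "Global", "CSVS", "EAS", "AMR", "FIN", "SAS", "ASH", "AFR")

VariantKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


class _Absent:
    """Sentinel: variant not present in a population's panel."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


@dataclass(frozen=True)
class PanelFrequency:
    """One population's allele count / number / frequency for one variant.

    CSVS-style rows carry only ``af`` (ac and an are None); gnomAD-style rows
    carry all three, with af recomputed as ac/an.
    """

    population: str
    af: float
    ac: int | None = None
    an: int | None = None

    def __post_init__(self) -> None:
        if self.ac is not None and self.an is not None:
            if not 0 <= self.ac <= self.an:
                raise ValueError(f"need 0 <= AC <= AN, got AC={self.ac} AN={self.an}")
            if abs(self.af - self.ac / self.an) > 1e-9:
                raise ValueError("AF inconsistent with AC/AN beyond 1e-9")
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"AF out of [0,1]: {self.af}")


@dataclass
class PanelLookupResult:
    key: VariantKey
    frequencies: dict[str, "PanelFrequency | _Absent"] = field(default_factory=dict)

    @property
    def novel(self) -> bool:
        """Absent from every requested population."""
        return all(f is ABSENT for f in self.frequencies.values()) and bool(self.frequencies)


class PanelTable:
    """Frequency rows indexed by (chrom, pos, ref, alt, population)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"CHROM", "POS", "REF", "ALT", "POP"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self._index: dict[tuple, PanelFrequency] = {}
        for row in self.frame.itertuples(index=False):
            key = (row.CHROM, int(row.POS), row.REF, row.ALT, row.POP)
            if key in self._index:
                raise ValueError(f"duplicate panel row for {key}")
            ac = getattr(row, "AC", None)
            an = getattr(row, "AN", None)
            ac = None if ac is None or (isinstance(ac, float) and math.isnan(ac)) else int(ac)
            an = None if an is None or (isinstance(an, float) and math.isnan(an)) else int(an)
            if ac is not None and an is not None:
                af = ac / an  # AF recomputed when both counts present
            else:
                af = float(row.AF)
            self._index[key] = PanelFrequency(population=row.POP, af=af, ac=ac, an=an)

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, variant: VariantKey, populations: Sequence[str]) -> PanelLookupResult:
        """Resolve one variant in each requested population (ABSENT if missing)."""
        res = PanelLookupResult(key=variant)
        for pop in populations:
            res.frequencies[pop] = self._index.get((*variant, pop), ABSENT)
        return res


def read_panel(path) -> PanelTable:
    """Read a panel TSV (columns CHROM,POS,REF,ALT[,GENE,CONSEQUENCE],POP[,AC,AN],AF)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"CHROM": str, "REF": str, "ALT": str})
    return PanelTable(frame)


def control_counts(
    freq: "PanelFrequency | _Absent",
    default_an: int | None = None,
) -> tuple[int, int]:
    """Integer control alt/total alleles (b, B) for the 2x2 table.

    Known AC/AN pass through; AF-only rows reconstruct b by round-half-even
    of AF*AN against the configured allele number; ABSENT is zero alt
    alleles out of the configured AN.
    """
    if freq is ABSENT:
        if default_an is None:
            raise ValueError("ABSENT panel entry needs an explicit default AN")
        return 0, int(default_an)
    assert isinstance(freq, PanelFrequency)
    if freq.ac is not None and freq.an is not None:
        return freq.ac, freq.an
    an = freq.an if freq.an is not None else default_an
    if an is None:
        raise ValueError(
            f"panel row for {freq.population} has AF only; configure an allele number"
        )
    b = int(round(freq.af * an))  # Python round: half-to-even
    return b, int(an)
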