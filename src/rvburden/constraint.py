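"""Missense-variant density along a coding sequence and constrained regions.

Constraint is read off the density of reference-panel missense variants in
sliding windows over the CDS: stretches where a population shows unusually
few missense variants are candidates for purifying selection, and a study
variant falling inside such a stretch gains pathogenicity support.  Study
variants are overlaid on the profile, never counted into their own
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "ConstraintProfile",
    "variant_density",
    "constrained_regions",
    "classify_site",
]

DEFAULT_WINDOW = 90  # bp (30 codons)
DEFAULT_STEP = 30  # bp


@dataclass
class ConstraintProfile:
    """Windowed variant density over one gene's CDS for one population."""

    gene: str
    population: str
    cds_length: int
    window_size: int
    step: int
    window_starts: np.ndarray
    window_lengths: np.ndarray
    density: np.ndarray
    quantile: float | None = None
    constrained: list[tuple[int, int]] | None = None
    degenerate: bool = False


def variant_density(
    positions,
    cds_length: int,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    gene: str = "",
    population: str = "",
) -> ConstraintProfile:
    """Distinct-variant density in half-open windows tiling [0, cds_length).

    density[w] = (#distinct positions in window w) / window length; the last
    window is truncated at the CDS end and normalised by its actual length.
    A window larger than the CDS collapses to a single whole-CDS window with
    a warning.
    """
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    pos = np.unique(np.asarray(positions, dtype=np.int64))
    if pos.size and (pos.min() < 0 or pos.max() >= cds_length):
        raise ValueError("positions must lie in [0, cds_length)")
    if window_size > cds_length:
        warnings.warn("window exceeds CDS length; using a single whole-CDS window")
        window_size = cds_length
        step = cds_length
    starts = np.arange(0, cds_length, step)
    # drop trailing windows fully covered by an earlier one
    starts = starts[starts < cds_length]
    lengths = np.minimum(window_size, cds_length - starts)
    counts = np.array([
        np.count_nonzero((pos >= s) & (pos < s + l))
        for s, l in zip(starts, lengths)
    ], dtype=float)
    return ConstraintProfile(
        gene=gene, population=population, cds_length=cds_length,
        window_size=window_size, step=step, window_starts=starts,
        window_lengths=lengths, density=counts / lengths,
    )


def constrained_regions(
    profile: ConstraintProfile, quantile: float = 0.25
) -> list[tuple[int, int]]:
    """Maximal low-density runs: windows with density <= the profile quantile.

    Consecutive qualifying windows are merged across the step grid into
    half-open CDS intervals.  A flat profile is degenerate: the whole CDS is
    returned with the profile's ``degenerate`` flag set.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    dens = profile.density
    profile.quantile = quantile
    if np.allclose(dens, dens[0]):
        profile.degenerate = True
        profile.constrained = [(0, profile.cds_length)]
        return profile.constrained
    threshold = float(np.quantile(dens, quantile))
    low = dens <= threshold
    intervals: list[tuple[int, int]] = []
    for i in np.flatnonzero(low):
        start = int(profile.window_starts[i])
        end = int(start + profile.window_lengths[i])
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    profile.degenerate = False
    profile.constrained = intervals
    return intervals


def classify_site(
    position: int, profile: ConstraintProfile, quantile: float = 0.25
) -> tuple[str, float]:
    """Classify a CDS position as low_density or high_density.

    Membership in a constrained (low-density) interval is half-open
    [start, end).  Returns the label and the local density (of the window
    containing the position, averaged when overlapping windows disagree).
    """
    if not 0 <= position < profile.cds_length:
        raise ValueError(f"position {position} outside CDS [0, {profile.cds_length})")
    if profile.constrained is None:
        constrained_regions(profile, quantile)
    covering = [
        d for s, l, d in zip(profile.window_starts, profile.window_lengths,
                             profile.density)
        if s <= position < s + l
    ]
    local = float(np.mean(covering)) if covering else 0.0
    for start, end in profile.constrained:
        if start <= position < end:
            return "low_density", local
    return "high_density", local
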