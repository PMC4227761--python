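"""Single-nucleotide border peak detection via the Chebyshev inequality.

Exonuclease stop sites appear as positions whose 5'-end signal is an
outlier against the local background.  For local background mean m and
standard deviation s, Chebyshev's inequality bounds, without any
distributional assumption,

    Pr(X - m >= k s) <= 1 / k^2   (k > 1).

A position with signal X gets k = (X - m)/s and pseudo p-value
min(1, 1/k^2); the bound is vacuous for k <= 1, where the pseudo p-value
is 1.  These are upper bounds, deliberately conservative: a binding site
has only two true borders, and excess candidate borders would flood the
downstream matching step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coverage_io import FORWARD, REVERSE, StrandedCoverageTrack

DEFAULT_MIN_SIGNAL = 5.0
DEFAULT_MERGE_GAP = 100
DEFAULT_BG_FLANK = 500
DEFAULT_ALPHA = 0.05
COLLAPSE_DISTANCE = 2  # nt; significant positions this close collapse to one


@dataclass(frozen=True)
class BorderPeak:
    """A single-nucleotide candidate border on one strand."""

    chrom: str
    position: int
    strand: str
    signal: float
    k_value: float
    pseudo_p: float


@dataclass
class CandidateRegion:
    """A strand-joint locus with per-strand local background statistics.

    m and s are computed over the region extended by ``bg_flank`` on each
    side, per strand, over *all* positions in that window including zeros
    (the window is the full local background population, so s uses the
    population 1/N denominator).
    """

    chrom: str
    start: int
    end: int
    background_mean: Dict[str, float] = field(default_factory=dict)
    background_sd: Dict[str, float] = field(default_factory=dict)
    peaks: Dict[str, List[BorderPeak]] = field(default_factory=dict)


def chebyshev_pvalue(signal: float, m: float, s: float) -> float:
    """Chebyshev pseudo p-value min(1, 1/k^2) with k = (signal - m)/s.

    Returns 1 when k <= 1 (vacuous bound) or s == 0 (no dispersion, no
    outlier call possible).
    """
    if s < 0:
        raise ValueError("standard deviation must be nonnegative")
    if s == 0:
        return 1.0
    k = (signal - m) / s
    if k <= 1.0:
        return 1.0
    return min(1.0, 1.0 / (k * k))


def segment_candidate_regions(
    fwd: StrandedCoverageTrack,
    rev: StrandedCoverageTrack,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    merge_gap: int = DEFAULT_MERGE_GAP,
    bg_flank: int = DEFAULT_BG_FLANK,
    chrom_length: Optional[int] = None,
) -> List[CandidateRegion]:
    """Segment consolidated tracks into candidate loci.

    Maximal runs of positions with combined (fwd + rev) signal >=
    ``min_signal`` are found; runs separated by less than ``merge_gap``
    bases are merged.  Each region carries per-strand background (m, s)
    computed over the region extended by ``bg_flank``.
    """
    if fwd.chrom != rev.chrom:
        raise ValueError("forward/reverse tracks are from different chromosomes")
    combined: Dict[int, float] = {}
    for track in (fwd, rev):
        for p, v in zip(track.positions.tolist(), track.values.tolist()):
            combined[p] = combined.get(p, 0.0) + v
    hot = sorted(p for p, v in combined.items() if v >= min_signal)
    if not hot:
        return []

    regions: List[Tuple[int, int]] = []
    run_start = prev = hot[0]
    for p in hot[1:]:
        if p - prev < merge_gap:
            prev = p
            continue
        regions.append((run_start, prev + 1))
        run_start = prev = p
    regions.append((run_start, prev + 1))

    out: List[CandidateRegion] = []
    for start, end in regions:
        region = CandidateRegion(fwd.chrom, start, end)
        bg_lo = max(0, start - bg_flank)
        bg_hi = end + bg_flank
        if chrom_length is not None:
            bg_hi = min(bg_hi, chrom_length)
        for strand, track in ((FORWARD, fwd), (REVERSE, rev)):
            window = track.dense(bg_lo, bg_hi)
            region.background_mean[strand] = float(window.mean())
            region.background_sd[strand] = float(window.std())  # population sd
        out.append(region)
    return out


def _collapse(peaks: List[BorderPeak]) -> List[BorderPeak]:
    """Collapse significant positions within COLLAPSE_DISTANCE nt on one
    strand to the single maximum; ties keep the leftmost."""
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.position)
    collapsed: List[BorderPeak] = []
    best = peaks[0]
    prev_pos = peaks[0].position
    for peak in peaks[1:]:
        if peak.position - prev_pos <= COLLAPSE_DISTANCE:
            if peak.signal > best.signal:  # strict: leftmost wins ties
                best = peak
        else:
            collapsed.append(best)
            best = peak
        prev_pos = peak.position
    collapsed.append(best)
    return collapsed


def call_border_peaks(
    region: CandidateRegion,
    fwd: StrandedCoverageTrack,
    rev: StrandedCoverageTrack,
    alpha: float = DEFAULT_ALPHA,
) -> CandidateRegion:
    """Call per-strand border peaks inside a candidate region.

    Every position whose pseudo p-value is <= ``alpha`` is reported, then
    adjacency-collapsed.  The region is returned with ``peaks`` filled in.
    """
    for strand, track in ((FORWARD, fwd), (REVERSE, rev)):
        m = region.background_mean[strand]
        s = region.background_sd[strand]
        candidates: List[BorderPeak] = []
        lo = np.searchsorted(track.positions, region.start)
        hi = np.searchsorted(track.positions, region.end)
        for pos, val in zip(
            track.positions[lo:hi].tolist(), track.values[lo:hi].tolist()
        ):
            p = chebyshev_pvalue(val, m, s)
            if p <= alpha:
                k = (val - m) / s if s > 0 else 0.0
                candidates.append(
                    BorderPeak(region.chrom, pos, strand, val, k, p)
                )
        region.peaks[strand] = _collapse(candidates)
    return region


def write_peaks_bed(peaks: Sequence[BorderPeak], path) -> None:
    """BED6 + k_value + pseudo_p; score = round(-10 log10 pseudo_p)."""
    with open(path, "w") as handle:
        for i, peak in enumerate(
            sorted(peaks, key=lambda p: (p.chrom, p.position, p.strand))
        ):
            score = int(round(-10.0 * np.log10(max(peak.pseudo_p, 1e-300))))
            handle.write(
                f"{peak.chrom}\t{peak.position}\t{peak.position + 1}"
                f"\tborder_{i + 1}\t{score}\t{peak.strand}"
                f"\t{peak.k_value:.4g}\t{peak.pseudo_p:.4g}\n"
            )
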