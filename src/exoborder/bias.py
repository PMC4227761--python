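"""Sequencing-depth normalization and nucleotide-composition bias correction.

Depth is normalized per replicate by a size factor F_j = common_scale / T_j
(default common scale 1e7 reads).  Nucleotide-composition bias -- the
dependence of base frequency on position within the read, visible at read
starts -- is estimated from *singleton reads* (uniquely mapped reads
overlapping no other read), which are free of IP / exonuclease / PCR
selection.  Each read is then weighted by

    W(h) = mean_n P_n(h) / P_0(h),   n = 1 .. L - k,

where h is the read's first k-mer (default hexamer), P_0 the proportion of
reads starting with h, and P_n the proportion carrying h at interior offset
n.  Without positional bias all W(h) are close to 1.  Correction is off by
default: it yields only a limited improvement on border calling and is
provided as an optional step.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

from .coverage_io import AlignedRead

logger = logging.getLogger(__name__)

DEFAULT_COMMON_SCALE = 1.0e7
WEIGHT_MIN, WEIGHT_MAX = 0.1, 10.0
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-replicate size factor bringing depth to a common scale."""

    total_reads: int
    common_scale: float = DEFAULT_COMMON_SCALE

    @property
    def size_factor(self) -> float:
        return compute_size_factor(self.total_reads, self.common_scale)


def compute_size_factor(total_reads: int, common_scale: float = DEFAULT_COMMON_SCALE) -> float:
    """F_j = common_scale / T_j; errors on an empty replicate."""
    if total_reads <= 0:
        raise ValueError("empty replicate: total_reads must be > 0")
    return common_scale / total_reads


def find_singleton_reads(reads: Iterable[AlignedRead]) -> List[AlignedRead]:
    """Reads whose interval overlaps no other read on the same chromosome.

    The overlap test is strand-agnostic: any overlap on either strand
    disqualifies.  Single sweep over start-sorted intervals per chromosome:
    a read is a singleton iff its overlap-connected cluster contains only
    itself (within a cluster every member overlaps at least one other).
    """
    by_chrom: Dict[str, List[AlignedRead]] = {}
    for read in reads:
        by_chrom.setdefault(read.chrom, []).append(read)
    singletons: List[AlignedRead] = []
    for chrom_reads in by_chrom.values():
        chrom_reads.sort(key=lambda r: (r.start, r.end))
        cluster: List[AlignedRead] = []
        cluster_end = -1
        for read in chrom_reads:
            if read.start < cluster_end:
                cluster.append(read)
                cluster_end = max(cluster_end, read.end)
            else:
                if len(cluster) == 1:
                    singletons.append(cluster[0])
                cluster = [read]
                cluster_end = read.end
        if len(cluster) == 1:
            singletons.append(cluster[0])
    return singletons


@dataclass
class KmerBiasModel:
    """Background (interior) vs start k-mer frequencies and derived weights.

    Weights are clamped to [0.1, 10]; a k-mer seen internally but never at
    offset 0 gets the upper clamp (the formula is undefined there and such
    k-mers are depleted at starts).  Unseen or ambiguous k-mers fall back
    to weight 1.
    """

    k: int
    read_length: int
    p0: Dict[str, float] = field(default_factory=dict)
    pn_mean: Dict[str, float] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)

    def weight(self, kmer: str | None) -> float:
        if kmer is None or len(kmer) < self.k:
            return 1.0
        return self.weights.get(kmer[: self.k].upper(), 1.0)

    def weight_for_read(self, read: AlignedRead) -> float:
        return self.weight(read.read_prefix)

    def to_table(self, path) -> None:
        """Dump (kmer, p0, pn_mean, weight) as TSV for inspection."""
        kmers = sorted(set(self.p0) | set(self.pn_mean))
        with open(path, "w") as handle:
            handle.write("kmer\tp0\tpn_mean\tweight\n")
            for kmer in kmers:
                handle.write(
                    f"{kmer}\t{self.p0.get(kmer, 0.0):.6g}"
                    f"\t{self.pn_mean.get(kmer, 0.0):.6g}"
                    f"\t{self.weights.get(kmer, 1.0):.6g}\n"
                )

    @classmethod
    def from_table(cls, path, k: int | None = None, read_length: int = 0) -> "KmerBiasModel":
        p0: Dict[str, float] = {}
        pn: Dict[str, float] = {}
        weights: Dict[str, float] = {}
        with open(path) as handle:
            next(handle)  # header
            for line in handle:
                kmer, a, b, w = line.split()
                p0[kmer], pn[kmer], weights[kmer] = float(a), float(b), float(w)
        if k is None:
            k = len(next(iter(weights), ""))
        return cls(k=k, read_length=read_length, p0=p0, pn_mean=pn, weights=weights)


def _clean(kmer: str) -> str | None:
    kmer = kmer.upper()
    return kmer if _ACGT.issuperset(kmer) else None


def estimate_kmer_bias(
    singletons: Iterable[AlignedRead],
    k: int = 6,
    read_length: int | None = None,
) -> KmerBiasModel:
    """Fit the k-mer bias model from singleton reads.

    P_0 is tallied from the k-mer at offset 0; P_n for each interior offset
    n = 1 .. L-k is tallied separately, normalized per offset, then averaged.
    K-mers containing non-ACGT bases are excluded from all tallies.
    """
    if not 4 <= k <= 8:
        raise ValueError("k-mer size must be in [4, 8]")
    prefixes = [r.read_prefix for r in singletons if r.read_prefix]
    if read_length is None:
        read_length = max((len(p) for p in prefixes), default=0)
    prefixes = [p for p in prefixes if len(p) >= k]
    if not prefixes or read_length <= k:
        raise ValueError(
            "no singleton reads with usable sequence; disable bias correction"
        )
    L = read_length
    start_counts: Counter[str] = Counter()
    offset_counts: List[Counter[str]] = [Counter() for _ in range(L - k)]
    for prefix in prefixes:
        kmer = _clean(prefix[:k])
        if kmer is not None:
            start_counts[kmer] += 1
        for n in range(1, min(len(prefix) - k, L - k) + 1):
            kmer = _clean(prefix[n : n + k])
            if kmer is not None:
                offset_counts[n - 1][kmer] += 1

    total0 = sum(start_counts.values())
    if total0 == 0:
        raise ValueError(
            "all singleton start k-mers ambiguous; disable bias correction"
        )
    p0 = {kmer: c / total0 for kmer, c in start_counts.items()}

    pn_sum: Dict[str, float] = {}
    n_offsets = 0
    for counts in offset_counts:
        total_n = sum(counts.values())
        if total_n == 0:
            continue
        n_offsets += 1
        for kmer, c in counts.items():
            pn_sum[kmer] = pn_sum.get(kmer, 0.0) + c / total_n
    if n_offsets == 0:
        raise ValueError("reads too short for interior offsets at this k")
    pn_mean = {kmer: s / n_offsets for kmer, s in pn_sum.items()}

    weights: Dict[str, float] = {}
    for kmer in set(p0) | set(pn_mean):
        if p0.get(kmer, 0.0) > 0:
            w = pn_mean.get(kmer, 0.0) / p0[kmer]
        else:  # depleted at starts; formula undefined
            w = WEIGHT_MAX
        weights[kmer] = min(WEIGHT_MAX, max(WEIGHT_MIN, w))

    return KmerBiasModel(k=k, read_length=L, p0=p0, pn_mean=pn_mean, weights=weights)


def apply_read_weights(
    reads: Iterable[AlignedRead], model: KmerBiasModel | None
) -> Iterator[Tuple[AlignedRead, float]]:
    """Pair each read with its bias weight (1.0 when correction is off)."""
    for read in reads:
        yield read, (1.0 if model is None else model.weight_for_read(read))
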