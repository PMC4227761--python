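"""Synthetic ChIP-exo alignments with known border truth.

The generator emulates the data model of a ChIP-exo experiment: lambda
exonuclease digests unbound DNA up to the protein footprint, leaving
homogeneous 5' fragment ends at the two site boundaries.  Each planted
site of width w therefore emits clonal forward-strand reads whose 5' ends
pile at the left border and clonal reverse-strand reads whose 5' ends pile
at the right border, with per-read Gaussian stop jitter.  Replicates vary
in depth (``depth_factors``) and carry independent uniform background
reads.  Optional start-k-mer enrichment reproduces nucleotide-composition
bias at read starts.  A fixed seed makes the output byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coverage_io import FORWARD, REVERSE, AlignedRead, GenomeAssembly

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class TruthSite:
    chrom: str
    forward: int  # left border (first base of the site)
    reverse: int  # right border (last base of the site)

    @property
    def width(self) -> int:
        return self.reverse - self.forward + 1


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults: one 500 kb chromosome carrying 200 non-overlapping sites of
    width 49 bp; 50 expected clonal reads per border (Poisson); 3
    replicates at relative depths (1.0, 0.8, 1.2); exonuclease stop jitter
    1 nt; 50 diffuse background reads per kb; 36 nt reads.
    ``site_width`` may be a single width or ((width, prob), ...) to mimic
    the double-stop (outer/inner border) geometry.
    """

    genome: Tuple[Tuple[str, int], ...] = (("chrSim", 500_000),)
    n_sites: int = 200
    site_width: int | Tuple[Tuple[int, float], ...] = 49
    border_depth: float = 50.0
    jitter_sd: float = 1.0
    background_rate: float = 50.0  # reads per kb per replicate (at factor 1)
    n_replicates: int = 3
    depth_factors: Tuple[float, ...] = (1.0, 0.8, 1.2)
    read_length: int = 36
    kmer_bias: Optional[Dict[str, float]] = None
    kmer_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depth_factors) != self.n_replicates:
            raise ValueError("need one depth factor per replicate")
        if self.border_depth < 0 or self.background_rate < 0 or self.jitter_sd < 0:
            raise ValueError("rates must be nonnegative")

    def assembly(self) -> GenomeAssembly:
        names, lengths = zip(*self.genome)
        return GenomeAssembly(tuple(names), tuple(lengths))

    def widths(self) -> Tuple[Tuple[int, float], ...]:
        if isinstance(self.site_width, int):
            return ((self.site_width, 1.0),)
        return tuple(self.site_width)


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: List[TruthSite]
    reads: List[List[AlignedRead]]  # per replicate

    @property
    def assembly(self) -> GenomeAssembly:
        return self.config.assembly()


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> List[TruthSite]:
    """Non-overlapping placement: sites count is apportioned to
    chromosomes by length; each site sits at a random offset inside its
    own equal slot, with a margin so reads cannot leave the chromosome."""
    widths = config.widths()
    max_width = max(w for w, _ in widths)
    margin = config.read_length + int(6 * config.jitter_sd) + 10
    total_len = sum(length for _, length in config.genome)
    sites: List[TruthSite] = []
    remaining = config.n_sites
    for idx, (chrom, length) in enumerate(config.genome):
        if idx == len(config.genome) - 1:
            n = remaining
        else:
            n = int(round(config.n_sites * length / total_len))
            n = min(n, remaining)
        remaining -= n
        if n == 0:
            continue
        usable = length - 2 * margin
        slot = usable // n if n else 0
        if slot < max_width + 2:
            raise ValueError(
                f"cannot pack {n} sites of width {max_width} into {chrom} "
                f"(length {length})"
            )
        width_vals = np.array([w for w, _ in widths])
        width_probs = np.array([p for _, p in widths], dtype=float)
        width_probs /= width_probs.sum()
        chosen = rng.choice(width_vals, size=n, p=width_probs)
        for i in range(n):
            w = int(chosen[i])
            lo = margin + i * slot
            start = int(rng.integers(lo, lo + slot - w))
            sites.append(TruthSite(chrom, start, start + w - 1))
    return sites


def _random_prefixes(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> List[str]:
    """Random read sequences; the start k-mer is optionally drawn from an
    enriched distribution while interior bases stay uniform."""
    L, k = config.read_length, config.kmer_size
    body = _BASES[rng.integers(0, 4, size=(n, L))]
    if config.kmer_bias:
        kmers = ["".join(t) for t in _all_kmers(k)]
        weights = np.array([config.kmer_bias.get(km, 1.0) for km in kmers])
        weights = weights / weights.sum()
        picks = rng.choice(len(kmers), size=n, p=weights)
        for i, pick in enumerate(picks):
            body[i, :k] = np.frombuffer(kmers[pick].encode(), dtype="S1")
    return [row.tobytes().decode() for row in body]


def _all_kmers(k: int) -> List[Tuple[str, ...]]:
    from itertools import product

    return list(product("ACGT", repeat=k))


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate alignments per replicate plus the planted truth table."""
    rng = np.random.default_rng(config.seed)
    sites = _place_sites(config, rng)
    lengths = dict(config.genome)
    L = config.read_length

    replicates: List[List[AlignedRead]] = []
    for j in range(config.n_replicates):
        factor = config.depth_factors[j]
        reads: List[AlignedRead] = []
        # border reads: clonal piles at each site edge
        for site in sites:
            chrom_len = lengths[site.chrom]
            for strand, border in ((FORWARD, site.forward), (REVERSE, site.reverse)):
                count = int(rng.poisson(config.border_depth * factor))
                if count == 0:
                    continue
                if config.jitter_sd > 0:
                    offsets = np.round(
                        rng.normal(0.0, config.jitter_sd, size=count)
                    ).astype(int)
                else:
                    offsets = np.zeros(count, dtype=int)
                for off in offsets:
                    p5 = border + int(off)
                    if strand == FORWARD:
                        start = min(max(p5, 0), chrom_len - L)
                        reads.append(
                            AlignedRead(site.chrom, start, start + L, FORWARD, None, j)
                        )
                    else:
                        p5 = min(max(p5, L - 1), chrom_len - 1)
                        reads.append(
                            AlignedRead(site.chrom, p5 - L + 1, p5 + 1, REVERSE, None, j)
                        )
        # diffuse background
        for chrom, chrom_len in config.genome:
            n_bg = int(rng.poisson(config.background_rate * chrom_len / 1000.0 * factor))
            if n_bg == 0:
                continue
            starts = rng.integers(0, chrom_len - L, size=n_bg)
            strands = rng.integers(0, 2, size=n_bg)
            for s, is_rev in zip(starts.tolist(), strands.tolist()):
                reads.append(
                    AlignedRead(chrom, s, s + L, REVERSE if is_rev else FORWARD, None, j)
                )
        # attach sequences in one deterministic batch
        prefixes = _random_prefixes(len(reads), config, rng)
        reads = [
            AlignedRead(r.chrom, r.start, r.end, r.strand, pre, r.replicate_id)
            for r, pre in zip(reads, prefixes)
        ]
        replicates.append(reads)
    return SimulationResult(config, sites, replicates)


# ---------------------------------------------------------------------------
# on-disk fixtures

from .coverage_io import _revcomp  # noqa: E402


def write_bed(reads: Sequence[AlignedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for i, r in enumerate(reads):
            handle.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i + 1}\t0\t{r.strand}\n")


def write_sam(
    reads: Sequence[AlignedRead], assembly: GenomeAssembly, path: str | os.PathLike
) -> None:
    """Plain-text SAM with sequences, so k-mer bias estimation works
    downstream (SEQ is stored on the forward genome strand)."""
    with open(path, "w") as handle:
        handle.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in zip(assembly.chrom_names, assembly.chrom_lengths):
            handle.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, r in enumerate(reads):
            flag = 16 if r.strand == REVERSE else 0
            seq = r.read_prefix or "*"
            if seq != "*" and r.strand == REVERSE:
                seq = _revcomp(seq)
            cigar = f"{r.end - r.start}M" if seq == "*" or len(seq) == r.end - r.start else f"{len(seq)}M"
            handle.write(
                f"read_{i + 1}\t{flag}\t{r.chrom}\t{r.start + 1}\t42\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\n"
            )


def write_truth(truth: Sequence[TruthSite], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tforward\treverse\twidth\n")
        for site in truth:
            handle.write(f"{site.chrom}\t{site.forward}\t{site.reverse}\t{site.width}\n")


def write_fixture_set(
    result: SimulationResult, outdir: str | os.PathLike, fmt: str = "bed"
) -> List[str]:
    """Write per-replicate alignments, truth TSV and chrom.sizes; returns
    the alignment paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: List[str] = []
    for j, reads in enumerate(result.reads):
        ext = "sam" if fmt == "sam" else "bed"
        path = os.path.join(str(outdir), f"rep{j + 1}.{ext}")
        if fmt == "sam":
            write_sam(reads, result.assembly, path)
        else:
            write_bed(reads, path)
        paths.append(path)
    write_truth(result.truth, os.path.join(str(outdir), "truth.tsv"))
    result.assembly.to_chrom_sizes(os.path.join(str(outdir), "chrom.sizes"))
    return paths
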