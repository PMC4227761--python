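"""Alignment input and strand-separated 5'-end coverage tracks.

ChIP-exo reads are digested by lambda exonuclease up to the bound protein,
so the 5' end of each read marks a putative binding-site boundary.  This
module reads alignments (SAM/BAM via pysam, or BED6), builds per-strand
tracks of 5'-end counts, and writes the tracks as bedGraph or BigWig.

Coordinate convention: 0-based half-open everywhere.  The 5' end of a
forward-strand read maps to ``start``; the 5' end of a reverse-strand read
is its highest genomic coordinate, ``end - 1``.

Clonal reads (identical coordinates) are expected in ChIP-exo -- the
exonuclease stops at the same base on every fragment -- and are never
deduplicated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
import pysam

FORWARD = "+"
REVERSE = "-"


class AlignmentError(ValueError):
    """Malformed or unresolvable alignment record."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths."""

    chrom_names: Tuple[str, ...]
    chrom_lengths: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in count")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> Dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @classmethod
    def from_chrom_sizes(cls, path: str | os.PathLike) -> "GenomeAssembly":
        """Read a two-column (name, length) chromosome-sizes file."""
        names: List[str] = []
        lengths: List[int] = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise AlignmentError(
                        f"{path}:{lineno}: expected 'name length', got {line!r}"
                    )
                names.append(fields[0])
                lengths.append(int(fields[1]))
        return cls(tuple(names), tuple(lengths))

    def to_chrom_sizes(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                handle.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely mapped read; ``read_prefix`` is the first L sequenced bases
    (as sequenced, i.e. already reverse-complemented for reverse-strand
    alignments by the aligner), used only for k-mer bias estimation."""

    chrom: str
    start: int
    end: int
    strand: str
    read_prefix: Optional[str] = None
    replicate_id: int = 0

    def five_prime(self) -> int:
        return self.start if self.strand == FORWARD else self.end - 1


@dataclass
class StrandedCoverageTrack:
    """Sparse per-chromosome, per-strand 5'-end signal.

    ``positions`` is sorted and unique; ``values`` are the nonnegative
    signal at those positions.  Memory is proportional to the number of
    covered positions, never to chromosome length.
    """

    chrom: str
    strand: str
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    replicate_id: int | str = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions/values shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("negative signal value")

    @classmethod
    def from_dict(
        cls,
        chrom: str,
        strand: str,
        signal: Dict[int, float],
        replicate_id: int | str = 0,
    ) -> "StrandedCoverageTrack":
        pos = np.array(sorted(signal), dtype=np.int64)
        val = np.array([signal[p] for p in pos], dtype=np.float64)
        return cls(chrom, strand, pos, val, replicate_id)

    def to_dict(self) -> Dict[int, float]:
        return dict(zip(self.positions.tolist(), self.values.tolist()))

    def mass(self) -> float:
        return float(self.values.sum())

    def dense(self, start: int, end: int) -> np.ndarray:
        """Dense signal over [start, end), zeros where uncovered."""
        out = np.zeros(end - start, dtype=np.float64)
        lo = np.searchsorted(self.positions, start)
        hi = np.searchsorted(self.positions, end)
        out[self.positions[lo:hi] - start] = self.values[lo:hi]
        return out

    def scaled(self, factor: float) -> "StrandedCoverageTrack":
        return StrandedCoverageTrack(
            self.chrom, self.strand, self.positions, self.values * factor,
            self.replicate_id,
        )


# ---------------------------------------------------------------------------
# alignment input


def _read_bed6(
    path: str | os.PathLike, assembly: GenomeAssembly, replicate_id: int
) -> Iterator[AlignedRead]:
    lengths = assembly.lengths
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) == 1:  # tolerate space-separated
                fields = line.split()
            if len(fields) < 6:
                raise AlignmentError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            if chrom not in lengths:
                raise AlignmentError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AlignmentError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in (FORWARD, REVERSE):
                raise AlignmentError(f"{path}:{lineno}: strand must be + or -")
            if not (0 <= start < end <= lengths[chrom]):
                raise AlignmentError(
                    f"{path}:{lineno}: interval [{start},{end}) out of bounds "
                    f"for {chrom} (length {lengths[chrom]})"
                )
            yield AlignedRead(chrom, start, end, strand, None, replicate_id)


def _read_sam(
    path: str | os.PathLike,
    assembly: GenomeAssembly,
    min_mapq: int,
    replicate_id: int,
) -> Iterator[AlignedRead]:
    lengths = assembly.lengths
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if chrom not in lengths:
                raise AlignmentError(
                    f"{path}: unknown chromosome {chrom!r} for read {rec.query_name}"
                )
            start, end = rec.reference_start, rec.reference_end
            if end is None or not (0 <= start < end <= lengths[chrom]):
                raise AlignmentError(
                    f"{path}: read {rec.query_name} out of bounds on {chrom}"
                )
            seq = rec.query_sequence
            if seq is not None and rec.is_reverse:
                # query_sequence is given on the forward genome strand;
                # recover the as-sequenced orientation for bias estimation
                seq = _revcomp(seq)
            yield AlignedRead(
                chrom, start, end,
                REVERSE if rec.is_reverse else FORWARD,
                seq, replicate_id,
            )


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def load_alignments(
    path: str | os.PathLike,
    assembly: GenomeAssembly,
    min_mapq: int = 20,
    replicate_id: int = 0,
) -> Iterator[AlignedRead]:
    """Stream uniquely mapped reads from SAM/BAM or BED6.

    Uniqueness is delegated to the mapping-quality filter (``min_mapq``,
    SAM/BAM only; BED input is taken as pre-filtered).  Clonal reads are
    all retained.  Unknown chromosomes and malformed records raise
    :class:`AlignmentError` naming the offending record.
    """
    suffix = str(path).lower()
    if suffix.endswith((".sam", ".bam")):
        return _read_sam(path, assembly, min_mapq, replicate_id)
    return _read_bed6(path, assembly, replicate_id)


# ---------------------------------------------------------------------------
# coverage construction


def five_prime_coverage(
    reads: Iterable[AlignedRead],
    assembly: GenomeAssembly,
    weight_fn: Optional[Callable[[AlignedRead], float]] = None,
    scale: float = 1.0,
    replicate_id: int | str | None = None,
) -> Dict[Tuple[str, str], StrandedCoverageTrack]:
    """Accumulate 5'-end signal per (chromosome, strand).

    Each forward read adds ``weight`` at ``start`` on the forward track;
    each reverse read adds ``weight`` at ``end - 1`` on the reverse track.
    ``weight`` is 1 unless ``weight_fn`` is given (k-mer bias correction);
    the whole track is multiplied by ``scale`` (the size factor F_j).
    Returns a dict keyed by (chrom, strand); only covered chromosomes and
    strands appear.
    """
    acc: Dict[Tuple[str, str], Dict[int, float]] = {}
    rep: int | str | None = replicate_id
    for read in reads:
        if rep is None:
            rep = read.replicate_id
        w = 1.0 if weight_fn is None else float(weight_fn(read))
        bucket = acc.setdefault((read.chrom, read.strand), {})
        pos = read.five_prime()
        bucket[pos] = bucket.get(pos, 0.0) + w
    lengths = assembly.lengths
    out: Dict[Tuple[str, str], StrandedCoverageTrack] = {}
    for (chrom, strand), signal in acc.items():
        if chrom not in lengths:
            raise AlignmentError(f"unknown chromosome {chrom!r}")
        track = StrandedCoverageTrack.from_dict(
            chrom, strand, signal, rep if rep is not None else 0
        )
        if scale != 1.0:
            track = track.scaled(scale)
        out[(chrom, strand)] = track
    return out


# ---------------------------------------------------------------------------
# track output / input


def _runs(track: StrandedCoverageTrack) -> Iterator[Tuple[int, int, float]]:
    """Merge adjacent equal-valued positions into half-open intervals."""
    pos, val = track.positions, track.values
    i, n = 0, len(pos)
    while i < n:
        j = i
        while (
            j + 1 < n
            and pos[j + 1] == pos[j] + 1
            and val[j + 1] == val[i]
        ):
            j += 1
        yield int(pos[i]), int(pos[j]) + 1, float(val[i])
        i = j + 1


def _fmt_value(value: float) -> str:
    # shortest exact representation so write->read is lossless; integral
    # values print without a decimal point
    if value == int(value) and abs(value) < 1e16:
        return str(int(value))
    return repr(value)


def write_bedgraph(track: StrandedCoverageTrack, path: str | os.PathLike) -> None:
    """Write 0-based half-open bedGraph; adjacent equal values merged.
    Values are written losslessly, so write->read is an exact round trip."""
    with open(path, "w") as handle:
        for start, end, value in _runs(track):
            handle.write(f"{track.chrom}\t{start}\t{end}\t{_fmt_value(value)}\n")


def read_bedgraph(
    path: str | os.PathLike,
    strand: str = FORWARD,
    replicate_id: int | str = 0,
) -> List[StrandedCoverageTrack]:
    """Read a bedGraph into one sparse track per chromosome."""
    per_chrom: Dict[str, Dict[int, float]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start_s, end_s, val_s = line.split()[:4]
            start, end, value = int(start_s), int(end_s), float(val_s)
            bucket = per_chrom.setdefault(chrom, {})
            for p in range(start, end):
                bucket[p] = value
    return [
        StrandedCoverageTrack.from_dict(chrom, strand, signal, replicate_id)
        for chrom, signal in sorted(per_chrom.items())
    ]


def write_bigwig(
    track: StrandedCoverageTrack,
    path: str | os.PathLike,
    assembly: GenomeAssembly,
) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader(list(zip(assembly.chrom_names, assembly.chrom_lengths)))
        starts, ends, values = [], [], []
        for start, end, value in _runs(track):
            starts.append(start)
            ends.append(end)
            values.append(value)
        if starts:
            bw.addEntries(
                [track.chrom] * len(starts), starts, ends=ends, values=values
            )
    finally:
        bw.close()


def read_bigwig(
    path: str | os.PathLike,
    chrom: str,
    strand: str = FORWARD,
    replicate_id: int | str = 0,
) -> StrandedCoverageTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        signal: Dict[int, float] = {}
        if chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                for p in range(start, end):
                    if value != 0.0:
                        signal[p] = value
    finally:
        bw.close()
    return StrandedCoverageTrack.from_dict(chrom, strand, signal, replicate_id)


def write_signal_track(
    track: StrandedCoverageTrack,
    path: str | os.PathLike,
    format: str = "bedgraph",
    assembly: Optional[GenomeAssembly] = None,
) -> None:
    """Write a track as bedGraph or BigWig (BigWig needs the assembly)."""
    if format == "bedgraph":
        write_bedgraph(track, path)
    elif format == "bigwig":
        if assembly is None:
            raise ValueError("BigWig output requires the genome assembly")
        write_bigwig(track, path, assembly)
    else:
        raise ValueError(f"unknown track format {format!r}")
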