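"""Four-stage pipeline orchestration.

Stages mirror the workflow: (1) preprocess -- depth normalization and
optional k-mer bias correction of per-replicate 5'-end tracks; (2)
consolidate -- entropy-weighted replicate consolidation; (3) callborders
-- Chebyshev border-peak calling; (4) pairborders -- size-model fitting
and Gale-Shapley border matching.  Every stage reads and writes ordinary
bedGraph / BED text files, so stages are independently inspectable and
composable; ``run_pipeline`` chains them and writes a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .bias import (
    DEFAULT_COMMON_SCALE,
    KmerBiasModel,
    apply_read_weights,
    compute_size_factor,
    estimate_kmer_bias,
    find_singleton_reads,
)
from .consolidation import ReplicateSignalMatrix, consolidate
from .coverage_io import (
    FORWARD,
    REVERSE,
    GenomeAssembly,
    StrandedCoverageTrack,
    five_prime_coverage,
    load_alignments,
    read_bedgraph,
    write_bedgraph,
)
from .detection import (
    DEFAULT_ALPHA,
    DEFAULT_BG_FLANK,
    DEFAULT_MERGE_GAP,
    DEFAULT_MIN_SIGNAL,
    CandidateRegion,
    call_border_peaks,
    segment_candidate_regions,
    write_peaks_bed,
)
from .matching import (
    DEFAULT_ALPHA_PAIR,
    DEFAULT_N_COMPONENTS,
    BorderPair,
    PairSizeModel,
    call_border_pairs,
    estimate_pair_size_model,
    high_confidence_sizes,
    write_pairs_bed,
)

logger = logging.getLogger(__name__)

_STRAND_SUFFIX = {FORWARD: "fwd", REVERSE: "rev"}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the documented design."""

    alignments: Tuple[str, ...] = ()
    assembly: str = ""
    min_mapq: int = 20
    common_scale: float = DEFAULT_COMMON_SCALE
    bias_correction: bool = False
    kmer_size: int = 6
    method: str = "entropy"
    pooled_proportions: bool = False
    min_signal: float = DEFAULT_MIN_SIGNAL
    merge_gap: int = DEFAULT_MERGE_GAP
    bg_flank: int = DEFAULT_BG_FLANK
    alpha: float = DEFAULT_ALPHA
    n_components: int = DEFAULT_N_COMPONENTS
    kernel_width: Optional[float] = None
    mu_t: Optional[float] = None
    sigma_t: Optional[float] = None
    max_span: Optional[int] = None
    alpha_pair: float = DEFAULT_ALPHA_PAIR
    seed: int = 0

    _BOOL = ("bias_correction", "pooled_proportions")

    def to_file(self, path) -> None:
        with open(path, "w") as handle:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if f.name == "alignments":
                    value = ",".join(value)
                handle.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: Dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Dict[str, str]) -> "RunConfig":
        kwargs: Dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if key == "alignments":
                kwargs[key] = tuple(v for v in value.split(",") if v)
            elif key in cls._BOOL:
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif value == "None":
                kwargs[key] = None
            elif key in ("min_mapq", "merge_gap", "bg_flank", "n_components",
                         "kmer_size", "max_span", "seed"):
                kwargs[key] = int(float(value))
            elif key in ("assembly", "method"):
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending record."""


def _track_path(outdir: str, stem: str, strand: str) -> str:
    return os.path.join(outdir, f"{stem}.{_STRAND_SUFFIX[strand]}.bedgraph")


def stage_preprocess(config: RunConfig, outdir: str) -> List[Dict[Tuple[str, str], StrandedCoverageTrack]]:
    """Per replicate: load reads, normalize depth, optionally bias-correct,
    and write one bedGraph per strand (suffix .fwd./.rev.)."""
    os.makedirs(outdir, exist_ok=True)
    assembly = GenomeAssembly.from_chrom_sizes(config.assembly)
    per_replicate: List[Dict[Tuple[str, str], StrandedCoverageTrack]] = []
    for j, path in enumerate(config.alignments):
        try:
            reads = list(load_alignments(path, assembly, config.min_mapq, j))
        except Exception as exc:
            raise PipelineError(f"preprocess: {path}: {exc}") from exc
        if not reads:
            raise PipelineError(f"preprocess: {path}: no usable reads")
        factor = compute_size_factor(len(reads), config.common_scale)
        model: Optional[KmerBiasModel] = None
        if config.bias_correction:
            singletons = find_singleton_reads(reads)
            model = estimate_kmer_bias(singletons, config.kmer_size)
            model.to_table(os.path.join(outdir, f"rep{j + 1}.kmer_weights.tsv"))
        weight_fn = model.weight_for_read if model is not None else None
        tracks = five_prime_coverage(
            reads, assembly, weight_fn=weight_fn, scale=factor, replicate_id=j
        )
        logger.info(
            "preprocess: replicate %d: %d reads, size factor %.4g",
            j + 1, len(reads), factor,
        )
        for (chrom, strand), track in sorted(tracks.items()):
            write_bedgraph(track, _track_path(outdir, f"rep{j + 1}.{chrom}", strand))
        per_replicate.append(tracks)
    return per_replicate


def stage_consolidate(
    config: RunConfig,
    outdir: str,
    per_replicate: Optional[Sequence[Dict[Tuple[str, str], StrandedCoverageTrack]]] = None,
) -> Dict[Tuple[str, str], StrandedCoverageTrack]:
    """Combine replicate tracks per (chromosome, strand) and write
    consolidated bedGraphs."""
    os.makedirs(outdir, exist_ok=True)
    assembly = GenomeAssembly.from_chrom_sizes(config.assembly)
    if per_replicate is None:
        per_replicate = []
        for j in range(len(config.alignments)):
            tracks: Dict[Tuple[str, str], StrandedCoverageTrack] = {}
            for chrom in assembly.chrom_names:
                for strand in (FORWARD, REVERSE):
                    path = _track_path(outdir, f"rep{j + 1}.{chrom}", strand)
                    if os.path.exists(path):
                        for t in read_bedgraph(path, strand, j):
                            tracks[(t.chrom, strand)] = t
            per_replicate.append(tracks)
    keys = sorted({key for tracks in per_replicate for key in tracks})
    consolidated: Dict[Tuple[str, str], StrandedCoverageTrack] = {}
    for chrom, strand in keys:
        replicate_tracks = [
            tracks.get(
                (chrom, strand),
                StrandedCoverageTrack(chrom, strand, replicate_id=j),
            )
            for j, tracks in enumerate(per_replicate)
        ]
        matrix = ReplicateSignalMatrix.from_tracks(replicate_tracks)
        track = consolidate(matrix, config.method, config.pooled_proportions)
        consolidated[(chrom, strand)] = track
        write_bedgraph(track, _track_path(outdir, f"consolidated.{chrom}", strand))
    return consolidated


def _load_consolidated(
    config: RunConfig, outdir: str
) -> Dict[Tuple[str, str], StrandedCoverageTrack]:
    assembly = GenomeAssembly.from_chrom_sizes(config.assembly)
    out: Dict[Tuple[str, str], StrandedCoverageTrack] = {}
    for chrom in assembly.chrom_names:
        for strand in (FORWARD, REVERSE):
            path = _track_path(outdir, f"consolidated.{chrom}", strand)
            if os.path.exists(path):
                for t in read_bedgraph(path, strand, "consolidated"):
                    out[(t.chrom, strand)] = t
    return out


def stage_callborders(
    config: RunConfig,
    outdir: str,
    consolidated: Optional[Dict[Tuple[str, str], StrandedCoverageTrack]] = None,
) -> List[CandidateRegion]:
    """Segment candidate loci and call Chebyshev border peaks; writes
    borders.bed (BED6 + k + pseudo_p)."""
    os.makedirs(outdir, exist_ok=True)
    assembly = GenomeAssembly.from_chrom_sizes(config.assembly)
    if consolidated is None:
        consolidated = _load_consolidated(config, outdir)
    lengths = assembly.lengths
    regions: List[CandidateRegion] = []
    for chrom in assembly.chrom_names:
        fwd = consolidated.get(
            (chrom, FORWARD), StrandedCoverageTrack(chrom, FORWARD)
        )
        rev = consolidated.get(
            (chrom, REVERSE), StrandedCoverageTrack(chrom, REVERSE)
        )
        if len(fwd.positions) == 0 and len(rev.positions) == 0:
            continue
        for region in segment_candidate_regions(
            fwd, rev, config.min_signal, config.merge_gap, config.bg_flank,
            lengths[chrom],
        ):
            regions.append(call_border_peaks(region, fwd, rev, config.alpha))
    peaks = [p for r in regions for ps in r.peaks.values() for p in ps]
    write_peaks_bed(peaks, os.path.join(outdir, "borders.bed"))
    logger.info("callborders: %d regions, %d border peaks", len(regions), len(peaks))
    return regions


def stage_pairborders(
    config: RunConfig,
    outdir: str,
    regions: Optional[List[CandidateRegion]] = None,
) -> Tuple[List[BorderPair], PairSizeModel]:
    """Fit the pair-size mixture and stable-match borders into pairs;
    writes pairs.bed and the size-model sidecar."""
    os.makedirs(outdir, exist_ok=True)
    if regions is None:
        regions = stage_callborders(config, outdir)
    sizes = high_confidence_sizes(regions)
    if config.mu_t is not None:
        sigma = config.sigma_t if config.sigma_t is not None else 1.0
        model = PairSizeModel(
            np.array([config.mu_t]), np.array([max(sigma, 1e-3)]),
            np.array([1.0]), config.kernel_width,
        )
    else:
        model = estimate_pair_size_model(
            sizes,
            n_components=config.n_components,
            seed=config.seed,
            kernel_width=config.kernel_width,
        )
    model.to_sidecar(os.path.join(outdir, "pair_size_model.txt"), sizes)
    pairs = call_border_pairs(regions, model, config.alpha_pair, config.max_span)
    write_pairs_bed(pairs, os.path.join(outdir, "pairs.bed"))
    logger.info(
        "pairborders: mu_T=%.2f sigma_T=%.2f, %d pairs", model.mu_t,
        model.sigma_t, len(pairs),
    )
    return pairs, model


def _md5(path: str) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig, outdir: str) -> Tuple[List[BorderPair], PairSizeModel]:
    """preprocess -> consolidate -> callborders -> pairborders.

    Writes all stage outputs plus a manifest (version, parameters, input
    checksums).  Identical config + inputs give identical outputs.
    """
    os.makedirs(outdir, exist_ok=True)
    for path in (config.assembly, *config.alignments):
        if not os.path.exists(path):
            raise PipelineError(f"run: missing input file {path}")
    per_replicate = stage_preprocess(config, outdir)
    consolidated = stage_consolidate(config, outdir, per_replicate)
    regions = stage_callborders(config, outdir, consolidated)
    pairs, model = stage_pairborders(config, outdir, regions)
    with open(os.path.join(outdir, "manifest.tsv"), "w") as handle:
        handle.write(f"version\t{__version__}\n")
        for f in dataclasses.fields(config):
            value = getattr(config, f.name)
            if f.name == "alignments":
                value = ",".join(value)
            handle.write(f"param.{f.name}\t{value}\n")
        for path in (config.assembly, *config.alignments):
            handle.write(f"input.{os.path.basename(path)}\t{_md5(path)}\n")
    return pairs, model
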