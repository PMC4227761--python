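"""Replicate consolidation by Shannon relative entropy.

At each covered position the normalized replicate signals v_ij = C_ij F_j W_i
are combined into one consolidated value

    S_i = (1/n) * sum_j v_ij  *  H(p) / H_max,

where p_j = v_ij / sum_j v_ij, H is Shannon entropy in nats and
H_max = ln n.  The entropy ratio is a 0-1 reproducibility weight: 1 when
all replicates agree exactly, 0 when a single replicate carries all the
signal.  Spurious positions supported by one replicate are thereby
suppressed while reproducible borders are preserved.

Arithmetic mean (AM), geometric mean (GM) and signal-to-noise ratio (SNR)
are provided as benchmarking comparators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .coverage_io import StrandedCoverageTrack

logger = logging.getLogger(__name__)

METHODS = ("entropy", "am", "gm", "snr")
SNR_CAP_FACTOR = 1.0e3  # zero-stdev cap: mean * 1e3 (comparator only)


def shannon_entropy(proportions: Sequence[float]) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0.

    ``proportions`` must be nonnegative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(proportions, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("negative proportion")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class ReplicateSignalMatrix:
    """Normalized replicate signals over the union of covered positions
    of one chromosome + strand; column j holds v_ij for replicate j."""

    chrom: str
    strand: str
    positions: np.ndarray  # (n_pos,) sorted
    values: np.ndarray  # (n_pos, n_replicates)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != self.positions.shape[0]:
            raise ValueError("row count must match position count")
        if np.any(self.values < 0):
            raise ValueError("negative normalized signal")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tracks(cls, tracks: Sequence[StrandedCoverageTrack]) -> "ReplicateSignalMatrix":
        """Align replicate tracks on the union of their covered positions."""
        if not tracks:
            raise ValueError("no tracks given")
        chrom, strand = tracks[0].chrom, tracks[0].strand
        for t in tracks[1:]:
            if (t.chrom, t.strand) != (chrom, strand):
                raise ValueError(
                    "mismatched tracks: all replicates must share chromosome "
                    f"and strand, got ({t.chrom},{t.strand}) vs ({chrom},{strand})"
                )
        union = np.unique(np.concatenate([t.positions for t in tracks]))
        mat = np.zeros((len(union), len(tracks)), dtype=np.float64)
        for j, t in enumerate(tracks):
            idx = np.searchsorted(union, t.positions)
            mat[idx, j] = t.values
        return cls(chrom, strand, union, mat)


def _entropy_weights(v: np.ndarray, pooled: bool) -> np.ndarray:
    """Per-position relative-entropy weight H(p)/ln n in [0, 1]."""
    n = v.shape[1]
    if n == 1:
        logger.warning("single replicate: entropy weight fixed at 1 (pass-through)")
        return np.ones(v.shape[0])
    h_max = np.log(n)
    if pooled:
        # per-locus reading: one p vector from replicate totals over the matrix
        totals = v.sum(axis=0)
        grand = totals.sum()
        if grand == 0:
            return np.zeros(v.shape[0])
        w = shannon_entropy(totals / grand) / h_max
        return np.full(v.shape[0], w)
    row_sums = v.sum(axis=1)
    weights = np.zeros(v.shape[0])
    nz = row_sums > 0
    p = v[nz] / row_sums[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    weights[nz] = -plogp.sum(axis=1) / h_max
    return np.clip(weights, 0.0, 1.0)


def consolidate(
    matrix: ReplicateSignalMatrix,
    method: str = "entropy",
    pooled_proportions: bool = False,
) -> StrandedCoverageTrack:
    """Collapse the replicate matrix into one consolidated track.

    ``pooled_proportions`` switches the entropy proportions p_j from the
    default per-position computation to a single per-locus vector pooled
    over all positions of the matrix.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    v = matrix.values
    n = matrix.n_replicates
    if n < 2 and method in ("entropy", "snr"):
        logger.warning("method %r is degenerate with a single replicate", method)

    if method == "entropy":
        s = v.mean(axis=1) * _entropy_weights(v, pooled_proportions)
    elif method == "am":
        s = v.mean(axis=1)
    elif method == "gm":
        s = np.exp(np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), -np.inf).mean(axis=1))
        s = np.where(np.any(v == 0, axis=1), 0.0, s)
    else:  # snr
        mean = v.mean(axis=1)
        sd = v.std(axis=1)  # population (1/n) denominator
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(sd > 0, mean / sd, mean * SNR_CAP_FACTOR)
        s = np.where(mean == 0, 0.0, s)

    keep = s > 0
    return StrandedCoverageTrack(
        matrix.chrom, matrix.strand, matrix.positions[keep], s[keep], "consolidated"
    )


def consolidate_tracks(
    tracks: Sequence[StrandedCoverageTrack],
    method: str = "entropy",
    pooled_proportions: bool = False,
) -> StrandedCoverageTrack:
    """Convenience wrapper: align replicate tracks, then consolidate."""
    return consolidate(
        ReplicateSignalMatrix.from_tracks(tracks), method, pooled_proportions
    )
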