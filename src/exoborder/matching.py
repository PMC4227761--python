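"""Border matching: pair forward and reverse borders into binding sites.

A binding site is demarcated by one forward border and one downstream
reverse border.  Because binding-site width is roughly constant genome-wide,
the expected pair size mu_T is first estimated from high-confidence pairs
(loci with exactly one significant border per strand) with a 1-D Gaussian
mixture fitted by EM -- the size distribution usually has more than one
mode, e.g. outer and inner exonuclease stops.  Candidate pairs are scored

    S_weighted = S_obs * exp(-(d_obs - mu_T)^2 / K^2),

penalizing sizes far from expectation, and matched with the Gale-Shapley
algorithm (forward borders proposing), which guarantees a stable matching:
no forward/reverse pair both prefer each other over their assigned
partners.  Since the two exonuclease digestions are independent events, the
two border pseudo p-values are combined by Fisher's method, whose closed
form for two p-values is q (1 - ln q) with q = p1 p2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detection import BorderPeak, CandidateRegion
from .coverage_io import FORWARD, REVERSE

logger = logging.getLogger(__name__)

MIN_HIGH_CONFIDENCE_SIZES = 20
DEFAULT_N_COMPONENTS = 2
DEFAULT_EM_TOL = 1e-8
DEFAULT_EM_MAX_ITER = 500
DEFAULT_EM_RESTARTS = 8
VARIANCE_FLOOR = 1e-6
PREFIT_MAX_SPAN = 500  # bp cap on candidate pairs before the size model exists
DEFAULT_ALPHA_PAIR = 0.05


@dataclass
class PairSizeModel:
    """Gaussian-mixture fit of border-pair sizes.

    mu_T / sigma_T come from the highest-weight component; the weighting
    kernel width K defaults to 2 sigma_T (floored at 1 bp so a near-point
    size distribution still admits K > 0).
    """

    means: np.ndarray
    sds: np.ndarray
    mixing: np.ndarray
    kernel_width: Optional[float] = None
    log_likelihood_path: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if np.any(self.mixing <= 0) or abs(self.mixing.sum() - 1) > 1e-6:
            raise ValueError("mixing weights must be positive and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")

    @property
    def dominant(self) -> int:
        return int(np.argmax(self.mixing))

    @property
    def mu_t(self) -> float:
        return float(self.means[self.dominant])

    @property
    def sigma_t(self) -> float:
        return float(self.sds[self.dominant])

    @property
    def k_width(self) -> float:
        if self.kernel_width is not None:
            return self.kernel_width
        return max(2.0 * self.sigma_t, 1.0)

    def max_span(self) -> int:
        return int(math.ceil(self.mu_t + 4.0 * self.sigma_t))

    def to_sidecar(self, path, sizes: Sequence[float] = ()) -> None:
        """Audit dump: fitted parameters plus the input size list."""
        with open(path, "w") as handle:
            handle.write("# pair size model\n")
            handle.write(f"mu_T\t{self.mu_t:.6g}\n")
            handle.write(f"sigma_T\t{self.sigma_t:.6g}\n")
            handle.write(f"kernel_width\t{self.k_width:.6g}\n")
            for c, (m, s, w) in enumerate(zip(self.means, self.sds, self.mixing)):
                handle.write(f"component_{c}\tmean={m:.6g}\tsd={s:.6g}\tweight={w:.6g}\n")
            if sizes:
                handle.write("# high-confidence sizes\n")
                handle.write("\t".join(str(int(s)) for s in sizes) + "\n")


def _gmm_log_likelihood(x: np.ndarray, means, sds, mixing) -> float:
    dens = np.zeros(len(x))
    for m, s, w in zip(means, sds, mixing):
        dens += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    return float(np.log(np.maximum(dens, 1e-300)).sum())


def _em_once(
    x: np.ndarray,
    n_components: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[float], bool]:
    means = rng.choice(x, size=n_components, replace=len(x) < n_components)
    means = means + rng.normal(0, 1e-3, n_components)  # break exact ties
    overall_var = max(float(x.var()), VARIANCE_FLOOR)
    variances = np.full(n_components, overall_var)
    mixing = np.full(n_components, 1.0 / n_components)

    path: List[float] = []
    prev_ll = -np.inf
    floored = False
    for _ in range(max_iter):
        # E step
        log_resp = np.empty((len(x), n_components))
        for c in range(n_components):
            log_resp[:, c] = (
                math.log(mixing[c])
                - 0.5 * math.log(2 * math.pi * variances[c])
                - 0.5 * (x - means[c]) ** 2 / variances[c]
            )
        log_norm = np.logaddexp.reduce(log_resp, axis=1)
        ll = float(log_norm.sum())
        path.append(ll)
        resp = np.exp(log_resp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0) + 1e-12
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        if np.any(variances < VARIANCE_FLOOR):
            floored = True
            variances = np.maximum(variances, VARIANCE_FLOOR)
        mixing = nk / nk.sum()
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return means, variances, mixing, path, floored


def estimate_pair_size_model(
    sizes: Sequence[float],
    n_components: int = DEFAULT_N_COMPONENTS,
    tol: float = DEFAULT_EM_TOL,
    max_iter: int = DEFAULT_EM_MAX_ITER,
    seed: int = 0,
    kernel_width: Optional[float] = None,
    n_restarts: int = DEFAULT_EM_RESTARTS,
) -> PairSizeModel:
    """Fit a 1-D Gaussian mixture to high-confidence pair sizes by EM.

    Initial means are drawn from the data with a seeded generator and the
    best of ``n_restarts`` runs (highest final log-likelihood) is kept, so
    the fit is deterministic given the seed.  Within a run the
    log-likelihood is nondecreasing across iterations (recorded in
    ``log_likelihood_path``); convergence when its increase drops below
    ``tol``.  Collapsing components are floored at variance 1e-6 with a
    warning.  Fewer than 20 sizes is an error: supply mu_T manually.
    """
    x = np.asarray(sizes, dtype=np.float64)
    if len(x) < MIN_HIGH_CONFIDENCE_SIZES:
        raise ValueError(
            f"only {len(x)} high-confidence pair sizes (< "
            f"{MIN_HIGH_CONFIDENCE_SIZES}); set the expected size manually "
            "(--mu-t)"
        )
    if n_components < 1:
        raise ValueError("need at least one mixture component")

    if n_components == 1:
        mean = float(x.mean())
        sd = float(max(x.std(), math.sqrt(VARIANCE_FLOOR)))
        model = PairSizeModel(
            np.array([mean]), np.array([sd]), np.array([1.0]), kernel_width
        )
        model.log_likelihood_path = [
            _gmm_log_likelihood(x, model.means, model.sds, model.mixing)
        ]
        return model

    rng = np.random.default_rng(seed)
    best = None
    any_floored = False
    for _ in range(max(1, n_restarts)):
        means, variances, mixing, path, floored = _em_once(
            x, n_components, tol, max_iter, rng
        )
        any_floored = any_floored or floored
        if best is None or path[-1] > best[3][-1]:
            best = (means, variances, mixing, path)
    if any_floored:
        logger.warning("EM component variance collapsed; floored at %g", VARIANCE_FLOOR)

    means, variances, mixing, path = best
    model = PairSizeModel(means, np.sqrt(variances), mixing, kernel_width)
    model.log_likelihood_path = path
    return model


def weight_pair_score(s_obs: float, d_obs: float, model: PairSizeModel) -> float:
    """S_weighted = S_obs * exp(-(d_obs - mu_T)^2 / K^2)."""
    if s_obs < 0:
        raise ValueError("S_obs must be nonnegative")
    k = model.k_width
    return s_obs * math.exp(-((d_obs - model.mu_t) ** 2) / (k * k))


def fisher_combine(p_forward: float, p_reverse: float) -> float:
    """Fisher combination of two p-values: q (1 - ln q), q = p1 p2.

    This is the closed-form chi-square (4 df) tail of Fisher's statistic
    -2 ln q.  Inputs must lie in (0, 1].
    """
    for p in (p_forward, p_reverse):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
    q = p_forward * p_reverse
    return min(1.0, q * (1.0 - math.log(q)))


@dataclass(frozen=True)
class BorderPair:
    """A matched forward + downstream reverse border demarcating a site."""

    forward: BorderPeak
    reverse: BorderPeak
    s_obs: float
    s_weighted: float
    p_pair: float

    @property
    def chrom(self) -> str:
        return self.forward.chrom

    @property
    def size(self) -> int:
        # inclusive span: borders on the first and last base of a site of
        # width w give d_obs = w
        return self.reverse.position - self.forward.position + 1


def pair_size(forward: BorderPeak, reverse: BorderPeak) -> int:
    return reverse.position - forward.position + 1


def _preferences(
    forward: Sequence[BorderPeak],
    reverse: Sequence[BorderPeak],
    model: PairSizeModel,
    max_span: int,
) -> Tuple[Dict[int, List[int]], Dict[int, List[int]], Dict[Tuple[int, int], float]]:
    """Admissible pairs and both sides' preference orders.

    Preference: descending S_weighted; ties broken by smaller
    |d_obs - mu_T|, then by smaller partner coordinate.
    """
    scores: Dict[Tuple[int, int], float] = {}
    for fi, f in enumerate(forward):
        for ri, r in enumerate(reverse):
            d = pair_size(f, r)
            if f.position <= r.position and d <= max_span:
                scores[(fi, ri)] = weight_pair_score(f.signal + r.signal, d, model)

    def rank_key(f: BorderPeak, r: BorderPeak, fi: int, ri: int, partner: BorderPeak):
        return (-scores[(fi, ri)], abs(pair_size(f, r) - model.mu_t), partner.position)

    fwd_prefs = {
        fi: sorted(
            (ri for (fj, ri) in scores if fj == fi),
            key=lambda ri: rank_key(forward[fi], reverse[ri], fi, ri, reverse[ri]),
        )
        for fi in range(len(forward))
    }
    rev_prefs = {
        ri: sorted(
            (fi for (fi, rj) in scores if rj == ri),
            key=lambda fi: rank_key(forward[fi], reverse[ri], fi, ri, forward[fi]),
        )
        for ri in range(len(reverse))
    }
    return fwd_prefs, rev_prefs, scores


def stable_match(
    forward: Sequence[BorderPeak],
    reverse: Sequence[BorderPeak],
    model: PairSizeModel,
    max_span: Optional[int] = None,
) -> List[BorderPair]:
    """Gale-Shapley stable matching of forward to reverse borders.

    Forward borders propose.  Candidate pairs are restricted to
    forward.position <= reverse.position and inclusive span <= max_span
    (default: mu_T + 4 sigma_T from the model).  The result is stable: no
    admissible (forward, reverse) pair both prefer each other over their
    assigned partners; each border appears in at most one pair.
    """
    if not forward or not reverse:
        return []
    if max_span is None:
        max_span = model.max_span()
    fwd_prefs, rev_prefs, scores = _preferences(forward, reverse, model, max_span)
    rev_rank = {
        ri: {fi: k for k, fi in enumerate(prefs)} for ri, prefs in rev_prefs.items()
    }

    engaged_rev: Dict[int, int] = {}  # reverse index -> forward index
    next_proposal = {fi: 0 for fi in fwd_prefs}
    free = [fi for fi, prefs in fwd_prefs.items() if prefs]
    while free:
        fi = free.pop()
        prefs = fwd_prefs[fi]
        while next_proposal[fi] < len(prefs):
            ri = prefs[next_proposal[fi]]
            next_proposal[fi] += 1
            if ri not in engaged_rev:
                engaged_rev[ri] = fi
                break
            incumbent = engaged_rev[ri]
            if rev_rank[ri][fi] < rev_rank[ri][incumbent]:
                engaged_rev[ri] = fi
                if next_proposal[incumbent] < len(fwd_prefs[incumbent]):
                    free.append(incumbent)
                break

    pairs: List[BorderPair] = []
    for ri, fi in engaged_rev.items():
        f, r = forward[fi], reverse[ri]
        s_obs = f.signal + r.signal
        pairs.append(
            BorderPair(
                f, r, s_obs, scores[(fi, ri)], fisher_combine(f.pseudo_p, r.pseudo_p)
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.forward.position))
    return pairs


def high_confidence_sizes(regions: Sequence[CandidateRegion]) -> List[int]:
    """Pair sizes from loci with exactly one border per strand -- pairs
    that can be matched unambiguously."""
    sizes: List[int] = []
    for region in regions:
        fwd = region.peaks.get(FORWARD, [])
        rev = region.peaks.get(REVERSE, [])
        if len(fwd) == 1 and len(rev) == 1 and fwd[0].position <= rev[0].position:
            d = pair_size(fwd[0], rev[0])
            if d <= PREFIT_MAX_SPAN:
                sizes.append(d)
    return sizes


def call_border_pairs(
    regions: Sequence[CandidateRegion],
    model: PairSizeModel,
    alpha_pair: float = DEFAULT_ALPHA_PAIR,
    max_span: Optional[int] = None,
) -> List[BorderPair]:
    """Stable-match each region's borders and keep pairs with
    p_pair <= alpha_pair, sorted by (chrom, start)."""
    pairs: List[BorderPair] = []
    for region in regions:
        matched = stable_match(
            region.peaks.get(FORWARD, []),
            region.peaks.get(REVERSE, []),
            model,
            max_span,
        )
        pairs.extend(p for p in matched if p.p_pair <= alpha_pair)
    pairs.sort(key=lambda p: (p.chrom, p.forward.position))
    return pairs


def write_pairs_bed(pairs: Sequence[BorderPair], path) -> None:
    """BED6+4: p_forward, p_reverse, p_pair, S_weighted; strand '.'."""
    with open(path, "w") as handle:
        for i, pair in enumerate(pairs):
            score = int(round(-10.0 * math.log10(max(pair.p_pair, 1e-300))))
            handle.write(
                f"{pair.chrom}\t{pair.forward.position}"
                f"\t{pair.reverse.position + 1}\tpair_{i + 1}\t{score}\t."
                f"\t{pair.forward.pseudo_p:.4g}\t{pair.reverse.pseudo_p:.4g}"
                f"\t{pair.p_pair:.4g}\t{pair.s_weighted:.4g}\n"
            )
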