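"""Pair-size EM, kernel weighting, Gale-Shapley matching, Fisher scores."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from exoborder import (
    PairSizeModel,
    call_border_pairs,
    estimate_pair_size_model,
    fisher_combine,
    stable_match,
    weight_pair_score,
)
from exoborder.detection import CandidateRegion
from exoborder.matching import high_confidence_sizes, pair_size

from conftest import make_peak


def _model(mu=49.0, sigma=2.0, K=None):
    return PairSizeModel(
        np.array([mu]), np.array([sigma]), np.array([1.0]), kernel_width=K
    )


class TestPairSizeEM:
    def test_point_mass_recovers_exact_size(self):
        model = estimate_pair_size_model([49.0] * 40, n_components=2, seed=1)
        assert model.mu_t == pytest.approx(49.0, abs=1e-3)
        assert model.mixing[model.dominant] > 0.5

    def test_two_component_parameter_recovery(self, rng):
        draws = np.concatenate(
            [rng.normal(49, 2, 300), rng.normal(13, 2, 200)]
        )
        model = estimate_pair_size_model(draws, n_components=2, seed=7)
        assert 48.0 <= model.mu_t <= 50.0
        assert sorted(model.means.round(0).tolist()) == pytest.approx(
            [13.0, 49.0], abs=1.0
        )

    def test_loglik_nondecreasing_every_iteration(self, rng):
        draws = np.concatenate([rng.normal(49, 2, 300), rng.normal(13, 2, 200)])
        model = estimate_pair_size_model(draws, n_components=2, seed=7)
        path = model.log_likelihood_path
        assert len(path) >= 2
        assert all(b >= a - 1e-8 for a, b in zip(path, path[1:]))

    def test_matches_sklearn_mixture_oracle(self, rng):
        from sklearn.mixture import GaussianMixture

        draws = np.concatenate([rng.normal(49, 2, 300), rng.normal(13, 2, 200)])
        model = estimate_pair_size_model(draws, n_components=2, seed=7)
        oracle = GaussianMixture(2, random_state=0, n_init=5).fit(draws[:, None])
        dominant = int(np.argmax(oracle.weights_))
        assert model.mu_t == pytest.approx(
            float(oracle.means_[dominant, 0]), abs=0.5
        )

    def test_single_component_closed_form(self, rng):
        draws = rng.normal(30, 4, 100)
        model = estimate_pair_size_model(draws, n_components=1)
        assert model.mu_t == pytest.approx(draws.mean())
        assert model.sigma_t == pytest.approx(draws.std())

    def test_too_few_sizes_is_error(self):
        with pytest.raises(ValueError, match="mu-t"):
            estimate_pair_size_model([49.0] * 10)

    def test_deterministic_given_seed(self, rng):
        draws = rng.normal(49, 3, 100)
        a = estimate_pair_size_model(draws, seed=3)
        b = estimate_pair_size_model(draws, seed=3)
        np.testing.assert_array_equal(a.means, b.means)


class TestWeightPairScore:
    def test_kernel_center_is_identity(self):
        assert weight_pair_score(10.0, 49.0, _model()) == 10.0

    def test_one_kernel_width_away(self):
        model = _model(K=6.0)
        assert weight_pair_score(10.0, 55.0, model) == pytest.approx(10 * math.exp(-1))
        assert weight_pair_score(10.0, 55.0, model) == pytest.approx(3.679, abs=5e-4)

    def test_symmetric_and_decreasing_in_distance(self):
        model = _model(K=6.0)
        for d in (1, 3, 7, 12):
            assert weight_pair_score(10, 49 + d, model) == pytest.approx(
                weight_pair_score(10, 49 - d, model)
            )
        weights = [weight_pair_score(10, 49 + d, model) for d in range(0, 15)]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_default_kernel_is_twice_sigma(self):
        assert _model(sigma=3.0).k_width == 6.0
        assert _model(sigma=0.1).k_width == 1.0  # floored


class TestFisherCombine:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (1.0, 1.0, 1.0),
            (0.05, 0.05, 0.0025 * (1 - math.log(0.0025))),
            (0.01, 1.0, 0.01 * (1 - math.log(0.01))),
        ],
    )
    def test_closed_form(self, p1, p2, expected):
        assert fisher_combine(p1, p2) == pytest.approx(expected, rel=1e-12)

    def test_equals_chi_square_tail_oracle(self):
        # Fisher's statistic -2 ln(p1 p2) ~ chi^2 with 4 df
        grid = np.geomspace(1e-8, 1.0, 40)
        for p1, p2 in itertools.product(grid, repeat=2):
            oracle = stats.chi2.sf(-2.0 * math.log(p1 * p2), df=4)
            assert abs(fisher_combine(p1, p2) - oracle) < 1e-10

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fisher_combine(bad, 0.5)
        with pytest.raises(ValueError):
            fisher_combine(0.5, bad)

    def test_monotone_and_bounded(self):
        grid = np.geomspace(1e-6, 1.0, 25)
        for p2 in grid:
            vals = [fisher_combine(p1, p2) for p1 in grid]
            assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))
            for p1, v in zip(grid, vals):
                assert p1 * p2 - 1e-15 <= v <= 1.0


def _is_stable(matching, forward, reverse, model, max_span):
    """Brute-force blocking-pair check over all admissible pairs."""
    def score(f, r):
        return weight_pair_score(f.signal + r.signal, pair_size(f, r), model)

    matched_f = {id(p.forward): p.reverse for p in matching}
    matched_r = {id(p.reverse): p.forward for p in matching}
    for f in forward:
        for r in reverse:
            if f.position > r.position or pair_size(f, r) > max_span:
                continue
            cur_r = matched_f.get(id(f))
            cur_f = matched_r.get(id(r))
            f_prefers = cur_r is None or score(f, r) > score(f, cur_r)
            r_prefers = cur_f is None or score(f, r) > score(cur_f, r)
            if f_prefers and r_prefers:
                return False
    return True


class TestStableMatch:
    def test_singleton_pair(self):
        pairs = stable_match([make_peak(100)], [make_peak(148, "-")], _model())
        assert len(pairs) == 1 and pairs[0].size == 49

    def test_no_downstream_reverse_gives_no_pairs(self):
        pairs = stable_match([make_peak(100)], [make_peak(50, "-")], _model())
        assert pairs == []

    def test_empty_side_gives_empty_output(self):
        assert stable_match([], [make_peak(50, "-")], _model()) == []
        assert stable_match([make_peak(50)], [], _model()) == []

    def test_max_span_excludes_distant_pairs(self):
        pairs = stable_match(
            [make_peak(100)], [make_peak(400, "-")], _model(), max_span=100
        )
        assert pairs == []

    def test_each_border_used_at_most_once(self):
        forward = [make_peak(p, signal=s) for p, s in [(100, 10), (105, 8)]]
        reverse = [make_peak(150, "-", signal=20)]
        pairs = stable_match(forward, reverse, _model(), max_span=200)
        assert len(pairs) == 1

    def test_random_instances_are_stable_by_enumeration(self, rng):
        # 200 random instances up to 5x5; exhaustively verify no blocking pair
        model = _model(mu=49, sigma=5, K=10.0)
        for _ in range(200):
            nf, nr = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            forward = [
                make_peak(int(p), signal=float(rng.uniform(1, 100)))
                for p in np.sort(rng.integers(0, 150, nf))
            ]
            reverse = [
                make_peak(int(p), "-", signal=float(rng.uniform(1, 100)))
                for p in np.sort(rng.integers(50, 260, nr))
            ]
            max_span = 250
            matching = stable_match(forward, reverse, model, max_span=max_span)
            assert _is_stable(matching, forward, reverse, model, max_span)
            used_f = [id(p.forward) for p in matching]
            used_r = [id(p.reverse) for p in matching]
            assert len(used_f) == len(set(used_f))
            assert len(used_r) == len(set(used_r))

    def test_double_stop_geometry_prefers_outer_and_inner(self):
        # two stops per strand around one site (outer F1-R1 = 49 bp,
        # inner F2-R2 = 13 bp); with mu_T at 49 the matcher must pick
        # F1-R1 + F2-R2, never the crossing F1-R2 / F2-R1 combinations
        f1, f2 = make_peak(100, signal=50.0), make_peak(118, signal=40.0)
        r1, r2 = make_peak(148, "-", signal=50.0), make_peak(130, "-", signal=40.0)
        model = _model(mu=49.0, sigma=2.0, K=10.0)
        pairs = stable_match([f1, f2], [r1, r2], model, max_span=200)
        got = {(p.forward.position, p.reverse.position) for p in pairs}
        assert got == {(100, 148), (118, 130)}


class TestCallBorderPairs:
    def _region(self, fwd_peaks, rev_peaks, start=0, end=300):
        region = CandidateRegion("chr1", start, end)
        region.peaks = {"+": fwd_peaks, "-": rev_peaks}
        return region

    def test_region_without_reverse_borders_gives_nothing(self):
        regions = [self._region([make_peak(100)], [])]
        assert call_border_pairs(regions, _model()) == []

    def test_pair_scores_and_filtering(self):
        f = make_peak(100, signal=30.0, k=10.0)
        r = make_peak(148, "-", signal=20.0, k=10.0)
        weak_f = make_peak(500, signal=5.0, k=1.5)
        weak_r = make_peak(548, "-", signal=5.0, k=1.5)
        regions = [
            self._region([f], [r]),
            self._region([weak_f], [weak_r], 400, 700),
        ]
        pairs = call_border_pairs(regions, _model(), alpha_pair=0.05)
        (pair,) = pairs  # weak pair (p = 0.44 each) fails the cutoff
        assert pair.s_obs == 50.0
        assert pair.s_weighted == pytest.approx(50.0)  # d == mu_T
        assert pair.p_pair == pytest.approx(fisher_combine(0.01, 0.01))

    def test_output_sorted_by_coordinate(self):
        regions = [
            self._region([make_peak(500)], [make_peak(548, "-")], 400, 700),
            self._region([make_peak(100)], [make_peak(148, "-")]),
        ]
        pairs = call_border_pairs(regions, _model())
        assert [p.forward.position for p in pairs] == [100, 500]

    def test_high_confidence_sizes_from_unambiguous_regions(self):
        regions = [
            self._region([make_peak(100)], [make_peak(148, "-")]),
            self._region([make_peak(10), make_peak(20)], [make_peak(60, "-")]),
            self._region([make_peak(700)], [make_peak(650, "-")]),
        ]
        assert high_confidence_sizes(regions) == [49]
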