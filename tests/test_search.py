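"""Monotone count-grid construction and exhaustive optimization."""

import itertools

import numpy as np
import pytest

from crmscan import (CRMConfig, HashGrid, PairTriple, PromoterSet,
                     SearchGrids, SearchParams, SequenceRecord, build_hash,
                     compute_presence, feasible_region, optimize_pair,
                     pwm_from_consensus, search_all_pairs, sequence_indicator)
from crmscan.search import _close_boxes

from conftest import make_random_pwm

COARSE = SearchGrids((0.5, 0.6, 0.7, 0.8, 0.9, 1.0), (0, 10, 20, 30))


def brute_indicator(triples, grids):
    """Cell-by-cell evaluation of the existential definition."""
    g = np.zeros(grids.shape, dtype=bool)
    for i, t1 in enumerate(grids.thr_values):
        for j, t2 in enumerate(grids.thr_values):
            for k, d in enumerate(grids.dist_values):
                g[i, j, k] = any(t.s1 >= t1 and t.s2 >= t2 and t.gap <= d
                                 for t in triples)
    return g


def random_monotone_grid(rng, grids, n):
    """A valid count grid: sum of n random single-sequence indicators."""
    counts = np.zeros(grids.shape, dtype=np.int64)
    for _ in range(n):
        trips = [PairTriple(rng.uniform(0.4, 1.0), rng.uniform(0.4, 1.0),
                            int(rng.integers(0, 40)))
                 for _ in range(rng.integers(0, 5))]
        counts += sequence_indicator(trips, grids)
    return HashGrid(counts, n, grids)


class TestSearchGrids:
    def test_default_axes(self):
        g = SearchGrids.default()
        assert g.thr_values[0] == 0.5 and g.thr_values[-1] == 1.0
        assert len(g.thr_values) == 51
        assert g.dist_values == tuple(range(0, 201, 5))

    def test_rejects_non_ascending_or_wrong_end(self):
        with pytest.raises(ValueError):
            SearchGrids((0.5, 0.5, 1.0), (0, 10))
        with pytest.raises(ValueError):
            SearchGrids((0.5, 0.9), (0, 10))


class TestSequenceIndicator:
    def test_no_triples_all_zero(self):
        assert not sequence_indicator([], COARSE).any()

    def test_single_triple_covers_its_box(self):
        g = sequence_indicator([PairTriple(0.9, 0.8, 10)], COARSE)
        for i, t1 in enumerate(COARSE.thr_values):
            for j, t2 in enumerate(COARSE.thr_values):
                for k, d in enumerate(COARSE.dist_values):
                    assert g[i, j, k] == (t1 <= 0.9 and t2 <= 0.8 and d >= 10)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            trips = [PairTriple(rng.uniform(0.3, 1.0), rng.uniform(0.3, 1.0),
                                int(rng.integers(0, 40)))
                     for _ in range(5)]
            np.testing.assert_array_equal(sequence_indicator(trips, COARSE),
                                          brute_indicator(trips, COARSE))

    def test_score_exactly_on_grid_value_included(self):
        g = sequence_indicator([PairTriple(0.7, 1.0, 0)], COARSE)
        assert g[COARSE.thr_index(0.7), COARSE.thr_index(1.0), 0]


class TestBuildHash:
    def test_background_has_no_perfect_consensus_modules(self):
        rng = np.random.default_rng(2)
        pwms = [pwm_from_consensus("a", "ACGTGTCA"), pwm_from_consensus("b", "TTGACAGG")]
        recs = tuple(SequenceRecord(f"s{i}", "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, 120)])) for i in range(6))
        h = build_hash(PromoterSet("positive", recs), pwms[0], pwms[1], COARSE)
        i = COARSE.thr_index(1.0)
        assert not h.counts[i, i, :].any()  # no perfect pair on random background
        assert h.is_monotone()

    def test_counts_equal_brute_force_indicator_sum(self, sharp_pair):
        from crmscan.scan import pair_triples, scan_pwm
        rng = np.random.default_rng(9)
        recs = tuple(SequenceRecord(f"s{i}", "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, 150)])) for i in range(8))
        pset = PromoterSet("positive", recs)
        a, b = sharp_pair
        h = build_hash(pset, a, b, COARSE)
        expected = np.zeros(COARSE.shape, dtype=np.int64)
        for idx, rec in enumerate(pset.records):
            trips = pair_triples(scan_pwm(a, rec, 0.5, idx),
                                 scan_pwm(b, rec, 0.5, idx),
                                 a.width, b.width, 30)
            expected += brute_indicator(trips, COARSE)
        np.testing.assert_array_equal(h.counts, expected)

    def test_monotone_along_all_axes(self):
        rng = np.random.default_rng(4)
        h = random_monotone_grid(rng, COARSE, 12)
        assert h.is_monotone()
        assert np.all(h.counts >= 0) and np.all(h.counts <= h.n)


class TestFeasibleRegion:
    def test_trivial_bounds(self):
        rng = np.random.default_rng(6)
        h = random_monotone_grid(rng, COARSE, 10)
        assert feasible_region(h, 0.0, "at_least").all()
        zero = HashGrid(np.zeros(COARSE.shape, dtype=np.int64), 10, COARSE)
        assert feasible_region(zero, 1.0, "at_most").all()

    def test_matches_cellwise_comparison(self):
        rng = np.random.default_rng(7)
        h = random_monotone_grid(rng, COARSE, 8)
        np.testing.assert_array_equal(feasible_region(h, 0.75, "at_least"),
                                      h.presence >= 0.75)
        np.testing.assert_array_equal(feasible_region(h, 0.5, "at_most"),
                                      h.presence <= 0.5)

    def test_at_least_mask_is_monotone_closed(self):
        rng = np.random.default_rng(8)
        h = random_monotone_grid(rng, COARSE, 10)
        m = feasible_region(h, 0.6, "at_least")
        np.testing.assert_array_equal(m, _close_boxes(m))


class TestOptimizePair:
    def make_pwms(self):
        return pwm_from_consensus("p1", "AAAA"), pwm_from_consensus("p2", "CCCC")

    def test_all_zero_positive_grid_gives_none(self):
        p1, p2 = self.make_pwms()
        zero = HashGrid(np.zeros(COARSE.shape, dtype=np.int64), 10, COARSE)
        assert optimize_pair(zero, zero, SearchParams(grids=COARSE), p1, p2) is None

    def test_matches_full_grid_scan_on_random_grids(self):
        p1, p2 = self.make_pwms()
        params = SearchParams(grids=COARSE)
        rng = np.random.default_rng(31)
        checked_some = False
        for _ in range(25):
            hp = random_monotone_grid(rng, COARSE, 8)
            hn = random_monotone_grid(rng, COARSE, 6)
            got = optimize_pair(hp, hn, params, p1, p2)
            # independent full scan with explicit tie-break chain
            eps = params.epsilon_for(hn.n)
            best = None
            for i, j, k in itertools.product(*map(range, COARSE.shape)):
                cp = hp.counts[i, j, k] / hp.n
                cn = hn.counts[i, j, k] / hn.n
                if cp < params.c_min_pos or cn > params.c_max_neg:
                    continue
                t1, t2 = COARSE.thr_values[i], COARSE.thr_values[j]
                d = COARSE.dist_values[k]
                key = (-cp / max(cn, eps), -cp, -(t1 + t2), d, t1)
                if best is None or key < best[0]:
                    best = (key, (t1, t2, d, cp, cn))
            if best is None:
                assert got is None
            else:
                checked_some = True
                t1, t2, d, cp, cn = best[1]
                assert (got.config.thr1, got.config.thr2, got.config.d) == (t1, t2, d)
                assert (got.c_pos, got.c_neg) == (cp, cn)
                assert got.ratio == cp / max(cn, eps)
        assert checked_some

    def test_grid_shape_mismatch_raises(self):
        p1, p2 = self.make_pwms()
        other = SearchGrids((0.5, 1.0), (0, 10))
        hp = HashGrid(np.zeros(COARSE.shape, dtype=np.int64), 5, COARSE)
        hn = HashGrid(np.zeros(other.shape, dtype=np.int64), 5, other)
        with pytest.raises(ValueError):
            optimize_pair(hp, hn, SearchParams(grids=COARSE), p1, p2)


class TestSearchAllPairs:
    def test_single_pwm_examines_only_homotypic_pair(self, sharp_pair):
        rng = np.random.default_rng(41)
        recs = tuple(SequenceRecord(f"s{i}", "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, 100)])) for i in range(4))
        pos = PromoterSet("positive", recs)
        neg = PromoterSet("negative", tuple(
            SequenceRecord(f"n{i}", r.residues) for i, r in enumerate(recs)))
        res = search_all_pairs(pos, neg, sharp_pair[:1], SearchParams(grids=COARSE))
        assert len(res) <= 1

    def test_empty_library_raises(self, small_set):
        with pytest.raises(ValueError):
            search_all_pairs(small_set, small_set, [], SearchParams(grids=COARSE))

    def test_presences_are_multiples_of_one_over_n(self, sharp_pair):
        from crmscan import SyntheticSpec, generate_sets
        spec = SyntheticSpec(pwm_pair=("ALPHA", "BETA"), n_pos=10, n_neg=8,
                             seq_len=200, seed=3)
        pos, neg, _ = generate_sets(spec, sharp_pair)
        res = search_all_pairs(pos, neg, sharp_pair,
                               SearchParams(grids=COARSE))
        assert res, "implanted pair should be found"
        for r in res:
            assert (r.c_pos * pos.n) == pytest.approx(round(r.c_pos * pos.n))
            assert (r.c_neg * neg.n) == pytest.approx(round(r.c_neg * neg.n))
            assert 0 <= r.c_neg <= r.c_pos <= 1

    def test_presence_recomputation_matches_grid(self, sharp_pair):
        from crmscan import SyntheticSpec, generate_sets
        spec = SyntheticSpec(pwm_pair=("ALPHA", "BETA"), n_pos=8, n_neg=8,
                             seq_len=200, seed=5)
        pos, neg, _ = generate_sets(spec, sharp_pair)
        res = search_all_pairs(pos, neg, sharp_pair, SearchParams(grids=COARSE))
        top = res[0]
        assert compute_presence(pos, top.config, sharp_pair) == top.c_pos
        assert compute_presence(neg, top.config, sharp_pair) == top.c_neg

    def test_unknown_pwm_name_in_presence_raises(self, small_set, sharp_pair):
        cfg = CRMConfig("nope", "BETA", 0.9, 0.9, 10)
        with pytest.raises(ValueError, match="nope"):
            compute_presence(small_set, cfg, sharp_pair)
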