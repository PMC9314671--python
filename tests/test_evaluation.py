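"""Fold construction, AUC, Boyce index, and max-SSS thresholding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_grid
from cryosdm import evaluation
from cryosdm.errors import (
    DegenerateBlockError,
    DegenerateThresholdError,
    EvaluationError,
    FoldError,
)
from cryosdm.grid import LAEA_NORTH_POLE


class TestRandomFolds:
    def test_balanced_sizes(self):
        cells = [(0, i) for i in range(10)]
        fa = evaluation.random_folds(cells, k=5, seed=0)
        sizes = np.bincount(fa.fold)[1:]
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_same_seed_identical(self):
        cells = [(0, i) for i in range(23)]
        a = evaluation.random_folds(cells, k=5, seed=9)
        b = evaluation.random_folds(cells, k=5, seed=9)
        np.testing.assert_array_equal(a.fold, b.fold)

    def test_size_multiset_matches_balanced_partition(self):
        for n, k in [(23, 5), (10, 3), (7, 7)]:
            fa = evaluation.random_folds([(0, i) for i in range(n)], k=k, seed=1)
            sizes = sorted(np.bincount(fa.fold)[1:])
            base, extra = divmod(n, k)
            assert sizes == sorted([base + 1] * extra + [base] * (k - extra))

    def test_too_few_cells_raise(self):
        with pytest.raises(FoldError):
            evaluation.random_folds([(0, 0)], k=5, seed=0)


class TestSpatialBlockFolds:
    def _grid(self):
        return make_grid(100, 100, x0=0.0, y_top=5000.0, cell=50.0,
                         crs=LAEA_NORTH_POLE)

    def test_cells_in_same_block_share_fold(self, rng):
        grid = self._grid()
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 100, 200), rng.integers(0, 100, 200))]
        fa = evaluation.spatial_block_folds(cells, grid, block_size_km=300, k=5, seed=0)
        x, y = grid.rowcol_to_xy(fa.cells[:, 0], fa.cells[:, 1])
        block = np.floor(x / 300).astype(int) * 1000 + np.floor(y / 300).astype(int)
        for b in np.unique(block):
            assert np.unique(fa.fold[block == b]).size == 1

    def test_five_separated_clusters_fill_five_folds(self):
        grid = self._grid()
        cells = []
        for corner in [(5, 5), (5, 90), (90, 5), (90, 90), (50, 50)]:
            cells += [(corner[0] + d, corner[1]) for d in range(4)]
        fa = evaluation.spatial_block_folds(cells, grid, block_size_km=300, k=5, seed=0)
        assert set(fa.fold) == {1, 2, 3, 4, 5}

    def test_single_block_degenerate(self):
        grid = self._grid()
        cells = [(50, 50), (50, 51), (51, 50)]
        with pytest.raises(DegenerateBlockError):
            evaluation.spatial_block_folds(cells, grid, block_size_km=5000, k=2, seed=0)

    def test_balance_close_to_exhaustive_optimum(self, rng):
        # 8 occupied blocks, k=3: exhaustive assignment search as oracle
        grid = self._grid()
        block_cols = [2, 12, 22, 32, 42, 52, 62, 72]
        sizes = [6, 5, 5, 4, 3, 2, 2, 1]
        cells = []
        for col, s in zip(block_cols, sizes):
            cells += [(r, col) for r in range(s)]
        fa = evaluation.spatial_block_folds(cells, grid, block_size_km=300, k=3, seed=0)
        ours = np.sort(np.bincount(fa.fold)[1:])
        best_spread = min(
            max(t) - min(t)
            for assign in itertools.product(range(3), repeat=8)
            if len(set(assign)) == 3
            for t in [tuple(sum(s for s, a in zip(sizes, assign) if a == f)
                            for f in range(3))]
        )
        assert (ours.max() - ours.min()) <= best_spread + 1


class TestAuc:
    def test_perfect_ranking_is_one(self):
        assert evaluation.auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_identical_sets_are_chance(self):
        scores = [0.1, 0.4, 0.7]
        assert evaluation.auc(scores, scores) == 0.5

    def test_worked_example_with_tie(self):
        # pairs: 3 wins for 0.9; 0.8 beats 0.7 and 0.1, ties 0.8 -> 5.5/6
        assert evaluation.auc([0.9, 0.8], [0.7, 0.8, 0.1]) == pytest.approx(11 / 12)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        p = rng.normal(0.5, 1, 50)
        b = np.round(rng.normal(0, 1, 50), 1)  # rounding forces some ties
        p = np.round(p, 1)
        wins = sum(
            1.0 if pi > bi else 0.5 if pi == bi else 0.0 for pi in p for bi in b
        )
        assert evaluation.auc(p, b) == pytest.approx(wins / (50 * 50), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(1, 1, 20)
        b = rng.normal(0, 1, 30)
        a1 = evaluation.auc(p, b)
        a2 = evaluation.auc(np.exp(p / 2), np.exp(b / 2))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            evaluation.auc([], [0.5])


class TestBoyceIndex:
    def test_presences_in_top_decile_score_high(self, rng):
        landscape = rng.uniform(0, 1, 5000)
        presences = rng.uniform(0.9, 1.0, 200)
        assert evaluation.boyce_index(presences, landscape) >= 0.9

    def test_uniform_presences_near_zero(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            landscape = rng.uniform(0, 1, 5000)
            presences = rng.choice(landscape, 800, replace=False)
            assert abs(evaluation.boyce_index(presences, landscape)) <= 0.3

    def test_five_window_example_matches_direct_computation(self):
        landscape = np.arange(1.0, 21.0)  # 20 printed values, 1..20
        presences = np.array([12.0, 15.0, 16.0, 18.0, 19.0, 20.0])
        got = evaluation.boyce_index(presences, landscape, n_windows=5,
                                     window_frac=0.4)
        # independent direct computation: width 7.6, starts 1, 3.85, ... 12.4
        width = 0.4 * 19.0
        starts = np.linspace(1.0, 20.0 - width, 5)
        mids, pe = [], []
        for a in starts:
            b = a + width
            e = np.mean((landscape >= a) & (landscape <= b))
            pres = np.mean((presences >= a) & (presences <= b))
            mids.append(a + width / 2)
            pe.append(pres / e)
        # mirror the duplicate-P/E reduction by hand
        seen, m2, p2 = set(), [], []
        for m, r in zip(mids, pe):
            if r not in seen:
                seen.add(r)
                m2.append(m)
                p2.append(r)
        expected = stats.spearmanr(m2, p2).statistic
        assert got == pytest.approx(expected)

    def test_perfectly_increasing_pe_gives_one(self, rng):
        # presences drawn with weight proportional to suitability rank
        landscape = rng.uniform(0, 1, 4000)
        w = landscape**4
        pres = rng.choice(landscape, size=300, replace=False, p=w / w.sum())
        assert evaluation.boyce_index(pres, landscape) > 0.95

    def test_constant_landscape_rejected(self):
        with pytest.raises(EvaluationError):
            evaluation.boyce_index([0.5], np.full(100, 0.7))


class TestMaxSssThreshold:
    def test_perfect_separation(self):
        t, sens, spec = evaluation.max_sss_threshold([0.8, 0.9], [0.1, 0.2])
        assert t == 0.8 and sens == 1.0 and spec == 1.0

    def test_identical_distributions_sum_to_one(self):
        scores = [0.2, 0.5, 0.9]
        t, sens, spec = evaluation.max_sss_threshold(scores, scores)
        assert sens + spec == pytest.approx(1.0)

    def test_all_identical_predictions_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            evaluation.max_sss_threshold([0.5, 0.5], [0.5])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(0, 1, 25), 2)
        b = np.round(rng.uniform(0, 1, 25), 2)
        if np.unique(np.concatenate([p, b])).size == 1:
            return
        t, sens, spec = evaluation.max_sss_threshold(p, b)
        # exhaustive scan with exact integer counts; ties -> smallest cutoff
        best = max(
            (int((p >= c).sum()) * b.size + int((b < c).sum()) * p.size, -c)
            for c in np.unique(np.concatenate([p, b]))
        )
        assert (sens + spec) * p.size * b.size == pytest.approx(best[0], abs=1e-9)
        assert t == pytest.approx(-best[1])
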