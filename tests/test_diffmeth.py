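import numpy as np
import pandas as pd
import pytest
from scipy import stats

from termeth.calling import call_sites
from termeth.diffmeth import test_windows as run_window_test
from termeth.diffmeth import (
    THETA_CEIL,
    assign_features,
    betabin_fit,
    betabin_loglik,
    dmg_table,
    filter_testable,
    local_dispersion,
    merge_dmrs,
    mom_dispersion,
    paired_intersection,
    tile_windows,
)
from termeth.io import AnnotationSet, GeneModel

from conftest import make_window_table


def grid_ml_pi(m, n, theta, step=1e-4):
    """Brute-force grid-search ML oracle for the group proportion."""
    grid = np.arange(step, 1.0, step)
    ll = np.zeros_like(grid)
    for mi, ni in zip(m, n):
        ll += stats.betabinom.logpmf(mi, ni, grid * theta, (1 - grid) * theta)
    return grid[np.argmax(ll)]


class TestTileWindows:
    def test_terminal_partial_window(self):
        w = tile_windows({"s": 500})
        assert list(w.itertuples(index=False, name=None)) == [
            ("s", 0, 200), ("s", 200, 400), ("s", 400, 500)
        ]

    def test_exact_fit(self):
        assert len(tile_windows({"s": 200})) == 1

    def test_empty_scaffold(self):
        assert len(tile_windows({"s": 0})) == 0

    def test_bad_width(self):
        with pytest.raises(ValueError):
            tile_windows({"s": 100}, width=0)


class TestBetabinFit:
    def test_identical_groups_zero_lrt(self):
        g = [(5, 5), (6, 4)]
        fit = betabin_fit(g, g, theta=20.0)
        assert fit["pi_a"] == pytest.approx(fit["pi_b"], abs=1e-6)
        assert fit["pi_a"] == pytest.approx(fit["pi_null"], abs=1e-6)
        assert abs(fit["ll_alt"] - fit["ll_null"]) < 1e-8

    def test_large_theta_approaches_binomial(self):
        m, n = np.array([7, 3]), np.array([10, 10])
        pi = 0.5
        ll_bb = betabin_loglik(m, n, pi, theta=1e9)
        ll_binom = float(np.sum(stats.binom.logpmf(m, n, pi)))
        assert ll_bb == pytest.approx(ll_binom, abs=1e-4)

    def test_matches_grid_search_oracle_on_spec_instance(self):
        a = [(8, 2), (9, 1)]
        b = [(2, 8), (1, 9)]
        fit = betabin_fit(a, b, theta=20.0)
        pa = grid_ml_pi([8, 9], [10, 10], 20.0)
        pb = grid_ml_pi([2, 1], [10, 10], 20.0)
        assert fit["pi_a"] == pytest.approx(pa, abs=1e-3)
        assert fit["pi_b"] == pytest.approx(pb, abs=1e-3)

    def test_matches_grid_search_oracle_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.uniform(5, 50)
            n = rng.integers(5, 30, size=4)
            m = rng.binomial(n, rng.uniform(0.1, 0.9))
            fit = betabin_fit(
                list(zip(m[:2], n[:2] - m[:2])),
                list(zip(m[2:], n[2:] - m[2:])),
                theta,
            )
            assert fit["pi_a"] == pytest.approx(
                grid_ml_pi(m[:2], n[:2], theta), abs=1e-3
            )

    def test_lrt_nonnegative_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(1, 20, size=4)
            m = rng.binomial(n, rng.uniform(0, 1))
            fit = betabin_fit(
                list(zip(m[:2], n[:2] - m[:2])),
                list(zip(m[2:], n[2:] - m[2:])),
                rng.uniform(2, 100),
            )
            assert fit["ll_alt"] - fit["ll_null"] > -1e-6


class TestDispersion:
    def test_identical_replicates_hit_ceiling(self):
        theta = mom_dispersion([(np.array([5, 5, 5, 5]), np.array([10, 10, 10, 10]))])
        assert theta == THETA_CEIL

    def test_moment_recovery_of_known_theta(self):
        # beta-binomial replicates with theta=15: the median estimate over
        # simulations should bracket the truth
        rng = np.random.default_rng(2)
        est = []
        for _ in range(100):
            cells = []
            for _ in range(50):
                pi = rng.uniform(0.3, 0.7)
                p = rng.beta(pi * 15, (1 - pi) * 15, size=8)
                n = rng.poisson(30, size=8) + 1
                m = rng.binomial(n, p)
                cells.append((m, n))
            est.append(mom_dispersion(cells))
        assert 10 <= np.median(est) <= 22

    def test_empty_flanks_fall_back_to_window_only(self):
        rng = np.random.default_rng(3)
        samples = list("abcdefgh")
        m = rng.integers(0, 10, size=(1, 8))
        u = rng.integers(1, 10, size=(1, 8))
        w = make_window_table(m, u, samples)
        lonely = local_dispersion(w, samples)
        cells = [(m[0], m[0] + u[0])]
        assert lonely[0] == mom_dispersion(cells)


class TestFilterTestable:
    def _calls(self, wide, samples):
        return {
            s: call_sites(
                wide[["scaffold", "pos"]].assign(m=wide[f"m_{s}"], u=wide[f"u_{s}"]),
                err=0.005,
            )
            for s in samples
        }

    def test_side_with_insufficient_covered_replicates_dropped(self):
        samples = list("abcdefgh")
        m = np.full((1, 8), 6)
        u = np.full((1, 8), 2)
        m[0, :2] = 0
        u[0, :2] = 0  # only 2 of 4 side-A libraries covered
        w = make_window_table(m, u, samples)
        wide = w.rename(columns={"start": "pos"}).drop(columns=["end", "n_cpg"])
        calls = self._calls(wide, samples)
        out = filter_testable(w, calls, samples[:4], samples[4:])
        assert len(out) == 0

    def test_unmethylated_window_dropped(self):
        samples = list("abcdefgh")
        m = np.zeros((1, 8), dtype=int)
        u = np.full((1, 8), 20)
        w = make_window_table(m, u, samples)
        wide = w.rename(columns={"start": "pos"}).drop(columns=["end", "n_cpg"])
        calls = self._calls(wide, samples)
        assert len(filter_testable(w, calls, samples[:4], samples[4:])) == 0

    def test_covered_methylated_window_kept(self):
        samples = list("abcdefgh")
        m = np.full((1, 8), 15)
        u = np.full((1, 8), 5)
        w = make_window_table(m, u, samples)
        wide = w.rename(columns={"start": "pos"}).drop(columns=["end", "n_cpg"])
        calls = self._calls(wide, samples)
        assert len(filter_testable(w, calls, samples[:4], samples[4:])) == 1

    def test_small_comparison_side_is_error(self):
        samples = list("abcd")
        w = make_window_table(np.ones((1, 4), int), np.ones((1, 4), int), samples)
        with pytest.raises(ValueError):
            filter_testable(w, {}, samples[:2], samples[2:])


class TestTestWindows:
    def test_effect_size_filter_blocks_small_differences(self):
        # diff ~= 0.14 with overwhelming coverage: tiny q but not significant
        samples = list("abcdefgh")
        n = 4000
        m = np.empty((1, 8), int)
        m[0, :4] = int(0.50 * n)
        m[0, 4:] = int(0.36 * n)
        u = n - m
        w = make_window_table(m, u, samples)
        res = run_window_test(w, samples[:4], samples[4:], theta=1e5)
        assert res["q"].iloc[0] < 1e-6
        assert abs(res["diff"].iloc[0]) < 0.15
        assert not res["significant"].iloc[0]

    def test_direction_consistent_with_sign(self):
        samples = list("abcdefgh")
        m = np.array([[18, 17, 18, 19, 5, 6, 5, 4]])
        u = 20 - m
        w = make_window_table(m, u, samples)
        res = run_window_test(w, samples[:4], samples[4:], theta=50.0,
                           label_a="alate", label_b="worker")
        assert res["diff"].iloc[0] > 0
        assert res["direction"].iloc[0] == "hyper-alate"


class TestMergeAndAssign:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=["scaffold", "start", "end", "direction", "q", "diff",
                     "significant"],
        )

    def test_adjacent_same_direction_merged(self):
        res = self._results([
            ("s", 0, 200, "hyper-alate", 0.01, 0.3, True),
            ("s", 200, 400, "hyper-alate", 0.02, 0.25, True),
        ])
        dmrs = merge_dmrs(res)
        assert len(dmrs) == 1
        assert (dmrs["start"].iloc[0], dmrs["end"].iloc[0]) == (0, 400)
        assert dmrs["n_windows"].iloc[0] == 2

    def test_opposite_directions_not_merged(self):
        res = self._results([
            ("s", 0, 200, "hyper-alate", 0.01, 0.3, True),
            ("s", 200, 400, "hyper-worker", 0.02, -0.25, True),
        ])
        assert len(merge_dmrs(res)) == 2

    def test_merge_order_independent(self):
        rows = [
            ("s", 400, 600, "hyper-alate", 0.01, 0.3, True),
            ("s", 0, 200, "hyper-alate", 0.01, 0.3, True),
            ("s", 200, 400, "hyper-alate", 0.01, 0.3, True),
        ]
        a = merge_dmrs(self._results(rows))
        b = merge_dmrs(self._results(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_feature_assignment_prefers_larger_overlap(self):
        ann = AnnotationSet([
            GeneModel("g", "s", "+", [(0, 120), (200, 400)], promoter=None)
        ])
        dmrs = pd.DataFrame(
            [{"scaffold": "s", "start": 0, "end": 200, "direction": "hyper-alate",
              "n_windows": 1, "min_q": 0.01, "max_abs_diff": 0.3}]
        )
        out = assign_features(dmrs, ann)
        # 120 bp exon beats 80 bp intron
        assert out["feature"].iloc[0] == "exon"
        assert out["gene"].iloc[0] == "g"

    def test_intergenic_dmr_unassigned(self):
        ann = AnnotationSet([GeneModel("g", "s", "+", [(5000, 6000)])])
        dmrs = pd.DataFrame(
            [{"scaffold": "s", "start": 0, "end": 200, "direction": "hyper-alate",
              "n_windows": 1, "min_q": 0.01, "max_abs_diff": 0.3}]
        )
        out = assign_features(dmrs, ann)
        assert out["feature"].iloc[0] == "intergenic"
        assert out["gene"].iloc[0] == ""

    def test_dmg_table_counts_directions(self):
        assigned = pd.DataFrame(
            [
                {"scaffold": "s", "start": 0, "end": 200,
                 "direction": "hyper-alate", "gene": "g1", "feature": "exon"},
                {"scaffold": "s", "start": 600, "end": 800,
                 "direction": "hyper-alate", "gene": "g1", "feature": "intron"},
            ]
        )
        t = dmg_table(assigned)
        assert t["n_dmrs"].iloc[0] == 2
        assert t["direction"].iloc[0] == "hyper-alate"


class TestPairedIntersection:
    def _dmg(self, rows):
        return pd.DataFrame(rows, columns=["gene", "direction"])

    def test_gene_in_one_comparison_excluded(self):
        out = paired_intersection(
            self._dmg([("g1", "hyper-alate")]), self._dmg([("g2", "hyper-alate")])
        )
        assert len(out) == 0

    def test_opposite_direction_excluded(self):
        out = paired_intersection(
            self._dmg([("g1", "hyper-alate")]), self._dmg([("g1", "hyper-worker")])
        )
        assert len(out) == 0

    def test_consistent_gene_included(self):
        out = paired_intersection(
            self._dmg([("g1", "hyper-alate")]), self._dmg([("g1", "hyper-alate")])
        )
        assert out["gene"].tolist() == ["g1"]
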