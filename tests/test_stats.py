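"""Mann-Whitney machinery, bootstrap mean-p procedure, hypergeometric enrichment."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import norm, rankdata

from nucshift import (
    bootstrap_mw,
    hypergeom_enrichment,
    mann_whitney_u,
    stars,
)
from nucshift.io import GeneSet


def textbook_mw_p(a, b):
    """Independent rank-sum implementation: tie-corrected normal approximation
    with continuity correction, two-sided."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term))
    z = (abs(u1 - mu) - 0.5) / sigma
    return min(1.0, 2 * norm.sf(z))


def brute_force_hypergeom_sf(N, M, K, k):
    """Upper-tail P(X >= k) from binomial coefficients."""
    total = math.comb(N, K)
    return sum(
        math.comb(M, j) * math.comb(N - M, K - j)
        for j in range(k, min(M, K) + 1)
        if K - j <= N - M
    ) / total


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]) == 1.0

    def test_complete_separation_exact(self):
        # all C(6,3)=20 rank assignments; the observed split is one of two
        # extremes -> two-sided exact p = 2/20
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_matches_independent_implementation(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(9, 60))
            b = rng.normal(rng.uniform(-1, 1), size=rng.integers(9, 60))
            assert mann_whitney_u(a, b) == pytest.approx(
                textbook_mw_p(a, b), abs=1e-9
            )

    def test_null_type_one_error_calibrated(self, rng):
        """Under H0 the plain test should reject at about the nominal rate."""
        rejections = sum(
            mann_whitney_u(rng.normal(size=30), rng.normal(size=30)) <= 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.9, "ns"), (0.051, "ns"), (0.05, "*"), (0.01, "**"),
         (0.001, "***"), (1e-4, "****"), (1e-7, "****")],
    )
    def test_coding(self, p, label):
        assert stars(p) == label


class TestBootstrapMW:
    def test_small_group_falls_back_to_plain_test(self, rng):
        target = rng.normal(size=1200)
        background = rng.normal(size=3000)
        res = bootstrap_mw(target, background, n_iter=10, seed=1)
        assert res.mode == "plain"
        assert res.mean_p == mann_whitney_u(target, background)

    def test_reproducible_under_seed(self, rng):
        target = rng.normal(size=1550)
        background = rng.normal(size=2500)
        r1 = bootstrap_mw(target, background, n_iter=25, seed=42)
        r2 = bootstrap_mw(target, background, n_iter=25, seed=42)
        assert r1.mean_p == r2.mean_p
        assert r1.mode == "n_matched"

    def test_null_is_nonsignificant(self, rng):
        for run in range(3):
            target = rng.normal(size=1520)
            background = rng.normal(size=2400)
            res = bootstrap_mw(target, background, n_iter=40, seed=run)
            assert res.mean_p > 0.05 and res.stars == "ns"

    def test_large_shift_maximally_significant(self, rng):
        target = rng.normal(size=1600)
        background = rng.normal(100.0, 1.0, size=2400)
        res = bootstrap_mw(target, background, n_iter=20, seed=0)
        assert res.mean_p <= 1e-4 and res.stars == "****"

    def test_fixed_500_mode(self, rng):
        a = rng.normal(size=1700)
        b = rng.normal(size=1800)
        res = bootstrap_mw(a, b, n_iter=20, mode="fixed_500", seed=5)
        assert res.mode == "fixed_500" and res.subsample_size == 500

    def test_mean_p_sd_shrinks_with_iterations(self, rng):
        """Across seeds, the spread of mean_p falls roughly as 1/sqrt(n_iter)."""
        target = rng.normal(0.05, 1, size=1510)
        background = rng.normal(size=1900)
        sds = []
        for n_iter in (40, 400):
            means = [
                bootstrap_mw(target, background, n_iter=n_iter, seed=s).mean_p
                for s in range(10)
            ]
            sds.append(np.std(means))
        ratio = sds[0] / sds[1]  # expect ~ sqrt(10) ~ 3.2
        assert 1.5 < ratio < 7.0

    def test_oversized_subsample_rejected(self, rng):
        a = rng.normal(size=1600)
        b = rng.normal(size=1500)
        with pytest.raises(ValueError):
            bootstrap_mw(b, a[:1500], n_iter=5, mode="fixed_500",
                         subsample_size=1501, seed=0)


class TestHypergeomEnrichment:
    def _sets(self, N, cluster_ids, annotated_ids):
        universe = GeneSet("universe", frozenset(f"g{i}" for i in range(N)))
        return (
            GeneSet("cluster", frozenset(cluster_ids)),
            GeneSet("annotated", frozenset(annotated_ids)),
            universe,
        )

    def test_closed_form_example(self):
        # N=20, M=5, K=4, k=4: p = C(5,4)/C(20,4) = 5/4845
        cluster, annotated, universe = self._sets(
            20, [f"g{i}" for i in range(4)], [f"g{i}" for i in range(5)]
        )
        res = hypergeom_enrichment(cluster, annotated, universe)
        assert res.fold == pytest.approx(4.0)
        assert res.p == pytest.approx(5 / 4845, rel=1e-12)

    def test_annotated_equals_universe(self):
        cluster, _, universe = self._sets(
            10, ["g0", "g1"], [f"g{i}" for i in range(10)]
        )
        res = hypergeom_enrichment(cluster, universe, universe)
        assert res.fold == 1.0 and res.p == pytest.approx(1.0)

    def test_expected_overlap_fold_one(self):
        # N=10, M=5, K=4 -> expected k = 2
        cluster, annotated, universe = self._sets(
            10, ["g0", "g1", "g5", "g6"], ["g0", "g1", "g2", "g3", "g4"]
        )
        res = hypergeom_enrichment(cluster, annotated, universe)
        assert res.fold == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_cases(self):
        for N in range(2, 16):
            for M, K in product(range(1, N + 1), repeat=2):
                for k in range(max(0, M + K - N), min(M, K) + 1):
                    got = float(
                        __import__("scipy.stats", fromlist=["hypergeom"])
                        .hypergeom(N, M, K)
                        .sf(k - 1)
                    )
                    want = brute_force_hypergeom_sf(N, M, K, k)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_p_monotone_in_overlap(self):
        N, M, K = 100, 30, 20
        universe = GeneSet("u", frozenset(f"g{i}" for i in range(N)))
        annotated = GeneSet("a", frozenset(f"g{i}" for i in range(M)))
        last = 1.1
        for k in range(0, K + 1):
            members = [f"g{i}" for i in range(k)] + [
                f"g{i}" for i in range(M, M + K - k)
            ]
            res = hypergeom_enrichment(
                GeneSet("c", frozenset(members)), annotated, universe
            )
            assert res.p <= last + 1e-12
            last = res.p

    def test_outside_universe_dropped_with_warning(self):
        cluster, annotated, universe = self._sets(10, ["g0", "zz"], ["g0", "g1"])
        with pytest.warns(UserWarning, match="outside"):
            res = hypergeom_enrichment(cluster, annotated, universe)
        assert res.cluster_size == 1
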