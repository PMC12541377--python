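"""Resampling statistics for gene-group comparisons.

Two-group comparisons are Mann–Whitney tests; when both groups are
large, a descriptive mean-p resampling scheme is used instead of a
single test so that the reported significance is not driven purely by
the enormous genome-wide n. Gene-set overlaps are scored with the
upper-tail hypergeometric probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import GeneSet

#: significance coding: smallest threshold whose bound the p-value meets
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

#: below this group size a single plain test replaces resampling
PLAIN_TEST_CUTOFF = 1500


def stars(p: float) -> str:
    """Render a p-value as the conventional significance stars."""
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann–Whitney p-value.

    Exact enumeration when both samples have at most 8 values and no
    ties straddle the groups; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the corrected normal
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class BootstrapTestResult:
    """Outcome of the resampled (or plain) Mann–Whitney comparison."""

    mean_p: float
    n_iter: int
    subsample_size: int
    mode: str  # n_matched | fixed_500 | plain
    seed: int
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_p <= 1.0:
            raise ValueError("mean_p must be a probability")


def _rng(seed: int) -> np.random.Generator:
    # counter-based generator: reproducible and stream-safe
    return np.random.Generator(np.random.Philox(seed))


def bootstrap_mw(
    target,
    background,
    n_iter: int = 20_000,
    mode: str = "n_matched",
    seed: int = 0,
    subsample_size: int = 500,
) -> BootstrapTestResult:
    """Mean Mann–Whitney p-value over resampled gene groups.

    mode ``n_matched``: each iteration draws ``len(target)`` values from
    the background without replacement and tests them against the full
    target group. mode ``fixed_500``: both inputs are genome-wide value
    sets; each iteration draws ``subsample_size`` values from each and
    tests the two subsamples. In either mode, when the smaller group has
    fewer than 1500 values a single plain test is performed instead and
    reported with mode ``plain``.
    """
    target = np.asarray(target, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if not (np.all(np.isfinite(target)) and np.all(np.isfinite(background))):
        raise ValueError("values must be finite")
    n_small = min(target.size, background.size)
    if n_small < PLAIN_TEST_CUTOFF:
        p = mann_whitney_u(target, background)
        return BootstrapTestResult(p, 1, n_small, "plain", seed, stars(p))
    rng = _rng(seed)
    if mode == "n_matched":
        k = target.size
        if k > background.size:
            raise ValueError("target larger than background: cannot subsample")
        ps = np.empty(n_iter)
        for i in range(n_iter):
            sample = rng.choice(background, size=k, replace=False)
            ps[i] = mann_whitney_u(target, sample)
    elif mode == "fixed_500":
        if subsample_size > n_small:
            raise ValueError("subsample size exceeds a group size")
        ps = np.empty(n_iter)
        for i in range(n_iter):
            sa = rng.choice(target, size=subsample_size, replace=False)
            sb = rng.choice(background, size=subsample_size, replace=False)
            ps[i] = mann_whitney_u(sa, sb)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean_p = float(ps.mean())
    size = target.size if mode == "n_matched" else subsample_size
    return BootstrapTestResult(mean_p, n_iter, size, mode, seed, stars(mean_p))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of an annotation in a cluster."""

    universe_size: int  # N
    set_size: int  # M: annotated genes in the universe
    cluster_size: int  # K: genes in the cluster
    overlap: int  # k
    fold: float  # (k/K) / (M/N)
    p: float  # P(X >= k), X ~ Hypergeometric(N, M, K)


def hypergeom_enrichment(
    cluster: GeneSet, annotated: GeneSet, universe: GeneSet
) -> EnrichmentResult:
    """Fold enrichment and upper-tail hypergeometric p for a gene cluster.

    Members of ``cluster`` or ``annotated`` outside the universe are
    dropped with a warning before computing the overlap.
    """
    import warnings

    if not universe.members:
        raise ValueError("empty universe")
    cl = cluster.members & universe.members
    an = annotated.members & universe.members
    dropped = (len(cluster.members) - len(cl)) + (len(annotated.members) - len(an))
    if dropped:
        warnings.warn(f"dropped {dropped} genes outside the universe", stacklevel=2)
    N, M, K = len(universe.members), len(an), len(cl)
    if K == 0 or M == 0:
        raise ValueError("cluster and annotation must intersect the universe")
    k = len(cl & an)
    fold = (k / K) / (M / N)
    p = float(sps.hypergeom(N, M, K).sf(k - 1))
    return EnrichmentResult(N, M, K, k, fold, p)
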