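"""Summit-overlap co-association with a Poisson accessible-region null.

The overlap between two ChIP-seq peak sets is the number of summits of the
first factor falling within 300 bp windows centered on the summits of the
second (maximum summit distance 150 bp, inclusive).  Significance is a
Poisson tail with expectation ``n_a * n_b / N`` where N is the number of
150 bp accessible (DNase-hypersensitive) regions, 250,000 by default.
P-values are Bonferroni corrected; the score is the signed -log10 of the
corrected p, negated when the observed overlap falls below expectation.
Underflowing p-values are clamped at the smallest positive subnormal double,
which caps the score at the integer ceiling 323 reported in output tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import AnalysisConfig, PeakSet, ValidationError

#: smallest positive (subnormal) double; the clamp floor for p-values
P_FLOOR = float(np.nextafter(0.0, 1.0))
#: score obtained at the clamp floor, ~323.31
SCORE_CEILING = -math.log10(P_FLOOR)


@dataclass(frozen=True)
class OverlapCount:
    """Ordered overlap counts between two peak sets.

    ``k`` counts summits of ``factor_a`` having at least one summit of
    ``factor_b`` within the window (each counted once); ``k_b`` is the
    reciprocal count.  Shares are the corresponding fractions.
    """

    factor_a: str
    factor_b: str
    n_a: int
    n_b: int
    k: int
    k_b: int

    @property
    def share_a(self) -> float:
        return self.k / self.n_a if self.n_a else 0.0

    @property
    def share_b(self) -> float:
        return self.k_b / self.n_b if self.n_b else 0.0


@dataclass(frozen=True)
class CoassocResult:
    counts: OverlapCount
    lambda_exp: float
    p_raw: float
    p_bonf: float
    score: float
    significant: bool
    degenerate: bool = False

    @property
    def int_score(self) -> int:
        """Score rounded to the integer precision used in output tables."""
        return int(round(self.score))


@dataclass
class CoassocMatrix:
    factors: list[str]
    scores: np.ndarray  # square, ordered as ``factors``
    mode: str = "global"  # or "anchored:<factor>"


def _count_into_windows(a: PeakSet, b: PeakSet, half_window: int) -> int:
    """Number of summits of ``a`` within ``half_window`` (inclusive) of some
    summit of ``b``, each ``a`` summit counted at most once."""
    k = 0
    b_summits = b.summits_by_chrom()
    for chrom, sa in a.summits_by_chrom().items():
        sb = b_summits.get(chrom)
        if sb is None or len(sb) == 0:
            continue
        lo = np.searchsorted(sb, sa - half_window, side="left")
        hi = np.searchsorted(sb, sa + half_window, side="right")
        k += int(np.count_nonzero(hi > lo))
    return k


def count_overlap(a: PeakSet, b: PeakSet, cfg: AnalysisConfig | None = None) -> OverlapCount:
    """Windowed summit-overlap count for the ordered pair (a, b).

    Runs in O((n_a + n_b) log n) via binary search on the sorted summits.
    """
    cfg = cfg or AnalysisConfig()
    w = cfg.overlap_half_window
    return OverlapCount(
        factor_a=a.factor, factor_b=b.factor,
        n_a=len(a), n_b=len(b),
        k=_count_into_windows(a, b, w),
        k_b=_count_into_windows(b, a, w),
    )


def poisson_score(counts: OverlapCount, n_tests: int = 1,
                  cfg: AnalysisConfig | None = None,
                  n_accessible: int | None = None) -> CoassocResult:
    """Signed -log10 Bonferroni-corrected Poisson tail score for an overlap.

    Enriched overlaps (k >= lambda) use the upper tail P(X >= k); depleted
    ones the lower tail P(X <= k) with the final score negated.
    """
    cfg = cfg or AnalysisConfig()
    N = n_accessible if n_accessible is not None else cfg.accessible_regions_n
    if N <= 0:
        raise ValidationError("accessible-region count must be positive")
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    lam = counts.n_a * counts.n_b / N
    k = counts.k
    if k >= lam:
        p_raw = float(stats.poisson.sf(k - 1, lam))  # P(X >= k)
        sign = 1.0
    else:
        p_raw = float(stats.poisson.cdf(k, lam))  # P(X <= k)
        sign = -1.0
    p_bonf = min(1.0, p_raw * n_tests)
    p_clamped = max(p_bonf, P_FLOOR)
    score = sign * (-math.log10(p_clamped))
    result = CoassocResult(counts=counts, lambda_exp=lam, p_raw=p_raw,
                           p_bonf=p_bonf, score=score, significant=False)
    return result


def significance_call(result: CoassocResult, anchor_share: float,
                      cfg: AnalysisConfig | None = None) -> bool:
    """Significant iff score > 100 and the anchor shares > 10% of its peaks
    with the factor (both strict)."""
    cfg = cfg or AnalysisConfig()
    return (result.score > cfg.coassoc_score_threshold
            and anchor_share > cfg.nfyb_share_threshold)


def restrict_to_anchor(ps: PeakSet, anchor: PeakSet,
                       cfg: AnalysisConfig | None = None) -> PeakSet:
    """Subset of ``ps`` whose summits lie within the overlap window of some
    anchor summit."""
    cfg = cfg or AnalysisConfig()
    w = cfg.overlap_half_window
    anchor_summits = anchor.summits_by_chrom()
    keep = []
    for p in ps:
        sb = anchor_summits.get(p.chrom)
        if sb is None or len(sb) == 0:
            keep.append(False)
            continue
        lo = np.searchsorted(sb, p.summit - w, side="left")
        hi = np.searchsorted(sb, p.summit + w, side="right")
        keep.append(hi > lo)
    return ps.subset(keep, suffix="|anchored")


def anchored_overlap(a: PeakSet, b: PeakSet, anchor: PeakSet,
                     cfg: AnalysisConfig | None = None,
                     n_tests: int = 1) -> CoassocResult:
    """Anchor-restricted co-association (e.g. within NF-YB-bound regions).

    Both sets are restricted to summits overlapping the anchor; the Poisson
    null then uses the anchor's peak count as N.
    """
    cfg = cfg or AnalysisConfig()
    if len(anchor) == 0:
        raise ValidationError("anchor peak set is empty")
    ra = restrict_to_anchor(a, anchor, cfg)
    rb = restrict_to_anchor(b, anchor, cfg)
    if len(ra) == 0 or len(rb) == 0:
        counts = OverlapCount(a.factor, b.factor, len(ra), len(rb), 0, 0)
        return CoassocResult(counts=counts, lambda_exp=0.0, p_raw=1.0,
                             p_bonf=1.0, score=0.0, significant=False,
                             degenerate=True)
    counts = count_overlap(ra, rb, cfg)
    return poisson_score(counts, n_tests=n_tests, cfg=cfg,
                         n_accessible=len(anchor))


def coassoc_matrix(peaksets: list[PeakSet], cfg: AnalysisConfig | None = None,
                   anchor: PeakSet | None = None,
                   n_tests: int | None = None) -> CoassocMatrix:
    """All ordered pairwise scores among ``peaksets``.

    The Bonferroni universe defaults to the number of ordered off-diagonal
    pairs evaluated in the run.
    """
    cfg = cfg or AnalysisConfig()
    n = len(peaksets)
    if n_tests is None:
        n_tests = max(1, n * (n - 1))
    scores = np.zeros((n, n))
    for i, a in enumerate(peaksets):
        for j, b in enumerate(peaksets):
            if anchor is not None:
                res = anchored_overlap(a, b, anchor, cfg, n_tests=n_tests)
            else:
                res = poisson_score(count_overlap(a, b, cfg), n_tests=n_tests, cfg=cfg)
            scores[i, j] = res.score
    mode = "global" if anchor is None else f"anchored:{anchor.factor}"
    return CoassocMatrix([p.factor for p in peaksets], scores, mode=mode)


# ---------------------------------------------------------------------------
# clustering


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def cluster_matrix(m: CoassocMatrix, method: str = "centroid"):
    """Hierarchical clustering of score rows with 1 - Pearson distance.

    Centroid linkage on a correlation distance follows the published
    procedure even though it is not geometrically well-founded for
    non-Euclidean distances; ``method="average"`` is available as an
    alternative.  Constant rows carry no correlation signal and are dropped
    with a warning.  Returns ``(linkage, ordered factor names, newick)``.
    """
    rows = np.asarray(m.scores, dtype=float)
    factors = list(m.factors)
    if len(factors) < 2:
        raise ValidationError("need at least two factors to cluster")
    keep = rows.std(axis=1) > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(factors, keep) if not k]
        warnings.warn(f"dropping constant rows from clustering: {dropped}")
        rows = rows[keep]
        factors = [f for f, k in zip(factors, keep) if k]
    if len(factors) < 2:
        raise ValidationError("matrix is (near-)constant; nothing to cluster")
    # deterministic leaf order: pre-sort rows by factor name so scipy's
    # tie-breaking (by observation index) is reproducible
    order = sorted(range(len(factors)), key=lambda i: factors[i])
    rows = rows[order]
    factors = [factors[i] for i in order]
    corr = np.corrcoef(rows)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    leaf_order = hierarchy.leaves_list(z)
    ordered = [factors[i] for i in leaf_order]
    newick = _tree_to_newick(hierarchy.to_tree(z), factors) + ";"
    return z, ordered, newick
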