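"""PWM scanning with global/local enrichment calls and CCAAT positional bias.

The scanner reconstructs the published motif-enrichment semantics: 150 bp
summit-centered windows are scanned on both strands with log-odds scores,
min-max normalized to [0, 1] per matrix.  "Global" enrichment compares peak
windows to an accessible-region background; "local" enrichment compares them
to immediately flanking windows.  Both are called significant below 1e-10.
Positional bias is the signed distance between a partner motif's center and
the middle A of the CCAAT pentanucleotide in co-bound regions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import AnalysisConfig, GenomicInterval, PeakSet, PositionWeightMatrix, ValidationError

REGION_WIDTH = 150  # summit-centered scan window, matching the overlap window


@dataclass(frozen=True)
class RegionScore:
    """Best normalized PWM match in one summit-centered window."""

    region: GenomicInterval
    best_score: float
    best_pos: int  # 0-based match start offset within the region
    best_strand: str  # "+" or "-"
    clipped: bool = False


@dataclass
class MotifEnrichment:
    matrix_id: str
    global_p: float
    local_p: float
    rank_global: int = 0
    enrichment_class: str = "none"


@dataclass
class PositionalBias:
    """Distribution of signed TF-motif-center to CCAAT-middle-A distances."""

    offsets: np.ndarray  # one signed distance (bp) per usable region
    orientation_split: dict[str, int]  # "same" / "opposite" strand counts
    bias_p: float
    mode_offset: int | None
    n_excluded: int  # regions without a CCAAT match above threshold


@dataclass
class BackgroundModel:
    """Best-score distribution of a matrix over accessible regions."""

    mean: float
    var: float
    n: int
    sample: np.ndarray | None = None

    @classmethod
    def from_scores(cls, scores: Sequence[RegionScore] | np.ndarray,
                    keep_sample: bool = True) -> "BackgroundModel":
        arr = np.asarray([s.best_score for s in scores]
                         if len(scores) and isinstance(scores[0], RegionScore)
                         else scores, dtype=float)
        return cls(mean=float(arr.mean()), var=float(arr.var(ddof=1)),
                   n=len(arr), sample=arr if keep_sample else None)


# ---------------------------------------------------------------------------
# scanning


def _score_windows(windows: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Raw log-odds scores for every start position of every window.

    ``windows``: (R, W) uint8 base codes (4 = N, contributes 0).
    Returns (R, W - L + 1).
    """
    L = lom.shape[0]
    lom5 = np.concatenate([lom, np.zeros((L, 1))], axis=1)  # N column
    view = np.lib.stride_tricks.sliding_window_view(windows, L, axis=1)
    return lom5[np.arange(L), view].sum(axis=2)


def _tie_dither(windows: np.ndarray, n_cols: int) -> np.ndarray:
    """Deterministic per-window pseudo-random values for tie-breaking.

    Keyed on window content so results do not depend on batch composition
    or call order; identical best scores (repeated k-mers within a window)
    are resolved without a positional bias.
    """
    out = np.empty((windows.shape[0], n_cols))
    for i in range(windows.shape[0]):
        key = zlib.crc32(windows[i].tobytes())
        out[i] = np.random.default_rng(key).random(n_cols)
    return out


def scan_windows(windows: np.ndarray, pwm: PositionWeightMatrix,
                 background: np.ndarray | None = None,
                 pseudo_frac: float = 0.01) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best normalized hit per window, both strands.

    Returns ``(best_score, best_pos, best_strand_code)`` arrays; strand code
    0 is forward, 1 is reverse.  Scores are min-max normalized so the
    consensus scores exactly 1.0 and the anti-consensus 0.0.  Ties between
    equally scoring positions are broken by a content-keyed deterministic
    dither rather than positional order.
    """
    lom = pwm.log_odds(background, pseudo_frac)
    lo_min = lom.min(axis=1).sum()
    lo_max = lom.max(axis=1).sum()
    span = lo_max - lo_min
    fwd = _score_windows(windows, lom)
    rev = _score_windows(windows, pwm.reverse_complement().log_odds(background, pseudo_frac))
    both = np.stack([fwd, rev])  # (2, R, P)
    flat = both.transpose(1, 0, 2).reshape(windows.shape[0], -1)
    best = (flat + 1e-7 * span * _tie_dither(windows, flat.shape[1])).argmax(axis=1)
    P = fwd.shape[1]
    strand = best // P
    pos = best % P
    score = (flat[np.arange(len(best)), best] - lo_min) / span
    return score, pos, strand


def _region_for_summit(summit: int, chrom_len: int, width: int) -> tuple[int, int, bool]:
    start = summit - width // 2
    end = start + width
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if end > chrom_len:
        end, clipped = chrom_len, True
    return start, end, clipped


def scan_regions(seq: Mapping[str, np.ndarray], summits: PeakSet,
                 pwm: PositionWeightMatrix, cfg: AnalysisConfig | None = None,
                 width: int = REGION_WIDTH, offset: int = 0,
                 background: np.ndarray | None = None) -> list[RegionScore]:
    """Scan the ``width`` bp window centered ``offset`` bp from each summit.

    ``offset`` of +/- ``width`` selects the immediately flanking windows used
    by the local-enrichment test.  Windows clipped at a chromosome end are
    flagged and scored on the remaining sequence.
    """
    cfg = cfg or AnalysisConfig()
    full: list[tuple[int, np.ndarray]] = []
    results: list[RegionScore | None] = []
    metas: list[tuple[str, int, int, bool]] = []
    for p in summits:
        codes = seq.get(p.chrom)
        if codes is None:
            raise ValidationError(f"no sequence for chromosome {p.chrom}")
        start, end, clipped = _region_for_summit(p.summit + offset, len(codes), width)
        metas.append((p.chrom, start, end, clipped))
    # batch the full-width windows; score clipped ones individually
    idx_full = [i for i, m in enumerate(metas) if m[2] - m[1] == width]
    results = [None] * len(metas)
    if idx_full:
        windows = np.stack([seq[metas[i][0]][metas[i][1]:metas[i][2]] for i in idx_full])
        score, pos, strand = scan_windows(windows, pwm, background,
                                          cfg.pwm_pseudocount_frac)
        for j, i in enumerate(idx_full):
            chrom, start, end, clipped = metas[i]
            results[i] = RegionScore(GenomicInterval(chrom, start, end),
                                     float(score[j]), int(pos[j]),
                                     "+" if strand[j] == 0 else "-", clipped)
    for i, (chrom, start, end, clipped) in enumerate(metas):
        if results[i] is not None:
            continue
        win = seq[chrom][start:end]
        if end - start < pwm.length:
            results[i] = RegionScore(GenomicInterval(chrom, start, max(end, start + 1)),
                                     0.0, 0, "+", True)
            continue
        score, pos, strand = scan_windows(win[None, :], pwm, background,
                                          cfg.pwm_pseudocount_frac)
        results[i] = RegionScore(GenomicInterval(chrom, start, end),
                                 float(score[0]), int(pos[0]),
                                 "+" if strand[0] == 0 else "-", True)
    return results  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# enrichment tests


def global_enrichment(scores: Sequence[RegionScore], background: BackgroundModel,
                      cfg: AnalysisConfig | None = None,
                      method: str = "z", n_perm: int = 10_000,
                      rng: np.random.Generator | None = None) -> float:
    """One-sided p that the mean best score in peak windows exceeds the
    accessible-region background mean.

    ``method="z"`` uses a z-test on the mean with the background variance;
    ``method="permutation"`` resamples same-size sets from the full
    background sample (requires one).
    """
    x = np.asarray([s.best_score for s in scores], dtype=float)
    if background.var <= 0:
        raise ValidationError("background variance is zero")
    if method == "z":
        z = (x.mean() - background.mean) / math.sqrt(background.var / len(x))
        return float(stats.norm.sf(z))
    if method == "permutation":
        if background.sample is None:
            raise ValidationError("permutation test needs a full background sample")
        rng = rng or np.random.default_rng(0)
        draws = rng.choice(background.sample, size=(n_perm, len(x)), replace=True)
        ge = int(np.count_nonzero(draws.mean(axis=1) >= x.mean()))
        return (ge + 1) / (n_perm + 1)
    raise ValidationError(f"unknown method {method!r}")


def local_enrichment(scores: Sequence[RegionScore],
                     flank_scores: tuple[Sequence[RegionScore], Sequence[RegionScore]],
                     cfg: AnalysisConfig | None = None) -> float:
    """One-sided paired test that central windows out-score their flanks.

    Flanks are the same-width windows immediately 5' and 3' of each central
    window; the statistic is the per-region difference between the central
    best score and the mean flank best score.
    """
    five, three = flank_scores
    if not (len(scores) == len(five) == len(three)):
        raise ValidationError("central and flank region counts differ")
    c = np.asarray([s.best_score for s in scores], dtype=float)
    f = (np.asarray([s.best_score for s in five], dtype=float)
         + np.asarray([s.best_score for s in three], dtype=float)) / 2.0
    d = c - f
    if np.allclose(d.std(ddof=1), 0.0):
        return 0.0 if d.mean() > 0 else 1.0
    return float(stats.ttest_1samp(d, 0.0, alternative="greater").pvalue)


def rank_enrichments(results: Sequence[MotifEnrichment]) -> None:
    """Assign 1-based global ranks in place (ascending global p, id tiebreak)."""
    order = sorted(results, key=lambda r: (r.global_p, r.matrix_id))
    for rank, r in enumerate(order, 1):
        r.rank_global = rank


def classify_ccaat(all_matrix_results: Sequence[MotifEnrichment],
                   cfg: AnalysisConfig | None = None) -> str:
    """CCAAT enrichment class for one factor from its per-matrix results.

    ``global_primary`` if CCAAT is globally significant and the top-ranked
    matrix; ``global_secondary`` if globally significant but outranked;
    ``local_only`` if only locally significant; ``none`` otherwise.
    """
    cfg = cfg or AnalysisConfig()
    ccaat = next((r for r in all_matrix_results
                  if r.matrix_id == cfg.ccaat_matrix_id), None)
    if ccaat is None:
        raise ValidationError(f"CCAAT matrix {cfg.ccaat_matrix_id} not among results")
    if ccaat.rank_global == 0:
        rank_enrichments(list(all_matrix_results))
    thr = cfg.motif_p_threshold
    if ccaat.global_p < thr:
        cls = "global_primary" if ccaat.rank_global == 1 else "global_secondary"
    elif ccaat.local_p < thr:
        cls = "local_only"
    else:
        cls = "none"
    ccaat.enrichment_class = cls
    return cls


# ---------------------------------------------------------------------------
# positional bias


def middle_a_offset(ccaat_pwm: PositionWeightMatrix) -> int:
    """Offset of the middle A of the CCAAT pentanucleotide within the matrix.

    Located by finding ``CCAAT`` in the consensus and taking its third base,
    so any CCAAT-box matrix can be swapped in.
    """
    idx = ccaat_pwm.consensus.find("CCAAT")
    if idx < 0:
        raise ValidationError(
            f"matrix {ccaat_pwm.matrix_id}: consensus "
            f"{ccaat_pwm.consensus!r} contains no CCAAT pentanucleotide")
    return idx + 2


def motif_center(start: int, length: int) -> int:
    """Integer motif-center convention used throughout: start + length // 2."""
    return start + length // 2


def positional_bias(co_bound: PeakSet, seq: Mapping[str, np.ndarray],
                    tf_pwm: PositionWeightMatrix,
                    ccaat_pwm: PositionWeightMatrix,
                    cfg: AnalysisConfig | None = None,
                    width: int = REGION_WIDTH) -> PositionalBias:
    """Signed TF-motif to CCAAT-middle-A distances in co-bound regions.

    Distances are measured on the CCAAT-defining strand: negative means the
    TF motif lies 5' of the CCAAT box.  Regions whose best CCAAT match falls
    below the normalized-score threshold are excluded (and counted).  The
    non-uniformity p-value is a chi-square against a uniform distribution
    over the attainable offsets, binned so expected counts stay reasonable.
    """
    cfg = cfg or AnalysisConfig()
    ma_off = middle_a_offset(ccaat_pwm)
    cc = scan_regions(seq, co_bound, ccaat_pwm, cfg, width=width)
    tf = scan_regions(seq, co_bound, tf_pwm, cfg, width=width)
    Lc, Lt = ccaat_pwm.length, tf_pwm.length
    offsets: list[int] = []
    ranges: list[tuple[int, int]] = []  # attainable offset interval per region
    orientation = {"same": 0, "opposite": 0}
    excluded = 0
    for c, t in zip(cc, tf):
        if c.best_score < cfg.min_ccaat_match:
            excluded += 1
            continue
        if c.best_strand == "+":
            mid_a = c.best_pos + ma_off
        else:
            mid_a = c.best_pos + (Lc - 1 - ma_off)
        d = motif_center(t.best_pos, Lt) - mid_a
        if c.best_strand == "-":
            d = -d
        offsets.append(d)
        orientation["same" if t.best_strand == c.best_strand else "opposite"] += 1
        # attainable TF-center positions within this region, relative to the
        # observed middle A (the null places the TF hit uniformly there)
        w_r = len(c.region)
        c_lo, c_hi = Lt // 2, (w_r - Lt) + Lt // 2
        d_lo, d_hi = c_lo - mid_a, c_hi - mid_a
        if c.best_strand == "-":
            d_lo, d_hi = -d_hi, -d_lo
        ranges.append((d_lo, d_hi))
    arr = np.asarray(offsets, dtype=int)
    if len(arr) == 0:
        return PositionalBias(arr, orientation, 1.0, None, excluded)
    # mode over exact integer offsets (smallest value on ties)
    vals, cnts = np.unique(arr, return_counts=True)
    mode = int(vals[np.argmax(cnts)])
    # chi-square against the aggregated uniform-over-attainable-offsets null,
    # binned so expected counts stay reasonable
    lo = min(r[0] for r in ranges)
    hi = max(r[1] for r in ranges)
    support = np.zeros(hi - lo + 1)
    for d_lo, d_hi in ranges:
        support[d_lo - lo:d_hi - lo + 1] += 1.0 / (d_hi - d_lo + 1)
    n_bins = max(2, min(hi - lo + 1, len(arr) // 5 or 2))
    edges = np.linspace(lo, hi + 1, n_bins + 1)
    hist, _ = np.histogram(arr, bins=edges)
    expected, _ = np.histogram(np.arange(lo, hi + 1), bins=edges, weights=support)
    keep = expected > 0
    expected = expected[keep] * hist.sum() / expected[keep].sum()
    chi_p = float(stats.chisquare(hist[keep], expected).pvalue)
    return PositionalBias(arr, orientation, chi_p, mode, excluded)
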