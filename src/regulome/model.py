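"""Shared genomic data model for the NF-Y co-association pipeline.

Coordinates are 0-based, half-open (`[start, end)`) throughout, matching the
BED/narrowPeak convention of the input files.  Summits are single 0-based
positions.  Peak strand is ignored in all overlap math (ChIP-seq peaks are
unstranded); strand matters only for promoter windows and motif scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end {self.end} <= start {self.start} on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq peak with its summit (position of maximal signal)."""

    interval: GenomicInterval
    summit: int
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.signal < 0:
            raise ValidationError("peak signal must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class PeakSet:
    """A named collection of peaks, kept sorted by (chrom, summit).

    This is the unit of all overlap computation.  Duplicate summit positions
    are retained (ENCODE files occasionally contain them).
    """

    def __init__(
        self,
        factor: str,
        cell_line: str,
        peaks: Iterable[Peak],
        experiment_id: str = "",
        is_tagged: bool = False,
    ) -> None:
        if not factor:
            raise ValidationError("PeakSet factor name is empty")
        if not cell_line:
            raise ValidationError("PeakSet cell line is empty")
        self.factor = factor
        self.cell_line = cell_line
        self.experiment_id = experiment_id or f"{factor}_{cell_line}"
        self.is_tagged = is_tagged
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.summit))
        self._summits: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def summits_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted summit positions per chromosome (cached)."""
        if self._summits is None:
            out: dict[str, list[int]] = {}
            for p in self.peaks:
                out.setdefault(p.chrom, []).append(p.summit)
            self._summits = {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}
        return self._summits

    def subset(self, keep: Sequence[bool], suffix: str = "") -> "PeakSet":
        peaks = [p for p, k in zip(self.peaks, keep) if k]
        return PeakSet(
            self.factor,
            self.cell_line,
            peaks,
            experiment_id=self.experiment_id + suffix,
            is_tagged=self.is_tagged,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PeakSet({self.factor}/{self.cell_line}, n={len(self)}, "
            f"id={self.experiment_id})"
        )


@dataclass
class PositionWeightMatrix:
    """A nucleotide count matrix (JASPAR-style PFM).

    ``counts`` has shape (length, 4) with columns ordered A, C, G, T.
    """

    matrix_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError("PWM counts must have shape (length, 4)")
        if self.length < 4:
            raise ValidationError(f"motif width {self.length} < 4")
        if np.any(self.counts < 0):
            raise ValidationError("PWM counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValidationError("every PWM position needs a positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=1))

    def log_odds(self, background: np.ndarray | None = None, pseudo_frac: float = 0.01) -> np.ndarray:
        """Log2-odds matrix with a per-cell pseudocount of ``pseudo_frac``
        times the column total (avoids -inf on zero counts)."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        totals = self.counts.sum(axis=1, keepdims=True)
        c = self.counts + pseudo_frac * totals
        probs = c / c.sum(axis=1, keepdims=True)
        return np.log2(probs / bg)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(self.matrix_id, self.name, self.counts[::-1, ::-1])


@dataclass
class ChromatinSegmentation:
    """Non-overlapping chromatin-state segments (chromHMM-style)."""

    segments: list[tuple[GenomicInterval, str]]
    state_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s[0].chrom, s[0].start))
        prev: GenomicInterval | None = None
        for iv, _ in self.segments:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValidationError(
                    f"overlapping segments at {iv.chrom}:{iv.start} (< {prev.end})"
                )
            prev = iv
        if not self.state_labels:
            self.state_labels = sorted({lab for _, lab in self.segments})


@dataclass
class GeneAnnotation:
    """Minimal gene model: one TSS and strand per gene."""

    genes: list[tuple[str, str, int, str]]  # (gene_id, chrom, tss, strand)

    def __post_init__(self) -> None:
        ids = [g[0] for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValidationError("gene ids are not unique")
        for gid, chrom, tss, strand in self.genes:
            if strand not in {"+", "-"}:
                raise ValidationError(f"gene {gid}: strand must be + or -")
            if tss < 0:
                raise ValidationError(f"gene {gid}: negative TSS")

    def gene_ids(self) -> set[str]:
        return {g[0] for g in self.genes}


@dataclass
class DegTable:
    """Per-gene differential-expression records (DESeq2-shaped)."""

    records: list[tuple[str, float, float]]  # (gene_id, log2_fold_change, fdr)
    fdr_max: float = 0.01
    abs_lfc_min: float = 1.0

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("DEG table gene ids are not unique")
        for gid, _lfc, fdr in self.records:
            if not (0.0 <= fdr <= 1.0):
                raise ValidationError(f"gene {gid}: FDR {fdr} outside [0,1]")


@dataclass
class AnalysisConfig:
    """Every numeric threshold of the analysis, in one place.

    Defaults are the published operating point of the pipeline:
    300 bp overlap windows (max summit distance 150 bp), a Poisson null on
    250,000 accessible 150 bp regions, co-association significance at
    score > 100 with > 10% anchor share, motif enrichment at p < 1e-10, the
    20% / 5% partner-group share boundaries, replicate curation at >= 10,000
    peaks and > 66% concordance, promoter windows (-1000, +100) for pathway
    assignment and (-450, +50) for TFBS enrichment, pathway filtering at
    p < 1e-5 with background <= 200 genes, and DEG calls at FDR < 0.01 with
    |log2FC| > 1.
    """

    overlap_half_window: int = 150
    accessible_regions_n: int = 250_000
    accessible_region_width: int = 150
    motif_p_threshold: float = 1e-10
    coassoc_score_threshold: float = 100.0
    nfyb_share_threshold: float = 0.10
    group1_min_factor_share: float = 0.20  # strict >
    group3_max_factor_share: float = 0.05  # strict <
    min_peaks_replicate: int = 10_000
    replicate_overlap_keep: float = 0.66
    minima_overlap_discard: float = 0.50
    promoter_window_pathways: tuple[int, int] = (-1000, 100)
    promoter_window_tfbs: tuple[int, int] = (-450, 50)
    pathway_p_threshold: float = 1e-5
    pathway_max_background: int = 200
    deg_fdr: float = 0.01
    deg_abs_lfc: float = 1.0
    segmentation_bin: int = 200
    ccaat_matrix_id: str = "MA0060.1"
    min_ccaat_match: float = 0.8
    pwm_pseudocount_frac: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.accessible_regions_n <= 0:
            raise ValidationError("accessible_regions_n must be positive")
        if self.overlap_half_window <= 0:
            raise ValidationError("overlap_half_window must be positive")
        for name in ("nfyb_share_threshold", "group1_min_factor_share",
                     "group3_max_factor_share", "replicate_overlap_keep",
                     "minima_overlap_discard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0,1]")
        for w in (self.promoter_window_pathways, self.promoter_window_tfbs):
            if w[0] >= w[1]:
                raise ValidationError(f"promoter window {w} not well-ordered")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    @classmethod
    def from_mapping(cls, m: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        bad = set(m) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        kw = dict(m)
        for key in ("promoter_window_pathways", "promoter_window_tfbs"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)
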