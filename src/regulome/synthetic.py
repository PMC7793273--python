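"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the structure the analysis assumes: a genome with
disjoint 150 bp accessible regions, peak sets whose summits occupy those
regions with planted pairwise co-association fractions, sequences with motif
consensus pairs planted at fixed signed offsets from the CCAAT middle A,
toy chromatin segmentations and gene annotations, and DEG tables with
planted UP/DOWN target-set overlaps.  Everything is reproducible bit-for-bit
under a fixed seed: one global seed fans out to per-stage child seeds via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import encode_sequence
from .model import (
    BASE_INDEX,
    ChromatinSegmentation,
    DegTable,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    PositionWeightMatrix,
    ValidationError,
)

ACCESSIBLE_WIDTH = 150  # bp, the DNase-hypersensitive region width of the null
SUMMIT_JITTER = 50  # bp, uniform summit jitter around region centers

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_pwm(consensus: str, matrix_id: str, name: str,
                  strength: float = 85.0, other: float = 5.0) -> PositionWeightMatrix:
    """A count matrix with one dominant base per position."""
    counts = np.full((len(consensus), 4), other)
    for i, base in enumerate(consensus):
        counts[i, BASE_INDEX[base]] = strength
    return PositionWeightMatrix(matrix_id, name, counts)


def ccaat_box_pwm(matrix_id: str = "MA0060.1") -> PositionWeightMatrix:
    """A synthetic 16 bp CCAAT-box matrix (stand-in for the JASPAR NF-YA
    matrix of the same id; the real counts are external data).  The consensus
    contains a single CCAAT pentanucleotide, so the middle-A locator works."""
    return consensus_pwm("GATTGGCCAATCAGCA", matrix_id, "NFYA-synthetic")


@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    accessible_regions: list[GenomicInterval]
    sequence: dict[str, np.ndarray] | None = None

    def region_centers(self) -> np.ndarray:
        return np.asarray([(iv.start + iv.end) // 2 for iv in self.accessible_regions])


@dataclass
class MotifPlant:
    """One planting instruction: CCAAT at region centers, an optional partner
    consensus at a signed center-to-middle-A offset and orientation."""

    partner: PositionWeightMatrix | None = None
    offset: int = 0
    orientation: str = "+"
    fraction: float = 1.0
    region_indices: Sequence[int] | None = None  # default: all regions


@dataclass
class PlantSpec:
    """Ground-truth container for planted peak sets."""

    n_factors: int
    peaks_per_factor: int
    coassoc: np.ndarray  # symmetric pairwise planted overlap fractions
    factor_names: list[str] = field(default_factory=list)
    cell_line: str = "SYN1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.coassoc = np.asarray(self.coassoc, dtype=float)
        if self.coassoc.shape != (self.n_factors, self.n_factors):
            raise ValidationError("coassoc matrix shape must be (n_factors, n_factors)")
        if not np.allclose(self.coassoc, self.coassoc.T):
            raise ValidationError("coassoc matrix must be symmetric")
        if np.any(self.coassoc < 0) or np.any(self.coassoc > 1):
            raise ValidationError("planted overlap fractions must be in [0,1]")
        if not self.factor_names:
            self.factor_names = [f"TF{i:02d}" for i in range(self.n_factors)]


def make_genome(n_chroms: int, chrom_len: int, n_accessible: int,
                seed: int) -> SyntheticGenome:
    """Place ``n_accessible`` disjoint 150 bp accessible regions uniformly at
    random across ``n_chroms`` chromosomes of equal length."""
    w = ACCESSIBLE_WIDTH
    if n_accessible * w > n_chroms * chrom_len:
        raise ValidationError(
            f"cannot pack {n_accessible} x {w} bp regions into "
            f"{n_chroms} x {chrom_len} bp")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    # proportional split of regions across chromosomes
    base = n_accessible // n_chroms
    counts = [base + (1 if i < n_accessible % n_chroms else 0)
              for i in range(n_chroms)]
    regions: list[GenomicInterval] = []
    for chrom, n in zip(chrom_sizes, counts):
        if n * w > chrom_len:
            raise ValidationError(f"{chrom}: cannot pack {n} regions")
        # gap method: n sorted draws from the free space, then spread by w
        free = chrom_len - n * w
        starts = np.sort(rng.integers(0, free + 1, size=n)) + w * np.arange(n)
        regions.extend(GenomicInterval(chrom, int(s), int(s) + w) for s in starts)
    return SyntheticGenome(chrom_sizes, regions)


def plant_peaksets(genome: SyntheticGenome, spec: PlantSpec) -> tuple[list[PeakSet], dict]:
    """Peak sets with planted pairwise co-association.

    Summits are sampled from accessible-region centers with uniform +/-50 bp
    jitter.  For each pair (i, j) with planted fraction f, ``round(f * n)``
    of factor j's summits are placed in regions occupied by factor i, which
    keeps the summit pair within the 150 bp rule (jitter difference <= 100).
    Returns the peak sets plus a ground-truth echo.
    """
    n_regions = len(genome.accessible_regions)
    npk = spec.peaks_per_factor
    if npk > n_regions:
        raise ValidationError("peaks_per_factor exceeds accessible regions")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    centers = genome.region_centers()
    chroms = [iv.chrom for iv in genome.accessible_regions]
    region_of: list[np.ndarray] = []  # region indices chosen per factor
    peaksets: list[PeakSet] = []
    for j in range(spec.n_factors):
        chosen: list[int] = []
        used: set[int] = set()
        for i in range(j):
            f = spec.coassoc[i, j]
            n_shared = int(round(f * npk))
            if n_shared == 0:
                continue
            if len(chosen) + n_shared > npk:
                raise ValidationError(
                    f"planted fractions for factor {spec.factor_names[j]} "
                    f"demand more than {npk} peaks")
            pool = [r for r in region_of[i] if r not in used]
            if n_shared > len(pool):
                raise ValidationError("planted fraction demands more shared "
                                      "regions than are available")
            take = rng.choice(len(pool), size=n_shared, replace=False)
            sel = [pool[t] for t in take]
            chosen.extend(sel)
            used.update(sel)
        n_rest = npk - len(chosen)
        pool = np.setdiff1d(np.arange(n_regions), np.asarray(list(used), dtype=int))
        rest = rng.choice(pool, size=n_rest, replace=False)
        chosen.extend(int(r) for r in rest)
        idx = np.asarray(chosen, dtype=int)
        region_of.append(idx)
        jitter = rng.integers(-SUMMIT_JITTER, SUMMIT_JITTER + 1, size=npk)
        peaks = []
        for r, dj in zip(idx, jitter):
            summit = int(centers[r] + dj)
            start = max(0, summit - 100)
            peaks.append(Peak(GenomicInterval(chroms[r], start, summit + 100),
                              summit, signal=1.0, name=f"{spec.factor_names[j]}_{r}"))
        peaksets.append(PeakSet(spec.factor_names[j], spec.cell_line, peaks,
                                experiment_id=f"{spec.factor_names[j]}_{spec.cell_line}"))
    echo = {
        "planted_coassoc": spec.coassoc.copy(),
        "factor_names": list(spec.factor_names),
        "region_indices": {spec.factor_names[j]: region_of[j]
                           for j in range(spec.n_factors)},
    }
    return peaksets, echo


def plant_sequences(genome: SyntheticGenome, ccaat: PositionWeightMatrix,
                    plants: Sequence[MotifPlant], seed: int) -> dict:
    """Fill the genome with i.i.d. uniform sequence and plant motif pairs.

    In the stated fraction of each plant's regions the CCAAT consensus is
    written with its middle A at the region center; the partner consensus is
    centered at the signed offset from that middle A (negative = 5' of
    CCAAT), reverse-complemented for ``orientation == "-"``.  Returns an echo
    of planted region indices per plant; the genome's ``sequence`` is set.
    """
    from .motifs import middle_a_offset, motif_center  # local import, no cycle

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    genome.sequence = {
        chrom: rng.integers(0, 4, size=size, dtype=np.uint8)
        for chrom, size in genome.chrom_sizes.items()
    }
    ma_off = middle_a_offset(ccaat)
    cc_codes = encode_sequence(ccaat.consensus)
    echo: list[np.ndarray] = []
    for plant in plants:
        indices = (np.arange(len(genome.accessible_regions))
                   if plant.region_indices is None
                   else np.asarray(plant.region_indices, dtype=int))
        n_plant = int(round(plant.fraction * len(indices)))
        sel = rng.choice(indices, size=n_plant, replace=False) if n_plant else np.asarray([], int)
        for r in sel:
            iv = genome.accessible_regions[int(r)]
            center = (iv.start + iv.end) // 2
            cc_start = center - ma_off
            if cc_start < iv.start or cc_start + ccaat.length > iv.end:
                raise ValidationError("CCAAT placement outside region")
            genome.sequence[iv.chrom][cc_start:cc_start + ccaat.length] = cc_codes
            if plant.partner is not None:
                L = plant.partner.length
                p_start = center + plant.offset - L // 2
                if p_start < iv.start or p_start + L > iv.end:
                    raise ValidationError(
                        f"partner placement at offset {plant.offset} outside region")
                cons = plant.partner.consensus
                if plant.orientation == "-":
                    cons = reverse_complement(cons)
                genome.sequence[iv.chrom][p_start:p_start + L] = encode_sequence(cons)
        echo.append(np.sort(sel))
    return {"planted_regions": echo}


def toy_segmentation(genome: SyntheticGenome, n_states: int = 18,
                     seed: int = 0, bin_size: int = 200) -> ChromatinSegmentation:
    """Random 18-state segmentation in 200 bp bins covering each chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    labels = [f"E{i + 1}" for i in range(n_states)]
    segments = []
    for chrom, size in genome.chrom_sizes.items():
        n_bins = size // bin_size
        states = rng.integers(0, n_states, size=n_bins)
        start = 0
        for b in range(n_bins):
            # merge consecutive identical states into one segment
            if b + 1 < n_bins and states[b + 1] == states[b]:
                continue
            end = (b + 1) * bin_size
            segments.append((GenomicInterval(chrom, start, end), labels[states[b]]))
            start = end
    return ChromatinSegmentation(segments, state_labels=labels)


def toy_gene_annotation(genome: SyntheticGenome, fraction_near_regions: float = 0.8,
                        seed: int = 0, n_genes: int | None = None) -> GeneAnnotation:
    """Genes whose TSSs sit near accessible-region centers (the given
    fraction) or at random positions, with random strands."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    centers = genome.region_centers()
    chroms = [iv.chrom for iv in genome.accessible_regions]
    n = n_genes if n_genes is not None else len(centers)
    genes = []
    for g in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < fraction_near_regions and g < len(centers):
            chrom, tss = chroms[g], int(centers[g] + rng.integers(-200, 201))
        else:
            chrom = rng.choice(list(genome.chrom_sizes))
            tss = int(rng.integers(0, genome.chrom_sizes[chrom]))
        genes.append((f"G{g:05d}", chrom, max(tss, 0), strand))
    return GeneAnnotation(genes)


def plant_deg_tables(n_genes: int, frac_up: float, frac_down: float,
                     tf_target_overlaps: Mapping[tuple[str, str], float] | None,
                     seed: int, factor_names: Sequence[str] = (),
                     targets_per_factor: int | None = None,
                     ) -> tuple[DegTable, dict[str, dict[str, set[str]]], dict]:
    """A DEG table with exact planted UP/DOWN counts plus per-factor target
    sets with planted pairwise overlaps inside each state's DEG universe.

    DEGs get FDR < 0.01 and |log2FC| > 1 by construction; neutral genes are
    kept safely outside both thresholds.
    """
    if frac_up + frac_down > 1:
        raise ValidationError("frac_up + frac_down > 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    perm = rng.permutation(n_genes)
    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    up_ids = [gene_ids[i] for i in perm[:n_up]]
    down_ids = [gene_ids[i] for i in perm[n_up:n_up + n_down]]
    records = []
    up_set, down_set = set(up_ids), set(down_ids)
    for gid in gene_ids:
        if gid in up_set:
            lfc = float(rng.uniform(1.2, 5.0))
            fdr = float(rng.uniform(0.0, 0.009))
        elif gid in down_set:
            lfc = float(-rng.uniform(1.2, 5.0))
            fdr = float(rng.uniform(0.0, 0.009))
        else:
            lfc = float(rng.uniform(-0.9, 0.9))
            fdr = float(rng.uniform(0.02, 1.0))
        records.append((gid, lfc, fdr))
    table = DegTable(records)

    targets: dict[str, dict[str, set[str]]] = {"UP": {}, "DOWN": {}}
    overlaps = dict(tf_target_overlaps or {})
    names = list(factor_names)
    for state, universe in (("UP", up_ids), ("DOWN", down_ids)):
        if not universe:
            targets[state] = {name: set() for name in names}
            continue
        m = targets_per_factor or max(1, len(universe) // 3)
        if m > len(universe):
            raise ValidationError("targets_per_factor exceeds state universe")
        drawn: dict[str, set[str]] = {}
        for j, name in enumerate(names):
            chosen: set[str] = set()
            for i in range(j):
                f = overlaps.get((names[i], name), overlaps.get((name, names[i]), 0.0))
                n_shared = int(round(f * m))
                if n_shared == 0:
                    continue
                pool = sorted(drawn[names[i]] - chosen)
                if len(chosen) + n_shared > m or n_shared > len(pool):
                    raise ValidationError("inconsistent target-overlap demands")
                chosen.update(rng.choice(pool, size=n_shared, replace=False))
            rest_pool = sorted(set(universe) - chosen)
            chosen.update(rng.choice(rest_pool, size=m - len(chosen), replace=False))
            drawn[name] = chosen
        targets[state] = drawn
    echo = {"n_up": n_up, "n_down": n_down, "overlaps": overlaps,
            "targets_per_factor": targets_per_factor}
    return table, targets, echo
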