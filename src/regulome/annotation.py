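"""Chromatin-state distributions, promoter target assignment, and pathway
over-representation with the published filtering and merging rules.

Pathway ORA is an in-repo one-sided hypergeometric test (the original
analysis used an external multi-database service; the statistic here is a
reconstruction on GMT-style gene sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coassociation import restrict_to_anchor
from .model import (
    AnalysisConfig,
    ChromatinSegmentation,
    GeneAnnotation,
    PeakSet,
    ValidationError,
)


@dataclass
class StateDistribution:
    factor: str
    scope: str  # "all_peaks" or "co_bound_with_anchor"
    counts: dict[str, int]
    unannotated: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / total for k, v in self.counts.items()}


@dataclass
class TargetGeneSet:
    factor: str
    genes: set[str]


@dataclass
class PathwayRow:
    pathway_id: str
    name: str
    background_size: int
    p_values: dict[str, float]  # per factor
    contributing_genes: frozenset[str]
    merged_ids: list[str] = field(default_factory=list)


@dataclass
class PathwayMatrix:
    rows: list[PathwayRow]
    factors: list[str]

    def membership(self, p_threshold: float) -> np.ndarray:
        """Binary factor x pathway table at the given significance."""
        out = np.zeros((len(self.factors), len(self.rows)), dtype=int)
        for j, row in enumerate(self.rows):
            for i, f in enumerate(self.factors):
                if row.p_values.get(f, 1.0) < p_threshold:
                    out[i, j] = 1
        return out


def state_distribution(peaks: PeakSet, seg: ChromatinSegmentation,
                       scope_filter: PeakSet | None = None,
                       cfg: AnalysisConfig | None = None) -> StateDistribution:
    """Assign each summit to the half-open segment containing it.

    With ``scope_filter``, only summits within the overlap window of the
    anchor's summits are counted.  Summits in no segment are reported
    separately as unannotated.
    """
    cfg = cfg or AnalysisConfig()
    ps = peaks if scope_filter is None else restrict_to_anchor(peaks, scope_filter, cfg)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for iv, label in seg.segments:
        by_chrom.setdefault(iv.chrom, ([], [], []))  # type: ignore[arg-type]
    tmp: dict[str, list] = {c: [[], [], []] for c in by_chrom}
    for iv, label in seg.segments:
        tmp[iv.chrom][0].append(iv.start)
        tmp[iv.chrom][1].append(iv.end)
        tmp[iv.chrom][2].append(label)
    index = {c: (np.asarray(v[0]), np.asarray(v[1]), v[2]) for c, v in tmp.items()}
    counts = {label: 0 for label in seg.state_labels}
    unannotated = 0
    for p in ps:
        entry = index.get(p.chrom)
        if entry is None:
            unannotated += 1
            continue
        starts, ends, labels = entry
        i = int(np.searchsorted(starts, p.summit, side="right")) - 1
        if i >= 0 and p.summit < ends[i]:
            counts[labels[i]] = counts.get(labels[i], 0) + 1
        else:
            unannotated += 1
    scope = "all_peaks" if scope_filter is None else "co_bound_with_anchor"
    return StateDistribution(peaks.factor, scope, counts, unannotated)


def promoter_targets(co_bound: PeakSet, ann: GeneAnnotation,
                     window: tuple[int, int] | None = None,
                     cfg: AnalysisConfig | None = None) -> TargetGeneSet:
    """Genes with a summit in their promoter window.

    The window is (-1000, +100) around the TSS by default (strand-mirrored
    for minus-strand genes, both ends inclusive); pass
    ``cfg.promoter_window_tfbs`` for the proximal (-450, +50) variant.
    """
    cfg = cfg or AnalysisConfig()
    up, down = window if window is not None else cfg.promoter_window_pathways
    summits = co_bound.summits_by_chrom()
    hits: set[str] = set()
    for gid, chrom, tss, strand in ann.genes:
        s = summits.get(chrom)
        if s is None or len(s) == 0:
            continue
        if strand == "+":
            lo, hi = tss + up, tss + down
        else:
            lo, hi = tss - down, tss - up
        if np.searchsorted(s, hi, side="right") > np.searchsorted(s, lo, side="left"):
            hits.add(gid)
    return TargetGeneSet(co_bound.factor, hits)


def pathway_ora(targets: TargetGeneSet,
                pathways: Mapping[str, tuple[str, set[str]]],
                universe: set[str]) -> dict[str, float]:
    """One-sided hypergeometric upper-tail p per pathway.

    The 2x2 margins are (target, pathway) membership within the universe.
    """
    if not universe:
        raise ValidationError("empty gene universe")
    tset = targets.genes & universe
    M, n = len(universe), len(tset)
    out: dict[str, float] = {}
    for pid, (_name, genes) in pathways.items():
        pset = genes & universe
        k = len(tset & pset)
        out[pid] = float(stats.hypergeom.sf(k - 1, M, len(pset), n))
    return out


def build_pathway_matrix(results: Mapping[str, dict[str, float]],
                         pathways: Mapping[str, tuple[str, set[str]]],
                         target_sets: Mapping[str, TargetGeneSet],
                         cfg: AnalysisConfig | None = None) -> PathwayMatrix:
    """Filter and merge per-factor ORA results into a pathway matrix.

    Rows are kept when some factor's p-value is below the threshold and the
    pathway background is at most 200 genes.  Rows whose contributing gene
    sets (union over significant factors of targets-in-pathway) are
    identical are merged into the most general one: the largest background,
    ties broken lexicographically by pathway id.  Order-independent.
    """
    cfg = cfg or AnalysisConfig()
    factors = sorted(results)
    thr = cfg.pathway_p_threshold
    rows: list[PathwayRow] = []
    for pid in sorted(pathways):
        name, genes = pathways[pid]
        pvals = {f: results[f].get(pid, 1.0) for f in factors}
        if min(pvals.values(), default=1.0) >= thr:
            continue
        if len(genes) > cfg.pathway_max_background:
            continue
        contributing: set[str] = set()
        for f in factors:
            if pvals[f] < thr:
                contributing |= target_sets[f].genes & genes
        rows.append(PathwayRow(pid, name, len(genes), pvals,
                               frozenset(contributing)))
    # merge rows with identical contributing gene sets
    by_genes: dict[frozenset[str], list[PathwayRow]] = {}
    for row in rows:
        by_genes.setdefault(row.contributing_genes, []).append(row)
    merged: list[PathwayRow] = []
    for gset, group in by_genes.items():
        rep = min(group, key=lambda r: (-r.background_size, r.pathway_id))
        rep.merged_ids = sorted(r.pathway_id for r in group if r is not rep)
        # representative keeps the best (smallest) p per factor over the group
        for f in factors:
            rep.p_values[f] = min(r.p_values[f] for r in group)
        merged.append(rep)
    merged.sort(key=lambda r: r.pathway_id)
    return PathwayMatrix(merged, factors)
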