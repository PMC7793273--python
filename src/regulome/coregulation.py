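"""Differential-expression co-regulation downstream of a knockdown.

DEGs are partitioned into UP and DOWN at FDR < 0.01 and |log2FC| > 1 (strict
inequalities).  For each state, pairwise Fisher exact tests measure whether
two factors regulate overlapping sets of DEGs; the -log10 p matrices are
clustered with the same Pearson/centroid procedure as the co-association
heatmaps.  The Fisher universe is the state's DEG set; a whole-annotation
universe is available via the ``universe`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .coassociation import P_FLOOR, CoassocMatrix, cluster_matrix
from .model import AnalysisConfig, DegTable, ValidationError


@dataclass
class DegPartition:
    up: set[str]
    down: set[str]
    neutral: set[str]


@dataclass(frozen=True)
class FisherCoregResult:
    state: str  # "UP" or "DOWN"
    factor_a: str
    factor_b: str
    table: tuple[int, int, int, int]  # both, a_only, b_only, neither
    p: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(max(self.p, P_FLOOR))


def partition_degs(table: DegTable) -> DegPartition:
    """Split genes into UP / DOWN / neutral at the table's thresholds."""
    up, down, neutral = set(), set(), set()
    for gid, lfc, fdr in table.records:
        if fdr < table.fdr_max and lfc > table.abs_lfc_min:
            up.add(gid)
        elif fdr < table.fdr_max and lfc < -table.abs_lfc_min:
            down.add(gid)
        else:
            neutral.add(gid)
    return DegPartition(up, down, neutral)


def fisher_coreg(a_targets: set[str], b_targets: set[str],
                 state_universe: set[str], state: str = "UP",
                 factor_a: str = "a", factor_b: str = "b") -> FisherCoregResult:
    """Two-sided Fisher exact test of target-set overlap within a state's
    DEG universe (point-probability method, the scipy default)."""
    if not state_universe:
        raise ValidationError("empty state universe")
    a = a_targets & state_universe
    b = b_targets & state_universe
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = len(state_universe) - both - a_only - b_only
    p = float(stats.fisher_exact([[both, a_only], [b_only, neither]],
                                 alternative="two-sided")[1])
    return FisherCoregResult(state, factor_a, factor_b,
                             (both, a_only, b_only, neither), p)


def coreg_matrix(target_sets: Mapping[str, set[str]], state_universe: set[str],
                 state: str) -> CoassocMatrix:
    """Square -log10 Fisher p matrix over all factor pairs for one state."""
    factors = sorted(target_sets)
    n = len(factors)
    scores = np.zeros((n, n))
    for i, fa in enumerate(factors):
        for j, fb in enumerate(factors):
            if j < i:
                scores[i, j] = scores[j, i]
                continue
            res = fisher_coreg(target_sets[fa], target_sets[fb],
                               state_universe, state, fa, fb)
            scores[i, j] = res.neg_log10_p
    return CoassocMatrix(factors, scores, mode=f"coreg:{state}")


def coreg_heatmaps(target_sets_by_state: Mapping[str, Mapping[str, set[str]]],
                   partition: DegPartition,
                   method: str = "centroid") -> dict[str, tuple]:
    """Clustered -log10 Fisher matrices, one per state (UP and DOWN)."""
    out = {}
    for state, universe in (("UP", partition.up), ("DOWN", partition.down)):
        sets = target_sets_by_state.get(state)
        if not sets or len(sets) < 2:
            continue
        m = coreg_matrix(sets, universe, state)
        out[state] = (m, cluster_matrix(m, method=method))
    return out


def expression_shift_report(table: DegTable, factor_list: Sequence[str],
                            flag_abs_lfc: float = 0.5) -> dict:
    """Per-factor log2FC / FDR lookup with |log2FC| >= 0.5 flags.

    Factors absent from the table are listed as missing, not fatal.
    """
    by_gene = {gid: (lfc, fdr) for gid, lfc, fdr in table.records}
    rows, missing, flagged = [], [], []
    for f in factor_list:
        if f not in by_gene:
            missing.append(f)
            continue
        lfc, fdr = by_gene[f]
        rows.append((f, lfc, fdr))
        if abs(lfc) >= flag_abs_lfc:
            flagged.append(f)
    return {"rows": rows, "missing": missing, "flagged": flagged}
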