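"""Four-group classification of NF-Y partner factors.

Groups, evaluated in order:

1. global CCAAT enrichment (primary or secondary) and factor share of
   peaks overlapping NF-YB strictly above 20% in at least one dataset;
2. CCAAT enrichment of any class and factor share in [5%, 20%] in some
   dataset (20% itself lands here, per the published boundary cases);
3. CCAAT enrichment but factor share below 5% in every dataset;
4. no CCAAT enrichment, but NF-YB shares more than 10% of its peaks with
   the factor at a co-association score above 100 in some dataset.

Treated-condition datasets are classified per dataset, so one factor can
appear in several groups across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AnalysisConfig, ValidationError

GLOBAL_CLASSES = {"global_primary", "global_secondary"}
CCAAT_CLASSES = GLOBAL_CLASSES | {"local_only"}


@dataclass(frozen=True)
class CellLineRecord:
    cell_line: str
    enrichment_class: str  # global_primary | global_secondary | local_only | none
    factor_share: float  # fraction of the factor's peaks overlapping NF-YB
    nfyb_share: float  # fraction of NF-YB peaks overlapping the factor
    coassoc_score: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.factor_share, self.nfyb_share):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"share {v} outside [0,1]")


@dataclass
class FactorSummary:
    factor: str
    records: list[CellLineRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError(f"{self.factor}: no cell-line records")


@dataclass
class GroupAssignment:
    factor: str
    group: int | None  # 1..4 or None
    qualifying_cell_lines: list[str] = field(default_factory=list)
    rationale: str = ""


def assign_group(summary: FactorSummary,
                 cfg: AnalysisConfig | None = None) -> GroupAssignment:
    """Assign one factor to a co-association group from its per-cell-line
    enrichment classes and overlap shares."""
    cfg = cfg or AnalysisConfig()
    recs = summary.records
    hi = cfg.group1_min_factor_share  # 0.20, strict > for group 1
    lo = cfg.group3_max_factor_share  # 0.05, strict < for group 3

    g1 = [r for r in recs
          if r.enrichment_class in GLOBAL_CLASSES and r.factor_share > hi]
    if g1:
        return GroupAssignment(
            summary.factor, 1, [r.cell_line for r in g1],
            f"global CCAAT enrichment with factor share > {hi:.0%} in "
            f"{[r.cell_line for r in g1]}")

    g2 = [r for r in recs
          if r.enrichment_class in CCAAT_CLASSES and lo <= r.factor_share <= hi]
    if g2:
        return GroupAssignment(
            summary.factor, 2, [r.cell_line for r in g2],
            f"CCAAT enrichment with factor share in [{lo:.0%}, {hi:.0%}] in "
            f"{[r.cell_line for r in g2]}")

    enriched = [r for r in recs if r.enrichment_class in CCAAT_CLASSES]
    if enriched and max(r.factor_share for r in recs) < lo:
        return GroupAssignment(
            summary.factor, 3, [r.cell_line for r in enriched],
            f"CCAAT enrichment but factor share < {lo:.0%} in all datasets")

    g4 = [r for r in recs
          if r.enrichment_class == "none"
          and r.nfyb_share > cfg.nfyb_share_threshold
          and r.coassoc_score > cfg.coassoc_score_threshold]
    if g4 and not enriched:
        return GroupAssignment(
            summary.factor, 4, [r.cell_line for r in g4],
            f"no CCAAT enrichment; NF-YB share > "
            f"{cfg.nfyb_share_threshold:.0%} with score > "
            f"{cfg.coassoc_score_threshold:g} in {[r.cell_line for r in g4]}")

    return GroupAssignment(summary.factor, None, [], "no group rule satisfied")
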