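"""Replicate curation: reduce an experiment manifest to one kept dataset per
factor per cell line.

Stages, applied in order within each (factor, cell line) group:

1. treated experiments are split into a side channel (they are analyzed
   separately, labeled by treatment, and bypass the remaining stages);
2. tagged-antibody duplicates are dropped when an untagged experiment for
   the same factor and cell line exists;
3. "minima" replicates are dropped: fewer than 10,000 peaks, or fewer than
   half the peaks of the next-larger replicate of the same factor;
4. surviving replicate groups are kept only if some pair exceeds 66% summit
   overlap, and then only the member with the most peaks is kept.

Singleton experiments enter the pipeline directly (stages 3-4 concern
replicate groups).  Every drop carries a machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .coassociation import count_overlap
from .model import AnalysisConfig, PeakSet, ValidationError


@dataclass(frozen=True)
class ManifestEntry:
    experiment_id: str
    factor: str
    cell_line: str
    is_tagged: bool = False
    treated: bool = False
    treatment: str = ""


@dataclass
class ExperimentManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.experiment_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("experiment ids are not unique")


@dataclass
class CurationReport:
    kept: list[str] = field(default_factory=list)
    treated: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    counts_by_stage: dict[str, int] = field(default_factory=dict)


def replicate_overlap(a: PeakSet, b: PeakSet,
                      cfg: AnalysisConfig | None = None) -> float:
    """Replicate concordance: the share of the smaller set's summits within
    the overlap window of some summit of the larger set.

    Defined on the smaller set as the most conservative symmetric choice.
    """
    cfg = cfg or AnalysisConfig()
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("replicate overlap needs two non-empty peak sets")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    oc = count_overlap(small, large, cfg)
    return oc.share_a


def curate(manifest: ExperimentManifest, peaks: Mapping[str, PeakSet],
           cfg: AnalysisConfig | None = None) -> CurationReport:
    """Apply the four-stage curation workflow to a manifest."""
    cfg = cfg or AnalysisConfig()
    for e in manifest.entries:
        if e.experiment_id not in peaks:
            raise ValidationError(f"no peak set for experiment {e.experiment_id}")
    report = CurationReport()
    report.counts_by_stage["input"] = len(manifest.entries)

    # stage 1: treated experiments go to the side channel
    main = [e for e in manifest.entries if not e.treated]
    report.treated = [e.experiment_id for e in manifest.entries if e.treated]
    report.counts_by_stage["not_treated"] = len(main)
    report.counts_by_stage["treated"] = len(report.treated)

    groups: dict[tuple[str, str], list[ManifestEntry]] = {}
    for e in main:
        groups.setdefault((e.factor, e.cell_line), []).append(e)

    for (factor, cell_line), entries in sorted(groups.items()):
        # stage 2: drop tagged duplicates when an untagged one exists
        if len(entries) > 1 and any(not e.is_tagged for e in entries):
            for e in entries:
                if e.is_tagged:
                    report.dropped.append((e.experiment_id, "tagged_duplicate"))
            entries = [e for e in entries if not e.is_tagged]
        if len(entries) == 1:
            report.kept.append(entries[0].experiment_id)
            continue
        # stage 3: minima filter within the replicate group
        sized = sorted(entries, key=lambda e: len(peaks[e.experiment_id]))
        survivors = []
        for i, e in enumerate(sized):
            n = len(peaks[e.experiment_id])
            next_larger = next(
                (len(peaks[s.experiment_id]) for s in sized[i + 1:]
                 if len(peaks[s.experiment_id]) > n), None)
            if n < cfg.min_peaks_replicate:
                report.dropped.append((e.experiment_id, "minima_below_min_peaks"))
            elif next_larger is not None and n < cfg.minima_overlap_discard * next_larger:
                report.dropped.append((e.experiment_id, "minima_below_half_of_next"))
            else:
                survivors.append(e)
        if not survivors:
            continue
        if len(survivors) == 1:
            report.kept.append(survivors[0].experiment_id)
            continue
        # stage 4: concordance gate, then keep the largest member
        best_pair_overlap = 0.0
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                ov = replicate_overlap(peaks[survivors[i].experiment_id],
                                       peaks[survivors[j].experiment_id], cfg)
                best_pair_overlap = max(best_pair_overlap, ov)
        if best_pair_overlap > cfg.replicate_overlap_keep:
            winner = max(survivors, key=lambda e: len(peaks[e.experiment_id]))
            report.kept.append(winner.experiment_id)
            for e in survivors:
                if e is not winner:
                    report.dropped.append((e.experiment_id, "smaller_concordant_replicate"))
        else:
            for e in survivors:
                report.dropped.append((e.experiment_id, "replicate_overlap_below_66"))

    report.counts_by_stage["kept"] = len(report.kept)
    report.counts_by_stage["dropped"] = len(report.dropped)
    return report
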