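"""End-to-end orchestration and the fully synthetic demo run.

``run_core`` composes the stages on in-memory objects:
curation -> co-association -> motif enrichment / positional bias ->
group classification -> chromatin states / targets / pathways ->
DEG co-regulation.  ``run_from_files`` is the file-based wrapper;
``demo`` builds a small synthetic cosmos (three cell lines, twelve partner
factors planted as Group 1-4 archetypes around an NF-YB-like anchor) and
checks the classifier recovers the planted groups.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import io as rio
from .annotation import build_pathway_matrix, pathway_ora, promoter_targets, state_distribution
from .coassociation import coassoc_matrix, count_overlap, poisson_score, restrict_to_anchor
from .coregulation import coreg_heatmaps, partition_degs
from .curation import CurationReport, ExperimentManifest, ManifestEntry, curate
from .groups import CellLineRecord, FactorSummary, assign_group
from .model import AnalysisConfig, PeakSet, ValidationError
from .motifs import (
    BackgroundModel,
    MotifEnrichment,
    classify_ccaat,
    global_enrichment,
    local_enrichment,
    positional_bias,
    rank_enrichments,
    scan_regions,
)
from .synthetic import (
    MotifPlant,
    PlantSpec,
    ccaat_box_pwm,
    consensus_pwm,
    make_genome,
    plant_deg_tables,
    plant_peaksets,
    plant_sequences,
    toy_gene_annotation,
    toy_segmentation,
)


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream input."""


@dataclass
class RunConfig:
    """Paths and switches for a file-based run."""

    out_dir: str
    manifest_path: str | None = None
    fasta_path: str | None = None
    jaspar_path: str | None = None
    segmentation_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    deg_path: str | None = None
    anchor_factor: str = "NFYB"
    stages: tuple[str, ...] = ("curate", "coassoc", "motifs", "classify",
                               "states", "targets", "pathways", "coreg")
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def load_run_config(path: str) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file.

    Top-level keys mirror the RunConfig fields; an ``analysis`` mapping
    overrides :class:`AnalysisConfig` defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    analysis = AnalysisConfig.from_mapping(data.pop("analysis", {}))
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return RunConfig(analysis=analysis, **data)


def config_hash(cfg: AnalysisConfig, seed: int) -> str:
    payload = json.dumps({**cfg.__dict__, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def factor_enrichment(peaks: PeakSet, seq: Mapping[str, np.ndarray],
                      matrices: Sequence, background_regions: PeakSet,
                      cfg: AnalysisConfig,
                      bg_cache: dict | None = None) -> list[MotifEnrichment]:
    """Per-matrix global/local enrichment for one factor's peak windows.

    ``bg_cache`` memoizes the per-matrix background model across factors of
    the same cell line.
    """
    results = []
    for pwm in matrices:
        center = scan_regions(seq, peaks, pwm, cfg)
        five = scan_regions(seq, peaks, pwm, cfg, offset=-150)
        three = scan_regions(seq, peaks, pwm, cfg, offset=150)
        key = pwm.matrix_id
        if bg_cache is not None and key in bg_cache:
            bg = bg_cache[key]
        else:
            bg_scores = scan_regions(seq, background_regions, pwm, cfg)
            bg = BackgroundModel.from_scores(bg_scores, keep_sample=False)
            if bg_cache is not None:
                bg_cache[key] = bg
        gp = global_enrichment(center, bg, cfg)
        lp = local_enrichment(center, (five, three), cfg)
        results.append(MotifEnrichment(pwm.matrix_id, gp, lp))
    rank_enrichments(results)
    return results


def run_core(kept_peaks: Mapping[str, dict[str, PeakSet]],
             cfg: AnalysisConfig,
             anchor_factor: str = "NFYB",
             seq_by_cell: Mapping[str, Mapping[str, np.ndarray]] | None = None,
             matrices: Sequence | None = None,
             matrices_by_factor: Mapping[str, Sequence] | None = None,
             background_by_cell: Mapping[str, PeakSet] | None = None,
             segmentation=None, gene_annotation=None, pathways=None,
             deg_table=None, deg_targets=None, stages: Sequence[str] = ()) -> dict:
    """Run the analysis stages on in-memory inputs.

    ``kept_peaks`` maps cell line -> factor -> PeakSet (post-curation).
    Raises :class:`DependencyError` when a requested stage lacks an input.
    """
    stages = tuple(stages) or ("coassoc", "motifs", "classify", "states",
                               "targets", "pathways", "coreg")
    report: dict = {"stages": {}, "timing": {}}
    t0 = time.time()

    def tick(name):
        report["timing"][name] = round(time.time() - t0, 3)

    # --- co-association ----------------------------------------------------
    overlap_records: dict[str, dict[str, dict]] = {}
    if "coassoc" in stages:
        for cell, factors in kept_peaks.items():
            if anchor_factor not in factors:
                raise DependencyError(
                    f"coassoc: anchor factor {anchor_factor} missing in {cell}")
            anchor = factors[anchor_factor]
            n_tests = max(1, len(factors) * (len(factors) - 1))
            recs = {}
            for name, ps in factors.items():
                oc = count_overlap(ps, anchor, cfg)
                res = poisson_score(oc, n_tests=n_tests, cfg=cfg)
                recs[name] = {"factor_share": oc.share_a, "nfyb_share": oc.share_b,
                              "score": res.score, "k": oc.k}
            overlap_records[cell] = recs
        matrices_by_cell = {
            cell: coassoc_matrix(sorted(factors.values(), key=lambda p: p.factor), cfg)
            for cell, factors in kept_peaks.items()}
        report["stages"]["coassoc"] = {"overlaps": overlap_records,
                                       "matrices": matrices_by_cell}
        tick("coassoc")

    # --- motif enrichment --------------------------------------------------
    enrich: dict[str, dict[str, list[MotifEnrichment]]] = {}
    if "motifs" in stages:
        if seq_by_cell is None or background_by_cell is None or (
                matrices is None and matrices_by_factor is None):
            raise DependencyError("motifs: needs sequences, matrices and a "
                                  "background region set")
        for cell, factors in kept_peaks.items():
            enrich[cell] = {}
            bg_cache: dict = {}
            for name, ps in factors.items():
                mats = (matrices_by_factor.get(name, matrices or [])
                        if matrices_by_factor is not None else matrices)
                enrich[cell][name] = factor_enrichment(
                    ps, seq_by_cell[cell], mats, background_by_cell[cell], cfg,
                    bg_cache=bg_cache)
        report["stages"]["motifs"] = enrich
        tick("motifs")

    # --- group classification ---------------------------------------------
    if "classify" in stages:
        if "coassoc" not in stages or "motifs" not in stages:
            raise DependencyError("classify: needs the coassoc and motifs stages")
        all_factors = sorted({f for factors in kept_peaks.values() for f in factors}
                             - {anchor_factor})
        assignments = {}
        for name in all_factors:
            recs = []
            for cell, factors in kept_peaks.items():
                if name not in factors:
                    continue
                cls = classify_ccaat(enrich[cell][name], cfg)
                ov = overlap_records[cell][name]
                recs.append(CellLineRecord(cell, cls, ov["factor_share"],
                                           ov["nfyb_share"], ov["score"]))
            assignments[name] = assign_group(FactorSummary(name, recs), cfg)
        report["stages"]["classify"] = assignments
        tick("classify")

    # --- chromatin states --------------------------------------------------
    if "states" in stages:
        if segmentation is None:
            raise DependencyError("states: needs a chromatin segmentation")
        dists = {}
        for cell, factors in kept_peaks.items():
            anchor = factors.get(anchor_factor)
            for name, ps in factors.items():
                dists[(cell, name)] = state_distribution(
                    ps, segmentation, scope_filter=anchor, cfg=cfg)
        report["stages"]["states"] = dists
        tick("states")

    # --- promoter targets & pathways ---------------------------------------
    target_sets = {}
    if "targets" in stages or "pathways" in stages:
        if gene_annotation is None:
            raise DependencyError("targets: needs a gene annotation")
        for cell, factors in kept_peaks.items():
            anchor = factors.get(anchor_factor)
            for name, ps in factors.items():
                co = ps if anchor is None else restrict_to_anchor(ps, anchor, cfg)
                target_sets[(cell, name)] = promoter_targets(co, gene_annotation,
                                                             cfg=cfg)
        report["stages"]["targets"] = target_sets
        tick("targets")
    if "pathways" in stages:
        if pathways is None:
            raise DependencyError("pathways: needs a GMT gene-set collection")
        universe = gene_annotation.gene_ids()
        ora = {f"{cell}:{name}": pathway_ora(ts, pathways, universe)
               for (cell, name), ts in target_sets.items()}
        flat_targets = {f"{cell}:{name}": ts
                        for (cell, name), ts in target_sets.items()}
        report["stages"]["pathways"] = build_pathway_matrix(
            ora, pathways, flat_targets, cfg)
        tick("pathways")

    # --- DEG co-regulation --------------------------------------------------
    if "coreg" in stages:
        if deg_table is None or deg_targets is None:
            raise DependencyError("coreg: needs a DEG table and per-factor "
                                  "target gene sets")
        partition = partition_degs(deg_table)
        report["stages"]["coreg"] = {
            "partition": partition,
            "heatmaps": coreg_heatmaps(deg_targets, partition),
        }
        tick("coreg")

    return report


# ---------------------------------------------------------------------------
# synthetic demo


DEMO_GROUP_PLAN = {  # planted archetype per partner factor
    "TF_G1a": 1, "TF_G1b": 1, "TF_G1c": 1,
    "TF_G2a": 2, "TF_G2b": 2, "TF_G2c": 2,
    "TF_G3a": 3, "TF_G3b": 3, "TF_G3c": 3,
    "TF_G4a": 4, "TF_G4b": 4, "TF_G4c": 4,
}
#: planted fraction of the factor's peaks sharing regions with the anchor
DEMO_ANCHOR_FRACTION = {1: 0.5, 2: 0.12, 3: 0.0, 4: 0.4}

_MOTIF_ALPHABET = ["TGACTCAG", "GGGCGGAG", "CACGTGAC", "TTCCGGAA",
                   "GATAAGAC", "AACCGGTT", "TGCCAAGG", "AGGTCAAG",
                   "CCGCTAAT", "TTGACGCA", "GAGGAAGT", "ACGCGTAC"]


def demo(seed: int = 42, out_dir: str | None = None,
         n_regions: int = 40_000, peaks_per_factor: int = 600,
         cell_lines: Sequence[str] = ("SYN1", "SYN2", "SYN3")) -> dict:
    """Generate a synthetic cosmos and run the full pipeline on it.

    Twelve partner factors are planted as Group 1-4 archetypes around an
    NF-YB-like anchor in each synthetic cell line; the returned report
    includes the planted truth, the recovered group assignments, the number
    of misclassifications, and the positional-bias mode of the factor
    planted at -11 bp.
    """
    cfg = AnalysisConfig(accessible_regions_n=n_regions, random_seed=seed)
    factor_names = ["NFYB"] + list(DEMO_GROUP_PLAN)
    n = len(factor_names)
    coassoc = np.zeros((n, n))
    for j, name in enumerate(DEMO_GROUP_PLAN, start=1):
        coassoc[0, j] = coassoc[j, 0] = DEMO_ANCHOR_FRACTION[DEMO_GROUP_PLAN[name]]
    ccaat = ccaat_box_pwm(cfg.ccaat_matrix_id)
    own_pwms = {name: consensus_pwm(_MOTIF_ALPHABET[i], f"SYN{i:03d}", name)
                for i, name in enumerate(DEMO_GROUP_PLAN)}

    kept: dict[str, dict[str, PeakSet]] = {}
    seq_by_cell: dict[str, Mapping[str, np.ndarray]] = {}
    bg_by_cell: dict[str, PeakSet] = {}
    posbias_by_cell: dict[str, object] = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cell_lines) + 1)

    for ci, cell in enumerate(cell_lines):
        cseed = int(child_seeds[ci]) % (2**31)
        genome = make_genome(2, 4_000_000, n_regions, seed=cseed)
        spec = PlantSpec(n, peaks_per_factor, coassoc, factor_names=factor_names,
                         cell_line=cell, seed=cseed)
        peaksets, echo = plant_peaksets(genome, spec)
        regions_of = echo["region_indices"]
        # Group 4 archetypes must stay CCAAT-free: exclude every region any
        # of them occupies from all CCAAT planting (they share regions with
        # the anchor and, by chance, with other factors)
        g4_union = np.concatenate([regions_of[f] for f, g in
                                   DEMO_GROUP_PLAN.items() if g == 4])
        plants = []
        for name in DEMO_GROUP_PLAN:
            group = DEMO_GROUP_PLAN[name]
            own = np.setdiff1d(regions_of[name], g4_union)
            if group in (1, 2, 3):
                # CCAAT plus the factor's own motif in its peak regions;
                # the first Group 1 factor carries the -11 bp archetype
                offset = -11 if name == "TF_G1a" else 25
                plants.append(MotifPlant(partner=own_pwms[name], offset=offset,
                                         fraction=0.9, region_indices=own))
        # the anchor's own CCAAT goes in its private regions
        nfyb_private = np.setdiff1d(
            regions_of["NFYB"],
            np.concatenate([regions_of[f] for f in DEMO_GROUP_PLAN]))
        plants.append(MotifPlant(partner=None, fraction=0.9,
                                 region_indices=nfyb_private))
        plant_sequences(genome, ccaat, plants, seed=cseed)

        kept[cell] = {ps.factor: ps for ps in peaksets}
        seq_by_cell[cell] = genome.sequence
        used = np.concatenate([regions_of[f] for f in factor_names])
        free = np.setdiff1d(np.arange(n_regions), used)
        rng = np.random.default_rng(np.random.SeedSequence([cseed, 9]))
        bg_idx = rng.choice(free, size=2000, replace=False)
        from .model import GenomicInterval, Peak
        bg_peaks = []
        for r in bg_idx:
            iv = genome.accessible_regions[int(r)]
            c = (iv.start + iv.end) // 2
            bg_peaks.append(Peak(GenomicInterval(iv.chrom, c - 75, c + 75), c))
        bg_by_cell[cell] = PeakSet("background", cell, bg_peaks)

        # positional bias for the -11 bp archetype, on co-bound regions
        co = restrict_to_anchor(kept[cell]["TF_G1a"], kept[cell]["NFYB"], cfg)
        posbias_by_cell[cell] = positional_bias(
            co, genome.sequence, own_pwms["TF_G1a"], ccaat, cfg)

    deg_seed = int(child_seeds[-1]) % (2**31)
    overlaps = {("TF_G1a", "TF_G1b"): 0.6, ("TF_G1a", "TF_G1c"): 0.3}
    deg_table, deg_targets, _ = plant_deg_tables(
        2000, 0.2, 0.2, overlaps, deg_seed,
        factor_names=list(DEMO_GROUP_PLAN), targets_per_factor=120)

    genome_last = make_genome(2, 4_000_000, n_regions, seed=deg_seed)
    seg = toy_segmentation(genome_last, seed=deg_seed)
    ann = toy_gene_annotation(genome_last, seed=deg_seed, n_genes=3000)
    gene_ids = sorted(ann.gene_ids())
    pathways = {f"PW{i:03d}": (f"pathway {i}", set(gene_ids[i * 50:(i + 1) * 50]))
                for i in range(20)}

    mats_by_factor = {name: [ccaat, own_pwms[name]] for name in DEMO_GROUP_PLAN}
    mats_by_factor["NFYB"] = [ccaat]
    report = run_core(kept, cfg, anchor_factor="NFYB",
                      seq_by_cell=seq_by_cell,
                      matrices_by_factor=mats_by_factor,
                      background_by_cell=bg_by_cell,
                      segmentation=seg, gene_annotation=ann, pathways=pathways,
                      deg_table=deg_table, deg_targets=deg_targets)

    assignments = report["stages"]["classify"]
    errors = {name: (DEMO_GROUP_PLAN[name], a.group)
              for name, a in assignments.items()
              if a.group != DEMO_GROUP_PLAN[name]}
    report["demo"] = {
        "seed": seed,
        "planted_groups": dict(DEMO_GROUP_PLAN),
        "recovered_groups": {name: a.group for name, a in assignments.items()},
        "misclassified": errors,
        "n_misclassified": len(errors),
        "posbias_mode": {cell: pb.mode_offset
                         for cell, pb in posbias_by_cell.items()},
        "posbias_p": {cell: pb.bias_p for cell, pb in posbias_by_cell.items()},
    }
    if out_dir:
        write_demo_outputs(report, cfg, out_dir)
    return report


def write_demo_outputs(report: dict, cfg: AnalysisConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    meta = {"seed": report["demo"]["seed"],
            "config_hash": config_hash(cfg, report["demo"]["seed"])}
    rows = [(name, report["demo"]["planted_groups"][name],
             report["demo"]["recovered_groups"][name])
            for name in report["demo"]["planted_groups"]]
    rio.write_tsv(os.path.join(out_dir, "groups.tsv"),
                  ["factor", "planted_group", "recovered_group"], rows, meta)
    for cell, recs in report["stages"]["coassoc"]["overlaps"].items():
        rio.write_tsv(
            os.path.join(out_dir, f"coassoc_{cell}.tsv"),
            ["factor", "factor_share", "nfyb_share", "score", "k"],
            [(f, f"{r['factor_share']:.4f}", f"{r['nfyb_share']:.4f}",
              f"{r['score']:.2f}", r["k"]) for f, r in sorted(recs.items())],
            meta)


# ---------------------------------------------------------------------------
# file-based runner


def read_manifest(path: str) -> tuple[ExperimentManifest, dict[str, str]]:
    """Manifest TSV: experiment_id, factor, cell_line, is_tagged, treated, path."""
    entries, paths = [], {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            e = ManifestEntry(p[idx["experiment_id"]], p[idx["factor"]],
                              p[idx["cell_line"]],
                              p[idx["is_tagged"]].lower() in ("1", "true", "yes"),
                              p[idx["treated"]].lower() in ("1", "true", "yes"))
            entries.append(e)
            paths[e.experiment_id] = p[idx["path"]]
    return ExperimentManifest(entries), paths


def run_from_files(rc: RunConfig) -> dict:
    """File-based pipeline run; writes per-stage TSVs under ``rc.out_dir``."""
    os.makedirs(rc.out_dir, exist_ok=True)
    cfg = rc.analysis
    meta = {"seed": rc.seed, "config_hash": config_hash(cfg, rc.seed)}
    if rc.manifest_path is None:
        raise DependencyError("run: a manifest is required")
    manifest, paths = read_manifest(rc.manifest_path)
    peaks = {e.experiment_id: rio.read_narrowpeak(paths[e.experiment_id],
                                                  e.factor, e.cell_line,
                                                  experiment_id=e.experiment_id,
                                                  is_tagged=e.is_tagged)
             for e in manifest.entries}
    curation: CurationReport = curate(manifest, peaks, cfg)
    rio.write_tsv(os.path.join(rc.out_dir, "curation.tsv"),
                  ["experiment_id", "status", "reason"],
                  [(i, "kept", "") for i in curation.kept]
                  + [(i, "treated", "side_channel") for i in curation.treated]
                  + [(i, "dropped", r) for i, r in curation.dropped], meta)
    kept: dict[str, dict[str, PeakSet]] = {}
    by_id = {e.experiment_id: e for e in manifest.entries}
    for eid in curation.kept:
        e = by_id[eid]
        kept.setdefault(e.cell_line, {})[e.factor] = peaks[eid]

    seq_by_cell = None
    matrices = None
    bg_by_cell = None
    if rc.fasta_path and rc.jaspar_path:
        seq = rio.read_fasta(rc.fasta_path)
        seq_by_cell = {cell: seq for cell in kept}
        matrices = rio.read_jaspar(rc.jaspar_path)
        bg_by_cell = {cell: next(iter(factors.values()))
                      for cell, factors in kept.items()}
    seg = rio.read_segmentation(rc.segmentation_path) if rc.segmentation_path else None
    ann = rio.read_gene_annotation(rc.annotation_path) if rc.annotation_path else None
    gmt = rio.read_gmt(rc.gmt_path) if rc.gmt_path else None
    deg = rio.read_deg_table(rc.deg_path) if rc.deg_path else None
    deg_targets = None
    if deg is not None and ann is not None:
        partition = partition_degs(deg)
        deg_targets = {"UP": {}, "DOWN": {}}
        for cell, factors in kept.items():
            anchor = factors.get(rc.anchor_factor)
            for name, ps in factors.items():
                co = ps if anchor is None else restrict_to_anchor(ps, anchor, cfg)
                t = promoter_targets(co, ann, cfg=cfg).genes
                deg_targets["UP"][f"{cell}:{name}"] = t & partition.up
                deg_targets["DOWN"][f"{cell}:{name}"] = t & partition.down

    report = run_core(kept, cfg, anchor_factor=rc.anchor_factor,
                      seq_by_cell=seq_by_cell, matrices=matrices,
                      background_by_cell=bg_by_cell, segmentation=seg,
                      gene_annotation=ann, pathways=gmt, deg_table=deg,
                      deg_targets=deg_targets, stages=rc.stages)
    report["curation"] = curation
    if "classify" in report["stages"]:
        rio.write_tsv(os.path.join(rc.out_dir, "groups.tsv"),
                      ["factor", "group", "qualifying_cell_lines", "rationale"],
                      [(n, a.group if a.group else "none",
                        ",".join(a.qualifying_cell_lines), a.rationale)
                       for n, a in sorted(report["stages"]["classify"].items())],
                      meta)
    return report
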