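"""Readers and writers for the plain-text formats the pipeline consumes.

narrowPeak (BED6+4), 4-column segmentation BED, JASPAR PFM text, TSV gene
annotation / DEG tables, FASTA, and GMT gene sets.  All coordinates are kept
0-based half-open exactly as they appear on disk.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, TextIO

import numpy as np

from .model import (
    BASES,
    ChromatinSegmentation,
    DegTable,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    PositionWeightMatrix,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on malformed input, naming the offending line."""


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: str | os.PathLike, factor: str, cell_line: str,
                    experiment_id: str = "", is_tagged: bool = False,
                    chrom_alias: bool = False) -> PeakSet:
    """Read an ENCODE-style narrowPeak file into a sorted :class:`PeakSet`.

    The summit is chromStart plus the column-10 offset; a ``-1`` offset falls
    back to the interval midpoint (floor).  Chromosome names are matched
    exactly downstream; ``chrom_alias=True`` normalizes them to carry a
    ``chr`` prefix (off by default so data errors stay visible).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak needs >= 10 fields, got {len(parts)}"
                )
            try:
                chrom = parts[0]
                if chrom_alias and not chrom.startswith("chr"):
                    chrom = "chr" + chrom
                start, end = int(parts[1]), int(parts[2])
                name = parts[3]
                strand = parts[5] if parts[5] in {"+", "-", "."} else "."
                signal = float(parts[6])
                offset = int(parts[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand), summit,
                         signal=max(signal, 0.0), name=name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(factor, cell_line, peaks, experiment_id=experiment_id,
                   is_tagged=is_tagged)


def write_narrowpeak(ps: PeakSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in ps:
            iv = p.interval
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), p.name, "0", iv.strand,
                     f"{p.signal:g}", "-1", "-1", str(p.summit - iv.start)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# JASPAR PFM text


def _parse_jaspar_rows(rows: list[tuple[str, str]], header: str,
                       lineno: int) -> np.ndarray:
    by_base: dict[str, list[float]] = {}
    for base, payload in rows:
        payload = payload.strip().lstrip("[").rstrip("]")
        try:
            by_base[base] = [float(x) for x in payload.split()]
        except ValueError as exc:
            raise ParseError(f"record {header!r}: bad {base} row: {exc}") from exc
    missing = set(BASES) - set(by_base)
    if missing:
        raise ParseError(f"record {header!r} (line {lineno}): missing base rows "
                         f"{sorted(missing)}")
    widths = {len(v) for v in by_base.values()}
    if len(widths) != 1:
        raise ParseError(f"record {header!r}: base rows of unequal width {widths}")
    return np.column_stack([by_base[b] for b in BASES])


def read_jaspar(path: str | os.PathLike) -> list[PositionWeightMatrix]:
    """Read a JASPAR-format PFM file (">ID name" header, A/C/G/T rows)."""
    matrices: list[PositionWeightMatrix] = []
    header: str | None = None
    header_line = 0
    rows: list[tuple[str, str]] = []

    def flush() -> None:
        if header is None:
            return
        counts = _parse_jaspar_rows(rows, header, header_line)
        fields = header[1:].split(None, 1)
        matrix_id = fields[0]
        name = fields[1].strip() if len(fields) > 1 else matrix_id
        matrices.append(PositionWeightMatrix(matrix_id, name, counts))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, header_line, rows = line, lineno, []
            else:
                base = line[0].upper()
                if base not in BASES:
                    raise ParseError(f"{path}:{lineno}: unexpected row {line[:20]!r}")
                payload = line[1:]
                if payload[:1] in {":",}:
                    payload = payload[1:]
                rows.append((base, payload))
        flush()
    return matrices


def write_jaspar(matrices: Iterable[PositionWeightMatrix],
                 path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f">{m.matrix_id} {m.name}\n")
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in m.counts[:, i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# segmentation BED, gene annotation, DEG tables, GMT


def read_segmentation(path: str | os.PathLike) -> ChromatinSegmentation:
    """Read a 4-column BED with the chromatin-state mnemonic in column 4."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: segmentation BED needs 4 fields")
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            segments.append((iv, parts[3]))
    return ChromatinSegmentation(segments)


def write_segmentation(seg: ChromatinSegmentation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv, label in seg.segments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """TSV with header: gene_id, chrom, tss, strand."""
    genes = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "chrom", "tss", "strand"):
            if col not in idx:
                raise ParseError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                genes.append((parts[idx["gene_id"]], parts[idx["chrom"]],
                              int(parts[idx["tss"]]), parts[idx["strand"]]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneAnnotation(genes)


def write_gene_annotation(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for gid, chrom, tss, strand in ann.genes:
            fh.write(f"{gid}\t{chrom}\t{tss}\t{strand}\n")


def read_deg_table(path: str | os.PathLike, fdr_max: float = 0.01,
                   abs_lfc_min: float = 1.0) -> DegTable:
    """TSV with header: gene_id, log2FC, FDR (DESeq2-shaped)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("gene_id", "log2FC", "FDR"):
            if col not in idx:
                raise ParseError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                records.append((parts[idx["gene_id"]],
                                float(parts[idx["log2FC"]]),
                                float(parts[idx["FDR"]])))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return DegTable(records, fdr_max=fdr_max, abs_lfc_min=abs_lfc_min)


def write_deg_table(table: DegTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2FC\tFDR\n")
        for gid, lfc, fdr in table.records:
            fh.write(f"{gid}\t{lfc:g}\t{fdr:g}\n")


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, set[str]]]:
    """GMT gene sets: pathway_id -> (description, gene set)."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs id, description, genes")
            out[parts[0]] = (parts[1], set(parts[2:]))
    return out


# ---------------------------------------------------------------------------
# FASTA (sequences kept as uint8 base codes internally)


def encode_sequence(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for base, code in zip("ACGT", range(4)):
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def read_fasta(path: str | os.PathLike) -> dict[str, np.ndarray]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence before first header")
                seqs[name].append(line)
    return {n: encode_sequence("".join(chunks)) for n, chunks in seqs.items()}


def write_fasta(seqs: Mapping[str, np.ndarray], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            s = decode_sequence(codes)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_tsv(path: str | os.PathLike, header: list[str],
              rows: Iterable[Iterable], meta: Mapping | None = None) -> None:
    """Small TSV writer; ``meta`` entries become leading ``# key=value`` lines."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
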