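"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ (phred+33) go through Biopython's streaming iterators; gene
annotations travel as BED12 plus a companion TSV (gene_id, group, status);
alignments are written as plain SAM text so standard viewers and pysam can
inspect them. Variant and consensus reports are TSV (positions 1-based in
reports, 0-based everywhere in memory). A flat ``key = value`` config file
round-trips the pipeline parameter set.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthlocus import GeneModel, ShortRead

log = logging.getLogger("paralocus")


class FormatError(ValueError):
    """A file failed to parse; the message carries the file position."""


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs in file order.

    Sequences are uppercased and U is mapped to T. Duplicate ids, empty
    records and empty ids are format errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}:1: expected '>' header, found {first!r}")
        fh.seek(0)
        for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            name = title.split()[0] if title.split() else ""
            if not name:
                raise FormatError(f"{path}: record {i}: empty header")
            if not seq:
                raise FormatError(f"{path}: record {i} ({name}): empty sequence")
            if name in seen:
                raise FormatError(f"{path}: record {i}: duplicate id {name!r}")
            seen.add(name)
            records.append((name, seq.upper().replace("U", "T")))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[ShortRead]:
    """Parse phred+33 FASTQ into ShortRead records."""
    path = Path(path)
    reads: list[ShortRead] = []
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                name = title.split()[0]
                if len(seq) != len(qual):
                    raise FormatError(f"{path}: record {name}: sequence/quality length mismatch")
                quals = tuple(ord(c) - 33 for c in qual)
                if any(q < 0 for q in quals):
                    raise FormatError(f"{path}: record {name}: quality below phred+33 range")
                reads.append(ShortRead(name, seq.upper(), quals))
        except ValueError as exc:  # Biopython flags truncated/malformed records
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(path, reads: Iterable[ShortRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(min(q, 93) + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# annotations: BED12 + companion TSV (gene_id, group, status)

def write_annotations(bed_path, tsv_path, genes: Iterable[GeneModel], chrom: str) -> None:
    genes = list(genes)
    with open(bed_path, "w") as bed:
        for g in genes:
            s, e = g.span
            sizes = ",".join(str(b - a) for a, b in g.exons)
            starts = ",".join(str(a - s) for a, b in g.exons)
            bed.write(
                f"{chrom}\t{s}\t{e}\t{g.gene_id}\t0\t{g.strand}\t{s}\t{e}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{starts}\n"
            )
    with open(tsv_path, "w") as tsv:
        tsv.write("gene_id\tgroup\tstatus\n")
        for g in genes:
            tsv.write(f"{g.gene_id}\t{g.group}\t{g.status}\n")


def read_annotations(bed_path, tsv_path=None, reference: str | None = None) -> list[GeneModel]:
    """Read BED12 gene models (0-based half-open, no coordinate shift).

    The companion TSV supplies group and status; without it every gene gets
    group "ungrouped", status "functional". If ``reference`` is given, exons
    beyond its length are a validation error.
    """
    meta: dict[str, tuple[str, str]] = {}
    if tsv_path is not None:
        with open(tsv_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    meta[parts[idx["gene_id"]]] = (parts[idx["group"]], parts[idx["status"]])
                except (KeyError, IndexError) as exc:
                    raise FormatError(f"{tsv_path}:{lineno}: bad annotation row") from exc

    genes: list[GeneModel] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{bed_path}:{lineno}: BED12 needs 12 fields, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{bed_path}:{lineno}: {exc}") from exc
            if start < 0:
                raise FormatError(f"{bed_path}:{lineno}: negative start")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{bed_path}:{lineno}: blockCount disagrees with block lists")
            exons = tuple((start + o, start + o + sz) for o, sz in zip(starts, sizes))
            if exons[-1][1] != end:
                raise FormatError(f"{bed_path}:{lineno}: blocks do not end at chromEnd")
            if reference is not None and end > len(reference):
                raise FormatError(f"{bed_path}:{lineno}: exon beyond reference length")
            group, status = meta.get(name, ("ungrouped", "functional"))
            genes.append(GeneModel(name, group, strand, exons, status))
    return genes


# ---------------------------------------------------------------------------
# SAM (write-only)

def write_sam(path, references: list[tuple[str, str]], mapped_reads, reads_by_id=None) -> None:
    """Write ungapped alignments as SAM.

    One line per hit; the XT tag mirrors the unique-mapping convention
    (XT:A:U unique, XT:A:R repeat/multi) and NM carries the mismatch count.
    Unmapped reads get flag 4. ``reads_by_id`` maps read_id -> ShortRead for
    sequence/quality output; omitted reads get '*'.
    """
    reads_by_id = reads_by_id or {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:paralocus\tPN:paralocus\n")
        for mr in mapped_reads:
            read = reads_by_id.get(mr.read_id)
            if mr.uniqueness == "unmapped" or not mr.hits:
                seq = read.bases if read else "*"
                qual = "".join(chr(min(q, 93) + 33) for q in read.quals) if read else "*"
                fh.write(f"{mr.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            tag = "U" if mr.uniqueness == "unique" else "R"
            mapq = 37 if mr.uniqueness == "unique" else 0
            for k, hit in enumerate(mr.hits):
                if read is not None:
                    bases = read.bases
                    qual = "".join(chr(min(q, 93) + 33) for q in read.quals)
                    if hit.strand == "-":
                        from .synthlocus import revcomp

                        bases = revcomp(bases)
                        qual = qual[::-1]
                    L = len(read.bases)
                else:
                    bases = qual = "*"
                    L = mr.read_length
                flag = 16 if hit.strand == "-" else 0
                if k > 0:
                    flag |= 256  # secondary
                fh.write(
                    f"{mr.read_id}\t{flag}\t{hit.ref_id}\t{hit.start + 1}\t{mapq}\t{L}M\t*\t0\t0\t"
                    f"{bases}\t{qual}\tNM:i:{hit.mismatches}\tXT:A:{tag}\n"
                )


# ---------------------------------------------------------------------------
# variant / consensus reports

def write_variants_tsv(path, variants) -> None:
    """Variant table: 1-based position, ref, alt, frequency, depth, effect."""
    with open(path, "w") as fh:
        fh.write("position\tref\talt\tfreq\tdepth\teffect\n")
        for v in variants:
            eff = v.effect or "."
            fh.write(f"{v.position + 1}\t{v.ref}\t{v.alt}\t{v.freq:.4f}\t{v.depth}\t{eff}\n")


def write_mask_bed(path, chrom: str, positions: Iterable[int]) -> None:
    """Masked positions (cross-source conflicts) as single-base BED intervals."""
    with open(path, "w") as fh:
        for p in sorted(positions):
            fh.write(f"{chrom}\t{p}\t{p + 1}\n")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Flat bag of pipeline defaults, serializable to ``key = value`` text."""

    tile_read_length: int = 35
    tile_quality: int = 30
    ancient_error_rate: float = 0.0
    n_ancient_reads: int = 10_000
    k: int = 11
    max_mismatches: int = 2
    max_hits_reported: int = 50
    coverage_window: int = 300
    identity_window: int = 500
    dotplot_window: int = 250
    control_min_depth: int = 1000
    min_alt_freq: float = 0.5001
    min_depth: int = 5
    conflict_min_depth_a: int = 8
    conflict_min_depth_b: int = 500
    majority_freq: float = 0.51
    verbosity: str = "info"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name in values:
                kwargs[f.name] = _coerce(values.pop(f.name), f.default)
        if values:
            raise FormatError(f"{path}: unknown keys: {sorted(values)}")
        return cls(**kwargs)


def _coerce(raw: str, default):
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def setup_logging(verbosity: str = "info") -> None:
    level = {"quiet": logging.WARNING, "info": logging.INFO, "verbose": logging.DEBUG}.get(
        verbosity, logging.INFO
    )
    logging.basicConfig(stream=sys.stderr, level=level, format="[paralocus] %(message)s")
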