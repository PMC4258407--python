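"""Synthetic locus generator: ground-truth haplotypes and simulated read sets.

Builds haplotypes with the architecture of a tandemly duplicated immune-gene
locus — near-identical multi-kilobase blocks, each carrying several paralogous
genes assigned to groups — plus allelic variants (SNP-only), gene deletions,
and two kinds of simulated reads: exhaustive 35-bp both-strand tiling reads
(the positive-control convention) and short ancient-DNA-like fragments with a
configurable uniform substitution error rate.

All randomness flows through explicit integer seeds; identical seeds and
parameters give byte-identical haplotypes and read sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SizingError(ValueError):
    """A length precondition cannot be satisfied."""


@dataclass(frozen=True)
class GeneModel:
    """A gene on a haplotype: ordered exons, paralog group, strand, status.

    Coordinates are 0-based half-open in haplotype space. ``span`` runs from
    the first exon start to the last exon end (introns included).
    """

    gene_id: str
    group: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    status: str = "functional"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for start, end in exons:
            if start < 0 or end <= start:
                raise ValueError(f"gene {self.gene_id}: bad exon interval ({start},{end})")
            if start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    def shifted(self, offset: int, **updates) -> "GeneModel":
        """Copy with all exon coordinates shifted by ``offset``."""
        exons = tuple((a + offset, b + offset) for a, b in self.exons)
        return dataclasses.replace(self, exons=exons, **updates)


@dataclass(frozen=True)
class Haplotype:
    """A locus sequence with named duplication-block intervals and gene models."""

    hap_id: str
    sequence: str
    blocks: tuple[tuple[str, int, int], ...] = ()
    genes: tuple[GeneModel, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("haplotype sequence must be non-empty")
        n = len(self.sequence)
        for name, start, end in self.blocks:
            if not (0 <= start < end <= n):
                raise ValueError(f"block {name}: interval ({start},{end}) outside sequence")
        for g in self.genes:
            if g.exons[-1][1] > n:
                raise ValueError(f"gene {g.gene_id}: exon beyond sequence end")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "genes", tuple(self.genes))

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene_id: {gene_id}")

    def gene_span_sequence(self, gene_id: str) -> str:
        s, e = self.gene(gene_id).span
        return self.sequence[s:e]

    def spliced_cds(self, gene_id: str) -> str:
        """Strand-aware spliced coding sequence of a gene."""
        g = self.gene(gene_id)
        cds = "".join(self.sequence[a:b] for a, b in g.exons)
        return revcomp(cds) if g.strand == "-" else cds


@dataclass(frozen=True)
class SimParams:
    """Read-simulation parameters.

    ``tile_read_length``/``tile_quality`` govern the exhaustive both-strand
    tiling control (35 bp at phred 30 by default). Ancient-DNA-like fragments
    are 36–70 bp with the bulk of the mass on 40–60 bp, and carry uniform
    per-base substitution errors at ``ancient_error_rate``.
    """

    tile_read_length: int = 35
    tile_quality: int = 30
    ancient_length_range: tuple[int, int] = (36, 70)
    ancient_length_mode: tuple[int, int] = (40, 60)
    ancient_mode_weight: float = 0.7
    ancient_error_rate: float = 0.0
    n_ancient_reads: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_read_length < 20:
            raise ValueError("tile_read_length must be >= 20")
        lo, hi = self.ancient_length_range
        if lo < 20 or hi < lo:
            raise ValueError("ancient read lengths must be >= 20 and lo <= hi")
        mlo, mhi = self.ancient_length_mode
        if not (lo <= mlo <= mhi <= hi):
            raise ValueError("ancient_length_mode must nest inside ancient_length_range")
        if not (0.0 <= self.ancient_error_rate < 0.1):
            raise ValueError("ancient_error_rate must be in [0, 0.1)")


@dataclass(frozen=True)
class ShortRead:
    """A sequencing read; truth_origin records (hap_id, 0-based start, strand)
    for simulated reads."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    truth_origin: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.read_id}: bases/quals length mismatch")
        if set(self.bases) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: bases outside ACGTN")
        object.__setattr__(self, "quals", tuple(int(q) for q in self.quals))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) random sense codons + a random stop codon."""
    body = [ _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2) ]
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def generate_block(
    length: int, n_genes: int, group_labels: list[str], seed: int
) -> tuple[str, list[GeneModel]]:
    """Generate one ancestral duplication block: a random sequence carrying
    ``n_genes`` non-overlapping multi-exon genes with intact reading frames,
    assigned to ``group_labels`` cycled in order.

    Gene anatomy (unspecified by any upstream data, chosen as plausible for a
    compact receptor gene): 4–6 exons of 36–300 bp, introns of 60–140 bp,
    spliced CDS capped near 1.1 kb so any block with length >= n_genes * 2000
    can host its genes. Deterministic for a fixed seed.
    """
    if not group_labels:
        raise ValueError("group_labels must be non-empty")
    if length < n_genes * 2000:
        raise SizingError(
            f"block length {length} too small for {n_genes} genes (need >= {n_genes * 2000})"
        )
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length))
    genes: list[GeneModel] = []

    slot = length // n_genes
    for i in range(n_genes):
        n_exons = int(rng.integers(4, 7))
        raw = rng.integers(36, 301, size=n_exons)
        # keep the spliced CDS comfortably inside the per-gene slot
        while raw.sum() > 1100:
            raw = np.maximum(36, raw - 30)
        total = int(raw.sum())
        total -= total % 3
        exon_lens = raw.astype(int).tolist()
        exon_lens[-1] -= int(raw.sum()) - total  # CDS length divisible by 3
        intron_lens = rng.integers(60, 141, size=n_exons - 1).astype(int).tolist()
        span = sum(exon_lens) + sum(intron_lens)

        slot_start, slot_end = i * slot, (i + 1) * slot
        margin = slot_end - slot_start - span
        if margin < 2:
            raise SizingError(f"gene {i} (span {span} bp) does not fit its {slot}-bp slot")
        gstart = slot_start + int(rng.integers(1, margin))

        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_cds(rng, total // 3)
        placed = cds if strand == "+" else revcomp(cds)
        # on '-', haplotype-order exons hold the revcomp CDS; splice order is
        # handled by Haplotype.spliced_cds
        if strand == "-":
            piece_lens = exon_lens[::-1]
        else:
            piece_lens = exon_lens
        exons = []
        pos, consumed = gstart, 0
        for j, elen in enumerate(piece_lens):
            seq[pos : pos + elen] = placed[consumed : consumed + elen]
            exons.append((pos, pos + elen))
            consumed += elen
            pos += elen
            if j < n_exons - 1:
                ilen = intron_lens[j]
                pos += ilen
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1}",
                group=group_labels[i % len(group_labels)],
                strand=strand,
                exons=tuple(exons),
                status="functional",
            )
        )
    return "".join(seq), genes


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    """Substitute each listed position to a uniformly chosen different base."""
    out = list(seq)
    for p in positions:
        old = out[p]
        choices = [b for b in BASES if b != old]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def build_haplotype(
    block: tuple[str, list[GeneModel]],
    n_copies: int,
    divergence: float,
    seed: int,
    hap_id: str = "H1",
) -> Haplotype:
    """Concatenate ``n_copies`` independently point-mutated copies of a block.

    Each copy receives Binomial(length, divergence) substitutions at uniform
    positions, emulating descent of sister blocks from a shared ancestor.
    Gene ids are suffixed per copy (gene1_c1, gene1_c2, ...); block intervals
    are recorded as (block1, block2, ...).
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if not (0.0 <= divergence <= 0.2):
        raise ValueError("divergence must be in [0, 0.2]")
    bseq, bgenes = block
    rng = np.random.default_rng(seed)
    n = len(bseq)
    parts: list[str] = []
    blocks: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []
    for c in range(n_copies):
        n_mut = int(rng.binomial(n, divergence)) if divergence > 0 else 0
        positions = rng.choice(n, size=n_mut, replace=False) if n_mut else np.array([], int)
        copy_seq = _mutate(rng, bseq, positions)
        offset = c * n
        parts.append(copy_seq)
        blocks.append((f"block{c + 1}", offset, offset + n))
        for g in bgenes:
            genes.append(g.shifted(offset, gene_id=f"{g.gene_id}_c{c + 1}"))
    return Haplotype(hap_id=hap_id, sequence="".join(parts), blocks=tuple(blocks), genes=tuple(genes))


def inject_allelic_snps(h1: Haplotype, n_snps: int, seed: int, hap_id: str = "H2") -> Haplotype:
    """Derive an allelic haplotype differing from ``h1`` at exactly ``n_snps``
    positions (substitutions only; identical gene organization)."""
    n = len(h1.sequence)
    if n_snps > n // 10:
        raise ValueError(f"n_snps {n_snps} exceeds length/10 = {n // 10}")
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_snps, replace=False) if n_snps else np.array([], int)
    seq = _mutate(rng, h1.sequence, positions)
    return dataclasses.replace(h1, hap_id=hap_id, sequence=seq)


def delete_gene(h: Haplotype, gene_id: str) -> Haplotype:
    """Remove a gene's genomic span from the haplotype; downstream coordinates
    shift left and the deleted model is dropped."""
    target = h.gene(gene_id)  # raises KeyError if unknown
    s, e = target.span
    removed = e - s
    seq = h.sequence[:s] + h.sequence[e:]

    def shift(x: int) -> int:
        if x <= s:
            return x
        if x >= e:
            return x - removed
        return s  # truncated into the breakpoint

    blocks = tuple(
        (name, shift(a), shift(b)) for name, a, b in h.blocks if shift(b) > shift(a)
    )
    genes = []
    for g in h.genes:
        if g.gene_id == gene_id:
            continue
        exons = tuple((shift(a), shift(b)) for a, b in g.exons)
        genes.append(dataclasses.replace(g, exons=exons))
    return Haplotype(hap_id=h.hap_id + f"_del_{gene_id}", sequence=seq, blocks=blocks, genes=tuple(genes))


def tile_reads(reference: str, p: SimParams, ref_id: str = "ref") -> list[ShortRead]:
    """Exhaustive tiling: every length-L window from the forward strand plus
    its reverse complement from the reverse strand, all at ``tile_quality``.

    Emits exactly 2*(N - L + 1) reads.
    """
    L = p.tile_read_length
    n = len(reference)
    if n < L:
        raise SizingError(f"reference length {n} < tile read length {L}")
    quals = (p.tile_quality,) * L
    reads: list[ShortRead] = []
    for i in range(n - L + 1):
        window = reference[i : i + L]
        reads.append(ShortRead(f"tile_{i}_f", window, quals, (ref_id, i, "+")))
        reads.append(ShortRead(f"tile_{i}_r", revcomp(window), quals, (ref_id, i, "-")))
    return reads


def sample_ancient_reads(reference: str, p: SimParams, ref_id: str = "ref") -> list[ShortRead]:
    """Draw short ancient-DNA-like fragments: uniform start positions and
    strands, lengths from the configured mixture (``ancient_mode_weight`` of
    the mass uniform on the 40–60 bp mode, the rest uniform on the tails),
    and independent per-base substitution errors at ``ancient_error_rate``.
    """
    if p.n_ancient_reads < 1:
        raise ValueError("n_ancient_reads must be >= 1")
    rng = np.random.default_rng(p.seed)
    lo, hi = p.ancient_length_range
    mlo, mhi = p.ancient_length_mode
    tail = [x for x in range(lo, hi + 1) if not (mlo <= x <= mhi)]
    n = len(reference)
    reads: list[ShortRead] = []
    for i in range(p.n_ancient_reads):
        if not tail or rng.random() < p.ancient_mode_weight:
            length = int(rng.integers(mlo, mhi + 1))
        else:
            length = tail[rng.integers(0, len(tail))]
        length = min(length, n)
        start = int(rng.integers(0, n - length + 1))
        frag = reference[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        if p.ancient_error_rate > 0:
            err = np.flatnonzero(rng.random(length) < p.ancient_error_rate)
            if err.size:
                frag = _mutate(rng, frag, err)
        reads.append(
            ShortRead(f"anc_{i}", frag, (p.tile_quality,) * length, (ref_id, start, strand))
        )
    return reads
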