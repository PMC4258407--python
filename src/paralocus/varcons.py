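"""Pileup, SNP calling, cross-source conflict filtering and majority consensus.

The calling conventions are deliberately literal: a variant needs read depth
strictly greater than 5 and a non-reference base frequency of at least 50.01%;
the consensus takes any base reaching 51% of the column depth and otherwise
falls back to the reference base, so the output never contains ambiguity
codes. Sites where two sequencing sources disagree are masked when the
conflicting source is below its depth threshold (8x / 500x by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from .mapper import MappedRead
from .synthlocus import GeneModel, ShortRead, revcomp

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


@dataclass(frozen=True)
class CallerParams:
    """Variant-calling cutoffs: frequency >= ``min_alt_freq`` (50.01%) at
    depth strictly greater than ``min_depth`` (5); conflict thresholds for
    the two-source filter (8x for source a, 500x for source b)."""

    min_alt_freq: float = 0.5001
    min_depth: int = 5
    conflict_min_depth_a: int = 8
    conflict_min_depth_b: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.min_alt_freq <= 1.0):
            raise ValueError("min_alt_freq must be in (0, 1]")


@dataclass(frozen=True)
class ConsensusParams:
    majority_freq: float = 0.51
    tie_policy: str = "reference"  # reference | first-alphabetical

    def __post_init__(self) -> None:
        if not self.majority_freq > 0.5:
            raise ValueError("majority_freq must exceed 0.5")
        if self.tie_policy not in ("reference", "first-alphabetical"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass(frozen=True)
class PileupColumn:
    position: int
    ref_base: str
    counts: tuple[int, int, int, int]  # A, C, G, T

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def count(self, base: str) -> int:
        return self.counts[_BASE_IDX[base]]


@dataclass(frozen=True)
class Variant:
    position: int
    ref: str
    alt: str
    freq: float
    depth: int
    effect: str | None = None


def pileup(
    mapped: list[MappedRead],
    reference: str,
    reads_by_id: dict[str, ShortRead],
    multi_policy: str = "exclude",
    ref_id: str | None = None,
) -> list[PileupColumn]:
    """Per-position base counts from ungapped hits.

    Multi-mapping reads are excluded by default so paralogous copies cannot
    inflate each other's variant frequencies; ``multi_policy="all_best"``
    counts them at every tied-best placement (the "normal coverage" view).
    Only columns with nonzero depth are returned, in positional order.
    """
    if multi_policy not in ("exclude", "all_best"):
        raise ValueError(f"unknown multi_policy {multi_policy!r}")
    n = len(reference)
    counts = np.zeros((n, 4), dtype=np.int64)
    for mr in mapped:
        if not mr.hits:
            continue
        if mr.uniqueness != "unique" and multi_policy == "exclude":
            continue
        read = reads_by_id[mr.read_id]
        best = mr.hits[0].mismatches
        for h in mr.hits:
            if h.mismatches != best:
                continue
            if ref_id is not None and h.ref_id != ref_id:
                continue
            bases = read.bases if h.strand == "+" else revcomp(read.bases)
            codes = np.frombuffer(bases.encode(), dtype=np.uint8)
            idx = np.full(codes.size, -1, dtype=np.int64)
            for b, i in _BASE_IDX.items():
                idx[codes == ord(b)] = i
            keep = idx >= 0  # skip N
            positions = np.arange(h.start, h.start + codes.size)[keep]
            np.add.at(counts, (positions, idx[keep]), 1)
    cols = []
    covered = np.flatnonzero(counts.sum(axis=1))
    for p in covered:
        cols.append(PileupColumn(int(p), reference[p], tuple(int(c) for c in counts[p])))
    return cols


def call_snps(columns: list[PileupColumn], p: CallerParams | None = None) -> list[Variant]:
    """Emit one variant per qualifying column: depth > min_depth and the
    modal non-reference base at frequency >= min_alt_freq; ties between
    non-reference bases are not called."""
    p = p or CallerParams()
    variants: list[Variant] = []
    for col in columns:
        depth = col.depth
        if depth <= p.min_depth:
            continue
        alt_counts = [
            (c, b) for b, c in zip(_IDX_BASE, col.counts) if b != col.ref_base
        ]
        best = max(c for c, _ in alt_counts)
        if best == 0:
            continue
        top = [b for c, b in alt_counts if c == best]
        if len(top) > 1:
            continue
        freq = best / depth
        if freq >= p.min_alt_freq:
            variants.append(Variant(col.position, col.ref_base, top[0], freq, depth))
    return variants


def _majority_base(col: PileupColumn) -> str | None:
    best = max(col.counts)
    if best == 0:
        return None
    top = [b for b, c in zip(_IDX_BASE, col.counts) if c == best]
    return top[0] if len(top) == 1 else None


def cross_source_filter(
    columns_a: list[PileupColumn],
    columns_b: list[PileupColumn],
    p: CallerParams | None = None,
) -> list[int]:
    """Positions where the two sources' majority bases conflict and the
    conflicting (disagreeing) source sits below its depth threshold — these
    are masked from consensus and variant output.

    A source is "disregarded" at a site when its depth is below its own
    threshold (a: 8x, b: 500x); a conflict site is returned if at least one
    side can be disregarded this way (the other side's call then stands).
    """
    p = p or CallerParams()
    by_pos_b = {c.position: c for c in columns_b}
    masked: list[int] = []
    for ca in columns_a:
        cb = by_pos_b.get(ca.position)
        if cb is None:
            continue
        ma, mb = _majority_base(ca), _majority_base(cb)
        if ma is None or mb is None or ma == mb:
            continue
        if ca.depth < p.conflict_min_depth_a or cb.depth < p.conflict_min_depth_b:
            masked.append(ca.position)
    return masked


def majority_consensus(
    columns: list[PileupColumn],
    reference: str,
    p: ConsensusParams | None = None,
    mask: list[int] | None = None,
) -> str:
    """Majority-rule consensus: per position the base reaching
    ``majority_freq`` of the depth; otherwise (no majority, zero depth, or a
    masked position) the tie policy applies — default: keep the reference
    base. Output is the reference length over {A,C,G,T} only."""
    p = p or ConsensusParams()
    out = list(reference)
    masked = set(mask or ())
    for col in columns:
        pos = col.position
        if pos in masked or col.depth == 0:
            continue
        best = max(col.counts)
        if best / col.depth >= p.majority_freq:
            top = [b for b, c in zip(_IDX_BASE, col.counts) if c == best]
            if len(top) == 1:
                out[pos] = top[0]
                continue
            # two bases tied above majority_freq is impossible (>0.5 each);
            # tied below falls through to the tie policy
        if p.tie_policy == "first-alphabetical":
            candidates = [b for b, c in zip(_IDX_BASE, col.counts) if c == best]
            out[pos] = sorted(candidates)[0]
        # "reference": keep out[pos] as-is
    return "".join(out)


def annotate_effects(
    variants: list[Variant], genes: list[GeneModel], reference: str
) -> list[Variant]:
    """Classify each variant against the spliced CDS of the gene whose exons
    contain it: synonymous, nonsynonymous, nonsense; positions outside any
    exon become intergenic/intronic. Genes whose spliced CDS length is not a
    multiple of 3 raise a warning and are skipped."""
    # map genomic position -> (gene, cds_index)
    cds_map: dict[int, tuple[GeneModel, str, int]] = {}
    for g in genes:
        cds = "".join(reference[a:b] for a, b in g.exons)
        genomic = [pos for a, b in g.exons for pos in range(a, b)]
        if g.strand == "-":
            cds = revcomp(cds)
            genomic = genomic[::-1]
        if len(cds) % 3 != 0:
            warnings.warn(
                f"gene {g.gene_id}: spliced CDS length {len(cds)} not divisible by 3; "
                "effects not annotated"
            )
            continue
        for ci, gp in enumerate(genomic):
            cds_map[gp] = (g, cds, ci)
    out: list[Variant] = []
    for v in variants:
        entry = cds_map.get(v.position)
        if entry is None:
            out.append(replace(v, effect="intergenic/intronic"))
            continue
        g, cds, ci = entry
        alt = v.alt if g.strand == "+" else revcomp(v.alt)
        codon_i = ci // 3
        codon = cds[codon_i * 3 : codon_i * 3 + 3]
        mutated = codon[: ci % 3] + alt + codon[ci % 3 + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutated).translate())
        if aa_alt == "*" and aa_ref != "*":
            effect = "nonsense"
        elif aa_alt == aa_ref:
            effect = "synonymous"
        else:
            effect = "nonsynonymous"
        out.append(replace(v, effect=effect))
    return out
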