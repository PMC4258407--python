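"""Ungapped all-best-hit short-read mapper with uniqueness classification.

The mapper exists to make "mapped uniquely" an exact, reproducible notion:
every end-to-end ungapped placement of a read with at most ``max_mismatches``
substitutions is enumerated, and a read is *unique* precisely when a single
placement attains the minimum mismatch count. This mirrors the unique-mapping
tag convention of production aligners while being simple enough to check
against a brute-force scan.

Seeding is an exact k-mer positional index over the forward strand, queried
at every read offset with the read and its reverse complement. Full
sensitivity at m mismatches is guaranteed whenever floor(L / k) > m (pigeonhole
over disjoint k-mers): with the default k=13 a 35-bp read is guaranteed at
1 mismatch; use k <= 11 to guarantee 2-mismatch sensitivity for reads >= 33 bp.
Indels are out of scope — a read spanning an indel simply fails to map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthlocus import ShortRead, revcomp

_BASE_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class MapParams:
    k: int = 13
    max_mismatches: int = 2
    max_hits_reported: int = 50

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if self.max_mismatches > 5:
            raise ValueError("max_mismatches must be <= 5")


@dataclass(frozen=True)
class Hit:
    """One ungapped placement: 0-based leftmost position on the forward
    reference, regardless of strand."""

    ref_id: str
    start: int
    strand: str
    mismatches: int


@dataclass
class MappedRead:
    read_id: str
    read_length: int
    hits: list[Hit] = field(default_factory=list)
    uniqueness: str = "unmapped"  # unique | multi | unmapped
    truncated: bool = False
    reason: str | None = None


class Index:
    """Exact k-mer positional index over the forward strands of one or more
    references. k-mers containing N are never seeded."""

    def __init__(self, references: list[tuple[str, str]], p: MapParams):
        if not references:
            raise ValueError("empty reference set")
        self.params = p
        self.ref_ids = [r[0] for r in references]
        self.sequences = {rid: seq for rid, seq in references}
        self._encoded = {rid: _encode(seq) for rid, seq in references}
        k = p.k
        for rid, seq in references:
            if len(seq) < k:
                raise ValueError(f"reference {rid} shorter than k={k}")
        table: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in references:
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                table.setdefault(kmer, []).append((rid, i))
        self._table = table

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])


def build_index(references: list[tuple[str, str]], p: MapParams | None = None) -> Index:
    return Index(references, p or MapParams())


def _mismatches(index: Index, rid: str, start: int, q_enc: np.ndarray, budget: int) -> int:
    ref = index._encoded[rid]
    window = ref[start : start + q_enc.size]
    mm = int(np.count_nonzero(window != q_enc))
    return mm if mm <= budget else -1


def map_read(read: ShortRead, index: Index, p: MapParams | None = None) -> MappedRead:
    p = p or index.params
    L = len(read.bases)
    if L < p.k:
        return MappedRead(read.read_id, L, [], "unmapped", reason=f"read shorter than k={p.k}")
    hits: list[Hit] = []
    for strand, query in (("+", read.bases), ("-", revcomp(read.bases))):
        q_enc = _encode(query)  # N encodes to 255 and can only mismatch ACGT
        seen: set[tuple[str, int]] = set()
        exact = index.sequences
        for off in range(L - p.k + 1):
            for rid, pos in index.lookup(query[off : off + p.k]):
                start = pos - off
                if start < 0 or start + L > len(exact[rid]):
                    continue
                key = (rid, start)
                if key in seen:
                    continue
                seen.add(key)
                if exact[rid][start : start + L] == query:
                    hits.append(Hit(rid, start, strand, 0))
                    continue
                mm = _mismatches(index, rid, start, q_enc, p.max_mismatches)
                if mm >= 0:
                    hits.append(Hit(rid, start, strand, mm))
    hits.sort(key=lambda h: (h.mismatches, h.ref_id, h.start, h.strand))
    truncated = len(hits) > p.max_hits_reported
    kept = hits[: p.max_hits_reported]
    if not kept:
        return MappedRead(read.read_id, L, [], "unmapped")
    best = kept[0].mismatches
    n_best = sum(1 for h in hits if h.mismatches == best)  # count before truncation
    uniqueness = "unique" if n_best == 1 else "multi"
    return MappedRead(read.read_id, L, kept, uniqueness, truncated=truncated)


def map_reads(reads: list[ShortRead], index: Index, p: MapParams | None = None) -> list[MappedRead]:
    p = p or index.params
    return [map_read(r, index, p) for r in reads]


def best_mismatches(mapped: MappedRead) -> int | None:
    return mapped.hits[0].mismatches if mapped.hits else None


def competitive_filter(
    reads: list[ShortRead], target_index: Index, decoy_index: Index, p: MapParams | None = None
) -> list[ShortRead]:
    """Keep reads placing strictly better on the target than on the decoy
    (or hitting only the target); equal best scores are discarded."""
    p = p or target_index.params
    kept: list[ShortRead] = []
    for r in reads:
        t = best_mismatches(map_read(r, target_index, p))
        if t is None:
            continue
        d = best_mismatches(map_read(r, decoy_index, p))
        if d is None or t < d:
            kept.append(r)
    return kept
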