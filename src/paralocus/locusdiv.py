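"""Duplication-block and diversity analytics.

Quantifies the structure a tandemly duplicated locus shows in a dot-plot —
near-identical blocks offset along the diagonal — and the divergence between
block alleles: window identity tracks, substitution counts with interval
masks, synonymous/nonsynonymous partitioning, p-distance matrices, ITIM
motif scanning, transmembrane adaptor classification and reading-frame
integrity. All pairwise operations expect pre-aligned input; the synthetic
generator emits gap-free co-linear sequences, and externally aligned input
is taken as-is (gap column conventions are documented per operation).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from Bio.Seq import Seq

from .synthlocus import GeneModel, Haplotype, revcomp

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class IdentityTrack:
    reference: str
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray  # percent identity per window


@dataclass(frozen=True)
class MotifHit:
    protein: str
    start: int  # 0-based residue
    motif_class: str  # ITIM_canonical | ITIM_disrupted_YtoF | TM_arginine | TM_lysine
    matched: str


@dataclass(frozen=True)
class OrfVerdict:
    gene_id: str
    status: str  # functional | pseudogene
    defects: tuple[tuple[str, int], ...]  # (kind, position) pairs


class SubstitutionCount(NamedTuple):
    """Differing-site count with gap-containing sites tallied separately."""

    substitutions: int
    gap_sites: int


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def dotplot_identity(
    seq_a: str, seq_b: str, window: int = 250, step: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percent-identity matrix between all window pairs of two sequences.

    Cell (i, j) compares seq_a[si:si+w] with seq_b[sj:sj+w] ungapped. Returns
    (matrix, a_starts, b_starts). Symmetric for a self-comparison. The step
    defaults to the window size (non-overlapping); pass step=1 for the
    classic dense plot on small inputs.
    """
    if window > len(seq_a) or window > len(seq_b):
        raise ValueError("window exceeds a sequence length")
    step = step or window
    a, b = _to_array(seq_a), _to_array(seq_b)
    a_starts = np.arange(0, len(seq_a) - window + 1, step)
    b_starts = np.arange(0, len(seq_b) - window + 1, step)
    mat = np.empty((a_starts.size, b_starts.size), dtype=np.float64)
    b_windows = np.lib.stride_tricks.sliding_window_view(b, window)[b_starts]
    for i, sa in enumerate(a_starts):
        mat[i] = 100.0 * (b_windows == a[sa : sa + window]).mean(axis=1)
    return mat, a_starts, b_starts


def window_identity_track(
    reference_block: str, other_block: str, window: int = 500, step: int = 1
) -> IdentityTrack:
    """Sliding-window percent identity of one block against a co-linear
    reference block. Gap characters score as mismatches, so deletions show
    as dips — the structural-divergence view."""
    if len(reference_block) != len(other_block):
        raise ValueError("blocks must be pre-aligned to equal length")
    n = len(reference_block)
    if window > n:
        raise ValueError(f"window {window} exceeds block length {n}")
    match = (_to_array(reference_block) == _to_array(other_block)).astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(match)))
    starts = np.arange(0, n - window + 1, step)
    values = 100.0 * (csum[starts + window] - csum[starts]) / window
    return IdentityTrack("reference_block", window, step, starts, values)


def count_substitutions(
    seq_a: str, seq_b: str, mask: list[tuple[int, int]] | None = None
) -> SubstitutionCount:
    """Count differing positions between two aligned sequences, optionally
    restricted to mask intervals (0-based half-open). Sites where either
    sequence has a gap are excluded from the substitution count and tallied
    separately."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be pre-aligned to equal length")
    a, b = _to_array(seq_a), _to_array(seq_b)
    if mask is not None:
        sel = np.zeros(a.size, dtype=bool)
        for s, e in mask:
            if s < 0 or e > a.size:
                raise ValueError(f"mask interval ({s},{e}) out of bounds")
            sel[s:e] = True
        a, b = a[sel], b[sel]
    gap = ord("-")
    gappy = (a == gap) | (b == gap)
    subs = int(np.count_nonzero((a != b) & ~gappy))
    return SubstitutionCount(subs, int(np.count_nonzero(gappy)))


def ns_s_counts(
    cds_a: str,
    cds_b: str,
    region_partition: list[tuple[str, int, int]] | None = None,
) -> dict[str, tuple[int, int, int]]:
    """Classify every differing coding site as nonsynonymous or synonymous.

    Each differing site is substituted alone into its cds_a codon and the
    amino acids compared (standard code; stop gains count as nonsynonymous).
    Codons differing at more than one site keep per-site classification
    against the cds_a context but are additionally counted in the multi-hit
    tally. Regions are labelled codon intervals [start, end) in codon units;
    omitted, everything lands in region "all". Returns
    {label: (NS, S, multi_hit_sites)}.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS pair must be aligned to equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    n_codons = len(cds_a) // 3
    if region_partition is None:
        region_partition = [("all", 0, n_codons)]
    results = {label: [0, 0, 0] for label, _, _ in region_partition}

    def region_of(codon_i: int) -> str | None:
        for label, s, e in region_partition:
            if s <= codon_i < e:
                return label
        return None

    for ci in range(n_codons):
        ca = cds_a[ci * 3 : ci * 3 + 3]
        cb = cds_b[ci * 3 : ci * 3 + 3]
        if ca == cb:
            continue
        label = region_of(ci)
        if label is None:
            continue
        diff_sites = [k for k in range(3) if ca[k] != cb[k]]
        multi = len(diff_sites) > 1
        aa_a = str(Seq(ca).translate())
        for k in diff_sites:
            mutated = ca[:k] + cb[k] + ca[k + 1 :]
            aa_m = str(Seq(mutated).translate())
            if aa_m == aa_a:
                results[label][1] += 1
            else:
                results[label][0] += 1
            if multi:
                results[label][2] += 1
    return {label: tuple(v) for label, v in results.items()}


def p_distance_matrix(sequences: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distance (differing sites / compared sites) over an aligned
    set, with pairwise deletion of gap-containing columns. Returns
    (labels, symmetric matrix with zero diagonal)."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [name for name, _ in sequences]
    arrays = [_to_array(seq) for _, seq in sequences]
    n = len(arrays)
    length = arrays[0].size
    for name, a in zip(labels, arrays):
        if a.size != length:
            raise ValueError(f"sequence {name} has different alignment length")
    gap = ord("-")
    mat = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arrays[i] != gap) & (arrays[j] != gap)
            compared = int(np.count_nonzero(ok))
            if compared == 0:
                d = np.nan
            else:
                d = np.count_nonzero(arrays[i][ok] != arrays[j][ok]) / compared
            mat[i, j] = mat[j, i] = d
    return labels, mat


_ITIM_CANONICAL = re.compile(r"(?=(V.Y..L))")
_ITIM_DISRUPTED = re.compile(r"(?=(V.F..L))")


def scan_itims(protein: str, label: str = "protein") -> list[MotifHit]:
    """Scan a protein for canonical ITIMs (VxYxxL) and their tyrosine-to-
    phenylalanine disrupted form (VxFxxL), which attenuates inhibitory
    signalling. Overlapping matches are all reported, sorted by position."""
    seq = protein.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid symbols in {label}: {sorted(bad)}")
    hits = [
        MotifHit(label, m.start(), "ITIM_canonical", m.group(1))
        for m in _ITIM_CANONICAL.finditer(seq)
    ] + [
        MotifHit(label, m.start(), "ITIM_disrupted_YtoF", m.group(1))
        for m in _ITIM_DISRUPTED.finditer(seq)
    ]
    return sorted(hits, key=lambda h: (h.start, h.motif_class))


def classify_tm_adaptor(tm_segment: str, flank: str) -> str:
    """Adaptor pairing logic for activating receptors: an arginine in the
    membrane-proximal flank implies Fc-gamma/CD3-zeta-type association; a
    lysine within the transmembrane segment implies DAP10/DAP12-type
    association. Returns "Fc_gamma_type", "DAP_type", "none", or "both"
    (with a warning) when both charged residues are present."""
    if not tm_segment:
        raise ValueError("empty transmembrane segment")
    tm, fl = tm_segment.upper(), flank.upper()
    for name, s in (("tm_segment", tm), ("flank", fl)):
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid symbols in {name}: {sorted(bad)}")
    has_r = "R" in fl
    has_k = "K" in tm
    if has_r and has_k:
        warnings.warn("both membrane-proximal arginine and transmembrane lysine present")
        return "both"
    if has_r:
        return "Fc_gamma_type"
    if has_k:
        return "DAP_type"
    return "none"


def orf_integrity(gene: GeneModel, sequence: str) -> OrfVerdict:
    """Reading-frame integrity of a gene's spliced CDS.

    Functional iff the CDS starts with ATG, ends with a stop codon, contains
    no internal stop, and has length divisible by 3. Any violation makes the
    gene a pseudogene, with each defect located: frameshift (CDS position 0,
    meaning the overall length), lost_start/lost_stop at their codon
    positions, premature_stop at each internal stop codon's CDS offset."""
    if gene.exons[-1][1] > len(sequence):
        raise ValueError(f"gene {gene.gene_id}: exons outside sequence")
    cds = "".join(sequence[a:b] for a, b in gene.exons)
    if gene.strand == "-":
        cds = revcomp(cds)
    defects: list[tuple[str, int]] = []
    if len(cds) % 3 != 0:
        defects.append(("frameshift", 0))
    if not cds.startswith("ATG"):
        defects.append(("lost_start", 0))
    stops = {"TAA", "TAG", "TGA"}
    n_full = len(cds) // 3
    if n_full >= 1 and cds[(n_full - 1) * 3 : n_full * 3] not in stops:
        defects.append(("lost_stop", (n_full - 1) * 3))
    for ci in range(n_full - 1):
        if cds[ci * 3 : ci * 3 + 3] in stops:
            defects.append(("premature_stop", ci * 3))
    status = "functional" if not defects else "pseudogene"
    return OrfVerdict(gene.gene_id, status, tuple(defects))


def haplotype_orf_report(h: Haplotype) -> list[OrfVerdict]:
    return [orf_integrity(g, h.sequence) for g in h.genes]
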