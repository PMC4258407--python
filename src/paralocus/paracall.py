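"""Presence/absence inference for individual members of a paralog family.

Two independent lines of evidence are combined per gene, mirroring how a
short-read sample is interrogated for members of a family of >90%-identical
paralogs:

1. *Diagnostic-SNP consistency*: reads that map exclusively to one paralog
   group are assigned to their best-matching member gene; at each alignment
   column that distinguishes intragroup members, the majority sample base is
   compared with the member's expected base (either allele of the gene counts
   as a match).
2. *Unique-coverage comparison*: the fraction of the gene span covered by
   uniquely mapping sample reads, judged against the same quantity computed
   from an exhaustive error-free tiling of the reference haplotype (the
   positive control, which bounds what unique coverage is attainable at all
   for a duplicated gene).

The decision rule synthesising the two is configurable; genes whose control
coverage is ~0 (fully duplicated spans) can only be resolved through the
diagnostic SNPs, and coverage shortfall is never interpreted as absence
unless the control predicts coverage, so missing data is not mistaken for a
missing gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .covprof import depth_profile, gene_coverage_pct
from .mapper import Index, MapParams, build_index, map_read, map_reads
from .synthlocus import Haplotype, ShortRead, SimParams, tile_reads
from .varcons import PileupColumn

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


@dataclass(frozen=True)
class ParalogGroup:
    group_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"group {self.group_id}: at least one member required")


@dataclass(frozen=True)
class DiagnosticPosition:
    """An alignment column separating intragroup members."""

    group_id: str
    column: int
    per_member_base: dict[str, str]
    discriminates: frozenset[str]

    def __post_init__(self) -> None:
        bases = {b for b in self.per_member_base.values() if b != "-"}
        if len(bases) < 2:
            raise ValueError("diagnostic column must show >= 2 distinct bases")


@dataclass(frozen=True)
class ConsistencyReport:
    gene_id: str
    n_diagnostic: int
    n_consistent: int
    n_inconsistent: int
    n_uncovered: int

    def __post_init__(self) -> None:
        if self.n_consistent + self.n_inconsistent + self.n_uncovered != self.n_diagnostic:
            raise ValueError("consistency partition does not sum to n_diagnostic")


@dataclass(frozen=True)
class PresenceThresholds:
    """Decision-rule knobs (all logged in each call's rationale).

    min_depth: reads required at a diagnostic site before its majority base
    is trusted. min_consistent / max_inconsistent_frac: SNP-branch bar.
    cov_frac: fraction of the control's unique coverage the sample must reach
    for the coverage branch. control_floor: control coverage (%) below which
    coverage is unassessable. absent_cov_frac: unique coverage below this
    fraction of the control counts as "approximately zero" for the absence
    branch (tolerant of the odd stray read on a multi-kilobase span).
    """

    min_depth: int = 3
    min_consistent: int = 2
    max_inconsistent_frac: float = 0.2
    cov_frac: float = 0.5
    control_floor: float = 1.0
    absent_cov_frac: float = 0.1


@dataclass(frozen=True)
class PresenceCall:
    gene_id: str
    status: str  # present | absent | indeterminate
    unique_cov_pct: float
    control_cov_pct: float
    consistency: ConsistencyReport
    rationale: str


def groups_from_genes(genes) -> list[ParalogGroup]:
    by_group: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        by_group[g.group].append(g.gene_id)
    return [ParalogGroup(gid, tuple(members)) for gid, members in sorted(by_group.items())]


def group_exclusive_reads(
    reads: list[ShortRead],
    gene_indexes: dict[str, Index],
    groups: list[ParalogGroup],
    target_group: str,
    p: MapParams | None = None,
) -> list[ShortRead]:
    """Reads hitting at least one member of ``target_group`` (within the
    mismatch budget) and no gene of any other group."""
    group_of: dict[str, str] = {}
    for grp in groups:
        for m in grp.members:
            group_of[m] = grp.group_id
    if target_group not in {g.group_id for g in groups}:
        raise KeyError(f"unknown group: {target_group}")
    kept: list[ShortRead] = []
    for r in reads:
        hit_groups: set[str] = set()
        for gene_id, idx in gene_indexes.items():
            mr = map_read(r, idx, p)
            if mr.hits:
                hit_groups.add(group_of.get(gene_id, gene_id))
        if hit_groups == {target_group}:
            kept.append(r)
    return kept


def diagnostic_positions(
    member_sequences: list[tuple[str, str]], group_id: str = "group"
) -> list[DiagnosticPosition]:
    """All columns of a gap-free/pre-aligned member set showing >= 2 distinct
    non-gap bases, with the per-member base map and the member subset each
    column separates (members carrying a minority base at the column)."""
    if len(member_sequences) < 2:
        return []
    length = len(member_sequences[0][1])
    for name, seq in member_sequences:
        if len(seq) != length:
            raise ValueError(f"member {name}: alignment length differs")
    out: list[DiagnosticPosition] = []
    names = [n for n, _ in member_sequences]
    seqs = [s for _, s in member_sequences]
    for col in range(length):
        bases = {name: seq[col] for name, seq in zip(names, seqs)}
        distinct = {b for b in bases.values() if b != "-"}
        if len(distinct) < 2:
            continue
        counts: dict[str, int] = defaultdict(int)
        for b in bases.values():
            if b != "-":
                counts[b] += 1
        modal = max(counts.values())
        discriminates = frozenset(
            n for n, b in bases.items() if b != "-" and counts[b] < modal
        ) or frozenset(bases)
        out.append(DiagnosticPosition(group_id, col, bases, discriminates))
    return out


def consistency_counts(
    sample_pileup: list[PileupColumn],
    diagnostics: list[DiagnosticPosition],
    gene_id: str,
    min_depth: int = 3,
    allele_bases: dict[int, set[str]] | None = None,
) -> ConsistencyReport:
    """Score each diagnostic column against the sample pileup (in member
    coordinates): *consistent* when the majority sample base matches the
    member's expected base (any allele's base, via ``allele_bases``),
    *inconsistent* when a clear different base dominates, *uncovered* below
    ``min_depth``."""
    by_pos = {c.position: c for c in sample_pileup}
    n_cons = n_incons = n_uncov = 0
    for d in diagnostics:
        expected = (
            allele_bases.get(d.column, set())
            if allele_bases is not None
            else {d.per_member_base.get(gene_id, "-")}
        )
        expected = {b for b in expected if b != "-"}
        col = by_pos.get(d.column)
        depth = col.depth if col else 0
        if depth < min_depth or not expected:
            n_uncov += 1
            continue
        best = max(col.counts)
        top = [b for b, c in zip(_IDX_BASE, col.counts) if c == best]
        if len(top) == 1 and top[0] in expected:
            n_cons += 1
        else:
            n_incons += 1
    return ConsistencyReport(gene_id, len(diagnostics), n_cons, n_incons, n_uncov)


def call_presence(
    gene_id: str,
    sample_unique_cov_pct: float,
    control_unique_cov_pct: float,
    report: ConsistencyReport,
    thresholds: PresenceThresholds | None = None,
    confirmed_cov_pct: float | None = None,
    group_corroborated: bool = False,
) -> PresenceCall:
    """Synthesise SNP and coverage evidence into present/absent/indeterminate.

    ``confirmed_cov_pct`` is the unique coverage restricted to positions
    supported by at least two reads; a single stray read is not treated as
    coverage evidence against absence. Defaults to ``sample_unique_cov_pct``.

    ``group_corroborated`` states that at least one *other* member of the
    gene's paralog group shows consistent diagnostic evidence — i.e. the
    group-exclusive read pool demonstrably contains data. Only then can a
    total lack of member-defining SNPs be read as absence rather than as
    missing data, even when allelic variation in a surviving paralog mimics
    this member's sequence well enough to leave residual unique coverage.
    """
    t = thresholds or PresenceThresholds()
    if confirmed_cov_pct is None:
        confirmed_cov_pct = sample_unique_cov_pct
    incons_frac = report.n_inconsistent / report.n_diagnostic if report.n_diagnostic else 0.0
    snp_present = (
        report.n_consistent >= t.min_consistent and incons_frac <= t.max_inconsistent_frac
    )
    assessable = control_unique_cov_pct >= t.control_floor
    cov_present = assessable and sample_unique_cov_pct >= t.cov_frac * control_unique_cov_pct
    cov_absent = assessable and confirmed_cov_pct < t.absent_cov_frac * control_unique_cov_pct
    snp_absent = report.n_consistent < t.min_consistent
    snp_strong_absent = (
        group_corroborated
        and report.n_diagnostic >= 3
        and report.n_consistent == 0
        and not cov_present
    )

    if snp_present:
        status, why = "present", (
            f"SNP evidence: {report.n_consistent}/{report.n_diagnostic} diagnostic sites "
            f"consistent, inconsistent fraction {incons_frac:.2f} <= {t.max_inconsistent_frac}"
        )
    elif cov_present:
        status, why = "present", (
            f"coverage evidence: unique coverage {sample_unique_cov_pct:.1f}% >= "
            f"{t.cov_frac:.2f} x control {control_unique_cov_pct:.1f}%"
        )
    elif (cov_absent or snp_strong_absent) and snp_absent:
        detail = (
            f"confirmed unique coverage {confirmed_cov_pct:.1f}% ~ 0 where control predicts "
            f"{control_unique_cov_pct:.1f}%"
            if cov_absent
            else f"0/{report.n_diagnostic} member-defining sites present although sibling "
            "genes in the group are corroborated"
        )
        status, why = "absent", (
            f"{detail}; only {report.n_consistent} consistent diagnostic site(s) "
            f"at depth >= {t.min_depth}"
        )
    elif not assessable:
        status, why = "indeterminate", (
            f"control unique coverage {control_unique_cov_pct:.1f}% below floor "
            f"{t.control_floor}% — coverage unassessable; SNP evidence insufficient "
            f"({report.n_consistent} consistent, {report.n_inconsistent} inconsistent)"
        )
    else:
        status, why = "indeterminate", (
            f"evidence mixed: unique coverage {sample_unique_cov_pct:.1f}% vs control "
            f"{control_unique_cov_pct:.1f}%; {report.n_consistent} consistent / "
            f"{report.n_inconsistent} inconsistent / {report.n_uncovered} uncovered"
        )
    return PresenceCall(
        gene_id, status, sample_unique_cov_pct, control_unique_cov_pct, report, why
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class LocusAssessment:
    calls: dict[str, PresenceCall]
    control_cov: dict[str, float]
    sample_cov: dict[str, float]


def _member_refs(
    hap: Haplotype, flank: int
) -> dict[str, tuple[str, int, int]]:
    """gene_id -> (flanked span sequence, flank_left, span_length)."""
    out = {}
    n = len(hap.sequence)
    for g in hap.genes:
        s, e = g.span
        fs, fe = max(0, s - flank), min(n, e + flank)
        out[g.gene_id] = (hap.sequence[fs:fe], s - fs, e - s)
    return out


def assess_locus(
    ref_hap: Haplotype,
    sample_reads: list[ShortRead],
    alt_hap: Haplotype | None = None,
    map_params: MapParams | None = None,
    sim_params: SimParams | None = None,
    thresholds: PresenceThresholds | None = None,
    flank: int = 70,
) -> LocusAssessment:
    """Run the full two-approach presence/absence pipeline against a
    reference haplotype (optionally with a second, allelic haplotype whose
    gene coordinates match; either allele's base counts as consistent).

    Steps: (1) control unique coverage from exhaustive tiling of the
    reference; (2) sample unique coverage; (3) group-exclusive read
    selection against all gene spans of both haplotypes, competitive
    within-group member assignment, per-member pileups in span coordinates;
    (4) diagnostic-column consistency; (5) the decision rule.
    """
    mp = map_params or MapParams(k=11)
    sp = sim_params or SimParams()
    t = thresholds or PresenceThresholds()

    ref_name = ref_hap.hap_id
    hap_index = build_index([(ref_name, ref_hap.sequence)], mp)
    n_ref = len(ref_hap.sequence)

    control_mapped = map_reads(tile_reads(ref_hap.sequence, sp, ref_name), hap_index, mp)
    control_profile = depth_profile(control_mapped, n_ref, ref_name)
    sample_mapped = map_reads(sample_reads, hap_index, mp)
    sample_profile = depth_profile(sample_mapped, n_ref, ref_name)

    control_cov = {
        g.gene_id: gene_coverage_pct(control_profile, g, use_unique=True, min_depth=1)
        for g in ref_hap.genes
    }
    sample_cov = {
        g.gene_id: gene_coverage_pct(sample_profile, g, use_unique=True, min_depth=1)
        for g in ref_hap.genes
    }
    sample_cov2 = {
        g.gene_id: gene_coverage_pct(sample_profile, g, use_unique=True, min_depth=2)
        for g in ref_hap.genes
    }

    groups = groups_from_genes(ref_hap.genes)
    group_of = {m: grp.group_id for grp in groups for m in grp.members}

    # combined member index: gene spans (+flank) from both haplotypes
    member_refs = {"ref": _member_refs(ref_hap, flank)}
    if alt_hap is not None:
        member_refs["alt"] = _member_refs(alt_hap, flank)
    refs = [
        (f"{gene_id}@{hap}", seq)
        for hap, table in member_refs.items()
        for gene_id, (seq, _, _) in table.items()
    ]
    member_index = build_index(refs, mp)

    # one mapping pass; per-read gene-hit tabulation and best-member assignment
    pile: dict[str, np.ndarray] = {
        g.gene_id: np.zeros((g.span_length, 4), dtype=np.int64) for g in ref_hap.genes
    }
    from .synthlocus import revcomp as _rc

    for read in sample_reads:
        mr = map_read(read, member_index, mp)
        if not mr.hits:
            continue
        genes_hit = {h.ref_id.rsplit("@", 1)[0] for h in mr.hits}
        groups_hit = {group_of[g] for g in genes_hit}
        if len(groups_hit) != 1:
            continue  # cross-group read: excluded everywhere
        best = mr.hits[0].mismatches
        best_genes = {
            h.ref_id.rsplit("@", 1)[0] for h in mr.hits if h.mismatches == best
        }
        if len(best_genes) != 1:
            # tied between members: the read cannot attribute evidence to one
            # gene, so it contributes to no member pileup (ties between the
            # two alleles of the same gene are fine and kept)
            continue
        # count the read once, at its first best placement (both alleles of a
        # gene share span coordinates, so the choice between them is moot)
        h = mr.hits[0]
        gene_id, hap = h.ref_id.rsplit("@", 1)
        _, flank_left, span_len = member_refs[hap][gene_id]
        bases = read.bases if h.strand == "+" else _rc(read.bases)
        for offset, b in enumerate(bases):
            pos = h.start + offset - flank_left
            if 0 <= pos < span_len and b in _BASE_IDX:
                pile[gene_id][pos, _BASE_IDX[b]] += 1

    calls: dict[str, PresenceCall] = {}
    for grp in groups:
        members = [(m, ref_hap.gene_span_sequence(m)) for m in grp.members]
        alt_members = (
            {m: alt_hap.gene_span_sequence(m) for m in grp.members} if alt_hap else {}
        )
        diag_input = members + [(f"{m}~alt", s) for m, s in alt_members.items()]
        diags = diagnostic_positions(diag_input, grp.group_id)
        reports: dict[str, ConsistencyReport] = {}
        for m, seq in members:
            cols = [
                PileupColumn(pos, seq[pos], tuple(int(c) for c in pile[m][pos]))
                for pos in range(len(seq))
                if pile[m][pos].sum() > 0
            ]
            allele_bases = {
                d.column: {
                    d.per_member_base[m],
                    d.per_member_base.get(f"{m}~alt", d.per_member_base[m]),
                }
                for d in diags
            }
            reports[m] = consistency_counts(cols, diags, m, t.min_depth, allele_bases)
        for m, _ in members:
            corroborated = any(
                reports[other].n_consistent >= t.min_consistent
                for other, _ in members
                if other != m
            )
            calls[m] = call_presence(
                m,
                sample_cov[m],
                control_cov[m],
                reports[m],
                t,
                confirmed_cov_pct=sample_cov2[m],
                group_corroborated=corroborated,
            )
    return LocusAssessment(calls, control_cov, sample_cov)
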