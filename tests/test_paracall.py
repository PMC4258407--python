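"""Presence/absence inference: filtering, diagnostics, ground-truth recovery."""

import numpy as np
import pytest

from paralocus import (
    ConsistencyReport,
    MapParams,
    ParalogGroup,
    PileupColumn,
    PresenceThresholds,
    ShortRead,
    SimParams,
    assess_locus,
    build_haplotype,
    build_index,
    call_presence,
    consistency_counts,
    delete_gene,
    diagnostic_positions,
    generate_block,
    group_exclusive_reads,
    inject_allelic_snps,
    tile_reads,
    sample_ancient_reads,
)
from conftest import random_seq


class TestGroupExclusiveReads:
    @pytest.fixture
    def two_groups(self):
        rng = np.random.default_rng(51)
        g1a, g1b = random_seq(rng, 300), random_seq(rng, 300)
        g2a = random_seq(rng, 300)
        shared = random_seq(rng, 80)
        g1b = g1b[:100] + shared + g1b[180:]
        g2a = g2a[:100] + shared + g2a[180:]  # cross-group shared stretch
        p = MapParams(k=11)
        indexes = {
            "g1a": build_index([("g1a", g1a)], p),
            "g1b": build_index([("g1b", g1b)], p),
            "g2a": build_index([("g2a", g2a)], p),
        }
        groups = [ParalogGroup("group1", ("g1a", "g1b")), ParalogGroup("group2", ("g2a",))]
        return g1a, g1b, g2a, indexes, groups, p

    def test_group_specific_read_kept_only_for_its_group(self, two_groups):
        g1a, _, _, indexes, groups, p = two_groups
        read = ShortRead("q", g1a[10:45], (30,) * 35)
        assert group_exclusive_reads([read], indexes, groups, "group1", p) == [read]
        assert group_exclusive_reads([read], indexes, groups, "group2", p) == []

    def test_cross_group_read_dropped_everywhere(self, two_groups):
        _, g1b, _, indexes, groups, p = two_groups
        read = ShortRead("q", g1b[110:150], (30,) * 40)  # inside the shared stretch
        assert group_exclusive_reads([read], indexes, groups, "group1", p) == []
        assert group_exclusive_reads([read], indexes, groups, "group2", p) == []

    def test_unknown_group_raises(self, two_groups):
        *_, indexes, groups, p = two_groups
        with pytest.raises(KeyError):
            group_exclusive_reads([], indexes, groups, "group9", p)

    def test_kept_set_matches_brute_force_tabulation(self, two_groups):
        from conftest import brute_force_hits

        g1a, g1b, g2a, indexes, groups, p = two_groups
        refs = {"g1a": g1a, "g1b": g1b, "g2a": g2a}
        group_of = {"g1a": "group1", "g1b": "group1", "g2a": "group2"}
        rng = np.random.default_rng(52)
        reads = []
        for i in range(30):
            src = [g1a, g1b, g2a][i % 3]
            s = int(rng.integers(0, 260))
            frag = list(src[s : s + 35])
            if rng.random() < 0.4:
                frag[int(rng.integers(0, 35))] = "ACGT"[rng.integers(0, 4)]
            reads.append(ShortRead(f"q{i}", "".join(frag), (30,) * 35))
        for target in ("group1", "group2"):
            kept = group_exclusive_reads(reads, indexes, groups, target, p)
            expected = []
            for r in reads:
                hit_groups = {
                    group_of[gid]
                    for gid, seq in refs.items()
                    if brute_force_hits(r.bases, [(gid, seq)], p.max_mismatches)
                }
                if hit_groups == {target}:
                    expected.append(r)
            assert kept == expected


class TestDiagnosticPositions:
    def test_three_differing_sites(self):
        a = "ACGTACGTAC"
        b = "ACCTACGAAG"  # differs at 2, 7, 9
        diags = diagnostic_positions([("x", a), ("y", b)], "grp")
        assert [d.column for d in diags] == [2, 7, 9]
        assert diags[0].per_member_base == {"x": "G", "y": "C"}

    def test_identical_members_no_diagnostics(self):
        assert diagnostic_positions([("x", "ACGT"), ("y", "ACGT")]) == []

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_positions([("x", "ACGT"), ("y", "ACG")])

    def test_columns_match_brute_force_scan(self, duplicated_haplotype):
        s1 = duplicated_haplotype.gene_span_sequence("gene1_c1")
        s2 = duplicated_haplotype.gene_span_sequence("gene1_c2")
        diags = diagnostic_positions([("a", s1), ("b", s2)])
        expected = [i for i in range(len(s1)) if s1[i] != s2[i]]
        assert [d.column for d in diags] == expected


class TestConsistencyCounts:
    def _pileup_from(self, seq, positions, depth=10):
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        cols = []
        for p in positions:
            counts = [0, 0, 0, 0]
            counts[idx[seq[p]]] = depth
            cols.append(PileupColumn(p, seq[p], tuple(counts)))
        return cols

    def test_reads_from_gene_itself_all_consistent(self):
        a, b = "ACGTACGTACGT", "ACCTACGAACGA"
        diags = diagnostic_positions([("x", a), ("y", b)])
        cols = self._pileup_from(a, [d.column for d in diags])
        rep = consistency_counts(cols, diags, "x", min_depth=3)
        assert (rep.n_consistent, rep.n_inconsistent, rep.n_uncovered) == (len(diags), 0, 0)

    def test_paralog_reads_inconsistent_where_members_differ(self):
        a, b = "ACGTACGTACGT", "ACCTACGAACGA"
        diags = diagnostic_positions([("x", a), ("y", b)])
        cols = self._pileup_from(b, [d.column for d in diags])  # sample is really y
        rep = consistency_counts(cols, diags, "x", min_depth=3)
        assert rep.n_inconsistent == len(diags)

    def test_low_depth_counts_as_uncovered(self):
        a, b = "ACGTACGTACGT", "ACCTACGAACGA"
        diags = diagnostic_positions([("x", a), ("y", b)])
        cols = self._pileup_from(a, [d.column for d in diags], depth=2)
        rep = consistency_counts(cols, diags, "x", min_depth=3)
        assert rep.n_uncovered == len(diags)

    def test_partition_always_sums(self):
        rng = np.random.default_rng(53)
        a = random_seq(rng, 100)
        b = random_seq(rng, 100)
        diags = diagnostic_positions([("x", a), ("y", b)])
        covered = [d.column for d in diags if rng.random() < 0.5]
        cols = self._pileup_from(a if rng.random() < 0.5 else b, covered)
        rep = consistency_counts(cols, diags, "x", min_depth=3)
        assert rep.n_consistent + rep.n_inconsistent + rep.n_uncovered == rep.n_diagnostic

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError):
            ConsistencyReport("g", 10, 3, 3, 3)


class TestCallPresence:
    def _report(self, n_diag, n_cons, n_incons):
        return ConsistencyReport("g", n_diag, n_cons, n_incons, n_diag - n_cons - n_incons)

    def test_snp_branch_fires(self):
        call = call_presence("g", 0.0, 0.0, self._report(10, 8, 0))
        assert call.status == "present"
        assert "SNP evidence" in call.rationale

    def test_coverage_branch_fires(self):
        call = call_presence("g", 80.0, 90.0, self._report(0, 0, 0))
        assert call.status == "present"
        assert "coverage evidence" in call.rationale

    def test_absent_needs_control_predicting_coverage(self):
        call = call_presence("g", 0.0, 90.0, self._report(10, 0, 0))
        assert call.status == "absent"
        # duplicated gene: control 0 -> coverage unassessable, SNPs undecided
        call = call_presence("g", 0.0, 0.0, self._report(10, 0, 0))
        assert call.status == "indeterminate"
        assert "unassessable" in call.rationale

    def test_inconsistency_blocks_snp_branch(self):
        call = call_presence("g", 0.0, 90.0, self._report(10, 4, 6))
        assert call.status != "present"


class TestGroundTruthRecovery:
    def _run_locus(self, seed, n_blocks, genes_per_block, delete_ids, depth, error):
        groups = [f"group{i}" for i in range(genes_per_block)]
        block = generate_block(genes_per_block * 3000, genes_per_block, groups, seed)
        h1 = build_haplotype(block, n_blocks, 0.02, seed + 1)
        h2 = inject_allelic_snps(h1, len(h1.sequence) // 100, seed + 2)
        truth = h2
        for gid in delete_ids:
            truth = delete_gene(truth, gid)
        n_reads = int(len(truth.sequence) * depth / 50)
        reads = sample_ancient_reads(
            truth.sequence,
            SimParams(n_ancient_reads=n_reads, ancient_error_rate=error, seed=seed + 3),
            truth.hap_id,
        )
        return assess_locus(h1, reads, alt_hap=h2, map_params=MapParams(k=11))

    @pytest.mark.parametrize("seed", range(20))
    def test_presence_calls_match_ground_truth(self, seed):
        """Over randomized synthetic loci (2-3 blocks, 4-6 genes, 0-2
        deletions, depth >= 15, error <= 1%), every gene with informative
        control coverage or >= 3 diagnostic positions is called correctly."""
        rng = np.random.default_rng(1000 + seed)
        n_blocks = int(rng.integers(2, 4))
        genes_per_block = int(rng.integers(2, 4))
        all_ids = [
            f"gene{i + 1}_c{c + 1}" for c in range(n_blocks) for i in range(genes_per_block)
        ]
        n_del = int(rng.integers(0, 3))
        delete_ids = list(rng.choice(all_ids, size=n_del, replace=False))
        depth = int(rng.integers(15, 26))
        error = float(rng.uniform(0.0, 0.01))
        res = self._run_locus(2000 + seed, n_blocks, genes_per_block, delete_ids, depth, error)
        for gid, call in res.calls.items():
            informative = (
                res.control_cov[gid] >= 5.0 or call.consistency.n_diagnostic >= 3
            )
            if not informative:
                continue
            expected = "absent" if gid in delete_ids else "present"
            assert call.status == expected, (gid, call.status, call.rationale)

    def test_depth_monotonicity(self):
        """Raising sample depth never flips a correct call to incorrect."""
        for seed in (3001, 3002):
            lo = self._run_locus(seed, 2, 2, ["gene2_c1"], 15, 0.005)
            hi = self._run_locus(seed, 2, 2, ["gene2_c1"], 30, 0.005)
            for gid in lo.calls:
                expected = "absent" if gid == "gene2_c1" else "present"
                if lo.calls[gid].status == expected:
                    assert hi.calls[gid].status == expected
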