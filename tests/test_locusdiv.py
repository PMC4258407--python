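"""Block-structure and diversity analytics: identity, NS/S, motifs, ORFs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paralocus import (
    build_haplotype,
    classify_tm_adaptor,
    count_substitutions,
    dotplot_identity,
    inject_allelic_snps,
    ns_s_counts,
    orf_integrity,
    p_distance_matrix,
    scan_itims,
    window_identity_track,
)
from paralocus.synthlocus import GeneModel
from conftest import random_seq


class TestDotplot:
    def test_self_comparison_diagonal_100(self):
        rng = np.random.default_rng(61)
        seq = random_seq(rng, 1500)
        mat, a_starts, b_starts = dotplot_identity(seq, seq, window=250)
        assert np.allclose(np.diag(mat), 100.0)
        assert np.allclose(mat, mat.T)

    def test_unrelated_sequences_near_25_percent(self):
        """Uniform random bases agree at ~1/4 of positions per window."""
        rng = np.random.default_rng(62)
        a, b = random_seq(rng, 2000), random_seq(rng, 2000)
        mat, _, _ = dotplot_identity(a, b, window=250)
        # binomial(250, .25): SD ~ 2.7 pct points; means across windows tighter
        assert 20.0 < mat.mean() < 30.0
        assert mat.max() < 45.0

    def test_duplicated_haplotype_shows_off_diagonal(self, small_block):
        h = build_haplotype(small_block, 2, 0.0, seed=1)
        n = len(small_block[0])
        mat, a_starts, b_starts = dotplot_identity(h.sequence, h.sequence, window=250, step=250)
        k = n // 250  # offset of the duplicate in window units
        off = np.array([mat[i, i + k] for i in range(len(a_starts) - k)])
        assert np.allclose(off[: (n // 250)], 100.0)  # copy1-vs-copy2 band

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            dotplot_identity("ACGT" * 10, "ACGT" * 10, window=250)


class TestWindowIdentityTrack:
    def test_identical_blocks_constant_100(self):
        rng = np.random.default_rng(63)
        seq = random_seq(rng, 1200)
        track = window_identity_track(seq, seq, window=500)
        assert np.allclose(track.values, 100.0)
        assert len(track.values) == 1200 - 500 + 1

    def test_clustered_substitutions_local_minimum(self):
        rng = np.random.default_rng(64)
        a = random_seq(rng, 2000)
        b = list(a)
        for i in range(900, 910):  # 10 substitutions in one window
            b[i] = "A" if a[i] != "A" else "C"
        track = window_identity_track(a, "".join(b), window=500)
        assert track.values.min() == pytest.approx(100.0 * 490 / 500)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(65)
        a = random_seq(rng, 800)
        b = "".join(
            c if rng.random() > 0.05 else "ACGT"[rng.integers(0, 4)] for c in a
        )
        track = window_identity_track(a, b, window=500)
        for idx in (0, 100, 300):
            expected = 100.0 * sum(
                x == y for x, y in zip(a[idx : idx + 500], b[idx : idx + 500])
            ) / 500
            assert track.values[idx] == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            window_identity_track("ACGT" * 200, "ACGT" * 199)


class TestCountSubstitutions:
    def test_single_difference(self):
        assert count_substitutions("ACGT", "ACGA").substitutions == 1

    def test_identical_with_mask_zero(self):
        assert count_substitutions("ACGTACGT", "ACGTACGT", mask=[(0, 4)]).substitutions == 0

    def test_gaps_tallied_separately(self):
        r = count_substitutions("AC-TA", "ACGTC")
        assert r == (1, 1)  # one substitution (A/C at 4), one gap site

    def test_generator_ground_truth(self, duplicated_haplotype):
        h2 = inject_allelic_snps(duplicated_haplotype, 123, seed=9)
        assert count_substitutions(duplicated_haplotype.sequence, h2.sequence).substitutions == 123

    def test_exon_mask_never_exceeds_unmasked(self, duplicated_haplotype, allelic_haplotype):
        exons = [iv for g in duplicated_haplotype.genes for iv in g.exons]
        masked = count_substitutions(
            duplicated_haplotype.sequence, allelic_haplotype.sequence, mask=exons
        ).substitutions
        total = count_substitutions(
            duplicated_haplotype.sequence, allelic_haplotype.sequence
        ).substitutions
        assert masked <= total

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions("ACGT", "ACG")


class TestNsSCounts:
    def test_synonymous_site(self):
        assert ns_s_counts("TTT", "TTC")["all"] == (0, 1, 0)

    def test_nonsynonymous_site(self):
        assert ns_s_counts("TTT", "GTT")["all"] == (1, 0, 0)

    def test_multi_hit_codon_flagged_and_conserved(self):
        # TTT vs CTC differs at two sites of one codon: both sites classified
        # singly against the TTT context and both flagged as multi-hit
        (ns, s, multi) = ns_s_counts("TTT", "CTC")["all"]
        assert ns + s == 2
        assert multi == 2

    def test_region_partition_sums_to_whole(self):
        rng = np.random.default_rng(66)
        n_codons = 60
        a = "".join(random_seq(rng, 3) for _ in range(n_codons))
        b = "".join(
            c if rng.random() > 0.08 else "ACGT"[rng.integers(0, 4)] for c in a
        )
        whole = ns_s_counts(a, b)["all"]
        parts = ns_s_counts(a, b, [("ig", 0, 25), ("stem", 25, 40), ("tail", 40, 60)])
        summed = tuple(sum(p[i] for p in parts.values()) for i in range(3))
        assert summed == whole

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            ns_s_counts("TTTA", "TTTA")


class TestPDistance:
    def test_identical_pair_zero(self):
        labels, mat = p_distance_matrix([("a", "ACGT"), ("b", "ACGT")])
        assert mat[0, 1] == 0.0

    def test_quarter_distance(self):
        _, mat = p_distance_matrix([("a", "AAAA"), ("b", "AAAT")])
        assert mat[0, 1] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        _, mat = p_distance_matrix([("a", "AC-T"), ("b", "ACGT"), ("c", "TTGT")])
        assert mat[0, 1] == 0.0  # 3 compared sites, 0 diffs
        assert mat[0, 2] == pytest.approx(2 / 3)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 6), length=st.integers(10, 80))
    def test_symmetric_in_range_matches_brute_force(self, seed, n, length):
        rng = np.random.default_rng(seed)
        seqs = []
        for i in range(n):
            s = "".join(
                "-" if rng.random() < 0.08 else "ACGT"[rng.integers(0, 4)]
                for _ in range(length)
            )
            seqs.append((f"s{i}", s))
        labels, mat = p_distance_matrix(seqs)
        assert np.allclose(mat, mat.T, equal_nan=True)
        finite = mat[np.isfinite(mat)]
        assert np.all((finite >= 0) & (finite <= 1))
        for i in range(n):
            for j in range(i + 1, n):
                pairs = [
                    (x, y)
                    for x, y in zip(seqs[i][1], seqs[j][1])
                    if x != "-" and y != "-"
                ]
                if pairs:
                    expected = sum(x != y for x, y in pairs) / len(pairs)
                    assert mat[i, j] == pytest.approx(expected)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            p_distance_matrix([("a", "ACGT")])


class TestMotifs:
    def test_canonical_itim(self):
        (hit,) = scan_itims("VTYAQL")
        assert (hit.start, hit.motif_class) == (0, "ITIM_canonical")

    def test_disrupted_itim_y_to_f(self):
        (hit,) = scan_itims("VTFAQL")
        assert (hit.start, hit.motif_class) == (0, "ITIM_disrupted_YtoF")

    def test_too_short_no_hit(self):
        assert scan_itims("VTYAQ") == []

    def test_overlapping_and_multiple_hits(self):
        hits = scan_itims("AVTYAQLXXVLFSSLE")
        classes = {(h.start, h.motif_class) for h in hits}
        assert (1, "ITIM_canonical") in classes
        assert (9, "ITIM_disrupted_YtoF") in classes

    def test_bad_symbols_rejected(self):
        with pytest.raises(ValueError):
            scan_itims("VTY1QL")

    @pytest.mark.parametrize(
        "tm,flank,expected",
        [
            ("LLVVAGILL", "QHRSS", "Fc_gamma_type"),  # membrane-proximal arginine
            ("LLVKAGILL", "QHSSS", "DAP_type"),  # transmembrane lysine
            ("LLVVAGILL", "QHSSS", "none"),
        ],
    )
    def test_tm_adaptor_classification(self, tm, flank, expected):
        assert classify_tm_adaptor(tm, flank) == expected

    def test_both_charges_warns(self):
        with pytest.warns(UserWarning):
            assert classify_tm_adaptor("LLVKAGILL", "QHRSS") == "both"

    def test_empty_tm_rejected(self):
        with pytest.raises(ValueError):
            classify_tm_adaptor("", "QHRSS")


class TestOrfIntegrity:
    def test_generated_genes_functional(self, small_block):
        seq, genes = small_block
        for g in genes:
            assert orf_integrity(g, seq).status == "functional"

    def test_premature_stop_detected(self, small_block):
        seq, genes = small_block
        g = next(x for x in genes if x.strand == "+")
        # force TAA into codon 5 of the spliced CDS (inside the first exon)
        s = g.exons[0][0]
        mutated = seq[: s + 15] + "TAA" + seq[s + 18 :]
        verdict = orf_integrity(g, mutated)
        assert verdict.status == "pseudogene"
        assert ("premature_stop", 15) in verdict.defects

    def test_exon_shrink_is_frameshift(self, small_block):
        seq, genes = small_block
        g = genes[0]
        exons = list(g.exons)
        a, b = exons[1]
        exons[1] = (a, b - 1)  # 1-bp shorter exon
        import dataclasses

        shrunk = dataclasses.replace(g, exons=tuple(exons))
        verdict = orf_integrity(shrunk, seq)
        assert verdict.status == "pseudogene"
        assert any(kind == "frameshift" for kind, _ in verdict.defects)

    def test_lost_start_and_stop(self):
        gene = GeneModel("g", "grp", "+", ((0, 9),))
        assert orf_integrity(gene, "ATGAAATAA").status == "functional"
        v = orf_integrity(gene, "TTGAAATAA")
        assert ("lost_start", 0) in v.defects
        v = orf_integrity(gene, "ATGAAAAAA")
        assert ("lost_stop", 6) in v.defects
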