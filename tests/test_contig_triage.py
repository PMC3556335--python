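"""Clustering, gating, structure filtering, loci, FMI, intron chains."""

import statistics

import pytest
from hypothesis import given, settings, strategies as st

from detriage.contig_triage import (
    assembly_stats,
    assign_loci,
    classify_structure,
    cluster_contigs,
    compare_intron_chain,
    evidence_overlap,
    fmi_filter,
    gate_alignments,
    sequence_identity,
    triage_contigs,
    TriageCall,
)
from detriage.formats_io import (
    ContigSeq,
    GeneLocus,
    GenomeAnnotation,
    SplicedAlignment,
    TranscriptModel,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestClustering:
    def test_identical_sequences_merge(self, rng):
        seq = _rand_seq(rng, 300)
        clusters = cluster_contigs([ContigSeq("a", seq), ContigSeq("b", seq)])
        assert len(clusters) == 1
        assert clusters[0].representative == "a"  # tie broken by id

    def test_exact_substring_joins(self, rng):
        seq = _rand_seq(rng, 400)
        sub = seq[10 : 10 + 380]  # 95%-length exact substring
        clusters = cluster_contigs(
            [ContigSeq("long", seq), ContigSeq("short", sub)]
        )
        assert len(clusters) == 1
        assert clusters[0].representative == "long"
        assert set(clusters[0].members) == {"long", "short"}

    def test_unrelated_sequences_stay_singletons(self, rng):
        contigs = [ContigSeq(f"c{i:02d}", _rand_seq(rng, 250)) for i in range(50)]
        clusters = cluster_contigs(contigs)
        assert len(clusters) == 50

    def test_agrees_with_brute_force(self, rng):
        contigs = []
        base = [_rand_seq(rng, 300) for _ in range(8)]
        for i in range(30):
            which = int(rng.integers(0, 8))
            if rng.random() < 0.5:
                seq = base[which]
            else:
                cut = int(rng.integers(0, 60))
                seq = base[which][cut : cut + 240]
            contigs.append(ContigSeq(f"c{i:02d}", seq))
        clusters = cluster_contigs(contigs)
        # independent re-derivation of the greedy assignment
        ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
        oracle = []  # list of (rep ContigSeq, member ids)
        for c in ordered:
            for rep, members in oracle:
                ident, cov = sequence_identity(c.sequence, rep.sequence)
                if ident > 0.9 and cov >= 1.0:
                    members.append(c.contig_id)
                    break
            else:
                oracle.append((c, [c.contig_id]))
        assert [(cl.representative, cl.members) for cl in clusters] == [
            (rep.contig_id, members) for rep, members in oracle
        ]
        # partition property
        all_members = [m for cl in clusters for m in cl.members]
        assert sorted(all_members) == sorted(c.contig_id for c in contigs)

    def test_input_order_invariance(self, rng):
        contigs = [ContigSeq(f"c{i}", _rand_seq(rng, 200 + i)) for i in range(12)]
        shuffled = list(contigs)
        rng.shuffle(shuffled)
        assert cluster_contigs(contigs) == cluster_contigs(shuffled)

    def test_kmer_mode_matches_align_mode_on_exact_copies(self, rng):
        seq = _rand_seq(rng, 500)
        contigs = [
            ContigSeq("a", seq),
            ContigSeq("b", seq[20:480]),
            ContigSeq("c", _rand_seq(rng, 400)),
        ]
        for method in ("align", "kmer"):
            clusters = cluster_contigs(contigs, method=method)
            assert {frozenset(c.members) for c in clusters} == {
                frozenset({"a", "b"}),
                frozenset({"c"}),
            }


class TestAssemblyStats:
    def test_worked_example(self):
        stats = assembly_stats([200, 300, 400, 500, 600])
        assert stats.n50 == 500  # 600+500=1100 >= 1000
        assert stats.n90 == 300
        assert stats.n == 5 and stats.median == 400

    def test_singleton(self):
        stats = assembly_stats([10])
        assert stats.n50 == stats.n90 == 10

    def test_uniform(self):
        stats = assembly_stats([1] * 100)
        assert stats.n50 == 1 and stats.median == 1

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=100_000), min_size=1,
                    max_size=50))
    def test_invariants_hold_for_any_length_list(self, lengths):
        got = assembly_stats(lengths)
        assert got.n90 <= got.n50 <= got.max
        assert got.min <= got.median <= got.max
        assert got.n50 in lengths and got.n90 in lengths
        # at least half the total resides in contigs >= N50
        assert sum(x for x in lengths if x >= got.n50) * 2 >= sum(lengths)

    def test_fuzz_against_cumulative_brute_force(self, rng):
        for _ in range(200):
            lengths = [int(x) for x in rng.integers(1, 5000,
                                                    int(rng.integers(1, 60)))]
            got = assembly_stats(lengths)
            total = sum(lengths)
            for frac, value in ((0.5, got.n50), (0.9, got.n90)):
                cum = 0
                for ln in sorted(lengths, reverse=True):
                    cum += ln
                    if cum >= frac * total:
                        assert value == ln
                        break
            assert got.n90 <= got.n50 <= got.max
            assert got.min <= got.median <= got.max
            assert got.mean == pytest.approx(statistics.mean(lengths))


def _seg(cid, chrom, blocks, ident=0.95, cov=0.95, group=0, strand="+"):
    full = []
    q = 0
    for s, e in blocks:
        full.append(((q, q + e - s), (s, e)))
        q += e - s
    return SplicedAlignment(cid, chrom, strand, full, ident, cov, group)


class TestGating:
    def test_both_gates_pass(self):
        mapped, unmapped, chimeras = gate_alignments(
            [_seg("c1", "chr1", [(0, 100)], ident=0.95, cov=0.92)]
        )
        assert list(mapped) == ["c1"] and not unmapped and not chimeras

    def test_coverage_gate_fails(self):
        mapped, unmapped, _ = gate_alignments(
            [_seg("c1", "chr1", [(0, 100)], ident=0.95, cov=0.80)]
        )
        assert unmapped == ["c1"] and not mapped

    def test_two_chromosome_chimera(self):
        segs = [
            _seg("c1", "chr1", [(0, 100)], cov=0.6, group=0),
            _seg("c1", "chr5", [(0, 100)], cov=0.4, group=1),
        ]
        _m, _u, chimeras = gate_alignments(segs)
        assert chimeras == ["c1"]

    def test_distant_same_chromosome_chimera(self):
        segs = [
            _seg("c1", "chr1", [(0, 100)], cov=0.5, group=0),
            _seg("c1", "chr1", [(2_000_000, 2_000_100)], cov=0.5, group=1),
        ]
        assert gate_alignments(segs)[2] == ["c1"]

    def test_small_second_segment_is_not_chimera(self):
        segs = [
            _seg("c1", "chr1", [(0, 100)], cov=0.95, ident=0.95, group=0),
            _seg("c1", "chr2", [(0, 20)], cov=0.1, group=1),
        ]
        mapped, _u, chimeras = gate_alignments(segs)
        assert not chimeras and "c1" in mapped


def _annotation():
    t1 = TranscriptModel(
        "g1.t1", "g1", "chr1", "+",
        [(1000, 1500), (1700, 2200), (2400, 2900)], (1100, 2800)
    )
    t2 = TranscriptModel("g2.t1", "g2", "chr1", "+", [(5000, 5400), (5600, 6000)],
                         (5050, 5950))
    t3 = TranscriptModel("g3.t1", "g3", "chr1", "+", [(6200, 6600), (6800, 7200)],
                         (6250, 7150))
    genes = {
        "g1": GeneLocus("g1", "chr1", "+", t1.span, ["g1.t1"]),
        "g2": GeneLocus("g2", "chr1", "+", t2.span, ["g2.t1"]),
        "g3": GeneLocus("g3", "chr1", "+", t3.span, ["g3.t1"]),
    }
    return GenomeAnnotation(
        genes=genes,
        transcripts={t.transcript_id: t for t in (t1, t2, t3)},
        repeats=[("chr1", 9000, 9500)],
    )


class TestStructure:
    def test_multi_block_retained(self):
        aln = _seg("c", "chr1", [(1000, 1500), (1700, 2200)])
        assert classify_structure(aln, _annotation()) == "multi_exon"

    def test_fragment_inside_exon(self):
        aln = _seg("c", "chr1", [(1100, 1180)])
        assert classify_structure(aln, _annotation()) == "exon_fragment"

    def test_matching_single_exon(self):
        aln = _seg("c", "chr1", [(1005, 1495)])  # within +-10 bp of [1000,1500)
        assert classify_structure(aln, _annotation()) == "single_exon"

    def test_partial_intron(self):
        # 100-bp block with 70 bp inside intron [1500,1700)
        aln = _seg("c", "chr1", [(1630, 1730)])
        assert classify_structure(aln, _annotation()) == "partial_intron"

    def test_novel_region_length_rule(self):
        long_block = _seg("c", "chr1", [(20_000, 20_400)])
        short_block = _seg("c", "chr1", [(20_000, 20_150)])
        assert classify_structure(long_block, _annotation()) == \
            "retained_single_block"
        assert classify_structure(short_block, _annotation()) == "exon_fragment"

    def test_intron_retaining_block_is_retained(self):
        # spans exon1 + intron1 + exon2 of g1; intron is <50% of the block
        aln = _seg("c", "chr1", [(1000, 2200)])
        assert classify_structure(aln, _annotation()) == "retained_single_block"


class TestLoci:
    def test_single_gene_assignment(self):
        mapped = {"c1": _seg("c1", "chr1", [(1000, 1500), (1700, 2200)])}
        assignments, merged, novel = assign_loci(mapped, _annotation())
        assert assignments["c1"] == ("gene", "g1")
        assert not merged and not novel

    def test_merged_adjacent_genes(self):
        mapped = {"c1": _seg("c1", "chr1", [(5600, 6000), (6200, 6600)])}
        assignments, merged, _ = assign_loci(mapped, _annotation())
        kind, locus = assignments["c1"]
        assert kind == "merged" and locus == "merged:g2+g3"
        assert merged[0]["genes"] == ["g2", "g3"]

    def test_novel_single_linkage(self):
        mapped = {
            "c1": _seg("c1", "chr1", [(20_000, 20_500)]),
            "c2": _seg("c2", "chr1", [(20_300, 20_800)]),
            "c3": _seg("c3", "chr1", [(30_000, 30_400)]),
        }
        assignments, _m, novel = assign_loci(mapped, _annotation())
        assert len(novel) == 2
        first = next(n for n in novel if "c1" in n.members)
        assert set(first.members) == {"c1", "c2"}
        assert assignments["c1"] == assignments["c2"]
        assert assignments["c3"] != assignments["c1"]

    def test_repeat_region(self):
        mapped = {"c1": _seg("c1", "chr1", [(9100, 9400)])}
        assignments, _m, _n = assign_loci(mapped, _annotation())
        assert assignments["c1"] == ("repeat", None)


class TestFmi:
    def test_below_threshold_discarded(self):
        kept, discarded = fmi_filter({"A": 100.0, "B": 4.9})
        assert discarded == ["B"] and kept == ["A"]

    def test_exact_threshold_kept(self):
        kept, discarded = fmi_filter({"A": 100.0, "B": 5.0})
        assert not discarded and kept == ["A", "B"]

    def test_all_zero_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="all-zero"):
            kept, discarded = fmi_filter({"A": 0.0, "B": 0.0})
        assert kept == ["A", "B"] and not discarded

    def test_equals_predicate_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 8))
            expr = {
                f"m{i}": float(rng.choice([0.0, 0.5, 2.0, 5.0, 40.0, 100.0]))
                for i in range(n)
            }
            if max(expr.values()) == 0:
                continue
            kept, discarded = fmi_filter(expr)
            major = max(sorted(expr), key=lambda c: expr[c])
            expected_discard = sorted(
                c for c in expr
                if c != major and expr[c] < 0.05 * expr[major]
            )
            assert discarded == expected_discard
            assert sorted(kept + discarded) == sorted(expr)

    def test_higher_threshold(self):
        kept, discarded = fmi_filter({"A": 100.0, "B": 8.0}, threshold=0.10)
        assert discarded == ["B"]


class TestIntronChain:
    def test_identical_chain(self):
        refs = [TranscriptModel("t", "g", "chr1", "+", [(0, 100), (200, 300)])]
        aln = _seg("c", "chr1", [(0, 100), (200, 300)])
        assert compare_intron_chain(aln, refs) == "identical"

    def test_skipped_intron_is_novel(self):
        refs = [
            TranscriptModel("t", "g", "chr1", "+",
                            [(0, 100), (200, 300), (400, 500)])
        ]
        aln = _seg("c", "chr1", [(0, 100), (400, 500)])
        assert compare_intron_chain(aln, refs) == "novel_isoform"

    def test_single_exon_contig_at_multi_exon_locus(self):
        refs = [TranscriptModel("t", "g", "chr1", "+", [(0, 100), (200, 300)])]
        aln = _seg("c", "chr1", [(0, 300)])
        assert compare_intron_chain(aln, refs) == "novel_isoform"

    def test_fuzz_equals_exhaustive_chain_comparison(self, rng):
        for _ in range(100):
            refs = []
            for t in range(int(rng.integers(1, 4))):
                n_ex = int(rng.integers(1, 5))
                pos = int(rng.integers(0, 500))
                exons = []
                for _e in range(n_ex):
                    end = pos + int(rng.integers(50, 200))
                    exons.append((pos, end))
                    pos = end + int(rng.integers(50, 200))
                refs.append(
                    TranscriptModel(f"t{t}", "g", "chr1", "+", exons)
                )
            pick = refs[int(rng.integers(0, len(refs)))]
            if rng.random() < 0.5 and len(pick.exons) >= 2:
                aln = _seg("c", "chr1", pick.exons)
            else:
                shifted = [(s + 7, e + 7) for s, e in pick.exons]
                aln = _seg("c", "chr1", shifted)
            expected = (
                "identical"
                if any(aln.introns == t.introns for t in refs)
                else "novel_isoform"
            )
            assert compare_intron_chain(aln, refs) == expected


class TestEvidenceOverlap:
    def test_at_least_one_semantics(self):
        calls = [TriageCall("c1", "identical_isoform", "g1")]
        blocks = {"c1": ("chr1", [(100, 200)])}
        evidence = {
            "est": [("chr1", 100, 200), ("chr1", 150, 180), ("chr1", 120, 130)],
            "cdna": [("chr2", 100, 200)],
        }
        counts = evidence_overlap(calls, blocks, evidence)
        assert counts == {("identical_isoform", "est"): 1}

    def test_disjoint_is_zero(self):
        calls = [TriageCall("c1", "novel_locus", "n1")]
        blocks = {"c1": ("chr1", [(0, 50)])}
        assert evidence_overlap(calls, blocks, {"est": [("chr1", 60, 90)]}) == {}


class TestEndToEnd:
    def test_classes_partition_input(self, dataset):
        calls, _m, _n = triage_contigs(
            dataset.alignments,
            dataset.annotation,
            dataset.expression,
            all_contig_ids=[c.contig_id for c in dataset.contigs],
        )
        assert sorted(c.contig_id for c in calls) == sorted(
            c.contig_id for c in dataset.contigs
        )

    def test_missing_expression_is_error(self, dataset):
        with pytest.raises(ValueError, match="expression"):
            triage_contigs(dataset.alignments, dataset.annotation, {})
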