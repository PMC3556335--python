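"""ORF scanning, coding potential, and the unmapped-contig decision trees."""

import pytest
from Bio.Seq import Seq

from detriage.formats_io import ContigSeq, HomologyHit
from detriage.novel_and_private import (
    classify_novel_locus,
    cluster_private,
    coding_potential,
    filter_hits,
    find_orfs,
    longest_orf,
    triage_unmapped,
    triage_unmapped_all,
)

_NONSTOP = [
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
]


def _codons(rng, n):
    return "".join(rng.choice(_NONSTOP) for _ in range(n))


class TestFindOrfs:
    def test_full_orf_with_34_codons(self, rng):
        seq = "ATG" + _codons(rng, 32) + "TAA"
        orfs = [o for o in find_orfs(seq) if o.completeness == "full"]
        assert len(orfs) >= 1
        best = max(orfs, key=lambda o: o.length_codons)
        assert best.length_codons == 34
        assert best.frame == 0 and best.start == 0 and best.end == 102

    def test_open_end_is_partial_3prime(self, rng):
        seq = "ATG" + _codons(rng, 40)  # runs through the contig end
        orfs = find_orfs(seq)
        frame0 = [o for o in orfs if o.frame == 0]
        assert frame0 and frame0[0].completeness == "partial_3prime"

    def test_boundary_run_in_is_partial_5prime(self, rng):
        seq = _codons(rng, 40).replace("ATG", "AAG") + "TAA"
        frame0 = [o for o in find_orfs(seq) if o.frame == 0]
        assert frame0 and frame0[0].completeness == "partial_5prime"

    def test_reverse_strand_frames(self, rng):
        fwd = "ATG" + _codons(rng, 40) + "TGA"
        seq = str(Seq(fwd).reverse_complement())
        full = [o for o in find_orfs(seq) if o.completeness == "full"]
        assert any(o.frame >= 3 and o.length_codons == 42 for o in full)

    def test_random_sequences_match_brute_force_scan(self, rng):
        def brute(seq, min_codons=33):
            found = set()
            for strand_i, s in enumerate(
                (seq, str(Seq(seq).reverse_complement()))
            ):
                for f in range(3):
                    codons = [s[i:i + 3] for i in range(f, len(s) - 2, 3)]
                    seg = []
                    start_codon_idx = 0
                    for idx, c in enumerate(codons + ["TAA"]):
                        stop_here = c in ("TAA", "TAG", "TGA") and idx < len(codons)
                        end_of_seq = idx == len(codons)
                        if stop_here or end_of_seq:
                            seg_codons = codons[start_codon_idx:
                                                idx + (1 if stop_here else 0)]
                            at_boundary = start_codon_idx == 0
                            atg = next(
                                (j for j, cc in enumerate(seg_codons[
                                    : len(seg_codons) - (1 if stop_here else 0)
                                ]) if cc == "ATG"),
                                None,
                            )
                            if at_boundary and atg != 0:
                                o_start = 0
                            elif atg is not None:
                                o_start = atg
                            else:
                                o_start = None
                            if o_start is not None:
                                length = len(seg_codons) - o_start
                                if length >= min_codons:
                                    found.add(
                                        (strand_i * 3 + f,
                                         f + 3 * (start_codon_idx + o_start),
                                         length)
                                    )
                            start_codon_idx = idx + 1
                    del seg
            return found

        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            got = {
                (o.frame, o.start, o.length_codons) for o in find_orfs(seq)
            }
            assert got == brute(seq)


class TestCodingPotential:
    def test_coding_construct_is_coding(self, rng):
        seq = "CCCCC" + "ATG" + _codons(rng, 150) + "TAA" + "CCCCC"
        score, is_coding = coding_potential(seq)
        assert is_coding and score >= 0.5

    def test_random_sequences_are_mostly_noncoding(self, rng):
        false_calls = 0
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            _score, is_coding = coding_potential(seq)
            false_calls += is_coding
        assert false_calls <= 5  # >= 95% specificity

    def test_short_sequence_not_coding(self):
        assert coding_potential("ATGAAATGA")[1] is False

    def test_deterministic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=800))
        assert coding_potential(seq) == coding_potential(seq)


def _hit(query="q", subject="s", db="nr_protein", taxon="Viridiplantae",
         evalue=1e-20, coverage=0.8, bitscore=300.0):
    return HomologyHit(query, subject, db, taxon, evalue, 0.95, coverage,
                       bitscore)


class TestHitFilter:
    def test_significance_gate(self):
        hits = [
            _hit(evalue=1e-20, coverage=0.8),
            _hit(evalue=1e-3, coverage=0.8),
            _hit(evalue=1e-20, coverage=0.1),
        ]
        assert filter_hits(hits) == [hits[0]]


class TestNovelLocusTree:
    def test_transposon_precedes_coding(self, rng):
        seq = "ATG" + _codons(rng, 150) + "TAA"
        call = classify_novel_locus(
            "n1", [seq], [_hit(db="transposon_protein")]
        )
        assert call.cls == "transposon_like"

    def test_full_orf_no_hits(self, rng):
        seq = "CC" + "ATG" + _codons(rng, 150) + "TAA" + "CC"
        assert classify_novel_locus("n1", [seq], []).cls == "coding_full_orf"

    def test_partial_orf(self, rng):
        seq = "ATG" + _codons(rng, 200)  # no stop: partial
        assert classify_novel_locus("n1", [seq], []).cls == "coding_partial_orf"

    def test_homology_supported_then_rfam_then_ncrna(self, rng):
        noncoding = None
        for _ in range(100):
            cand = "".join(rng.choice(list("ACGT"), size=300))
            if longest_orf(cand) is None:
                noncoding = cand
                break
        assert noncoding is not None
        assert classify_novel_locus(
            "n", [noncoding], [_hit(db="nr_protein")]
        ).cls == "homology_supported"
        assert classify_novel_locus(
            "n", [noncoding], [_hit(db="rfam")]
        ).cls == "rna_family_like"
        assert classify_novel_locus("n", [noncoding], []).cls == "putative_ncRNA"

    def test_hit_order_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = [_hit(db="rfam"), _hit(db="nr_protein"),
                _hit(db="transposon_protein")]
        calls = {
            classify_novel_locus("n", [seq], perm).cls
            for perm in (hits, hits[::-1], [hits[1], hits[2], hits[0]])
        }
        assert calls == {"transposon_like"}


class TestUnmappedTriage:
    def test_fungal_best_hit_is_contaminant(self, rng):
        contig = ContigSeq("c", "".join(rng.choice(list("ACGT"), size=400)))
        call = triage_unmapped(contig, [_hit(taxon="Fungi")])
        assert call.cls == "contaminant"

    def test_plant_hit_without_raw_reads_is_private(self, rng):
        contig = ContigSeq("c", "".join(rng.choice(list("ACGT"), size=400)))
        call = triage_unmapped(contig, [_hit(db="plant_protein")])
        assert call.cls == "private_candidate"

    def test_raw_read_hit_with_orf_is_missing_coding(self, rng):
        seq = "CC" + "ATG" + _codons(rng, 150) + "TAA" + "CC"
        call = triage_unmapped(
            ContigSeq("c", seq),
            [_hit(db="genome_raw_reads"), _hit(db="vvgi_est")],
        )
        assert call.cls == "missing_from_assembly_coding"

    def test_tied_conflicting_taxa_resolve_to_contaminant(self, rng):
        contig = ContigSeq("c", "".join(rng.choice(list("ACGT"), size=400)))
        hits = [
            _hit(subject="p", taxon="Viridiplantae", bitscore=500.0),
            _hit(subject="f", taxon="Fungi", bitscore=500.0),
        ]
        assert triage_unmapped(contig, hits).cls == "contaminant"

    def test_plant_best_hit_overrides_weaker_fungal(self, rng):
        contig = ContigSeq("c", "".join(rng.choice(list("ACGT"), size=400)))
        hits = [
            _hit(subject="p", taxon="Viridiplantae", bitscore=500.0,
                 db="nr_protein"),
            _hit(subject="f", taxon="Fungi", bitscore=100.0),
            _hit(subject="v", db="vvgi_est"),
        ]
        assert triage_unmapped(contig, hits).cls == "private_candidate"

    def test_no_qualifying_hit(self, rng):
        contig = ContigSeq("c", "".join(rng.choice(list("ACGT"), size=400)))
        assert triage_unmapped(contig, []).cls == "no_evidence"

    def test_classes_partition_unmapped_set(self, clean_dataset):
        ds = clean_dataset
        truth = dict(zip(ds.contig_truth.contig_id, ds.contig_truth.triage_class))
        unmapped_ids = {
            cid
            for cid, cls in truth.items()
            if cls in {"contaminant", "missing_from_assembly",
                       "missing_from_assembly_coding", "private_candidate",
                       "no_evidence"}
        }
        contigs = [c for c in ds.contigs if c.contig_id in unmapped_ids]
        calls = triage_unmapped_all(contigs, ds.hits)
        assert len(calls) == len(unmapped_ids)
        for call in calls:
            assert call.cls == truth[call.contig_id]


class TestPrivateClustering:
    def _contigs(self, rng, n=5):
        return [
            ContigSeq(f"p{i}", "".join(rng.choice(list("ACGT"), size=400)))
            for i in range(n)
        ]

    def test_shared_subject_links(self, rng):
        contigs = self._contigs(rng, 3)
        hits = [
            _hit("p0", "S1", db="vvgi_est"),
            _hit("p1", "S1", db="vvgi_est"),
            _hit("p2", "S2", db="vvgi_est"),
        ]
        clusters = cluster_private(contigs, hits)
        assert sorted(sorted(c.members) for c in clusters) == [
            ["p0", "p1"], ["p2"]
        ]

    def test_no_shared_evidence_gives_singletons(self, rng):
        contigs = self._contigs(rng, 3)
        hits = [_hit(f"p{i}", f"S{i}", db="vvgi_est") for i in range(3)]
        assert len(cluster_private(contigs, hits)) == 3

    def test_sequence_similarity_links(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=400))
        near = list(base)
        for i in range(0, 400, 50):  # 2% divergence
            near[i] = "A" if near[i] != "A" else "C"
        contigs = [ContigSeq("p0", base), ContigSeq("p1", "".join(near))]
        clusters = cluster_private(contigs, [])
        assert len(clusters) == 1

    def test_clusters_equal_connected_components_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 10))
            contigs = self._contigs(rng, n)
            hits = []
            edges = set()
            for i in range(n):
                subj = f"S{int(rng.integers(0, max(1, n // 2)))}"
                hits.append(_hit(f"p{i}", subj, db="vvgi_est"))
            best = {f"p{i}": h.subject_id for i, h in enumerate(hits)}
            for i in range(n):
                for j in range(i + 1, n):
                    if best[f"p{i}"] == best[f"p{j}"]:
                        edges.add((f"p{i}", f"p{j}"))
            # DFS connected components as the oracle
            adj = {f"p{i}": set() for i in range(n)}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen, comps = set(), []
            for node in sorted(adj):
                if node in seen:
                    continue
                stack, comp = [node], set()
                while stack:
                    cur = stack.pop()
                    if cur in comp:
                        continue
                    comp.add(cur)
                    stack.extend(adj[cur] - comp)
                seen |= comp
                comps.append(sorted(comp))
            got = sorted(sorted(c.members) for c in cluster_private(contigs, hits))
            assert got == sorted(comps)

    def test_representative_is_longest_and_coding_flagged(self, rng):
        long_coding = "CC" + "ATG" + _codons(rng, 150) + "TAA" + "CC"
        short = "".join(rng.choice(list("ACGT"), size=100))
        contigs = [ContigSeq("a", short), ContigSeq("b", long_coding)]
        hits = [_hit("a", "S", db="vvgi_est"), _hit("b", "S", db="vvgi_est")]
        (cluster,) = cluster_private(contigs, hits)
        assert cluster.representative == "b" and cluster.coding
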