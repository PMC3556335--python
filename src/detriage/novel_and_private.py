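"""Novel-locus classification and unmapped-contig triage.

Contigs mapping into non-annotated genome regions are classified by a
decision tree: transposon-protein similarity first, then coding potential
(full ORFs begin with a start codon and end with an in-frame stop; partial
ORFs miss one of the two), then protein-database homology, then RNA-family
similarity, with putative non-coding RNA as the default leaf.

Contigs that do not map at all are triaged into contaminants (best protein
hit outside the green plants), genes missing from the reference assembly
(matching the reference's raw sequencing reads), and candidate private
genes (matching expressed plant sequences only), which are then collapsed
into private-gene clusters by shared database subjects or direct sequence
similarity.

Coding potential is a transparent heuristic — longest-ORF fraction of the
contig plus codon-position compositional bias — playing the same
binary decision role a trained coding/non-coding classifier would.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .formats_io import ContigSeq, HomologyHit
from .contig_triage import sequence_identity

#: taxa counted as plant; anything else among best protein hits marks a
#: contaminant (fungal contamination dominates in practice)
PLANT_TAXA = frozenset({"Viridiplantae"})

UNMAPPED_CLASSES = (
    "contaminant",
    "missing_from_assembly",
    "missing_from_assembly_coding",
    "private_candidate",
    "no_evidence",
)

NOVEL_LOCUS_CLASSES = (
    "transposon_like",
    "coding_full_orf",
    "coding_partial_orf",
    "homology_supported",
    "rna_family_like",
    "putative_ncRNA",
)


@dataclass
class OrfCall:
    """A maximal open reading frame in one of the six frames.

    ``frame`` is 0-2 on the forward strand, 3-5 on the reverse complement;
    ``start``/``end`` are half-open nucleotide offsets on the scanned
    strand's sequence, and ``length_codons`` includes the stop codon when
    present.
    """

    contig_id: str
    frame: int
    start: int
    end: int
    completeness: str  # full | partial_5prime | partial_3prime | partial_both
    length_codons: int


@dataclass
class NovelLocusCall:
    locus_id: str
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in NOVEL_LOCUS_CLASSES:
            raise ValueError(f"unknown novel-locus class {self.cls!r}")


@dataclass
class UnmappedCall:
    contig_id: str
    cls: str
    support: str | None = None  # subject id of the decisive hit

    def __post_init__(self) -> None:
        if self.cls not in UNMAPPED_CLASSES:
            raise ValueError(f"unknown unmapped class {self.cls!r}")


@dataclass
class PrivateGeneCluster:
    cluster_id: str
    members: list[str]
    representative: str
    coding: bool


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def find_orfs(
    sequence: str, min_codons: int = 33, contig_id: str = ""
) -> list[OrfCall]:
    """All maximal ORFs of >= ``min_codons`` codons across six frames.

    Each inter-stop segment of a frame yields at most one maximal ORF: from
    the first ATG when the segment starts mid-sequence, or from the
    sequence boundary when the frame runs in from the contig end (open
    5' end).  Completeness is full only when the ORF begins with ATG and
    ends with an in-frame stop inside the contig.
    """
    sequence = sequence.upper()
    orfs: list[OrfCall] = []
    for strand_i, seq in enumerate(
        (sequence, str(Seq(sequence).reverse_complement()))
    ):
        for f in range(3):
            frame = strand_i * 3 + f
            codons = [
                seq[i : i + 3] for i in range(f, len(seq) - 2, 3)
            ]
            seg_start = 0  # codon index where the current segment starts
            i = 0
            n = len(codons)
            while seg_start < n:
                stop_at = None
                for i in range(seg_start, n):
                    if codons[i] in _STOPS:
                        stop_at = i
                        break
                seg_end = stop_at + 1 if stop_at is not None else n
                at_boundary = seg_start == 0
                atg_at = next(
                    (
                        j
                        for j in range(seg_start, seg_end if stop_at is None
                                       else stop_at)
                        if codons[j] == "ATG"
                    ),
                    None,
                )
                if at_boundary and atg_at != seg_start:
                    orf_start, has_atg = seg_start, False
                elif atg_at is not None:
                    orf_start, has_atg = atg_at, True
                else:
                    orf_start = None
                    has_atg = False
                if orf_start is not None:
                    has_stop = stop_at is not None
                    length = seg_end - orf_start
                    if length >= min_codons:
                        if has_atg and has_stop:
                            comp = "full"
                        elif has_atg:
                            comp = "partial_3prime"
                        elif has_stop:
                            comp = "partial_5prime"
                        else:
                            comp = "partial_both"
                        orfs.append(
                            OrfCall(
                                contig_id=contig_id,
                                frame=frame,
                                start=f + 3 * orf_start,
                                end=f + 3 * seg_end,
                                completeness=comp,
                                length_codons=length,
                            )
                        )
                seg_start = seg_end
    return orfs


def longest_orf(sequence: str, min_codons: int = 33) -> OrfCall | None:
    orfs = find_orfs(sequence, min_codons=min_codons)
    if not orfs:
        return None
    return max(orfs, key=lambda o: (o.length_codons, -o.frame, -o.start))


# ---------------------------------------------------------------------------
# coding potential
# ---------------------------------------------------------------------------


def _positional_bias(orf_seq: str) -> float:
    """Mean total-variation distance between the nucleotide compositions of
    the three codon positions — near zero for random sequence, elevated for
    real coding sequence."""
    counts = [{b: 0 for b in "ACGT"} for _ in range(3)]
    total = 0
    for i, base in enumerate(orf_seq):
        if base in "ACGT":
            counts[i % 3][base] += 1
            total += 1
    if total < 30:
        return 0.0
    freqs = []
    for c in counts:
        s = sum(c.values()) or 1
        freqs.append({b: v / s for b, v in c.items()})
    pairs = [(0, 1), (0, 2), (1, 2)]
    tv = [
        0.5 * sum(abs(freqs[i][b] - freqs[j][b]) for b in "ACGT")
        for i, j in pairs
    ]
    return sum(tv) / len(tv)


def coding_potential(
    sequence: str, min_codons: int = 33
) -> tuple[float, bool]:
    """Heuristic coding score in [0,1] and a binary coding call.

    The score combines the longest ORF's fraction of the contig (weight
    0.7) with the ORF's codon-position compositional bias (weight 0.3); the
    contig is called coding when it has an ORF of at least ``min_codons``
    codons and the score reaches 0.5.  Deterministic in the sequence alone.
    """
    orf = longest_orf(sequence, min_codons=min_codons)
    if orf is None:
        return 0.0, False
    seq = sequence.upper()
    scanned = seq if orf.frame < 3 else str(Seq(seq).reverse_complement())
    orf_seq = scanned[orf.start : orf.end]
    frac = min(1.0, (orf.end - orf.start) / max(1, len(sequence)))
    score = min(1.0, 0.7 * frac + 0.3 * _positional_bias(orf_seq))
    return score, score >= 0.5


# ---------------------------------------------------------------------------
# hit filtering and the decision trees
# ---------------------------------------------------------------------------


def filter_hits(
    hits: list[HomologyHit],
    max_e_value: float = 1e-5,
    min_query_coverage: float = 0.20,
) -> list[HomologyHit]:
    """Significance gate for homology evidence (E <= 1e-5, coverage >= 20%)."""
    return [
        h
        for h in hits
        if h.e_value <= max_e_value and h.query_coverage >= min_query_coverage
    ]


def classify_novel_locus(
    locus_id: str,
    sequences: list[str],
    hits: list[HomologyHit],
    min_codons: int = 33,
) -> NovelLocusCall:
    """Decision tree for a novel locus (hits must be pre-filtered).

    Precedence: transposon-protein similarity > coding potential (full vs
    partial ORF) > protein homology > RNA-family similarity > putative
    non-coding RNA.  The call depends only on the hit set and the locus's
    longest sequence, never on hit order.
    """
    databases = {h.database for h in hits}
    if "transposon_protein" in databases:
        return NovelLocusCall(locus_id, "transposon_like")
    rep = max(sequences, key=len) if sequences else ""
    _score, is_coding = coding_potential(rep, min_codons=min_codons)
    if is_coding:
        orf = longest_orf(rep, min_codons=min_codons)
        cls = "coding_full_orf" if orf.completeness == "full" else "coding_partial_orf"
        return NovelLocusCall(locus_id, cls)
    if databases & {"nr_protein", "plant_protein"}:
        return NovelLocusCall(locus_id, "homology_supported")
    if "rfam" in databases:
        return NovelLocusCall(locus_id, "rna_family_like")
    return NovelLocusCall(locus_id, "putative_ncRNA")


def _best_hit(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Hits tied for best by (bitscore desc, e-value asc)."""
    if not hits:
        return []
    key = max((h.bitscore, -h.e_value) for h in hits)
    return [h for h in hits if (h.bitscore, -h.e_value) == key]


def triage_unmapped(
    contig: ContigSeq, hits: list[HomologyHit], min_codons: int = 33
) -> UnmappedCall:
    """Triage one unmapped contig (hits pre-filtered, same query).

    Decision order: a best protein hit outside the green plants marks a
    contaminant (ties among equal-score best hits with conflicting taxa
    resolve conservatively to contaminant); a raw-genome-read hit marks a
    gene missing from the reference assembly (coding subclass when the
    contig looks protein-coding); an expressed-plant-sequence or plant
    protein hit leaves a private-gene candidate; otherwise no evidence.
    """
    nr_hits = [h for h in hits if h.database == "nr_protein"]
    best = _best_hit(nr_hits)
    if best:
        taxa = {h.taxon for h in best}
        if taxa - PLANT_TAXA:
            culprit = sorted(h.subject_id for h in best if h.taxon not in PLANT_TAXA)
            return UnmappedCall(contig.contig_id, "contaminant", culprit[0])
    raw = sorted(
        (h for h in hits if h.database == "genome_raw_reads"),
        key=lambda h: (-h.bitscore, h.e_value, h.subject_id),
    )
    if raw:
        _score, is_coding = coding_potential(contig.sequence, min_codons=min_codons)
        cls = "missing_from_assembly_coding" if is_coding else "missing_from_assembly"
        return UnmappedCall(contig.contig_id, cls, raw[0].subject_id)
    plantish = sorted(
        (h for h in hits if h.database in {"vvgi_est", "plant_protein"}),
        key=lambda h: (-h.bitscore, h.e_value, h.subject_id),
    )
    if plantish:
        return UnmappedCall(contig.contig_id, "private_candidate",
                            plantish[0].subject_id)
    return UnmappedCall(contig.contig_id, "no_evidence")


def triage_unmapped_all(
    contigs: list[ContigSeq],
    hits: list[HomologyHit],
    prefilter: bool = True,
    min_codons: int = 33,
) -> list[UnmappedCall]:
    if prefilter:
        hits = filter_hits(hits)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return [
        triage_unmapped(c, by_query.get(c.contig_id, []), min_codons=min_codons)
        for c in sorted(contigs, key=lambda c: c.contig_id)
    ]


# ---------------------------------------------------------------------------
# private-gene clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_private(
    candidates: list[ContigSeq],
    hits: list[HomologyHit],
    min_identity: float = 0.90,
    min_short_coverage: float = 0.80,
) -> list[PrivateGeneCluster]:
    """Single-linkage clustering of private-gene candidates.

    Two candidates are linked when their best database subjects coincide or
    when they align to each other with identity above ``min_identity`` over
    at least ``min_short_coverage`` of the shorter sequence.  Each cluster
    is one putative private gene; the longest member represents it and
    carries the coding-potential flag.
    """
    ids = sorted(c.contig_id for c in candidates)
    seqs = {c.contig_id: c.sequence for c in candidates}
    uf = _UnionFind(ids)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_id in seqs and h.database in {"vvgi_est", "plant_protein"}:
            by_query.setdefault(h.query_id, []).append(h)
    best_subject = {}
    for cid, qh in by_query.items():
        best = _best_hit(qh)
        best_subject[cid] = min(h.subject_id for h in best)
    by_subject: dict[str, list[str]] = {}
    for cid, subj in best_subject.items():
        by_subject.setdefault(subj, []).append(cid)
    for members in by_subject.values():
        for other in members[1:]:
            uf.union(members[0], other)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if uf.find(ids[i]) == uf.find(ids[j]):
                continue
            ident, cov = sequence_identity(seqs[ids[i]], seqs[ids[j]])
            if ident > min_identity and cov >= min_short_coverage:
                uf.union(ids[i], ids[j])
    groups: dict[str, list[str]] = {}
    for cid in ids:
        groups.setdefault(uf.find(cid), []).append(cid)
    clusters = []
    for k, root in enumerate(sorted(groups), start=1):
        members = sorted(groups[root])
        rep = max(members, key=lambda c: (len(seqs[c]), c))
        _score, coding = coding_potential(seqs[rep])
        clusters.append(
            PrivateGeneCluster(
                cluster_id=f"private_{k:03d}",
                members=members,
                representative=rep,
                coding=coding,
            )
        )
    return clusters
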