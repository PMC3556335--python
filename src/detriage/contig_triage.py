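"""Triage of assembled contigs against an annotated reference genome.

The pipeline mirrors how a de novo transcriptome is reconciled with an
existing annotation: redundant contigs are collapsed by greedy clustering
(longest representative, identity > 90% over the full shorter sequence);
spliced alignments are gated at >= 90% identity and query coverage with
chimeras set aside; single-block contigs that are only exons, exon
fragments or partial introns are removed; survivors are assigned to
annotated gene loci (detecting adjacent genes merged by read-through
contigs) or grouped into novel loci; lowly expressed members of a locus are
discarded as incompletely spliced pre-mRNA when they fall below a fraction
(default 5%) of the locus's major isoform; and the remaining contigs are
called identical to a known transcript or a novel isoform by exact
intron-chain comparison.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import edlib

from .formats_io import (
    ContigSeq,
    GenomeAnnotation,
    SplicedAlignment,
    group_alignments,
)

#: classes a contig can end in; they partition every input set
TRIAGE_CLASSES = (
    "identical_isoform",
    "novel_isoform",
    "pre_mrna_filtered",
    "fragment_removed",
    "chimera_excluded",
    "repeat_region",
    "novel_locus",
    "unmapped",
)

#: structure classes whose contigs are removed from the catalog
REMOVAL_STRUCTURES = {"single_exon", "exon_fragment", "partial_intron"}


@dataclass
class ContigCluster:
    representative: str
    members: list[str]


@dataclass
class TriageCall:
    contig_id: str
    triage_class: str
    locus_id: str | None = None
    merged: bool = False

    def __post_init__(self) -> None:
        if self.triage_class not in TRIAGE_CLASSES:
            raise ValueError(f"unknown triage class {self.triage_class!r}")


@dataclass
class AssemblyStats:
    n: int
    max: int
    min: int
    mean: float
    median: float
    n50: int
    n90: int


@dataclass
class NovelLocus:
    locus_id: str
    chrom: str
    span: tuple[int, int]
    members: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def sequence_identity(a: str, b: str) -> tuple[float, float]:
    """(identity, coverage-of-shorter) via infix alignment of the shorter
    sequence inside the longer; the whole shorter sequence is aligned so its
    coverage is 1 by construction."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    identity = max(0.0, 1.0 - res["editDistance"] / len(short))
    return identity, 1.0


def _kmer_containment(a: str, b: str, k: int = 31) -> tuple[float, float]:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < k:
        return (1.0, 1.0) if short in long_ else (0.0, 0.0)
    kmers_s = {short[i : i + k] for i in range(len(short) - k + 1)}
    kmers_l = {long_[i : i + k] for i in range(len(long_) - k + 1)}
    shared = len(kmers_s & kmers_l) / len(kmers_s)
    return shared, shared


def cluster_contigs(
    contigs: list[ContigSeq],
    min_identity: float = 0.90,
    min_short_coverage: float = 1.0,
    method: str = "align",
) -> list[ContigCluster]:
    """Greedy length-descending clustering, longest member as representative.

    Contigs are visited longest-first (ties by id); each joins the first
    existing cluster whose representative aligns with identity strictly
    above ``min_identity`` over at least ``min_short_coverage`` of the
    shorter sequence, else founds its own cluster.  ``method='kmer'`` swaps
    the aligner for exact 31-mer containment when sequences are long but a
    full alignment is unnecessary.
    """
    if not contigs:
        raise ValueError("no contigs to cluster")
    simfun = sequence_identity if method == "align" else _kmer_containment
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    clusters: list[ContigCluster] = []
    reps: dict[str, str] = {}
    for contig in ordered:
        joined = False
        for cluster in clusters:
            ident, cov = simfun(contig.sequence, reps[cluster.representative])
            if ident > min_identity and cov >= min_short_coverage:
                cluster.members.append(contig.contig_id)
                joined = True
                break
        if not joined:
            clusters.append(ContigCluster(contig.contig_id, [contig.contig_id]))
            reps[contig.contig_id] = contig.sequence
    return clusters


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


def assembly_stats(lengths: list[int]) -> AssemblyStats:
    """Length statistics of an assembly, N50/N90 by descending cumulative sum."""
    if not lengths:
        raise ValueError("empty length list")
    if min(lengths) <= 0:
        raise ValueError("lengths must be positive")
    total = sum(lengths)

    def _nx(frac: float) -> int:
        cum = 0
        for ln in sorted(lengths, reverse=True):
            cum += ln
            if cum >= frac * total:
                return ln
        return min(lengths)  # pragma: no cover

    return AssemblyStats(
        n=len(lengths),
        max=max(lengths),
        min=min(lengths),
        mean=total / len(lengths),
        median=statistics.median(lengths),
        n50=_nx(0.5),
        n90=_nx(0.9),
    )


# ---------------------------------------------------------------------------
# alignment gating
# ---------------------------------------------------------------------------


def _is_chimera(
    segments: list[SplicedAlignment],
    min_segment_coverage: float = 0.20,
    max_distance: int = 1_000_000,
) -> bool:
    big = [s for s in segments if s.query_coverage >= min_segment_coverage]
    for i in range(len(big)):
        for j in range(i + 1, len(big)):
            a, b = big[i], big[j]
            if a.chrom != b.chrom:
                return True
            if a.strand != b.strand and "." not in (a.strand, b.strand):
                return True
            gap = max(
                b.target_span[0] - a.target_span[1],
                a.target_span[0] - b.target_span[1],
            )
            if gap > max_distance:
                return True
    return False


def gate_alignments(
    alignments: list[SplicedAlignment],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> tuple[dict[str, SplicedAlignment], list[str], list[str]]:
    """Split contigs into mapped (best passing segment), unmapped, chimeras.

    A contig is chimeric when >= 2 alignment segments each covering >= 20%
    of the query lie on different chromosomes, different strands, or more
    than 1 Mb apart.  Otherwise the best single segment (highest query
    coverage, then identity) must pass both gates for the contig to count
    as mapped.
    """
    mapped: dict[str, SplicedAlignment] = {}
    unmapped: list[str] = []
    chimeras: list[str] = []
    for contig_id, segments in sorted(group_alignments(alignments).items()):
        if len(segments) >= 2 and _is_chimera(segments):
            chimeras.append(contig_id)
            continue
        best = max(segments, key=lambda s: (s.query_coverage, s.identity))
        if best.identity >= min_identity and best.query_coverage >= min_coverage:
            mapped[contig_id] = best
        else:
            unmapped.append(contig_id)
    return mapped, unmapped, chimeras


# ---------------------------------------------------------------------------
# structure classification
# ---------------------------------------------------------------------------


def classify_structure(
    alignment: SplicedAlignment,
    annotation: GenomeAnnotation,
    end_tolerance: int = 10,
    intron_overlap_frac: float = 0.5,
    min_novel_single_exon: int = 200,
) -> str:
    """Structural class of a mapped alignment.

    Multi-block alignments are kept (``multi_exon``).  Single-block
    alignments are removed when they merely recapitulate annotation pieces:
    ``single_exon`` (matches one annotated exon within +-``end_tolerance``
    bp per end), ``exon_fragment`` (strictly inside one exon), or
    ``partial_intron`` (overlapping an annotated intron by more than half
    the block).  Remaining single blocks are ``retained_single_block`` —
    candidates for pre-mRNA filtering at annotated loci or for novel
    single-exon loci (only when >= ``min_novel_single_exon`` bp) elsewhere.
    """
    if len(alignment.blocks) >= 2:
        return "multi_exon"
    ts, te = alignment.target_blocks[0]
    block_len = te - ts
    chrom = alignment.chrom
    exons = [
        ex
        for tx in annotation.transcripts.values()
        if tx.chrom == chrom
        for ex in tx.exons
    ]
    for es, ee in exons:
        if abs(ts - es) <= end_tolerance and abs(te - ee) <= end_tolerance:
            return "single_exon"
    for es, ee in exons:
        if es <= ts and te <= ee:
            return "exon_fragment"
    introns = [
        iv
        for tx in annotation.transcripts.values()
        if tx.chrom == chrom
        for iv in tx.introns
    ]
    for is_, ie in introns:
        overlap = max(0, min(te, ie) - max(ts, is_))
        if overlap > intron_overlap_frac * block_len:
            return "partial_intron"
    in_annotation = any(
        tx.chrom == chrom and max(ts, tx.span[0]) < min(te, tx.span[1])
        for tx in annotation.transcripts.values()
    )
    if in_annotation:
        return "retained_single_block"
    return (
        "retained_single_block"
        if block_len >= min_novel_single_exon
        else "exon_fragment"
    )


# ---------------------------------------------------------------------------
# locus assignment
# ---------------------------------------------------------------------------


def _exonic_overlap(alignment: SplicedAlignment, tx_exons) -> int:
    total = 0
    for _q, (ts, te) in alignment.blocks:
        for es, ee in tx_exons:
            total += max(0, min(te, ee) - max(ts, es))
    return total


def _strand_compatible(a: str, b: str) -> bool:
    return "." in (a, b) or a == b


def assign_loci(
    mapped: dict[str, SplicedAlignment], annotation: GenomeAnnotation
) -> tuple[dict[str, tuple[str, str | None]], list[dict], list[NovelLocus]]:
    """Assign structure-filtered contigs to loci.

    Returns per-contig ``(kind, locus_id)`` with kind one of ``gene``,
    ``merged``, ``novel``, ``repeat``; a merged-loci report (contigs whose
    exonic overlap spans >= 2 annotated genes, evidence the annotation split
    one gene in two); and the novel loci built by single-linkage overlap of
    contigs in non-annotated regions.
    """
    gene_exons: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    for gid, g in annotation.genes.items():
        exons = [ex for tid in g.transcript_ids
                 for ex in annotation.transcripts[tid].exons]
        gene_exons[gid] = (g.chrom, g.strand, exons)

    assignments: dict[str, tuple[str, str | None]] = {}
    merged_report: list[dict] = []
    novel_candidates: list[tuple[str, SplicedAlignment]] = []

    for contig_id, aln in sorted(mapped.items()):
        overlaps = {}
        for gid, (chrom, strand, exons) in gene_exons.items():
            if chrom != aln.chrom or not _strand_compatible(strand, aln.strand):
                continue
            ov = _exonic_overlap(aln, exons)
            if ov > 0:
                overlaps[gid] = ov
        if len(overlaps) >= 2:
            members = sorted(overlaps)
            locus_id = "merged:" + "+".join(members)
            assignments[contig_id] = ("merged", locus_id)
            merged_report.append(
                {"locus_id": locus_id, "genes": members, "contig_id": contig_id}
            )
        elif len(overlaps) == 1:
            assignments[contig_id] = ("gene", next(iter(overlaps)))
        else:
            ts, te = aln.target_span
            on_repeat = any(
                c == aln.chrom and max(ts, s) < min(te, e)
                for c, s, e in annotation.repeats
            )
            if on_repeat:
                assignments[contig_id] = ("repeat", None)
            else:
                novel_candidates.append((contig_id, aln))

    # single-linkage grouping of novel-region contigs by target overlap
    novel_candidates.sort(key=lambda x: (x[1].chrom, x[1].target_span))
    novel_loci: list[NovelLocus] = []
    current: NovelLocus | None = None
    for contig_id, aln in novel_candidates:
        ts, te = aln.target_span
        if (
            current is not None
            and aln.chrom == current.chrom
            and ts < current.span[1]
        ):
            current.members.append(contig_id)
            current.span = (current.span[0], max(current.span[1], te))
        else:
            current = NovelLocus(
                locus_id=f"novel_{len(novel_loci) + 1:04d}",
                chrom=aln.chrom,
                span=(ts, te),
                members=[contig_id],
            )
            novel_loci.append(current)
    for locus in novel_loci:
        for contig_id in locus.members:
            assignments[contig_id] = ("novel", locus.locus_id)
    return assignments, merged_report, novel_loci


# ---------------------------------------------------------------------------
# fraction-of-major-isoform filter
# ---------------------------------------------------------------------------


def fmi_filter(
    expression: dict[str, float], threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Discard locus members expressed below ``threshold`` x the major isoform.

    The major isoform (highest FPKM, ties by id) is always kept; the
    comparison is strict, so a member at exactly the threshold fraction
    survives.  An all-zero locus is kept whole with a warning.
    """
    if not expression:
        return [], []
    for cid, fpkm in expression.items():
        if fpkm is None:
            raise ValueError(f"member {cid} lacks an expression value")
    major = max(sorted(expression), key=lambda c: expression[c])
    if expression[major] == 0:
        warnings.warn("all-zero expression at locus; keeping all members",
                      stacklevel=2)
        return sorted(expression), []
    kept, discarded = [], []
    for cid in sorted(expression):
        if cid != major and expression[cid] < threshold * expression[major]:
            discarded.append(cid)
        else:
            kept.append(cid)
    return kept, discarded


# ---------------------------------------------------------------------------
# isoform comparison
# ---------------------------------------------------------------------------


def compare_intron_chain(alignment: SplicedAlignment, references) -> str:
    """``identical`` iff the alignment's ordered intron intervals exactly
    equal those of some reference transcript, else ``novel_isoform``.

    A single-block contig matches only references that are themselves
    single-exon (empty chain = empty chain); at multi-exon loci it is a
    novel isoform.
    """
    chain = alignment.introns
    for tx in references:
        if tx.chrom == alignment.chrom and chain == tx.introns:
            return "identical"
    return "novel_isoform"


# ---------------------------------------------------------------------------
# evidence overlap
# ---------------------------------------------------------------------------


def evidence_overlap(
    calls: list[TriageCall],
    contig_blocks: dict[str, tuple[str, list[tuple[int, int]]]],
    evidence: dict[str, list[tuple[str, int, int]]],
) -> dict[tuple[str, str], int]:
    """Contig-level counts of >= 1 bp exonic intersection with each
    evidence source (at-least-one semantics: a contig overlapping three
    ESTs counts once for the est source)."""
    counts: dict[tuple[str, str], int] = {}
    for call in calls:
        placed = contig_blocks.get(call.contig_id)
        if placed is None:
            continue
        chrom, blocks = placed
        for source, intervals in evidence.items():
            hit = any(
                c == chrom and max(bs, s) < min(be, e)
                for c, s, e in intervals
                for bs, be in blocks
            )
            if hit:
                key = (call.triage_class, source)
                counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# full triage
# ---------------------------------------------------------------------------


def triage_contigs(
    alignments: list[SplicedAlignment],
    annotation: GenomeAnnotation,
    expression: dict[str, float],
    all_contig_ids: list[str] | None = None,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    fmi_threshold: float = 0.05,
    end_tolerance: int = 10,
    min_novel_single_exon: int = 200,
) -> tuple[list[TriageCall], list[dict], list[NovelLocus]]:
    """Run the whole contig-triage chain and return one call per contig.

    Order: alignment gating (chimeras out, sub-threshold contigs unmapped),
    structure filtering, locus assignment (annotated / merged / repeat /
    novel), pre-mRNA removal by the fraction-of-major-isoform rule within
    each annotated locus, then intron-chain comparison of survivors.
    Contig ids in ``all_contig_ids`` with no alignment records are reported
    unmapped, so the returned classes partition the full input set.
    """
    calls: dict[str, TriageCall] = {}
    mapped, unmapped, chimeras = gate_alignments(
        alignments, min_identity, min_coverage
    )
    for cid in chimeras:
        calls[cid] = TriageCall(cid, "chimera_excluded")
    for cid in unmapped:
        calls[cid] = TriageCall(cid, "unmapped")

    retained: dict[str, SplicedAlignment] = {}
    for cid, aln in mapped.items():
        structure = classify_structure(
            aln,
            annotation,
            end_tolerance=end_tolerance,
            min_novel_single_exon=min_novel_single_exon,
        )
        if structure in REMOVAL_STRUCTURES:
            calls[cid] = TriageCall(cid, "fragment_removed")
        else:
            retained[cid] = aln

    assignments, merged_report, novel_loci = assign_loci(retained, annotation)
    for cid, (kind, locus_id) in assignments.items():
        if kind == "repeat":
            calls[cid] = TriageCall(cid, "repeat_region")
        elif kind == "novel":
            calls[cid] = TriageCall(cid, "novel_locus", locus_id=locus_id)

    # pre-mRNA filtering and isoform comparison per annotated locus
    by_locus: dict[str, list[str]] = {}
    for cid, (kind, locus_id) in assignments.items():
        if kind in {"gene", "merged"}:
            by_locus.setdefault(locus_id, []).append(cid)
    for locus_id, members in sorted(by_locus.items()):
        merged = locus_id.startswith("merged:")
        gene_ids = locus_id[7:].split("+") if merged else [locus_id]
        references = [
            annotation.transcripts[tid]
            for gid in gene_ids
            for tid in annotation.genes[gid].transcript_ids
        ]
        try:
            locus_expr = {cid: expression[cid] for cid in members}
        except KeyError as exc:
            raise ValueError(
                f"locus {locus_id}: member {exc.args[0]} has no expression value"
            ) from exc
        kept, discarded = fmi_filter(locus_expr, fmi_threshold)
        for cid in discarded:
            calls[cid] = TriageCall(cid, "pre_mrna_filtered", merged=merged)
        for cid in kept:
            verdict = compare_intron_chain(retained[cid], references)
            cls = "identical_isoform" if verdict == "identical" else "novel_isoform"
            calls[cid] = TriageCall(cid, cls, locus_id=locus_id, merged=merged)

    if all_contig_ids is not None:
        for cid in all_contig_ids:
            if cid not in calls:
                calls[cid] = TriageCall(cid, "unmapped")
    return [calls[cid] for cid in sorted(calls)], merged_report, novel_loci
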