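"""Variant filtering and projection onto coding gene models.

Filtered polymorphisms (read depth >= 5, call quality >= 80, alternative
allele frequency >= 0.75 by default) are projected onto the annotation:
each variant is placed in a region class (CDS / UTR / intron / splice site /
intergenic) and, when it falls in coding sequence, its consequence on the
protein is derived by translating the reference and mutated CDS — the same
categories the study used to call proteins "potentially changed"
(substitutions) or "potentially destroyed" (frameshifts, premature stops,
stop-codon losses, splice-site mutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import Counter

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .formats_io import (
    GenomeAnnotation,
    GenomeModel,
    TranscriptModel,
    VariantRecord,
)

REGION_SEVERITY = ["splice_site", "CDS", "five_prime_UTR", "three_prime_UTR", "intron"]

#: consequences that can destroy a protein vs merely change it
DESTRUCTIVE = {"frameshift", "stop_gain", "stop_loss", "splice_site"}
CHANGING = {"missense", "in_frame_indel"}

_CONSEQUENCE_SEVERITY = [
    "splice_site",
    "stop_gain",
    "stop_loss",
    "frameshift",
    "missense",
    "in_frame_indel",
    "synonymous",
    "none",
]


@dataclass
class VariantEffect:
    variant: VariantRecord
    transcript_id: str
    region: str
    consequence: str = "none"

    def __post_init__(self) -> None:
        if self.consequence != "none" and self.region not in {"CDS", "splice_site"}:
            raise ValueError("coding consequence requires region CDS or splice_site")


@dataclass
class GeneImpactSummary:
    gene_id: str
    impact: str  # unaffected | changed | potentially_destroyed


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_variants(
    variants: list[VariantRecord],
    min_depth: int = 5,
    min_qual: float = 80.0,
    min_alt_freq: float = 0.75,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Keep variants with depth, quality and alt frequency at or above the
    thresholds (all inclusive); rejected records come back with the first
    failing criterion so that kept + rejected always partition the input."""
    kept, rejected = [], []
    for v in variants:
        if v.depth < min_depth:
            rejected.append((v, "depth"))
        elif v.qual < min_qual:
            rejected.append((v, "quality"))
        elif v.alt_frequency < min_alt_freq:
            rejected.append((v, "alt_frequency"))
        else:
            kept.append(v)
    return kept, rejected


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------


def _region_in_transcript(
    pos: int, tx: TranscriptModel, splice_window: int = 2
) -> str | None:
    s, e = tx.span
    if not (s <= pos < e):
        return None
    for isx, ise in tx.introns:
        if isx <= pos < min(isx + splice_window, ise) or max(
            isx, ise - splice_window
        ) <= pos < ise:
            return "splice_site"
    in_exon = any(es <= pos < ee for es, ee in tx.exons)
    if not in_exon:
        return "intron"
    if tx.cds_span is None:
        # noncoding transcript: exonic hits cannot be split into 5'/3' UTR
        return "three_prime_UTR"
    cs, ce = tx.cds_span
    if cs <= pos < ce:
        return "CDS"
    upstream = pos < cs
    if tx.strand == "+":
        return "five_prime_UTR" if upstream else "three_prime_UTR"
    return "three_prime_UTR" if upstream else "five_prime_UTR"


class TranscriptIndex:
    """Interval index of transcript spans per chromosome."""

    def __init__(self, annotation: GenomeAnnotation):
        self.annotation = annotation
        self._trees: dict[str, IntervalTree] = {}
        for tx in annotation.transcripts.values():
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            tree[tx.span[0] : tx.span[1]] = tx.transcript_id

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.annotation.transcripts[iv.data] for iv in tree[pos]),
            key=lambda t: t.transcript_id,
        )


def classify_region(
    variant: VariantRecord,
    annotation: GenomeAnnotation,
    splice_window: int = 2,
    index: TranscriptIndex | None = None,
) -> str:
    """Most severe region class of a variant across overlapping transcripts.

    Severity order: splice_site > CDS > UTR > intron; a variant hitting no
    transcript (or a chromosome absent from the annotation) is intergenic.
    """
    if index is None:
        index = TranscriptIndex(annotation)
    if variant.chrom not in annotation.chroms:
        warnings.warn(
            f"chromosome {variant.chrom!r} absent from annotation; "
            "classifying as intergenic",
            stacklevel=2,
        )
        return "intergenic"
    regions = [
        r
        for tx in index.overlapping(variant.chrom, variant.pos)
        if (r := _region_in_transcript(variant.pos, tx, splice_window)) is not None
    ]
    if not regions:
        return "intergenic"
    return min(regions, key=REGION_SEVERITY.index)


# ---------------------------------------------------------------------------
# coding-effect projection
# ---------------------------------------------------------------------------


def _spliced_cds(tx: TranscriptModel, genome: GenomeModel) -> str:
    seq = "".join(genome.sequences[tx.chrom][s:e] for s, e in tx.cds_exons())
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(tx: TranscriptModel, pos: int) -> int | None:
    """Map a genomic position into spliced-CDS coordinates (strand-aware)."""
    offset = 0
    plus_off = None
    for s, e in tx.cds_exons():
        if s <= pos < e:
            plus_off = offset + (pos - s)
            break
        offset += e - s
    if plus_off is None:
        return None
    if tx.strand == "-":
        total = sum(e - s for s, e in tx.cds_exons())
        return total - 1 - plus_off
    return plus_off


def _snv_consequence(cds: str, offset: int, ref_base: str, alt_base: str) -> str:
    mutated = cds[:offset] + alt_base + cds[offset + 1 :]
    ref_prot = str(Seq(cds).translate())
    mut_prot = str(Seq(mutated).translate())
    n = len(ref_prot)
    # new in-frame stop before the terminal codon
    for i in range(n - 1):
        if mut_prot[i] == "*" and ref_prot[i] != "*":
            return "stop_gain"
    if ref_prot[-1] == "*" and mut_prot[-1] != "*":
        return "stop_loss"
    return "missense" if mut_prot != ref_prot else "synonymous"


def annotate_coding_effect(
    variant: VariantRecord,
    transcript: TranscriptModel,
    genome: GenomeModel,
    splice_window: int = 2,
) -> VariantEffect:
    """Consequence of one variant on one coding transcript.

    Splice-site variants get the splice_site consequence without
    translation.  CDS indels are frameshift or in_frame_indel by the length
    difference mod 3; CDS substitutions are classified by translating the
    reference and mutated spliced CDS (multi-base substitutions are
    decomposed base-by-base and the most severe consequence is kept).
    """
    region = _region_in_transcript(variant.pos, transcript, splice_window)
    if region not in {"CDS", "splice_site"}:
        raise ValueError(
            f"variant at {variant.chrom}:{variant.pos} is {region}, "
            "not CDS/splice_site, for this transcript"
        )
    if transcript.cds_span is None:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    if region == "splice_site":
        return VariantEffect(
            variant, transcript.transcript_id, "splice_site", "splice_site"
        )

    cds = _spliced_cds(transcript, genome)
    if len(cds) % 3 != 0:
        raise ValueError(
            f"transcript {transcript.transcript_id}: CDS length {len(cds)} "
            "is not a multiple of 3 (annotation fault)"
        )
    if len(variant.ref) != len(variant.alt):
        diff = abs(len(variant.alt) - len(variant.ref))
        cons = "frameshift" if diff % 3 else "in_frame_indel"
        return VariantEffect(variant, transcript.transcript_id, "CDS", cons)

    # substitution: decompose MNVs into per-base SNVs
    best = "synonymous"
    for i, (rb, ab) in enumerate(zip(variant.ref, variant.alt)):
        if rb == ab:
            continue
        offset = _cds_offset(transcript, variant.pos + i)
        if offset is None:
            continue
        if transcript.strand == "-":
            ab = str(Seq(ab).complement())
        cons = _snv_consequence(cds, offset, rb, ab)
        if _CONSEQUENCE_SEVERITY.index(cons) < _CONSEQUENCE_SEVERITY.index(best):
            best = cons
    return VariantEffect(variant, transcript.transcript_id, "CDS", best)


def annotate_variants(
    variants: list[VariantRecord],
    annotation: GenomeAnnotation,
    genome: GenomeModel,
    splice_window: int = 2,
) -> list[VariantEffect]:
    """Project every variant onto every overlapping transcript."""
    index = TranscriptIndex(annotation)
    effects = []
    for v in variants:
        for tx in index.overlapping(v.chrom, v.pos):
            region = _region_in_transcript(v.pos, tx, splice_window)
            if region is None:
                continue
            if region in {"CDS", "splice_site"} and tx.cds_span is not None:
                effects.append(annotate_coding_effect(v, tx, genome, splice_window))
            else:
                effects.append(VariantEffect(v, tx.transcript_id, region, "none"))
    return effects


# ---------------------------------------------------------------------------
# gene-level roll-up
# ---------------------------------------------------------------------------


def summarize_gene_impact(
    effects: list[VariantEffect], annotation: GenomeAnnotation
) -> tuple[list[GeneImpactSummary], Counter]:
    """Roll per-transcript effects up to genes.

    A gene is potentially destroyed if any member transcript carries a
    frameshift, premature stop, stop loss or splice-site mutation; changed
    if (not destroyed and) any missense or in-frame indel; else unaffected.
    """
    by_gene: dict[str, set[str]] = {g: set() for g in annotation.genes}
    for eff in effects:
        tx = annotation.transcripts.get(eff.transcript_id)
        if tx is not None:
            by_gene.setdefault(tx.gene_id, set()).add(eff.consequence)
    summaries = []
    counts: Counter = Counter()
    for gene_id in sorted(by_gene):
        cons = by_gene[gene_id]
        if cons & DESTRUCTIVE:
            impact = "potentially_destroyed"
        elif cons & CHANGING:
            impact = "changed"
        else:
            impact = "unaffected"
        summaries.append(GeneImpactSummary(gene_id, impact))
        counts[impact] += 1
    return summaries, counts


def region_counts(
    variants: list[VariantRecord],
    annotation: GenomeAnnotation,
    splice_window: int = 2,
) -> Counter:
    """Variant counts per (most severe) region class."""
    index = TranscriptIndex(annotation)
    return Counter(
        classify_region(v, annotation, splice_window, index) for v in variants
    )
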