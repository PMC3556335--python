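"""Read-pair geometry and genome-coverage summaries.

Two small computations sit upstream of the triage proper: the mate-spacer
geometry a spliced aligner needs (fragment size minus the two reads), and
the per-base genome coverage track used to ask how much of the reference is
transcribed and in which annotation class (exon / intron / intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import GenomeAnnotation, GenomeModel, SplicedAlignment


def estimate_insert_geometry(
    fragment_mean: float, fragment_sd: float, read_length: int
) -> tuple[float, float]:
    """Mean and SD of the unsequenced spacer between paired-end mates.

    For a library with fragment size ``fragment_mean`` ± ``fragment_sd`` and
    reads of ``read_length`` bp from both ends, the spacer is the fragment
    minus the two reads; the SD is untouched because the read length is
    fixed.  Overlapping mates (fragment < 2 reads) are unsupported.
    """
    if fragment_mean < 2 * read_length:
        raise ValueError(
            f"fragment mean {fragment_mean} < 2 x read length {read_length}: "
            "overlapping mates unsupported"
        )
    return fragment_mean - 2 * read_length, fragment_sd


@dataclass
class CoverageTrack:
    depth: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.depth.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"negative depth on {chrom}")


@dataclass
class CoverageClassSummary:
    total_covered: int
    counts: dict[str, int]  # annotated_exon / intron / intergenic

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_covered:
            raise ValueError("class counts do not sum to total covered")

    @property
    def fractions(self) -> dict[str, float]:
        if self.total_covered == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.total_covered for k, v in self.counts.items()}


def coverage_from_alignments(
    alignments: list[SplicedAlignment], genome: GenomeModel
) -> CoverageTrack:
    """Per-base depth: number of alignment blocks overlapping each base."""
    depth = {c: np.zeros(n + 1, dtype=np.int64) for c, n in genome.lengths.items()}
    for aln in alignments:
        if aln.chrom not in depth:
            raise ValueError(f"alignment on unknown chromosome {aln.chrom!r}")
        arr = depth[aln.chrom]
        for _q, (ts, te) in aln.blocks:
            if ts < 0 or te > len(arr) - 1:
                raise ValueError(
                    f"block {ts}-{te} outside chromosome {aln.chrom}"
                )
            arr[ts] += 1
            arr[te] -= 1
    return CoverageTrack(
        {c: np.cumsum(arr[:-1]).astype(np.int64) for c, arr in depth.items()}
    )


def _annotation_masks(
    annotation: GenomeAnnotation, chrom: str, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """(exon mask, transcript-span mask) for one chromosome."""
    exon = np.zeros(length, dtype=bool)
    span = np.zeros(length, dtype=bool)
    for tx in annotation.transcripts.values():
        if tx.chrom != chrom:
            continue
        s, e = tx.span
        span[max(0, s) : min(length, e)] = True
        for es, ee in tx.exons:
            exon[max(0, es) : min(length, ee)] = True
    return exon, span


def classify_covered_bases(
    track: CoverageTrack, annotation: GenomeAnnotation, min_depth: int = 3
) -> CoverageClassSummary:
    """Partition bases covered at >= min_depth into exon/intron/intergenic.

    Precedence is annotated_exon > intron > intergenic: a base exonic in any
    isoform counts as exonic; intronic means inside a transcript span but in
    no exon of that chromosome.  Each covered base lands in exactly one
    class.
    """
    counts = {"annotated_exon": 0, "intron": 0, "intergenic": 0}
    total = 0
    for chrom, arr in track.depth.items():
        covered = np.asarray(arr) >= min_depth
        n_cov = int(covered.sum())
        if n_cov == 0:
            continue
        total += n_cov
        exon, span = _annotation_masks(annotation, chrom, len(arr))
        n_exon = int((covered & exon).sum())
        n_intron = int((covered & span & ~exon).sum())
        counts["annotated_exon"] += n_exon
        counts["intron"] += n_intron
        counts["intergenic"] += n_cov - n_exon - n_intron
    return CoverageClassSummary(total_covered=total, counts=counts)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = np.asarray(track.depth[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def read_bedgraph(path, lengths: dict[str, int]) -> CoverageTrack:
    depth = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split()[:4]
            depth[chrom][int(s) : int(e)] = int(float(v))
    return CoverageTrack(depth)
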