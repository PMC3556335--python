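"""Deterministic generator of a toy study with machine-readable truth.

Emulates the data a de novo transcriptome project produces — an annotated
multi-gene genome, assembled contigs of every triage class (exact and novel
isoforms, intron-retaining pre-mRNA fragments, chimeras, read-throughs over
adjacent gene pairs, novel coding/noncoding loci, repeat contigs, private
genes, assembly-gap genes, contaminants), filtered and sub-threshold
variants of every coding-effect class, homology hits with database/taxon
labels, and negative-binomial counts for three berry stages x three
replicates with planted four-pattern profiles.  Every entity carries a
truth record, and a fixed seed reproduces every output byte-for-byte.

Alignments are emitted directly from the generative truth (an aligner's
job, not this package's): each contig's BED12 blocks are the genome
intervals it was built from.  An optional error mode jitters block edges by
up to 5 bp to exercise downstream tolerances; it is off by default because
exact intron-chain comparison is intentionally exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats_io import (
    ContigSeq,
    CountTable,
    GeneLocus,
    GenomeAnnotation,
    GenomeModel,
    HomologyHit,
    SplicedAlignment,
    TranscriptModel,
)
from .novel_and_private import longest_orf

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

_AA = {c: str(Seq(c).translate()) for c in (x + y + z for x in "ACGT"
                                            for y in "ACGT" for z in "ACGT")}

VARIANT_CLASSES = (
    "synonymous",
    "missense",
    "stop_gain",
    "stop_loss",
    "frameshift",
    "splice_site",
    "intron",
    "intergenic",
)


@dataclass
class SimulationConfig:
    """Study conditions for the toy dataset.

    Defaults give two 500-kb chromosomes carrying 60 genes, a contig set
    covering every triage class, 240 effect-planted variants plus
    sub-threshold decoys, and 3 stages x 3 replicates of NB counts at mean
    200 and dispersion 0.05 with 8-fold planted patterns — small enough to
    run the whole chain in seconds, rich enough to exercise every rule.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    isoforms_per_gene: tuple[int, int] = (1, 2)
    # planted contig classes
    n_identical: int = 10
    n_novel_isoform: int = 8
    n_pre_mrna: int = 6
    n_chimera: int = 5
    n_merged_pairs: int = 4
    n_novel_coding: int = 5
    n_novel_noncoding: int = 5
    n_repeat_contigs: int = 3
    n_private: int = 6
    n_assembly_gap: int = 4
    n_contaminant: int = 6
    n_no_evidence: int = 3
    # variants
    variants_per_class: int = 30
    n_subthreshold_variants: int = 12
    # expression counts
    n_features: int = 200
    n_per_pattern: int = 30
    nb_mean: float = 200.0
    nb_dispersion: float = 0.05
    fold_change: float = 8.0
    # noise
    substitution_error_rate: float = 0.01
    edge_jitter: int = 0  # max +-bp applied to block edges when > 0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and name != "seed" and value < 0:
                raise ValueError(f"{name} must be >= 0")
        if 4 * self.n_per_pattern > self.n_features:
            raise ValueError("n_features too small for the patterned features")


@dataclass
class GenomeLayout:
    """Bookkeeping of planted structure the annotation does not show."""

    merged_pairs: list[tuple[str, str]] = field(default_factory=list)
    novel_coding: list[dict] = field(default_factory=list)
    novel_noncoding: list[dict] = field(default_factory=list)
    repeat_slots: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeModel
    annotation: GenomeAnnotation
    layout: GenomeLayout
    variants: list
    variant_truth: pd.DataFrame
    contigs: list[ContigSeq]
    alignments: list[SplicedAlignment]
    hits: list[HomologyHit]
    expression: dict[str, float]
    raw_read_pool: list[tuple[str, str]]
    contig_truth: pd.DataFrame
    counts: CountTable
    profile_truth: pd.DataFrame
    term_map: dict[str, set[str]]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _orf_free_seq(rng: np.random.Generator, length: int,
                  min_codons: int = 33) -> str:
    """Random sequence with no ORF of >= min_codons in any of six frames.

    Rejection sampling alone stalls for longer sequences, so any surviving
    ORF is broken constructively by writing a stop codon into its middle
    (on the strand the ORF lives on) until none remains.
    """
    for _attempt in range(50):
        seq = _random_seq(rng, length)
        for _round in range(100):
            orf = longest_orf(seq, min_codons=min_codons)
            if orf is None:
                return seq
            mid = orf.start + 3 * (orf.length_codons // 2)
            if orf.frame < 3:
                seq = seq[:mid] + "TAA" + seq[mid + 3 :]
            else:  # scanned strand is the reverse complement
                j = length - mid - 3
                seq = seq[:j] + "TTA" + seq[j + 3 :]
    raise RuntimeError("could not construct an ORF-free sequence")


def _design_gene(rng: np.random.Generator, n_exons: int) -> dict:
    """A gene in transcript space: exon/intron lengths, UTRs, a valid CDS."""
    exon_lens = rng.integers(150, 451, n_exons)
    intron_lens = rng.integers(100, 301, max(0, n_exons - 1))
    total_ex = int(exon_lens.sum())
    u5 = int(rng.integers(20, 61))
    u3 = int(rng.integers(20, 61))
    cds_len = total_ex - u5 - u3
    cds_len -= cds_len % 3
    u3 = total_ex - u5 - cds_len
    n_internal = cds_len // 3 - 2
    codons = [str(rng.choice(_CODONS)) for _ in range(n_internal)]
    cds = "ATG" + "".join(codons) + str(rng.choice(_STOPS))
    spliced = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    # unspliced pre-mRNA with exon offsets
    unspliced = []
    exon_offsets = []
    pos = 0
    spliced_pos = 0
    for i, ln in enumerate(exon_lens):
        exon_offsets.append((pos, pos + int(ln)))
        unspliced.append(spliced[spliced_pos : spliced_pos + int(ln)])
        spliced_pos += int(ln)
        pos += int(ln)
        if i < n_exons - 1:
            unspliced.append(_random_seq(rng, int(intron_lens[i])))
            pos += int(intron_lens[i])
    return {
        "unspliced": "".join(unspliced),
        "exon_offsets": exon_offsets,
        "cds_spliced": (u5, u5 + cds_len),
        "exon_lens": [int(x) for x in exon_lens],
    }


def _spliced_to_unspliced(exon_offsets, spliced_pos: int) -> int:
    acc = 0
    for s, e in exon_offsets:
        ln = e - s
        if spliced_pos < acc + ln:
            return s + (spliced_pos - acc)
        acc += ln
    raise ValueError("spliced position outside exons")


def _place_gene(design: dict, g0: int, strand: str, chrom: str,
                gene_id: str, tx_id: str) -> tuple[str, TranscriptModel]:
    """Genome-sense sequence of the gene plus its transcript model."""
    unspliced = design["unspliced"]
    length = len(unspliced)
    cs_s = _spliced_to_unspliced(design["exon_offsets"], design["cds_spliced"][0])
    cs_e = (
        _spliced_to_unspliced(design["exon_offsets"], design["cds_spliced"][1] - 1)
        + 1
    )
    if strand == "+":
        seq = unspliced
        exons = [(g0 + s, g0 + e) for s, e in design["exon_offsets"]]
        cds_span = (g0 + cs_s, g0 + cs_e)
    else:
        seq = str(Seq(unspliced).reverse_complement())
        exons = sorted(
            (g0 + length - e, g0 + length - s) for s, e in design["exon_offsets"]
        )
        cds_span = (g0 + length - cs_e, g0 + length - cs_s)
    tx = TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_span=cds_span,
    )
    return seq, tx


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[GenomeModel, GenomeAnnotation, GenomeLayout]:
    """Random genome with planted gene models, repeats and hidden novel loci.

    Genes have 2-5 exons, a valid CDS (ATG..stop, length a multiple of 3)
    and both strands; same-strand adjacent pairs are reserved for
    read-through (merged-locus) contigs.  Novel coding/noncoding loci are
    written into the sequence but kept out of the annotation.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom_ids = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_seqs = {
        c: np.array(list(_random_seq(rng, config.chrom_length)))
        for c in chrom_ids
    }
    needed = config.n_genes + 2 * config.n_merged_pairs
    min_len = needed // max(1, config.n_chroms) * 4000 + 20_000
    if config.chrom_length < min_len:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small for {needed} genes; "
            f"need >= {min_len}"
        )

    cursors = {c: 2000 for c in chrom_ids}
    transcripts: dict[str, TranscriptModel] = {}
    genes: dict[str, GeneLocus] = {}
    layout = GenomeLayout()

    def _write(chrom: str, g0: int, seq: str) -> None:
        chrom_seqs[chrom][g0 : g0 + len(seq)] = list(seq)

    def _next_slot(chrom_i: int, length: int) -> tuple[str, int]:
        chrom = chrom_ids[chrom_i % len(chrom_ids)]
        g0 = cursors[chrom]
        if g0 + length + 2000 > config.chrom_length:
            raise ValueError("genome too small for requested content")
        cursors[chrom] = g0 + length + int(rng.integers(1500, 4000))
        return chrom, g0

    def _add_gene(idx: int, chrom: str, g0: int, strand: str,
                  n_exons: int) -> TranscriptModel:
        gid, tid = f"gene_{idx:03d}", f"gene_{idx:03d}.t1"
        design = _design_gene(rng, n_exons)
        seq, tx = _place_gene(design, g0, strand, chrom, gid, tid)
        _write(chrom, g0, seq)
        transcripts[tid] = tx
        genes[gid] = GeneLocus(gid, chrom, strand, tx.span, [tid])
        # optional second (noncoding, exon-skipped) isoform
        if (
            config.isoforms_per_gene[1] >= 2
            and n_exons >= 3
            and rng.random() < 0.4
        ):
            skipped = tx.exons[:1] + tx.exons[2:]
            t2 = TranscriptModel(
                transcript_id=f"{gid}.t2",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=skipped,
                cds_span=None,
            )
            transcripts[t2.transcript_id] = t2
            genes[gid].transcript_ids.append(t2.transcript_id)
        return tx

    idx = 0
    for i in range(config.n_genes):
        n_exons = int(rng.integers(2, 6))
        strand = "+" if rng.random() < 0.5 else "-"
        design_len = 451 * 5 + 301 * 4  # generous upper bound
        chrom, g0 = _next_slot(i, design_len)
        _add_gene(idx, chrom, g0, strand, n_exons)
        idx += 1
    for p in range(config.n_merged_pairs):
        chrom, g0 = _next_slot(p, 2 * (451 * 5 + 301 * 4) + 200)
        strand = "+" if p % 2 == 0 else "-"
        tx1 = _add_gene(idx, chrom, g0, strand, 2)
        gap = int(rng.integers(120, 200))
        tx2_start = tx1.span[1] + gap
        tx2 = _add_gene(idx + 1, chrom, tx2_start, strand, 2)
        layout.merged_pairs.append((tx1.gene_id, tx2.gene_id))
        idx += 2

    for k in range(config.n_novel_coding):
        design = _design_gene(rng, 2)
        chrom, g0 = _next_slot(k, len(design["unspliced"]))
        _write(chrom, g0, design["unspliced"])
        layout.novel_coding.append(
            {
                "chrom": chrom,
                "exons": [(g0 + s, g0 + e) for s, e in design["exon_offsets"]],
            }
        )
    for k in range(config.n_novel_noncoding):
        length = int(rng.integers(300, 501))
        chrom, g0 = _next_slot(k + 1, length)
        _write(chrom, g0, _orf_free_seq(rng, length))
        layout.novel_noncoding.append(
            {"chrom": chrom, "span": (g0, g0 + length)}
        )
    for k in range(config.n_repeat_contigs):
        length = 2000
        chrom, g0 = _next_slot(k, length)
        layout.repeat_slots.append((chrom, g0, g0 + length))

    genome = GenomeModel({c: "".join(arr) for c, arr in chrom_seqs.items()})
    annotation = GenomeAnnotation(
        genes=genes, transcripts=transcripts, repeats=list(layout.repeat_slots)
    )
    return genome, annotation, layout


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def _cds_genome_positions(tx: TranscriptModel) -> list[int]:
    pieces = tx.cds_exons()
    if tx.strand == "+":
        return [p for s, e in pieces for p in range(s, e)]
    return [p for s, e in reversed(pieces) for p in range(e - 1, s - 1, -1)]


def _comp(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A"}[base]


def plant_variants(
    config: SimulationConfig,
    genome: GenomeModel,
    annotation: GenomeAnnotation,
) -> tuple[list, pd.DataFrame]:
    """Variants of every effect class with above-threshold depth/quality/
    frequency, plus sub-threshold decoys failing exactly one filter."""
    from .formats_io import VariantRecord

    rng = np.random.default_rng([config.seed, 2])
    coding = sorted(
        t.transcript_id
        for t in annotation.transcripts.values()
        if t.cds_span is not None
    )
    if not coding:
        raise ValueError("annotation has no coding transcript")
    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def _passing() -> tuple[int, float, float]:
        return (
            int(rng.integers(5, 80)),
            float(rng.integers(80, 1000)),
            float(rng.uniform(0.75, 1.0)),
        )

    def _emit(chrom, pos, ref, alt, cls, tx_id, kept=True,
              depth=None, qual=None, freq=None) -> None:
        if depth is None:
            depth, qual, freq = _passing()
        records.append(
            VariantRecord(chrom, pos, ref, alt, depth, qual, freq)
        )
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "transcript_id": tx_id,
                "effect_class": cls,
                "kept": kept,
            }
        )
        used.add((chrom, pos))

    def _free(chrom: str, pos: int, ref_len: int = 1) -> bool:
        return all((chrom, pos + i) not in used for i in range(ref_len + 1))

    def _snv_for_class(cls: str) -> None:
        for _try in range(5000):
            tx = annotation.transcripts[str(rng.choice(coding))]
            cds_pos = _cds_genome_positions(tx)
            cds = "".join(
                genome.sequences[tx.chrom][p] if tx.strand == "+"
                else _comp(genome.sequences[tx.chrom][p])
                for p in cds_pos
            )
            n_cod = len(cds) // 3
            if cls == "stop_loss":
                j = n_cod - 1
            else:
                j = int(rng.integers(1, n_cod - 1))
            codon = cds[3 * j : 3 * j + 3]
            options = []
            for off in range(3):
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    new = codon[:off] + b + codon[off + 1 :]
                    ok = {
                        "synonymous": _AA[new] == _AA[codon] and new not in _STOPS,
                        "missense": (
                            _AA[new] != _AA[codon]
                            and new not in _STOPS
                            and _AA[new] != "*"
                        ),
                        "stop_gain": new in _STOPS,
                        "stop_loss": codon in _STOPS and new not in _STOPS,
                    }[cls]
                    if ok:
                        options.append((off, b))
            if not options:
                continue
            off, b = options[int(rng.integers(0, len(options)))]
            i = 3 * j + off
            pos = cds_pos[i]
            if not _free(tx.chrom, pos):
                continue
            ref = genome.sequences[tx.chrom][pos]
            alt = b if tx.strand == "+" else _comp(b)
            _emit(tx.chrom, pos, ref, alt, cls, tx.transcript_id)
            return
        raise RuntimeError(f"could not place a {cls} variant")

    def _frameshift() -> None:
        for _try in range(5000):
            tx = annotation.transcripts[str(rng.choice(coding))]
            cds_pos = sorted(_cds_genome_positions(tx))
            i = int(rng.integers(3, len(cds_pos) - 4))
            pos = cds_pos[i]
            if cds_pos[i + 1] != pos + 1 or not _free(tx.chrom, pos, 2):
                continue
            ref_base = genome.sequences[tx.chrom][pos]
            if rng.random() < 0.5:  # insertion
                ins = str(rng.choice(list("ACGT")))
                _emit(tx.chrom, pos, ref_base, ref_base + ins,
                      "frameshift", tx.transcript_id)
            else:  # 1-bp deletion
                ref = genome.sequences[tx.chrom][pos : pos + 2]
                _emit(tx.chrom, pos, ref, ref_base,
                      "frameshift", tx.transcript_id)
            return
        raise RuntimeError("could not place a frameshift variant")

    def _near_boundary(chrom: str, pos: int, window: int) -> bool:
        for tx in annotation.transcripts.values():
            if tx.chrom != chrom:
                continue
            for s, e in tx.introns:
                if min(abs(pos - s), abs(pos - (e - 1))) <= window:
                    return True
        return False

    def _in_any_exon(chrom: str, pos: int) -> bool:
        return any(
            tx.chrom == chrom and any(s <= pos < e for s, e in tx.exons)
            for tx in annotation.transcripts.values()
        )

    def _splice_or_intron(cls: str) -> None:
        for _try in range(5000):
            tx = annotation.transcripts[str(rng.choice(coding))]
            if not tx.introns:
                continue
            s, e = tx.introns[int(rng.integers(0, len(tx.introns)))]
            if cls == "splice_site":
                pos = int(rng.choice([s, s + 1, e - 2, e - 1]))
            else:
                if e - s <= 12:
                    continue
                pos = int(rng.integers(s + 4, e - 4))
                if _near_boundary(tx.chrom, pos, 3):
                    continue
            if not _free(tx.chrom, pos) or _in_any_exon(tx.chrom, pos):
                continue
            ref = genome.sequences[tx.chrom][pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            _emit(tx.chrom, pos, ref, alt, cls, tx.transcript_id)
            return
        raise RuntimeError(f"could not place a {cls} variant")

    spans = [
        (t.chrom, *t.span) for t in annotation.transcripts.values()
    ]

    def _intergenic(cls: str = "intergenic", kept: bool = True,
                    depth=None, qual=None, freq=None) -> None:
        chroms = sorted(genome.sequences)
        for _try in range(5000):
            chrom = str(rng.choice(chroms))
            pos = int(rng.integers(100, genome.lengths[chrom] - 100))
            near = any(
                c == chrom and s - 50 <= pos < e + 50 for c, s, e in spans
            )
            if near or not _free(chrom, pos):
                continue
            ref = genome.sequences[chrom][pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            _emit(chrom, pos, ref, alt, cls, "", kept, depth, qual, freq)
            return
        raise RuntimeError("could not place an intergenic variant")

    for cls in ("synonymous", "missense", "stop_gain", "stop_loss"):
        for _ in range(config.variants_per_class):
            _snv_for_class(cls)
    for _ in range(config.variants_per_class):
        _frameshift()
    for cls in ("splice_site", "intron"):
        for _ in range(config.variants_per_class):
            _splice_or_intron(cls)
    for _ in range(config.variants_per_class):
        _intergenic()
    fails = [
        {"depth": 4, "qual": 500.0, "freq": 0.9},
        {"depth": 30, "qual": 79.0, "freq": 0.9},
        {"depth": 30, "qual": 500.0, "freq": 0.74},
    ]
    for i in range(config.n_subthreshold_variants):
        f = fails[i % 3]
        _intergenic(kept=False, depth=f["depth"], qual=f["qual"],
                    freq=f["freq"])
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# contigs, alignments, hits
# ---------------------------------------------------------------------------


def _blocks_seq(genome: GenomeModel, chrom: str,
                blocks: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(genome.sequences[chrom][s:e] for s, e in sorted(blocks))
    return str(Seq(seq).reverse_complement()) if strand == "-" else seq


def _spliced_interval_blocks(
    exons: list[tuple[int, int]], s: int, e: int
) -> list[tuple[int, int]]:
    """Genome blocks of spliced interval [s, e) over ascending exons."""
    out = []
    acc = 0
    for es, ee in exons:
        ln = ee - es
        lo, hi = max(s, acc), min(e, acc + ln)
        if lo < hi:
            out.append((es + (lo - acc), es + (hi - acc)))
        acc += ln
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, float]:
    if rate <= 0:
        return seq, 1.0
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr), 1.0 - len(hits) / max(1, len(arr))


def _jitter_blocks(rng, blocks, jitter: int):
    if jitter <= 0:
        return blocks
    out = []
    for (qs, qe), (ts, te) in blocks:
        d1 = int(rng.integers(-jitter, jitter + 1))
        d2 = int(rng.integers(-jitter, jitter + 1))
        ts2, te2 = ts + d1, te + d2
        if te2 - ts2 < 20:
            ts2, te2 = ts, te
        out.append(((qs, qe), (ts2, te2)))
    return out


def _single_segment(contig_id, chrom, strand, target_blocks, identity,
                    rng=None, jitter=0) -> SplicedAlignment:
    blocks = []
    q = 0
    for ts, te in sorted(target_blocks):
        blocks.append(((q, q + te - ts), (ts, te)))
        q += te - ts
    if jitter:
        blocks = _jitter_blocks(rng, blocks, jitter)
    return SplicedAlignment(
        contig_id=contig_id,
        chrom=chrom,
        strand=strand,
        blocks=blocks,
        identity=identity,
        query_coverage=1.0,
    )


def simulate_contigs(
    config: SimulationConfig,
    genome: GenomeModel,
    annotation: GenomeAnnotation,
    layout: GenomeLayout,
) -> tuple[
    list[ContigSeq],
    list[SplicedAlignment],
    list[HomologyHit],
    dict[str, float],
    list[tuple[str, str]],
    pd.DataFrame,
]:
    """Contigs of every class, their truth-derived alignments, homology
    hits, per-contig FPKM, and the raw-read pool covering assembly gaps."""
    rng = np.random.default_rng([config.seed, 3])
    err = config.substitution_error_rate
    jit = config.edge_jitter

    contigs: list[ContigSeq] = []
    alignments: list[SplicedAlignment] = []
    hits: list[HomologyHit] = []
    expression: dict[str, float] = {}
    raw_pool: list[tuple[str, str]] = []
    truth: list[dict] = []

    merged_gene_ids = {g for pair in layout.merged_pairs for g in pair}
    pool = [
        gid
        for gid in sorted(annotation.genes)
        if gid not in merged_gene_ids
    ]
    multi3 = [
        gid
        for gid in pool
        if len(annotation.transcripts[f"{gid}.t1"].exons) >= 3
    ]
    identical_genes = pool[: config.n_identical]
    novel_genes = [g for g in multi3 if g not in identical_genes][
        : config.n_novel_isoform
    ]

    def _retainable_introns(gid: str) -> list[int]:
        """Introns whose retained block (exon j + intron + exon j+1) is not
        mostly inside any annotated intron of the gene's isoforms."""
        tx = annotation.transcripts[f"{gid}.t1"]
        all_introns = [
            iv
            for tid in annotation.genes[gid].transcript_ids
            for iv in annotation.transcripts[tid].introns
        ]
        good = []
        for j, (s, e) in enumerate(tx.introns):
            bs, be = tx.exons[j][0], tx.exons[j + 1][1]
            if all(
                max(0, min(be, ie) - max(bs, is_)) <= 0.5 * (be - bs)
                for is_, ie in all_introns
            ):
                good.append(j)
        return good

    pre_genes = [g for g in identical_genes if _retainable_introns(g)][
        : config.n_pre_mrna
    ]
    if len(pre_genes) < config.n_pre_mrna:
        raise ValueError("not enough genes with a retainable intron")

    def _add(cid, seq, cls, locus=None, merged=False, fpkm=5.0):
        contigs.append(ContigSeq(cid, seq))
        expression[cid] = fpkm
        truth.append(
            {
                "contig_id": cid,
                "triage_class": cls,
                "locus_id": locus or "",
                "merged": merged,
            }
        )

    # --- exact isoform copies ------------------------------------------------
    for i, gid in enumerate(identical_genes):
        tx = annotation.transcripts[f"{gid}.t1"]
        seq = _blocks_seq(genome, tx.chrom, tx.exons, tx.strand)
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_ident_{i:03d}"
        _add(cid, seq, "identical_isoform", locus=gid,
             fpkm=float(rng.uniform(50, 80)))
        alignments.append(
            _single_segment(cid, tx.chrom, tx.strand, tx.exons, ident,
                            rng, jit)
        )

    # --- novel isoforms: one intron extended 18 bp into its 5' exon ----------
    for i, gid in enumerate(novel_genes):
        tx = annotation.transcripts[f"{gid}.t1"]
        exons = [list(e) for e in tx.exons]
        k = int(rng.integers(0, len(exons) - 1))
        exons[k][1] -= 18
        blocks = [tuple(e) for e in exons]
        seq = _blocks_seq(genome, tx.chrom, blocks, tx.strand)
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_noviso_{i:03d}"
        _add(cid, seq, "novel_isoform", locus=gid,
             fpkm=float(rng.uniform(15, 30)))
        alignments.append(
            _single_segment(cid, tx.chrom, tx.strand, blocks, ident, rng, jit)
        )

    # --- intron-retaining pre-mRNA fragments (low expression) ---------------
    for i, gid in enumerate(pre_genes):
        tx = annotation.transcripts[f"{gid}.t1"]
        choices = _retainable_introns(gid)
        j = choices[int(rng.integers(0, len(choices)))]
        block = (tx.exons[j][0], tx.exons[j + 1][1])
        seq = _blocks_seq(genome, tx.chrom, [block], tx.strand)
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_premrna_{i:03d}"
        _add(cid, seq, "pre_mrna_filtered", locus=gid,
             fpkm=float(rng.uniform(0.5, 1.5)))
        alignments.append(
            _single_segment(cid, tx.chrom, tx.strand, [block], ident, rng, jit)
        )

    # --- chimeras: two-locus fusions on different chromosomes ---------------
    chrom_of = {gid: annotation.genes[gid].chrom for gid in pool}
    for i in range(config.n_chimera):
        g1 = pool[int(rng.integers(0, len(pool)))]
        others = [g for g in pool if chrom_of[g] != chrom_of[g1]]
        g2 = others[int(rng.integers(0, len(others)))]
        # equal-length pieces keep both segments above the 20% query floor
        piece = min(
            sum(e - s for s, e in annotation.transcripts[f"{g}.t1"].exons)
            for g in (g1, g2)
        ) // 2
        parts = []
        q = 0
        seqs = []
        for seg, gid in enumerate((g1, g2)):
            tx = annotation.transcripts[f"{gid}.t1"]
            tblocks = _spliced_interval_blocks(tx.exons, 0, piece)
            seg_seq = _blocks_seq(genome, tx.chrom, tblocks, "+")
            seqs.append(seg_seq)
            blocks = []
            qq = q
            for ts, te in tblocks:
                blocks.append(((qq, qq + te - ts), (ts, te)))
                qq += te - ts
            parts.append((tx.chrom, blocks, len(seg_seq)))
            q += len(seg_seq)
        full = "".join(seqs)
        full, ident = _mutate(rng, full, err)
        cid = f"ctg_chimera_{i:03d}"
        _add(cid, full, "chimera_excluded")
        total = len(full)
        for seg, (chrom, blocks, seg_len) in enumerate(parts):
            alignments.append(
                SplicedAlignment(
                    contig_id=cid,
                    chrom=chrom,
                    strand="+",
                    blocks=blocks,
                    identity=ident,
                    query_coverage=seg_len / total,
                    segment_group=seg,
                )
            )

    # --- read-throughs over adjacent gene pairs (merged loci) ---------------
    for i, (g1, g2) in enumerate(layout.merged_pairs):
        t1 = annotation.transcripts[f"{g1}.t1"]
        t2 = annotation.transcripts[f"{g2}.t1"]
        blocks = sorted(t1.exons + t2.exons)
        seq = _blocks_seq(genome, t1.chrom, blocks, t1.strand)
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_merged_{i:03d}"
        _add(cid, seq, "novel_isoform",
             locus=f"merged:{'+'.join(sorted((g1, g2)))}", merged=True,
             fpkm=float(rng.uniform(30, 50)))
        alignments.append(
            _single_segment(cid, t1.chrom, t1.strand, blocks, ident, rng, jit)
        )

    # --- novel loci (hidden in the genome, absent from the annotation) ------
    for i, slot in enumerate(layout.novel_coding):
        seq = _blocks_seq(genome, slot["chrom"], slot["exons"], "+")
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_novloc_c{i:03d}"
        _add(cid, seq, "novel_locus", fpkm=float(rng.uniform(5, 20)))
        alignments.append(
            _single_segment(cid, slot["chrom"], "+", slot["exons"], ident,
                            rng, jit)
        )
    for i, slot in enumerate(layout.novel_noncoding):
        s, e = slot["span"]
        seq = genome.sequences[slot["chrom"]][s:e]
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_novloc_n{i:03d}"
        _add(cid, seq, "novel_locus", fpkm=float(rng.uniform(5, 20)))
        alignments.append(
            _single_segment(cid, slot["chrom"], "+", [(s, e)], ident, rng, jit)
        )

    # --- contigs from annotated repeats --------------------------------------
    for i, (chrom, s, e) in enumerate(layout.repeat_slots):
        s2 = s + 200
        e2 = min(e, s2 + 600)
        seq = genome.sequences[chrom][s2:e2]
        seq, ident = _mutate(rng, seq, err)
        cid = f"ctg_repeat_{i:03d}"
        _add(cid, seq, "repeat_region")
        alignments.append(
            _single_segment(cid, chrom, "+", [(s2, e2)], ident, rng, jit)
        )

    # --- unmapped: private genes ---------------------------------------------
    def _coding_construct(n_codons: int) -> str:
        codons = [str(rng.choice(_CODONS)) for _ in range(n_codons)]
        return (
            _random_seq(rng, 15)
            + "ATG"
            + "".join(codons)
            + str(rng.choice(_STOPS))
            + _random_seq(rng, 15)
        )

    def _noncoding_construct(lo=300, hi=500) -> str:
        return _orf_free_seq(rng, int(rng.integers(lo, hi)))

    def _hit(query, subject, db, taxon, bitscore=400.0, evalue=1e-40,
             coverage=0.9):
        hits.append(
            HomologyHit(
                query_id=query,
                subject_id=subject,
                database=db,
                taxon=taxon,
                e_value=evalue,
                identity=0.95,
                query_coverage=coverage,
                bitscore=bitscore,
            )
        )

    private_seqs: list[str] = []
    for i in range(config.n_private):
        cid = f"ctg_private_{i:03d}"
        if i == 1 and private_seqs:
            # member of a sequence-similarity cluster with private_000
            seq, _ = _mutate(rng, private_seqs[0], 0.02)
        elif i < 4:
            seq = _coding_construct(int(rng.integers(120, 220)))
        else:
            seq = _noncoding_construct()
        private_seqs.append(seq)
        _add(cid, seq, "private_candidate")
        if i in (2, 3):
            subject = "VvGI_shared"  # shared best subject -> one cluster
        else:
            subject = f"VvGI_{i:03d}"
        _hit(cid, subject, "vvgi_est", "Viridiplantae")
        if i == 0:
            _hit(cid, f"plantprot_{i:03d}", "plant_protein", "Viridiplantae",
                 bitscore=250.0)
            _hit(cid, f"nrplant_{i:03d}", "nr_protein", "Viridiplantae",
                 bitscore=200.0)

    # --- unmapped: genes missing from the reference assembly ----------------
    for i in range(config.n_assembly_gap):
        cid = f"ctg_gap_{i:03d}"
        coding = i < config.n_assembly_gap // 2
        seq = (
            _coding_construct(int(rng.integers(120, 220)))
            if coding
            else _noncoding_construct()
        )
        cls = "missing_from_assembly_coding" if coding else "missing_from_assembly"
        _add(cid, seq, cls)
        _hit(cid, f"rawread_{i:03d}", "genome_raw_reads", "Viridiplantae")
        if i == 0:
            # also matches VvGI; the raw-read evidence must take precedence
            _hit(cid, "VvGI_decoy", "vvgi_est", "Viridiplantae", bitscore=100.0)
        for t in range(0, max(1, len(seq) - 100) + 1, 50):
            raw_pool.append((f"rawread_{i:03d}_{t}", seq[t : t + 100]))

    # --- unmapped: contaminants ----------------------------------------------
    for i in range(config.n_contaminant):
        cid = f"ctg_contam_{i:03d}"
        seq = _coding_construct(int(rng.integers(100, 200)))
        _add(cid, seq, "contaminant")
        taxon = "Fungi" if i < config.n_contaminant - 1 else "Bacteria"
        _hit(cid, f"contamprot_{i:03d}", "nr_protein", taxon, bitscore=500.0)
        if i == 0:
            # plant-database decoy hit; the non-plant best hit must win
            _hit(cid, "VvGI_contam_decoy", "vvgi_est", "Viridiplantae",
                 bitscore=90.0)

    # --- unmapped: no qualifying evidence ------------------------------------
    for i in range(config.n_no_evidence):
        cid = f"ctg_noev_{i:03d}"
        _add(cid, _noncoding_construct(), "no_evidence")
        # a junk hit failing the significance gate
        _hit(cid, f"junk_{i:03d}", "nr_protein", "Fungi", bitscore=30.0,
             evalue=1e-2, coverage=0.1)

    return (
        contigs,
        alignments,
        hits,
        expression,
        raw_pool,
        pd.DataFrame(truth),
    )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _pattern_means(pattern: int | str, m: float, f: float) -> tuple:
    if pattern == "flat":
        return (m, m, m)
    return {
        1: (m, m / f, m / f),
        2: (m, m / f, m),
        3: (m, m * f, m),
        4: (m, m * f, m * f),
    }[pattern]


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame]:
    """NB counts for 3 stages x 3 replicates with planted profiles.

    The first ``n_per_pattern`` features carry pattern 1, the next pattern
    2, and so on; the remainder are flat.  Pattern fold changes multiply or
    divide the base mean by ``fold_change``.
    """
    rng = np.random.default_rng([config.seed, 4])
    stages = ("PFS", "PR", "PHWII")
    samples = [f"{st}_{r + 1}" for st in stages for r in range(3)]
    stage_of = {s: s.rsplit("_", 1)[0] for s in samples}
    rep_of = {s: int(s.rsplit("_", 1)[1]) for s in samples}

    patterns: list[int | str] = []
    for p in (1, 2, 3, 4):
        patterns.extend([p] * config.n_per_pattern)
    patterns.extend(["flat"] * (config.n_features - len(patterns)))

    disp = config.nb_dispersion
    n_param = 1.0 / disp
    rows = []
    for pattern in patterns:
        means = _pattern_means(pattern, config.nb_mean, config.fold_change)
        row = []
        for st_i in range(3):
            mu = means[st_i]
            p_param = n_param / (n_param + mu)
            row.extend(rng.negative_binomial(n_param, p_param, size=3))
        rows.append(row)
    features = [f"feat_{i:04d}" for i in range(config.n_features)]
    counts = pd.DataFrame(rows, index=features, columns=samples, dtype=int)
    table = CountTable(counts=counts, stages=stage_of, replicates=rep_of)
    profile_truth = pd.DataFrame(
        {"feature_id": features, "pattern": [str(p) for p in patterns]}
    )
    return table, profile_truth


def _make_term_map(
    config: SimulationConfig, profile_truth: pd.DataFrame,
    rng: np.random.Generator
) -> dict[str, set[str]]:
    term_map: dict[str, set[str]] = {}
    for fid, pattern in zip(profile_truth["feature_id"],
                            profile_truth["pattern"]):
        term = f"term_pattern{pattern}" if pattern != "flat" else "term_flat"
        if rng.random() < 0.8:
            term_map.setdefault(fid, set()).add(term)
        if rng.random() < 0.05:
            term_map.setdefault(fid, set()).add("term_background")
    return term_map


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    genome, annotation, layout = generate_genome_and_annotation(config)
    variants, variant_truth = plant_variants(config, genome, annotation)
    (
        contigs,
        alignments,
        hits,
        expression,
        raw_pool,
        contig_truth,
    ) = simulate_contigs(config, genome, annotation, layout)
    counts, profile_truth = simulate_counts(config)
    rng = np.random.default_rng([config.seed, 5])
    term_map = _make_term_map(config, profile_truth, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        annotation=annotation,
        layout=layout,
        variants=variants,
        variant_truth=variant_truth,
        contigs=contigs,
        alignments=alignments,
        hits=hits,
        expression=expression,
        raw_read_pool=raw_pool,
        contig_truth=contig_truth,
        counts=counts,
        profile_truth=profile_truth,
        term_map=term_map,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every dataset component plus truth tables; returns the paths."""
    from pathlib import Path

    from . import formats_io as fio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "annotation.gff3",
        "variants": out / "variants.vcf",
        "contigs": out / "contigs.fasta",
        "alignments": out / "alignments.bed",
        "hits": out / "hits.tsv",
        "expression": out / "expression.tsv",
        "counts": out / "counts.tsv",
        "stages": out / "stages.tsv",
        "raw_reads": out / "raw_read_pool.fasta",
        "term_map": out / "gene_terms.tsv",
        "truth_contigs": out / "truth_contigs.tsv",
        "truth_variants": out / "truth_variants.tsv",
        "truth_profiles": out / "truth_profiles.tsv",
    }
    fio.write_fasta(ds.genome, paths["genome"])
    fio.write_gff3(ds.annotation, paths["annotation"])
    fio.write_vcf(ds.variants, paths["variants"], ds.genome.lengths)
    fio.write_fasta(ds.contigs, paths["contigs"])
    fio.write_bed12(ds.alignments, paths["alignments"])
    fio.write_homology_tab(
        ds.hits, paths["hits"],
        query_lengths={c.contig_id: c.length for c in ds.contigs},
    )
    fio.write_expression_tsv(ds.expression, paths["expression"])
    fio.write_counts(ds.counts, paths["counts"], paths["stages"])
    fio.write_fasta(ds.raw_read_pool, paths["raw_reads"])
    with open(paths["term_map"], "w") as fh:
        for gene in sorted(ds.term_map):
            for term in sorted(ds.term_map[gene]):
                fh.write(f"{gene}\t{term}\n")
    ds.contig_truth.to_csv(paths["truth_contigs"], sep="\t", index=False)
    ds.variant_truth.to_csv(paths["truth_variants"], sep="\t", index=False)
    ds.profile_truth.to_csv(paths["truth_profiles"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
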