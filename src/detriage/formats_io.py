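"""Domain types and readers/writers for every external format.

Single home for the coordinate convention: everything in memory is 0-based,
half-open.  GFF3 and VCF are converted at the I/O boundary (both are 1-based
on disk); BED12 is already 0-based half-open.  Writers restore each format's
native convention so that read∘write round-trips are the identity.

The BED12 dialect used for spliced contig-to-genome alignments carries two
extension columns (13: alignment identity, 14: query coverage, both as
fractions) because standard BED12 has no slot for them.  A contig whose
alignment splits into several segments (a chimera candidate) occupies several
BED12 lines sharing the same name; segment groups are numbered in file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_DATABASES = frozenset(
    {
        "nr_protein",
        "vvgi_est",
        "plant_protein",
        "genome_raw_reads",
        "transposon_protein",
        "rfam",
        "est",
        "cdna",
    }
)

_ALPHABET = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """A reference genome: chromosome id -> uppercase A/C/G/T/N sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"chrom {chrom!r}: invalid characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class TranscriptModel:
    """A transcript's exon/CDS structure on a chromosome.

    ``exons`` are sorted, non-overlapping, half-open 0-based genome
    intervals.  ``cds_span`` (when present) is a single half-open genome
    interval contained in the exon union; the spliced CDS is the exon
    sequence intersected with it, reverse-complemented for minus-strand
    transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon interval ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ValueError(f"{self.transcript_id}: CDS outside exon union")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def cds_exons(self) -> list[tuple[int, int]]:
        """Exon pieces inside the CDS span, in genomic order."""
        if self.cds_span is None:
            return []
        cs, ce = self.cds_span
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, cs), min(e, ce)
            if s2 < e2:
                out.append((s2, e2))
        return out


@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """Gene loci, transcript models and annotated repeats for one genome."""

    genes: dict[str, GeneLocus]
    transcripts: dict[str, TranscriptModel]
    repeats: list[tuple[str, int, int]] = field(default_factory=list)

    def transcripts_of(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    @property
    def chroms(self) -> set[str]:
        return {t.chrom for t in self.transcripts.values()} | {
            c for c, _, _ in self.repeats
        }


@dataclass
class ContigSeq:
    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError(f"{self.contig_id}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"{self.contig_id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SplicedAlignment:
    """One alignment segment of a contig on the genome.

    ``blocks`` pairs half-open query intervals with half-open target
    intervals; target blocks are sorted and non-overlapping.  A chimeric
    contig carries several SplicedAlignment records with distinct
    ``segment_group`` tags.  ``strand`` may be '.' for unstranded
    alignments (flagged, tolerated downstream).
    """

    contig_id: str
    chrom: str
    strand: str
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    identity: float
    query_coverage: float
    segment_group: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.contig_id}: strand must be +, - or .")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError(f"{self.contig_id}: identity/coverage outside [0,1]")
        prev = -1
        for (_qs, _qe), (ts, te) in self.blocks:
            if ts < prev or ts >= te:
                raise ValueError(
                    f"{self.contig_id}: target blocks must be sorted, non-overlapping"
                )
            prev = te

    @property
    def target_blocks(self) -> list[tuple[int, int]]:
        return [t for _q, t in self.blocks]

    @property
    def target_span(self) -> tuple[int, int]:
        return (self.blocks[0][1][0], self.blocks[-1][1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Target gaps between consecutive blocks (the intron chain)."""
        tb = self.target_blocks
        return [(tb[i][1], tb[i + 1][0]) for i in range(len(tb) - 1)]


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    qual: float
    alt_frequency: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.depth < 0:
            raise ValueError("negative read depth")
        if not (0.0 <= self.alt_frequency <= 1.0):
            raise ValueError("alt_frequency outside [0,1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    database: str
    taxon: str
    e_value: float
    identity: float
    query_coverage: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.database not in VALID_DATABASES:
            raise ValueError(
                f"unknown database label {self.database!r}; "
                f"allowed: {sorted(VALID_DATABASES)}"
            )
        if self.e_value < 0:
            raise ValueError("negative e-value")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError("identity/coverage outside [0,1]")


@dataclass
class CountTable:
    """Per-feature, per-sample fragment counts with stage metadata.

    ``counts`` is a features x samples integer DataFrame; every sample has a
    stage label (PFS / PR / PHWII for the berry design) and a replicate
    index.
    """

    counts: pd.DataFrame
    stages: dict[str, str]
    replicates: dict[str, int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.stages)
        if missing:
            raise ValueError(f"samples without stage label: {sorted(missing)}")

    def samples_of(self, stage: str) -> list[str]:
        return [s for s in self.counts.columns if self.stages[s] == stage]


@dataclass
class ParseReport:
    """Accounting for a parse: nothing is dropped silently."""

    n_read: int = 0
    n_kept: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _read_fasta_records(path) -> list[tuple[str, str]]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        records.append((rec.id, seq))
    return records


def read_genome_fasta(path) -> GenomeModel:
    return GenomeModel(dict(_read_fasta_records(path)))


def read_contig_fasta(path) -> list[ContigSeq]:
    return [ContigSeq(i, s) for i, s in _read_fasta_records(path)]


def write_fasta(records, path, width: int = 60) -> None:
    """Write (id, sequence) pairs, ContigSeqs, or a GenomeModel."""
    if isinstance(records, GenomeModel):
        records = list(records.sequences.items())
    pairs = [
        (r.contig_id, r.sequence) if isinstance(r, ContigSeq) else tuple(r)
        for r in records
    ]
    with open(path, "w") as fh:
        for name, seq in pairs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _gff_attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path, genome: GenomeModel | None = None) -> GenomeAnnotation:
    """Parse gene/mRNA/exon/CDS (and repeat_region) features.

    GFF3's 1-based closed coordinates become 0-based half-open.  An exon or
    CDS whose Parent is not a declared transcript is an error, as is a
    feature extending past its chromosome end when a genome is supplied.
    """
    genes_raw: dict[str, tuple[str, str, int, int]] = {}
    tx_raw: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int, str]]] = {}
    repeats: list[tuple[str, int, int]] = []
    deferred: list[tuple[str, str, int, int, str]] = []

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start1, end1, _score, strand, phase, attrs = f[:9]
            start, end = int(start1) - 1, int(end1)
            if start < 0 or start >= end:
                raise ValueError(f"out-of-range interval in GFF3: {line!r}")
            if genome is not None:
                if chrom not in genome or end > genome.lengths[chrom]:
                    raise ValueError(
                        f"feature beyond chromosome bounds: {chrom}:{start}-{end}"
                    )
            a = _gff_attrs(attrs)
            if ftype == "gene":
                genes_raw[a["ID"]] = (chrom, strand, start, end)
            elif ftype in _TRANSCRIPT_TYPES:
                tx_raw[a["ID"]] = {
                    "gene": a.get("Parent", a["ID"]),
                    "chrom": chrom,
                    "strand": strand,
                }
            elif ftype in {"exon", "CDS"}:
                deferred.append((ftype, a.get("Parent", ""), start, end, phase))
            elif ftype == "repeat_region":
                repeats.append((chrom, start, end))

    for ftype, parent, start, end, phase in deferred:
        if parent not in tx_raw:
            raise ValueError(f"{ftype} with Parent {parent!r} lacks an mRNA parent")
        if ftype == "exon":
            exons.setdefault(parent, []).append((start, end))
        else:
            cds.setdefault(parent, []).append((start, end, phase))

    transcripts: dict[str, TranscriptModel] = {}
    genes: dict[str, GeneLocus] = {}
    for tid, info in tx_raw.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise ValueError(f"transcript {tid} has no exons")
        cspan = None
        phase = 0
        if tid in cds:
            pieces = sorted(cds[tid])
            cspan = (pieces[0][0], pieces[-1][1])
            first = pieces[-1] if info["strand"] == "-" else pieces[0]
            phase = int(first[2]) if first[2] not in {".", ""} else 0
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=info["gene"],
            chrom=info["chrom"],
            strand=info["strand"],
            exons=ex,
            cds_span=cspan,
            phase=phase,
        )
        # every declared CDS piece must lie inside the exon union
        if tid in cds:
            for cs, ce, _ph in cds[tid]:
                inside = sum(
                    max(0, min(e, ce) - max(s, cs)) for s, e in ex
                )
                if inside != ce - cs:
                    raise ValueError(f"transcript {tid}: CDS outside exon union")

    for tid, tx in transcripts.items():
        gid = tx.gene_id
        if gid not in genes:
            chrom, strand, gs, ge = genes_raw.get(
                gid, (tx.chrom, tx.strand, tx.span[0], tx.span[1])
            )
            genes[gid] = GeneLocus(gid, chrom, strand, (gs, ge), [])
        genes[gid].transcript_ids.append(tid)

    # span = union hull of member transcripts
    for g in genes.values():
        spans = [transcripts[t].span for t in g.transcript_ids]
        g.span = (min(s for s, _ in spans), max(e for _, e in spans))
    return GenomeAnnotation(genes=genes, transcripts=transcripts, repeats=repeats)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            fh.write(
                f"{g.chrom}\tdetriage\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            for tid in sorted(g.transcript_ids):
                tx = annotation.transcripts[tid]
                fh.write(
                    f"{tx.chrom}\tdetriage\tmRNA\t{tx.span[0] + 1}\t{tx.span[1]}\t.\t"
                    f"{tx.strand}\t.\tID={tid};Parent={gid}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{tx.chrom}\tdetriage\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t"
                        f".\tParent={tid}\n"
                    )
                if tx.cds_span is not None:
                    for i, (s, e) in enumerate(tx.cds_exons()):
                        ph = tx.phase if i == 0 else "."
                        fh.write(
                            f"{tx.chrom}\tdetriage\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{tx.strand}\t{ph}\tParent={tid}\n"
                        )
        for chrom, s, e in annotation.repeats:
            fh.write(
                f"{chrom}\tdetriage\trepeat_region\t{s + 1}\t{e}\t.\t.\t.\t"
                f"ID=repeat_{chrom}_{s}\n"
            )


# ---------------------------------------------------------------------------
# BED12 (+2 extension columns)
# ---------------------------------------------------------------------------


def read_bed12(path) -> list[SplicedAlignment]:
    alignments: list[SplicedAlignment] = []
    seg_counter: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line with <12 columns: {line!r}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(
                    f"blockSizes/blockStarts length mismatch for {name!r}"
                )
            identity = float(f[12]) if len(f) > 12 else 1.0
            coverage = float(f[13]) if len(f) > 13 else 1.0
            blocks = []
            q = 0
            for size, rel in zip(sizes, starts):
                ts = chrom_start + rel
                blocks.append(((q, q + size), (ts, ts + size)))
                q += size
            group = seg_counter.get(name, 0)
            seg_counter[name] = group + 1
            alignments.append(
                SplicedAlignment(
                    contig_id=name,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    identity=identity,
                    query_coverage=coverage,
                    segment_group=group,
                )
            )
    return alignments


def write_bed12(alignments: list[SplicedAlignment], path) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            tb = aln.target_blocks
            chrom_start, chrom_end = tb[0][0], tb[-1][1]
            sizes = ",".join(str(e - s) for s, e in tb)
            rel = ",".join(str(s - chrom_start) for s, _ in tb)
            fh.write(
                "\t".join(
                    [
                        aln.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        aln.contig_id,
                        "0",
                        aln.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(tb)),
                        sizes,
                        rel,
                        f"{aln.identity:.6g}",
                        f"{aln.query_coverage:.6g}",
                    ]
                )
                + "\n"
            )


def group_alignments(
    alignments: list[SplicedAlignment],
) -> dict[str, list[SplicedAlignment]]:
    """All alignment segments per contig, in segment_group order."""
    by_contig: dict[str, list[SplicedAlignment]] = {}
    for aln in alignments:
        by_contig.setdefault(aln.contig_id, []).append(aln)
    for segs in by_contig.values():
        segs.sort(key=lambda a: a.segment_group)
    return by_contig


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> tuple[list[VariantRecord], ParseReport]:
    """Read VCF 4.x; POS becomes 0-based; multi-allelic rows are split.

    The alternative-allele frequency comes from INFO/AF when present, else
    from AO/(AO+RO); a row with neither DP nor AO/RO support is excluded
    with a warning and counted in the report.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    report = ParseReport()

    def _per_alt(value, i, n_alt):
        if value is None:
            return None
        if isinstance(value, (tuple, list, np.ndarray)):
            seq = list(value)
            return seq[i] if len(seq) == n_alt else seq[0]
        return value

    for v in VCF(str(path)):
        alts = v.ALT
        for i, alt in enumerate(alts):
            report.n_read += 1
            dp = v.INFO.get("DP")
            af = _per_alt(v.INFO.get("AF"), i, len(alts))
            ao = _per_alt(v.INFO.get("AO"), i, len(alts))
            ro = v.INFO.get("RO")
            if af is None:
                if ao is not None and ro is not None and (ao + ro) > 0:
                    af = float(ao) / (float(ao) + float(ro))
                    if dp is None:
                        dp = int(ao) + int(ro)
                else:
                    report.rejected.append(
                        (f"{v.CHROM}:{v.POS}:{alt}", "no AF and no AO/RO")
                    )
                    warnings.warn(
                        f"variant {v.CHROM}:{v.POS} alt {alt}: "
                        "missing DP and AO/RO, excluded",
                        stacklevel=2,
                    )
                    continue
            if dp is None:
                report.rejected.append((f"{v.CHROM}:{v.POS}:{alt}", "no DP"))
                warnings.warn(
                    f"variant {v.CHROM}:{v.POS} alt {alt}: missing DP, excluded",
                    stacklevel=2,
                )
                continue
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS - 1,
                    ref=v.REF,
                    alt=alt,
                    depth=int(dp),
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    # AF is stored float32 in the BCF representation
                    alt_frequency=round(float(af), 6),
                )
            )
            report.n_kept += 1
    return records, report


def write_vcf(records: list[VariantRecord], path, contigs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.qual:.6g}\t.\t"
                f"DP={r.depth};AF={r.alt_frequency:.6g}\n"
            )


# ---------------------------------------------------------------------------
# tabular: homology hits, counts, expression, gene->term map
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "database",
    "taxon",
]


def read_homology_tab(path) -> list[HomologyHit]:
    """12-column tabular hit format plus database (13) and taxon (14).

    Percent identity is divided by 100; query coverage is derived from the
    aligned query span when the file does not carry it explicitly (the
    qstart/qend columns are 1-based inclusive, and the query length is taken
    from an optional 15th column when present, else coverage falls back to
    the aligned fraction of the reported HSP length).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 14:
        raise ValueError("homology table needs >=14 columns (12 + database + taxon)")
    hits = []
    for row in df.itertuples(index=False):
        r = list(row)
        qlen = float(r[14]) if len(r) > 14 and not pd.isna(r[14]) else None
        span = abs(float(r[7]) - float(r[6])) + 1
        coverage = min(1.0, span / qlen) if qlen else min(1.0, span / float(r[3]))
        hits.append(
            HomologyHit(
                query_id=str(r[0]),
                subject_id=str(r[1]),
                database=str(r[12]),
                taxon=str(r[13]),
                e_value=float(r[10]),
                identity=float(r[2]) / 100.0,
                query_coverage=coverage,
                bitscore=float(r[11]),
            )
        )
    return hits


def write_homology_tab(hits: list[HomologyHit], path, query_lengths=None) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qlen = (query_lengths or {}).get(h.query_id)
            if qlen:
                span = max(1, round(h.query_coverage * qlen))
                qstart, qend = 1, span
            else:
                qlen, qstart, qend = "", 1, max(1, round(h.query_coverage * 100))
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100:.2f}",
                        qend - qstart + 1,
                        0,
                        0,
                        qstart,
                        qend,
                        1,
                        qend - qstart + 1,
                        f"{h.e_value:.3g}",
                        f"{h.bitscore:.1f}",
                        h.database,
                        h.taxon,
                        qlen,
                    ]
                )
                + "\n"
            )


def read_counts(counts_path, stages_path) -> CountTable:
    """Counts TSV (feature rows x sample columns) + sidecar stage map.

    The stage map has columns sample_id, stage, replicate.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    df = df.astype(int)
    meta = pd.read_csv(stages_path, sep="\t")
    stages = dict(zip(meta["sample_id"], meta["stage"]))
    reps = dict(zip(meta["sample_id"], meta["replicate"].astype(int)))
    return CountTable(counts=df, stages=stages, replicates=reps)


def write_counts(table: CountTable, counts_path, stages_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
    with open(stages_path, "w") as fh:
        fh.write("sample_id\tstage\treplicate\n")
        for s in table.counts.columns:
            fh.write(f"{s}\t{table.stages[s]}\t{table.replicates[s]}\n")


def read_gene_term_map(path) -> dict[str, set[str]]:
    """TSV with columns gene_id, term_id (one pair per line)."""
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"])
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(g), set()).add(str(t))
    return out


def read_expression_tsv(path) -> dict[str, float]:
    """Per-contig FPKM table (contig_id, fpkm)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig_id", "fpkm"])
    return dict(zip(df["contig_id"].astype(str), df["fpkm"].astype(float)))


def write_expression_tsv(expression: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(expression):
            fh.write(f"{cid}\t{expression[cid]:.6g}\n")
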