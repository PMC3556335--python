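"""Orchestration of the full triage chain over files on disk.

Each stage consumes the standard formats, writes TSV summary tables, and
contributes counts to a RunReport whose stage in/out accounting must always
add up.  Every threshold default is the field-standard value documented in
docs/methods.md, so a bare run needs no configuration.
"""

from __future__ import annotations

import json
import time
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__, formats_io as fio
from .alignment_summaries import classify_covered_bases, coverage_from_alignments
from .contig_triage import triage_contigs
from .expression_profiles import (
    assign_profile_cluster,
    compute_fpkm,
    enrich_terms,
    is_expressed,
    nb_test,
)
from .novel_and_private import cluster_private, triage_unmapped_all
from .variant_effects import (
    annotate_variants,
    filter_variants,
    region_counts,
    summarize_gene_impact,
)


@dataclass
class PipelineConfig:
    """All thresholds of the chain with their documented defaults."""

    # variant filters
    min_depth: int = 5
    min_qual: float = 80.0
    min_alt_freq: float = 0.75
    splice_window: int = 2
    # alignment gates
    min_identity: float = 0.90
    min_coverage: float = 0.90
    fmi_threshold: float = 0.05
    # coverage classes
    coverage_min_depth: int = 3
    # homology-hit gate
    max_e_value: float = 1e-5
    min_hit_coverage: float = 0.20
    # differential expression
    fdr: float = 0.05
    min_lfc: float = 1.0
    # inputs
    genome: str | None = None
    gff3: str | None = None
    vcf: str | None = None
    contigs: str | None = None
    alignments: str | None = None
    hits: str | None = None
    expression: str | None = None
    counts: str | None = None
    stages: str | None = None
    term_map: str | None = None
    outdir: str = "triage_out"

    def validate(self) -> None:
        for name in ("min_identity", "min_coverage", "fmi_threshold",
                     "min_alt_freq", "min_hit_coverage", "fdr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_depth < 0 or self.coverage_min_depth < 0:
            raise ValueError("depth thresholds must be >= 0")


@dataclass
class RunReport:
    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> {n_in, n_out, secs}
    tables: dict = field(default_factory=dict)  # name -> {category: count}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _require(config: PipelineConfig, stage: str, *names: str) -> None:
    for name in names:
        path = getattr(config, name)
        if path is None:
            raise StageError(stage, ValueError(f"missing input --{name}"))
        if not Path(path).exists():
            raise StageError(stage, FileNotFoundError(path))


def run_variants_stage(config: PipelineConfig, report: RunReport,
                       outdir: Path) -> None:
    _require(config, "variants", "vcf", "gff3", "genome")
    t0 = time.time()
    genome = fio.read_genome_fasta(config.genome)
    annotation = fio.read_gff3(config.gff3)
    variants, parse = fio.read_vcf(config.vcf)
    kept, rejected = filter_variants(
        variants, config.min_depth, config.min_qual, config.min_alt_freq
    )
    effects = annotate_variants(kept, annotation, genome, config.splice_window)
    summaries, impact_counts = summarize_gene_impact(effects, annotation)
    regions = region_counts(kept, annotation, config.splice_window)
    with open(outdir / "variant_effects.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\ttranscript_id\tregion\tconsequence\n")
        for e in effects:
            v = e.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{e.transcript_id}\t"
                f"{e.region}\t{e.consequence}\n"
            )
    with open(outdir / "gene_impact.tsv", "w") as fh:
        fh.write("gene_id\timpact\n")
        for s in summaries:
            fh.write(f"{s.gene_id}\t{s.impact}\n")
    report.stages["variants"] = {
        "n_in": parse.n_read,
        "n_kept": len(kept),
        "n_rejected": len(rejected) + parse.n_rejected,
        "secs": round(time.time() - t0, 3),
    }
    report.tables["variant_regions"] = dict(regions)
    report.tables["gene_impact"] = dict(impact_counts)


def run_coverage_stage(config: PipelineConfig, report: RunReport,
                       outdir: Path) -> None:
    _require(config, "coverage", "alignments", "gff3", "genome")
    t0 = time.time()
    genome = fio.read_genome_fasta(config.genome)
    annotation = fio.read_gff3(config.gff3)
    alignments = fio.read_bed12(config.alignments)
    track = coverage_from_alignments(alignments, genome)
    summary = classify_covered_bases(track, annotation, config.coverage_min_depth)
    with open(outdir / "coverage_classes.tsv", "w") as fh:
        fh.write("class\tbases\tfraction\n")
        for cls, n in summary.counts.items():
            fh.write(f"{cls}\t{n}\t{summary.fractions[cls]:.6g}\n")
    report.stages["coverage"] = {
        "n_in": len(alignments),
        "n_out": summary.total_covered,
        "secs": round(time.time() - t0, 3),
    }
    report.tables["coverage_classes"] = dict(summary.counts)


def run_contigs_stage(config: PipelineConfig, report: RunReport,
                      outdir: Path) -> list:
    _require(config, "contigs", "contigs", "alignments", "gff3", "expression")
    t0 = time.time()
    contigs = fio.read_contig_fasta(config.contigs)
    annotation = fio.read_gff3(config.gff3)
    alignments = fio.read_bed12(config.alignments)
    expression = fio.read_expression_tsv(config.expression)
    calls, merged_report, novel_loci = triage_contigs(
        alignments,
        annotation,
        expression,
        all_contig_ids=[c.contig_id for c in contigs],
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        fmi_threshold=config.fmi_threshold,
    )
    with open(outdir / "triage_calls.tsv", "w") as fh:
        fh.write("contig_id\tclass\tlocus_id\tmerged\n")
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.triage_class}\t{c.locus_id or ''}\t"
                f"{int(c.merged)}\n"
            )
    with open(outdir / "merged_loci.tsv", "w") as fh:
        fh.write("locus_id\tgenes\tcontig_id\n")
        for row in merged_report:
            fh.write(f"{row['locus_id']}\t{','.join(row['genes'])}\t"
                     f"{row['contig_id']}\n")
    with open(outdir / "novel_loci.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in novel_loci:
            fh.write(
                f"{locus.chrom}\tdetriage\tgene\t{locus.span[0] + 1}\t"
                f"{locus.span[1]}\t.\t.\t.\tID={locus.locus_id};"
                f"members={','.join(locus.members)}\n"
            )
    counts = Counter(c.triage_class for c in calls)
    if sum(counts.values()) != len(calls):  # pragma: no cover
        raise StageError("contigs", AssertionError("class counts do not sum"))
    report.stages["contigs"] = {
        "n_in": len(contigs),
        "n_out": len(calls),
        "secs": round(time.time() - t0, 3),
    }
    report.tables["triage_classes"] = dict(counts)
    return calls


def run_unmapped_stage(config: PipelineConfig, report: RunReport,
                       outdir: Path, unmapped_ids: set[str] | None = None) -> None:
    _require(config, "unmapped", "contigs", "hits")
    t0 = time.time()
    contigs = fio.read_contig_fasta(config.contigs)
    if unmapped_ids is not None:
        contigs = [c for c in contigs if c.contig_id in unmapped_ids]
    from .novel_and_private import filter_hits

    hits = filter_hits(
        fio.read_homology_tab(config.hits),
        max_e_value=config.max_e_value,
        min_query_coverage=config.min_hit_coverage,
    )
    calls = triage_unmapped_all(contigs, hits, prefilter=False)
    candidates = [
        c for c in contigs
        if any(u.contig_id == c.contig_id and u.cls == "private_candidate"
               for u in calls)
    ]
    clusters = cluster_private(candidates, hits)
    with open(outdir / "unmapped_calls.tsv", "w") as fh:
        fh.write("contig_id\tclass\tsupport\n")
        for u in calls:
            fh.write(f"{u.contig_id}\t{u.cls}\t{u.support or ''}\n")
    with open(outdir / "private_clusters.tsv", "w") as fh:
        fh.write("cluster_id\trepresentative\tcoding\tmembers\n")
        for cl in clusters:
            fh.write(
                f"{cl.cluster_id}\t{cl.representative}\t{int(cl.coding)}\t"
                f"{','.join(cl.members)}\n"
            )
    report.stages["unmapped"] = {
        "n_in": len(contigs),
        "n_out": len(calls),
        "secs": round(time.time() - t0, 3),
    }
    report.tables["unmapped_classes"] = dict(Counter(u.cls for u in calls))
    report.tables["private_clusters"] = {"n_clusters": len(clusters)}


def run_express_stage(config: PipelineConfig, report: RunReport,
                      outdir: Path) -> None:
    _require(config, "express", "counts", "stages")
    t0 = time.time()
    table = fio.read_counts(config.counts, config.stages)
    lengths = {str(f): 1000 for f in table.counts.index}
    records = compute_fpkm(table, lengths)
    expressed = {
        r.feature_id for r in records if is_expressed(r)
    }
    de1 = nb_test(table, "PFS", "PR")
    de2 = nb_test(table, "PR", "PHWII")
    clusters = assign_profile_cluster(de1, de2, config.fdr, config.min_lfc)
    for name, de in (("PFS_PR", de1), ("PR_PHWII", de2)):
        with open(outdir / f"de_{name}.tsv", "w") as fh:
            fh.write("feature_id\tlog2_fc\tmoderated_log2_fc\tp\tp_adj\n")
            for r in de:
                fh.write(
                    f"{r.feature_id}\t{r.log2_fc:.4f}\t"
                    f"{r.moderated_log2_fc:.4f}\t{r.p_value:.4g}\t"
                    f"{r.p_adjusted:.4g}\n"
                )
    with open(outdir / "profile_clusters.tsv", "w") as fh:
        fh.write("feature_id\tcluster\n")
        for fid in sorted(clusters):
            fh.write(f"{fid}\t{clusters[fid] or ''}\n")
    cluster_counts = Counter(v for v in clusters.values() if v is not None)
    if config.term_map and Path(config.term_map).exists():
        term_map = fio.read_gene_term_map(config.term_map)
        universe = {str(f) for f in table.counts.index}
        groups = {
            f"cluster_{k}": {f for f, v in clusters.items() if v == k}
            for k in (1, 2, 3, 4)
        }
        enrich = enrich_terms(groups, term_map, universe)
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("group\tterm_id\toverlap\tgroup_size\tterm_size\tp\tp_adj\n")
            for e in enrich:
                fh.write(
                    f"{e.group}\t{e.term_id}\t{e.overlap}\t{e.group_size}\t"
                    f"{e.term_size}\t{e.p_value:.4g}\t{e.p_adjusted:.4g}\n"
                )
    report.stages["express"] = {
        "n_in": int(table.counts.shape[0]),
        "n_expressed": len(expressed),
        "secs": round(time.time() - t0, 3),
    }
    report.tables["profile_clusters"] = {
        str(k): v for k, v in sorted(cluster_counts.items())
    }


_STAGE_RUNNERS = {
    "variants": run_variants_stage,
    "coverage": run_coverage_stage,
    "contigs": run_contigs_stage,
    "unmapped": run_unmapped_stage,
    "express": run_express_stage,
}


def run_pipeline(config: PipelineConfig,
                 stages: list[str] | None = None) -> RunReport:
    """Execute the stages in analysis order, failing fast with the stage named.

    The unmapped stage automatically restricts itself to the contigs the
    triage stage left unmapped when both stages run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: v for k, v in asdict(config).items()})
    order = stages or ["variants", "coverage", "contigs", "unmapped", "express"]
    unmapped_ids: set[str] | None = None
    for stage in order:
        runner = _STAGE_RUNNERS[stage]
        try:
            if stage == "contigs":
                calls = runner(config, report, outdir)
                unmapped_ids = {
                    c.contig_id for c in calls if c.triage_class == "unmapped"
                }
            elif stage == "unmapped":
                runner(config, report, outdir, unmapped_ids)
            else:
                runner(config, report, outdir)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
    report.to_json(outdir / "run_report.json")
    return report
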