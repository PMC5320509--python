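"""End-to-end orchestration: mask -> filter -> detect -> catalogue ->
quantify -> test -> integrate -> motifs, with a machine-readable report.

`run_memory` drives the whole flow on in-memory objects (what the tests
and the synthetic generator use); `run_all` is the file-based variant
behind the command line, resumable from its on-disk stage outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation_integration as integ
from .erna_identification import (
    ERNARecord,
    detect_candidates,
    filter_by_h3k27ac,
    funnel_counts,
    merge_candidates,
)
from .io_model import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    PWMotif,
    read_alignments,
    read_bed,
    read_gtf,
    read_jaspar,
    write_bed,
    write_reads_bed,
)
from .motif_enrichment import enrich_motifs, gc_summary
from .peak_calling import PeakCallParams, estimate_shift
from .quantify_diff import count_reads, differential_test
from .read_filtering import build_genic_mask, filter_reads

logger = logging.getLogger("ernakit")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineParams:
    """All stage parameters, defaulting to the published settings."""

    up_ext: int = 3000
    down_ext: int = 10000
    p_threshold: float = 1e-4
    effective_genome_size: float | None = None  # None: sum of chrom sizes
    window: int = 200
    gap: int = 600
    e_value: float = 1000.0
    fdr: float = 1e-2
    effective_genome_fraction: float = 0.77
    n_resamples: int = 100
    alpha: float = 0.05
    motif_p_threshold: float = 1e-4
    seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineResult:
    records: list[ERNARecord]
    counts: pd.DataFrame
    diff: pd.DataFrame
    report: dict
    motif_table: pd.DataFrame | None = None

    def catalogue_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "erna_id": r.erna_id,
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "detected_in": ",".join(sorted(r.detected_in)),
                    "h3k27ac_support": ",".join(sorted(r.h3k27ac_support)),
                    "base_mean": r.base_mean,
                    "log2fc": r.log2fc,
                    "pvalue": r.pvalue,
                    "padj": r.padj,
                    "status": r.status,
                    "gene_id": r.gene_id,
                    "is_super_enhancer": r.is_super_enhancer,
                    "rnapii_wt": r.rnapii_wt,
                    "rnapii_hd": r.rnapii_hd,
                }
            )
        return pd.DataFrame(rows)


def _pool(reads_by_sample, condition_of, condition):
    pooled = []
    for sample, reads in reads_by_sample.items():
        if condition_of[sample] == condition:
            pooled.extend(reads)
    return pooled


def run_memory(
    genes: Sequence[GeneModel],
    reads_by_sample: Mapping[str, Sequence],
    condition_of: Mapping[str, str],
    islands_by_condition: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
    params: PipelineParams | None = None,
    rnapii_by_condition: Mapping[str, Sequence[GenomicInterval]] | None = None,
    super_enhancers: Sequence[GenomicInterval] | None = None,
    genome=None,
    motifs: Sequence[PWMotif] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs; returns the catalogue,
    count matrix, differential table and a report dict."""
    params = params or PipelineParams()
    t0 = time.time()
    timings: dict[str, float] = {}
    conditions = sorted(set(condition_of.values()))

    mask = build_genic_mask(
        genes, up_ext=params.up_ext, down_ext=params.down_ext,
        chrom_sizes=chrom_sizes,
    )
    filtered: dict[str, list] = {}
    filter_reports = {}
    for sample, reads in reads_by_sample.items():
        kept, rep = filter_reads(reads, mask)
        filtered[sample] = kept
        filter_reports[sample] = rep.as_dict()
    timings["filter"] = time.time() - t0

    t1 = time.time()
    all_filtered = [r for kept in filtered.values() for r in kept]
    shift = estimate_shift(all_filtered)
    egs = params.effective_genome_size or float(sum(chrom_sizes.values()))
    peak_params = PeakCallParams(
        p_threshold=params.p_threshold,
        shift=shift,
        mode="global_background",
        effective_genome_size=egs,
    )
    pooled = {
        c: _pool(filtered, condition_of, c) for c in conditions
    }
    candidate_sets = detect_candidates(pooled, peak_params, chrom_sizes)
    merged = merge_candidates(candidate_sets)
    records, discarded = filter_by_h3k27ac(merged, islands_by_condition)
    timings["identify"] = time.time() - t1
    logger.info(
        "identified %d candidates -> %d catalogued eRNAs", len(merged), len(records)
    )

    t2 = time.time()
    counts = count_reads(records, filtered)
    diff = differential_test(
        counts, dict(condition_of), alpha=params.alpha
    )
    for rec in records:
        row = diff.loc[rec.erna_id]
        rec.counts = {s: int(counts.loc[rec.erna_id, s]) for s in counts.columns}
        rec.base_mean = float(row["base_mean"])
        rec.log2fc = None if pd.isna(row["log2fc"]) else float(row["log2fc"])
        rec.pvalue = None if pd.isna(row["wald_p"]) else float(row["wald_p"])
        rec.padj = None if pd.isna(row["padj"]) else float(row["padj"])
        rec.status = str(row["status"])
    timings["quantify"] = time.time() - t2

    t3 = time.time()
    gene_assign = integ.assign_nearest_gene(records, genes)
    for rec in records:
        rec.gene_id = gene_assign[rec.erna_id]
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "params": {**params.as_dict(), "shift": shift},
        "filter_reports": filter_reports,
        "funnel": funnel_counts(candidate_sets, merged, records),
        "n_discarded_no_h3k27ac": len(discarded),
        "status_counts": {
            s: sum(r.status == s for r in records)
            for s in ("down", "up", "unchanged")
        },
    }

    if super_enhancers is not None:
        integ.flag_super_enhancers(records, super_enhancers)
        n_se = sum(r.is_super_enhancer for r in records)
        enrich = {}
        for status in ("down", "up"):
            members = [r for r in records if r.status == status]
            if members and 0 < n_se < len(records):
                res = integ.overlap_enrichment(
                    sum(r.is_super_enhancer for r in members),
                    len(members),
                    n_se,
                    len(records),
                )
                enrich[status] = {
                    "observed": res.observed,
                    "expected": res.expected,
                    "chi2": res.chi2,
                    "p": res.p,
                    "enriched": res.enriched,
                }
        report["se_enrichment"] = enrich

    if rnapii_by_condition is not None:
        summary = integ.rnapii_accounting(
            records,
            rnapii_by_condition.get("WT"),
            rnapii_by_condition.get("HD"),
        )
        report["rnapii"] = {
            "n_with_peak_wt": summary.n_with_peak_wt,
            "n_with_peak_hd": summary.n_with_peak_hd,
            "per_status": summary.per_status,
        }

    size_prof = integ.size_profile(records, islands_by_condition)
    report["island_size"] = {
        "medians": size_prof["medians"],
        "wilcoxon_p": size_prof["wilcoxon_p"],
    }
    timings["integrate"] = time.time() - t3

    motif_table = None
    if motifs is not None and genome is not None:
        t4 = time.time()
        targets = [r.interval for r in records if r.status == "down"]
        universe = [r.interval for r in records]
        if targets and len(universe) >= len(targets):
            motif_table = enrich_motifs(
                targets,
                universe,
                motifs,
                genome,
                n=params.n_resamples,
                seed=params.seed,
                p_threshold=params.motif_p_threshold,
            )
            report["motifs"] = motif_table.reset_index().to_dict("records")
        report["gc"] = gc_summary(
            [r.interval for r in records],
            universe,
            genome,
            chrom_sizes,
            seed=params.seed,
        )
        timings["motifs"] = time.time() - t4

    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    return PipelineResult(
        records=records, counts=counts, diff=diff, report=report,
        motif_table=motif_table,
    )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (paths + parameters + seed)."""

    genes_gtf: str
    reads_by_sample: dict[str, str]  # sample -> BED/SAM path
    condition_of: dict[str, str]
    islands_bed: dict[str, str]  # condition -> BED path
    chrom_sizes: dict[str, int]
    outdir: str = "ernakit_out"
    rnapii_bed: dict[str, str] | None = None
    super_enhancers_bed: str | None = None
    genome_fasta: str | None = None
    motifs_file: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def run_all(config: PipelineConfig, resume: bool = False) -> PipelineResult:
    """File-based full run; writes stage outputs and report.json.

    With ``resume=True`` the filtered-read stage outputs already present
    in the output directory are reloaded instead of recomputed
    (determinism makes re-entry outputs identical to a full run).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        genes = read_gtf(config.genes_gtf)
    except OSError as exc:
        raise RuntimeError(f"stage gene-annotation: cannot read input: {exc}") from exc

    mask = build_genic_mask(
        genes,
        up_ext=config.params.up_ext,
        down_ext=config.params.down_ext,
        chrom_sizes=config.chrom_sizes,
    )
    write_bed(mask.stranded_regions, outdir / "genic_mask.bed")

    reads_by_sample = {}
    for sample, path in config.reads_by_sample.items():
        cached = outdir / f"filtered_{sample}.bed"
        if resume and cached.exists():
            reads_by_sample[sample] = read_alignments(cached, format="bed")
        else:
            try:
                raw = read_alignments(path)
            except OSError as exc:
                raise RuntimeError(
                    f"stage read-filtering: cannot read input {path}"
                ) from exc
            kept, _rep = filter_reads(raw, mask)
            write_reads_bed(kept, cached)
            reads_by_sample[sample] = kept

    islands = {}
    for condition, path in config.islands_bed.items():
        try:
            islands[condition] = list(read_bed(path))
        except OSError as exc:
            raise RuntimeError(
                f"stage eRNA-filter: missing H3K27ac islands input {path}"
            ) from exc

    rnapii = None
    if config.rnapii_bed:
        rnapii = {c: list(read_bed(p)) for c, p in config.rnapii_bed.items()}
    super_enh = (
        list(read_bed(config.super_enhancers_bed))
        if config.super_enhancers_bed
        else None
    )
    genome = None
    if config.genome_fasta:
        from pyfaidx import Fasta

        genome = Fasta(config.genome_fasta)
    motifs = read_jaspar(config.motifs_file) if config.motifs_file else None

    # reads are pre-filtered above; masking inside run_memory is a no-op
    # for them but re-applies the split/strand rules deterministically
    result = run_memory(
        genes,
        reads_by_sample,
        config.condition_of,
        islands,
        config.chrom_sizes,
        params=config.params,
        rnapii_by_condition=rnapii,
        super_enhancers=super_enh,
        genome=genome,
        motifs=motifs,
    )

    result.catalogue_frame().to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
    result.counts.to_csv(outdir / "counts.tsv", sep="\t")
    result.diff.to_csv(outdir / "diff.tsv", sep="\t")
    if result.motif_table is not None:
        result.motif_table.to_csv(outdir / "motifs.tsv", sep="\t")
    write_bed([r.interval for r in result.records], outdir / "ernas.bed")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
    return result
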