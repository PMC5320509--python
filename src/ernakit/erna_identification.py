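"""From filtered RNA-seq reads to the H3K27ac-vetted eRNA catalogue.

The funnel: per-condition Poisson peak detection on filtered reads, union
merge of the per-condition candidate sets, then retention of candidates
supported by an H3K27ac island in at least one condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_model import GenomicInterval, IntervalSet, ReadAlignment, merge_intervals
from .peak_calling import Island, Peak, PeakCallParams, call_peaks


@dataclass
class ERNARecord:
    """One catalogue entry: interval, provenance, counts and statistics."""

    erna_id: str
    interval: GenomicInterval
    detected_in: frozenset[str] = frozenset()
    h3k27ac_support: frozenset[str] = frozenset()
    counts: dict[str, int] = field(default_factory=dict)
    base_mean: float | None = None
    log2fc: float | None = None
    pvalue: float | None = None
    padj: float | None = None
    status: str = "unchanged"
    gene_id: str | None = None
    is_super_enhancer: bool = False
    rnapii_wt: bool = False
    rnapii_hd: bool = False


def detect_candidates(
    filtered_reads_by_condition: Mapping[str, Sequence[ReadAlignment]],
    peak_params: PeakCallParams,
    chrom_sizes: Mapping[str, int],
) -> dict[str, IntervalSet]:
    """Per-condition candidate regions from pooled filtered reads.

    Runs the global-background Poisson caller separately per condition
    (reads pooled across that condition's replicates upstream).
    """
    out: dict[str, IntervalSet] = {}
    for condition, reads in filtered_reads_by_condition.items():
        peaks = call_peaks(reads, peak_params, chrom_sizes)
        out[condition] = IntervalSet(
            name=condition, intervals=[p.interval for p in peaks]
        ).normalize()
    return out


def merge_candidates(
    condition_sets: Mapping[str, IntervalSet],
) -> list[tuple[GenomicInterval, frozenset[str]]]:
    """Union-merge candidate intervals across conditions.

    Intervals overlapping by >= 1 bp merge into their span; each merged
    interval records the contributing conditions.
    """
    if not condition_sets:
        raise ValueError("merge_candidates requires at least one condition set")
    flat: list[GenomicInterval] = []
    labels: list[str] = []
    for condition, ivset in condition_sets.items():
        for iv in ivset:
            flat.append(iv)
            labels.append(condition)
    merged = merge_intervals(flat)
    return [
        (span, frozenset(labels[i] for i in members))
        for span, members in merged
    ]


def filter_by_h3k27ac(
    candidates: Sequence[tuple[GenomicInterval, frozenset[str]]],
    islands_by_condition: Mapping[str, Sequence[Island] | Sequence[GenomicInterval]],
) -> tuple[list[ERNARecord], list[tuple[GenomicInterval, str]]]:
    """Keep candidates overlapping >= 1 bp an island in any condition.

    Overlap is strand-ignored; eRNA records carry strand '.' (enhancer
    regions can be bidirectionally transcribed). Returns the catalogue
    and the discarded candidates with a reason.
    """
    island_spans: dict[str, list[GenomicInterval]] = {}
    for condition, islands in islands_by_condition.items():
        spans = [
            isl.interval if isinstance(isl, Island) else isl for isl in islands
        ]
        island_spans[condition] = sorted(spans, key=lambda iv: (iv.chrom, iv.start))

    records: list[ERNARecord] = []
    discarded: list[tuple[GenomicInterval, str]] = []
    n = 0
    for span, detected_in in candidates:
        support = frozenset(
            condition
            for condition, spans in island_spans.items()
            if any(span.overlap_length(isl) >= 1 for isl in spans)
        )
        if not support:
            discarded.append((span, "no H3K27ac island overlap"))
            continue
        n += 1
        records.append(
            ERNARecord(
                erna_id=f"eRNA_{n:05d}",
                interval=GenomicInterval(span.chrom, span.start, span.end, "."),
                detected_in=detected_in,
                h3k27ac_support=support,
            )
        )
    return records, discarded


def funnel_counts(
    condition_sets: Mapping[str, IntervalSet],
    merged: Sequence[tuple[GenomicInterval, frozenset[str]]],
    catalogue: Sequence[ERNARecord],
) -> dict[str, int]:
    """Stage-by-stage counts of the identification funnel."""
    out = {f"candidates_{c}": len(s) for c, s in condition_sets.items()}
    out["merged_candidates"] = len(merged)
    out["catalogue"] = len(catalogue)
    return out
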