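"""Gene association and integrative summaries for the eRNA catalogue.

Covers nearest-TSS gene assignment, observed-vs-expected chi-square
enrichment, RNAPII peak presence/loss/gain accounting, gene-list
intersections and H3K27ac enhancer-size comparisons between status
classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .erna_identification import ERNARecord
from .io_model import GeneModel, GenomicInterval

ENRICH_P = 1e-2  # significance threshold for observed-vs-expected calls


@dataclass
class ContingencyResult:
    observed: int
    expected: float
    chi2: float
    p: float
    enriched: bool


@dataclass
class RNAPIISummary:
    n_with_peak_wt: int
    n_with_peak_hd: int
    per_status: dict[str, dict[str, float]]


def assign_nearest_gene(
    ernas: Sequence[ERNARecord],
    genes: Sequence[GeneModel],
    max_distance: int | None = None,
) -> dict[str, str | None]:
    """Nearest-TSS gene per eRNA midpoint (any strand).

    Ties resolve to the lexicographically smaller gene_id; farther than
    ``max_distance`` (when given) yields None.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append((g.tss, g.gene_id))
    for items in by_chrom.values():
        items.sort()
    tss_arr = {c: np.array([t for t, _ in items]) for c, items in by_chrom.items()}

    out: dict[str, str | None] = {}
    for rec in ernas:
        items = by_chrom.get(rec.interval.chrom)
        if not items:
            out[rec.erna_id] = None
            continue
        mid = rec.interval.midpoint
        arr = tss_arr[rec.interval.chrom]
        i = int(np.searchsorted(arr, mid))
        cand = [j for j in (i - 1, i) if 0 <= j < len(items)]
        dmin = min(abs(items[j][0] - mid) for j in cand)
        if max_distance is not None and dmin > max_distance:
            out[rec.erna_id] = None
            continue
        # all genes at the minimal distance (tied TSS may repeat)
        lo, hi = i, i
        while lo - 1 >= 0 and abs(items[lo - 1][0] - mid) <= dmin:
            lo -= 1
        while hi < len(items) and abs(items[hi][0] - mid) <= dmin:
            hi += 1
        tied = [
            gid for t, gid in items[lo:hi] if abs(t - mid) == dmin
        ]
        out[rec.erna_id] = min(tied)
    return out


def overlap_enrichment(
    hits_in_subset: int,
    subset_size: int,
    hits_in_universe: int,
    universe_size: int,
    p_threshold: float = ENRICH_P,
) -> ContingencyResult:
    """Observed-vs-expected 1-df chi-square on a subset's hit count.

    Expected hits under independence are ``subset * universe_rate``; the
    statistic sums (O-E)^2/E over the subset's hit / non-hit cells.
    ``enriched`` requires both p below threshold and observed > expected.
    """
    if not (0 <= hits_in_subset <= subset_size <= universe_size):
        raise ValueError("inconsistent contingency counts")
    if hits_in_universe > universe_size:
        raise ValueError("inconsistent contingency counts")
    expected = subset_size * hits_in_universe / universe_size
    expected_miss = subset_size - expected
    if expected <= 0 or expected_miss <= 0:
        raise ValueError("expected cell count is zero; test undefined")
    obs_miss = subset_size - hits_in_subset
    chi2 = (hits_in_subset - expected) ** 2 / expected + (
        obs_miss - expected_miss
    ) ** 2 / expected_miss
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(
        observed=hits_in_subset,
        expected=float(expected),
        chi2=float(chi2),
        p=p,
        enriched=bool(p < p_threshold and hits_in_subset > expected),
    )


def _has_overlap(
    iv: GenomicInterval, spans_by_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    spans = spans_by_chrom.get(iv.chrom)
    if spans is None:
        return False
    starts, maxend = spans
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi == 0:
        return False
    return bool(maxend[hi - 1] > iv.start)


def _index_spans(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def flag_peak_presence(
    ernas: Sequence[ERNARecord],
    peaks_wt: Sequence[GenomicInterval],
    peaks_hd: Sequence[GenomicInterval],
) -> None:
    """Set rnapii_wt / rnapii_hd on records (>= 1 bp overlap)."""
    wt_idx = _index_spans(peaks_wt)
    hd_idx = _index_spans(peaks_hd)
    for rec in ernas:
        rec.rnapii_wt = _has_overlap(rec.interval, wt_idx)
        rec.rnapii_hd = _has_overlap(rec.interval, hd_idx)


def pct(numerator: int, denominator: int) -> int:
    """Integer-rounded percentage (report granularity)."""
    if denominator == 0:
        return 0
    return int(round(100.0 * numerator / denominator))


def rnapii_accounting(
    ernas: Sequence[ERNARecord],
    rnapii_peaks_wt: Sequence[GenomicInterval] | None = None,
    rnapii_peaks_hd: Sequence[GenomicInterval] | None = None,
) -> RNAPIISummary:
    """Peak presence, loss and gain per differential-status class.

    An eRNA has a peak in a condition iff it overlaps one by >= 1 bp
    (flags may also be preset on the records). Loss percentage is taken
    over the class members with a WT peak; gain percentage over the class
    size; both integer-rounded.
    """
    if rnapii_peaks_wt is not None and rnapii_peaks_hd is not None:
        flag_peak_presence(ernas, rnapii_peaks_wt, rnapii_peaks_hd)
    per_status: dict[str, dict[str, float]] = {}
    for status in ("down", "up", "unchanged"):
        members = [r for r in ernas if r.status == status]
        with_wt = [r for r in members if r.rnapii_wt]
        lost = [r for r in with_wt if not r.rnapii_hd]
        gained = [r for r in members if not r.rnapii_wt and r.rnapii_hd]
        per_status[status] = {
            "n_status": len(members),
            "n_with_wt_peak": len(with_wt),
            "n_lost": len(lost),
            "n_gained": len(gained),
            "pct_lost": pct(len(lost), len(with_wt)),
            "pct_gained": pct(len(gained), len(members)),
        }
    return RNAPIISummary(
        n_with_peak_wt=sum(r.rnapii_wt for r in ernas),
        n_with_peak_hd=sum(r.rnapii_hd for r in ernas),
        per_status=per_status,
    )


def crosslist(a: set[str], b: set[str]) -> dict[str, object]:
    """Intersection of two gene lists with sizes."""
    inter = set(a) & set(b)
    return {
        "intersection": inter,
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
    }


def size_profile(
    ernas: Sequence[ERNARecord],
    islands_by_condition: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, object]:
    """Summed overlapping-island width per eRNA per condition.

    Returns per-eRNA widths and per-status medians, plus the rank-sum
    (Wilcoxon) p-value comparing down- vs up-class widths per condition.
    """
    cond_spans = {}
    for condition, islands in islands_by_condition.items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in islands:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for spans in by_chrom.values():
            spans.sort()
        cond_spans[condition] = by_chrom

    widths: dict[str, dict[str, int]] = {c: {} for c in cond_spans}
    for rec in ernas:
        for condition, by_chrom in cond_spans.items():
            total = 0
            for s, e in by_chrom.get(rec.interval.chrom, ()):
                if s < rec.interval.end and e > rec.interval.start:
                    total += e - s
            widths[condition][rec.erna_id] = total

    summary: dict[str, object] = {"widths": widths, "medians": {}, "wilcoxon_p": {}}
    for condition in cond_spans:
        med = {}
        for status in ("down", "up", "unchanged"):
            vals = [
                widths[condition][r.erna_id] for r in ernas if r.status == status
            ]
            med[status] = float(np.median(vals)) if vals else float("nan")
        summary["medians"][condition] = med
        down = [widths[condition][r.erna_id] for r in ernas if r.status == "down"]
        up = [widths[condition][r.erna_id] for r in ernas if r.status == "up"]
        if down and up:
            stat = stats.mannwhitneyu(down, up, alternative="two-sided")
            summary["wilcoxon_p"][condition] = float(stat.pvalue)
        else:
            summary["wilcoxon_p"][condition] = float("nan")
    return summary


def flag_super_enhancers(
    ernas: Sequence[ERNARecord], super_enhancers: Sequence[GenomicInterval]
) -> None:
    """Set is_super_enhancer where the eRNA overlaps an SE interval."""
    idx = _index_spans(super_enhancers)
    for rec in ernas:
        rec.is_super_enhancer = _has_overlap(rec.interval, idx)
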