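"""Extended genic exclusion mask and putative-eRNA read filtering.

Genic spans are extended 3 kb upstream of the TSS and 10 kb downstream of
the transcript end to absorb polymerase read-through. With a first-strand
library (reads map antisense to their source RNA), a read antisense to a
gene is genic signal, so reads overlapping a mask region on the OPPOSITE
strand by >= 1 bp are discarded, along with all split-mapped reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_model import GeneModel, GenomicInterval, ReadAlignment


@dataclass
class GenicMask:
    """Stranded extended-gene exclusion regions."""

    stranded_regions: list[GenomicInterval] = field(default_factory=list)
    up_ext: int = 3000
    down_ext: int = 10000


@dataclass
class FilterReport:
    """Per-rule removal accounting from filter_reads."""

    n_input: int = 0
    n_split_removed: int = 0
    n_genic_removed: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_split_removed": self.n_split_removed,
            "n_genic_removed": self.n_genic_removed,
            "n_retained": self.n_retained,
        }


def build_genic_mask(
    genes: Sequence[GeneModel],
    up_ext: int = 3000,
    down_ext: int = 10000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenicMask:
    """Extend each gene span upstream/downstream of TSS/TES, keeping strand.

    For a + gene [s,e): region [s-up_ext, e+down_ext); for a - gene:
    [s-down_ext, e+up_ext). Clipped at 0 and at the chromosome length when
    ``chrom_sizes`` is given.
    """
    regions = []
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            start = iv.start - up_ext
            end = iv.end + down_ext
        else:
            start = iv.start - down_ext
            end = iv.end + up_ext
        start = max(0, start)
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        regions.append(GenomicInterval(iv.chrom, start, end, iv.strand))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return GenicMask(stranded_regions=regions, up_ext=up_ext, down_ext=down_ext)


def filter_reads(
    reads: Sequence[ReadAlignment],
    mask: GenicMask,
) -> tuple[list[ReadAlignment], FilterReport]:
    """Remove split reads and reads overlapping opposite-strand mask regions.

    A read with strand '.' is rejected: the opposite-strand rule is
    undefined without read strand. Overlap is on the read's full span.
    """
    report = FilterReport(n_input=len(reads))
    if any(r.interval.strand == "." for r in reads):
        raise ValueError("filter_reads requires stranded reads (strand '.')")

    # mask regions grouped by (chrom, strand of reads they remove)
    # a + mask region removes - reads, and vice versa
    removal: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for region in mask.stranded_regions:
        opposite = "-" if region.strand == "+" else "+"
        removal[(region.chrom, opposite)].append((region.start, region.end))
    spans = {
        key: (
            np.array([s for s, _ in ivs]),
            np.array([e for _, e in ivs]),
        )
        for key, ivs in removal.items()
    }

    kept: list[ReadAlignment] = []
    # vectorize per (chrom, strand) group
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        if r.is_split:
            report.n_split_removed += 1
            continue
        groups[(r.interval.chrom, r.interval.strand)].append(i)

    for key, idxs in groups.items():
        starts = np.array([reads[i].interval.start for i in idxs])
        ends = np.array([reads[i].interval.end for i in idxs])
        genic = np.zeros(len(idxs), dtype=bool)
        if key in spans:
            m_starts, m_ends = spans[key]
            for ms, me in zip(m_starts, m_ends):
                genic |= (starts < me) & (ends > ms)
        report.n_genic_removed += int(genic.sum())
        for i, g in zip(idxs, genic):
            if not g:
                kept.append(reads[i])

    report.n_retained = len(kept)
    kept.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return kept, report
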