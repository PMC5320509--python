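"""Core genomic coordinate model and readers/writers.

All coordinates are 0-based, half-open (BED-native). GTF input (1-based,
closed) is converted on read. Strand is one of ``+``, ``-`` or ``.``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

STRANDS = ("+", "-", ".")

#: The 13 Ensembl biotypes retained when building the genic exclusion set.
DEFAULT_BIOTYPES = frozenset(
    {
        "IG_C_gene",
        "IGD_gene",
        "IG_J_gene",
        "IG_LV_gene",
        "IG_V_pseudogene",
        "Mt_rRNA",
        "Mt_tRNA",
        "polymorphic_pseudogene",
        "protein_coding",
        "pseudogene",
        "rRNA",
        "TR_V_gene",
        "TR_V_pseudogene",
    }
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene as a stranded span with a biotype label.

    The span covers the gene's full extent (min start to max end over its
    transcripts). TSS/TES follow strand orientation.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand == ".":
            raise ValueError(f"gene {self.gene_id} must be stranded")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A strand-specific sequencing fragment; split iff multi-block."""

    interval: GenomicInterval
    n_blocks: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def is_split(self) -> bool:
        return self.n_blocks > 1


@dataclass
class IntervalSet:
    """Named ordered collection of intervals; ``normalize()`` sorts."""

    name: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)

    def normalize(self) -> "IntervalSet":
        self.intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        return self

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class PWMotif:
    """Position weight matrix over A, C, G, T with a 0-order background."""

    motif_id: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if (m < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    biotype_filter: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Read gene models from an Ensembl-dialect GTF.

    ``gene`` feature rows are used directly; if a gene_id has none, its span
    is the union of all its feature rows. Coordinates are converted from
    1-based closed to 0-based half-open. Only genes whose ``gene_biotype``
    is in ``biotype_filter`` (default: the 13 retained Ensembl biotypes)
    are returned.
    """
    wanted = DEFAULT_BIOTYPES if biotype_filter is None else set(biotype_filter)
    # gene_id -> [chrom, start0, end, strand, biotype, has_gene_row]
    spans: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr = fields
            try:
                start0 = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            if start0 < 0 or start0 >= end:
                raise ParseError(
                    f"{path}: line {lineno}: invalid span {start1}..{end1}"
                )
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            rec = spans.get(gene_id)
            is_gene_row = feature == "gene"
            if rec is None:
                spans[gene_id] = [chrom, start0, end, strand, biotype, is_gene_row]
            elif is_gene_row:
                spans[gene_id] = [chrom, start0, end, strand, biotype, True]
            elif not rec[5]:
                rec[1] = min(rec[1], start0)
                rec[2] = max(rec[2], end)
                if biotype and not rec[4]:
                    rec[4] = biotype
    genes = []
    for gene_id, (chrom, start0, end, strand, biotype, _) in spans.items():
        if biotype not in wanted:
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, start0, end, strand),
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Alignments


def _read_sam(path: str | Path) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                n_unmapped += 1
                continue
            blocks = rec.get_blocks()
            n_blocks = max(1, len(blocks))
            strand = "-" if rec.is_reverse else "+"
            reads.append(
                ReadAlignment(
                    interval=GenomicInterval(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        strand,
                    ),
                    n_blocks=n_blocks,
                )
            )
    if not reads and n_unmapped:
        warnings.warn(f"{path}: no mapped primary records", stacklevel=2)
    return reads


def _read_bed_reads(path: str | Path) -> list[ReadAlignment]:
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: read BED requires >= 6 columns "
                    "(strand is mandatory)"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: missing or invalid strand"
                )
            n_blocks = int(fields[6]) if len(fields) > 6 else 1
            reads.append(
                ReadAlignment(
                    interval=GenomicInterval(chrom, start, end, strand),
                    n_blocks=n_blocks,
                )
            )
    return reads


def read_alignments(path: str | Path, format: str | None = None) -> list[ReadAlignment]:
    """Read primary mapped records from SAM text or BED6(+blockCount).

    A read is split iff its CIGAR contains an N gap (SAM) or its
    blockCount column exceeds 1 (BED).
    """
    if format is None:
        format = "sam" if str(path).endswith(".sam") else "bed"
    if format == "sam":
        return _read_sam(path)
    if format == "bed":
        return _read_bed_reads(path)
    raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------------------
# BED interval sets


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet (strand '.' if absent)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: BED requires >= 3 columns"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return IntervalSet(name=name or Path(path).stem, intervals=intervals)


def write_bed(intervals: IntervalSet | Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_reads_bed(reads: Sequence[ReadAlignment], path: str | Path) -> None:
    """Write reads as BED6 plus a 7th blockCount column."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tr{i}\t0\t{iv.strand}\t{r.n_blocks}\n"
            )


# ---------------------------------------------------------------------------
# Interval intersection


def _strand_ok(a: str, b: str, mode: str) -> bool:
    if mode == "ignore":
        return True
    if mode == "same":
        return a == b
    if mode == "opposite":
        return (a == "+" and b == "-") or (a == "-" and b == "+")
    raise ValueError(f"unknown strand_mode {mode!r}")


def intersect(
    a: IntervalSet | Sequence[GenomicInterval],
    b: IntervalSet | Sequence[GenomicInterval],
    min_overlap: int = 1,
    strand_mode: str = "ignore",
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs (a_i, b_j) overlapping by >= min_overlap bases.

    Overlap of [s1,e1) and [s2,e2) is ``max(0, min(e1,e2) - max(s1,s2))``.
    ``strand_mode`` is one of ``ignore``, ``same``, ``opposite``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a_ivs = list(a)
    b_ivs = sorted(b, key=lambda iv: (iv.chrom, iv.start))
    # sweep: group b by chrom with sorted starts for binary search
    from collections import defaultdict

    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in b_ivs:
        by_chrom[iv.chrom].append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    maxend = {}
    for c, ivs in by_chrom.items():
        ends = np.array([iv.end for iv in ivs])
        maxend[c] = np.maximum.accumulate(ends)

    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for av in a_ivs:
        ivs = by_chrom.get(av.chrom)
        if not ivs:
            continue
        # candidates: start < av.end; prune left tail via running max end
        hi = int(np.searchsorted(starts[av.chrom], av.end - min_overlap, side="right"))
        lo = int(np.searchsorted(maxend[av.chrom][:hi], av.start + min_overlap, side="left"))
        for bv in ivs[lo:hi]:
            ov = min(av.end, bv.end) - max(av.start, bv.start)
            if ov >= min_overlap and _strand_ok(av.strand, bv.strand, strand_mode):
                pairs.append((av, bv))
    return pairs


def merge_intervals(
    intervals: Sequence[GenomicInterval], min_gap: int = 0
) -> list[tuple[GenomicInterval, list[int]]]:
    """Merge intervals whose spans overlap (or are within ``min_gap``).

    Returns merged spans (strand '.') with the member indices of each.
    """
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    merged: list[tuple[GenomicInterval, list[int]]] = []
    for idx in order:
        iv = intervals[idx]
        if merged:
            last, members = merged[-1]
            if last.chrom == iv.chrom and iv.start <= last.end + min_gap:
                merged[-1] = (
                    GenomicInterval(last.chrom, last.start, max(last.end, iv.end)),
                    members + [idx],
                )
                continue
        merged.append((GenomicInterval(iv.chrom, iv.start, iv.end), [idx]))
    return merged


# ---------------------------------------------------------------------------
# PWM readers (JASPAR PFM text and MEME-motif format)


def read_jaspar(path: str | Path) -> list[PWMotif]:
    """Read JASPAR 2014-style PFM text (``>ID name`` then 4 count rows)."""
    motifs: list[PWMotif] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ParseError(f"{path}: expected '>' header, got {lines[i]!r}")
        motif_id = lines[i][1:].split()[0]
        rows = []
        for j in range(1, 5):
            row = lines[i + j]
            # tolerate "A [ 1 2 3 ]" and bare "1 2 3"
            row = row.split("[")[-1].rstrip("]").strip()
            row = row.lstrip("ACGT").strip()
            rows.append([float(x) for x in row.split()])
        counts = np.array(rows, dtype=float).T  # (width, 4)
        probs = counts / counts.sum(axis=1, keepdims=True)
        motifs.append(PWMotif(motif_id=motif_id, matrix=probs))
        i += 5
    return motifs


def read_meme(path: str | Path) -> list[PWMotif]:
    """Read minimal MEME-motif format (letter-probability matrices)."""
    motifs: list[PWMotif] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array(
                [float(vals[vals.index(b) + 1]) for b in "ACGT"]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability" not in lines[j]:
                j += 1
            if j >= len(lines):
                raise ParseError(f"{path}: MOTIF {motif_id} has no matrix")
            rows = []
            j += 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                j += 1
            m = np.array(rows)
            motifs.append(
                PWMotif(
                    motif_id=motif_id,
                    matrix=m / m.sum(axis=1, keepdims=True),
                    background=background,
                )
            )
            i = j
            continue
        i += 1
    return motifs
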