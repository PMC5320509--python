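"""Synthetic two-condition striatum-like dataset with known ground truth.

Emulates the statistical structure the pipeline is built for: a small
random genome carrying stranded genes and intergenic enhancers (typical
and broad/super), strand-specific RNA-seq reads in which genic fragments
map antisense to their gene (first-strand chemistry) with exponential
read-through past gene ends, enhancer transcription on both strands with
planted HD-vs-WT fold changes, H3K27ac islands centred on enhancers
(narrower in HD at down-enhancers), RNAPII peaks present or absent per
condition, and a motif consensus embedded in a fraction of
down-enhancers. Everything is deterministic under the seed.

Planted elements are pairwise non-overlapping and at least 15 kb from
any gene span, so they sit outside the default 3 kb / 10 kb extended
genic masks and the identification funnel cannot lose truth to masking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .erna_identification import ERNARecord
from .io_model import (
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    write_bed,
    write_reads_bed,
)

CONDITIONS = ("WT", "HD")
_GENE_ENHANCER_GAP = 15000
_READTHROUGH_FRACTION = 0.15
_SPLIT_FRACTION = 0.02
_BACKGROUND_READ_FRACTION = 0.25
_GENIC_READ_FRACTION = 0.60


@dataclass
class SimulationConfig:
    genome_size: int = 2_000_000
    n_contigs: int = 2
    n_genes: int = 40
    n_enhancers: int = 60
    n_super: int = 12
    background_gc: float = 0.42
    enhancer_gc: float = 0.55
    read_length: int = 50
    fragment_length: int = 200
    depth: int = 400_000  # reads per condition, summed over replicates
    n_replicates: int = 4
    readthrough_decay: float = 2000.0
    erna_enrichment: float = 10.0
    n_down: int = 15
    n_up: int = 8
    fold_down: float = 0.25
    fold_up: float = 4.0
    nb_dispersion: float = 0.05
    motif_consensus: str = "CCATATTAGG"
    motif_plant_fraction: float = 0.5
    rnapii_presence_fraction: float = 0.6
    rnapii_loss_fraction: float = 0.4
    rnapii_gain_fraction: float = 0.05
    h3k27ac_as_reads: bool = False
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_super > self.n_enhancers:
            raise ValueError("n_super cannot exceed n_enhancers")
        if self.n_down + self.n_up > self.n_enhancers:
            raise ValueError("more planted effects than enhancers")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    reads: dict[str, list[list[ReadAlignment]]]  # condition -> per-replicate
    h3k27ac_islands: dict[str, list[GenomicInterval]]
    h3k27ac_reads: dict[str, list[ReadAlignment]]
    rnapii_peaks: dict[str, list[GenomicInterval]]
    super_enhancers: list[GenomicInterval]
    truth: pd.DataFrame
    gene_weights: np.ndarray

    @property
    def sample_reads(self) -> dict[str, list[ReadAlignment]]:
        """Per-sample read lists keyed like 'WT_1'."""
        out = {}
        for condition, reps in self.reads.items():
            for i, r in enumerate(reps, start=1):
                out[f"{condition}_{i}"] = r
        return out

    @property
    def condition_of(self) -> dict[str, str]:
        return {s: s.split("_")[0] for s in self.sample_reads}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / "genes.gtf", "w") as fh:
            for g in self.genes:
                iv = g.interval
                fh.write(
                    f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tgene_id \"{g.gene_id}\"; "
                    f"gene_biotype \"{g.biotype}\";\n"
                )
        for sample, reads in self.sample_reads.items():
            write_reads_bed(reads, outdir / f"reads_{sample}.bed")
        for condition in CONDITIONS:
            write_bed(
                self.h3k27ac_islands[condition],
                outdir / f"h3k27ac_islands_{condition}.bed",
            )
            write_bed(
                self.rnapii_peaks[condition], outdir / f"rnapii_{condition}.bed"
            )
            if self.h3k27ac_reads.get(condition):
                write_reads_bed(
                    self.h3k27ac_reads[condition],
                    outdir / f"h3k27ac_reads_{condition}.bed",
                )
        write_bed(self.super_enhancers, outdir / "super_enhancers.bed")
        self.truth.to_csv(outdir / "truth_enhancers.tsv", sep="\t", index=False)
        with open(outdir / "chrom_sizes.json", "w") as fh:
            json.dump(self.chrom_sizes, fh)


def _exact_gc_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Sequence with GC count exact to rounding (encoded 0..3)."""
    n_gc = int(round(length * gc))
    n_at = length - n_gc
    bases = np.concatenate(
        [
            rng.choice([1, 2], size=n_gc),  # C or G
            rng.choice([0, 3], size=n_at),  # A or T
        ]
    )
    rng.shuffle(bases)
    return bases


def _decode(arr: np.ndarray) -> str:
    return arr.astype(np.uint8).tobytes().translate(
        bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
    ).decode()


def _place_elements(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[dict], list[dict]]:
    """Lay out genes then enhancers per contig with required clearances."""
    contig_len = cfg.genome_size // cfg.n_contigs
    genes: list[dict] = []
    enhancers: list[dict] = []
    # round-robin split of counts across contigs
    per_contig_genes = [
        cfg.n_genes // cfg.n_contigs + (1 if i < cfg.n_genes % cfg.n_contigs else 0)
        for i in range(cfg.n_contigs)
    ]
    per_contig_enh = [
        cfg.n_enhancers // cfg.n_contigs
        + (1 if i < cfg.n_enhancers % cfg.n_contigs else 0)
        for i in range(cfg.n_contigs)
    ]
    n_super_left = cfg.n_super
    for ci in range(cfg.n_contigs):
        chrom = f"chr{ci + 1}"
        n_sup_here = min(
            n_super_left,
            cfg.n_super // cfg.n_contigs
            + (1 if ci < cfg.n_super % cfg.n_contigs else 0),
        )
        n_super_left -= n_sup_here
        cursor = 3000
        for _ in range(per_contig_genes[ci]):
            cursor += int(rng.integers(2000, 6000))
            length = int(rng.integers(2000, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                {"chrom": chrom, "start": cursor, "end": cursor + length,
                 "strand": strand}
            )
            cursor += length
        cursor += _GENE_ENHANCER_GAP + 2000
        prev_island_end = cursor
        for ei in range(per_contig_enh[ci]):
            is_super = ei < n_sup_here
            if is_super:
                span_w = int(rng.integers(1500, 2500))
                island_w = int(rng.integers(8000, 15000))
            else:
                span_w = int(rng.integers(500, 1500))
                island_w = int(rng.integers(500, 2000))
            overhang = max(0, (island_w - span_w) // 2)
            start = max(cursor, prev_island_end + 800 + overhang) + int(
                rng.integers(200, 1200)
            )
            end = start + span_w
            prev_island_end = (start + end) // 2 + island_w // 2
            cursor = end
            if prev_island_end > contig_len - 2000:
                raise ValueError(
                    "infeasible placement: too many elements for genome_size"
                )
            enhancers.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "class": "super" if is_super else "typical",
                    "island_w": island_w,
                }
            )
    return genes, enhancers


def generate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Build the full synthetic dataset from a configuration."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    contig_len = cfg.genome_size // cfg.n_contigs
    chroms = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    chrom_sizes = {c: contig_len for c in chroms}

    gene_specs, enh_specs = _place_elements(rng, cfg)

    # planted statuses: broad (super) enhancers preferentially, but not
    # exclusively, down (the down class is SE-enriched; a size-matched
    # resampling control stays non-degenerate)
    supers = [i for i, e in enumerate(enh_specs) if e["class"] == "super"]
    typicals = [i for i, e in enumerate(enh_specs) if e["class"] == "typical"]
    rng.shuffle(typicals)
    n_super_down = min(cfg.n_down, (3 * cfg.n_super) // 4)
    down_idx = supers[:n_super_down] + typicals[: cfg.n_down - n_super_down]
    remaining = [i for i in typicals if i not in down_idx]
    up_idx = remaining[: cfg.n_up]
    status = ["null"] * len(enh_specs)
    for i in down_idx:
        status[i] = "down"
    for i in up_idx:
        status[i] = "up"

    motif_planted = [False] * len(enh_specs)
    for i in down_idx:
        if rng.random() < cfg.motif_plant_fraction:
            motif_planted[i] = True

    rnapii_wt = [bool(rng.random() < cfg.rnapii_presence_fraction) for _ in enh_specs]
    rnapii_hd = list(rnapii_wt)
    for i, e in enumerate(enh_specs):
        if status[i] == "down" and rnapii_wt[i]:
            if rng.random() < cfg.rnapii_loss_fraction:
                rnapii_hd[i] = False
        elif status[i] == "up" and not rnapii_wt[i]:
            if rng.random() < cfg.rnapii_gain_fraction:
                rnapii_hd[i] = True

    # genome sequence: iid background, enhancer spans at elevated GC,
    # motif consensus embedded centrally where planted
    genome_arr = {
        c: rng.choice(
            4,
            size=contig_len,
            p=[
                (1 - cfg.background_gc) / 2,
                cfg.background_gc / 2,
                cfg.background_gc / 2,
                (1 - cfg.background_gc) / 2,
            ],
        )
        for c in chroms
    }
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, e in enumerate(enh_specs):
        w = e["end"] - e["start"]
        genome_arr[e["chrom"]][e["start"] : e["end"]] = _exact_gc_sequence(
            rng, w, cfg.enhancer_gc
        )
        if motif_planted[i]:
            m = np.array([base_code[b] for b in cfg.motif_consensus])
            mid = e["start"] + (w - len(m)) // 2
            genome_arr[e["chrom"]][mid : mid + len(m)] = m
    genome = {c: _decode(a) for c, a in genome_arr.items()}

    # expected read counts
    bg_density = _BACKGROUND_READ_FRACTION * cfg.depth / cfg.genome_size
    gene_weights = rng.lognormal(0.0, 0.8, size=len(gene_specs))
    gene_weights /= gene_weights.sum()
    gene_mu = _GENIC_READ_FRACTION * cfg.depth / cfg.n_replicates * gene_weights
    enh_mu_base = np.array(
        [
            cfg.erna_enrichment * bg_density * (e["end"] - e["start"])
            / cfg.n_replicates
            for e in enh_specs
        ]
    )
    fold = {
        "WT": np.ones(len(enh_specs)),
        "HD": np.array(
            [
                cfg.fold_down
                if status[i] == "down"
                else cfg.fold_up
                if status[i] == "up"
                else 1.0
                for i in range(len(enh_specs))
            ]
        ),
    }

    def _nb(mu: float) -> int:
        if mu <= 0:
            return 0
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        return int(rng.poisson(lam))

    def _make_read(chrom: str, frag_start: int, strand: str) -> ReadAlignment:
        L = chrom_sizes[chrom]
        if strand == "+":
            s = frag_start
        else:
            s = frag_start + cfg.fragment_length - cfg.read_length
        s = int(np.clip(s, 0, L - cfg.read_length))
        n_blocks = 2 if rng.random() < _SPLIT_FRACTION else 1
        return ReadAlignment(
            interval=GenomicInterval(chrom, s, s + cfg.read_length, strand),
            n_blocks=n_blocks,
        )

    reads: dict[str, list[list[ReadAlignment]]] = {}
    for condition in CONDITIONS:
        reps = []
        for _rep in range(cfg.n_replicates):
            rep_reads: list[ReadAlignment] = []
            # intergenic / unannotated background, random strand
            n_bg = rng.poisson(
                _BACKGROUND_READ_FRACTION * cfg.depth / cfg.n_replicates
            )
            for _ in range(n_bg):
                chrom = chroms[int(rng.integers(len(chroms)))]
                fs = int(rng.integers(0, contig_len - cfg.fragment_length))
                strand = "+" if rng.random() < 0.5 else "-"
                rep_reads.append(_make_read(chrom, fs, strand))
            # genic fragments, antisense to the gene, with TES read-through
            for gi, g in enumerate(gene_specs):
                n_g = _nb(gene_mu[gi])
                anti = "-" if g["strand"] == "+" else "+"
                glen = g["end"] - g["start"]
                for _ in range(n_g):
                    if rng.random() < _READTHROUGH_FRACTION:
                        off = rng.exponential(cfg.readthrough_decay)
                        if g["strand"] == "+":
                            fs = g["end"] + int(off)
                        else:
                            fs = g["start"] - int(off) - cfg.fragment_length
                    else:
                        fs = g["start"] + int(rng.integers(0, max(1, glen)))
                    fs = int(
                        np.clip(fs, 0, contig_len - cfg.fragment_length)
                    )
                    rep_reads.append(_make_read(g["chrom"], fs, anti))
            # enhancer transcription, both strands
            for ei, e in enumerate(enh_specs):
                n_e = _nb(enh_mu_base[ei] * fold[condition][ei])
                span = e["end"] - e["start"]
                for _ in range(n_e):
                    fs = e["start"] + int(rng.integers(0, max(1, span)))
                    fs = int(np.clip(fs, 0, contig_len - cfg.fragment_length))
                    strand = "+" if rng.random() < 0.5 else "-"
                    rep_reads.append(_make_read(e["chrom"], fs, strand))
            reps.append(rep_reads)
        reads[condition] = reps

    # H3K27ac islands per condition (HD narrower at down-enhancers)
    islands: dict[str, list[GenomicInterval]] = {c: [] for c in CONDITIONS}
    for i, e in enumerate(enh_specs):
        center = (e["start"] + e["end"]) // 2
        for condition in CONDITIONS:
            w = e["island_w"]
            if condition == "HD" and status[i] == "down":
                w = int(w * 0.6)
            start = max(0, center - w // 2)
            islands[condition].append(
                GenomicInterval(e["chrom"], start, start + w)
            )

    h3k27ac_reads: dict[str, list[ReadAlignment]] = {c: [] for c in CONDITIONS}
    if cfg.h3k27ac_as_reads:
        chip_depth = 60000
        for condition in CONDITIONS:
            isl = islands[condition]
            widths = np.array([iv.length() for iv in isl], dtype=float)
            n_isl_reads = rng.poisson(0.7 * chip_depth * widths / widths.sum())
            for iv, n in zip(isl, n_isl_reads):
                for _ in range(int(n)):
                    s = iv.start + int(rng.integers(0, max(1, iv.length())))
                    s = int(np.clip(s, 0, chrom_sizes[iv.chrom] - cfg.read_length))
                    strand = "+" if rng.random() < 0.5 else "-"
                    h3k27ac_reads[condition].append(
                        ReadAlignment(
                            interval=GenomicInterval(
                                iv.chrom, s, s + cfg.read_length, strand
                            )
                        )
                    )
            for _ in range(rng.poisson(0.3 * chip_depth)):
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, contig_len - cfg.read_length))
                strand = "+" if rng.random() < 0.5 else "-"
                h3k27ac_reads[condition].append(
                    ReadAlignment(
                        interval=GenomicInterval(chrom, s, s + cfg.read_length, strand)
                    )
                )

    rnapii: dict[str, list[GenomicInterval]] = {c: [] for c in CONDITIONS}
    for i, e in enumerate(enh_specs):
        center = (e["start"] + e["end"]) // 2
        peak = GenomicInterval(e["chrom"], max(0, center - 200), center + 200)
        if rnapii_wt[i]:
            rnapii["WT"].append(peak)
        if rnapii_hd[i]:
            rnapii["HD"].append(peak)

    super_enhancers = [
        islands["WT"][i]
        for i, e in enumerate(enh_specs)
        if e["class"] == "super"
    ]

    genes = [
        GeneModel(
            gene_id=f"gene_{gi:04d}",
            interval=GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),
            biotype="protein_coding",
        )
        for gi, g in enumerate(gene_specs)
    ]

    truth = pd.DataFrame(
        {
            "enhancer_id": [f"enh_{i:04d}" for i in range(len(enh_specs))],
            "chrom": [e["chrom"] for e in enh_specs],
            "start": [e["start"] for e in enh_specs],
            "end": [e["end"] for e in enh_specs],
            "class": [e["class"] for e in enh_specs],
            "status": status,
            "fold_change": fold["HD"],
            "motif_planted": motif_planted,
            "rnapii_wt": rnapii_wt,
            "rnapii_hd": rnapii_hd,
            "island_w_wt": [iv.length() for iv in islands["WT"]],
            "island_w_hd": [iv.length() for iv in islands["HD"]],
            "expected_count_wt": enh_mu_base * fold["WT"],
            "expected_count_hd": enh_mu_base * fold["HD"],
        }
    )

    return SyntheticDataset(
        config=cfg,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        reads=reads,
        h3k27ac_islands=islands,
        h3k27ac_reads=h3k27ac_reads,
        rnapii_peaks=rnapii,
        super_enhancers=super_enhancers,
        truth=truth,
        gene_weights=gene_weights,
    )


def score_recovery(
    truth: pd.DataFrame, catalogue: Sequence[ERNARecord]
) -> dict[str, object]:
    """Sensitivity/precision of the catalogue against planted enhancers.

    A planted enhancer is recovered iff overlapped by >= 1 bp by a
    catalogue record; precision is the fraction of records overlapping
    any planted element. The confusion table compares planted vs called
    status for recovered enhancers.
    """
    truth_iv = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in truth.itertuples(index=False)
    ]
    recovered = np.zeros(len(truth_iv), dtype=bool)
    record_hits = np.zeros(len(catalogue), dtype=bool)
    called_status: dict[int, str] = {}
    for j, rec in enumerate(catalogue):
        for i, tv in enumerate(truth_iv):
            if rec.interval.overlap_length(tv) >= 1:
                recovered[i] = True
                record_hits[j] = True
                called_status.setdefault(i, rec.status)
    sensitivity = float(recovered.mean()) if len(truth_iv) else float("nan")
    precision = float(record_hits.mean()) if len(catalogue) else float("nan")
    statuses = ("down", "up", "null", "unchanged")
    confusion = pd.DataFrame(
        0,
        index=pd.Index(["down", "up", "null"], name="planted"),
        columns=pd.Index(["down", "up", "unchanged", "missed"], name="called"),
    )
    for i, planted in enumerate(truth["status"]):
        called = called_status.get(i, "missed") if recovered[i] else "missed"
        confusion.loc[planted, called] += 1
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "confusion": confusion,
    }
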