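"""PWM scanning and resampling Z-score motif enrichment.

Motif occurrences are counted in target eRNA sequences with a log-odds
scanner whose score-to-p mapping comes from exact dynamic programming
over the discretized score distribution under a 0-order background. The
same count is taken on n (default 100) size-matched sets of regions
resampled from the eRNA catalogue itself — which controls for eRNA
nucleotide composition — and significance is the Z-score

    z = (x - mu) / sigma

with x the observed count and mu, sigma the resample mean and standard
deviation, converted to an upper-tail normal p and BH-adjusted across
motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import GenomicInterval, PWMotif
from .quantify_diff import bh_adjust

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SCORE_BINS = 1000
_SIZE_REL_TOL = 0.25


@dataclass
class EnrichmentResult:
    motif_id: str
    x: int
    mu: float
    sigma: float
    z: float
    p: float
    padj: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class MotifHit:
    seq_index: int
    offset: int
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode(
            "latin1"
        ),
        dtype=np.uint8,
    ).copy()


def get_sequence(genome, iv: GenomicInterval) -> str:
    """Fetch the sequence of an interval from a dict or indexed FASTA."""
    if isinstance(genome, Mapping):
        contig = genome[iv.chrom]
        if iv.end > len(contig):
            raise ValueError(f"{iv.chrom}:{iv.start}-{iv.end} beyond contig end")
        return contig[iv.start : iv.end]
    rec = genome[iv.chrom]
    if iv.end > len(rec):
        raise ValueError(f"{iv.chrom}:{iv.start}-{iv.end} beyond contig end")
    return str(rec[iv.start : iv.end])


def estimate_background(sequences: Sequence[str]) -> np.ndarray:
    """0-order A/C/G/T frequencies of the scanned sequences (N ignored)."""
    counts = np.ones(4)  # +1 regularizer so no frequency is exactly 0
    for seq in sequences:
        enc = _encode(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    return counts / counts.sum()


def _log_odds(motif: PWMotif, background: np.ndarray, pseudocount: float) -> np.ndarray:
    p = motif.matrix + pseudocount * background[None, :]
    p = p / p.sum(axis=1, keepdims=True)
    if (p <= 0).any():
        raise ValueError(
            f"motif {motif.motif_id}: zero probability with no pseudocount; "
            "log-odds undefined"
        )
    return np.log2(p / background[None, :])


def _score_pvalue_table(
    int_scores: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact tail probabilities P(score >= s) under the background model."""
    max_total = int(int_scores.max(axis=1).sum())
    pdf = np.zeros(max_total + 1)
    pdf[0] = 1.0
    for k in range(int_scores.shape[0]):
        new = np.zeros_like(pdf)
        for b in range(4):
            s = int(int_scores[k, b])
            new[s:] += pdf[: len(pdf) - s] * background[b]
        pdf = new
    return np.cumsum(pdf[::-1])[::-1]  # tail sums


def _discretize(log_odds: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Shift/scale log-odds rows to non-negative integers.

    Returns (integer score matrix, scale, per-row offsets); raw score of a
    word maps to ``round((score - offsets.sum()) * scale)`` bin-wise.
    """
    row_min = log_odds.min(axis=1, keepdims=True)
    span = float((log_odds.max(axis=1) - log_odds.min(axis=1)).sum())
    scale = _SCORE_BINS / span if span > 0 else 1.0
    int_scores = np.round((log_odds - row_min) * scale).astype(int)
    return int_scores, scale, row_min[:, 0]


def scan_pwm(
    sequences: Sequence[str],
    motif: PWMotif,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> tuple[int, list[MotifHit]]:
    """Count motif hits over all sequences and both strands.

    A hit is an offset whose log-odds score has exact background
    p-value < ``p_threshold``; windows containing N never match.
    """
    if background is None:
        background = estimate_background(sequences)
    lo = _log_odds(motif, background, pseudocount)
    int_scores, _, _ = _discretize(lo)
    tail = _score_pvalue_table(int_scores, background)
    # critical integer score: smallest s with tail[s] < p_threshold
    crit_candidates = np.flatnonzero(tail < p_threshold)
    if len(crit_candidates) == 0:
        return 0, []
    crit = int(crit_candidates[0])

    # reverse-complement scores share the discretization (same row multiset)
    int_rc = int_scores[::-1, ::-1]
    w = motif.width
    hits: list[MotifHit] = []
    for si, seq in enumerate(sequences):
        L = len(seq)
        if L < w:
            continue
        enc = _encode(seq)
        idx = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (idx != 4).all(axis=1)
        pos = np.arange(w)
        for strand, mat in (("+", int_scores), ("-", int_rc)):
            safe = np.where(idx == 4, 0, idx)
            scores = mat[pos[None, :], safe].sum(axis=1)
            ok = valid & (scores >= crit)
            for off in np.flatnonzero(ok):
                hits.append(
                    MotifHit(
                        seq_index=si,
                        offset=int(off),
                        strand=strand,
                        score=float(scores[off]),
                    )
                )
    return len(hits), hits


def sample_matched_regions(
    target_regions: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    n: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> list[list[GenomicInterval]]:
    """n random size-matched draws from the catalogue, without replacement.

    For each target size the draw picks uniformly among the unused
    catalogue regions whose size lies within 25% of it, falling back to
    the nearest-size unused region(s) when none does. The draw is random
    within the size window — a deterministic nearest-size assignment
    would redraw the targets themselves whenever region sizes are unique,
    collapsing the resampling null.
    """
    if len(universe) < len(target_regions):
        raise ValueError("universe smaller than target set")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sizes = np.array([iv.length() for iv in universe])
    t_sizes = [iv.length() for iv in target_regions]
    resamples: list[list[GenomicInterval]] = []
    for _ in range(n):
        unused = np.ones(len(universe), dtype=bool)
        drawn: list[GenomicInterval] = []
        for t in rng.permutation(len(t_sizes)):
            dist = np.abs(sizes - t_sizes[t]).astype(float)
            dist[~unused] = np.inf
            pool = np.flatnonzero(dist <= _SIZE_REL_TOL * t_sizes[t])
            if len(pool) == 0:
                pool = np.flatnonzero(dist == dist.min())
            choice = int(rng.choice(pool))
            unused[choice] = False
            drawn.append(universe[choice])
        resamples.append(drawn)
    return resamples


def motif_zscore(x: int, resample_counts: Sequence[float]) -> EnrichmentResult:
    """Z-score of the observed count against the resample distribution."""
    counts = np.asarray(resample_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 resample counts")
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=1))
    if sigma == 0:
        degenerate = True
        if x <= mu:
            z, p = 0.0, 1.0
        else:
            z, p = float("inf"), 1e-300
    else:
        degenerate = False
        z = (x - mu) / sigma
        p = float(stats.norm.sf(z))
        p = max(p, 1e-300)
    return EnrichmentResult(
        motif_id="", x=int(x), mu=mu, sigma=sigma, z=float(z), p=p,
        degenerate=degenerate,
    )


def enrich_motifs(
    target_regions: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    motifs: Sequence[PWMotif],
    genome,
    n: int = 100,
    seed: int = 0,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Resampling motif enrichment over the eRNA catalogue background.

    Returns a frame with columns x, mu, sigma, z, p, padj, degenerate,
    indexed by motif id; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    target_seqs = [get_sequence(genome, iv) for iv in target_regions]
    resamples = sample_matched_regions(target_regions, universe, n=n, rng_seed=rng)
    resample_seqs = [
        [get_sequence(genome, iv) for iv in draw] for draw in resamples
    ]
    rows = []
    for motif in motifs:
        x, _ = scan_pwm(target_seqs, motif, p_threshold=p_threshold)
        counts = [
            scan_pwm(seqs, motif, p_threshold=p_threshold)[0]
            for seqs in resample_seqs
        ]
        res = motif_zscore(x, counts)
        res.motif_id = motif.motif_id
        rows.append(res)
    padj = bh_adjust([r.p for r in rows])
    for r, q in zip(rows, padj):
        r.padj = float(q)
    return pd.DataFrame(
        {
            "x": [r.x for r in rows],
            "mu": [r.mu for r in rows],
            "sigma": [r.sigma for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
            "padj": [r.padj for r in rows],
            "degenerate": [r.degenerate for r in rows],
        },
        index=pd.Index([r.motif_id for r in rows], name="motif_id"),
    )


def gc_content(
    regions: Sequence[GenomicInterval], genome
) -> pd.Series:
    """Per-region G+C fraction; N bases excluded from the denominator."""
    vals = []
    ids = []
    for i, iv in enumerate(regions):
        seq = get_sequence(genome, iv).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gc = seq.count("G") + seq.count("C")
        vals.append(gc / acgt if acgt else float("nan"))
        ids.append(f"{iv.chrom}:{iv.start}-{iv.end}")
    return pd.Series(vals, index=ids, name="gc")


def gc_summary(
    target_regions: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
    genome,
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
) -> dict[str, float]:
    """Mean GC of targets, catalogue, and size-matched random genomic spans."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    random_regions = []
    for iv in target_regions:
        size = iv.length()
        for _ in range(50):
            c = chroms[int(rng.choice(len(chroms), p=probs))]
            if chrom_sizes[c] <= size:
                continue
            start = int(rng.integers(0, chrom_sizes[c] - size))
            random_regions.append(GenomicInterval(c, start, start + size))
            break
    return {
        "target_mean_gc": float(np.nanmean(gc_content(target_regions, genome))),
        "universe_mean_gc": float(np.nanmean(gc_content(universe, genome))),
        "random_mean_gc": float(np.nanmean(gc_content(random_regions, genome))),
    }
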