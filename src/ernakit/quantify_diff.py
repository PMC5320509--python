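"""Counting, normalization and HD-vs-WT differential testing.

Counts per region are normalized by median-of-ratios size factors and
tested with a negative-binomial Wald test: per-row method-of-moments
dispersion shrunk 50/50 toward a fitted mean-dispersion trend
``a0/mu + a1``, an NB log-link GLM fitted by iteratively reweighted least
squares with size-factor offsets, a Wald z on the condition coefficient,
and Benjamini-Hochberg adjustment. This is a deliberately simple,
simulation-calibrated stand-in for a full shrinkage-based DE engine; an
externally produced result table can be supplied instead (see
:func:`import_results`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .erna_identification import ERNARecord
from .io_model import GenomicInterval, ReadAlignment

_DISP_FLOOR = 1e-8
_DISP_CAP = 20.0
_BETA_CLAMP = 30.0  # natural-log scale
# Wald reference: t with effective df. The 50/50 moderation toward the
# (essentially noise-free) trend quarters the variance of the dispersion
# estimator, so its effective df is about 4x the residual df
# (Satterthwaite); the normal reference is anti-conservative here.
_EFFECTIVE_DF_FACTOR = 4


def _region_pairs(
    regions: Sequence[ERNARecord] | Sequence[GenomicInterval],
) -> list[tuple[str, GenomicInterval]]:
    pairs = []
    for i, r in enumerate(regions):
        if isinstance(r, ERNARecord):
            pairs.append((r.erna_id, r.interval))
        else:
            pairs.append((f"region_{i:05d}", r))
    return pairs


def count_reads(
    regions: Sequence[ERNARecord] | Sequence[GenomicInterval],
    reads_by_sample: Mapping[str, Sequence[ReadAlignment]],
) -> pd.DataFrame:
    """Count reads per region per sample (strand-ignored, >= 1 bp overlap).

    Regions must be non-overlapping (the post-merge catalogue). A read
    overlapping two regions is assigned to the larger overlap, leftmost
    on ties.
    """
    pairs = _region_pairs(regions)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, (_rid, iv) in enumerate(pairs):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    arr = {}
    for chrom, items in by_chrom.items():
        items.sort()
        starts = np.array([s for s, _, _ in items])
        ends = np.array([e for _, e, _ in items])
        idxs = np.array([i for _, _, i in items])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(
                "count_reads requires non-overlapping regions; "
                "merge candidates first"
            )
        arr[chrom] = (starts, ends, idxs)

    ids = [rid for rid, _ in pairs]
    matrix = pd.DataFrame(
        0, index=pd.Index(ids, name="id"), columns=list(reads_by_sample), dtype=int
    )
    for sample, reads in reads_by_sample.items():
        counts = np.zeros(len(pairs), dtype=int)
        chrom_reads: dict[str, list[tuple[int, int]]] = {}
        for r in reads:
            chrom_reads.setdefault(r.interval.chrom, []).append(
                (r.interval.start, r.interval.end)
            )
        for chrom, spans in chrom_reads.items():
            if chrom not in arr:
                continue
            starts, ends, idxs = arr[chrom]
            r_start = np.array([s for s, _ in spans])
            r_end = np.array([e for _, e in spans])
            lo = np.searchsorted(ends, r_start, side="right")
            hi = np.searchsorted(starts, r_end, side="left")
            nhit = hi - lo
            one = nhit == 1
            np.add.at(counts, idxs[lo[one]], 1)
            for k in np.flatnonzero(nhit > 1):
                cand = slice(lo[k], hi[k])
                ov = np.minimum(ends[cand], r_end[k]) - np.maximum(
                    starts[cand], r_start[k]
                )
                best = int(np.argmax(ov))  # leftmost on tie
                counts[idxs[cand][best]] += 1
        matrix[sample] = counts
    return matrix


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors per sample.

    ``s_j = median_i k_ij / (prod_v k_iv)^(1/m)`` over rows with
    all-positive counts.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no row with all-positive counts; supply a pseudo-reference "
            "explicitly rather than relying on a silent fallback"
        )
    log_counts = np.log(counts[positive])
    log_geo = log_counts.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_counts - log_geo, axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


def _fit_dispersion(norm: np.ndarray, cond_idx: list[np.ndarray]) -> np.ndarray:
    """Per-row dispersion: pooled within-condition MoM, shrunk to trend."""
    n_rows = norm.shape[0]
    raw = np.full(n_rows, np.nan)
    num = np.zeros(n_rows)
    den = np.zeros(n_rows)
    for idx in cond_idx:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        w = len(idx) - 1
        a = np.where(ok, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += np.where(ok, w * a, 0.0)
        den += np.where(ok, w, 0.0)
    valid = den > 0
    raw[valid] = num[valid] / den[valid]
    raw = np.clip(raw, _DISP_FLOOR, _DISP_CAP)

    mu = norm.mean(axis=1)
    fit_rows = valid & (mu > 0)
    if fit_rows.sum() >= 2:
        X = np.column_stack([1.0 / mu[fit_rows], np.ones(fit_rows.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[fit_rows], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = 0.0, float(np.nanmean(raw)) if valid.any() else 0.01
    trend = np.clip(a0 / np.maximum(mu, 1e-12) + a1, _DISP_FLOOR, _DISP_CAP)
    alpha = 0.5 * np.where(valid, raw, trend) + 0.5 * trend
    return np.clip(alpha, _DISP_FLOOR, _DISP_CAP)


def _nb_wald(
    y: np.ndarray, sf: np.ndarray, x: np.ndarray, alpha_disp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row NB log-link IRLS; returns (beta1, se_beta1).

    Design is intercept + condition indicator with log size-factor
    offsets; the Fisher-scoring normal equations are solved in closed
    form (2x2) simultaneously for all rows.
    """
    n_rows, _ = y.shape
    log_sf = np.log(sf)[None, :]
    norm = y / sf[None, :]
    m_ref = norm[:, x == 0].mean(axis=1)
    m_alt = norm[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(m_ref, 0.1))
    b1 = np.log(np.maximum(m_alt, 0.1)) - b0
    xb = x[None, :]
    a = alpha_disp[:, None]
    for _ in range(100):
        eta = b0[:, None] + b1[:, None] * xb + log_sf
        mu = np.exp(np.clip(eta, -700, 50))
        w = mu / (1.0 + a * mu)
        z = eta - log_sf + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * xb).sum(axis=1)
        swxx = (w * xb * xb).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * xb * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        nb0 = np.clip(nb0, -_BETA_CLAMP, _BETA_CLAMP)
        nb1 = np.clip(nb1, -_BETA_CLAMP, _BETA_CLAMP)
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if delta.max() < 1e-10:
            break
    eta = b0[:, None] + b1[:, None] * xb + log_sf
    mu = np.exp(np.clip(eta, -700, 50))
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * xb).sum(axis=1)
    swxx = (w * xb * xb).sum(axis=1)
    det = sw * swxx - swx**2
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    se1 = np.sqrt(np.maximum(sw / det, 0.0))
    return b1, se1


def differential_test(
    matrix: pd.DataFrame,
    condition_labels: Mapping[str, str],
    alpha: float = 0.05,
    reference: str = "WT",
) -> pd.DataFrame:
    """NB Wald differential test per row (test condition vs reference).

    Returns a frame indexed like ``matrix`` with columns base_mean,
    log2fc, se_log2fc, wald_p, padj and status. All-zero rows are
    excluded from testing and carry NaN statistics.
    """
    conds = [condition_labels[c] for c in matrix.columns]
    levels = sorted(set(conds))
    if len(levels) != 2:
        raise ValueError(f"exactly two conditions required, got {levels}")
    if reference not in levels:
        reference = levels[0]
    test_level = next(l for l in levels if l != reference)
    x = np.array([0 if c == reference else 1 for c in conds])
    for lvl in levels:
        if sum(c == lvl for c in conds) < 2:
            raise ValueError(f"condition {lvl!r} has fewer than 2 samples")

    y_all = matrix.to_numpy(dtype=float)
    sf = size_factors(matrix).to_numpy()
    norm_all = y_all / sf[None, :]
    nonzero = y_all.sum(axis=1) > 0

    res = pd.DataFrame(
        index=matrix.index,
        columns=["base_mean", "log2fc", "se_log2fc", "wald_p", "padj"],
        dtype=float,
    )
    res["base_mean"] = norm_all.mean(axis=1)
    if nonzero.any():
        y = y_all[nonzero]
        norm = norm_all[nonzero]
        cond_idx = [np.flatnonzero(x == 0), np.flatnonzero(x == 1)]
        alpha_disp = _fit_dispersion(norm, cond_idx)
        b1, se1 = _nb_wald(y, sf, x, alpha_disp)
        ln2 = np.log(2.0)
        wald_z = b1 / np.where(se1 > 0, se1, np.inf)
        eff_df = _EFFECTIVE_DF_FACTOR * (len(conds) - 2)
        wald_p = 2.0 * stats.t.sf(np.abs(wald_z), df=eff_df)
        res.loc[nonzero, "log2fc"] = b1 / ln2
        res.loc[nonzero, "se_log2fc"] = se1 / ln2
        res.loc[nonzero, "wald_p"] = wald_p
        res.loc[nonzero, "padj"] = bh_adjust(wald_p)
    res.attrs["test_level"] = test_level
    res.attrs["reference"] = reference
    res["status"] = classify_status(res, alpha=alpha)
    return res


def classify_status(results: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """down / up / unchanged from padj and log2fc sign."""
    padj = results["padj"]
    lfc = results["log2fc"]
    status = pd.Series("unchanged", index=results.index, name="status")
    status[(padj < alpha) & (lfc < 0)] = "down"
    status[(padj < alpha) & (lfc > 0)] = "up"
    return status


def import_results(path: str, alpha: float = 0.05) -> pd.DataFrame:
    """Load an externally produced DE table (id, base_mean, log2fc, padj).

    Bypass seam so a full shrinkage-based DE engine's output can replace
    the built-in test downstream.
    """
    res = pd.read_csv(path, sep="\t", index_col=0)
    required = {"base_mean", "log2fc", "padj"}
    missing = required - set(res.columns)
    if missing:
        raise ValueError(f"imported DE table missing columns: {sorted(missing)}")
    if "wald_p" not in res.columns:
        res["wald_p"] = res["padj"]
    res["status"] = classify_status(res, alpha=alpha)
    return res
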