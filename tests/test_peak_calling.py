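import numpy as np
import pytest
from scipy import stats

from ernakit.io_model import GenomicInterval, ReadAlignment
from ernakit.peak_calling import (
    IslandCallParams,
    PeakCallParams,
    _windows_to_islands,
    call_islands,
    call_peaks,
    estimate_shift,
)


def read(start, end, strand, chrom="chr1"):
    return ReadAlignment(GenomicInterval(chrom, start, end, strand))


class TestEstimateShift:
    def test_exact_offset_recovered(self):
        rng = np.random.default_rng(0)
        reads = []
        for p in rng.integers(100, 5000, size=300):
            p = int(p)
            reads.append(read(p, p + 50, "+"))
            # minus-strand 5' end (end-1) placed exactly 146 bp downstream
            reads.append(read(p + 146 - 49, p + 147, "-"))
        assert estimate_shift(reads) == 73

    def test_identical_profiles_give_zero(self):
        rng = np.random.default_rng(1)
        reads = []
        for p in rng.integers(100, 2000, size=100):
            p = int(p)
            reads.append(read(p, p + 50, "+"))
            reads.append(read(p - 49, p + 1, "-"))
        assert estimate_shift(reads) == 0

    def test_planted_fragment_length(self):
        # 200 bp fragments covering point sources: strand 5' profiles
        # separate by the fragment length, so the shift is half of it
        rng = np.random.default_rng(2)
        reads = []
        for site in rng.integers(500, 50000, size=100):
            for _ in range(100):
                s = int(site) - int(rng.integers(0, 200))
                if rng.random() < 0.5:
                    reads.append(read(s, s + 50, "+"))
                else:
                    reads.append(read(s + 150, s + 200, "-"))
        assert abs(estimate_shift(reads) - 100) <= 5

    def test_single_strand_errors(self):
        with pytest.raises(ValueError, match="both strands"):
            estimate_shift([read(0, 50, "+")])


def _brute_peaks(reads, params, chrom_len):
    """Naive per-position re-derivation of the Poisson caller."""
    ext = 2 * params.shift if params.shift > 0 else reads[0].interval.length()
    cover = np.zeros(chrom_len, dtype=int)
    for r in reads:
        fp = r.interval.start if r.interval.strand == "+" else r.interval.end - 1
        c = fp + params.shift if r.interval.strand == "+" else fp - params.shift
        s, e = max(0, c - ext // 2), min(chrom_len, c - ext // 2 + ext)
        cover[s:e] += 1
    lam = len(reads) * ext / params.effective_genome_size
    sig = stats.poisson.sf(cover - 1, lam) < params.p_threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
    runs = list(zip(edges[::2].tolist(), edges[1::2].tolist()))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= ext:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged], cover, lam


class TestCallPeaks:
    def _toy(self, seed=0, n_bg=100, stack=30, site=5000):
        rng = np.random.default_rng(seed)
        reads = [
            read(int(s), int(s) + 50, rng.choice(["+", "-"]))
            for s in rng.integers(0, 9900, size=n_bg)
        ]
        reads += [read(site, site + 50, "+") for _ in range(stack)]
        return reads

    def test_planted_site_is_sole_peak(self):
        reads = self._toy()
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        peaks = call_peaks(reads, params, {"chr1": 10000})
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 5050 <= peaks[0].interval.end

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        reads = self._toy(seed=seed, n_bg=int(rng.integers(50, 200)),
                          stack=int(rng.integers(15, 40)),
                          site=int(rng.integers(1000, 9000)))
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        peaks = call_peaks(reads, params, {"chr1": 10000})
        want, cover, lam = _brute_peaks(reads, params, 10000)
        got = [(p.interval.start, p.interval.end) for p in peaks]
        assert got == want
        for p in peaks:
            assert stats.poisson.sf(cover[p.summit] - 1, lam) < params.p_threshold

    def test_zero_reads_zero_peaks(self):
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        assert call_peaks([], params, {"chr1": 10000}) == []

    def test_local_lambda_subset_of_global(self):
        rng = np.random.default_rng(5)
        # broad local bump: many reads scattered over 2 kb around the site
        reads = self._toy(seed=5, n_bg=100, stack=12)
        reads += [
            read(int(s), int(s) + 50, "+")
            for s in rng.integers(4000, 6000, size=150)
        ]
        base = dict(shift=50, effective_genome_size=10000)
        glob = call_peaks(reads, PeakCallParams(mode="global_background", **base),
                          {"chr1": 10000})
        loc = call_peaks(reads, PeakCallParams(mode="local_lambda", **base),
                         {"chr1": 10000})
        glob_spans = [(p.interval.start, p.interval.end) for p in glob]
        for p in loc:
            assert any(
                p.interval.start >= s and p.interval.end <= e for s, e in glob_spans
            )
        assert len(loc) <= len(glob)

    def test_peaks_non_overlapping(self):
        reads = self._toy(seed=9, n_bg=300, stack=25)
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        peaks = sorted(
            call_peaks(reads, params, {"chr1": 10000}),
            key=lambda p: p.interval.start,
        )
        for a, b in zip(peaks, peaks[1:]):
            assert a.interval.end <= b.interval.start

    def test_duplicated_stack_keeps_peak(self):
        reads = self._toy()
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        doubled = reads + [
            ReadAlignment(r.interval, n_blocks=r.n_blocks) for r in reads
        ]
        peaks = call_peaks(doubled, params, {"chr1": 10000})
        assert any(
            p.interval.start <= 5050 <= p.interval.end for p in peaks
        )

    def test_bad_genome_size_errors(self):
        params = PeakCallParams(shift=50, effective_genome_size=10000)
        params.effective_genome_size = 0
        with pytest.raises(ValueError):
            call_peaks(self._toy(), params, {"chr1": 10000})


def _brute_merge(indices, window, gap):
    """Quadratic merge oracle on eligible window indices."""
    indices = sorted(indices)
    if not indices:
        return []
    groups = [[indices[0]]]
    for i in indices[1:]:
        # ineligible stretch between consecutive eligible windows
        if (i - groups[-1][-1] - 1) * window <= gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1]) for g in groups]


class TestCallIslands:
    def _reads_in_windows(self, window_offsets, per_window=10):
        reads = []
        for off in window_offsets:
            for k in range(per_window):
                s = off + 3 * k  # distinct starts: survive deduplication
                reads.append(read(s, s + 50, "+"))
        return reads

    def test_gap600_merges_all_three(self):
        reads = self._reads_in_windows([0, 400, 1200])
        params = IslandCallParams(window=200, gap=600)
        islands = call_islands(reads, None, params, {"chr1": 1_000_000})
        assert [(i.interval.start, i.interval.end) for i in islands] == [(0, 1400)]

    def test_gap200_splits(self):
        reads = self._reads_in_windows([0, 400, 1200])
        params = IslandCallParams(window=200, gap=200)
        islands = call_islands(reads, None, params, {"chr1": 1_000_000})
        # the eligible windows start at 0, 400 and 1200; with a 200 bp gap
        # the first two merge into [0, 600) and the third stands alone
        assert [(i.interval.start, i.interval.end) for i in islands] == [
            (0, 600),
            (1200, 1400),
        ]

    def test_uniform_background_bounded_by_e_value(self):
        rng = np.random.default_rng(0)
        reads = [
            read(int(s), int(s) + 50, rng.choice(["+", "-"]))
            for s in rng.integers(0, 999_000, size=20000)
        ]
        params = IslandCallParams()
        islands = call_islands(reads, None, params, {"chr1": 1_000_000})
        assert len(islands) <= params.e_value

    @pytest.mark.parametrize("seed", range(10))
    def test_window_merge_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        idx = np.unique(rng.integers(0, 100, size=rng.integers(1, 30)))
        window = int(rng.choice([100, 200]))
        gap = window * int(rng.integers(0, 5))
        got = _windows_to_islands(idx, window, gap)
        assert got == _brute_merge(idx.tolist(), window, gap)

    def test_gap_zero_is_maximal_runs(self):
        got = _windows_to_islands(np.array([0, 1, 2, 5, 7, 8]), 200, 0)
        assert got == [(0, 2), (5, 5), (7, 8)]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            IslandCallParams(window=0)
        with pytest.raises(ValueError):
            IslandCallParams(window=200, gap=500)  # not a multiple
        with pytest.raises(ValueError):
            IslandCallParams(effective_genome_fraction=0)

    def test_control_filters_islands(self):
        # chip enrichment at one locus; control matching another locus
        chip = self._reads_in_windows([0, 5000], per_window=15)
        control = self._reads_in_windows([5000], per_window=15)
        params = IslandCallParams(fdr=0.05)
        with_ctrl = call_islands(chip, control, params, {"chr1": 1_000_000})
        starts = {i.interval.start for i in with_ctrl}
        assert 0 in starts and 5000 not in starts
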