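import numpy as np
import pytest

from conftest import pwm_from_consensus
from ernakit.io_model import GenomicInterval, PWMotif
from ernakit.motif_enrichment import (
    _discretize,
    _log_odds,
    enrich_motifs,
    estimate_background,
    gc_content,
    gc_summary,
    motif_zscore,
    sample_matched_regions,
    scan_pwm,
)

RC = str.maketrans("ACGT", "TGCA")


def rand_seq(rng, n, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=n))


class TestScanPWM:
    def test_planted_consensus_is_hit(self):
        # width >= 8 so the exact background p of the consensus can clear
        # the 1e-4 default threshold (4^-8 ~ 1.5e-5)
        rng = np.random.default_rng(0)
        pwm = pwm_from_consensus("ACGTTGCA", "m")
        seq = rand_seq(rng, 50)
        planted = seq[:20] + "ACGTTGCA" + seq[28:]
        count, hits = scan_pwm([planted], pwm)
        assert count >= 1
        assert any(h.offset == 20 and h.strand == "+" for h in hits)

    def test_sequence_shorter_than_motif(self):
        pwm = pwm_from_consensus("ACGTACGT", "m")
        assert scan_pwm(["ACG"], pwm)[0] == 0

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(1)
        pwm = pwm_from_consensus("ACGGTA", "m")
        seq = rand_seq(rng, 120)
        planted = seq[:40] + "ACGGTA" + seq[46:]
        rc = planted[::-1].translate(RC)
        bg = np.full(4, 0.25)
        assert scan_pwm([planted], pwm, background=bg)[0] == scan_pwm(
            [rc], pwm, background=bg
        )[0]

    def test_window_with_n_never_matches(self):
        pwm = pwm_from_consensus("ACGT", "m", strength=0.97)
        bg = np.full(4, 0.25)
        # sanity: without N this threshold does admit consensus hits
        assert scan_pwm(["ACGTACGT"], pwm, p_threshold=0.05, background=bg)[0] > 0
        count, _ = scan_pwm(["ACNT" * 3], pwm, p_threshold=0.05, background=bg)
        assert count == 0

    def test_zero_probability_without_pseudocount_errors(self):
        m = PWMotif("m", np.tile([1.0, 0, 0, 0], (4, 1)))
        with pytest.raises(ValueError, match="pseudocount"):
            scan_pwm(["AAAAAA"], m, pseudocount=0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_hit_set_matches_word_enumeration(self, seed):
        """DP score-to-p and the vectorized scan vs brute enumeration."""
        rng = np.random.default_rng(seed)
        w = int(rng.integers(4, 8))
        mat = rng.dirichlet(np.ones(4) * 0.4, size=w)
        pwm = PWMotif(f"m{seed}", mat)
        seqs = [rand_seq(rng, int(rng.integers(w, 200))) for _ in range(3)]
        bg = estimate_background(seqs)
        p_thr = 10 ** float(rng.uniform(-4, -1.5))
        count, hits = scan_pwm(seqs, pwm, p_threshold=p_thr, background=bg)

        lo = _log_odds(pwm, bg, 1e-3)
        int_scores, _, _ = _discretize(lo)
        # exact tail by enumerating every length-w word
        words = np.stack(
            np.meshgrid(*[np.arange(4)] * w, indexing="ij"), axis=-1
        ).reshape(-1, w)
        word_scores = int_scores[np.arange(w), words].sum(axis=1)
        word_probs = np.prod(bg[words], axis=1)

        def exact_p(s):
            return word_probs[word_scores >= s].sum()

        int_rc = int_scores[::-1, ::-1]
        brute = set()
        enc = {"A": 0, "C": 1, "G": 2, "T": 3}
        for si, seq in enumerate(seqs):
            for off in range(len(seq) - w + 1):
                window = [enc[b] for b in seq[off : off + w]]
                for strand, mat_i in (("+", int_scores), ("-", int_rc)):
                    s = sum(mat_i[k, b] for k, b in enumerate(window))
                    if exact_p(s) < p_thr:
                        brute.add((si, off, strand))
        got = {(h.seq_index, h.offset, h.strand) for h in hits}
        assert got == brute
        assert count == len(brute)


class TestSampleMatchedRegions:
    def _ivs(self, sizes):
        out, pos = [], 0
        for s in sizes:
            out.append(GenomicInterval("chr1", pos, pos + s))
            pos += s + 1000
        return out

    def test_exact_sizes_always_drawn(self):
        targets = self._ivs([200, 500])
        universe = self._ivs([200, 500, 900])
        for draw in sample_matched_regions(targets, universe, n=20, rng_seed=0):
            assert sorted(iv.length() for iv in draw) == [200, 500]

    def test_target_equals_universe_is_identity(self):
        universe = self._ivs([100, 300, 700])
        for draw in sample_matched_regions(universe, universe, n=10, rng_seed=1):
            assert sorted((iv.start, iv.end) for iv in draw) == sorted(
                (iv.start, iv.end) for iv in universe
            )

    def test_fixed_seed_is_deterministic(self):
        targets = self._ivs([150, 420])
        universe = self._ivs([100, 160, 400, 440, 800])
        a = sample_matched_regions(targets, universe, n=5, rng_seed=7)
        b = sample_matched_regions(targets, universe, n=5, rng_seed=7)
        assert a == b

    def test_draws_vary_across_resamples(self):
        targets = self._ivs([1000])
        universe = self._ivs([1000, 1050, 1100, 950, 900])
        draws = sample_matched_regions(targets, universe, n=50, rng_seed=3)
        assert len({d[0].start for d in draws}) > 1

    def test_small_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            sample_matched_regions(self._ivs([10, 20]), self._ivs([10]), n=2)


class TestMotifZscore:
    def test_formula(self):
        rng = np.random.default_rng(0)
        counts = rng.normal(5, 2, size=400)
        res = motif_zscore(12, counts)
        assert res.z == pytest.approx((12 - counts.mean()) / counts.std(ddof=1))

    def test_x_at_mean_gives_half(self):
        res = motif_zscore(5, [4, 5, 6, 5])
        assert res.z == 0 and res.p == pytest.approx(0.5)

    def test_identity_z_sigma_mu(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.poisson(8, size=30)
            x = int(rng.poisson(8))
            res = motif_zscore(x, counts)
            if not res.degenerate:
                assert res.z * res.sigma + res.mu == pytest.approx(x, abs=1e-9)

    def test_degenerate_sd_zero(self):
        res = motif_zscore(3, [3, 3, 3])
        assert res.degenerate and res.p == 1.0
        res = motif_zscore(9, [3, 3, 3])
        assert res.degenerate and res.p < 1e-200

    def test_too_few_resamples(self):
        with pytest.raises(ValueError):
            motif_zscore(1, [2])


class TestEnrichMotifs:
    def _toy_world(self, rng, n_universe=60, size=300, planted_frac=0.5,
                   consensus="CCATATTAGG"):
        genome = {}
        universe = []
        n_targets = 16
        for i in range(n_universe):
            seq = rand_seq(rng, size)
            if i < n_targets * planted_frac:  # motif only in target regions
                seq = seq[: size // 2] + consensus + seq[size // 2 + len(consensus):]
            genome[f"c{i}"] = seq
            universe.append(GenomicInterval(f"c{i}", 0, size))
        return genome, universe[:n_targets], universe

    def test_planted_motif_enriched_decoy_not(self):
        rng = np.random.default_rng(5)
        genome, targets, universe = self._toy_world(rng)
        motifs = [
            pwm_from_consensus("CCATATTAGG", "planted"),
            pwm_from_consensus("TGACGTCA", "decoy"),
        ]
        table = enrich_motifs(targets, universe, motifs, genome, n=100, seed=2)
        assert table.loc["planted", "padj"] < 0.05
        assert table.loc["decoy", "padj"] > 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        genome, targets, universe = self._toy_world(rng)
        motifs = [pwm_from_consensus("CCATATTAGG", "m")]
        a = enrich_motifs(targets, universe, motifs, genome, n=20, seed=9)
        b = enrich_motifs(targets, universe, motifs, genome, n=20, seed=9)
        assert a.equals(b)

    def test_minimum_two_resamples_runs(self):
        rng = np.random.default_rng(7)
        genome, targets, universe = self._toy_world(rng, n_universe=30)
        motifs = [pwm_from_consensus("ACGTAC", "m")]
        table = enrich_motifs(targets, universe, motifs, genome, n=2, seed=0)
        assert len(table) == 1


class TestGCContent:
    def test_simple_fraction(self):
        genome = {"c": "ACGT"}
        vals = gc_content([GenomicInterval("c", 0, 4)], genome)
        assert vals.iloc[0] == 0.5

    def test_all_n_is_missing(self):
        genome = {"c": "NNNN"}
        vals = gc_content([GenomicInterval("c", 0, 4)], genome)
        assert np.isnan(vals.iloc[0])

    def test_region_beyond_contig_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            gc_content([GenomicInterval("c", 0, 10)], {"c": "ACGT"})

    def test_planted_gc_separation(self, small_dataset):
        ds = small_dataset
        enh = [
            GenomicInterval(t.chrom, t.start, t.end)
            for t in ds.truth.itertuples(index=False)
        ]
        out = gc_summary(enh, enh, ds.genome, ds.chrom_sizes, seed=0)
        sep = out["target_mean_gc"] - out["random_mean_gc"]
        cfg = ds.config
        assert sep == pytest.approx(cfg.enhancer_gc - cfg.background_gc, abs=0.03)
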