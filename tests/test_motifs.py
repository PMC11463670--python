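from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pgcmultiome.core import GenomicInterval, PeakSet, ValidationError
from pgcmultiome import motifs as mt


def _consensus_pwm(cons: str, count: float = 20.0) -> mt.Pwm:
    pfm = np.ones((4, len(cons)))
    for j, b in enumerate(cons):
        pfm["ACGT".index(b), j] = count
    return mt.pfm_to_pwm(pfm, "M1", "TF1")


class TestPfmToPwm:
    def test_uniform_pfm_all_zero(self):
        pwm = mt.pfm_to_pwm(np.ones((4, 5)))
        np.testing.assert_allclose(pwm.matrix, 0.0, atol=1e-12)
        assert pwm.max_score == pytest.approx(0.0)

    def test_single_base_column_closed_form(self):
        c = 10.0
        pfm = np.zeros((4, 1))
        pfm[0, 0] = c
        pwm = mt.pfm_to_pwm(pfm, pseudocount=0.8)
        expected = np.log2((c + 0.2) / (c + 0.8) / 0.25)
        assert pwm.matrix[0, 0] == pytest.approx(expected)
        assert pwm.max_score == pytest.approx(expected)

    def test_matches_independent_loop(self, rng):
        pfm = rng.integers(0, 25, size=(4, 8)).astype(float) + 0.5
        pwm = mt.pfm_to_pwm(pfm, pseudocount=0.8)
        for b in range(4):
            for j in range(8):
                expected = np.log2(
                    ((pfm[b, j] + 0.8 * 0.25) / (pfm[:, j].sum() + 0.8)) / 0.25
                )
                assert pwm.matrix[b, j] == pytest.approx(expected)

    def test_zero_column_rejected(self):
        pfm = np.ones((4, 3))
        pfm[:, 1] = 0
        with pytest.raises(ValidationError):
            mt.pfm_to_pwm(pfm)


def _brute_scan(seq, pwm, frac=0.8):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[b] for b in reversed(seq))
    L = pwm.length
    hits = set()
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(len(s) - L + 1):
            score = 0.0
            for j, b in enumerate(s[off : off + L]):
                if b != "N":
                    score += pwm.matrix["ACGT".index(b), j]
            if score >= frac * pwm.max_score - 1e-12:
                o = off if strand == "+" else len(seq) - L - off
                hits.add((strand, o))
    return hits


class TestScanSequences:
    def test_consensus_exact_hit(self):
        pwm = _consensus_pwm("ACGTACGT")
        hits = mt.scan_sequences({"p": "ACGTACGT"}, pwm)
        fwd = hits[hits["strand"] == "+"]
        assert len(fwd) == 1
        assert fwd.iloc[0]["offset"] == 0
        assert fwd.iloc[0]["score"] == pytest.approx(pwm.max_score)

    def test_all_n_no_hits(self):
        pwm = _consensus_pwm("ACGT")
        assert len(mt.scan_sequences({"p": "N" * 30}, pwm)) == 0

    def test_short_sequence_no_error(self):
        pwm = _consensus_pwm("ACGTACGTAC")
        assert len(mt.scan_sequences({"p": "ACG"}, pwm)) == 0

    def test_matches_bruteforce_both_strands(self, rng):
        pwm = mt.pfm_to_pwm(rng.integers(1, 15, size=(4, 5)).astype(float), "M", "M")
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGTN"), 60))
            got = mt.scan_sequences({"p": seq}, pwm, threshold_frac=0.6)
            got_set = set(zip(got["strand"], got["offset"]))
            assert got_set == _brute_scan(seq, pwm, 0.6)


class TestMatchedBackground:
    def _peaks(self, gc, acc):
        n = len(gc)
        return PeakSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 300) for i in range(n)],
            np.asarray(gc), np.asarray(acc),
        )

    def test_single_stratum_foreground(self, rng):
        gc = np.concatenate([np.full(30, 0.30), np.linspace(0.5, 0.9, 170)])
        acc = np.ones(200)
        peaks = self._peaks(gc, acc)
        fg = np.arange(10)  # all in the low-GC stratum
        bg = mt.matched_background_peaks(fg, peaks, 15, seed=1)
        assert set(bg).isdisjoint(set(fg))
        assert (gc[bg] <= 0.35).all()

    def test_quality_beats_uniform_draw(self, rng):
        gc = rng.uniform(0.2, 0.8, 500)
        acc = rng.uniform(0.1, 3, 500)
        peaks = self._peaks(gc, acc)
        fg = np.flatnonzero(gc > 0.6)[:60]
        bins = np.clip(((gc - 0.2) / 0.6 * 10).astype(int), 0, 9)

        def chi2(idx):
            h1 = np.bincount(bins[fg], minlength=10) / len(fg)
            h2 = np.bincount(bins[idx], minlength=10) / len(idx)
            return ((h1 - h2) ** 2 / np.maximum(h1 + h2, 1e-9)).sum()

        wins = 0
        for seed in range(20):
            matched = mt.matched_background_peaks(fg, peaks, 60, seed=seed)
            r2 = np.random.default_rng(seed)
            uniform = r2.choice(np.setdiff1d(np.arange(500), fg), 60, replace=False)
            wins += chi2(matched) < chi2(uniform)
        assert wins >= 16


class TestMotifEnrichment:
    def test_closed_form_extreme(self):
        H = sp.csr_matrix(np.zeros((100, 1)))
        H[:10, 0] = 1
        out = mt.motif_enrichment(np.arange(10), np.arange(10, 100), H, ["m"])
        assert out.loc[0, "p_value"] == pytest.approx(1 / comb(100, 10))

    def test_equal_rates_not_enriched(self):
        H = sp.csr_matrix(np.zeros((100, 1)))
        H[::10, 0] = 1  # 10% in fg and bg alike
        out = mt.motif_enrichment(np.arange(50), np.arange(50, 100), H, ["m"])
        assert out.loc[0, "p_value"] >= 0.5

    def test_matches_exact_enumeration_small_universe(self, rng):
        """Hypergeometric p equals direct enumeration of fg subsets on a
        12-peak universe."""
        hits = rng.random(12) < 0.5
        H = sp.csr_matrix(hits.astype(float).reshape(-1, 1))
        fg, bg = np.arange(5), np.arange(5, 12)
        out = mt.motif_enrichment(fg, bg, H, ["m"])
        k_obs = hits[fg].sum()
        total = 0
        extreme = 0
        for combo in combinations(range(12), 5):
            total += 1
            if hits[list(combo)].sum() >= k_obs:
                extreme += 1
        assert out.loc[0, "p_value"] == pytest.approx(extreme / total)

    def test_empty_foreground_rejected(self):
        H = sp.csr_matrix(np.zeros((10, 1)))
        with pytest.raises(ValidationError):
            mt.motif_enrichment(np.array([]), np.arange(10), H, ["m"])


class TestChromvarDeviations:
    def _peaks(self, n, rng):
        return PeakSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 300) for i in range(n)],
            rng.uniform(0.3, 0.7, n), rng.uniform(0.5, 2, n),
        )

    def test_proportional_counts_zero_deviation(self, rng):
        n_peaks, n_cells = 50, 30
        e = rng.uniform(1, 5, n_peaks)
        depth = rng.integers(50, 200, n_cells)
        C = sp.csr_matrix(np.outer(e / e.sum(), depth) * e.sum())
        H = sp.csr_matrix((rng.random((n_peaks, 2)) < 0.3).astype(float))
        dev = mt.chromvar_deviations(
            C, H, self._peaks(n_peaks, rng), ["a", "b"],
            [f"c{i}" for i in range(n_cells)], n_iterations=5, seed=0,
        )
        np.testing.assert_allclose(dev.raw, 0.0, atol=1e-10)

    def test_raw_matches_dense_loop(self, rng):
        n_peaks, n_cells = 40, 25
        C = sp.csr_matrix(rng.poisson(2, size=(n_peaks, n_cells)).astype(float))
        H = sp.csr_matrix((rng.random((n_peaks, 3)) < 0.25).astype(float))
        dev = mt.chromvar_deviations(
            C, H, self._peaks(n_peaks, rng), ["a", "b", "c"],
            [f"c{i}" for i in range(n_cells)], n_iterations=3, seed=0,
        )
        Cd, Hd = C.toarray(), H.toarray()
        T = Cd.sum(axis=0)
        e = Cd.sum(axis=1) / Cd.sum()
        for k in range(3):
            for i in range(n_cells):
                obs = Cd[Hd[:, k] > 0, i].sum()
                exp = T[i] * e[Hd[:, k] > 0].sum()
                assert dev.raw[k, i] == pytest.approx((obs - exp) / exp, abs=1e-10)

    def test_planted_active_population_positive_z(self):
        """Cells with doubled counts in motif peaks get mean z > 1 and
        above the null population, across 20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_peaks, n_cells = 300, 200
            base = rng.uniform(1, 4, n_peaks)
            motif_peaks = rng.choice(n_peaks, 40, replace=False)
            rates = np.tile(base[:, None], (1, n_cells))
            active = np.arange(n_cells) < 100
            rates[np.ix_(motif_peaks, active)] *= 2
            C = sp.csr_matrix(rng.poisson(rates).astype(float))
            H = sp.lil_matrix((n_peaks, 1))
            H[motif_peaks, 0] = 1
            dev = mt.chromvar_deviations(
                C, sp.csr_matrix(H), self._peaks(n_peaks, rng), ["m"],
                [f"c{i}" for i in range(n_cells)], n_iterations=50, seed=seed,
            )
            z = dev.z[0]
            wins += int(z[active].mean() > 1 and z[active].mean() > z[~active].mean())
        assert wins == 20

    def test_null_z_calibration(self, rng):
        """Exchangeable null counts give per-motif z with small mean and
        sd near 1 across >= 500 cells."""
        n_peaks, n_cells = 300, 500
        base = rng.uniform(0.5, 3, n_peaks)
        C = sp.csr_matrix(rng.poisson(np.tile(base[:, None], (1, n_cells))).astype(float))
        H = sp.lil_matrix((n_peaks, 5))
        for k in range(5):
            H[rng.choice(n_peaks, 15, replace=False), k] = 1
        dev = mt.chromvar_deviations(
            C, sp.csr_matrix(H), self._peaks(n_peaks, rng), list("abcde"),
            [f"c{i}" for i in range(n_cells)], n_iterations=50, seed=1,
        )
        for k in range(5):
            z = dev.z[k][np.isfinite(dev.z[k])]
            assert abs(z.mean()) < 0.15
            assert 0.8 <= z.std() <= 1.2
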