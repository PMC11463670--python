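from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import hypergeom, kstest, rankdata

from pgcmultiome.core import GenomicInterval, PeakSet, ValidationError, make_gene_table
from pgcmultiome import differential as de
from pgcmultiome import embed


def exact_u_oracle(x, y):
    """Independent exhaustive enumeration of the two-sided rank-sum p."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    n1, n = len(x), len(pooled)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * (n - n1) / 2
    count = 0
    for combo in combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / comb(n, n1)


class TestWilcoxon:
    def test_textbook_separation(self):
        assert de.wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert de.wilcoxon_test([2, 2, 2], [2, 2, 2]) == 1.0

    @pytest.mark.parametrize("trial", range(20))
    def test_exact_matches_enumeration_with_ties(self, trial, rng):
        n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        x = rng.integers(0, 4, n1).astype(float)  # heavy ties
        y = rng.integers(0, 4, n2).astype(float)
        assert de.wilcoxon_test(x, y) == pytest.approx(exact_u_oracle(x, y))

    def test_normal_approx_close_to_exact_at_boundary(self, rng):
        diffs = []
        for _ in range(30):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.3, 1, 8)
            p_exact = de.wilcoxon_test(x, y)
            ranks = rankdata(np.concatenate([x, y]))
            u1 = ranks[:8].sum() - 36
            p_norm = de._normal_u_p(ranks, 8, 8, u1)
            diffs.append(abs(p_exact - p_norm))
        assert np.median(diffs) < 2e-2

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            de.wilcoxon_test([], [1.0])


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert de.log2_fold_change(np.array([2.0]), np.array([2.0]))[0] == 0.0

    def test_closed_form(self):
        assert de.log2_fold_change(np.array([3.0]), np.array([1.0]))[0] == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(0, 10, 20), rng.uniform(0, 10, 20)
        np.testing.assert_allclose(
            de.log2_fold_change(a, b), -de.log2_fold_change(b, a), atol=1e-12
        )


class TestBhAdjust:
    def test_stepup_hand_computation(self):
        np.testing.assert_allclose(
            de.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_value_unchanged(self):
        assert de.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        q = de.bh_adjust(p)
        q_perm = de.bh_adjust(p[perm])
        np.testing.assert_allclose(q[perm], q_perm, atol=1e-12)

    def test_matches_stepup_definition(self, rng):
        p = rng.uniform(0, 1, 40)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        q_expected = np.empty(m)
        q_expected[order] = np.minimum(q_sorted, 1)
        np.testing.assert_allclose(de.bh_adjust(p), q_expected, atol=1e-12)


class TestFindMarkers:
    def test_planted_gene_is_top_marker(self, rng):
        n_genes, n = 100, 80
        counts = rng.poisson(3, size=(n_genes, 2 * n))
        counts[10, :n] += 12
        C = sp.csr_matrix(counts)
        N = embed.lognormalize(C)
        g1 = np.zeros(2 * n, dtype=bool)
        g1[:n] = True
        res = de.find_markers(C, N, [f"g{i}" for i in range(n_genes)], g1, ~g1)
        assert res.iloc[0]["feature"] == "g10"
        assert res.iloc[0]["significant"]

    def test_low_pct_feature_not_tested(self):
        counts = np.zeros((2, 100))
        counts[0, :10] = 5  # expressed in 10% < min_pct
        counts[1, :] = 3
        C = sp.csr_matrix(counts)
        N = embed.lognormalize(C)
        g1 = np.arange(100) < 50
        res = de.find_markers(C, N, ["rare", "common"], g1, ~g1, min_pct=0.25, logfc_threshold=0.0)
        assert "rare" not in set(res["feature"])

    def test_label_permutation_kills_signal(self, small_ds, rng):
        cells = small_ds.truth.cells.set_index("barcode")
        pgc = (
            (cells["population"] == "PGC") & ~cells["is_doublet"]
        ).reindex(small_ds.rna.cell_ids).to_numpy()
        C = small_ds.rna.values[:, pgc]
        N = embed.lognormalize(C)
        n = C.shape[1]
        perm = rng.permutation(n)
        g1 = np.zeros(n, dtype=bool)
        g1[perm[: n // 2]] = True
        res = de.find_markers(
            C, N, small_ds.rna.feature_ids, g1, ~g1, min_pct=0.0, logfc_threshold=0.0
        )
        assert (res["p_value"] < 0.05).mean() <= 0.08

    def test_cluster_renaming_permutes_blocks(self, rng):
        counts = rng.poisson(2, size=(50, 90))
        counts[5, :30] += 8
        counts[9, 30:60] += 8
        C = sp.csr_matrix(counts)
        N = embed.lognormalize(C)
        ids = [f"g{i}" for i in range(50)]
        lab1 = np.repeat([0, 1, 2], 30)
        lab2 = np.repeat([2, 0, 1], 30)
        r1 = de.find_all_markers(C, N, ids, lab1)
        r2 = de.find_all_markers(C, N, ids, lab2)
        for old, new in ((0, 2), (1, 0), (2, 1)):
            a = r1[r1["cluster"] == old].drop(columns="cluster").reset_index(drop=True)
            b = r2[r2["cluster"] == new].drop(columns="cluster").reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)


class TestAnnotatePeaks:
    GENES = make_gene_table(
        ["plus", "minus"], ["chr1", "chr1"], [50_000, 200_000], [60_000, 210_000], ["+", "-"]
    )

    def test_peak_on_tss_is_promoter(self):
        peaks = PeakSet([GenomicInterval("chr1", 49_900, 50_100)])
        out = de.annotate_peaks(peaks, self.GENES)
        assert out.loc[0, "category"] == "promoter"

    def test_distal_peak(self):
        peaks = PeakSet([GenomicInterval("chr1", 100_000, 100_300)])
        out = de.annotate_peaks(peaks, self.GENES)
        assert out.loc[0, "category"] == "distal_intergenic"

    def test_gene_body_is_intron(self):
        peaks = PeakSet([GenomicInterval("chr1", 56_000, 56_300)])
        out = de.annotate_peaks(peaks, self.GENES)
        assert out.loc[0, "category"] == "intron"

    def test_matches_bruteforce_precedence(self, rng):
        starts = [int(s) for s in rng.integers(0, 500_000, 10)]
        genes = make_gene_table(
            [f"g{i}" for i in range(10)],
            ["chr1"] * 10,
            starts,
            [s + 20_000 for s in starts],
            [str(rng.choice(["+", "-"])) for _ in range(10)],
        )
        peaks = PeakSet(
            [GenomicInterval("chr1", int(s), int(s) + 300) for s in rng.integers(0, 520_000, 150)]
        )
        out = de.annotate_peaks(peaks, genes)
        for iv, cat in zip(peaks.intervals, out["category"]):
            promoter = False
            body = False
            for _, g in genes.iterrows():
                lo = g["tss"] - 3000 if g["strand"] == "+" else g["tss"] - 3000
                hi = g["tss"] + 3001
                if iv.start < hi and lo < iv.end:
                    promoter = True
                if iv.start < g["end"] and g["start"] < iv.end:
                    body = True
            expected = "promoter" if promoter else ("intron" if body else "distal_intergenic")
            assert cat == expected


class TestGenesetOra:
    def test_full_overlap_trivial_p(self):
        uni = [f"g{i}" for i in range(10)]
        out = de.geneset_ora(uni, uni, {"all": uni})
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_closed_form_tail(self):
        uni = [f"g{i}" for i in range(20)]
        s = uni[:5]
        out = de.geneset_ora(s, uni, {"s": s})
        assert out.loc[0, "p_value"] == pytest.approx(1 / comb(20, 5))

    def test_null_p_uniform(self, rng):
        uni = [f"g{i}" for i in range(500)]
        ps = []
        for i in range(300):
            hits = list(rng.choice(uni, 50, replace=False))
            members = list(rng.choice(uni, 40, replace=False))
            p = de.geneset_ora(hits, uni, {"s": members}).loc[0, "p_value"]
            # mid-p style smoothing for the discrete KS check: draw within
            # the attained level using the hypergeometric pmf
            k = de.geneset_ora(hits, uni, {"s": members}).loc[0, "overlap"]
            pmf = hypergeom.pmf(k, 500, 40, 50)
            ps.append(p - rng.uniform(0, 1) * pmf)
        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            de.geneset_ora([], [], {"s": ["a"]})
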