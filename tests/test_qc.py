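import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pgcmultiome.config import PipelineConfig
from pgcmultiome.core import CountMatrix, GenomicInterval, PeakSet, ValidationError, make_gene_table
from pgcmultiome import qc


def _cm(arr, genes, cells, modality="rna"):
    return CountMatrix(sp.csr_matrix(np.asarray(arr)), genes, cells, modality)


@pytest.fixture()
def tiny_genes():
    return make_gene_table(
        ["mt-a", "g1", "g2"],
        ["chrM", "chr1", "chr1"],
        [0, 1000, 50000],
        [100, 11000, 60000],
        ["+", "+", "-"],
    )


class TestRnaQc:
    def test_pct_mito_arithmetic(self, tiny_genes):
        cm = _cm([[25], [40], [35]], ["mt-a", "g1", "g2"], ["c1"])
        m = qc.compute_rna_qc(cm, tiny_genes)
        assert m.loc[0, "n_count_rna"] == 100
        assert m.loc[0, "pct_mito"] == 25.0

    def test_all_zero_cell(self, tiny_genes):
        cm = _cm([[0], [0], [0]], ["mt-a", "g1", "g2"], ["c1"])
        m = qc.compute_rna_qc(cm, tiny_genes)
        assert m.loc[0, "n_count_rna"] == 0
        assert m.loc[0, "pct_mito"] == 0.0

    def test_matches_dense_loop(self, small_ds):
        m = qc.compute_rna_qc(small_ds.rna, small_ds.genes)
        X = small_ds.rna.values.toarray()
        mito = small_ds.genes.set_index("gene")["is_mitochondrial"].reindex(
            small_ds.rna.feature_ids
        ).to_numpy()
        for j in [0, 17, 100]:
            total = X[:, j].sum()
            exp_pct = 100 * X[mito, j].sum() / total if total else 0.0
            assert m.loc[j, "n_count_rna"] == total
            assert m.loc[j, "pct_mito"] == pytest.approx(exp_pct)

    def test_unknown_feature_rejected(self, tiny_genes):
        cm = _cm([[1]], ["mystery"], ["c1"])
        with pytest.raises(ValidationError):
            qc.compute_rna_qc(cm, tiny_genes)


class TestNucleosomeSignal:
    def test_stated_ratio(self):
        frags = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": list(range(10)) + list(range(5)),
                "end": [i + 100 for i in range(10)] + [i + 200 for i in range(5)],
                "barcode": ["c1"] * 15,
                "count": 1,
            }
        )
        ns = qc.compute_nucleosome_signal(frags, ["c1"])
        assert ns["c1"] == pytest.approx(0.5)

    def test_no_fragments_zero(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
        ns = qc.compute_nucleosome_signal(frags, ["c1"])
        assert ns["c1"] == 0.0

    def test_matches_direct_count(self, small_ds):
        ns = qc.compute_nucleosome_signal(small_ds.fragments, small_ds.rna.cell_ids)
        bc = small_ds.rna.cell_ids[3]
        f = small_ds.fragments[small_ds.fragments["barcode"] == bc]
        L = (f["end"] - f["start"]).to_numpy()
        expected = ((L >= 147) & (L <= 294)).sum() / max(1, (L < 147).sum())
        assert ns[bc] == pytest.approx(expected)


class TestTssEnrichment:
    def test_uniform_coverage_fold_one(self):
        genes = make_gene_table(["g1"], ["chr1"], [100000], [110000], ["+"])
        # tile fragments uniformly across the TSS region
        starts = np.arange(97000, 103000, 10)
        frags = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + 10,
                "barcode": "c1",
                "count": 1,
            }
        )
        fold = qc.compute_tss_enrichment(frags, genes, ["c1"])
        assert fold["c1"] == pytest.approx(1.0, abs=0.05)

    def test_center_only_gives_sentinel(self):
        genes = make_gene_table(["g1"], ["chr1"], [100000], [110000], ["+"])
        frags = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [99950, 100050],
                "end": [100050, 100150],
                "barcode": "c1",
                "count": 1,
            }
        )
        fold = qc.compute_tss_enrichment(frags, genes, ["c1"])
        assert fold["c1"] == qc.TSS_SENTINEL

    def test_planted_pileup_enriched(self, small_ds):
        fold = qc.compute_tss_enrichment(
            small_ds.fragments, small_ds.genes, small_ds.rna.cell_ids
        )
        nfrag = small_ds.fragments.groupby("barcode").size()
        cells = [b for b in small_ds.rna.cell_ids if nfrag.get(b, 0) >= 100]
        assert (fold[cells] > 1).all()

    def test_empty_gene_table_rejected(self):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "count"])
        with pytest.raises(ValidationError):
            qc.compute_tss_enrichment(frags, pd.DataFrame(columns=["chrom", "tss"]), ["c1"])


class TestFilterCells:
    CFG = PipelineConfig()

    def _metrics(self, **kw):
        base = dict(
            barcode="c", n_count_rna=1500, pct_mito=10.0, n_count_atac=5000,
            nucleosome_signal=1.0, tss_enrichment=2.0,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_boundary_rna_count_excluded(self):
        retained, _ = qc.filter_cells(self._metrics(n_count_rna=1000), self.CFG)
        assert retained == []

    def test_all_pass(self):
        retained, _ = qc.filter_cells(self._metrics(), self.CFG)
        assert retained == ["c"]

    def test_matches_rowwise_oracle(self, rng):
        m = pd.DataFrame(
            {
                "barcode": [f"c{i}" for i in range(300)],
                "n_count_rna": rng.uniform(0, 30000, 300),
                "pct_mito": rng.uniform(0, 60, 300),
                "n_count_atac": rng.uniform(0, 120000, 300),
                "nucleosome_signal": rng.uniform(0, 4, 300),
                "tss_enrichment": rng.uniform(0, 5, 300),
            }
        )
        retained, counts = qc.filter_cells(m, self.CFG)
        expected = [
            r["barcode"]
            for _, r in m.iterrows()
            if 1000 < r["n_count_rna"] < 25000
            and r["pct_mito"] < 25
            and 1000 < r["n_count_atac"] < 100000
            and r["nucleosome_signal"] < 2
            and r["tss_enrichment"] > 1
        ]
        assert retained == expected

    def test_filters_commute(self, rng):
        """Applying per-rule masks in any order yields the same set."""
        m = pd.DataFrame(
            {
                "barcode": [f"c{i}" for i in range(100)],
                "n_count_rna": rng.uniform(0, 30000, 100),
                "pct_mito": rng.uniform(0, 60, 100),
                "n_count_atac": rng.uniform(0, 120000, 100),
                "nucleosome_signal": rng.uniform(0, 4, 100),
                "tss_enrichment": rng.uniform(0, 5, 100),
            }
        )
        r1, _ = qc.filter_cells(m, self.CFG)
        r2, _ = qc.filter_cells(m.iloc[::-1].reset_index(drop=True), self.CFG)
        assert set(r1) == set(r2)


class TestFilterPeaks:
    def test_boundary_width_removed(self):
        peaks = PeakSet([GenomicInterval("chr1", 0, 20)])
        kept, _ = qc.filter_peaks(peaks, {"chr1"})
        assert len(kept) == 0

    def test_nonstandard_chrom_removed(self):
        peaks = PeakSet([GenomicInterval("chrUn_random", 0, 300)])
        kept, _ = qc.filter_peaks(peaks, {"chr1", "chrX"})
        assert len(kept) == 0

    def test_blacklist_matches_bruteforce(self, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 100000, 200)
        ]
        peaks = PeakSet(ivs)
        bl = PeakSet(
            [GenomicInterval("chr1", int(s), int(s) + 500) for s in rng.integers(0, 100000, 20)]
        )
        kept, mask = qc.filter_peaks(peaks, {"chr1"}, bl)
        for iv, k in zip(ivs, mask):
            overlap = any(
                iv.start < b.end and b.start < iv.end for b in bl.intervals
            )
            assert k == (not overlap)


class TestCellTypes:
    GENES = ["Ddx4", "Pou5f1", "Foxl2", "Runx1", "Sox9", "Insl3", "Wt1",
             "Plvap", "Mafb", "Pdgfra", "Nr2f2", "Tspan8", "Krt19", "Pecam1"]

    def _matrix(self, counts: dict) -> CountMatrix:
        col = np.zeros((len(self.GENES), 1))
        for g, v in counts.items():
            col[self.GENES.index(g), 0] = v
        return _cm(col, self.GENES, ["c1"])

    def test_clean_pgc(self):
        calls = qc.call_cell_types(self._matrix({"Ddx4": 5}))
        assert calls.loc[0, "label"] == "PGC"

    def test_doublet_rule_excludes(self):
        calls = qc.call_cell_types(self._matrix({"Ddx4": 5, "Foxl2": 1}))
        assert calls.loc[0, "label"] != "PGC"

    def test_wt1_needs_more_than_one_count(self):
        assert qc.call_cell_types(self._matrix({"Wt1": 1})).loc[0, "label"] != "supporting"
        assert qc.call_cell_types(self._matrix({"Wt1": 2})).loc[0, "label"] == "supporting"

    def test_missing_marker_named(self):
        cm = _cm([[1]], ["Ddx4"], ["c1"])
        with pytest.raises(ValidationError, match="Pou5f1|Foxl2"):
            qc.call_cell_types(cm)

    def test_triage_on_synthetic_truth(self, small_ds):
        """>= 90% of cross-population doublets are rejected and planted
        PGC singlets are recovered."""
        calls = qc.call_cell_types(small_ds.rna).set_index("barcode")
        cells = small_ds.truth.cells.set_index("barcode")
        dbl = cells[cells["is_doublet"]].index
        assert (~calls.loc[dbl, "label"].isin(["PGC", "supporting"])).mean() >= 0.9
        pgc = cells[(cells["population"] == "PGC") & ~cells["is_doublet"]].index
        assert (calls.loc[pgc, "label"] == "PGC").mean() >= 0.95


class TestDropMito:
    def test_removes_only_mito_rows(self, tiny_genes):
        cm = _cm(np.ones((3, 2)), ["mt-a", "g1", "g2"], ["c1", "c2"])
        out = qc.drop_mito_features(cm, tiny_genes)
        assert out.feature_ids == ["g1", "g2"]
        assert out.cell_ids == ["c1", "c2"]

    def test_no_mito_identity(self):
        genes = make_gene_table(["g1"], ["chr1"], [0], [100], ["+"])
        cm = _cm([[1, 2]], ["g1"], ["c1", "c2"])
        out = qc.drop_mito_features(cm, genes)
        assert out.feature_ids == ["g1"]

    def test_pct_mito_zero_after_removal(self, small_ds):
        out = qc.drop_mito_features(small_ds.rna, small_ds.genes)
        m = qc.compute_rna_qc(out, small_ds.genes)
        assert (m["pct_mito"] == 0).all()
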