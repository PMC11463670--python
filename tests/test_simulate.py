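import numpy as np
import pandas as pd
import pytest

from pgcmultiome.core import ValidationError
from pgcmultiome.simulate import (
    SynthConfig,
    coupling_coefficient,
    inject_doublets,
    simulate_multiome,
)

SMALL = dict(n_pgc=40, n_supporting=40, n_somatic=30, n_genes=800, n_peaks=1200, frags_per_cell=60)


class TestConfigValidation:
    def test_infeasible_links_rejected(self):
        with pytest.raises(ValidationError):
            SynthConfig(n_peaks=50, n_de_genes=60, n_links_null=20)

    def test_doublet_rate_bounds(self):
        with pytest.raises(ValidationError):
            SynthConfig(doublet_rate=1.0)


class TestDeterminism:
    def test_same_seed_identical(self):
        a = simulate_multiome(SynthConfig(**SMALL), seed=1)
        b = simulate_multiome(SynthConfig(**SMALL), seed=1)
        assert (a.rna.values != b.rna.values).nnz == 0
        assert (a.atac.values != b.atac.values).nnz == 0
        pd.testing.assert_frame_equal(a.fragments, b.fragments)
        pd.testing.assert_frame_equal(a.truth.cells, b.truth.cells)

    def test_different_seed_differs(self):
        a = simulate_multiome(SynthConfig(**SMALL), seed=1)
        b = simulate_multiome(SynthConfig(**SMALL), seed=2)
        assert (a.rna.values != b.rna.values).nnz > 0


class TestStructuralTruth:
    def test_chrY_silent_in_xx_singlets(self, small_ds):
        cells = small_ds.truth.cells.set_index("barcode")
        fi = small_ds.rna.feature_index()
        ygenes = [g for g in ("Kdm5d", "Eif2s3y", "Uty", "Ddx3y")]
        xx = (
            (cells["sex"] == "XX") & ~cells["is_doublet"]
        ).reindex(small_ds.rna.cell_ids).to_numpy()
        Y = small_ds.rna.values[[fi[g] for g in ygenes], :]
        assert Y[:, xx].sum() == 0

    def test_chrY_fragments_only_in_xy(self, small_ds):
        cells = small_ds.truth.cells.set_index("barcode")
        y = small_ds.fragments[small_ds.fragments["chrom"] == "chrY"]
        sexes = cells.loc[y["barcode"], "sex"]
        assert (sexes == "XY").all()

    def test_nb_mean_variance_relation(self, small_ds):
        """Across genes, empirical variance should exceed the mean
        (over-dispersion) on the non-degenerate expressed genes."""
        cells = small_ds.truth.cells.set_index("barcode")
        keep = (
            (cells["population"] == "PGC")
            & (cells["sex"] == "XX")
            & ~cells["is_doublet"]
        ).reindex(small_ds.rna.cell_ids).to_numpy()
        X = small_ds.rna.values[:, keep].toarray()
        mean = X.mean(axis=1)
        var = X.var(axis=1)
        expressed = mean > 1
        assert (var[expressed] >= 0.8 * mean[expressed]).mean() > 0.95

    def test_every_link_references_real_features(self, small_ds):
        t = small_ds.truth
        assert t.links["gene"].isin(set(small_ds.rna.feature_ids)).all()
        assert t.links["peak"].isin(set(small_ds.atac.feature_ids)).all()
        # every TF edge has a motif hit in the target's linked peak
        hits = set(zip(t.motif_hits["peak"], t.motif_hits["motif_id"]))
        for _, e in t.tf_edges.iterrows():
            assert (e["peak"], e["motif_id"]) in hits


class TestLinkCoupling:
    def test_planted_correlation_near_configured_strength(self):
        """Null-link (non-DE) planted pairs hit the configured Pearson r
        within +/-0.1 at n >= 500 cells, measured within one sex."""
        cfg = SynthConfig(
            n_pgc=170, n_supporting=1, n_somatic=1, n_genes=300, n_peaks=500,
            frags_per_cell=1, n_junk_peaks=0,
        )
        ds = simulate_multiome(cfg, seed=3)
        cells = ds.truth.cells.set_index("barcode")
        mask = (
            (cells["population"] == "PGC")
            & (cells["sex"] == "XX")
            & ~cells["is_doublet"]
        ).reindex(ds.rna.cell_ids).to_numpy()
        assert mask.sum() >= 500
        fi, pi = ds.rna.feature_index(), ds.atac.feature_index()
        nulls = ds.truth.links[~ds.truth.links["is_de_gene"]]
        rs = []
        for _, l in nulls.iterrows():
            a = ds.atac.values[pi[l["peak"]], :].toarray().ravel()[mask]
            r = ds.rna.values[fi[l["gene"]], :].toarray().ravel()[mask]
            rs.append(np.corrcoef(a, r)[0, 1])
        assert abs(np.mean(rs) - cfg.link_strength) < 0.1

    def test_zero_strength_gives_zero_correlation(self):
        """With the coupling dial at ~0 the planted pairs decorrelate."""
        assert coupling_coefficient(0.0, 4, 3, 10, 0.06, 0.09) == 0.0
        cfg = SynthConfig(
            n_pgc=170, n_supporting=1, n_somatic=1, n_genes=300, n_peaks=500,
            frags_per_cell=1, link_strength=1e-6, n_junk_peaks=0,
        )
        ds = simulate_multiome(cfg, seed=4)
        cells = ds.truth.cells.set_index("barcode")
        mask = (
            (cells["population"] == "PGC") & (cells["sex"] == "XX") & ~cells["is_doublet"]
        ).reindex(ds.rna.cell_ids).to_numpy()
        fi, pi = ds.rna.feature_index(), ds.atac.feature_index()
        nulls = ds.truth.links[~ds.truth.links["is_de_gene"]]
        rs = []
        for _, l in nulls.iterrows():
            a = ds.atac.values[pi[l["peak"]], :].toarray().ravel()[mask]
            r = ds.rna.values[fi[l["gene"]], :].toarray().ravel()[mask]
            rs.append(np.corrcoef(a, r)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_coupling_solver_matches_target_moments(self):
        # closed-form check: plugging the solved coefficient back into the
        # moment equations recovers the target r
        for r in (0.2, 0.5, 0.7):
            a = coupling_coefficient(r, 4.0, 3.0, 10.0, 0.06, 0.09)
            va = np.expm1(a * a)
            cov = 12 * va
            vg = 4 + 16 * ((1.1) * (1 + va) * 1.06 - 1)
            vp = 3 + 9 * ((1 + va) * 1.09 - 1)
            assert abs(cov / np.sqrt(vg * vp) - r) < 1e-6


class TestDoublets:
    def test_rate_zero_identity(self, small_ds):
        rna, atac, tbl = inject_doublets(
            small_ds.rna, small_ds.atac, 0.0,
            small_ds.truth.cells.set_index("barcode")["population"], seed=0,
        )
        assert rna is small_ds.rna and atac is small_ds.atac
        assert len(tbl) == 0

    def test_exact_doublet_count(self):
        cfg = SynthConfig(**{**SMALL, "doublet_rate": 0.0})
        ds = simulate_multiome(cfg, seed=5)
        n = len(ds.rna.cell_ids)
        rna2, atac2, tbl = inject_doublets(
            ds.rna, ds.atac, 0.1,
            ds.truth.cells.set_index("barcode")["population"], seed=1,
        )
        assert len(tbl) == round(0.1 * n)
        assert len(rna2.cell_ids) == n + len(tbl)

    def test_doublet_counts_are_donor_sums(self):
        cfg = SynthConfig(**{**SMALL, "doublet_rate": 0.0})
        ds = simulate_multiome(cfg, seed=6)
        rna2, _, tbl = inject_doublets(
            ds.rna, ds.atac, 0.05,
            ds.truth.cells.set_index("barcode")["population"], seed=2,
        )
        ci = rna2.cell_index()
        for _, r in tbl.head(5).iterrows():
            d = rna2.values[:, ci[r["barcode"]]].toarray().ravel()
            a = rna2.values[:, ci[r["donor1"]]].toarray().ravel()
            b = rna2.values[:, ci[r["donor2"]]].toarray().ravel()
            np.testing.assert_array_equal(d, a + b)

    def test_pgc_supporting_doublet_coexpresses_markers(self):
        """A PGC + supporting doublet carries both the germ marker (Ddx4)
        and the supporting marker (Wt1): each donor contributes its own
        marker counts by construction."""
        cfg = SynthConfig(**{**SMALL, "doublet_rate": 0.0})
        ds = simulate_multiome(cfg, seed=8)
        pops = ds.truth.cells.set_index("barcode")["population"]
        rna2, _, tbl = inject_doublets(ds.rna, ds.atac, 0.2, pops, seed=3)
        ci = rna2.cell_index()
        fi = rna2.feature_index()
        ddx4 = rna2.values[fi["Ddx4"], :].toarray().ravel()
        wt1 = rna2.values[fi["Wt1"], :].toarray().ravel()
        mixed = tbl[
            (pops.loc[tbl["donor1"]].to_numpy() == "PGC")
            & (pops.loc[tbl["donor2"]].to_numpy() == "supporting")
            | (pops.loc[tbl["donor1"]].to_numpy() == "supporting")
            & (pops.loc[tbl["donor2"]].to_numpy() == "PGC")
        ]
        assert len(mixed) > 5
        cols = [ci[b] for b in mixed["barcode"]]
        both = (ddx4[cols] >= 1) & (wt1[cols] >= 1)
        assert both.mean() >= 0.9
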