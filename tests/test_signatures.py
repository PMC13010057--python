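"""Rank-sum DE, signature construction and the rank-based module score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellprograms import signatures as sg
from conftest import make_adata, make_cells


def u_score_oracle(expression_row, sig_cols, ceiling):
    """Direct evaluation of the U-statistic score for one cell."""
    ranks = stats.rankdata(-np.asarray(expression_row), method="average")
    ranks = np.minimum(ranks, ceiling + 1)
    r = ranks[sig_cols]
    n = len(sig_cols)
    u = r.sum() - n * (n + 1) / 2
    return max(0.0, 1.0 - u / (n * ceiling))


class TestRankSumDE:
    def _exclusive_cohort(self, n_side=25, n_genes=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.poisson(1.0, size=(2 * n_side, n_genes)).astype(float)
        X[:n_side, 0] += 5.0  # gene 0 expressed essentially only in target
        X[n_side:, 0] = 0.0
        cells = make_cells(
            [f"c{i}" for i in range(2 * n_side)],
            ["s"] * (2 * n_side),
            ["tgt"] * n_side + ["rest"] * n_side,
        )
        return make_adata(X), cells

    def test_exclusive_gene_tops_table(self):
        adata, cells = self._exclusive_cohort()
        de = sg.rank_sum_de(adata, cells, "tgt", "level1")
        assert de["log2fc"].idxmax() == "g0"
        assert de.loc["g0", "padj"] < 0.05

    def test_null_pvalues_are_uniform(self):
        """Identically distributed genes give approximately uniform raw
        p-values (KS test non-significant at alpha = 0.01)."""
        rng = np.random.default_rng(8)
        X = rng.gamma(2.0, 1.0, size=(120, 400))
        cells = make_cells(
            [f"c{i}" for i in range(120)], ["s"] * 120,
            ["tgt"] * 60 + ["rest"] * 60,
        )
        de = sg.rank_sum_de(make_adata(X), cells, "tgt", "level1")
        ks_p = stats.kstest(de["pvalue"], "uniform").pvalue
        assert ks_p > 0.01

    def test_all_zero_gene_degenerate_handling(self):
        X = np.ones((10, 3))
        X[:, 2] = 0.0
        cells = make_cells(
            [f"c{i}" for i in range(10)], ["s"] * 10, ["tgt"] * 5 + ["rest"] * 5
        )
        de = sg.rank_sum_de(make_adata(X), cells, "tgt", "level1")
        assert de.loc["g2", "pvalue"] == 1.0
        assert de.loc["g2", "log2fc"] == 0.0

    def test_adjusted_p_dominates_raw(self, small_adata, small_cohort):
        cells, _ = small_cohort
        de = sg.rank_sum_de(small_adata, cells, "T0", "level1")
        assert (de["padj"] >= de["pvalue"] - 1e-15).all()
        assert de[["pvalue", "padj"]].ge(0).all().all()
        assert de[["pvalue", "padj"]].le(1).all().all()

    def test_target_must_have_complement(self):
        X = np.ones((4, 2))
        cells = make_cells(["c0", "c1", "c2", "c3"], ["s"] * 4, ["t"] * 4)
        with pytest.raises(ValueError):
            sg.rank_sum_de(make_adata(X), cells, "t", "level1")


class TestBuildSignature:
    def _de(self, n=50):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "log2fc": np.linspace(3, -1, n),
                "pvalue": np.full(n, 1e-6),
                "padj": np.full(n, 1e-5),
            },
            index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene"),
        )

    def test_truncates_to_top_n_descending(self):
        sig = sg.build_signature(self._de(), "s", top_n=20, min_lfc=0.25,
                                 max_padj=0.05)
        assert len(sig.genes) == 20
        lfc = self._de()["log2fc"]
        assert list(sig.genes) == list(lfc.index[:20])

    def test_few_passing_genes_warn(self):
        de = self._de(10)
        de.loc[de.index[3:], "padj"] = 0.5  # only 3 genes pass
        with pytest.warns(UserWarning, match="3 of 20"):
            sig = sg.build_signature(de, "s", top_n=20, min_lfc=0.25,
                                     max_padj=0.05)
        assert len(sig.genes) == 3

    def test_spatial_preset_strict_inequalities(self):
        de = pd.DataFrame(
            {
                "log2fc": [0.5, 0.50001, 2.0, 2.0],
                "padj": [1e-5, 1e-5, 1e-4, 9.9e-5],
            },
            index=pd.Index(["at_lfc", "above", "at_p", "pass2"], name="gene"),
        )
        sig = sg.build_signature(de, "s", **sg.SPATIAL_PRESET)
        # log2FC must exceed 0.5 and padj must be under 1e-4, both strictly
        assert set(sig.genes) == {"above", "pass2"}

    def test_no_passing_genes_errors_with_counts(self):
        de = self._de()
        de["padj"] = 0.9
        with pytest.raises(ValueError, match="padj < 0.05: 0"):
            sg.build_signature(de, "s", top_n=20, min_lfc=0.25, max_padj=0.05)

    def test_tie_break_by_gene_name(self):
        de = pd.DataFrame(
            {"log2fc": [1.0, 1.0, 1.0], "padj": [1e-6] * 3},
            index=pd.Index(["zz", "aa", "mm"], name="gene"),
        )
        sig = sg.build_signature(de, "s", top_n=3, min_lfc=0.5, max_padj=0.05)
        assert sig.genes == ["aa", "mm", "zz"]


class TestModuleScore:
    def test_top_ranked_signature_scores_one(self):
        # signature genes occupy ranks 1..n exactly -> U = 0 -> score 1
        X = np.array([[9.0, 8.0, 7.0, 1.0, 0.5, 0.2]])
        adata = make_adata(X, normalize=False)
        sig = sg.GeneSignature("top", ["g0", "g1", "g2"])
        s = sg.module_score(adata, sig, rank_ceiling=6, layer=None)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_worked_value_with_ceiling(self):
        """Ranks (1,2,3,4,1501) at ceiling 1500 -> U = 1496 -> 0.80053..."""
        n_genes = 1600
        X = np.zeros((1, n_genes))
        X[0, :4] = [40, 30, 20, 10]  # ranks 1..4
        X[0, 4:] = np.linspace(5, 1, n_genes - 4)  # last sig gene ranked last
        sig_cols = [0, 1, 2, 3, n_genes - 1]
        adata = make_adata(X, normalize=False)
        sig = sg.GeneSignature("w", [f"g{j}" for j in sig_cols])
        s = sg.module_score(adata, sig, rank_ceiling=1500, layer=None)
        assert s.iloc[0] == pytest.approx(1 - 1496 / 7500, abs=1e-12)
        assert s.iloc[0] == pytest.approx(
            u_score_oracle(X[0], sig_cols, 1500), abs=1e-12
        )

    def test_all_genes_beyond_ceiling(self):
        # 5 signature genes all at rank ceiling+1: U = 5*1501 - 15 = 7490
        n_genes = 1600
        X = np.zeros((1, n_genes))
        X[0, :1505] = np.linspace(100, 10, 1505)
        sig_cols = list(range(n_genes - 5, n_genes))  # all-zero, bottom ties
        # force the 5 signature genes into the tie block beyond the ceiling
        adata = make_adata(X, normalize=False)
        sig = sg.GeneSignature("w", [f"g{j}" for j in sig_cols])
        s = sg.module_score(adata, sig, rank_ceiling=1500, layer=None)
        oracle = u_score_oracle(X[0], sig_cols, 1500)
        assert s.iloc[0] == pytest.approx(oracle, abs=1e-12)
        assert s.iloc[0] == pytest.approx(1 - 7490 / 7500, abs=1e-6)

    def test_matches_direct_formula_on_random_cases(self):
        rng = np.random.default_rng(21)
        X = rng.gamma(1.0, 2.0, size=(30, 200)) * (rng.random((30, 200)) > 0.4)
        adata = make_adata(X, normalize=False)
        for _ in range(100):
            n_sig = rng.integers(3, 15)
            cols = rng.choice(200, size=n_sig, replace=False)
            ceiling = int(rng.integers(n_sig, 200))
            sig = sg.GeneSignature("r", [f"g{j}" for j in cols])
            got = sg.module_score(adata, sig, rank_ceiling=ceiling, layer=None)
            cell = int(rng.integers(0, 30))
            want = u_score_oracle(X[cell], cols, ceiling)
            assert got.iloc[cell] == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_under_positive_cell_scaling(self, factor):
        rng = np.random.default_rng(5)
        X = rng.gamma(1.0, 1.0, size=(4, 50))
        sig = sg.GeneSignature("s", ["g1", "g7", "g30"])
        a = sg.module_score(make_adata(X, normalize=False), sig,
                            rank_ceiling=40, layer=None)
        b = sg.module_score(make_adata(X * factor, normalize=False), sig,
                            rank_ceiling=40, layer=None)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_scores_bounded(self, small_adata):
        sig = sg.GeneSignature("b", [f"g{i:04d}" for i in range(0, 40, 3)])
        s = sg.module_score(small_adata, sig, rank_ceiling=150)
        assert (s >= 0).all() and (s <= 1).all()

    def test_own_marker_signature_scores_highest(self, small_config,
                                                 small_cohort, small_adata):
        """A cell type's marker signature scores strictly higher in that
        type than in every other type (marker_fold = 4)."""
        cells, _ = small_cohort
        labels = cells.set_index("cell_id").loc[
            list(small_adata.obs_names), "level1"
        ]
        for ct in ("T2", "T5"):
            sig = sg.GeneSignature(ct, small_config.marker_genes()[ct])
            s = sg.module_score(small_adata, sig, rank_ceiling=150)
            own = s[(labels == ct).to_numpy()].mean()
            for other in small_config.cell_types:
                if other == ct:
                    continue
                assert own > s[(labels == other).to_numpy()].mean()

    def test_absent_signature_rejected(self):
        adata = make_adata(np.ones((2, 3)), normalize=False)
        sig = sg.GeneSignature("x", ["nope"])
        with pytest.raises(ValueError, match="no gene"):
            sg.module_score(adata, sig, rank_ceiling=3, layer=None)


class TestGMT:
    def test_round_trip(self, tmp_path):
        sigs = [
            sg.GeneSignature("a", ["g1", "g2"]),
            sg.GeneSignature("b", ["g3", "g4", "g5"]),
        ]
        path = tmp_path / "sets.gmt"
        sg.write_gmt(sigs, path)
        back = sg.read_gmt(path)
        assert [(s.name, s.genes) for s in back] == [
            (s.name, s.genes) for s in sigs
        ]
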