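"""Cluster enrichment, fold changes, and the anticorrelation screen."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retinodiff.markers import (
    anticorrelation_screen,
    enriched_genes,
    log2fc,
    surface_filter,
)
from retinodiff.preprocess import _dense_layer
from retinodiff.signatures import GeneSignature

from conftest import count_dataset, normalized_dataset, screen_mixture


class TestEnrichedGenes:
    def planted_dataset(self, seed=0, fold=8.0, n_per=20, p=300):
        rng = np.random.default_rng(seed)
        base = 0.5 * np.exp(rng.standard_normal(p))
        lam = np.tile(base, (2 * n_per, 1)).copy()
        # plant markers among detectably expressed genes
        planted = rng.choice(np.flatnonzero(base >= np.median(base)), 10, replace=False)
        lam[:n_per, planted] *= fold
        ds = count_dataset(
            rng.poisson(lam),
            cell_meta=pd.DataFrame({"cluster": ["A"] * n_per + ["B"] * n_per}),
        )
        return ds, [f"g{j:04d}" for j in planted]

    def test_planted_marker_top_ranked_and_significant(self):
        ds, planted = self.planted_dataset(seed=1)
        tab = enriched_genes(ds)
        a = tab[tab["cluster"] == "A"].set_index("gene")
        assert a.loc[planted, "adjusted_p"].max() < 0.01
        assert a.loc[planted, "log2_fold_change"].min() > 0
        assert set(a[a["rank"] <= 10].index) >= set(planted) - set(
            a[a["adjusted_p"] >= 0.01].index
        )

    def test_null_false_positive_rate_controlled(self):
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            base = 0.5 * np.exp(rng.standard_normal(200))
            ds = count_dataset(
                rng.poisson(np.tile(base, (60, 1))),
                cell_meta=pd.DataFrame({"cluster": ["A"] * 30 + ["B"] * 30}),
            )
            tab = enriched_genes(ds)
            fracs.append((tab["adjusted_p"] < 0.05).mean())
        assert np.mean(fracs) <= 0.07

    def test_rank_sum_statistic_matches_pair_count_oracle(self):
        # 4 cells (2 vs 2), 2 genes: U equals the brute-force count of
        # (A, B) pairs where A wins, and the standardized statistic follows
        vals = np.array([[3.0, 1.0], [5.0, 2.0], [1.0, 4.0], [2.0, 6.0]])
        ds = normalized_dataset(vals)
        ds.obs["cluster"] = ["A", "A", "B", "B"]
        tab = enriched_genes(ds, min_cells=2)
        for gi, gene in enumerate(["g0000", "g0001"]):
            u_oracle = sum(
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in vals[:2, gi]
                for b in vals[2:, gi]
            )
            z_oracle = (u_oracle - 2.0) / np.sqrt(2 * 2 * 5 / 12.0)
            row = tab[(tab["cluster"] == "A") & (tab["gene"] == gene)].iloc[0]
            assert row["statistic"] == pytest.approx(z_oracle, abs=1e-12)
            # exact permutation p-value from enumerating label assignments
            null_u = []
            for combo in combinations(range(4), 2):
                mask = np.zeros(4, dtype=bool)
                mask[list(combo)] = True
                null_u.append(
                    sum(
                        1.0 if a > b else (0.5 if a == b else 0.0)
                        for a in vals[mask, gi]
                        for b in vals[~mask, gi]
                    )
                )
            exact_p = np.mean(
                np.abs(np.array(null_u) - 2.0) >= np.abs(u_oracle - 2.0) - 1e-12
            )
            exact = stats.mannwhitneyu(
                vals[:2, gi], vals[2:, gi], alternative="two-sided", method="exact"
            ).pvalue
            assert exact == pytest.approx(exact_p, abs=1e-12)

    def test_bh_adjustment_is_monotone_within_cluster(self):
        ds, _ = self.planted_dataset(seed=2)
        tab = enriched_genes(ds)
        for _, grp in tab.groupby("cluster"):
            srt = grp.sort_values("p_value")
            assert np.all(np.diff(srt["adjusted_p"].values) >= -1e-12)
            assert np.all(srt["adjusted_p"].values >= srt["p_value"].values - 1e-12)

    def test_small_cluster_skipped_single_cluster_fatal(self):
        rng = np.random.default_rng(3)
        ds = count_dataset(
            rng.poisson(1.0, size=(22, 30)),
            cell_meta=pd.DataFrame({"cluster": ["A"] * 10 + ["B"] * 10 + ["C"] * 2}),
        )
        with pytest.warns(UserWarning, match="skipped"):
            tab = enriched_genes(ds, min_cells=3)
        assert set(tab["cluster"]) == {"A", "B"}
        ds2 = count_dataset(
            rng.poisson(1.0, size=(10, 30)),
            cell_meta=pd.DataFrame({"cluster": ["A"] * 10}),
        )
        with pytest.raises(ValueError, match="at least 2"):
            enriched_genes(ds2)


class TestLog2FC:
    def test_identical_groups_are_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(1, 1, size=(10, 20))
        ds = normalized_dataset(np.vstack([vals, vals]))
        mask = np.array([True] * 10 + [False] * 10)
        assert np.allclose(log2fc(ds, mask, ~mask), 0.0)

    def test_hand_fixture_value(self):
        # means (3, 1), pseudocount 1 -> log2(4/2) = 1
        ds = normalized_dataset(np.array([[3.0], [1.0]]))
        out = log2fc(ds, [True, False], [False, True])
        assert out.iloc[0] == pytest.approx(1.0)

    def test_small_pseudocount_limit(self):
        ds = normalized_dataset(np.array([[2.0], [1.0]]))
        out = log2fc(ds, [True, False], [False, True], pseudocount=1e-9)
        assert out.iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_rejected(self):
        ds = normalized_dataset(np.ones((4, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            log2fc(ds, [False] * 4, [True] * 4)


class TestScreen:
    def test_low_expression_genes_excluded_exactly(self):
        adata, truth = screen_mixture(0, n_cells=400)
        rpe = GeneSignature("rpe", tuple(truth.programs["RPE"]))
        nt = GeneSignature("nt", tuple(truth.programs["NeuralTube"]))
        out = anticorrelation_screen(adata, rpe, nt)
        Y = _dense_layer(adata, "normalized")
        means = pd.Series(Y.mean(axis=0), index=adata.var_names)
        assert (means.loc[out["gene"]] >= 0.5).all()
        excluded = means[means < 0.5].index
        assert not set(out["gene"]) & set(excluded)

    def test_rpe_signature_gene_not_top_ranked(self):
        adata, truth = screen_mixture(1, n_cells=800)
        rpe = GeneSignature("rpe", tuple(truth.programs["RPE"]))
        nt = GeneSignature("nt", tuple(truth.programs["NeuralTube"]))
        out = anticorrelation_screen(adata, rpe, nt)
        present = out.set_index("gene")
        rpe_in = [g for g in rpe.genes if g in present.index]
        assert len(rpe_in) > 0
        assert present.loc[rpe_in, "correlation_to_rpe"].max() > 0
        top5 = set(out["gene"].head(5))
        assert not top5 & set(rpe.genes)

    def test_planted_progenitor_marker_ranks_top_among_surface_candidates(self):
        hits = 0
        for seed in range(6):
            adata, truth = screen_mixture(seed, n_cells=800)
            rpe = GeneSignature("rpe", tuple(truth.programs["RPE"]))
            nt = GeneSignature("nt", tuple(truth.programs["NeuralTube"]))
            out = anticorrelation_screen(adata, rpe, nt, seed=seed)
            Y = _dense_layer(adata, "normalized")
            vi = pd.Index(adata.var_names)
            prog = truth.programs["RetProg"]
            planted = prog[int(np.argmax(Y.mean(0)[vi.get_indexer(prog)]))]
            rng = np.random.default_rng(seed + 99)
            nonprog = [g for g in adata.var_names if g not in set(prog)]
            surfaceome = [planted] + list(rng.choice(nonprog, 49, replace=False))
            surf = surface_filter(out, surfaceome)
            pos = surf.index[surf["gene"] == planted]
            hits += len(pos) > 0 and int(pos[0]) < 5
        assert hits >= 5

    def test_invariant_to_cell_order(self):
        adata, truth = screen_mixture(2, n_cells=300)
        rpe = GeneSignature("rpe", tuple(truth.programs["RPE"]))
        nt = GeneSignature("nt", tuple(truth.programs["NeuralTube"]))
        out1 = anticorrelation_screen(adata, rpe, nt, seed=0)
        perm = np.random.default_rng(0).permutation(adata.n_obs)
        out2 = anticorrelation_screen(adata[perm].copy(), rpe, nt, seed=0)
        assert list(out1["gene"]) == list(out2["gene"])
        assert np.allclose(out1["combined_score"], out2["combined_score"])

    def test_no_gene_passing_filter_is_error(self):
        ds = normalized_dataset(np.full((20, 30), 0.1))
        sig = GeneSignature("s", ("g0000",))
        with pytest.raises(ValueError, match="min_mean|no gene"):
            anticorrelation_screen(ds, sig, sig)


class TestSurfaceFilter:
    def make_screen(self):
        return pd.DataFrame({
            "gene": ["NCAM1", "RAX", "TTR"],
            "mean_normalized_expression": [1.0, 1.0, 1.0],
            "correlation_to_rpe": [-0.5, -0.4, 0.6],
            "correlation_to_neural_tube": [-0.4, -0.5, 0.2],
            "combined_score": [-0.45, -0.45, 0.4],
            "surface_flag": [False] * 3,
        })

    def test_ncam1_retained_when_in_surfaceome(self):
        out = surface_filter(self.make_screen(), ["NCAM1", "CDH2"])
        assert list(out["gene"]) == ["NCAM1"]
        assert out["surface_flag"].all()

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning, match="no screened gene"):
            out = surface_filter(self.make_screen(), ["CPAMD8"])
        assert out.empty

    def test_duplicates_deduplicated(self):
        out1 = surface_filter(self.make_screen(), ["NCAM1", "TTR"])
        out2 = surface_filter(self.make_screen(), ["NCAM1", "NCAM1", "TTR", "TTR"])
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_surfaceome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            surface_filter(self.make_screen(), [])
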