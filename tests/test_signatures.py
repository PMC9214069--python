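"""Signature scoring, cell-cycle assignment, positivity, cross-reference maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from retinodiff import preprocess
from retinodiff.signatures import (
    GeneSignature,
    assign_cell_cycle,
    builtin_signatures,
    group_correlation_matrix,
    positive_fraction,
    read_signatures,
    reference_signature_scores,
    score_signature,
)
from retinodiff.simulate import SimConfig, simulate_timecourse

from conftest import count_dataset, normalized_dataset, screen_mixture, type_mixture


def auroc(scores, labels):
    r = rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    return (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestScoreSignature:
    def test_all_zero_matrix_scores_zero(self):
        ds = normalized_dataset(np.zeros((10, 40)))
        sig = GeneSignature("s", ("g0000", "g0001"))
        assert np.allclose(score_signature(ds, sig), 0.0)

    def test_random_signature_scores_near_zero(self):
        rng = np.random.default_rng(0)
        ds = normalized_dataset(rng.gamma(1.0, 1.0, size=(1000, 300)))
        genes = tuple(f"g{j:04d}" for j in rng.choice(300, 20, replace=False))
        sc = score_signature(ds, GeneSignature("rand", genes), seed=1)
        assert abs(sc.mean()) < 0.05

    def test_planted_type_separates_with_high_auroc(self, timecourse):
        adata, truth = timecourse
        sig = GeneSignature("late", tuple(truth.programs["LateRPE"][:20]))
        sc = score_signature(adata, sig, seed=0)
        is_late = (adata.obs["cell_type"] == "LateRPE").values
        assert auroc(sc, is_late) > 0.95

    def test_invariant_to_absent_genes(self, timecourse):
        adata, truth = timecourse
        sig = GeneSignature("a", tuple(truth.programs["RetProg"][:10]))
        padded = GeneSignature("a", sig.genes + ("NOT_A_GENE_1", "NOT_A_GENE_2"))
        s1 = score_signature(adata, sig, seed=3)
        with pytest.warns(UserWarning, match="absent"):
            s2 = score_signature(adata, padded, seed=3)
        assert np.allclose(s1, s2)

    def test_all_genes_absent_is_error(self, timecourse):
        adata, _ = timecourse
        with pytest.raises(ValueError, match="no gene"):
            score_signature(adata, GeneSignature("none", ("NOPE",)))

    def test_deterministic_under_seed(self, timecourse):
        adata, truth = timecourse
        sig = GeneSignature("s", tuple(truth.programs["RetProg"]))
        assert np.array_equal(
            score_signature(adata, sig, seed=5), score_signature(adata, sig, seed=5)
        )


class TestCellCycle:
    def test_decision_rule_cases(self):
        ds = normalized_dataset(np.zeros((3, 20)))
        # monkeypatch-free: drive via explicit threshold on synthetic scores
        from retinodiff.signatures import CyclePhaseAssignment

        cc = CyclePhaseAssignment(
            phase=np.array(["S", "G1_G0", "G2M"]),
            s_score=np.array([0.8, -0.2, 0.1]),
            g2m_score=np.array([-0.1, -0.3, 0.5]),
        )
        assert list(cc.cycling) == [True, False, True]

    def test_rule_applied_from_scores(self, timecourse):
        adata, truth = timecourse
        sig_s = GeneSignature("S", tuple(truth.programs["cycle_S"]))
        sig_g = GeneSignature("G2M", tuple(truth.programs["cycle_G2M"]))
        cc = assign_cell_cycle(adata, sig_s, sig_g, seed=0)
        both_low = (cc.s_score <= 0) & (cc.g2m_score <= 0)
        assert np.all(cc.phase[both_low] == "G1_G0")
        s_wins = (~both_low) & (cc.s_score >= cc.g2m_score)
        assert np.all(cc.phase[s_wins] == "S")

    def test_cycling_fraction_recovery_across_seeds(self):
        errs = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, cycling_fraction=(0.3,) * 7,
                            n_cells_per_timepoint=150)
            adata, truth = simulate_timecourse(cfg)
            preprocess.normalize_log(adata)
            sig_s = GeneSignature("S", tuple(truth.programs["cycle_S"]))
            sig_g = GeneSignature("G2M", tuple(truth.programs["cycle_G2M"]))
            cc = assign_cell_cycle(adata, sig_s, sig_g, seed=seed)
            true_frac = (truth.cells["cycle_phase"] != "G1_G0").mean()
            errs.append(cc.cycling.mean() - true_frac)
        assert np.max(np.abs(errs)) < 0.05


class TestPositivity:
    def make(self, counts_column, groups):
        counts = np.zeros((len(counts_column), 3), dtype=int)
        counts[:, 0] = counts_column
        counts[:, 1] = 1
        counts[:, 2] = 2
        return count_dataset(
            counts, cell_meta=pd.DataFrame({"time_point": groups}), normalize=False
        )

    def test_none_positive_hits_lower_bound_zero(self):
        ds = self.make([0] * 8, ["D7"] * 8)
        out = positive_fraction(ds, "g0000")
        assert out.loc["D7", "fraction"] == 0
        assert out.loc["D7", "ci_low"] == 0

    def test_five_of_ten_matches_wilson_closed_form(self):
        ds = self.make([1] * 5 + [0] * 5, ["D7"] * 10)
        out = positive_fraction(ds, "g0000")
        assert out.loc["D7", "fraction"] == 0.5
        # Wilson with z = 1.95996
        assert out.loc["D7", "ci_low"] == pytest.approx(0.2366, abs=1e-3)
        assert out.loc["D7", "ci_high"] == pytest.approx(0.7634, abs=1e-3)

    def test_single_positive_cell_boundary(self):
        ds = self.make([3], ["D7"])
        out = positive_fraction(ds, "g0000")
        assert out.loc["D7", "fraction"] == 1
        assert out.loc["D7", "ci_high"] == 1

    def test_wilson_coverage_calibrated(self):
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(0)
        cover = 0
        n_rep = 2000
        for _ in range(n_rep):
            k = rng.binomial(50, 0.3)
            lo, hi = proportion_confint(k, 50, method="wilson")
            cover += lo <= 0.3 <= hi
        assert 0.93 <= cover / n_rep <= 0.97

    def test_missing_gene_or_group_errors(self, timecourse):
        adata, _ = timecourse
        with pytest.raises(ValueError, match="not in dataset"):
            positive_fraction(adata, "NOPE")
        with pytest.raises(ValueError, match="missing"):
            positive_fraction(adata, adata.var_names[0], group_by="nope")


class TestReferenceSignatures:
    def test_reference_scored_against_itself_is_diagonally_dominant(self):
        adata, truth = type_mixture(0, n_types=4, n_cells=600)
        adata.obs["cluster"] = adata.obs["cell_type"]
        rankings = {f"T{i}": truth.programs[f"T{i}"] for i in range(4)}
        mat = reference_signature_scores(adata, rankings, top_n=20)
        for t in rankings:
            assert mat[t].idxmax() == t

    def test_short_ranking_clamped_with_warning(self):
        adata, truth = type_mixture(1, n_types=3, n_cells=300)
        rankings = {"T0": truth.programs["T0"][:5], "T1": truth.programs["T1"]}
        with pytest.warns(UserWarning, match="only 5"):
            mat = reference_signature_scores(adata, rankings, top_n=30)
        assert set(mat.columns) == {"T0", "T1"}

    def test_planted_correspondence_recovered_across_seeds(self):
        ok = 0
        for seed in range(5):
            adata, truth = type_mixture(seed, n_types=4, n_cells=600)
            rankings = {f"T{i}": truth.programs[f"T{i}"] for i in range(4)}
            mat = reference_signature_scores(adata, rankings, top_n=20, seed=seed)
            ok += all(mat[t].idxmax() == t for t in rankings)
        assert ok == 5

    def test_empty_ranking_is_error(self):
        adata, _ = type_mixture(2, n_types=3, n_cells=300)
        with pytest.raises(ValueError, match="no enriched genes"):
            reference_signature_scores(adata, {"T0": []})


class TestGroupCorrelation:
    def test_hand_built_profiles_match_manual_pearson(self):
        profiles = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 1.0, 4.0, 3.0],
            [4.0, 3.0, 2.0, 1.0],
        ])
        vals = np.repeat(profiles, 2, axis=0)  # 2 identical cells per group
        ds = normalized_dataset(vals)
        ds.obs["grp"] = ["a", "a", "b", "b", "c", "c"]
        out = group_correlation_matrix(ds, "grp")
        manual = np.corrcoef(profiles)
        assert np.allclose(out.values, manual, atol=1e-12)
        assert np.allclose(np.diag(out.values), 1.0)
        assert np.allclose(out.values, out.values.T)

    def test_duplicated_group_correlates_at_one(self):
        rng = np.random.default_rng(0)
        prof = rng.gamma(1, 1, 30)
        vals = np.vstack([prof, prof, prof * 0.5 + rng.gamma(1, 1, 30)])
        ds = normalized_dataset(vals)
        ds.obs["grp"] = ["a", "b", "c"]
        out = group_correlation_matrix(ds, "grp")
        assert out.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_flagged_nan(self):
        vals = np.vstack([np.ones(10), np.random.default_rng(1).gamma(1, 1, 10)])
        ds = normalized_dataset(vals)
        ds.obs["grp"] = ["flat", "ok"]
        out = group_correlation_matrix(ds, "grp")
        assert np.isnan(out.loc["flat", "ok"])


def test_builtin_signature_files_parse(tmp_path):
    sigs = builtin_signatures()
    assert {"pluripotency", "retinal_progenitor", "rpe", "S", "G2M"} <= set(sigs)
    assert "RPE65" in sigs["rpe"].genes
    # round-trip a signature file
    p = tmp_path / "sig.tsv"
    p.write_text("mysig\tRAX\nmysig\tVSX2\n")
    out = read_signatures(p)
    assert out["mysig"].genes == ("RAX", "VSX2")
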