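import numpy as np
import pytest

from dnbpipe import (
    TransitionSimSpec,
    bootstrap_significance,
    build_windows,
    candidate_modules,
    composite_index,
    detect_dnb,
    pairwise_pcc,
    simulate_transition,
)
from tests.conftest import make_dataset
from tests.oracles import ci_brute_force, pearson


class TestPairwisePcc:
    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        mat = np.vstack([x, 2 * x + 1, -x])
        pcc = pairwise_pcc(mat)
        assert pcc[0, 1] == pytest.approx(1.0)
        assert pcc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(10, 6))
        pcc = pairwise_pcc(mat)
        assert pcc == pytest.approx(pcc.T)
        np.testing.assert_array_equal(np.diag(pcc), np.ones(10))
        for i in range(10):
            for j in range(i + 1, 10):
                assert pcc[i, j] == pytest.approx(
                    pearson(list(mat[i]), list(mat[j])), abs=1e-12
                )

    def test_constant_row_correlates_zero(self):
        mat = np.vstack([np.ones(5), np.arange(5.0)])
        pcc = pairwise_pcc(mat)
        assert pcc[0, 1] == 0.0 and pcc[0, 0] == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_pcc(np.ones((3, 1)))


class TestCandidateModules:
    def test_recovers_perfect_blocks(self):
        n = 14  # two 5-blocks + 4 noise genes
        pcc = np.eye(n)
        for block in (range(0, 5), range(5, 10)):
            for i in block:
                for j in block:
                    pcc[i, j] = 1.0 if i == j else 0.95
        modules = candidate_modules(pcc, min_size=5, cut_height=0.5)
        assert modules == [tuple(range(0, 5)), tuple(range(5, 10))]

    def test_identity_matrix_yields_no_modules(self):
        assert candidate_modules(np.eye(20), min_size=2) == []

    def test_planted_module_jaccard(self):
        # 30-gene module among 100, strong coupling, 40 samples
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=40)
            module = np.sqrt(0.9) * z + np.sqrt(0.1) * rng.normal(size=(30, 40))
            noise = rng.normal(size=(70, 40))
            pcc = pairwise_pcc(np.vstack([module, noise]))
            found = candidate_modules(pcc, min_size=5, cut_height=0.35)
            best = max(found, key=len)
            truth = set(range(30))
            jac = len(truth & set(best)) / len(truth | set(best))
            hits += jac >= 0.9
        assert hits >= 18

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pcc = pairwise_pcc(rng.normal(size=(40, 8)))
        assert candidate_modules(pcc) == candidate_modules(pcc)


class TestCompositeIndex:
    def test_constant_module_scores_zero(self):
        mat = np.vstack([np.zeros((2, 5)), np.random.default_rng(0).normal(size=(3, 5))])
        genes = [f"g{i}" for i in range(5)]
        score = composite_index(genes[:2], mat, genes)
        assert score.sd_d == 0.0 and score.ci == 0.0

    def test_duplicated_gene_pair_has_unit_pcc_d(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        mat = np.vstack([x, x, rng.normal(size=(4, 6))])
        genes = [f"g{i}" for i in range(6)]
        score = composite_index(genes[:2], mat, genes)
        assert score.pcc_d == pytest.approx(1.0)
        assert score.ci == pytest.approx(score.sd_d / max(score.pcc_o, 1e-6))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(12, 6))
        genes = [f"g{i}" for i in range(12)]
        members = ["g1", "g4", "g7", "g10"]
        score = composite_index(members, mat, genes)
        rows = {g: list(mat[i]) for i, g in enumerate(genes)}
        sd_d, pcc_d, pcc_o, ci = ci_brute_force(
            [rows[g] for g in members],
            [rows[g] for g in genes if g not in members],
        )
        assert score.sd_d == pytest.approx(sd_d, abs=1e-10)
        assert score.pcc_d == pytest.approx(pcc_d, abs=1e-10)
        assert score.pcc_o == pytest.approx(pcc_o, abs=1e-10)
        assert score.ci == pytest.approx(ci, abs=1e-10)

    def test_module_equal_to_universe_rejected(self):
        mat = np.random.default_rng(0).normal(size=(3, 5))
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError, match="PCC_o"):
            composite_index(genes, mat, genes)

    def test_scaling_members_scales_ci_linearly(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(10, 6))
        genes = [f"g{i}" for i in range(10)]
        members = genes[:4]
        base = composite_index(members, mat, genes)
        scaled = mat.copy()
        scaled[:4] *= 3.0
        score = composite_index(members, scaled, genes)
        assert score.sd_d == pytest.approx(3 * base.sd_d)
        assert score.pcc_d == pytest.approx(base.pcc_d)
        assert score.pcc_o == pytest.approx(base.pcc_o)
        assert score.ci == pytest.approx(3 * base.ci)

    def test_invariant_to_gene_relabeling_and_sample_permutation(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(8, 7))
        genes = [f"g{i}" for i in range(8)]
        base = composite_index(genes[:3], mat, genes)
        perm = rng.permutation(8)
        permuted = composite_index(
            [genes[i] for i in perm if i < 3],
            mat[perm][:, rng.permutation(7)],
            [genes[i] for i in perm],
        )
        assert permuted.ci == pytest.approx(base.ci)


class TestDetectDnb:
    def test_amplified_noise_window_wins(self):
        # 3 time points; the last one is an amplified copy of the noise level
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 6))
        amplified = 5.0 * rng.normal(size=(20, 3))
        values = np.hstack([base, amplified])
        ds = make_dataset(values, times=[0] * 3 + [1] * 3 + [2] * 3,
                          reps=[1, 2, 3] * 3)
        res = detect_dnb(ds, build_windows(ds), min_size=2, cut_height=0.6)
        assert res.tipping_window == 2

    def test_deterministic_rerun(self):
        ds, _ = simulate_transition(TransitionSimSpec(n_genes=100, module_size=10, seed=8))
        w = build_windows(ds)
        r1 = detect_dnb(ds, w)
        r2 = detect_dnb(ds, w)
        assert r1.ci_curve == r2.ci_curve
        assert r1.dnb_genes == r2.dnb_genes
        assert r1.tipping_window == r2.tipping_window

    def test_curve_invariants(self):
        ds, truth = simulate_transition(TransitionSimSpec(n_genes=100, module_size=10, seed=9))
        w = build_windows(ds)
        res = detect_dnb(ds, w)
        assert len(res.ci_curve) == len(w)
        assert res.ci_curve[res.tipping_window - 1] == max(res.ci_curve)
        assert res.dnb_genes
        assert set(res.dnb_genes) <= set(ds.gene_ids)

    def test_needs_two_windows(self, small_dataset):
        w = build_windows(small_dataset)
        with pytest.raises(ValueError, match="2 windows"):
            detect_dnb(small_dataset, w)


class TestBootstrap:
    def test_zero_ci_module_gets_p_one(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(30, 6))
        values[:2, 3:] = 7.0  # constant case values -> SD_d = 0 -> CI = 0
        ds = make_dataset(values, times=[0] * 3 + [1] * 3, reps=[1, 2, 3] * 2)
        w = build_windows(ds)[0]
        p = bootstrap_significance(ds, w, ["g0", "g1"], n_boot=100, seed=0)
        assert p == 1.0

    def test_reproducible_given_seed(self):
        ds, truth = simulate_transition(TransitionSimSpec(n_genes=80, module_size=8, seed=3))
        w = build_windows(ds)[truth["tipping_index"] - 1]
        p1 = bootstrap_significance(ds, w, truth["module_genes"], n_boot=150, seed=5)
        p2 = bootstrap_significance(ds, w, truth["module_genes"], n_boot=150, seed=5)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_planted_module_is_significant(self):
        ds, truth = simulate_transition(TransitionSimSpec(n_genes=200, module_size=20, seed=4))
        w = build_windows(ds)[truth["tipping_index"] - 1]
        p = bootstrap_significance(ds, w, truth["module_genes"], n_boot=200, seed=1)
        assert p <= 0.05

    def test_small_n_boot_rejected(self, small_dataset):
        w = build_windows(small_dataset)[0]
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_significance(small_dataset, w, ["g0"], n_boot=10, seed=0)
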