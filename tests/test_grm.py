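"""GRM estimator arithmetic, cross-GRM expectations, pruning, GCTA IO."""

import numpy as np
import pandas as pd
import pytest

import famgreml as fg
from famgreml.grm import (
    GRM,
    GRMSet,
    compute_cross_grm,
    compute_grm,
    prune_relatedness,
    read_gcta_grm,
    write_gcta_grm,
)


def _ids(labels):
    return pd.DataFrame({"fid": labels, "iid": labels})


class TestComputeGrm:
    def test_single_snp_hand_arithmetic(self):
        # x = 2 at p = 0.5: (2 - 1)^2 / (2 * 0.5 * 0.5) = 2
        g = compute_grm(np.array([[2.0]]), freqs=np.array([0.5]))
        assert g.values[0, 0] == pytest.approx(2.0)

    def test_identical_genotypes_equal_diagonal(self):
        rng = np.random.default_rng(0)
        row = rng.binomial(2, 0.4, 300).astype(float)
        g = compute_grm(np.vstack([row, row]), freqs=np.full(300, 0.4))
        assert g.values[0, 1] == pytest.approx(g.values[0, 0])

    def test_unrelated_sample_diag_and_offdiag(self):
        # sample-frequency centering makes the expected off-diagonal mean
        # -1/(n-1), so n must be large enough for the +/-0.005 band
        rng = np.random.default_rng(1)
        n, m = 500, 2000
        p = rng.uniform(0.1, 0.5, m)
        geno = rng.binomial(2, p, size=(n, m))
        g = compute_grm(geno)
        assert 0.98 < np.diag(g.values).mean() < 1.02
        off = g.values[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.005

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(2)
        geno = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        perm = rng.permutation(200)
        a = compute_grm(geno).values
        b = compute_grm(geno[:, perm]).values
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_genotypes_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        geno = rng.binomial(2, 0.4, size=(12, 60)).astype(float)
        geno[rng.random(geno.shape) < 0.15] = np.nan
        freqs = np.full(60, 0.4)
        g = compute_grm(geno, freqs=freqs)
        # brute-force per-pair loop over shared observed SNPs
        z = (geno - 2 * 0.4) / np.sqrt(2 * 0.4 * 0.6)
        for j in range(12):
            for k in range(j, 12):
                shared = ~np.isnan(z[j]) & ~np.isnan(z[k])
                expected = np.nanmean(z[j, shared] * z[k, shared])
                assert g.values[j, k] == pytest.approx(expected, abs=1e-12)
                assert g.n_pairs[j, k] == shared.sum()

    def test_monomorphic_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            compute_grm(np.array([[0.0], [0.0]]), freqs=np.array([0.0]))


class TestCrossGrm:
    def test_true_pairs_concentrate_at_half(self):
        cfg = fg.SimulationConfig(n_families=500, n_snps=2000, n_causal=2000, seed=4)
        cohort = fg.simulate_trio_genotypes(cfg)
        cross = compute_cross_grm(cohort.child_genotypes, cohort.mother_genotypes)
        diag = np.diag(cross.values)
        assert abs(diag.mean() - 0.5) < 3 * diag.std() / np.sqrt(len(diag))

    def test_off_family_entries_near_zero(self):
        cfg = fg.SimulationConfig(n_families=300, n_snps=1500, n_causal=1500, seed=5)
        cohort = fg.simulate_trio_genotypes(cfg)
        cross = compute_cross_grm(cohort.child_genotypes, cohort.mother_genotypes)
        off = cross.values[~np.eye(300, dtype=bool)]
        assert abs(off.mean()) < 0.005

    def test_estimator_symmetric_across_pathways(self):
        # the same individual supplied as a child row and as a parent column
        rng = np.random.default_rng(6)
        geno = rng.binomial(2, 0.3, size=(8, 400)).astype(float)
        freqs = np.full(400, 0.3)
        cross = compute_cross_grm(geno, geno, freqs=freqs)
        within = compute_grm(geno, freqs=freqs)
        assert np.allclose(cross.values, within.values, atol=1e-12)

    def test_snp_panel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compute_cross_grm(np.zeros((3, 10)), np.zeros((3, 12)))

    def test_joint_two_generation_matrix_near_psd(self):
        cfg = fg.SimulationConfig(n_families=200, n_snps=5000, n_causal=5000, seed=7)
        cohort = fg.simulate_trio_genotypes(cfg)
        gs = fg.build_grm_set(cohort.family_ids, cohort.child_genotypes,
                              cohort.mother_genotypes)
        joint = np.block([[gs.offspring.values, gs.cross.values],
                          [gs.cross.values.T, gs.parental.values]])
        assert np.linalg.eigvalsh(joint).min() > -0.05


def _toy_grm_set(values, fids):
    n = len(fids)
    g = GRM(_ids(fids), np.asarray(values, dtype=float), 100)
    return GRMSet(g, None, None, np.asarray(fids))


class TestPruneRelatedness:
    def test_all_below_cutoff_retains_everyone(self):
        vals = np.eye(4)
        gs = _toy_grm_set(vals, ["F1", "F2", "F3", "F4"])
        assert list(prune_relatedness(gs, 0.025)) == ["F1", "F2", "F3", "F4"]

    def test_single_related_pair_removes_larger_index(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.5
        gs = _toy_grm_set(vals, ["F1", "F2", "F3"])
        retained = list(prune_relatedness(gs, 0.025))
        # brute-force minimal removal: exactly one of {F1, F2}; tie -> F2 out
        assert retained == ["F1", "F3"]

    def test_sibling_cluster_removed_greedily(self):
        n = 100
        vals = np.eye(n) * 1.0
        for i in range(4):
            for j in range(4):
                if i != j:
                    vals[i, j] = 0.5
        gs = _toy_grm_set(vals, [f"F{i:03d}" for i in range(n)])
        retained = prune_relatedness(gs, 0.025)
        assert len(retained) == 97
        assert "F000" in retained  # greedy keeps one member of the clique

    def test_cross_matrix_violations_count_but_own_pair_exempt(self):
        n = 3
        off = np.eye(n)
        par = np.eye(n)
        cross = np.full((n, n), 0.0)
        np.fill_diagonal(cross, 0.5)  # own parent: exempt
        g_off = GRM(_ids(["F1", "F2", "F3"]), off, 100)
        g_par = GRM(_ids(["M1", "M2", "M3"]), par, 100)
        from famgreml.grm import CrossGRM

        c = CrossGRM(_ids(["F1", "F2", "F3"]), _ids(["M1", "M2", "M3"]), cross, 100)
        gs = GRMSet(g_off, g_par, c, np.array(["F1", "F2", "F3"]))
        assert len(prune_relatedness(gs, 0.025)) == 3
        # now plant a cross-generation violation: child 0 related to parent 2
        cross2 = cross.copy()
        cross2[0, 2] = 0.3
        gs2 = GRMSet(g_off, g_par,
                     CrossGRM(_ids(["F1", "F2", "F3"]), _ids(["M1", "M2", "M3"]), cross2, 100),
                     np.array(["F1", "F2", "F3"]))
        assert len(prune_relatedness(gs2, 0.025)) == 2

    def test_postcondition_exact_scan(self):
        rng = np.random.default_rng(8)
        n = 60
        vals = rng.normal(0, 0.02, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        fids = np.array([f"F{i:03d}" for i in range(n)])
        gs = _toy_grm_set(vals, fids)
        retained = prune_relatedness(gs, 0.025)
        idx = np.flatnonzero(np.isin(fids, retained))
        sub = vals[np.ix_(idx, idx)]
        off = sub[~np.eye(len(idx), dtype=bool)]
        assert (off <= 0.025).all()

    def test_nonpositive_cutoff_rejected(self):
        gs = _toy_grm_set(np.eye(2), ["F1", "F2"])
        with pytest.raises(ValueError):
            prune_relatedness(gs, 0.0)


class TestGctaIO:
    def test_small_roundtrip_exact(self, tmp_path):
        vals = np.array([[1.0, 0.1, 0.0], [0.1, 0.9, 0.25], [0.0, 0.25, 1.1]])
        g = GRM(_ids(["A", "B", "C"]), vals, 500)
        prefix = str(tmp_path / "toy")
        write_gcta_grm(g, prefix)
        assert (tmp_path / "toy.grm.bin").stat().st_size == 6 * 4  # 6 float32 values
        back = read_gcta_grm(prefix)
        assert np.allclose(back.values, vals, atol=0)  # values are float32-exact
        assert list(back.ids["iid"]) == ["A", "B", "C"]

    def test_large_roundtrip_within_float32(self, tmp_path):
        rng = np.random.default_rng(9)
        n = 200
        vals = rng.normal(0, 0.05, (n, n))
        vals = (vals + vals.T) / 2 + np.eye(n)
        g = GRM(_ids([f"I{i}" for i in range(n)]), vals, 1234)
        prefix = str(tmp_path / "big")
        write_gcta_grm(g, prefix)
        back = read_gcta_grm(prefix)
        assert np.abs(back.values - vals).max() < 1e-6
        assert back.n_snps == 1234

    def test_inconsistent_sizes_rejected(self, tmp_path):
        g = GRM(_ids(["A", "B", "C"]), np.eye(3), 10)
        prefix = str(tmp_path / "bad")
        write_gcta_grm(g, prefix)
        with open(prefix + ".grm.id", "a") as fh:
            fh.write("D\tD\n")
        with pytest.raises(ValueError, match="expected"):
            read_gcta_grm(prefix)

    def test_subsampling_snps_perturbs_entries_at_root_m_scale(self):
        rng = np.random.default_rng(10)
        geno = rng.binomial(2, 0.3, size=(50, 4000)).astype(float)
        full = compute_grm(geno, freqs=np.full(4000, 0.3)).values
        half = compute_grm(geno[:, :1000], freqs=np.full(1000, 0.3)).values
        off = ~np.eye(50, dtype=bool)
        spread = (half - full)[off].std()
        assert 0.3 / np.sqrt(1000) < spread < 3.0 / np.sqrt(1000)
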