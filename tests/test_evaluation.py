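"""Phenotype adjustment, ANOVA variance components, CV machinery,
percent-change reporting and LD decay."""

import numpy as np
import pandas as pd
import pytest

from gbspredict import (MCMCConfig, ModelSpec, PhenotypeParams,
                        VarianceComponents, adjust_phenotypes, anova_varcomp,
                        heritability, ld_r2, make_partitions, percent_change,
                        run_cv, simulate_phenotypes, simulate_study)
from gbspredict.relmat import RelationshipMatrix


class TestAdjustPhenotypes:
    def test_no_nuisance_effects_recovers_raw_means(self, study):
        geno = study[0]
        params = PhenotypeParams(sigma_ge2=0.0, sigma_e2=0.0, block_sd=0.0,
                                 env_sd=0.0)
        plots, _ = simulate_phenotypes(geno, params, seed=1)
        adj = adjust_phenotypes(plots)
        raw = plots.groupby("line", sort=False)["value"].mean()
        np.testing.assert_allclose(adj, raw.reindex(adj.index), atol=1e-8)

    def test_environment_shift_invariance_up_to_constant(self, study):
        plots, _ = simulate_phenotypes(study[0], PhenotypeParams(), seed=2)
        adj = adjust_phenotypes(plots)
        shifted = plots.copy()
        shifted.loc[shifted["env"] == "env1", "value"] += 10.0
        adj2 = adjust_phenotypes(shifted)
        delta = (adj2 - adj).to_numpy()
        np.testing.assert_allclose(delta, delta[0], atol=1e-8)

    def test_adjustment_improves_genetic_signal(self, study):
        geno = study[0]
        params = PhenotypeParams(block_sd=3.0)
        plots, tbv = simulate_phenotypes(geno, params, seed=3)
        adj = adjust_phenotypes(plots).reindex(tbv.index)
        raw = plots.groupby("line")["value"].mean().reindex(tbv.index)
        r_adj = np.corrcoef(adj, tbv)[0, 1]
        r_raw = np.corrcoef(raw, tbv)[0, 1]
        assert r_adj >= r_raw

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            adjust_phenotypes(pd.DataFrame({"line": [], "value": []}))

    def test_disconnected_design_rejected(self):
        plots = pd.DataFrame({
            "line": ["a", "a", "b", "b"],
            "env": ["e1"] * 4,
            "rep": [1, 2, 1, 2],
            "block": ["b1", "b1", "b2", "b2"],  # lines never share a block
            "value": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ValueError, match="orphan blocks"):
            adjust_phenotypes(plots)


class TestVarianceComponents:
    def test_moment_recovery_at_scale(self):
        geno, *_ = simulate_study(n_lines=500, n_chrom=2, markers_per_chrom=120,
                                  seed=21)
        params = PhenotypeParams(n_qtl=100, sigma_g2=1.0, sigma_ge2=1.0,
                                 sigma_e2=1.0, n_env=4, n_rep=2, block_sd=0.0)
        plots, _ = simulate_phenotypes(geno, params, seed=22)
        vc = anova_varcomp(plots)
        assert vc.sigma_g2 == pytest.approx(1.0, rel=0.15)
        assert vc.sigma_ge2 == pytest.approx(1.0, rel=0.15)
        assert vc.sigma_e2 == pytest.approx(1.0, rel=0.15)

    def test_zero_noise_degenerate_case(self, study):
        params = PhenotypeParams(sigma_ge2=0.0, sigma_e2=0.0, block_sd=0.0,
                                 env_sd=0.0)
        plots, tbv = simulate_phenotypes(study[0], params, seed=23)
        vc = anova_varcomp(plots)
        assert vc.sigma_e2 == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma_g2 == pytest.approx(np.var(tbv.to_numpy()), rel=0.05)

    def test_permuting_lines_within_env_destroys_genetic_variance(self, study):
        params = PhenotypeParams(block_sd=0.0)
        plots, _ = simulate_phenotypes(study[0], params, seed=24)
        rng = np.random.default_rng(25)
        shuffled = plots.copy()
        for env, idx in shuffled.groupby("env").groups.items():
            vals = shuffled.loc[idx, "value"].to_numpy()
            shuffled.loc[idx, "value"] = rng.permutation(vals)
        vc0 = anova_varcomp(plots)
        vc1 = anova_varcomp(shuffled)
        assert vc1.sigma_g2 < 0.2 * max(vc0.sigma_g2, 1e-9)

    def test_unbalanced_rejected(self, study):
        plots, _ = simulate_phenotypes(study[0], PhenotypeParams(), seed=26)
        with pytest.raises(ValueError, match="nbalanced"):
            anova_varcomp(plots.iloc[:-1])


class TestHeritability:
    def test_worked_example(self):
        vc = VarianceComponents(1.0, 1.0, 1.0, n_env=4, n_rep=2)
        assert heritability(vc) == pytest.approx(0.7273, abs=1e-4)

    def test_zero_genetic_variance(self):
        assert heritability(VarianceComponents(0, 1, 1, 2, 2)) == 0.0

    def test_limits_and_monotonicity(self):
        base = heritability(VarianceComponents(1, 1, 1, 4, 2))
        assert heritability(VarianceComponents(1, 1, 1, 400000, 2)) \
            == pytest.approx(1.0, abs=1e-4)
        assert heritability(VarianceComponents(2, 1, 1, 4, 2)) > base
        assert heritability(VarianceComponents(1, 1, 1, 8, 2)) > base
        assert 0 <= base <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0, 0, 0, 1, 1))


class TestPartitions:
    def test_sizes_and_disjointness(self):
        parts = make_partitions(10, 0.7, 5, seed=0)
        for p in parts:
            assert len(p.train) == 7 and len(p.test) == 3
            assert set(p.train).isdisjoint(p.test)
            assert set(p.train) | set(p.test) == set(range(10))

    def test_seed_determinism(self):
        a = make_partitions(50, 0.7, 10, seed=1)
        b = make_partitions(50, 0.7, 10, seed=1)
        c = make_partitions(50, 0.7, 10, seed=2)
        assert all(np.array_equal(x.test, y.test) for x, y in zip(a, b))
        assert any(not np.array_equal(x.test, y.test) for x, y in zip(a, c))

    def test_test_set_membership_frequency(self):
        parts = make_partitions(100, 0.7, 50, seed=3)
        counts = np.zeros(100)
        for p in parts:
            counts[p.test] += 1
        expect = 0.3 * 50
        tol = 2 * np.sqrt(50 * 0.3 * 0.7)
        assert np.all(np.abs(counts - expect) <= tol + 3)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            make_partitions(5)
        with pytest.raises(ValueError):
            make_partitions(20, train_fraction=1.5)


class TestPercentChange:
    @pytest.mark.parametrize("model,base,expect", [
        (0.545, 0.518, 5.2),
        (0.469, 0.518, -9.5),
        (0.5, 0.5, 0.0),
    ])
    def test_values(self, model, base, expect):
        assert percent_change(model, base) == expect

    def test_zero_baseline(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.5, 0.0)


class TestRunCV:
    def test_null_trait_mean_correlation_near_zero(self):
        rng = np.random.default_rng(30)
        n = 120
        y = rng.normal(size=n)
        K = RelationshipMatrix(
            np.kron(np.eye(6), np.full((20, 20), 0.4)) + 0.6 * np.eye(n),
            "pedigree-A")
        parts = make_partitions(n, 0.7, 8, seed=31)
        res = run_cv(y, [ModelSpec({"K": K}, "m")], parts,
                     MCMCConfig(n_iter=600, burn_in=200, thin=2, seed=32))
        mean = res.correlations["corr"].mean()
        sd = res.correlations["corr"].std(ddof=1)
        assert abs(mean) < 2 * sd + 0.05

    def test_summary_invariant_to_partition_order(self):
        rng = np.random.default_rng(33)
        n = 60
        y = rng.normal(size=n)
        K = RelationshipMatrix(np.eye(n), "genomic-G")
        parts = make_partitions(n, 0.7, 4, seed=34)
        cfg = MCMCConfig(n_iter=300, burn_in=100, thin=2, seed=35)
        a = run_cv(y, [ModelSpec({"K": K}, "m")], parts, cfg)
        b = run_cv(y, [ModelSpec({"K": K}, "m")], parts[::-1], cfg)
        assert a.summary().equals(
            b.summary().sort_index())

    def test_duplicate_labels_rejected(self):
        K = RelationshipMatrix(np.eye(12), "genomic-G")
        specs = [ModelSpec({"K": K}, "m"), ModelSpec({"K": K}, "m")]
        with pytest.raises(ValueError, match="unique"):
            run_cv(np.zeros(12), specs, make_partitions(12, 0.7, 2, 0),
                   MCMCConfig(n_iter=20, burn_in=5, thin=1, seed=0))


class TestLdR2:
    def test_duplicated_marker_gives_unit_r2_at_zero_distance(self):
        from gbspredict import GenotypeMatrix
        rng = np.random.default_rng(40)
        col = rng.choice([0, 2], size=20).astype(np.int8)
        calls = np.column_stack([col, col])
        g = GenotypeMatrix(calls, [f"l{i}" for i in range(20)], ["a", "b"],
                           ["1", "1"], [100, 100])
        pairs, _ = ld_r2(g, max_distance_bp=1000)
        assert len(pairs) == 1
        assert pairs["distance"].iloc[0] == 0
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_loci_have_tiny_mean_r2(self):
        from gbspredict import GenotypeMatrix
        rng = np.random.default_rng(41)
        n = 500
        calls = rng.choice([0, 2], size=(n, 30)).astype(np.int8)
        g = GenotypeMatrix(calls, [f"l{i}" for i in range(n)],
                           [f"m{j}" for j in range(30)], ["1"] * 30,
                           np.arange(1, 31))
        pairs, _ = ld_r2(g, max_distance_bp=100)
        assert pairs["r2"].mean() < 0.01

    def test_family_structure_elevates_long_distance_ld(self):
        _, obs_fam, *_ = simulate_study(n_lines=150, n_chrom=1,
                                        markers_per_chrom=100, coverage=50,
                                        seed=42)
        from gbspredict import GeneticMap, simulate_founders
        gmap = GeneticMap.uniform(1, 100)
        panel = simulate_founders(150, gmap, maf_low=0.1, maf_high=0.5,
                                  seed=43)
        far = 50_000_000
        fam_pairs, _ = ld_r2(obs_fam, max_distance_bp=10**9)
        pan_pairs, _ = ld_r2(panel, max_distance_bp=10**9)
        fam_far = fam_pairs.loc[fam_pairs["distance"] > far, "r2"].median()
        pan_far = pan_pairs.loc[pan_pairs["distance"] > far, "r2"].median()
        assert fam_far > pan_far

    def test_monomorphic_loci_counted_and_skipped(self):
        from gbspredict import GenotypeMatrix
        calls = np.array([[0, 0], [0, 2], [0, 0], [0, 2]], np.int8)
        g = GenotypeMatrix(calls, list("abcd"), ["m1", "m2"], ["1", "1"],
                           [1, 2])
        pairs, _ = ld_r2(g, max_distance_bp=100)
        assert len(pairs) == 0
        assert pairs.attrs["n_monomorphic"] == 1
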