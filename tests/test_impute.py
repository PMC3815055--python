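"""Haplotype-clustering imputation against an exhaustive brute-force oracle
and its contract invariants (called calls never change, missing set only
shrinks, pairwise compatibility within clusters)."""

import numpy as np
import pytest

from gbspredict import (GenotypeMatrix, HaplotypeImputer, ImputeParams,
                        cluster_at_marker, count_disagreements,
                        haplotype_incidence, impute_at_marker, run_imputation)
from gbspredict.impute import PROV_BIO_MISSING, PROV_CALLED, PROV_IMPUTED


from oracles import (oracle_disagreements, oracle_impute_column,
                     oracle_partition)


def _random_inbred(n, m, miss, seed):
    rng = np.random.default_rng(seed)
    calls = rng.choice([0, 2], size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < miss] = -1
    return GenotypeMatrix(calls, [f"l{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], ["1"] * m,
                          np.arange(1, m + 1))


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------

class TestCountDisagreements:
    def test_identical_lines_zero(self, toy_geno):
        assert count_disagreements(0, 0, np.array([0, 1]), toy_geno) == 0

    def test_single_opposing_locus(self):
        g = _random_inbred(2, 5, 0.0, 1)
        g.calls[0] = [0, 0, 0, 0, 0]
        g.calls[1] = [0, 2, 0, 0, 0]
        assert count_disagreements(0, 1, np.arange(5), g) == 1

    def test_missing_is_never_disagreement(self):
        g = _random_inbred(2, 5, 0.0, 1)
        g.calls[0] = -1
        assert count_disagreements(0, 1, np.arange(5), g) == 0

    def test_empty_window_warns_and_returns_zero(self, toy_geno):
        with pytest.warns(UserWarning, match="empty"):
            assert count_disagreements(0, 1, np.array([], int), toy_geno) == 0


class TestClusterAtMarker:
    def test_identical_lines_single_cluster(self):
        g = _random_inbred(6, 20, 0.0, 2)
        g.calls[:] = g.calls[0]
        labels = cluster_at_marker(g, 10, ImputeParams(flank_size=5))
        assert len(set(labels)) == 1

    def test_two_blocks_differing_beyond_threshold(self):
        g = _random_inbred(10, 20, 0.0, 3)
        g.calls[:5] = 0
        g.calls[5:] = 0
        g.calls[5:, 5:11] = 2  # 5 flanking disagreements > 4 (focal excluded)
        labels = cluster_at_marker(g, 7, ImputeParams(flank_size=5))
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_conflicting_line_is_singleton(self):
        g = _random_inbred(6, 20, 0.0, 4)
        g.calls[:] = 0
        g.calls[-1, 3:9] = 2  # conflicts with everyone at >= 5 loci
        labels = cluster_at_marker(g, 6, ImputeParams(flank_size=5))
        assert sum(labels == labels[-1]) == 1


class TestImputeAtMarker:
    def _geno(self, column):
        g = _random_inbred(len(column), 3, 0.0, 5)
        g.calls[:, 1] = column
        return g

    def test_cluster_with_one_call_imputes_missing(self):
        g = self._geno([2, -1])
        col, prov = impute_at_marker(g, 1, np.array([0, 0]))
        assert col[1] == 2 and prov[1] == PROV_IMPUTED

    def test_all_missing_cluster_stays_missing(self):
        g = self._geno([-1, -1])
        col, prov = impute_at_marker(g, 1, np.array([0, 0]))
        assert list(col) == [-1, -1]
        assert all(p == PROV_BIO_MISSING for p in prov)

    def test_majority_consensus_and_tie(self):
        g = self._geno([0, 0, 2, -1])
        col, _ = impute_at_marker(g, 1, np.zeros(4, int))
        assert col[3] == 0  # majority
        g2 = self._geno([0, 2, -1])
        col2, _ = impute_at_marker(g2, 1, np.zeros(3, int))
        assert col2[2] == -1  # exact tie left missing

    def test_called_members_untouched(self):
        g = self._geno([0, 0, 2, -1])
        col, prov = impute_at_marker(g, 1, np.zeros(4, int))
        assert list(col[:3]) == [0, 0, 2]
        assert all(p == PROV_CALLED for p in prov[:3])


class TestRunImputation:
    def test_complete_matrix_unchanged(self):
        g = _random_inbred(8, 30, 0.0, 6)
        imp, _ = run_imputation(g, ImputeParams(flank_size=5))
        np.testing.assert_array_equal(imp.geno.calls, g.calls)
        assert (imp.provenance == PROV_CALLED).all()

    def test_heterozygotes_rejected(self):
        g = _random_inbred(4, 10, 0.1, 7)
        g.calls[0, 0] = 1
        with pytest.raises(ValueError, match="set_heterozygotes_missing"):
            run_imputation(g)

    def test_called_cells_never_altered_and_missing_only_shrinks(self):
        g = _random_inbred(15, 60, 0.4, 8)
        imp, _ = run_imputation(g, ImputeParams(flank_size=10))
        called = g.calls != -1
        np.testing.assert_array_equal(imp.geno.calls[called], g.calls[called])
        assert not (imp.geno.missing_mask & ~g.missing_mask).any()

    def test_provenance_exhaustive(self):
        g = _random_inbred(15, 60, 0.4, 9)
        imp, _ = run_imputation(g, ImputeParams(flank_size=10))
        assert set(np.unique(imp.provenance)) <= {PROV_CALLED, PROV_IMPUTED,
                                                  PROV_BIO_MISSING}
        assert ((imp.provenance == PROV_CALLED) == (g.calls != -1)).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        """Sweep output equals the exhaustive pairwise oracle marker by
        marker, for clustering labels and imputed calls alike."""
        g = _random_inbred(10, 30, 0.35, 100 + seed)
        params = ImputeParams(flank_size=4, max_disagreements=1)
        imp, clus = run_imputation(g, params)
        for marker in range(g.n_markers):
            labels = oracle_partition(g.calls, marker, 4, 1)
            np.testing.assert_array_equal(
                clus.labels[:, marker], labels,
                err_msg=f"cluster mismatch at marker {marker}")
            np.testing.assert_array_equal(
                imp.geno.calls[:, marker],
                oracle_impute_column(g.calls, marker, labels),
                err_msg=f"imputation mismatch at marker {marker}")

    def test_python_api_agrees_with_sweep(self):
        g = _random_inbred(8, 40, 0.3, 11)
        params = ImputeParams(flank_size=6, max_disagreements=2)
        imp, clus = run_imputation(g, params)
        for marker in (0, 7, 20, 39):
            np.testing.assert_array_equal(
                cluster_at_marker(g, marker, params), clus.labels[:, marker])

    def test_pairwise_property_within_clusters(self):
        """Any pair sharing a cluster has <= max_disagreements opposing
        homozygotes over that marker's window (complete linkage)."""
        g = _random_inbred(10, 40, 0.3, 12)
        params = ImputeParams(flank_size=5, max_disagreements=2)
        _, clus = run_imputation(g, params)
        for marker in range(0, 40, 7):
            window = [w for w in range(max(0, marker - 5), min(40, marker + 6))
                      if w != marker]
            labels = clus.labels[:, marker]
            for i in range(10):
                for j in range(i + 1, 10):
                    if labels[i] == labels[j]:
                        assert oracle_disagreements(
                            g.calls, i, j, window) <= 2

    def test_shrinking_flank_never_imputes_fewer_cells(self):
        g = _random_inbred(20, 80, 0.4, 13)
        n_by_flank = [run_imputation(g, ImputeParams(flank_size=f))[0].n_imputed
                      for f in (5, 20, 80)]
        assert n_by_flank[0] >= n_by_flank[1] >= n_by_flank[2]


class TestHaplotypeIncidence:
    def test_partition_property_row_sums(self):
        g = _random_inbred(12, 30, 0.3, 14)
        _, clus = run_imputation(g, ImputeParams(flank_size=5))
        H, names = haplotype_incidence(clus)
        assert H.shape[0] == 12
        # each line carries exactly one haplotype allele per marker
        n_markers = clus.labels.shape[1]
        assert H.sum() == 12 * n_markers
        col_marker = [nm.rsplit(".c", 1)[0] for nm in names]
        import pandas as pd
        per_marker = pd.DataFrame(H, columns=col_marker).T.groupby(level=0).sum()
        assert (per_marker == 1).all().all()

    def test_single_cluster_gives_all_ones_column(self):
        g = _random_inbred(5, 10, 0.0, 15)
        g.calls[:] = g.calls[0]
        _, clus = run_imputation(g, ImputeParams(flank_size=3))
        H, names = haplotype_incidence(clus)
        assert H.shape == (5, 10)
        assert (H == 1).all()

    def test_hand_built_partition(self):
        from gbspredict.impute import HaplotypeClustering
        labels = np.array([[0], [0], [0], [1], [1]])
        clus = HaplotypeClustering(labels, [f"l{i}" for i in range(5)],
                                   ["m0"], np.array(["1"], object))
        H, names = clus.incidence()
        np.testing.assert_array_equal(
            H, [[1, 0], [1, 0], [1, 0], [0, 1], [0, 1]])
        assert names == ["m0.c0", "m0.c1"]

    def test_stride_thins_markers(self):
        g = _random_inbred(6, 20, 0.2, 16)
        imp = HaplotypeImputer(flank_size=4, stride=5).fit(g)
        H, names = imp.haplotype_incidence()
        markers = {nm.rsplit(".c", 1)[0] for nm in names}
        assert len(markers) == 4


class TestEstimatorApi:
    def test_sklearn_params_round_trip(self):
        imp = HaplotypeImputer(flank_size=50)
        assert imp.get_params()["flank_size"] == 50
        imp.set_params(max_disagreements=0)
        assert imp.max_disagreements == 0

    def test_fit_transform_returns_imputed_matrix(self):
        g = _random_inbred(10, 30, 0.3, 17)
        out = HaplotypeImputer(flank_size=5).fit_transform(g)
        assert out.missing_fraction() <= g.missing_fraction()
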