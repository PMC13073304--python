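from __future__ import annotations

import math

import numpy as np
import pytest

from propolis_risk import (
    Element,
    GeneratorSpec,
    Policy,
    build_paper_fixture,
    correlation_report,
    cut_clusters,
    default_paper_spec,
    flag_outliers,
    generate,
    run_pca,
    to_matrix,
    ward_cluster,
)
from propolis_risk.chemometrics import classify_r, region_association

from conftest import make_records


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def pca_oracle(X):
    """Eigen-decomposition of the correlation matrix: explained-variance
    percentages and loadings with the largest-entry-positive convention."""
    R = np.corrcoef(X, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] *= -1
    return 100.0 * eigvals / eigvals.sum(), eigvecs


def ward_oracle(X):
    """Scan-all-pairs agglomeration with the Lance-Williams Ward update,
    lowest-index tie-break. Returns (a, b, height, size) merges."""
    n = len(X)
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(np.linalg.norm(X[i] - X[j]))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    merges = []
    for step in range(n - 1):
        best = None
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                d = D[(min(a, b), max(a, b))]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        sa, sb = sizes[a], sizes[b]
        new = n + step
        merges.append((a, b, d, sa + sb))
        for c in active:
            if c in (a, b):
                continue
            sc = sizes[c]
            dac = D[(min(a, c), max(a, c))]
            dbc = D[(min(b, c), max(b, c))]
            d2 = ((sa + sc) * dac**2 + (sb + sc) * dbc**2 - sc * d**2) / (sa + sb + sc)
            D[(min(new, c), max(new, c))] = math.sqrt(max(d2, 0.0))
        active.remove(a)
        active.remove(b)
        active.append(new)
        sizes[new] = sa + sb
    return merges


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------

class TestCorrelation:
    def test_labels(self):
        assert classify_r(0.80) == "high"
        assert classify_r(0.4) == "moderate"
        assert classify_r(0.51) == "high"
        assert classify_r(0.5) == "moderate"
        assert classify_r(0.3) == "moderate"
        assert classify_r(0.29) == "weak"
        assert classify_r(-0.9) == "weak"
        assert classify_r(float("nan")) == "undefined"

    def test_matrix_invariants(self, fixture_samples):
        report = correlation_report(fixture_samples)
        mat = report.matrix.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.all(np.abs(mat) <= 1.0 + 1e-12)

    def test_identical_columns_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 50, 8)
        X = np.column_stack([rng.uniform(1, 5, 8), v, rng.uniform(1, 5, 8), v])
        report = correlation_report(make_records(X))
        assert report.pair("Cd", "Mn") == pytest.approx(1.0)
        assert report.labels[("Cd", "Mn")] == "high"

    def test_zero_variance_column_undefined(self):
        rng = np.random.default_rng(1)
        X = np.column_stack(
            [np.full(6, 5.0), rng.uniform(1, 5, 6), rng.uniform(1, 5, 6), rng.uniform(1, 50, 6)]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            report = correlation_report(make_records(X))
        assert math.isnan(report.pair("As", "Cd"))
        assert report.labels[("As", "Cd")] == "undefined"
        assert report.pair("As", "As") == 1.0

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            correlation_report(make_records([[1, 1, 1, 10], [2, 2, 2, 20]]))


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class TestPca:
    def test_rank_one_pc1_explains_all(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = np.column_stack([t, 2 * t, 3 * t, 10 * t])
        result = run_pca(make_records(X))
        assert result.explained_variance_pct[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self, fixture_samples):
        result = run_pca(fixture_samples)
        assert result.explained_variance_pct.sum() == pytest.approx(100.0, rel=1e-9)
        assert np.all(result.explained_variance_pct >= -1e-12)

    def test_loadings_orthonormal(self, fixture_samples):
        L = run_pca(fixture_samples).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_scores_covariance_diagonal(self, fixture_samples):
        S = run_pca(fixture_samples).scores.to_numpy()
        cov = np.cov(S, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_sign_convention(self, fixture_samples):
        L = run_pca(fixture_samples).loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1.0, 50.0, size=(4, 4))
        result = run_pca(make_records(X))
        evr, loadings = pca_oracle(X)
        assert np.allclose(result.explained_variance_pct, evr, atol=1e-8)
        # compare spanned directions component-wise (sign fixed identically)
        k = np.sum(evr > 1e-9)
        assert np.allclose(result.loadings.to_numpy()[:, :k], loadings[:, :k], atol=1e-8)

    def test_constant_column_error_names_column(self):
        X = np.column_stack(
            [np.full(5, 5.0), np.arange(1.0, 6.0), np.arange(1.0, 6.0) * 2, np.arange(10.0, 15.0)]
        )
        with pytest.raises(ValueError, match="As"):
            run_pca(make_records(X))

    def test_unstandardized_allows_constant_column(self):
        X = np.column_stack(
            [np.full(5, 5.0), np.arange(1.0, 6.0), np.arange(1.0, 6.0) * 2, np.arange(10.0, 15.0)]
        )
        result = run_pca(make_records(X), standardize=False)
        assert result.explained_variance_pct.sum() == pytest.approx(100.0)


# --------------------------------------------------------------------------
# Ward clustering
# --------------------------------------------------------------------------

class TestWard:
    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 50, size=(5, 4))
        X[3] = X[1]
        dendro = ward_cluster(make_records(X))
        a, b, h, size = dendro.merges[0]
        assert {a, b} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)
        assert size == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(1.0, 60.0, size=(6, 4))
        dendro = ward_cluster(make_records(X), normalize=False)
        expected = ward_oracle(X)
        for (a, b, h, c), (ea, eb, eh, ec) in zip(dendro.merges, expected):
            assert {a, b} == {ea, eb}
            assert h == pytest.approx(eh, rel=1e-9)
            assert c == ec

    def test_merge_heights_monotone_on_random_data(self):
        spec0 = default_paper_spec(n_samples=8)
        for seed in range(200):
            spec = GeneratorSpec(
                n_samples=8,
                margins=spec0.margins,
                correlation=spec0.correlation,
                seed=seed,
            )
            dendro = ward_cluster(generate(spec), policy=Policy.HALF_LOQ)
            heights = [m[2] for m in dendro.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_duplicate_ids_rejected(self):
        recs = make_records(np.random.default_rng(0).uniform(1, 50, (3, 4)))
        with pytest.raises(ValueError, match="duplicate"):
            ward_cluster(recs + recs)

    @pytest.mark.parametrize("seed", range(10))
    def test_fixture_p06_p10_co_cluster(self, seed):
        # Pb's raw magnitude drives the split, hence the unnormalized tree.
        dendro = ward_cluster(build_paper_fixture(seed), normalize=False)
        labels = cut_clusters(dendro, 3)
        assert labels["P06"] == labels["P10"]

    def test_newick_round_trip_leaf_count(self, fixture_samples):
        import dendropy

        newick = ward_cluster(fixture_samples).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == 12
        names = {leaf.taxon.label for leaf in tree.leaf_nodes()}
        assert names == {f"P{i:02d}" for i in range(1, 13)}

    def test_merge_table_shape(self, fixture_samples):
        table = ward_cluster(fixture_samples).to_merge_table()
        assert len(table) == 11
        assert list(table.columns) == ["cluster_a", "cluster_b", "height", "size"]


# --------------------------------------------------------------------------
# Outlier flagging
# --------------------------------------------------------------------------

class TestFlagOutliers:
    @pytest.mark.parametrize("seed", range(10))
    def test_fixture_flags_p06_p10(self, seed):
        pca = run_pca(build_paper_fixture(seed), standardize=False)
        assert set(flag_outliers(pca)) == {"P06", "P10"}

    def test_identical_rows_no_outliers(self):
        X = np.tile([1.0, 1.0, 1.0, 10.0], (6, 1))
        pca = run_pca(make_records(X), standardize=False)
        assert flag_outliers(pca) == []

    def test_injected_gross_outlier_flagged(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1.0, 5.0, size=(12, 4))
        X[7, 2] = 500.0  # gross single-element outlier
        pca = run_pca(make_records(X), standardize=False)
        flagged = flag_outliers(pca)
        assert "S08" in flagged
        # verify against a direct distance computation
        scores = pca.scores.to_numpy()
        d = np.linalg.norm(scores - scores.mean(0), axis=1)
        assert d[7] > 2 * np.median(d)


def test_region_association_returns_valid_p(fixture_samples):
    dendro = ward_cluster(fixture_samples, normalize=False)
    labels = cut_clusters(dendro, 3)
    result = region_association(fixture_samples, labels, n_permutations=99, seed=0)
    assert 0 < result["p_value"] <= 1
    assert result["statistic"] >= 0


def test_to_matrix_policy_changes_censored_cells(fixture_samples):
    zero = to_matrix(fixture_samples, Policy.ZERO)
    half = to_matrix(fixture_samples, Policy.HALF_LOQ)
    assert zero.loc["P11", "Cd"] == 0.0
    assert half.loc["P11", "Cd"] == pytest.approx(0.004)
    assert zero.loc["P06", "Pb"] == half.loc["P06", "Pb"] == 117.01
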