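"""Factorability diagnostics, PCA extraction, varimax rotation, assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spascreen.cohort import CohortDataset, ItemSpec, SubjectRecord
from spascreen.factor import (
    CorrelationMatrix,
    assign_items,
    bartlett_sphericity,
    correlation_matrix,
    extract_components,
    factorability,
    kmo_index,
    rotate_solution,
    tetrachoric_rho,
    varimax_criterion,
    varimax_rotate,
)


def corr(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"v{i}" for i in range(values.shape[0]))
    return CorrelationMatrix(values=values, items=tuple(labels))


def random_correlation(rng, p):
    """Random positive-definite correlation matrix via random factors."""
    f = rng.normal(size=(p, p + 4))
    s = f @ f.T + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


def make_binary_cohort(matrix, item_ids=None):
    p = matrix.shape[1]
    items = tuple(
        ItemSpec(item_ids[j] if item_ids else f"q{j + 1:02d}", f"k{j}",
                 "none", 0.0, (0.5, 0.5, 0.5))
        for j in range(p)
    )
    subjects = tuple(
        SubjectRecord(f"S{i}", "case", 40.0, "M", None, tuple(int(v) for v in row))
        for i, row in enumerate(matrix)
    )
    return CohortDataset(subjects=subjects, items=items)


class TestCorrelationMatrix:
    def test_duplicated_items_correlate_perfectly(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        ds = make_binary_cohort(np.column_stack([x, x]))
        R = correlation_matrix(ds)
        assert R.values[0, 1] == pytest.approx(1.0)

    def test_complementary_items_anticorrelate(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        ds = make_binary_cohort(np.column_stack([x, 1 - x]))
        assert correlation_matrix(ds).values[0, 1] == pytest.approx(-1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(11)
        n = 4000
        ds = make_binary_cohort((rng.random((n, 2)) < 0.5).astype(int))
        assert abs(correlation_matrix(ds).values[0, 1]) < 3 / np.sqrt(n)

    def test_zero_variance_item_flagged(self, rng):
        x = (rng.random(50) < 0.5).astype(int)
        ds = make_binary_cohort(np.column_stack([x, np.zeros(50, dtype=int)]))
        R = correlation_matrix(ds)
        assert R.degenerate == ("q02",)
        assert R.values[0, 1] == 0.0

    def test_all_constant_rejected(self):
        ds = make_binary_cohort(np.zeros((20, 3), dtype=int))
        with pytest.raises(ValueError):
            correlation_matrix(ds)

    def test_tetrachoric_recovers_latent_rho(self):
        rng = np.random.default_rng(5)
        n = 5000
        rho = 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        ds = make_binary_cohort((z > 0).astype(int))
        R = correlation_matrix(ds, method="tetrachoric")
        assert R.values[0, 1] == pytest.approx(rho, abs=0.05)
        # phi on the same data is attenuated below the latent correlation
        phi = correlation_matrix(ds).values[0, 1]
        assert phi < R.values[0, 1]

    def test_tetrachoric_perfect_table(self):
        assert tetrachoric_rho(40, 0, 0, 40) > 0.9


class TestKmo:
    def test_identity_matrix_rejected(self):
        with pytest.raises(ValueError):
            kmo_index(corr(np.eye(4)))

    def test_three_variable_partial_correlation_oracle(self):
        # brute-force oracle: first-order partial correlations
        r12, r13, r23 = 0.5, 0.4, 0.3
        R = corr([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])

        def partial(rij, rik, rjk):
            return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))

        p12 = partial(r12, r13, r23)
        p13 = partial(r13, r12, r23)
        p23 = partial(r23, r12, r13)
        r2 = 2 * (r12**2 + r13**2 + r23**2)
        q2 = 2 * (p12**2 + p13**2 + p23**2)
        assert kmo_index(R) == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_one_factor_matrix_is_adequate(self):
        p = 6
        R = corr(np.full((p, p), 0.5) + 0.5 * np.eye(p))
        assert kmo_index(R) > 0.7

    def test_singular_matrix_rejected(self):
        v = np.array([[1, 1.0], [1.0, 1]])
        with pytest.raises(ValueError, match="singular"):
            kmo_index(corr(v))


class TestBartlett:
    def test_identity_gives_zero(self):
        chi2, df, p = bartlett_sphericity(corr(np.eye(5)), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 10
        assert p == pytest.approx(1.0)

    def test_two_variable_closed_form(self):
        R = corr([[1, 0.5], [0.5, 1]])
        chi2, df, _ = bartlett_sphericity(R, n=101)
        assert chi2 == pytest.approx(-(100 - 9 / 6) * np.log(0.75), rel=1e-12)
        assert df == 1

    def test_statistic_increases_with_correlation(self):
        stats_ = [
            bartlett_sphericity(corr([[1, r], [r, 1]]), n=50)[0]
            for r in (0.1, 0.3, 0.5, 0.7)
        ]
        assert all(a < b for a, b in zip(stats_, stats_[1:]))

    def test_requires_n_above_p(self):
        with pytest.raises(ValueError):
            bartlett_sphericity(corr(np.eye(5)), n=5)


class TestExtractComponents:
    def test_eigenvalue_conservation(self, rng):
        R = corr(random_correlation(rng, 7))
        sol = extract_components(R)
        assert sol.eigenvalues.sum() == pytest.approx(7.0, rel=1e-10)
        assert np.all(np.diff(sol.eigenvalues) <= 1e-10)

    def test_two_equal_blocks_split_evenly(self):
        block = np.full((3, 3), 0.6) + 0.4 * np.eye(3)
        R = corr(np.block([
            [block, np.zeros((3, 3))],
            [np.zeros((3, 3)), block],
        ]))
        sol = extract_components(R, retention="kaiser")
        assert sol.n_components == 2
        assert sol.variance_shares[0] == pytest.approx(0.5, abs=1e-10)

    def test_rank_k_reconstruction_matches_svd_oracle(self, rng):
        R = corr(random_correlation(rng, 6))
        sol = extract_components(R, retention="fixed_k", k=2)
        approx = sol.loadings @ sol.loadings.T
        u, s, vt = np.linalg.svd(R.values)
        best = (u[:, :2] * s[:2]) @ vt[:2]
        assert np.linalg.norm(R.values - approx) == pytest.approx(
            np.linalg.norm(R.values - best), rel=1e-8
        )

    def test_communalities_are_row_sums(self, rng):
        R = corr(random_correlation(rng, 5))
        sol = extract_components(R, retention="fixed_k", k=3)
        assert np.allclose(sol.communalities, (sol.loadings**2).sum(axis=1))
        assert sol.variance_shares.sum() == pytest.approx(1.0)


class TestVarimax:
    def test_single_component_unchanged(self, rng):
        lam = rng.normal(size=(6, 1))
        out, converged = varimax_rotate(lam)
        assert converged
        assert np.allclose(np.abs(out), np.abs(lam))

    def test_perfect_simple_structure_fixed_point(self):
        lam = np.array(
            [[0.9, 0.0], [0.8, 0.0], [0.85, 0.0], [0.0, 0.7], [0.0, 0.75]]
        )
        out, _ = varimax_rotate(lam, kaiser_normalize=False)
        # unchanged up to column sign/permutation
        got = sorted(np.abs(out).sum(axis=0))
        want = sorted(np.abs(lam).sum(axis=0))
        assert np.allclose(got, want, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_column_rotation_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.normal(size=(6, 2))
        out, _ = varimax_rotate(lam, kaiser_normalize=False, tol=1e-12)
        crit = varimax_criterion(out)
        best = -np.inf
        for theta in np.arange(0.0, np.pi / 2, 1e-4):
            c, s = np.cos(theta), np.sin(theta)
            rot = lam @ np.array([[c, -s], [s, c]])
            best = max(best, varimax_criterion(rot))
        assert crit >= best - 1e-6

    @given(st.integers(0, 1000))
    def test_communalities_preserved(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.normal(size=(8, 3))
        out, _ = varimax_rotate(lam)
        assert np.allclose((out**2).sum(axis=1), (lam**2).sum(axis=1), atol=1e-8)

    def test_criterion_never_decreases(self, rng):
        lam = rng.normal(size=(10, 4))
        out, _ = varimax_rotate(lam, kaiser_normalize=False)
        assert varimax_criterion(out) >= varimax_criterion(lam) - 1e-12


class TestRotateSolutionAndAssign:
    def test_rotation_preserves_communalities_and_shares(self, rng):
        R = corr(random_correlation(rng, 8))
        sol = extract_components(R, retention="fixed_k", k=3)
        rot = rotate_solution(sol)
        assert np.allclose(rot.communalities, sol.communalities, atol=1e-8)
        assert rot.variance_shares.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(rot.variance_shares) <= 1e-12)
        # total retained variance unchanged by the orthogonal rotation
        assert (rot.loadings**2).sum() == pytest.approx(
            (sol.loadings**2).sum(), rel=1e-10
        )

    def test_argmax_assignment(self):
        from spascreen.factor import FactorSolution

        lam = np.array([[0.9, 0.2], [0.1, 0.8], [0.2, 0.1]])
        sol = FactorSolution(
            eigenvalues=np.array([2.0, 1.0, 0.5]),
            loadings=lam,
            communalities=(lam**2).sum(axis=1),
            variance_shares=np.array([0.6, 0.4]),
            items=("a", "b", "c"),
            rotated=True,
        )
        asg = assign_items(sol, loading_threshold=0.36)
        assert asg.assignments["a"] == (1, pytest.approx(0.9))
        assert asg.assignments["b"] == (2, pytest.approx(0.8))
        assert asg.unassigned == ("c",)

    def test_all_below_threshold_unassigned(self):
        from spascreen.factor import FactorSolution

        lam = np.full((4, 2), 0.1)
        sol = FactorSolution(
            eigenvalues=np.ones(4),
            loadings=lam,
            communalities=(lam**2).sum(axis=1),
            variance_shares=np.array([0.5, 0.5]),
            items=("a", "b", "c", "d"),
            rotated=True,
        )
        asg = assign_items(sol)
        assert asg.unassigned == ("a", "b", "c", "d")
        assert asg.assignments == {}

    def test_tie_breaks_to_lower_component(self):
        from spascreen.factor import FactorSolution

        lam = np.array([[0.5, 0.5]])
        sol = FactorSolution(
            eigenvalues=np.ones(1),
            loadings=lam,
            communalities=(lam**2).sum(axis=1),
            variance_shares=np.array([0.5, 0.5]),
            items=("a",),
            rotated=True,
        )
        assert assign_items(sol).assignments["a"][0] == 1


class TestDefaultCohortFactorability:
    def test_diagnostics_show_factorable_items(self, default_cohort):
        R = correlation_matrix(default_cohort)
        rep = factorability(R, n=400)
        assert 0.5 < rep.kmo < 1.0
        assert rep.bartlett_p < 0.001
        assert rep.bartlett_df == 190

    def test_planted_partition_recovered_at_default_seed(self, default_cohort):
        R = correlation_matrix(default_cohort)
        rot = rotate_solution(extract_components(R))
        asg = assign_items(rot)
        axial = [it.item_id for it in default_cohort.items if it.factor == "axial"]
        peri = [it.item_id for it in default_cohort.items if it.factor == "peripheral"]
        ax_comps = {asg.assignments[i][0] for i in axial}
        pe_comps = {asg.assignments[i][0] for i in peri}
        assert len(ax_comps) == 1 and len(pe_comps) == 1
        assert ax_comps != pe_comps
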