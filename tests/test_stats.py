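"""Multivariate statistics: Bray-Curtis, PERMANOVA, PERMDISP, nMDS (with the
pool-adjacent-violators core), ANCOVA and centroid ellipses.

scikit-bio, scipy and scikit-learn serve as independent oracles; the
implementations under test are this package's own.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copepodamides.stats import (
    ancova,
    bray_curtis,
    centroid_ellipses,
    Ellipse,
    nmds,
    pava,
    pcoa,
    permanova,
    permdisp,
)


def _euclidean_dm(points):
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


class TestBrayCurtis:
    def test_identical_rows(self):
        d = bray_curtis(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_computed_example(self):
        # (6,2) vs (2,2) raw: |4| + |0| over 8 + 4 = 4/12
        d = bray_curtis(np.array([[6.0, 2.0], [2.0, 2.0]]), normalise=False)
        assert d.iloc[0, 1] == pytest.approx(4.0 / 12.0)

    def test_against_scipy(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(6, 8))
        d = bray_curtis(x, normalise=False)
        for i in range(6):
            for j in range(6):
                assert d.iloc[i, j] == pytest.approx(scipy_bc(x[i], x[j]), abs=1e-12)

    def test_zero_row_pair_is_nan_with_warning(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(x)
        assert math.isnan(d.iloc[0, 1])
        assert d.iloc[0, 2] == 1.0

    @given(
        st.integers(0, 2**31 - 1),
        st.integers(3, 8),
        st.integers(2, 6),
    )
    @settings(max_examples=40, deadline=None)
    def test_metric_axioms(self, seed, n, p):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(size=(n, p))
        d = bray_curtis(x).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, -1.0], [1.0, 1.0]]))


class TestPermanova:
    def test_exact_enumeration_two_by_two(self):
        """Two tight groups of 2 at distance 1: of the 6 distinct label
        assignments, 2 give the extreme pseudo-F, so exact p = 1/3."""
        d = np.array(
            [
                [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
            ]
        )
        result = permanova(d, ["a", "a", "b", "b"], method="exact")
        assert result.p_value == pytest.approx(1.0 / 3.0)
        assert result.n_permutations == 6

    def test_statistic_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(2)
        x = rng.lognormal(size=(12, 6))
        groups = ["a"] * 6 + ["b"] * 6
        d = bray_curtis(x)
        ours = permanova(d, groups, n_permutations=999, seed=0,
                         method="permutation")
        theirs = skbio_permanova(
            DistanceMatrix(d.to_numpy()), groups, permutations=999
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert ours.p_value == pytest.approx(theirs["p-value"], abs=0.08)

    def test_duplicated_dataset_same_r_squared(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=(8, 5))
        groups = ["a"] * 4 + ["b"] * 4
        d1 = bray_curtis(x)
        d2 = bray_curtis(np.vstack([x, x]))
        r1 = permanova(d1, groups, n_permutations=99, seed=0,
                       method="permutation").r_squared
        r2 = permanova(d2, groups * 2, n_permutations=99, seed=0,
                       method="permutation").r_squared
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_p_floor(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.lognormal(size=(5, 4)),
                       10 + rng.lognormal(size=(5, 4))])
        d = bray_curtis(x, normalise=False)
        result = permanova(d, ["a"] * 5 + ["b"] * 5, n_permutations=99, seed=1,
                           method="permutation")
        assert result.p_value >= 1.0 / 100.0

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(size=(10, 5))
        d = bray_curtis(x)
        result = permanova(d, ["a", "b"] * 5, n_permutations=199, seed=0,
                           method="permutation")
        assert result.p_value > 0.05

    def test_all_equal_distances_undefined(self):
        d = np.ones((4, 4)) - np.eye(4)
        # SS_within == SS per permutation: F finite but constant; the fully
        # degenerate case is all-zero distances
        with pytest.raises(ValueError):
            permanova(np.zeros((4, 4)), ["a", "a", "b", "b"], method="exact")


class TestPermdisp:
    def test_statistic_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix, permdisp as skbio_permdisp

        rng = np.random.default_rng(6)
        x = rng.lognormal(size=(14, 6))
        groups = ["a"] * 7 + ["b"] * 7
        d = bray_curtis(x)
        ours = permdisp(d, groups, n_permutations=99, seed=0)
        theirs = skbio_permdisp(
            DistanceMatrix(d.to_numpy()), groups, permutations=99, test="centroid"
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-6)

    def test_detects_dispersion_difference(self):
        rng = np.random.default_rng(7)
        tight = rng.normal(0, 0.05, size=(20, 3))
        spread = rng.normal(0, 0.5, size=(20, 3))
        d = _euclidean_dm(np.vstack([tight, spread]))
        result = permdisp(d, ["a"] * 20 + ["b"] * 20, n_permutations=199, seed=0)
        assert result.p_value <= 0.05

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(24, 3))
        d = _euclidean_dm(x)
        ps = [
            permdisp(d, list(rng.permutation(["a"] * 12 + ["b"] * 12)),
                     n_permutations=99, seed=s).p_value
            for s in range(5)
        ]
        assert min(ps) > 0.001 and max(ps) > 0.2

    def test_all_points_identical_degenerate(self):
        d = np.zeros((6, 6))
        result = permdisp(d, ["a"] * 3 + ["b"] * 3, n_permutations=49, seed=0)
        assert result.method == "degenerate"
        assert math.isnan(result.statistic)


class TestPava:
    def test_textbook_example(self):
        assert np.allclose(pava(np.array([3.0, 1.0, 2.0])), [2.0, 2.0, 2.0])

    def test_already_monotone_unchanged(self):
        y = np.array([1.0, 2.0, 5.0])
        assert np.allclose(pava(y), y)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    @settings(max_examples=50, deadline=None)
    def test_against_sklearn_isotonic(self, seed, n):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        ours = pava(y, w)
        theirs = IsotonicRegression().fit_transform(
            np.arange(n), y, sample_weight=w
        )
        assert np.allclose(ours, theirs, atol=1e-9)


class TestNmds:
    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        result = nmds(d, k=2, n_restarts=1, seed=0)
        assert result.stress < 1e-6

    def test_self_recovery_of_euclidean_configuration(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(10, 2))
        d = _euclidean_dm(points)
        result = nmds(d, k=2, n_restarts=2, seed=0)
        assert result.stress < 1e-4

    def test_stress_invariant_to_scaling_of_distances(self):
        rng = np.random.default_rng(10)
        x = rng.lognormal(size=(8, 5))
        d = bray_curtis(x).to_numpy()
        r1 = nmds(d, k=2, n_restarts=1, seed=1)
        r2 = nmds(3.7 * d, k=2, n_restarts=1, seed=1)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-6)

    def test_stress_nonincreasing_within_restart(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(size=(9, 4))
        d = bray_curtis(x).to_numpy()
        result = nmds(d, k=2, n_restarts=1, seed=0)
        history = np.array(result.stress_history)
        assert (np.diff(history) <= 1e-9).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)), k=2)

    def test_coordinates_shape_and_labels(self):
        x = np.random.default_rng(12).lognormal(size=(6, 4))
        df = bray_curtis(pd.DataFrame(x, index=list("abcdef")))
        result = nmds(df, k=2, n_restarts=1, seed=0)
        assert list(result.coordinates.index) == list("abcdef")
        assert result.coordinates.shape == (6, 2)


class TestPcoa:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(13)
        points = rng.normal(size=(7, 3))
        d = _euclidean_dm(points)
        coords, eigval = pcoa(d, k=3)
        assert np.allclose(_euclidean_dm(coords), d, atol=1e-8)
        assert (eigval[3:] < 1e-8).all()


class TestAncova:
    def _data(self, n=60, group_effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        g = np.repeat(["a", "b"], n // 2)
        x = rng.uniform(0, 10, n)
        y = 2.0 + 0.5 * x + group_effect * (g == "b") + rng.normal(0, 1, n)
        return y, g, x

    def test_detects_group_effect_with_eta(self):
        y, g, x = self._data(group_effect=3.0, seed=1)
        result = ancova(y, g, x)
        assert result.group_p < 1e-6
        assert 0 < result.group_partial_eta_sq <= 1
        assert result.covariate_p < 1e-6

    def test_perfect_separation_eta_one(self):
        n = 30
        g = np.repeat(["a", "b"], n)
        y = (g == "b").astype(float)
        x = np.random.default_rng(2).uniform(size=2 * n)
        result = ancova(y, g, x)
        assert result.group_partial_eta_sq == pytest.approx(1.0, abs=1e-6)

    def test_response_equals_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        g = np.repeat(["a", "b"], 20)
        y = x + rng.normal(0, 1e-6, 40)
        result = ancova(y, g, x)
        assert result.covariate_partial_eta_sq > 0.999
        assert result.group_partial_eta_sq < 0.05

    def test_single_group_reduces_to_linear_regression(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 25)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.5, 25)
        result = ancova(y, ["only"] * 25, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert result.covariate_p == pytest.approx(ols.pvalues[1], rel=1e-9)
        assert math.isnan(result.group_f)

    def test_constant_covariate_dropped(self):
        y, g, _ = self._data(group_effect=1.0, seed=5)
        with pytest.warns(UserWarning, match="constant covariate"):
            result = ancova(y, g, np.ones_like(y))
        assert result.covariate_dropped

    def test_type_i_error_calibrated(self):
        """With no group effect, the group p-value is approximately uniform:
        rejection rate at alpha = 0.05 stays within binomial error."""
        rejections = 0
        n_sim = 200
        for seed in range(n_sim):
            y, g, x = self._data(group_effect=0.0, seed=seed)
            if ancova(y, g, x).group_p < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.04)

    def test_diagnostics_reported(self):
        y, g, x = self._data(group_effect=1.0, seed=6)
        result = ancova(y, g, x)
        assert result.interaction_p is not None
        assert 0 <= result.shapiro_p <= 1
        assert result.df_group[0] == 1

    def test_too_few_per_group(self):
        with pytest.raises(ValueError):
            ancova([1.0, 2.0, 3.0], ["a", "a", "b"], [1.0, 2.0, 3.0])


class TestCentroidEllipses:
    def test_isotropic_cloud_nearly_circular(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(400, 2))
        result = centroid_ellipses(pts, ["g"] * 400)
        ell = result["g"]
        assert isinstance(ell, Ellipse)
        ratio = ell.semi_axes[0] / ell.semi_axes[1]
        assert 1.0 <= ratio < 1.3

    def test_identical_points_zero_area(self):
        pts = np.ones((5, 2))
        ell = centroid_ellipses(pts, ["g"] * 5)["g"]
        assert ell.area == 0.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(20, 2))
        e1 = centroid_ellipses(pts, ["g"] * 20)["g"]
        e2 = centroid_ellipses(pts + 5.0, ["g"] * 20)["g"]
        assert np.allclose(np.array(e2.center) - np.array(e1.center), 5.0)
        assert e1.semi_axes == pytest.approx(e2.semi_axes)

    def test_small_group_centroid_only(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        result = centroid_ellipses(pts, ["g", "g"])
        assert result["g"] == (0.5, 0.5)
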