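"""Tests for standardization, distance matrices, Mantel machinery and
correlograms, cross-checked against exhaustive enumeration and scikit-bio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meadowpath import mantel as mm
from meadowpath import geostat, synth


class TestStandardize:
    def test_hand_example(self):
        assert np.allclose(mm.standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        z = mm.standardize(rng.normal(3, 2, 50))
        assert np.allclose(mm.standardize(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="moisture"):
            mm.standardize([4.0, 4.0, 4.0], name="moisture")


class TestEuclideanDmat:
    def test_single_column_absolute_differences(self):
        d = mm.euclidean_dmat(np.array([0.0, 3.0, 4.0])).values
        assert d[0, 1] == 3 and d[0, 2] == 4 and d[1, 2] == 1

    def test_coordinates_345(self):
        d = mm.euclidean_dmat(np.array([[0, 0], [3, 4], [0, 1]], dtype=float)).values
        assert d[0, 1] == pytest.approx(5.0)

    def test_categorical_mismatch(self):
        labels = np.array(["a", "b", "a", "c"])
        d = mm.euclidean_dmat(labels).values
        expected = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 1], [0, 1, 0, 1], [1, 1, 1, 0]], dtype=float
        )
        assert np.array_equal(d, expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mm.DistanceMatrix(np.ones((3, 4)))


class TestMantel:
    def test_identity_r_one(self, rng):
        d = mm.euclidean_dmat(rng.normal(size=20))
        assert mm.mantel(d, d, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_worked_three_point_example(self):
        """Values [0,1,2] vs [0,2,1]: upper triangles (1,2,1) and (2,1,1)
        give r = -0.5; the exact p enumerates all 3! = 6 relabelings."""
        da = mm.euclidean_dmat(np.array([0.0, 1.0, 2.0]))
        db = mm.euclidean_dmat(np.array([0.0, 2.0, 1.0]))
        res = mm.mantel(da, db, exact=True)
        assert res.r == pytest.approx(-0.5)
        assert res.n_perm == 6
        # independent enumeration oracle over explicit relabelings
        import itertools

        b = db.values
        iu = np.triu_indices(3, 1)
        a_vec = da.values[iu]
        stats = []
        for p in itertools.permutations(range(3)):
            p = np.array(p)
            stats.append(np.corrcoef(a_vec, b[np.ix_(p, p)][iu])[0, 1])
        expected_p = np.mean(np.array(stats) >= res.r - 1e-12)
        assert res.p_value == pytest.approx(expected_p)

    def test_sampled_p_converges_to_exact(self, rng):
        x = rng.normal(size=6)
        y = x + rng.normal(scale=1.0, size=6)
        da, db = mm.euclidean_dmat(x), mm.euclidean_dmat(y)
        exact = mm.mantel(da, db, exact=True)
        sampled = mm.mantel(da, db, n_perm=20000, seed=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
        assert abs(sampled.p_value - exact.p_value) <= 4 * se + 2 / 20001

    def test_agrees_with_skbio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(size=25)
        da, db = mm.euclidean_dmat(x), mm.euclidean_dmat(y)
        mine = mm.mantel(da, db, n_perm=9999, seed=3, tail="greater")
        r_sk, p_sk, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(da.values),
            skbio_distance.DistanceMatrix(db.values),
            permutations=9999,
            alternative="greater",
        )
        assert mine.r == pytest.approx(r_sk, abs=1e-12)
        assert mine.p_value == pytest.approx(p_sk, abs=0.01)

    @given(shift=st.floats(0.0, 5.0), scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_r_invariant_to_offdiag_affine(self, shift, scale):
        rng = np.random.default_rng(7)
        a = mm.euclidean_dmat(rng.normal(size=12)).values
        b = mm.euclidean_dmat(rng.normal(size=12)).values
        r0 = mm.mantel(a, b, n_perm=1, seed=0).r
        b2 = scale * b + shift
        np.fill_diagonal(b2, 0.0)
        r1 = mm.mantel(a, b2, n_perm=1, seed=0).r
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_zero_variance_rejected(self):
        d0 = np.zeros((4, 4))
        d1 = mm.euclidean_dmat(np.arange(4.0))
        with pytest.raises(ValueError):
            mm.mantel(d0, d1, n_perm=10, seed=0)


class TestPartialMantel:
    def test_empty_partials_equals_simple(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        da, db = mm.euclidean_dmat(x), mm.euclidean_dmat(y)
        simple = mm.mantel(da, db, n_perm=499, seed=11)
        partial = mm.partial_mantel(da, db, [], n_perm=499, seed=11)
        assert partial.r == pytest.approx(simple.r, abs=1e-12)
        assert partial.p_value == pytest.approx(simple.p_value, abs=1e-12)

    def test_constant_pattern_partial_equals_simple_r(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        da, db = mm.euclidean_dmat(x), mm.euclidean_dmat(y)
        const = np.ones((20, 20)) * 2.5
        np.fill_diagonal(const, 0.0)
        res = mm.partial_mantel(da, db, [mm.DistanceMatrix(const)], n_perm=99, seed=0)
        assert res.r == pytest.approx(mm.mantel(da, db, n_perm=1, seed=0).r, abs=1e-10)

    def test_same_matrix_residual_r_one(self, rng):
        x, z = rng.normal(size=20), rng.normal(size=20)
        da = mm.euclidean_dmat(x)
        dz = mm.euclidean_dmat(z)
        res = mm.partial_mantel(da, da, [dz], n_perm=9, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_chain_partial_removes_indirect(self):
        """A -> B -> C with no direct A-C link: partial r(C,A | B) sits near
        zero while the simple r(C,A) stays clearly positive."""
        partials, simples = [], []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 200
            a = rng.normal(size=n)
            b = a + 0.4 * rng.normal(size=n)
            c = b + 0.4 * rng.normal(size=n)
            da = mm.euclidean_dmat(mm.standardize(a))
            db = mm.euclidean_dmat(mm.standardize(b))
            dc = mm.euclidean_dmat(mm.standardize(c))
            partials.append(mm.partial_mantel(dc, da, [db], n_perm=1, seed=0).r)
            simples.append(mm.mantel(dc, da, n_perm=1, seed=0).r)
        assert abs(np.mean(partials)) < 0.05
        assert np.mean(simples) > 0.3

    def test_collinear_partials_rejected(self, rng):
        x = rng.normal(size=15)
        da = mm.euclidean_dmat(x)
        dz = mm.euclidean_dmat(rng.normal(size=15))
        dz2 = mm.DistanceMatrix(dz.values * 2.0)
        with pytest.raises(ValueError, match="[Cc]ollinear"):
            mm.partial_mantel(da, da, [dz, dz2], n_perm=9, seed=0)


class TestCorrelogram:
    def test_pair_counts_conserved(self, rng):
        n = 60
        loc = rng.uniform((0, 0), (40, 50), size=(n, 2))
        geo = mm.euclidean_dmat(loc)
        vals = mm.euclidean_dmat(rng.normal(size=n))
        max_lag = 20.0
        cg = mm.correlogram(vals, geo, lag_width=2.5, max_lag=max_lag, n_perm=49, seed=0)
        g = geo.condensed()
        assert cg.bins["n_pairs"].sum() == np.sum(g < max_lag)
        assert np.allclose(np.diff(cg.bins["lower"]), 2.5)

    def test_single_close_pair_flagged(self):
        loc = np.array([[0, 0], [0.5, 0], [100, 0], [200, 0], [300, 0]], dtype=float)
        geo = mm.euclidean_dmat(loc)
        vals = mm.euclidean_dmat(np.array([1.0, 2.0, 5.0, 0.5, 9.0]))
        cg = mm.correlogram(vals, geo, lag_width=2.5, max_lag=5.0, n_perm=19, seed=0)
        assert cg.bins["n_pairs"].iloc[0] == 1
        assert not cg.bins["usable"].iloc[0]

    def test_autocorrelated_field_decays(self):
        """GRF with phi = 4 m: near bins positive and significant, statistic
        declining with distance."""
        params = geostat.GPParams(beta=0, sigma2=1.0, phi=4.0, tau2_rel=0.05)
        rng = np.random.default_rng(21)
        loc = rng.uniform((0, 0), (40, 50), size=(200, 2))
        fld = synth.simulate_grf(loc, params, seed=5)
        geo = mm.euclidean_dmat(loc)
        dm = mm.euclidean_dmat(mm.standardize(fld.values))
        cg = mm.correlogram(dm, geo, n_perm=499, seed=9)
        first = cg.bins.iloc[0]
        assert first["mantel_r"] > 0 and first["p_value"] <= 0.05
        mid = cg.bins["midpoint"].to_numpy()
        r = cg.bins["mantel_r"].to_numpy()
        near = r[mid <= 5].mean()
        far = r[(mid >= 15) & np.isfinite(r)].mean()
        assert near > far


class TestAutocorrRange:
    def _result(self, pvals, stats, midpoints, usable=None):
        n = len(pvals)
        bins = pd.DataFrame(
            {
                "lower": midpoints - 1.25,
                "upper": midpoints + 1.25,
                "midpoint": midpoints,
                "n_pairs": np.full(n, 100),
                "mantel_r": stats,
                "p_value": pvals,
                "significant": np.array(pvals) <= 0.05,
                "usable": np.ones(n, dtype=bool) if usable is None else usable,
            }
        )
        return mm.CorrelogramResult(bins=bins, range_m=None)

    def test_run_of_significant_bins(self):
        res = self._result(
            pvals=np.array([0.01, 0.02, 0.04, 0.3, 0.01]),
            stats=np.array([0.3, 0.2, 0.1, 0.0, 0.2]),
            midpoints=np.array([1.25, 3.75, 6.25, 8.75, 11.25]),
        )
        assert mm.autocorr_range(res) == pytest.approx(6.25)

    def test_first_bin_not_significant(self):
        res = self._result(
            pvals=np.array([0.2, 0.01]),
            stats=np.array([0.1, 0.3]),
            midpoints=np.array([1.25, 3.75]),
        )
        assert mm.autocorr_range(res) is None

    def test_all_significant_truncated(self):
        res = self._result(
            pvals=np.array([0.01, 0.01, 0.01]),
            stats=np.array([0.3, 0.25, 0.2]),
            midpoints=np.array([1.25, 3.75, 6.25]),
        )
        assert mm.autocorr_range(res) == pytest.approx(6.25)
        assert res.truncated

    def test_negative_statistic_breaks_run(self):
        res = self._result(
            pvals=np.array([0.01, 0.01, 0.01]),
            stats=np.array([0.3, -0.2, 0.2]),
            midpoints=np.array([1.25, 3.75, 6.25]),
        )
        assert mm.autocorr_range(res) == pytest.approx(1.25)


class TestBootstrapCI:
    def test_identical_matrices_collapse_near_one(self, rng):
        d = mm.euclidean_dmat(rng.normal(size=30))
        lo, hi = mm.bootstrap_ci(d, d, n_boot=200, seed=4)
        assert lo > 0.99 and hi <= 1.0 + 1e-12

    def test_independent_straddles_zero(self, rng):
        da = mm.euclidean_dmat(rng.normal(size=40))
        db = mm.euclidean_dmat(rng.normal(size=40))
        lo, hi = mm.bootstrap_ci(da, db, n_boot=300, seed=4)
        assert lo < 0.15 and hi > -0.15

    def test_nboot_minimum(self, rng):
        d = mm.euclidean_dmat(rng.normal(size=10))
        with pytest.raises(ValueError):
            mm.bootstrap_ci(d, d, n_boot=50, seed=0)
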