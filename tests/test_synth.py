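"""Tests for the synthetic meadow generator against its declared ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from meadowpath import synth
from meadowpath.geostat import GPParams
from meadowpath.synth import Domain, TruthConfig


class TestSimulateGRF:
    def test_degenerate_variance_returns_trend(self):
        p = GPParams(beta=5.0, sigma2=1e-320, phi=1.0)
        fld = synth.simulate_grf([(0.0, 0.0)], p, seed=0)
        assert fld.values[0] == pytest.approx(5.0)

    def test_coincident_points_fully_correlated(self):
        p = GPParams(beta=0.0, sigma2=1.0, phi=2.0, tau2_rel=0.0)
        fld = synth.simulate_grf([(1.0, 1.0), (1.0, 1.0)], p, seed=3)
        assert fld.values[0] == pytest.approx(fld.values[1], abs=1e-4)

    def test_reproducible_under_seed(self, rng):
        p = GPParams(beta=0.0, sigma2=1.0, phi=3.0, tau2_rel=0.1)
        loc = rng.uniform(0, 20, size=(30, 2))
        a = synth.simulate_grf(loc, p, seed=11).values
        b = synth.simulate_grf(loc, p, seed=11).values
        assert np.array_equal(a, b)

    def test_variogram_reaches_sill(self):
        """Method-of-moments variogram at 3 phi should sit near the sill
        sigma^2 (1 + tau2_rel)."""
        p = GPParams(beta=0.0, sigma2=1.0, phi=5.0, tau2_rel=0.0)
        rng = np.random.default_rng(17)
        sills = []
        for s in range(8):
            loc = rng.uniform((0, 0), (100, 100), size=(500, 2))
            fld = synth.simulate_grf(loc, p, seed=1000 + s)
            d = pdist(loc)
            dv = pdist(fld.values[:, None]) ** 2 / 2.0
            sel = (d > 13.0) & (d < 17.0)  # lag ~15 m = 3 phi
            sills.append(dv[sel].mean())
        # theoretical variogram at 3 phi: sigma^2 (1 - e^-3) = 0.95
        assert np.mean(sills) == pytest.approx(0.95, abs=0.15)

    def test_empirical_covariance_matches_model(self):
        """Across replicates, the sample covariance at a fixed pair decays
        as sigma^2 exp(-h / phi)."""
        p = GPParams(beta=1.0, sigma2=2.0, phi=4.0, tau2_rel=0.0)
        loc = np.array([[0.0, 0.0], [4.0, 0.0], [20.0, 0.0]])
        vals = np.array(
            [synth.simulate_grf(loc, p, seed=s).values for s in range(4000)]
        )
        cov = np.cov(vals.T)
        assert cov[0, 0] == pytest.approx(2.0, abs=0.2)
        assert cov[0, 1] == pytest.approx(2.0 * np.exp(-1), abs=0.2)
        assert cov[0, 2] == pytest.approx(2.0 * np.exp(-5), abs=0.2)


class TestPlantLocations:
    def _uniform_surface(self, domain):
        xs = np.arange(0, domain.width + 0.25, 0.5)
        ys = np.arange(0, domain.height + 0.25, 0.5)
        return synth.GridSurface(xs, ys, np.ones((len(ys), len(xs))))

    def test_zero_target_empty(self):
        dom = Domain(10, 10)
        pts = synth.simulate_plant_locations(dom, self._uniform_surface(dom), 0, seed=0)
        assert pts.shape == (0, 2)

    def test_half_domain_intensity(self):
        dom = Domain(10, 10)
        xs = np.arange(0, 10.5, 0.5)
        ys = np.arange(0, 10.5, 0.5)
        vals = np.where(xs[None, :] < 5.0, 1.0, 0.0) * np.ones((len(ys), 1))
        surf = synth.GridSurface(xs, ys, vals)
        pts = synth.simulate_plant_locations(dom, surf, 100, seed=1)
        # bilinear taper puts the support edge at x = 5.5
        assert np.all(pts[:, 0] <= 5.5)

    def test_all_zero_intensity_rejected(self):
        dom = Domain(10, 10)
        xs = ys = np.arange(0, 10.5, 0.5)
        surf = synth.GridSurface(xs, ys, np.zeros((len(ys), len(xs))))
        with pytest.raises(ValueError):
            synth.simulate_plant_locations(dom, surf, 10, seed=0)

    def test_uniform_intensity_passes_quadrat_test(self):
        """Chi-square quadrat-count test should not reject uniformity at
        alpha = 0.01 in at least 18 of 20 seeds."""
        dom = Domain(40, 50)
        surf = self._uniform_surface(dom)
        passes = 0
        for s in range(20):
            pts = synth.simulate_plant_locations(dom, surf, 400, seed=s)
            counts, *_ = np.histogram2d(
                pts[:, 0], pts[:, 1], bins=[4, 5], range=[[0, 40], [0, 50]]
            )
            _, p = stats.chisquare(counts.ravel())
            passes += p > 0.01
        assert passes >= 18


class TestAssignLines:
    def test_single_line(self, rng):
        loc = rng.uniform(0, 10, size=(30, 2))
        labels = synth.assign_lines(loc, 1, 2.0, seed=0)
        assert set(labels) == {1}

    def test_voronoi_limit(self, rng):
        """With dispersal scale >> domain size the exp decay never fires a
        random relabel, so labels equal nearest-founder labels."""
        loc = rng.uniform(0, 10, size=(50, 2))
        labels = synth.assign_lines(loc, 5, 1e9, seed=4)
        rng2 = np.random.default_rng(4)
        founders = rng2.choice(50, size=5, replace=False)
        from scipy.spatial.distance import cdist

        nearest = np.argmin(cdist(loc, loc[founders]), axis=1) + 1
        nearest[founders] = np.arange(1, 6)
        assert np.array_equal(labels, nearest)

    def test_every_line_used(self, rng):
        loc = rng.uniform(0, 40, size=(100, 2))
        labels = synth.assign_lines(loc, 12, 3.0, seed=1)
        assert set(labels) == set(range(1, 13))

    def test_invalid_counts(self, rng):
        loc = rng.uniform(0, 10, size=(5, 2))
        with pytest.raises(ValueError):
            synth.assign_lines(loc, 0, 1.0, seed=0)
        with pytest.raises(ValueError):
            synth.assign_lines(loc, 6, 1.0, seed=0)

    def test_labels_spatially_clustered(self, rng):
        """Join-count statistic (like-labeled nearest neighbors) exceeds its
        permutation null mean."""
        loc = rng.uniform(0, 40, size=(200, 2))
        labels = synth.assign_lines(loc, 8, 8.0, seed=3)
        d = squareform(pdist(loc))
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        observed = np.mean(labels == labels[nn])
        null = [
            np.mean(lp == lp[nn])
            for lp in (rng.permutation(labels) for _ in range(200))
        ]
        assert observed > np.mean(null) + 3 * np.std(null)


class TestSimulateTraits:
    def _locations(self, rng, n=150):
        return rng.uniform((0, 0), (40, 50), size=(n, 2))

    def test_zero_effects_independent(self, rng):
        loc = self._locations(rng)
        cfg = synth.default_truth_config()
        cfg.edge_list = [(s, t, sign, 0.0) for s, t, sign, _ in cfg.edge_list]
        fields = {"elevation": rng.normal(size=len(loc)),
                  "soil_moisture": rng.normal(size=len(loc))}
        df = synth.simulate_traits(loc, fields, cfg, seed=5)
        assert abs(np.corrcoef(df.elevation, df.soil_moisture)[0, 1]) < 0.2
        assert abs(np.corrcoef(df.stalk_herbivory, df.fruit_number)[0, 1]) < 0.2

    def test_large_effect_positive_correlation(self, rng):
        loc = self._locations(rng)
        cfg = synth.default_truth_config()
        df = synth.simulate_traits(loc, {"elevation": rng.normal(size=len(loc)),
                                         "soil_moisture": np.zeros(len(loc))},
                                   cfg, seed=6)
        assert np.corrcoef(df.rosette_diameter, df.stalk_number)[0, 1] > 0.5
        assert np.corrcoef(df.stalk_herbivory, df.fruit_number)[0, 1] < -0.3

    def test_noise_free_single_parent_deterministic(self, rng):
        loc = self._locations(rng, n=50)
        cfg = TruthConfig(
            edge_list=[("a", "b", "+", 2.0)],
            base_values={"b": 1.0},
            noise_sd={},
            n_plants=50,
        )
        a = rng.normal(size=50)
        df = synth.simulate_traits(loc, {"a": a}, cfg, seed=0)
        za = (a - a.mean()) / a.std(ddof=1)
        assert np.allclose(df.b, 1.0 + 2.0 * za)

    def test_cycle_rejected(self, rng):
        loc = self._locations(rng, n=20)
        cfg = TruthConfig(
            edge_list=[("a", "b", "+", 1.0), ("b", "a", "+", 1.0)],
            n_plants=20,
        )
        with pytest.raises(ValueError, match="cycle"):
            synth.simulate_traits(loc, {}, cfg, seed=0)

    def test_counts_nonnegative_integers(self, default_study):
        plants, *_ = default_study
        for c in synth.COUNT_COLUMNS:
            assert pd.api.types.is_integer_dtype(plants[c])
            assert (plants[c] >= 0).all()


class TestNeighborCounts:
    def test_no_neighbors(self):
        out = synth.neighbor_counts([(0, 0), (1, 1)], np.zeros((0, 2)), 0.15)
        assert np.array_equal(out, [0, 0])

    def test_hand_example(self):
        out = synth.neighbor_counts(
            [(0.0, 0.0)], [(0.1, 0.0), (0.2, 0.0)], 0.15
        )
        assert out[0] == 1  # 0.1 <= 0.15 < 0.2

    def test_boundary_inclusive(self):
        out = synth.neighbor_counts([(0.0, 0.0)], [(0.15, 0.0)], 0.15)
        assert out[0] == 1

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            synth.neighbor_counts([(0, 0)], [(1, 1)], 0.0)


class TestGenerateStudy:
    def test_default_shape(self, default_study):
        plants, env, surfaces, cfg = default_study
        assert len(plants) == 234
        assert len(env) == 71
        dom = Domain()
        assert dom.contains(plants[["x", "y"]].to_numpy()).all()
        assert dom.contains(env[["x", "y"]].to_numpy()).all()
        assert set(synth.PLANT_COLUMNS) <= set(plants.columns)
        assert plants["line"].between(1, cfg.n_lines).all()

    def test_same_seed_identical(self):
        cfg1 = synth.default_truth_config(seed=77)
        cfg2 = synth.default_truth_config(seed=77)
        p1, e1, *_ = synth.generate_study(cfg1, cell=2.0)
        p2, e2, *_ = synth.generate_study(cfg2, cell=2.0)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_different_seed_different_coordinates(self):
        p1, *_ = synth.generate_study(synth.default_truth_config(seed=1), cell=2.0)
        p2, *_ = synth.generate_study(synth.default_truth_config(seed=2), cell=2.0)
        assert not np.allclose(p1[["x", "y"]].to_numpy(), p2[["x", "y"]].to_numpy())

    def test_truth_json_round_trip(self, default_study):
        import json

        *_, cfg = default_study
        payload = json.loads(cfg.to_json())
        assert payload["n_plants"] == 234
        assert payload["surface_params"]["elevation"]["phi"] == pytest.approx(8.0)
        assert [e[:2] for e in payload["edge_list"]] == [
            ["elevation", "soil_moisture"],
            ["rosette_diameter", "stalk_number"],
            ["stalk_herbivory", "fruit_number"],
            ["dandelion_density", "rosette_herbivory"],
        ]
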