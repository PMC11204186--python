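"""FISH spot simulator: geometry, projection law, determinism."""

import numpy as np
import pytest
import scipy.stats

from loopdist import fish_sim
from loopdist.fish_sim import (
    DistanceModel,
    NucleusConfig,
    default_distance_model,
    pair_distances,
    projected_distance,
    sample_orientation,
    simulate_cohort,
    simulate_nucleus,
)


class TestSampleOrientation:
    def test_unit_norm(self):
        rng = np.random.default_rng(0)
        v = sample_orientation(rng, size=1000)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-12)

    def test_uniform_on_sphere_moments(self):
        # first moment ~ 0 by symmetry; per-component variance is 1/3
        rng = np.random.default_rng(7)
        n = 10**5
        v = sample_orientation(rng, size=n)
        bound = 3.0 / np.sqrt(3 * n)
        assert np.all(np.abs(v.mean(axis=0)) < bound)
        assert abs((v[:, 2] ** 2).mean() - 1.0 / 3.0) < 0.01


class TestSimulateNucleus:
    def test_rigid_mode_exact_separation(self):
        model = default_distance_model()  # tau = sigma_loc = 0
        cfg = NucleusConfig()
        rng = np.random.default_rng(3)
        spots = simulate_nucleus((2, 3), "AA", model, cfg, rng)
        for h in range(2):
            d3 = np.linalg.norm(spots[h, 0] - spots[h, 1])
            assert d3 == pytest.approx(2.2, abs=1e-12)

    def test_zero_separation_gives_coincident_spots(self):
        model = DistanceModel(mu={((2, 3), "AA"): 0.0}, tau=0.0, sigma_loc=0.0)
        spots = simulate_nucleus((2, 3), "AA", model, NucleusConfig(), np.random.default_rng(0))
        assert np.allclose(spots[:, 0, :], spots[:, 1, :])

    def test_homolog_separation_contract(self):
        model = default_distance_model()
        cfg = NucleusConfig(radius=3.5, homolog_min_sep=2.0)
        rng = np.random.default_rng(11)
        for _ in range(2000):
            spots = simulate_nucleus((4, 5), "GG", model, cfg, rng)
            centers = spots.mean(axis=1)
            assert np.linalg.norm(centers[0] - centers[1]) >= cfg.homolog_min_sep - 1e-9

    def test_spots_stay_inside_nucleus_without_noise(self):
        model = default_distance_model()
        cfg = NucleusConfig()
        rng = np.random.default_rng(5)
        for _ in range(500):
            spots = simulate_nucleus((2, 3), "AA", model, cfg, rng)
            assert np.all(np.linalg.norm(spots.reshape(-1, 3), axis=1) <= cfg.radius + 1e-9)

    def test_infeasible_geometry_rejected(self):
        model = default_distance_model()
        with pytest.raises(ValueError, match="infeasible"):
            simulate_nucleus(
                (2, 3), "AA", model, NucleusConfig(radius=2.0, homolog_min_sep=2.0),
                np.random.default_rng(0),
            )


class TestSimulateCohort:
    def test_row_count(self):
        t = simulate_cohort((2, 3), "AA", 200, seed=0)
        assert len(t) == 800  # 2 homologs x 2 probes x 200 nuclei
        assert set(t["probe"]) == {2, 3}

    def test_same_seed_identical(self):
        a = simulate_cohort((1, 4), "AG", 50, seed=42)
        b = simulate_cohort((1, 4), "AG", 50, seed=42)
        assert a.equals(b)

    def test_different_seed_differs(self):
        a = simulate_cohort((1, 4), "AG", 50, seed=1)
        b = simulate_cohort((1, 4), "AG", 50, seed=2)
        assert not a.equals(b)

    def test_projection_factor_law(self):
        # rigid mode, mu = 1: projected/true ratio has CDF 1 - sqrt(1 - x^2)
        n = 50_000
        t = simulate_cohort((2, 3), "AA", n,
                            model=DistanceModel(mu={((2, 3), "AA"): 1.0}), seed=123)
        ratios = pair_distances(t, homologs_per_nucleus=2)
        assert len(ratios) == 2 * n
        d = scipy.stats.kstest(ratios, lambda x: 1.0 - np.sqrt(1.0 - np.clip(x, 0, 1) ** 2))
        assert d.statistic < 0.01

    def test_projection_contracts(self):
        t = simulate_cohort((2, 3), "AA", 300, seed=9)
        proj = pair_distances(t, homologs_per_nucleus=2)
        true3d = pair_distances(t, homologs_per_nucleus=2, projected=False)
        assert np.all(proj <= true3d + 1e-12)
        assert np.allclose(true3d, 2.2)

    def test_scale_equivariance(self):
        c = 2.5
        base = DistanceModel(mu={((2, 3), "AA"): 1.0}, tau=0.1, sigma_loc=0.05)
        scaled = DistanceModel(
            mu={((2, 3), "AA"): c}, tau=0.1 * c, sigma_loc=0.05 * c
        )
        cfg = NucleusConfig(radius=3.5, homolog_min_sep=2.0)
        cfg_s = NucleusConfig(radius=3.5 * c, homolog_min_sep=2.0 * c)
        a = pair_distances(simulate_cohort((2, 3), "AA", 200, base, cfg, seed=5))
        b = pair_distances(simulate_cohort((2, 3), "AA", 200, scaled, cfg_s, seed=5))
        assert np.allclose(b, c * a, rtol=1e-10)

    def test_overlapping_pair_genotype_invariant(self):
        # the #4-#5 calibration is identical across genotypes, so with the
        # same seed the projected-distance distributions coincide
        dists = {
            g: pair_distances(simulate_cohort((4, 5), g, 200, seed=77))
            for g in fish_sim.GENOTYPES
        }
        assert np.allclose(dists["AA"], dists["AG"])
        assert np.allclose(dists["AA"], dists["GG"])


class TestProjectedDistance:
    def _spot(self, nucleus, homolog, x, y, z=0.0):
        import pandas as pd

        return pd.Series(
            {"nucleus": nucleus, "homolog": homolog, "x_um": x, "y_um": y, "z_um": z}
        )

    def test_345_triangle(self):
        assert projected_distance(self._spot(0, 1, 0, 0), self._spot(0, 1, 3, 4)) == 5.0

    def test_z_ignored(self):
        assert projected_distance(
            self._spot(0, 1, 0, 0, 0), self._spot(0, 1, 0, 0, 2.2)
        ) == 0.0

    def test_cross_homolog_rejected(self):
        with pytest.raises(ValueError, match="homolog"):
            projected_distance(self._spot(0, 1, 0, 0), self._spot(0, 2, 1, 1))


def test_spot_table_tsv_round_trip(tmp_path):
    t = simulate_cohort((4, 5), "GG", 20, seed=3)
    path = tmp_path / "spots.tsv"
    fish_sim.write_spot_table(t, path, header_comments=["seed=3"])
    again = fish_sim.read_spot_table(path)
    assert np.allclose(again[["x_um", "y_um", "z_um"]], t[["x_um", "y_um", "z_um"]])
    assert list(again["probe"]) == list(t["probe"])
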