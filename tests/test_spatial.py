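"""Density estimation, level-set summaries, local testing and CDF comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import ghostmap as gm
from ghostmap.spatial import _bandwidth, _kde_at_points


def _cloud(points, subpop=None, animals=None):
    n = len(points)
    return gm.PointCloud3D(
        np.asarray(points, float),
        np.array(subpop if subpop is not None else ["all"] * n, dtype=object),
        np.array(animals if animals is not None else ["a0"] * n, dtype=object))


# ---------------------------------------------------------------------------
# KDE
# ---------------------------------------------------------------------------

def test_single_point_density_peaks_at_nearest_node():
    cloud = _cloud([[101.0, 52.0, 203.0]])
    params = gm.KdeParams(bandwidth_rule="fixed", fixed_bandwidth=30.0,
                          grid_spacing=20.0, min_points=1)
    field = gm.estimate_density(cloud, params=params)
    idx = np.unravel_index(np.argmax(field.values), field.values.shape)
    node = [field.axes[a][idx[a]] for a in range(3)]
    point = cloud.points[0]
    for a in range(3):
        others = np.abs(field.axes[a] - point[a])
        assert abs(node[a] - point[a]) == pytest.approx(others.min())


def test_density_mass_is_normalised(shifted_cloud):
    for subpop in ("all", "typical", "ghost"):
        field = gm.estimate_density(shifted_cloud, subpop,
                                    params=gm.KdeParams(grid_spacing=30.0))
        assert 0.95 <= field.total_mass <= 1.05


def test_grid_kde_equals_bruteforce_kernel_sum():
    """Separable grid evaluation == direct per-node kernel sum to 1e-10."""
    rng = np.random.default_rng(12)
    pts = rng.normal([100, 100, 200], [40, 50, 60], size=(300, 3))
    cloud = _cloud(pts)
    params = gm.KdeParams(grid_spacing=35.0)
    field = gm.estimate_density(cloud, params=params)
    coords = field.node_coordinates()
    pick = rng.choice(len(coords), size=100, replace=False)
    h = _bandwidth(pts, params)
    brute = _kde_at_points(pts, coords[pick], h)
    # independent direct sum, one node at a time
    direct = []
    for node in coords[pick]:
        u = (node[None, :] - pts) / h
        k = np.exp(-0.5 * (u ** 2).sum(axis=1)) / ((2 * np.pi) ** 1.5 * h.prod())
        direct.append(k.mean())
    np.testing.assert_allclose(field.values.ravel()[pick], direct, atol=1e-10)
    np.testing.assert_allclose(brute, direct, atol=1e-12)


def test_too_few_points_is_an_error(shifted_cloud):
    with pytest.raises(gm.InsufficientDataError, match="nosuch"):
        gm.estimate_density(shifted_cloud, "typical", "nosuch")


# ---------------------------------------------------------------------------
# Super-level sets
# ---------------------------------------------------------------------------

def test_superlevel_volumes_monotone_and_quantile_range(shifted_cloud):
    field = gm.estimate_density(shifted_cloud, "all",
                                params=gm.KdeParams(grid_spacing=30.0))
    table = gm.isosurface_levels(field, [0.1, 0.5, 0.9])
    vols = table["volume_um3"].to_numpy()
    assert vols[0] >= vols[1] >= vols[2]
    with pytest.raises(gm.ValidationError):
        gm.isosurface_levels(field, [1.5])


def test_superlevel_centroids_recover_caudal_shift(shifted_cloud):
    params = gm.KdeParams(grid_spacing=25.0)
    cen = {}
    for subpop in ("typical", "ghost"):
        field = gm.estimate_density(shifted_cloud, subpop, params=params)
        cen[subpop] = gm.isosurface_levels(field, [0.5])["centroid_z"].iloc[0]
    assert cen["ghost"] - cen["typical"] == pytest.approx(200.0, abs=15.0)


# ---------------------------------------------------------------------------
# Local subpopulation test
# ---------------------------------------------------------------------------

def test_identical_subpops_give_p_one_everywhere():
    rng = np.random.default_rng(13)
    pts = rng.normal(0, 80, size=(60, 3))
    points = np.vstack([pts, pts])
    subpop = np.array(["typical"] * 60 + ["ghost"] * 60, dtype=object)
    animals = np.array(list(np.repeat(["a0", "a1", "a2"], 20)) * 2, dtype=object)
    cloud = gm.PointCloud3D(points, subpop, animals)
    field = gm.local_subpopulation_test(cloud, gm.KdeParams(grid_spacing=50.0))
    assert (field.p == 1.0).all()
    assert (field.direction == 0).all()


def test_missing_subpop_lists_offending_animal():
    pts = np.random.default_rng(0).normal(0, 50, size=(40, 3))
    subpop = np.array(["typical"] * 40, dtype=object)
    subpop[:10] = "ghost"
    animals = np.array(["a0"] * 20 + ["a1"] * 20, dtype=object)
    cloud = gm.PointCloud3D(pts, subpop, animals)   # a1 has no ghosts
    with pytest.raises(gm.InsufficientDataError, match="a1"):
        gm.local_subpopulation_test(cloud, gm.KdeParams(grid_spacing=50.0))


def test_caudal_shift_detected_in_caudal_occupied_nodes():
    cloud = gm.gen_point_cloud(gm.SpatialSpec(
        n_typical=1200, n_ghost=1200, caudal_shift=300.0, n_animals=4, seed=2))
    field = gm.local_subpopulation_test(cloud, gm.KdeParams(grid_spacing=40.0))
    z = field.nodes[:, 2]
    caudal = z >= np.quantile(z, 0.75)
    frac = np.mean((field.p[caudal] < 0.05) & (field.direction[caudal] == -1))
    assert frac >= 0.80


def test_label_shuffle_null_is_calibrated():
    """Within-animal label shuffles give ~5% of nodes below p = 0.05."""
    rng = np.random.default_rng(7)
    fracs = []
    for rep in range(10):
        cloud = gm.gen_point_cloud(gm.SpatialSpec(
            n_typical=400, n_ghost=400, caudal_shift=0.0, n_animals=4,
            seed=300 + rep))
        sub = cloud.subpop.copy()
        for a in cloud.animals:
            idx = np.flatnonzero(cloud.animal_id == a)
            sub[idx] = sub[rng.permutation(idx)]
        cloud.subpop = sub
        field = gm.local_subpopulation_test(cloud,
                                            gm.KdeParams(grid_spacing=40.0))
        fracs.append(np.mean(field.p < 0.05))
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.03)


def test_permutation_mode_agrees_with_t_mode_direction():
    cloud = gm.gen_point_cloud(gm.SpatialSpec(
        n_typical=300, n_ghost=300, caudal_shift=300.0, n_animals=3, seed=4))
    params = gm.KdeParams(grid_spacing=60.0)
    f_t = gm.local_subpopulation_test(cloud, params, mode="t")
    f_p = gm.local_subpopulation_test(cloud, params, mode="permutation",
                                      n_permutations=99, seed=0)
    assert (f_t.direction == f_p.direction).mean() > 0.9
    assert (f_p.p > 0).all() and (f_p.p <= 1).all()


# ---------------------------------------------------------------------------
# Cumulative distributions and Gaussian CDF fits
# ---------------------------------------------------------------------------

def test_cdf_of_three_points():
    cloud = _cloud([[0, 0, 1.0], [0, 0, 2.0], [0, 0, 3.0]])
    cdf = gm.cumulative_axis_distribution(cloud)
    assert cdf["position"].tolist() == [1.0, 2.0, 3.0]
    np.testing.assert_allclose(cdf["cum_frac"], [1 / 3, 2 / 3, 1.0])


def test_cdf_matches_counting_oracle():
    rng = np.random.default_rng(14)
    z = rng.normal(0, 50, 1000)
    cloud = _cloud(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
    cdf = gm.cumulative_axis_distribution(cloud)
    assert (np.diff(cdf["cum_frac"]) >= 0).all()
    assert cdf["cum_frac"].iloc[-1] == 1.0
    for _ in range(20):
        pos = rng.uniform(z.min(), z.max())
        expected = np.mean(z <= pos)
        got = cdf.loc[cdf["position"] <= pos, "cum_frac"].max()
        assert got == pytest.approx(expected, abs=1e-12)


def test_gaussian_cdf_fit_self_consistency():
    x = np.linspace(40, 160, 50)
    cdf = pd.DataFrame({"position": x,
                        "cum_frac": scipy.stats.norm.cdf(x, 100.0, 20.0)})
    fit = gm.fit_gaussian_cdf(cdf)
    assert fit.mu == pytest.approx(100.0, abs=0.5)
    assert fit.sigma == pytest.approx(20.0, abs=0.5)
    assert fit.rss < 1e-10


def test_gaussian_cdf_fit_parameter_recovery():
    rng = np.random.default_rng(15)
    z = rng.normal(0.0, 50.0, 5000)
    cloud = _cloud(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
    fit = gm.fit_gaussian_cdf(gm.cumulative_axis_distribution(cloud))
    assert fit.mu == pytest.approx(0.0, abs=3 * 50.0 / np.sqrt(5000))
    assert fit.sigma == pytest.approx(50.0, abs=3 * 50.0 / np.sqrt(2 * 5000))


def test_degenerate_positions_raise_fit_error():
    cdf = pd.DataFrame({"position": [5.0] * 6,
                        "cum_frac": np.linspace(0.1, 1.0, 6)})
    with pytest.raises(gm.FitError):
        gm.fit_gaussian_cdf(cdf)


def test_identical_cdfs_give_f_zero_p_one():
    rng = np.random.default_rng(16)
    z = rng.normal(0, 30, 200)
    cloud = _cloud(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
    cdf = gm.cumulative_axis_distribution(cloud)
    rep = gm.compare_fits_extra_ss(cdf, cdf.copy())
    assert rep["F"] == pytest.approx(0.0, abs=1e-4)
    assert rep["p"] == pytest.approx(1.0, abs=1e-3)


def test_f_test_power_on_separated_samples():
    """Means 2 sigma/sqrt(n) apart are rejected at alpha = 0.001 mostly."""
    rng = np.random.default_rng(17)
    n, sigma = 2000, 50.0
    shift = 2.0 * sigma / np.sqrt(n)
    rej = 0
    n_sims = 20
    for _ in range(n_sims):
        za = np.sort(rng.normal(0, sigma, n))
        zb = np.sort(rng.normal(shift, sigma, n))
        ca = pd.DataFrame({"position": za, "cum_frac": np.arange(1, n + 1) / n})
        cb = pd.DataFrame({"position": zb, "cum_frac": np.arange(1, n + 1) / n})
        rej += gm.compare_fits_extra_ss(ca, cb)["p"] < 0.001
    assert rej / n_sims >= 0.8


def test_f_test_type_i_error_under_its_regression_model():
    rng = np.random.default_rng(18)
    x = np.linspace(-100, 100, 60)
    rej = 0
    n_sims = 400
    for _ in range(n_sims):
        ya = scipy.stats.norm.cdf(x, 0, 40) + rng.normal(0, 0.02, len(x))
        yb = scipy.stats.norm.cdf(x, 0, 40) + rng.normal(0, 0.02, len(x))
        rep = gm.compare_fits_extra_ss(
            pd.DataFrame({"position": x, "cum_frac": ya}),
            pd.DataFrame({"position": x, "cum_frac": yb}))
        rej += rep["p"] < 0.05
    assert rej / n_sims == pytest.approx(0.05, abs=0.03)
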