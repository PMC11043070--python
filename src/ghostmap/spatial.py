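"""3D spatial statistics of labelled cell-centroid clouds.

Per-subpopulation probability density fields are estimated on a regular
grid with a Gaussian product kernel (Scott's rule per axis by default).
Super-level ("isosurface") sets summarise where each subpopulation
concentrates; a node-wise paired t-test across animals localises where the
two subpopulations differ ("p-value spheres" restricted to the space
occupied by the whole traced population); and the rostro-caudal shift is
quantified by fitting Gaussian CDFs to the empirical cumulative
distributions of the two subpopulations and comparing pooled vs separate
fits with an extra-sum-of-squares F-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .core import (
    CAUDAL_AXIS, FitError, InsufficientDataError, PointCloud3D,
    ValidationError,
)

#: smallest reportable p-value (keeps the field invariant p in (0, 1])
P_FLOOR = 1e-300


@dataclass
class KdeParams:
    bandwidth_rule: str = "scott"       # scott | silverman | fixed
    fixed_bandwidth: float = 50.0       # um per axis when rule = fixed
    grid_spacing: float = 25.0          # um
    occupancy_quantile: float = 0.25    # defines the occupied region
    min_points: int = 5

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValidationError("grid_spacing must be > 0")
        if self.bandwidth_rule == "fixed" and self.fixed_bandwidth <= 0:
            raise ValidationError("fixed_bandwidth must be > 0")
        if not 0 < self.occupancy_quantile < 1:
            raise ValidationError("occupancy_quantile must lie in (0, 1)")


@dataclass
class DensityField:
    """KDE values on a regular 3D grid for one (subpop, animal) selection."""
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]   # node coordinates per axis
    values: np.ndarray                                # (n0, n1, n2), integrates to ~1
    bandwidth: np.ndarray                             # (3,) um
    subpop: str = "all"
    animal: str | None = None

    @property
    def voxel_volume(self) -> float:
        return float(np.prod([ax[1] - ax[0] if len(ax) > 1 else 1.0
                              for ax in self.axes]))

    @property
    def total_mass(self) -> float:
        """Riemann sum x voxel volume; ~1 when the grid covers the kernels."""
        return float(self.values.sum() * self.voxel_volume)

    def node_coordinates(self) -> np.ndarray:
        """(n_nodes, 3) array of node coordinates in C order."""
        g = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class PValueField:
    """Node-wise two-tailed p-values on the occupied region of the grid."""
    nodes: np.ndarray        # (m, 3) node coordinates, um
    p: np.ndarray            # (m,) in (0, 1]
    direction: np.ndarray    # (m,) +1 typical-enriched, -1 ghost-enriched, 0 tied
    axes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


@dataclass
class CdfFit:
    """Least-squares Gaussian CDF fit to an empirical cumulative distribution."""
    mu: float
    sigma: float
    rss: float
    n_points: int
    model: str = "separate"   # separate | pooled


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

def _bandwidth(points: np.ndarray, params: KdeParams) -> np.ndarray:
    n, d = points.shape
    if params.bandwidth_rule == "fixed":
        return np.full(d, float(params.fixed_bandwidth))
    sd = points.std(axis=0, ddof=1) if n > 1 else np.ones(d)
    sd = np.where(sd > 0, sd, 1.0)
    if params.bandwidth_rule == "scott":
        factor = n ** (-1.0 / (d + 4))
    elif params.bandwidth_rule == "silverman":
        factor = (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    else:
        raise ValidationError(f"unknown bandwidth rule {params.bandwidth_rule!r}")
    return sd * factor


def make_grid(points: np.ndarray, spacing: float, pad: np.ndarray | float
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regular per-axis node coordinates covering points +- pad."""
    pad = np.broadcast_to(np.asarray(pad, float), (3,))
    axes = []
    for a in range(3):
        lo = points[:, a].min() - pad[a]
        hi = points[:, a].max() + pad[a]
        n = max(2, int(np.ceil((hi - lo) / spacing)) + 1)
        axes.append(lo + np.arange(n) * spacing)
    return tuple(axes)


def _kde_on_grid(points: np.ndarray, axes, bandwidth: np.ndarray,
                 block: int = 512) -> np.ndarray:
    """Gaussian-product-kernel KDE evaluated on the grid (separable kernels)."""
    n = len(points)
    out = np.zeros(tuple(len(ax) for ax in axes))
    for start in range(0, n, block):
        chunk = points[start:start + block]
        g = [scipy.stats.norm.pdf((ax[:, None] - chunk[:, a][None, :])
                                  / bandwidth[a]) / bandwidth[a]
             for a, ax in enumerate(axes)]
        out += np.einsum("ip,jp,kp->ijk", g[0], g[1], g[2])
    return out / n


def estimate_density(cloud: PointCloud3D, subpop: str = "all",
                     animal: str | None = None,
                     params: KdeParams | None = None,
                     axes=None) -> DensityField:
    """KDE of one (subpop, animal) selection on a regular grid.

    The grid defaults to the selection's bounding box padded by 3 bandwidths
    (so the density integrates to ~1); pass ``axes`` to evaluate several
    selections on a shared grid.
    """
    params = params or KdeParams()
    sel = cloud.select(subpop, animal)
    if len(sel) < params.min_points:
        raise InsufficientDataError(
            f"selection (subpop={subpop!r}, animal={animal!r}) has {len(sel)} "
            f"points; need >= {params.min_points}")
    pts = sel.points
    h = _bandwidth(pts, params)
    if axes is None:
        axes = make_grid(pts, params.grid_spacing, 3.0 * h)
    values = _kde_on_grid(pts, axes, h)
    return DensityField(tuple(axes), values, h, subpop=subpop, animal=animal)


# ---------------------------------------------------------------------------
# Super-level ("isosurface") summaries
# ---------------------------------------------------------------------------

def isosurface_levels(field: DensityField, quantiles) -> pd.DataFrame:
    """Summarise super-level sets of the density at each density quantile.

    For each q, the set of nodes whose density reaches the q-quantile of the
    positive node densities is summarised by node count, physical volume and
    the (unweighted) centroid of its nodes.  Volumes are non-increasing in q.
    """
    rows = []
    positive = field.values[field.values > 0]
    if positive.size == 0:
        raise ValidationError("density field has no positive values")
    coords = field.node_coordinates()
    flat = field.values.ravel()
    for q in quantiles:
        if not 0 < q < 1:
            raise ValidationError(f"quantile {q} outside (0, 1)")
        level = np.quantile(positive, q)
        in_set = flat >= level
        sel = coords[in_set]
        rows.append({
            "quantile": q, "level": float(level),
            "n_nodes": int(in_set.sum()),
            "volume_um3": float(in_set.sum() * field.voxel_volume),
            "centroid_x": float(sel[:, 0].mean()),
            "centroid_y": float(sel[:, 1].mean()),
            "centroid_z": float(sel[:, 2].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Node-wise local comparison ("p-value spheres")
# ---------------------------------------------------------------------------

def _kde_at_points(points: np.ndarray, query: np.ndarray,
                   bandwidth: np.ndarray, block: int = 512) -> np.ndarray:
    """Direct Gaussian-product-kernel sum evaluated at arbitrary locations."""
    norm = len(points) * np.prod(bandwidth) * (2.0 * np.pi) ** (len(bandwidth) / 2.0)
    out = np.empty(len(query))
    for start in range(0, len(query), block):
        q = query[start:start + block]
        u = (q[:, None, :] - points[None, :, :]) / bandwidth
        out[start:start + block] = np.exp(-0.5 * (u ** 2).sum(-1)).sum(1) / norm
    return out


def occupied_region(cloud: PointCloud3D, params: KdeParams
                    ) -> tuple[tuple, np.ndarray, DensityField]:
    """Shared grid + boolean mask of the space occupied by the neurons.

    The occupancy level is the ``occupancy_quantile`` of the all-cells
    density evaluated at the cell positions themselves, so the super-level
    set covers the region holding the densest (1 - q) fraction of cells
    rather than scaling with how far the evaluation grid is padded.
    """
    all_field = estimate_density(cloud, "all", None, params)
    dens_at_cells = _kde_at_points(cloud.points, cloud.points,
                                   all_field.bandwidth)
    level = np.quantile(dens_at_cells, params.occupancy_quantile)
    mask = all_field.values >= level
    return all_field.axes, mask, all_field


def _per_animal_difference_fields(cloud: PointCloud3D, subpop_labels: np.ndarray,
                                  axes, params: KdeParams) -> np.ndarray:
    """Stack of (typical - ghost) normalised density fields, one per animal."""
    diffs = []
    for animal in cloud.animals:
        a_mask = cloud.animal_id == animal
        fields = {}
        for name in ("typical", "ghost"):
            pts = cloud.points[a_mask & (subpop_labels == name)]
            if len(pts) < params.min_points:
                raise InsufficientDataError(
                    f"animal {animal!r} has {len(pts)} {name!r} points; "
                    f"need >= {params.min_points}")
            h = _bandwidth(pts, params)
            fields[name] = _kde_on_grid(pts, axes, h)
        diffs.append(fields["typical"] - fields["ghost"])
    return np.stack(diffs)


def local_subpopulation_test(cloud: PointCloud3D,
                             params: KdeParams | None = None,
                             mode: str = "t",
                             n_permutations: int = 200,
                             seed: int = 0) -> PValueField:
    """Node-wise two-tailed comparison of the two subpopulations' local
    density, paired across animals, restricted to the occupied region.

    ``mode='t'`` (default) runs a paired t-test on the per-animal
    (typical - ghost) normalised densities at each node; all-zero paired
    differences give p = 1 by convention.  ``mode='permutation'`` permutes
    subpopulation labels within animal and compares the observed mean
    difference to the permutation distribution (two-tailed, add-one
    corrected).
    """
    params = params or KdeParams()
    animals = cloud.animals
    if len(animals) < 2:
        raise InsufficientDataError("need >= 2 animals for the paired test")
    missing = [a for a in animals for s in ("typical", "ghost")
               if (cloud.subpop[cloud.animal_id == a] == s).sum() < params.min_points]
    if missing:
        raise InsufficientDataError(
            f"animals missing a subpopulation (or below {params.min_points} "
            f"points): {sorted(set(missing))}")

    axes, occ_mask, _ = occupied_region(cloud, params)
    occ_flat = occ_mask.ravel()
    diffs = _per_animal_difference_fields(cloud, cloud.subpop, axes, params)
    d = diffs.reshape(len(animals), -1)[:, occ_flat]   # (A, m)
    mean_d = d.mean(axis=0)

    if mode == "t":
        sd = d.std(axis=0, ddof=1)
        A = len(animals)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = mean_d / (sd / np.sqrt(A))
            p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=A - 1)
        p = np.where(sd == 0, np.where(mean_d == 0, 1.0, P_FLOOR), p)
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        count = np.zeros(mean_d.shape)
        for _ in range(n_permutations):
            perm = cloud.subpop.copy()
            for animal in animals:
                idx = np.flatnonzero(cloud.animal_id == animal)
                perm[idx] = perm[rng.permutation(idx)]
            pd_fields = _per_animal_difference_fields(cloud, perm, axes, params)
            perm_mean = pd_fields.reshape(len(animals), -1)[:, occ_flat].mean(axis=0)
            count += np.abs(perm_mean) >= np.abs(mean_d) - 1e-15
        p = (count + 1.0) / (n_permutations + 1.0)
    else:
        raise ValidationError(f"unknown mode {mode!r} ('t' or 'permutation')")

    p = np.clip(p, P_FLOOR, 1.0)
    coords = np.stack([a.ravel() for a in
                       np.meshgrid(*axes, indexing="ij")], axis=1)[occ_flat]
    return PValueField(nodes=coords, p=p,
                       direction=np.sign(mean_d).astype(int), axes=tuple(axes))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Optional BH adjustment of the node-wise p-values."""
    return scipy.stats.false_discovery_control(p, method="bh")


# ---------------------------------------------------------------------------
# Cumulative distributions along an axis and Gaussian CDF fits
# ---------------------------------------------------------------------------

def cumulative_axis_distribution(cloud: PointCloud3D, subpop: str = "all",
                                 axis: int = CAUDAL_AXIS) -> pd.DataFrame:
    """Empirical CDF of a subpopulation's positions along one axis,
    pooled across animals: sorted positions with cumulative fraction k/n."""
    sel = cloud.select(subpop)
    if len(sel) < 2:
        raise InsufficientDataError(
            f"subpop {subpop!r} has {len(sel)} points; need >= 2")
    pos = np.sort(sel.points[:, axis])
    return pd.DataFrame({"position": pos,
                         "cum_frac": np.arange(1, len(pos) + 1) / len(pos)})


def _gauss_cdf(x, mu, sigma):
    return scipy.stats.norm.cdf(x, loc=mu, scale=sigma)


def fit_gaussian_cdf(cdf: pd.DataFrame, model: str = "separate") -> CdfFit:
    """Least-squares fit of a Gaussian CDF to (position, cum_frac) points."""
    x = cdf["position"].to_numpy(float)
    y = cdf["cum_frac"].to_numpy(float)
    if len(x) < 5:
        raise InsufficientDataError("need >= 5 CDF points to fit")
    if np.ptp(x) == 0:
        raise FitError("degenerate CDF: all positions identical")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    mu0 = float(np.interp(0.5, ys, xs))
    sigma0 = max((np.interp(0.84, ys, xs) - np.interp(0.16, ys, xs)) / 2.0,
                 np.ptp(x) / 100.0)
    last_err = None
    for p0 in ((mu0, sigma0), (x.mean(), max(x.std(), np.ptp(x) / 10.0)),
               (np.median(x), np.ptp(x) / 4.0)):
        try:
            popt, _ = scipy.optimize.curve_fit(
                _gauss_cdf, x, y, p0=p0,
                bounds=([-np.inf, np.ptp(x) * 1e-6], [np.inf, np.inf]),
                maxfev=10_000)
            rss = float(((y - _gauss_cdf(x, *popt)) ** 2).sum())
            return CdfFit(mu=float(popt[0]), sigma=float(popt[1]),
                          rss=rss, n_points=len(x), model=model)
        except RuntimeError as err:   # pragma: no cover - restart path
            last_err = err
    raise FitError(f"Gaussian CDF fit failed after restarts: {last_err}")


def compare_fits_extra_ss(cdf_a: pd.DataFrame, cdf_b: pd.DataFrame) -> dict:
    """Extra-sum-of-squares F-test: one shared Gaussian CDF for both data
    sets (2 parameters) vs separate ones (4 parameters).

    F = ((RSS_pooled - RSS_sep) / 2) / (RSS_sep / (n - 4)) with p from the
    F(2, n-4) tail.  RSS_sep = 0 is reported as F = inf, p = 0, flagged
    degenerate.  Cumulative fractions are treated as independent
    observations, as in the graphing convention this mirrors.
    """
    fit_a = fit_gaussian_cdf(cdf_a)
    fit_b = fit_gaussian_cdf(cdf_b)
    pooled_df = pd.concat([cdf_a, cdf_b], ignore_index=True)
    fit_p = fit_gaussian_cdf(pooled_df, model="pooled")
    n = fit_a.n_points + fit_b.n_points
    rss_sep = fit_a.rss + fit_b.rss
    rss_pooled = fit_p.rss
    df_sep = n - 4
    df_num = 2
    if df_sep <= 0:
        raise InsufficientDataError("too few points for the 4-parameter model")
    if rss_sep == 0:
        return {"F": np.inf, "df1": df_num, "df2": df_sep, "p": 0.0,
                "degenerate": True, "fit_a": fit_a, "fit_b": fit_b,
                "fit_pooled": fit_p}
    F = max(0.0, (rss_pooled - rss_sep) / df_num / (rss_sep / df_sep))
    p = float(scipy.stats.f.sf(F, df_num, df_sep))
    return {"F": float(F), "df1": df_num, "df2": df_sep, "p": p,
            "degenerate": False, "fit_a": fit_a, "fit_b": fit_b,
            "fit_pooled": fit_p}
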