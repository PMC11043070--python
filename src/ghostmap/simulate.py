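"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's raw data: multichannel image stacks of
lineage-reporter-positive cells where a fraction lacks the identity marker
("ghost" cells); 3D centroid clouds in which the ghost subpopulation is
shifted caudally; current-clamp recordings around a hormone application with
prescribed membrane-potential and input-resistance effects; and
negative-binomial gene-by-cell count matrices with cluster-specific marker
programs, a depletable identity-gene program and diet-dependent cluster
sizes.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CellTable, CountMatrix, EphysRecording, PointCloud3D, ResponseCall,
    ValidationError, derive_gene_flags,
)
from .ephys import classify_response


class PackingError(ValidationError):
    """Requested cells cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Intensity model of one imaging channel, by true cell class."""
    name: str
    typical_mean_intensity: float
    ghost_mean_intensity: float
    noise_sd: float = 2.0


@dataclass
class ImageStackSpec:
    """Geometry and intensity model of a synthetic multichannel Z-stack.

    The reporter channel is equally bright for both classes; the identity
    marker channel ('pomc') is bright in typical cells and dark in ghost
    cells, emulating promoter-reporter mismatch.
    """
    shape: tuple[int, int, int] = (32, 288, 288)     # (Z, Y, X) voxels
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)   # um, (z, y, x)
    n_cells: int = 200
    ghost_fraction: float = 0.10
    cell_radius: tuple[float, float] = (3.0, 0.4)    # um (mean, sd)
    channels: list[ChannelSpec] = field(default_factory=lambda: [
        ChannelSpec("reporter", 100.0, 100.0, 2.0),
        ChannelSpec("pomc", 80.0, 0.0, 2.0),
    ])
    background: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ghost_fraction <= 1.0:
            raise ValidationError("ghost_fraction must lie in [0, 1]")
        if self.background < 0 or any(
                c.typical_mean_intensity < 0 or c.ghost_mean_intensity < 0
                or c.noise_sd < 0 for c in self.channels):
            raise ValidationError("intensities and noise sd must be >= 0")


MAX_PACKING_RETRIES = 10_000


def _pack_spheres(spec: ImageStackSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Place spheres whose XY-projection disks do not overlap (hard-core
    rejection).  Projection separation implies 3D separation, so the ground
    truth is unambiguous for both 2D and 3D segmentation."""
    vz, vy, vx = spec.voxel_size
    extent = np.array([spec.shape[2] * vx, spec.shape[1] * vy, spec.shape[0] * vz])
    centers = np.empty((spec.n_cells, 3))
    radii = np.empty(spec.n_cells)
    placed = 0
    retries = 0
    while placed < spec.n_cells:
        r = max(2.2, rng.normal(*spec.cell_radius))   # soma radius floor, um
        lo, hi = r, extent - r
        if (hi <= lo).any():
            raise PackingError("cell radius exceeds volume extent")
        c = rng.uniform(lo, hi)
        if placed and (np.linalg.norm(centers[:placed, :2] - c[:2], axis=1)
                       < radii[:placed] + r + 3.0).any():
            retries += 1
            if retries > MAX_PACKING_RETRIES:
                raise PackingError(
                    f"could not place {spec.n_cells} non-overlapping cells "
                    f"after {MAX_PACKING_RETRIES} retries"
                )
            continue
        centers[placed] = c
        radii[placed] = r
        placed += 1
    return centers, radii


def gen_image_stack(spec: ImageStackSpec) -> tuple[dict[str, np.ndarray], CellTable]:
    """Simulate a multichannel Z-stack plus its ground-truth cell table.

    Returns ``(stack, truth)`` where ``stack`` maps channel name to a
    float (Z, Y, X) array and ``truth`` holds one row per cell with its true
    class in column ``true_label``.  Ghost count is ``round(n_cells *
    ghost_fraction)`` exactly; cell interiors add the class mean intensity to
    the background, then voxel-wise Gaussian noise (clipped at 0) is applied.
    """
    rng = np.random.default_rng(spec.seed)
    centers, radii = _pack_spheres(spec, rng)
    n_ghost = int(round(spec.n_cells * spec.ghost_fraction))
    labels = np.array(["typical"] * spec.n_cells, dtype=object)
    ghost_idx = rng.choice(spec.n_cells, size=n_ghost, replace=False)
    labels[ghost_idx] = "ghost"

    vz, vy, vx = spec.voxel_size
    nz, ny, nx = spec.shape
    stack = {ch.name: np.full(spec.shape, spec.background, dtype=float)
             for ch in spec.channels}
    # voxel-centre physical coordinates
    for i in range(spec.n_cells):
        cx, cy, cz = centers[i]
        r = radii[i]
        z0, z1 = int(max(0, (cz - r) / vz - 1)), int(min(nz, (cz + r) / vz + 2))
        y0, y1 = int(max(0, (cy - r) / vy - 1)), int(min(ny, (cy + r) / vy + 2))
        x0, x1 = int(max(0, (cx - r) / vx - 1)), int(min(nx, (cx + r) / vx + 2))
        zz = (np.arange(z0, z1) + 0.5) * vz
        yy = (np.arange(y0, y1) + 0.5) * vy
        xx = (np.arange(x0, x1) + 0.5) * vx
        inside = ((zz[:, None, None] - cz) ** 2 + (yy[None, :, None] - cy) ** 2
                  + (xx[None, None, :] - cx) ** 2) <= r ** 2
        for ch in spec.channels:
            level = (ch.typical_mean_intensity if labels[i] == "typical"
                     else ch.ghost_mean_intensity)
            sub = stack[ch.name][z0:z1, y0:y1, x0:x1]
            sub[inside] += level
    for ch in spec.channels:
        if ch.noise_sd > 0:
            stack[ch.name] += rng.normal(0.0, ch.noise_sd, size=spec.shape)
            np.clip(stack[ch.name], 0.0, None, out=stack[ch.name])

    truth = pd.DataFrame({
        "cell_id": [f"c{i:04d}" for i in range(spec.n_cells)],
        "animal_id": "a0",
        "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
        "radius_um": radii,
        "true_label": labels,
        "lineage_positive": True,
    })
    return stack, CellTable(truth)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

@dataclass
class SpatialSpec:
    """Two trivariate-normal subpopulations, the ghost one shifted caudally.

    Default extents put each subpopulation in a compact domain a few hundred
    micrometres across, within an arcuate-nucleus-scale volume; the default
    caudal shift matches the magnitude resolvable by cumulative-distribution
    analysis at a few thousand cells per subpopulation.
    """
    n_typical: int = 2000
    n_ghost: int = 2000
    typical_center: tuple[float, float, float] = (400.0, 400.0, 800.0)
    ghost_center: tuple[float, float, float] = (400.0, 400.0, 800.0)
    covariances: dict[str, np.ndarray] = field(default_factory=lambda: {
        "typical": np.diag([100.0 ** 2, 100.0 ** 2, 120.0 ** 2]),
        "ghost": np.diag([100.0 ** 2, 100.0 ** 2, 120.0 ** 2]),
    })
    caudal_shift: float = 200.0    # um, applied to ghost_center along axis 2
    n_animals: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        for name, cov in self.covariances.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValidationError(f"covariance for {name!r} not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValidationError(f"covariance for {name!r} not positive definite")
            self.covariances[name] = cov


def gen_point_cloud(spec: SpatialSpec) -> PointCloud3D:
    """Draw the two labelled subpopulations; animals assigned round-robin."""
    rng = np.random.default_rng(spec.seed)
    ghost_center = np.asarray(spec.ghost_center, dtype=float).copy()
    ghost_center[2] += spec.caudal_shift
    pts, subpop, animals = [], [], []
    for name, n, center in (("typical", spec.n_typical, np.asarray(spec.typical_center)),
                            ("ghost", spec.n_ghost, ghost_center)):
        if n == 0:
            continue
        draws = rng.multivariate_normal(center, spec.covariances[name], size=n,
                                        method="cholesky")
        pts.append(draws)
        subpop.extend([name] * n)
        animals.extend(f"a{i % spec.n_animals}" for i in range(n))
    if not pts:
        return PointCloud3D(np.empty((0, 3)), np.array([], dtype=object),
                            np.array([], dtype=object))
    return PointCloud3D(np.vstack(pts), np.array(subpop, dtype=object),
                        np.array(animals, dtype=object))


# ---------------------------------------------------------------------------
# Electrophysiology cohorts
# ---------------------------------------------------------------------------

@dataclass
class EphysCohortSpec:
    """Cohort of hormone-application recordings with prescribed effects.

    Effect sizes are (delta RMP in mV, delta Ri in %) per response class;
    classes must sit strictly beyond the classification thresholds
    (|dRMP| - 2 mV >= 3 * noise_sd recommended) so the ground truth is
    unambiguous.
    """
    n_per_class: dict[str, int] = field(default_factory=lambda: {
        "activated": 8, "inhibited": 9, "nonresponsive": 7})
    effect_sizes: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "activated": (4.0, 15.0), "inhibited": (-4.0, -15.0),
        "nonresponsive": (0.0, 0.0)})
    noise_sd: float = 0.3          # mV, voltage sample noise
    rmp: float = -55.0             # mV baseline resting potential
    ri: float = 150.0              # MOhm baseline input resistance
    fs: float = 500.0              # Hz sampling rate
    baseline_duration: float = 60.0   # s before hormone onset
    post_duration: float = 340.0      # s after onset (covers the +300 s window)
    pulse_current: float = -5.0    # pA monitor pulse
    pulse_width: float = 0.5       # s
    pulse_period: float = 2.0      # s
    transition: float = 120.0      # s, linear ramp of the hormone effect
    condition: str = "CD"
    preselect_label: str = "typical"
    hormone: str = "leptin"
    seed: int = 0


def _monitor_trace(spec: EphysCohortSpec, d_rmp: float, d_ri_pct: float,
                   rng: np.random.Generator, cell_id: str) -> EphysRecording:
    n = int(round((spec.baseline_duration + spec.post_duration) * spec.fs))
    t = np.arange(n) / spec.fs
    onset = spec.baseline_duration
    # hormone effect ramps linearly over `transition`, then plateaus
    frac = np.clip((t - onset) / spec.transition, 0.0, 1.0)
    v = spec.rmp + d_rmp * frac
    ri = spec.ri * (1.0 + d_ri_pct / 100.0 * frac)   # MOhm
    current = np.zeros(n)
    in_pulse = (t % spec.pulse_period) < spec.pulse_width
    current[in_pulse] = spec.pulse_current
    # instantaneous ohmic deflection: dV[mV] = I[pA] * R[GOhm]
    v = v + current * ri / 1000.0
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=n)
    return EphysRecording(cell_id=cell_id, time=t, voltage=v, current=current,
                          condition=spec.condition,
                          preselect_label=spec.preselect_label,
                          protocol="monitor", hormone=spec.hormone,
                          application_onset=onset)


def gen_ephys_cohort(spec: EphysCohortSpec
                     ) -> tuple[list[EphysRecording], list[ResponseCall]]:
    """Simulate recordings for each requested class; return traces + truth.

    The ground-truth :class:`ResponseCall` is what the classification rule
    yields on the noiseless effect sizes; a warning is issued if a requested
    class's effect sizes fall in the rule's dead zone.
    """
    rng = np.random.default_rng(spec.seed)
    recordings: list[EphysRecording] = []
    truth: list[ResponseCall] = []
    i = 0
    for category in ("activated", "inhibited", "nonresponsive"):
        n = spec.n_per_class.get(category, 0)
        d_rmp, d_ri = spec.effect_sizes.get(category, (0.0, 0.0))
        noiseless = classify_response(d_rmp, d_ri)
        if n > 0 and noiseless.category != category:
            warnings.warn(
                f"effect sizes {d_rmp, d_ri} for class {category!r} classify as "
                f"{noiseless.category!r} even without noise", stacklevel=2)
        for _ in range(n):
            recordings.append(_monitor_trace(spec, d_rmp, d_ri, rng, f"cell{i:03d}"))
            truth.append(ResponseCall(d_rmp, d_ri, category))
            i += 1
    return recordings, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

#: identity-program genes depletable in ghost-like clusters (arcuate markers)
DEFAULT_POMC_PROGRAM = ["Pomc", "Cartpt", "Tbx3", "Glipr1", "Lepr",
                        "Glp1r", "Insr", "Prdm12"]
#: housekeeping flag exemplars so QC fractions are exercised
_MITO_GENES = [f"mt-G{i}" for i in range(8)]
_RIBO_GENES = [f"Rps{i}" for i in range(1, 9)] + [f"Rpl{i}" for i in range(1, 9)]


@dataclass
class CountMatrixSpec:
    """Negative-binomial counts with per-cluster marker programs.

    Variance model: var = mean + mean^2 / dispersion.  Each cluster gets
    ``markers_per_cluster`` exclusive genes whose mean is multiplied by
    ``marker_fold`` in that cluster; the identity program's genes (high
    baseline) are divided by ``depletion_fold`` in the designated ghost-like
    clusters.  Cell metadata records the requested CD/HFD split.
    """
    n_cells_per_cluster: dict[str, dict[str, int]] = field(default_factory=lambda: {
        "a": {"CD": 27, "HFD": 18}, "b": {"CD": 6, "HFD": 7},
        "c": {"CD": 4, "HFD": 8}, "d": {"CD": 1, "HFD": 5}})
    n_genes: int = 500
    markers_per_cluster: int = 40
    baseline_mean: float = 2.0
    marker_fold: float = 8.0
    dispersion: float = 2.0
    program_genes: list[str] = field(default_factory=lambda: list(DEFAULT_POMC_PROGRAM))
    program_mean: float = 20.0
    depleted_in: tuple[str, ...] = ("c", "d")
    depletion_fold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold < 1 or self.depletion_fold < 1:
            raise ValidationError("fold changes must be >= 1")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        for cl, split in self.n_cells_per_cluster.items():
            if sum(split.values()) == 0:
                raise ValidationError(f"cluster {cl!r} requested with 0 cells")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def gen_count_matrix(spec: CountMatrixSpec) -> tuple[CountMatrix, np.ndarray]:
    """Simulate a gene-by-cell count matrix; return it with true labels."""
    rng = np.random.default_rng(spec.seed)
    clusters = list(spec.n_cells_per_cluster)
    special = spec.program_genes + _MITO_GENES + _RIBO_GENES
    n_marker = len(clusters) * spec.markers_per_cluster
    n_filler = spec.n_genes - n_marker - len(special)
    if n_filler < 0:
        raise ValidationError("n_genes too small for marker and program genes")
    marker_genes = {cl: [f"mk_{cl}_{j}" for j in range(spec.markers_per_cluster)]
                    for cl in clusters}
    genes = ([g for cl in clusters for g in marker_genes[cl]] + special
             + [f"gene{j:04d}" for j in range(n_filler)])

    cells, labels, conditions = [], [], []
    for cl in clusters:
        for cond in ("CD", "HFD"):
            for _ in range(spec.n_cells_per_cluster[cl].get(cond, 0)):
                cells.append(f"{cond}_{cl}_{len(cells):03d}")
                labels.append(cl)
                conditions.append(cond)
    labels = np.array(labels, dtype=object)

    gene_idx = {g: i for i, g in enumerate(genes)}
    base = np.full((len(genes), len(cells)), spec.baseline_mean)
    for g in spec.program_genes:
        base[gene_idx[g]] = spec.program_mean
    for cl in clusters:
        cols = np.flatnonzero(labels == cl)
        for g in marker_genes[cl]:
            base[gene_idx[g], cols] *= spec.marker_fold
        if cl in spec.depleted_in:
            for g in spec.program_genes:
                base[gene_idx[g], cols] /= spec.depletion_fold
    counts = _nb_sample(rng, base, spec.dispersion)

    meta = pd.DataFrame({
        "condition": conditions,
        "preselect_label": ["ghost" if cl in spec.depleted_in else "typical"
                            for cl in labels],
        "true_cluster": labels,
    }, index=pd.Index(cells, name="cell"))
    matrix = CountMatrix(genes, cells, counts, cell_meta=meta,
                         gene_flags=derive_gene_flags(genes))
    return matrix, labels
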