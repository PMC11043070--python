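"""Domain types and file IO shared by all pipeline stages.

The central objects are tidy per-cell tables (:class:`CellTable`), labelled 3D
point clouds of cell centroids (:class:`PointCloud3D`), whole-cell recordings
(:class:`EphysRecording`) and gene-by-cell count matrices
(:class:`CountMatrix`).  All tables round-trip losslessly through CSV; count
matrices round-trip through MatrixMarket triplets or dense CSV.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GhostmapError(Exception):
    """Base class for all package errors."""


class SchemaError(GhostmapError):
    """A mandatory column is missing or cannot be resolved."""


class FormatError(GhostmapError):
    """A file does not conform to its declared format."""


class ValidationError(GhostmapError):
    """Data violate a domain invariant."""


class ConfigError(GhostmapError):
    """A configuration parameter is out of its legal range."""


class InsufficientDataError(GhostmapError):
    """Too few observations for the requested computation."""


class FitError(GhostmapError):
    """A nonlinear fit failed to converge."""


# ---------------------------------------------------------------------------
# CellTable
# ---------------------------------------------------------------------------

#: canonical non-channel columns of a cell table, in writing order
CELL_TABLE_COLUMNS = (
    "cell_id", "animal_id", "section_id", "group",
    "x", "y", "z", "area_or_volume",
    "lineage_positive", "class_label",
)

CLASS_LABELS = ("typical", "ghost", "unassigned")


@dataclass
class CellTable:
    """One row per segmented reporter-positive cell.

    Channel statistics live in columns named ``<channel>_mean`` and
    ``<channel>_max`` (arbitrary units, >= 0); marker calls in boolean
    columns named ``<marker>_pos``.  ``class_label`` is one of ``typical``,
    ``ghost`` or ``unassigned`` and may be non-``unassigned`` only for
    lineage-positive cells.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("cell_id", "animal_id"):
            if col not in df.columns:
                raise SchemaError(f"cell table is missing mandatory column {col!r}")
        for col, default in (
            ("section_id", "s0"), ("group", "na"),
            ("lineage_positive", True), ("class_label", "unassigned"),
        ):
            if col not in df.columns:
                df[col] = default
        bad = ~df["class_label"].isin(CLASS_LABELS)
        if bad.any():
            raise ValidationError(
                f"unknown class labels: {sorted(df.loc[bad, 'class_label'].unique())}"
            )
        assigned = df["class_label"].isin(("typical", "ghost"))
        if (assigned & ~df["lineage_positive"].astype(bool)).any():
            raise ValidationError(
                "class_label may be typical/ghost only for lineage-positive cells"
            )
        for ch in self.channels:
            for stat in ("mean", "max"):
                col = f"{ch}_{stat}"
                vals = pd.to_numeric(df[col], errors="coerce")
                if vals.isna().any():
                    idx = int(np.flatnonzero(vals.isna())[0])
                    raise FormatError(f"non-numeric intensity in {col!r} at row {idx}")
                if (vals < 0).any():
                    raise ValidationError(f"negative intensity in column {col!r}")
                df[col] = vals.astype(float)
        if {"x", "y", "z"} <= set(df.columns):
            xyz = df[["x", "y", "z"]].to_numpy(float)
            if not np.isfinite(xyz).all():
                raise ValidationError("non-finite centroid coordinates")
        dup = df.duplicated(subset=["animal_id", "section_id", "cell_id"])
        if dup.any():
            raise ValidationError("cell_id not unique within (animal_id, section_id)")

    @property
    def channels(self) -> list[str]:
        """Channel names, inferred from ``<channel>_mean`` columns."""
        out = []
        for col in self.df.columns:
            if col.endswith("_mean") and f"{col[:-5]}_max" in self.df.columns:
                out.append(col[:-5])
        return out

    @property
    def markers(self) -> list[str]:
        return [c[:-4] for c in self.df.columns if c.endswith("_pos")]

    def __len__(self) -> int:
        return len(self.df)

    def channel_stat(self, channel: str, stat: str) -> np.ndarray:
        col = f"{channel}_{stat}"
        if col not in self.df.columns:
            raise SchemaError(
                f"channel column {col!r} not present; available channels: {self.channels}"
            )
        return self.df[col].to_numpy(float)


def load_cell_table(path: str | os.PathLike, schema: Mapping[str, str] | None = None) -> CellTable:
    """Read a tidy one-row-per-cell CSV/TSV.

    ``schema`` maps canonical column names (``cell_id``, ``animal_id``,
    ``<channel>_mean``, ...) to the column names used in the file; unknown
    file columns are preserved as passthrough metadata.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        missing_src = [src for src in schema.values() if src not in df.columns]
        if missing_src:
            raise SchemaError(f"schema refers to absent column(s): {missing_src}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    return CellTable(df)


def write_cell_table(cells: CellTable, path: str | os.PathLike) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cells.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# PointCloud3D
# ---------------------------------------------------------------------------

DEFAULT_AXIS_NAMES = ("medio-lateral", "dorso-ventral", "rostro-caudal")

#: index of the rostro-caudal axis in the default frame
CAUDAL_AXIS = 2


@dataclass
class PointCloud3D:
    """Cell centroids (um) with per-point subpopulation and animal labels."""

    points: np.ndarray                       # (n, 3) float, um
    subpop: np.ndarray                       # (n,) str in {typical, ghost, all}
    animal_id: np.ndarray                    # (n,) str
    axis_names: tuple[str, str, str] = DEFAULT_AXIS_NAMES

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.subpop = np.asarray(self.subpop, dtype=object)
        self.animal_id = np.asarray(self.animal_id, dtype=object)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValidationError("non-finite coordinates in point cloud")
        n = len(self.points)
        if len(self.subpop) != n or len(self.animal_id) != n:
            raise ValidationError("subpop and animal_id must have one entry per point")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, subpop: str | None = None, animal: str | None = None) -> "PointCloud3D":
        """Subset by subpopulation and/or animal; ``subpop='all'`` keeps everything."""
        mask = np.ones(len(self), dtype=bool)
        if subpop is not None and subpop != "all":
            mask &= self.subpop == subpop
        if animal is not None:
            mask &= self.animal_id == animal
        return PointCloud3D(self.points[mask], self.subpop[mask],
                            self.animal_id[mask], self.axis_names)

    @property
    def animals(self) -> list[str]:
        return sorted(set(self.animal_id.tolist()))


def load_point_cloud(path: str | os.PathLike) -> PointCloud3D:
    df = pd.read_csv(path)
    for col in ("x", "y", "z", "subpop", "animal_id"):
        if col not in df.columns:
            raise SchemaError(f"point-cloud file is missing column {col!r}")
    return PointCloud3D(df[["x", "y", "z"]].to_numpy(float),
                        df["subpop"].to_numpy(object),
                        df["animal_id"].to_numpy(object))


def write_point_cloud(cloud: PointCloud3D, path: str | os.PathLike) -> None:
    pd.DataFrame({
        "x": cloud.points[:, 0], "y": cloud.points[:, 1], "z": cloud.points[:, 2],
        "subpop": cloud.subpop, "animal_id": cloud.animal_id,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Electrophysiology types
# ---------------------------------------------------------------------------

@dataclass
class EphysRecording:
    """A continuous current-clamp recording around a hormone application.

    ``time`` is in seconds (strictly increasing), ``voltage`` in mV,
    ``current`` (optional) in pA.  ``application_onset`` marks the start of
    hormone perfusion on the ``time`` axis.
    """

    cell_id: str
    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray | None = None
    condition: str = "CD"
    preselect_label: str = "typical"
    protocol: str = "monitor"
    hormone: str = "none"
    application_onset: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.current is not None:
            self.current = np.asarray(self.current, dtype=float)
            if self.current.shape != self.time.shape:
                raise ValidationError("current and time must have equal length")
        if self.time.shape != self.voltage.shape:
            raise ValidationError("time and voltage must have equal length")
        if len(self.time) > 1 and not (np.diff(self.time) > 0).all():
            raise ValidationError("time must be strictly increasing")
        if not np.isfinite(self.voltage).all():
            raise ValidationError("non-finite voltage samples")


@dataclass
class StepSweep:
    """One sweep of a current-step train: constant injected current + response."""

    current_pA: float
    time: np.ndarray
    voltage: np.ndarray


@dataclass
class IntrinsicFeatures:
    Em_rest: float            # mV
    Ri: float                 # MOhm
    rheobase: float | None    # pA
    Cm: float | None = None   # pF, carried as metadata
    ap_threshold: float | None = None
    ap_amplitude: float | None = None
    ap_halfwidth: float | None = None
    fAHP: float | None = None
    mAHP: float | None = None


RESPONSE_CATEGORIES = ("activated", "inhibited", "nonresponsive")


@dataclass(frozen=True)
class ResponseCall:
    delta_rmp: float       # mV, post - pre window mean
    delta_ri_pct: float    # %, 100*(Ri_post - Ri_pre)/Ri_pre
    category: str          # activated | inhibited | nonresponsive


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

#: default gene-name prefixes flagging mitochondrial / ribosomal genes (mouse)
MITO_PREFIXES = ("mt-", "Mt-", "MT-")
RIBO_PREFIXES = ("Rps", "Rpl", "Mrps", "Mrpl")


@dataclass
class CountMatrix:
    """Gene-by-cell raw counts with per-cell metadata and per-gene flags."""

    genes: list[str]
    cells: list[str]
    counts: np.ndarray                  # (n_genes, n_cells) int
    cell_meta: pd.DataFrame = None      # indexed by cell id
    gene_flags: pd.DataFrame = None     # indexed by gene id: is_mito, is_ribo

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, atol=0):
                raise ValidationError("counts must be integers")
            self.counts = as_int.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cells, name="cell"))
        if self.gene_flags is None:
            self.gene_flags = derive_gene_flags(self.genes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def derive_gene_flags(genes: Sequence[str],
                      mito_prefixes: Sequence[str] = MITO_PREFIXES,
                      ribo_prefixes: Sequence[str] = RIBO_PREFIXES) -> pd.DataFrame:
    """Flag mitochondrial/ribosomal genes by name prefix."""
    return pd.DataFrame({
        "is_mito": [any(g.startswith(p) for p in mito_prefixes) for g in genes],
        "is_ribo": [any(g.startswith(p) for p in ribo_prefixes) for g in genes],
    }, index=pd.Index(list(genes), name="gene"))


def _check_mtx_nnz(mtx_path: str) -> None:
    # MatrixMarket declares nnz in its size line; verify against actual entries
    with open(mtx_path) as fh:
        header = None
        n_entries = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if header is None:
                header = line.split()
            else:
                n_entries += 1
    if header is None:
        raise FormatError(f"{mtx_path}: no size header found")
    nnz = int(header[2])
    if nnz != n_entries:
        raise FormatError(
            f"{mtx_path}: header declares {nnz} entries but file contains {n_entries}"
        )


def load_count_matrix(path: str | os.PathLike,
                      cell_meta: pd.DataFrame | None = None) -> CountMatrix:
    """Read counts from an MTX triplet directory or a dense CSV.

    MTX layout: ``matrix.mtx`` (genes x cells) with ``genes.tsv`` and
    ``cells.tsv`` sidecars (one identifier per line).  Dense CSV layout:
    genes as rows (first column = gene id), cells as columns.
    """
    path = str(path)
    if os.path.isdir(path):
        mtx = os.path.join(path, "matrix.mtx")
        if not os.path.exists(mtx):
            raise FormatError(f"{path}: expected matrix.mtx in MTX directory")
        _check_mtx_nnz(mtx)
        counts = np.asarray(scipy.io.mmread(mtx).todense())
        genes = pd.read_csv(os.path.join(path, "genes.tsv"),
                            header=None, sep="\t")[0].astype(str).tolist()
        cells = pd.read_csv(os.path.join(path, "cells.tsv"),
                            header=None, sep="\t")[0].astype(str).tolist()
    else:
        df = pd.read_csv(path, index_col=0)
        genes = df.index.astype(str).tolist()
        cells = df.columns.astype(str).tolist()
        counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        as_int = np.rint(counts)
        if not np.array_equal(counts, as_int):
            raise ValidationError("count matrix contains fractional values")
        if (counts < 0).any():
            raise ValidationError("count matrix contains negative values")
        counts = as_int.astype(np.int64)
    return CountMatrix(genes, cells, counts, cell_meta=cell_meta)


def write_count_matrix(matrix: CountMatrix, path: str | os.PathLike,
                       fmt: str = "mtx") -> None:
    """Write counts as an MTX triplet directory (``fmt='mtx'``) or dense CSV."""
    path = str(path)
    if fmt == "mtx":
        os.makedirs(path, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sparse, field="integer")
        with open(os.path.join(path, "genes.tsv"), "w") as fh:
            fh.write("\n".join(matrix.genes) + "\n")
        with open(os.path.join(path, "cells.tsv"), "w") as fh:
            fh.write("\n".join(matrix.cells) + "\n")
    elif fmt == "csv":
        pd.DataFrame(matrix.counts, index=matrix.genes,
                     columns=matrix.cells).to_csv(path)
    else:
        raise ConfigError(f"unknown count-matrix format {fmt!r} (mtx or csv)")
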