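"""Lattice landscape model, synthetic forest generators and raster I/O.

A landscape is a rectangular grid of square cells.  Each cell is a node of
the fire-spread network; node ``k = row * n_cols + col`` (0-based, row-major,
row 0 at the north edge, raster convention).  Two model kinds are supported:

``simple``
    A flat, single-vegetation-type forest where the only per-cell property is
    *emptiness* ``s2 ∈ [0, 1]`` — 0 means very dense vegetation, 1 means an
    empty (or already burned) cell.  The ignition probability of a cell is
    ``1 − s2``.

``full``
    A heterogeneous landscape with per-cell vegetation-type effect,
    vegetation-density effect and elevation (m).  The ignition probability is
    the nominal probability ``p0`` modulated by the two vegetation effects and
    an exponential slope gain (see :mod:`firebreaks.spread`).

File formats are plain text: ESRI ASCII grids (``.asc``) for real-valued
layers and plain PGM (``P2``) for quantized grayscale frequency maps.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger("firebreaks")

# Burn-state codes (s1): susceptible -> burning -> burned, in that order.
SUSCEPTIBLE: int = 0
BURNING: int = 1
BURNED: int = -1

#: Vegetation-density categories and their multiplicative-effect offsets s3.
DENSITY_EFFECTS: dict[str, float] = {"sparse": -0.4, "moderate": 0.0, "dense": 0.3}
#: Vegetation-type categories and their multiplicative-effect offsets s2.
TYPE_EFFECTS: dict[str, float] = {"agricultural": -0.3, "other": 0.0, "pine": 0.4}

#: Default integer raster codes for categorical layers.
DEFAULT_TYPE_CODES: dict[int, str] = {1: "agricultural", 2: "other", 3: "pine"}
DEFAULT_DENSITY_CODES: dict[int, str] = {1: "sparse", 2: "moderate", 3: "dense"}


class LandscapeError(ValueError):
    """Invalid landscape construction or I/O input."""


@dataclass
class CAParams:
    """Constants of the heterogeneous cellular-automata spread kernel.

    Parameters
    ----------
    p0
        Nominal fire-spread probability between flat, moderate-density,
        baseline-type neighbours (no wind).  Calibrated from field data.
    slope_coeff
        Slope coefficient ``a`` (> 0) of the exponential slope gain
        ``exp(a * theta_s)``.
    cell_side
        Side length of a square cell in meters (symbol ``l``).
    density_effect_table, type_effect_table
        Category -> additive effect used in the factors ``(1 + s3)`` and
        ``(1 + s2)`` of the transition probability.
    """

    p0: float = 0.58
    slope_coeff: float = 0.078
    cell_side: float = 10.0
    density_effect_table: dict[str, float] = field(
        default_factory=lambda: dict(DENSITY_EFFECTS)
    )
    type_effect_table: dict[str, float] = field(
        default_factory=lambda: dict(TYPE_EFFECTS)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 <= 1.0):
            raise LandscapeError(f"p0 must lie in (0, 1], got {self.p0}")
        if self.slope_coeff <= 0.0:
            raise LandscapeError(f"slope_coeff must be > 0, got {self.slope_coeff}")
        if self.cell_side <= 0.0:
            raise LandscapeError(f"cell_side must be > 0, got {self.cell_side}")


@dataclass
class LandscapeGrid:
    """Per-cell state of a landscape plus its geometry and boundary mode.

    Exactly one of the two model kinds is populated: ``emptiness`` for the
    simple model, or ``type_effect``/``density_effect``/``elevation`` (with
    ``fuel_mask`` and retained category labels) for the full model.
    """

    n_rows: int
    n_cols: int
    boundary: str  # "periodic" | "absorbing"
    model_kind: str  # "simple" | "full"
    burn_state: np.ndarray  # int8, values in {-1, 0, 1}
    emptiness: np.ndarray | None = None  # float in [0, 1], simple model
    type_effect: np.ndarray | None = None  # full model
    density_effect: np.ndarray | None = None  # full model
    elevation: np.ndarray | None = None  # meters, full model
    fuel_mask: np.ndarray | None = None  # bool, full model: cell contains fuel
    type_label: np.ndarray | None = None  # category names, full model
    density_label: np.ndarray | None = None  # category names, full model
    cell_side: float | None = None  # meters; unset for the flat simple model

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def node_index(self, row: int, col: int) -> int:
        """Row-major node index of cell (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.shape} grid")
        return row * self.n_cols + col

    def node_coords(self, k: int) -> tuple[int, int]:
        """Inverse of :meth:`node_index`."""
        if not (0 <= k < self.n_nodes):
            raise IndexError(f"node {k} outside grid of {self.n_nodes} nodes")
        return divmod(k, self.n_cols)

    # -- derived state ------------------------------------------------------

    @property
    def flammable(self) -> np.ndarray:
        """Boolean field: cell contains fuel and is not a fire break."""
        if self.model_kind == "simple":
            return self.emptiness < 1.0
        return self.fuel_mask.copy()

    def copy(self) -> "LandscapeGrid":
        out = dataclasses.replace(self)
        for name in (
            "burn_state",
            "emptiness",
            "type_effect",
            "density_effect",
            "elevation",
            "fuel_mask",
            "type_label",
            "density_label",
        ):
            arr = getattr(out, name)
            if arr is not None:
                setattr(out, name, arr.copy())
        return out

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LandscapeError("grid must have positive dimensions")
        if self.boundary not in ("periodic", "absorbing"):
            raise LandscapeError(f"unknown boundary mode {self.boundary!r}")
        if self.model_kind not in ("simple", "full"):
            raise LandscapeError(f"unknown model kind {self.model_kind!r}")
        if self.burn_state.shape != self.shape:
            raise LandscapeError("burn_state shape does not match grid")
        if not np.isin(self.burn_state, (BURNED, SUSCEPTIBLE, BURNING)).all():
            raise LandscapeError("burn_state values must lie in {-1, 0, 1}")
        if self.model_kind == "simple":
            if self.emptiness is None:
                raise LandscapeError("simple model requires an emptiness field")
            if self.type_effect is not None or self.elevation is not None:
                raise LandscapeError("simple model must not carry full-model fields")
            if self.emptiness.shape != self.shape:
                raise LandscapeError("emptiness shape does not match grid")
            if (self.emptiness < 0).any() or (self.emptiness > 1).any():
                raise LandscapeError("emptiness must lie in [0, 1]")
        else:
            for name in ("type_effect", "density_effect", "elevation", "fuel_mask"):
                arr = getattr(self, name)
                if arr is None or arr.shape != self.shape:
                    raise LandscapeError(f"full model requires field {name}")
            if self.emptiness is not None:
                raise LandscapeError("full model must not carry an emptiness field")
            if self.cell_side is None or self.cell_side <= 0:
                raise LandscapeError("full model requires a positive cell_side")


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------


def generate_artificial_forest(n: int, seed: int) -> LandscapeGrid:
    """Generate a random artificial forest for the simple spread model.

    An ``n x n`` torus (periodic boundaries) of a single vegetation type on
    flat terrain; per-cell emptiness drawn iid Uniform(0, 1).  Reproducible:
    the same seed yields a bit-identical grid.
    """
    if n < 3:
        raise LandscapeError(f"artificial forest needs n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    emptiness = rng.random((n, n))
    return LandscapeGrid(
        n_rows=n,
        n_cols=n,
        boundary="periodic",
        model_kind="simple",
        burn_state=np.zeros((n, n), dtype=np.int8),
        emptiness=emptiness,
    )


def generate_heterogeneous_landscape(
    n: int,
    seed: int,
    params: CAParams | None = None,
    relief_scale: float = 120.0,
    type_probs: Mapping[str, float] | None = None,
) -> LandscapeGrid:
    """Generate a synthetic heterogeneous landscape for the full model.

    A stand-in for a real co-registered raster stack: categorical vegetation
    type and density drawn per cell, plus a smooth synthetic relief built from
    low-frequency cosine modes (amplitude ``relief_scale`` meters).  Uses
    absorbing boundaries, as a real landscape cannot wrap.
    """
    if n < 3:
        raise LandscapeError(f"landscape needs n >= 3, got {n}")
    params = params or CAParams()
    rng = np.random.default_rng(seed)
    if type_probs is None:
        type_probs = {"pine": 0.45, "other": 0.35, "agricultural": 0.2}
    type_names = list(type_probs)
    type_label = rng.choice(type_names, size=(n, n), p=[type_probs[t] for t in type_names])
    density_names = list(DENSITY_EFFECTS)
    density_label = rng.choice(density_names, size=(n, n))

    # Smooth relief: a few random low-order Fourier modes.
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    elevation = np.zeros((n, n))
    for _ in range(4):
        fy, fx = rng.integers(1, 4, size=2)
        phy, phx = rng.random(2) * 2 * np.pi
        elevation += np.cos(2 * np.pi * fy * yy / n + phy) * np.cos(
            2 * np.pi * fx * xx / n + phx
        )
    elevation *= relief_scale / max(np.ptp(elevation), 1e-12)
    elevation -= elevation.min()

    type_effect = np.vectorize(params.type_effect_table.__getitem__)(type_label)
    density_effect = np.vectorize(params.density_effect_table.__getitem__)(density_label)
    fuel_mask = np.ones((n, n), dtype=bool)
    return LandscapeGrid(
        n_rows=n,
        n_cols=n,
        boundary="absorbing",
        model_kind="full",
        burn_state=np.zeros((n, n), dtype=np.int8),
        type_effect=type_effect.astype(float),
        density_effect=density_effect.astype(float),
        elevation=elevation,
        fuel_mask=fuel_mask,
        type_label=type_label,
        density_label=density_label,
        cell_side=params.cell_side,
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_esri_ascii(
    array: np.ndarray,
    path: str | Path,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999,
    fmt: str = "%.12g",
) -> Path:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = north edge)."""
    array = np.asarray(array)
    if array.ndim != 2:
        raise LandscapeError("raster layers must be 2-D")
    path = Path(path)
    header = (
        f"ncols {array.shape[1]}\n"
        f"nrows {array.shape[0]}\n"
        f"xllcorner {xllcorner:.12g}\n"
        f"yllcorner {yllcorner:.12g}\n"
        f"cellsize {cellsize:.12g}\n"
        f"NODATA_value {nodata:.12g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt=fmt)
    return path


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid; returns (array, header dict)."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    data = np.loadtxt(lines[i:], ndmin=2)
    nrows, ncols = int(meta.get("nrows", data.shape[0])), int(
        meta.get("ncols", data.shape[1])
    )
    if data.shape != (nrows, ncols):
        raise LandscapeError(
            f"{path}: data block {data.shape} does not match header ({nrows}, {ncols})"
        )
    return data, meta


def read_landscape_rasters(
    elevation_path: str | Path,
    type_path: str | Path,
    density_path: str | Path,
    params: CAParams | None = None,
    type_codes: Mapping[int, str] | None = None,
    density_codes: Mapping[int, str] | None = None,
    boundary: str = "absorbing",
) -> LandscapeGrid:
    """Assemble a full-model grid from three co-registered ESRI ASCII rasters.

    The type and density rasters hold integer category codes which are mapped
    to effect values through the ``CAParams`` tables; cells equal to a
    raster's NODATA code carry no fuel and get no network edges.
    """
    params = params or CAParams()
    type_codes = dict(type_codes or DEFAULT_TYPE_CODES)
    density_codes = dict(density_codes or DEFAULT_DENSITY_CODES)

    elevation, meta_e = read_esri_ascii(elevation_path)
    types, meta_t = read_esri_ascii(type_path)
    densities, meta_d = read_esri_ascii(density_path)

    for name, meta in (("type", meta_t), ("density", meta_d)):
        if (int(meta["nrows"]), int(meta["ncols"])) != elevation.shape:
            raise LandscapeError(
                f"co-registration error: {name} raster is "
                f"{int(meta['nrows'])}x{int(meta['ncols'])} but elevation is "
                f"{elevation.shape[0]}x{elevation.shape[1]}"
            )
        for key in ("cellsize", "xllcorner", "yllcorner"):
            if not np.isclose(meta.get(key, meta_e.get(key, 0.0)), meta_e.get(key, 0.0)):
                raise LandscapeError(
                    f"co-registration error: {name} raster {key} differs from elevation"
                )

    n_rows, n_cols = elevation.shape
    nodata_t = meta_t.get("nodata_value", -9999)
    nodata_d = meta_d.get("nodata_value", -9999)
    fuel_mask = (types != nodata_t) & (densities != nodata_d)

    type_effect = np.zeros_like(elevation)
    density_effect = np.zeros_like(elevation)
    type_label = np.full((n_rows, n_cols), "nonfuel", dtype=object)
    density_label = np.full((n_rows, n_cols), "nonfuel", dtype=object)
    for code, cat in type_codes.items():
        if cat not in params.type_effect_table:
            raise LandscapeError(f"type category {cat!r} missing from effect table")
    for code, cat in density_codes.items():
        if cat not in params.density_effect_table:
            raise LandscapeError(f"density category {cat!r} missing from effect table")

    for raster, codes, table, effect, label, which in (
        (types, type_codes, params.type_effect_table, type_effect, type_label, "type"),
        (
            densities,
            density_codes,
            params.density_effect_table,
            density_effect,
            density_label,
            "density",
        ),
    ):
        seen = np.zeros(raster.shape, dtype=bool)
        for code, cat in codes.items():
            hit = raster == code
            effect[hit] = table[cat]
            label[hit] = cat
            seen |= hit
        unknown = ~seen & fuel_mask
        if unknown.any():
            bad = sorted(set(raster[unknown].astype(int).tolist()))
            raise LandscapeError(f"unknown {which} category code(s) {bad}")

    cellsize = meta_e.get("cellsize", params.cell_side)
    return LandscapeGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        boundary=boundary,
        model_kind="full",
        burn_state=np.zeros((n_rows, n_cols), dtype=np.int8),
        type_effect=type_effect,
        density_effect=density_effect,
        elevation=elevation,
        fuel_mask=fuel_mask,
        type_label=type_label,
        density_label=density_label,
        cell_side=float(cellsize),
    )


def read_simple_grid(path: str | Path, boundary: str = "periodic") -> LandscapeGrid:
    """Read a simple-model grid from a single emptiness raster."""
    emptiness, _ = read_esri_ascii(path)
    return LandscapeGrid(
        n_rows=emptiness.shape[0],
        n_cols=emptiness.shape[1],
        boundary=boundary,
        model_kind="simple",
        burn_state=np.zeros(emptiness.shape, dtype=np.int8),
        emptiness=np.clip(emptiness, 0.0, 1.0),
    )


def write_grid(grid: LandscapeGrid, prefix: str | Path) -> list[Path]:
    """Write a grid's real-valued layers as ESRI ASCII files.

    Simple model: ``<prefix>_emptiness.asc``.  Full model: one file per layer
    (``type_effect``, ``density_effect``, ``elevation``) plus a 0/1
    ``fuel_mask`` layer.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cellsize = grid.cell_side or 1.0
    written: list[Path] = []
    if grid.model_kind == "simple":
        written.append(
            write_esri_ascii(grid.emptiness, f"{prefix}_emptiness.asc", cellsize)
        )
    else:
        for name in ("type_effect", "density_effect", "elevation"):
            written.append(
                write_esri_ascii(getattr(grid, name), f"{prefix}_{name}.asc", cellsize)
            )
        written.append(
            write_esri_ascii(
                grid.fuel_mask.astype(int), f"{prefix}_fuel_mask.asc", cellsize, fmt="%d"
            )
        )
    return written


# ---------------------------------------------------------------------------
# Grayscale frequency-map export
# ---------------------------------------------------------------------------


def write_frequency_map(gray_levels: np.ndarray, path: str | Path) -> Path:
    """Write a quantized gray-level map as a plain (P2) PGM image.

    The numeric map keeps the exact nominal levels (16, 32, ..., 256); the
    nominal level 256 exceeds the 8-bit range and is clamped to 255 on export
    only.
    """
    gray = np.asarray(gray_levels)
    if gray.ndim != 2:
        raise LandscapeError("frequency map must be 2-D")
    path = Path(path)
    clamped = np.clip(np.rint(gray).astype(int), 0, 255)
    with open(path, "w") as fh:
        fh.write(f"P2\n{gray.shape[1]} {gray.shape[0]}\n255\n")
        np.savetxt(fh, clamped, fmt="%d")
    return path


def read_frequency_map(path: str | Path) -> np.ndarray:
    """Read a plain PGM image back as an integer array."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().split("\n") if ln and not ln.startswith("#")]
    if lines[0].strip() != "P2":
        raise LandscapeError(f"{path} is not a plain PGM (P2) file")
    w, h = map(int, lines[1].split())
    data = np.loadtxt(lines[3:], ndmin=2).astype(int)
    if data.shape != (h, w):
        raise LandscapeError(f"{path}: PGM data does not match header size")
    return data
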