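"""Transmission-line transect grids and 2-D field maps.

A transect survey measures AC electric-field strength (V/m) on a rectilinear
grid of horizontal distances from directly beneath the line (0 m, one-sided)
by heights above ground. The survey instrument saturates at a ceiling
(2000 V/m for the hand-held meter emulated here), so near-line nodes are
stored at the ceiling with an overrange flag: they are lower bounds, not
estimates. Maps are built by bilinear interpolation on the grid; cells
touching an overrange node propagate an "uncertain" mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DEFAULT_HORIZONTAL_M",
    "DEFAULT_HEIGHTS_M",
    "DEFAULT_CEILING_VPM",
    "TransectGrid",
    "DenseFieldMap",
    "load_transects",
    "interpolate_map",
    "experimental_range_mask",
]

DEFAULT_HORIZONTAL_M = np.arange(0.0, 105.0, 5.0)  # 0-100 m in 5 m steps
DEFAULT_HEIGHTS_M = np.array([0.225, 0.5, 1.0, 2.0])
DEFAULT_CEILING_VPM = 2000.0


@dataclass
class TransectGrid:
    """Field-strength samples on a (horizontal distance x height) grid.

    ``efield_vpm`` and ``overrange`` are (n_heights, n_horizontal) arrays;
    flagged nodes carry the ceiling value. Missing nodes are NaN.
    """

    horizontal_m: np.ndarray
    heights_m: np.ndarray
    efield_vpm: np.ndarray
    overrange: np.ndarray
    ceiling_vpm: float = DEFAULT_CEILING_VPM

    def __post_init__(self) -> None:
        self.horizontal_m = np.asarray(self.horizontal_m, dtype=float)
        self.heights_m = np.asarray(self.heights_m, dtype=float)
        self.efield_vpm = np.asarray(self.efield_vpm, dtype=float)
        self.overrange = np.asarray(self.overrange, dtype=bool)
        shape = (self.heights_m.size, self.horizontal_m.size)
        if self.efield_vpm.shape != shape or self.overrange.shape != shape:
            raise ValueError(
                f"grid arrays must have shape {shape} (heights x distances), got "
                f"{self.efield_vpm.shape} and {self.overrange.shape}"
            )
        if self.ceiling_vpm <= 0:
            raise ValueError("ceiling must be positive")
        with np.errstate(invalid="ignore"):
            if np.any(self.efield_vpm < 0):
                raise ValueError("field strengths must be non-negative")
        if np.any(self.overrange & ~np.isclose(self.efield_vpm, self.ceiling_vpm)):
            raise ValueError("overrange nodes must carry the ceiling value")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.efield_vpm).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with the shared transect CSV columns."""
        hh, xx = np.meshgrid(self.heights_m, self.horizontal_m, indexing="ij")
        return pd.DataFrame(
            {
                "horizontal_m": xx.ravel(),
                "height_m": hh.ravel(),
                "efield_vpm": self.efield_vpm.ravel(),
                "overrange": self.overrange.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_transects(
    table: pd.DataFrame,
    ceiling_vpm: float = DEFAULT_CEILING_VPM,
    horizontal_m: np.ndarray | None = None,
    heights_m: np.ndarray | None = None,
) -> TransectGrid:
    """Validate a long-format transect table into a :class:`TransectGrid`.

    Grid axes default to the unique sorted coordinates found in the table.
    Values above the ceiling are clipped to it and flagged overrange (values
    already flagged in the table keep their flag). Duplicate coordinates and
    coordinates off the declared grid are rejected.
    """
    required = {"horizontal_m", "height_m", "efield_vpm"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"transect table is missing columns: {sorted(missing_cols)}")
    if len(table) == 0:
        raise ValueError("transect table is empty")
    xs = np.sort(table["horizontal_m"].unique()) if horizontal_m is None else np.asarray(horizontal_m, float)
    hs = np.sort(table["height_m"].unique()) if heights_m is None else np.asarray(heights_m, float)
    efield = np.full((hs.size, xs.size), np.nan)
    over = np.zeros((hs.size, xs.size), dtype=bool)
    seen = np.zeros_like(over)
    flags = table["overrange"] if "overrange" in table.columns else np.zeros(len(table))
    for idx, (x, h, e, fl) in enumerate(
        zip(table["horizontal_m"], table["height_m"], table["efield_vpm"], flags)
    ):
        ix = np.flatnonzero(np.isclose(xs, x))
        ih = np.flatnonzero(np.isclose(hs, h))
        if ix.size != 1 or ih.size != 1:
            raise ValueError(
                f"row {idx}: coordinates ({x} m, {h} m) are not on the declared grid"
            )
        if seen[ih[0], ix[0]]:
            raise ValueError(f"row {idx}: duplicate node at ({x} m, {h} m)")
        seen[ih[0], ix[0]] = True
        if e < 0:
            raise ValueError(f"row {idx}: negative field strength {e}")
        if e >= ceiling_vpm or fl:
            efield[ih[0], ix[0]] = ceiling_vpm
            over[ih[0], ix[0]] = True
        else:
            efield[ih[0], ix[0]] = e
    return TransectGrid(xs, hs, efield, over, ceiling_vpm)


@dataclass
class DenseFieldMap:
    """Bilinearly interpolated field map with an overrange-uncertainty mask."""

    horizontal_m: np.ndarray
    heights_m: np.ndarray
    efield_vpm: np.ndarray  # (n_heights, n_horizontal)
    uncertain: np.ndarray  # True where an overrange node influences the value
    ceiling_vpm: float
    threshold_masks: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.efield_vpm,
            index=pd.Index(self.heights_m, name="height_m"),
            columns=pd.Index(self.horizontal_m, name="horizontal_m"),
        )


def interpolate_map(grid: TransectGrid, resolution_m: float = 1.0) -> DenseFieldMap:
    """Bilinear interpolation of the transect grid onto a dense map.

    Exact at the grid nodes. Overrange nodes interpolate at the ceiling value
    (a floor-of-truth, not an estimate) and every interpolated point inside a
    cell touching such a node is flagged uncertain. No extrapolation is
    performed outside the grid's hull.
    """
    if grid.n_missing:
        raise ValueError(f"grid has {grid.n_missing} missing nodes; cannot interpolate")
    if grid.horizontal_m.size < 2 or grid.heights_m.size < 2:
        raise ValueError("need at least 2 distinct coordinates along each axis")
    if resolution_m <= 0:
        raise ValueError("resolution must be positive")
    def dense_axis(nodes: np.ndarray, step: float) -> np.ndarray:
        n_steps = int(np.floor((nodes[-1] - nodes[0]) / step + 1e-9))
        axis = nodes[0] + step * np.arange(n_steps + 1)
        # keep nodes exactly representable and stay inside the hull
        return np.union1d(np.clip(axis, nodes[0], nodes[-1]), nodes)

    xs = dense_axis(grid.horizontal_m, resolution_m)
    hs = dense_axis(grid.heights_m, resolution_m / 10)
    interp = RegularGridInterpolator(
        (grid.heights_m, grid.horizontal_m), grid.efield_vpm,
        method="linear", bounds_error=True,
    )
    flag_interp = RegularGridInterpolator(
        (grid.heights_m, grid.horizontal_m), grid.overrange.astype(float),
        method="linear", bounds_error=True,
    )
    hh, xx = np.meshgrid(hs, xs, indexing="ij")
    pts = np.column_stack([hh.ravel(), xx.ravel()])
    values = interp(pts).reshape(hh.shape)
    uncertain = flag_interp(pts).reshape(hh.shape) > 0
    return DenseFieldMap(xs, hs, values, uncertain, grid.ceiling_vpm)


def experimental_range_mask(
    fmap: DenseFieldMap, threshold_vpm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Region where the interpolated field is within the experimental range.

    Returns the boolean mask (field <= threshold) and its area fraction of
    the mapped domain, computed as the fraction of dense map points inside
    the region.
    """
    if threshold_vpm <= 0:
        raise ValueError("threshold must be positive")
    mask = fmap.efield_vpm <= threshold_vpm
    fraction = float(mask.mean())
    fmap.threshold_masks[threshold_vpm] = fraction
    return mask, fraction
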