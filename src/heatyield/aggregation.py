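"""Crop-weighted aggregation of cell-level exposures to administrative units.

Because the yield response is nonlinear in temperature, all nonlinear
transforms (bin exposures, degree days) must be computed at the grid-cell
level *first* and only then averaged to counties; averaging temperatures
before transforming masks the extremes.  This module builds the unit × cell
weight matrix — crop share times the fraction of the cell overlapping the
unit, row-normalized — and applies it to already-transformed exposures.

Two linking rules mirror common practice with gridded weather: fine grids
assign each cell wholly to the unit containing its centroid; coarse grids
weight by the cell/unit overlap fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WeightMatrix", "build_weights_centroid", "build_weights_overlap", "aggregate_exposure"]

logger = logging.getLogger("heatyield")

_EPS = 1e-12


@dataclass
class WeightMatrix:
    """Row-stochastic unit × cell weights; rows with no crop mass are flagged."""

    matrix: np.ndarray          # (n_units, n_cells), rows sum to 1 or 0
    unit_ids: np.ndarray        # unit label per row
    cropless: np.ndarray        # bool per row: no crop mass, excluded downstream

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def active(self) -> "WeightMatrix":
        """Drop cropless units."""
        keep = ~self.cropless
        return WeightMatrix(self.matrix[keep], self.unit_ids[keep], self.cropless[keep])


def _normalize(raw: np.ndarray, unit_ids: np.ndarray) -> WeightMatrix:
    rowsum = raw.sum(axis=1)
    cropless = rowsum <= _EPS
    if np.any(cropless):
        logger.warning("dropping %d unit(s) with no crop weight: %s",
                       cropless.sum(), unit_ids[cropless].tolist())
    W = np.zeros_like(raw)
    W[~cropless] = raw[~cropless] / rowsum[~cropless, None]
    return WeightMatrix(W, np.asarray(unit_ids), cropless)


def build_weights_centroid(unit_of_cell, crop_shares, n_units: int | None = None) -> WeightMatrix:
    """Weights for a centroid link: each cell belongs wholly to one unit.

    Parameters
    ----------
    unit_of_cell : array of int, per cell, the unit whose boundary contains
        the cell centroid (0-based).
    crop_shares : array in [0, 1] per cell.
    """
    unit_of_cell = np.asarray(unit_of_cell, dtype=int)
    crop = np.asarray(crop_shares, dtype=float)
    if crop.shape != unit_of_cell.shape:
        raise ValueError("crop_shares and unit_of_cell must align")
    if np.any((crop < 0) | (crop > 1)):
        raise ValueError("crop shares must lie in [0, 1]")
    if np.any(unit_of_cell < 0):
        raise ValueError("cell centroid outside all units")
    n_units = int(unit_of_cell.max()) + 1 if n_units is None else int(n_units)
    raw = np.zeros((n_units, unit_of_cell.size))
    raw[unit_of_cell, np.arange(unit_of_cell.size)] = crop
    return _normalize(raw, np.arange(n_units))


def build_weights_overlap(overlaps: pd.DataFrame, crop_shares,
                          n_units: int | None = None) -> WeightMatrix:
    """Weights for an area-overlap link: cells may straddle unit boundaries.

    ``overlaps`` has columns ``cell``, ``unit``, ``fraction`` where fractions
    for a given cell sum to at most 1; weight ∝ crop share × fraction.
    """
    crop = np.asarray(crop_shares, dtype=float)
    cell = overlaps["cell"].to_numpy(dtype=int)
    unit = overlaps["unit"].to_numpy(dtype=int)
    frac = overlaps["fraction"].to_numpy(dtype=float)
    if np.any(frac < 0):
        raise ValueError("overlap fractions must be nonnegative")
    sums = pd.Series(frac).groupby(cell).sum()
    if np.any(sums.to_numpy() > 1 + 1e-9):
        raise ValueError("overlap fractions for a cell must sum to <= 1")
    n_units = int(unit.max()) + 1 if n_units is None else int(n_units)
    raw = np.zeros((n_units, crop.size))
    np.add.at(raw, (unit, cell), crop[cell] * frac)
    return _normalize(raw, np.arange(n_units))


def aggregate_exposure(cell_values: np.ndarray, W: WeightMatrix,
                       drop_cropless: bool = True) -> np.ndarray:
    """Weighted mean of cell-level values over each unit.

    ``cell_values`` has the cell axis last-but-zero flexible: any shape
    ``(..., n_cells)`` or ``(..., n_cells, k)``.  Aggregation is linear, so
    it conserves bin mass (each unit's bins still sum to the season length)
    and is the identity on homogeneous inputs.
    """
    M = W.active().matrix if drop_cropless else W.matrix
    v = np.asarray(cell_values, dtype=float)
    if v.shape[-1] == W.n_cells:
        return np.einsum("uc,...c->...u", M, v)
    if v.ndim >= 2 and v.shape[-2] == W.n_cells:
        return np.einsum("uc,...ck->...uk", M, v)
    raise ValueError(
        f"cell axis of size {W.n_cells} not found in values of shape {v.shape}")
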