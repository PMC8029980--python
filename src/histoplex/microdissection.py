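"""In-silico tissue microdissection: tiling, tumor and germinal-center masks.

The tissue is rasterized into square tiles (default 50 px, i.e. 22.5 µm side
at 0.45 µm/px). Tumor areas are tiles holding at least one melanoma cell,
cleaned with a 3x3 binary median filter (zero padding). Germinal-center
areas are tiles where fDC + germinal-center B cells + B cells make up at
least half of the cells; connected objects smaller than 10 tiles or lacking
any of the three defining phenotypes are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import vocab


@dataclass
class TileGrid:
    """Per-tile phenotype counts on a regular raster.

    ``counts`` has shape (n_rows, n_cols, n_phenotypes); tile (r, c) covers
    the half-open pixel square [c*tile_px, (c+1)*tile_px) x
    [r*tile_px, (r+1)*tile_px) in image convention (origin top-left,
    y increasing downward).
    """

    tile_px: int
    counts: np.ndarray
    phenotypes: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    def counts_for(self, phenotypes: Sequence[str]) -> np.ndarray:
        """Summed 2-D count map over the given phenotypes (missing -> 0)."""
        idx = [self.phenotypes.index(p) for p in phenotypes if p in self.phenotypes]
        if not idx:
            return np.zeros(self.shape, dtype=self.counts.dtype)
        return self.counts[:, :, idx].sum(axis=2)

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=2)


@dataclass
class RegionMask:
    """Boolean tile mask with labelled connected components."""

    label: str
    mask: np.ndarray
    tile_px: int
    connectivity: int = 8

    def components(self) -> tuple[np.ndarray, int]:
        structure = (
            np.ones((3, 3), dtype=bool)
            if self.connectivity == 8
            else ndimage.generate_binary_structure(2, 1)
        )
        return ndimage.label(self.mask, structure=structure)

    @property
    def n_tiles(self) -> int:
        return int(self.mask.sum())

    def area_mm2(self, resolution_um_per_px: float = vocab.DEFAULT_RESOLUTION_UM_PER_PX) -> float:
        """Mask area in mm²: n_tiles x (tile_px x µm/px / 1000)²."""
        side_mm = self.tile_px * resolution_um_per_px / 1000.0
        return self.n_tiles * side_mm**2


def tile_grid(
    cells: pd.DataFrame,
    tile_px: int = 50,
    *,
    shape: tuple[int, int] | None = None,
    phenotype_col: str = "phenotype",
) -> TileGrid:
    """Rasterize cells into half-open square tiles; counts are conserved.

    ``shape`` (n_rows, n_cols) may be given to fix the raster extent (e.g.
    from the image dimensions); by default it is inferred from the data.
    """
    if tile_px <= 0:
        raise ValueError("tile_px must be positive")
    x = cells["x_px"].to_numpy(float)
    y = cells["y_px"].to_numpy(float)
    if len(x) and (x.min() < 0 or y.min() < 0):
        raise ValueError("coordinates must be non-negative")
    col = np.floor(x / tile_px).astype(int)
    row = np.floor(y / tile_px).astype(int)
    phenos = sorted(pd.unique(cells[phenotype_col].astype(str)))
    if shape is None:
        shape = (int(row.max()) + 1 if len(row) else 1,
                 int(col.max()) + 1 if len(col) else 1)
    counts = np.zeros((*shape, len(phenos)), dtype=np.int64)
    code = pd.Categorical(cells[phenotype_col].astype(str), categories=phenos).codes
    np.add.at(counts, (row, col, code), 1)
    return TileGrid(tile_px=tile_px, counts=counts, phenotypes=phenos)


def median_filter_mask(mask: np.ndarray, size: int = 3) -> np.ndarray:
    """Binary median filter with zero (background) padding."""
    filtered = ndimage.median_filter(
        mask.astype(np.uint8), size=size, mode="constant", cval=0
    )
    return filtered.astype(bool)


def tumor_mask(
    grid: TileGrid,
    *,
    tumor_phenotypes: Sequence[str] = vocab.MELANOMA,
    min_cells: int = 1,
    filter_size: int = 3,
) -> RegionMask:
    """Tiles with >= 1 tumor cell, then a 3x3 median filter against outliers."""
    present = [p for p in tumor_phenotypes if p in grid.phenotypes]
    if not present:
        raise ValueError(
            f"grid has no tumor phenotype columns among {tuple(tumor_phenotypes)}"
        )
    raw = grid.counts_for(present) >= min_cells
    return RegionMask(label="tumor", mask=median_filter_mask(raw, filter_size),
                      tile_px=grid.tile_px)


def gc_mask(
    grid: TileGrid,
    fraction: float = 0.5,
    min_tiles: int = 10,
    *,
    defining_phenotypes: Sequence[str] = vocab.GC_DEFINING,
    connectivity: int = 8,
    label: str = "GC",
) -> RegionMask:
    """Germinal-center mask.

    A tile qualifies when the defining phenotypes make up at least
    ``fraction`` of its cells (empty tiles never qualify). Connected objects
    (8-connectivity by default) smaller than ``min_tiles`` tiles, or missing
    any one of the defining phenotypes, are removed.
    """
    missing = [p for p in defining_phenotypes if p not in grid.phenotypes]
    if len(missing) == len(list(defining_phenotypes)):
        raise ValueError(f"grid lacks all defining phenotype columns: {missing}")
    gc_counts = grid.counts_for(defining_phenotypes)
    total = grid.total()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, gc_counts / np.maximum(total, 1), 0.0)
    mask = (total > 0) & (frac >= fraction)

    region = RegionMask(label=label, mask=mask, tile_px=grid.tile_px,
                        connectivity=connectivity)
    labelled, n = region.components()
    keep = np.zeros_like(mask)
    for comp in range(1, n + 1):
        comp_mask = labelled == comp
        if comp_mask.sum() < min_tiles:
            continue
        has_all = all(
            p in grid.phenotypes and grid.counts_for([p])[comp_mask].sum() > 0
            for p in defining_phenotypes
        )
        if has_all:
            keep |= comp_mask
    region.mask = keep
    return region


def assign_regions(
    cells: pd.DataFrame,
    masks: Mapping[str, RegionMask],
    *,
    precedence: Sequence[str] | None = None,
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Label each cell with the region of its tile; count is conserved.

    ``precedence`` orders overlapping masks (first wins). If masks overlap
    and no precedence is given, an error is raised.
    """
    if not masks:
        out = cells.copy()
        out["region"] = unassigned_label
        return out
    tile_sizes = {m.tile_px for m in masks.values()}
    if len(tile_sizes) != 1:
        raise ValueError("masks must share a single tile size")
    tile_px = tile_sizes.pop()

    if precedence is None:
        names = list(masks)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ma, mb = masks[a].mask, masks[b].mask
                r = min(ma.shape[0], mb.shape[0])
                c = min(ma.shape[1], mb.shape[1])
                if (ma[:r, :c] & mb[:r, :c]).any():
                    raise ValueError(
                        f"masks {a!r} and {b!r} overlap; supply a precedence order"
                    )
        precedence = names
    unknown = set(precedence) - set(masks)
    if unknown:
        raise ValueError(f"precedence names unknown masks: {sorted(unknown)}")

    col = np.floor(cells["x_px"].to_numpy(float) / tile_px).astype(int)
    row = np.floor(cells["y_px"].to_numpy(float) / tile_px).astype(int)
    region = np.full(len(cells), unassigned_label, dtype=object)
    unset = np.ones(len(cells), dtype=bool)
    for name in precedence:
        m = masks[name].mask
        inside = (row < m.shape[0]) & (col < m.shape[1])
        hit = np.zeros(len(cells), dtype=bool)
        hit[inside] = m[row[inside], col[inside]]
        region[hit & unset] = name
        unset &= ~hit
    out = cells.copy()
    out["region"] = region
    return out
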