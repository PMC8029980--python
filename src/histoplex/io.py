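"""Cell-table I/O, run configuration and the run manifest.

The cell table is delimited text (comma or tab) with a header row; required
columns are ``cell_id, sample_id, x_px, y_px`` plus one column per marker
MFI and optional ``phenotype`` / ``region`` columns. Coordinates are 0-based
pixels, origin top-left, y increasing downward (image convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

REQUIRED_COLUMNS = ("cell_id", "sample_id", "x_px", "y_px")
OPTIONAL_COLUMNS = ("phenotype", "region")


class CellTableError(ValueError):
    """Malformed cell table."""


def read_cell_table(path: str | Path, markers: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a delimited cell table.

    Malformed numeric rows are reported with 1-based file line numbers.
    An empty file with a header is a valid empty table.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"missing required column(s): {', '.join(missing)}")
    if markers is not None:
        absent = [m for m in markers if m not in df.columns]
        if absent:
            raise CellTableError(f"declared marker column(s) absent: {absent}")
    for col in ("x_px", "y_px"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad][:10]]  # +1 header +1 1-based
            raise CellTableError(
                f"non-numeric {col!r} values at file line(s) {lines}"
            )
        df[col] = coerced
    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        raise CellTableError(
            f"duplicate cell_id within sample at file line(s) "
            f"{[int(i) + 2 for i in df.index[dup][:10]]}"
        )
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> Path:
    """Write a cell table; format (comma/tab) follows the file extension."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cells.to_csv(path, sep=sep, index=False)
    return path


@dataclass
class RunConfig:
    """All pipeline stage parameters, with standard-protocol defaults."""

    seed: int = 0
    z_trim: float = 5.0
    subsample: int = 25000
    n_clusters: int | None = None
    tile_px: int = 50
    gc_fraction: float = 0.5
    min_object_tiles: int = 10
    radius_px: float = 50.0
    n_permutations: int = 1000
    strong_p: float = 0.05
    moderate_p: float = 0.1
    resolution_um_per_px: float = 0.45

    def validate(self) -> None:
        if self.z_trim <= 0:
            raise ValueError("z_trim must be positive")
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if not (0 < self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in (0, 1]")
        if self.min_object_tiles < 1:
            raise ValueError("min_object_tiles must be >= 1")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.strong_p < self.moderate_p:
            raise ValueError("strong_p must be below moderate_p")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the effective parameters (changes iff any does)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: RunConfig,
                   artifacts: dict[str, str]) -> Path:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
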