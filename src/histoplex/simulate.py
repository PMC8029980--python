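"""Synthetic tissue and cytokine data with known ground truth.

The tissue generator produces per-cell tables with the spatial regimes the
downstream analyses assume: melanoma cells packed into disc-shaped tumor
nests, immune infiltrates enriched in an annulus at the tumor-stroma
interface, germinal-center-like blobs jointly populated by fDC, germinal
center B cells and B cells, and a uniform background. Marker intensities are
drawn log-normally around per-phenotype fingerprints so that phenotype
recovery, microdissection and neighborhood statistics can all be checked
against simulated truth.

One call simulates one sample (core); multi-sample datasets are built by
repeated calls with distinct seeds, which keeps the cross-sample weighted
integration path exercisable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import vocab

SpatialMode = Literal["uniform", "nest", "border", "gc_blob"]

_MODES = ("uniform", "nest", "border", "gc_blob")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Expected count and spatial placement regime of one phenotype."""

    name: str
    count: int
    mode: SpatialMode = "uniform"


@dataclass
class TissueSimConfig:
    """Parameters of one simulated tissue sample.

    ``fingerprint_means`` holds the expected natural-log marker intensity per
    phenotype (rows) and marker (columns); cells draw their log-intensities
    normally around that row with standard deviation ``noise_sd``.
    """

    seed: int
    phenotype_table: Sequence[PhenotypeSpec]
    fingerprint_means: pd.DataFrame
    width_px: int = 2000
    height_px: int = 2000
    resolution_um_per_px: float = vocab.DEFAULT_RESOLUTION_UM_PER_PX
    noise_sd: float = 0.35
    nest_count: int = 3
    nest_radius_px: float = 300.0
    gc_count: int = 1
    gc_radius_px: float = 150.0
    sample_id: str = "S1"

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("tissue dimensions must be positive")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution_um_per_px must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for spec in self.phenotype_table:
            if spec.count < 0:
                raise ValueError(f"negative expected count for {spec.name!r}")
            if spec.mode not in _MODES:
                raise ValueError(f"unknown spatial mode {spec.mode!r}")
            if spec.name not in self.fingerprint_means.index:
                raise ValueError(
                    f"phenotype {spec.name!r} missing from fingerprint_means"
                )
        needs_nest = any(s.mode in ("nest", "border") for s in self.phenotype_table)
        if needs_nest and self.nest_count < 1:
            raise ValueError("nest_count must be >= 1 when nest/border modes are used")
        needs_gc = any(s.mode == "gc_blob" for s in self.phenotype_table)
        if needs_gc and self.gc_count < 1:
            raise ValueError("gc_count must be >= 1 when gc_blob mode is used")


def _disc_points(rng: np.random.Generator, center: np.ndarray, radius: float,
                 n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    return center + np.c_[r * np.cos(theta), r * np.sin(theta)]


def _annulus_points(rng: np.random.Generator, center: np.ndarray, r_in: float,
                    r_out: float, n: int) -> np.ndarray:
    # area-uniform radii within [r_in, r_out]
    u = rng.random(n)
    r = np.sqrt(r_in ** 2 + u * (r_out ** 2 - r_in ** 2))
    theta = rng.random(n) * 2.0 * math.pi
    return center + np.c_[r * np.cos(theta), r * np.sin(theta)]


def _scatter_centers(rng: np.random.Generator, n: int, width: float, height: float,
                     margin: float, avoid: np.ndarray | None = None,
                     min_dist: float = 0.0, self_dist: float = 0.0,
                     tries: int = 200) -> np.ndarray:
    """Uniform centers with a margin, rejection-sampled away from ``avoid``
    and (by ``self_dist``) from each other."""
    lo = np.array([min(margin, width / 2), min(margin, height / 2)])
    hi = np.array([max(width - margin, width / 2), max(height - margin, height / 2)])
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(tries):
            c = lo + rng.random(2) * (hi - lo)
            ok = True
            if avoid is not None and len(avoid):
                ok = np.min(np.hypot(*(avoid - c).T)) >= min_dist
            if ok and centers and self_dist > 0:
                ok = np.min(np.hypot(*(np.asarray(centers) - c).T)) >= self_dist
            if ok:
                break
        centers.append(c)
    return np.asarray(centers).reshape(n, 2)


def simulate_tissue(config: TissueSimConfig) -> pd.DataFrame:
    """Simulate one tissue sample; returns one row per cell.

    Columns: ``cell_id, sample_id, x_px, y_px, phenotype`` followed by one
    raw-intensity column per marker of ``config.fingerprint_means``. The
    ``phenotype`` column carries the simulated ground truth. Identical seed
    and config yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width, height = float(config.width_px), float(config.height_px)
    markers = list(config.fingerprint_means.columns)

    nest_centers = _scatter_centers(
        rng, config.nest_count, width, height, margin=config.nest_radius_px
    )
    # germinal centers stay clear of nests and of one another (distinct blobs)
    gc_centers = _scatter_centers(
        rng, config.gc_count, width, height, margin=config.gc_radius_px,
        avoid=nest_centers,
        min_dist=1.5 * config.nest_radius_px + config.gc_radius_px,
        self_dist=3.0 * config.gc_radius_px,
    )

    xs: list[np.ndarray] = []
    phenos: list[str] = []
    for spec in config.phenotype_table:
        n = spec.count
        if n == 0:
            continue
        if spec.mode == "uniform":
            pts = rng.random((n, 2)) * [width, height]
        elif spec.mode == "nest":
            which = rng.integers(0, config.nest_count, n)
            pts = np.empty((n, 2))
            for k in range(config.nest_count):
                sel = which == k
                pts[sel] = _disc_points(
                    rng, nest_centers[k], config.nest_radius_px, int(sel.sum())
                )
        elif spec.mode == "border":
            # tumor-stroma interface: annulus of width nest_radius/2 around nests
            which = rng.integers(0, config.nest_count, n)
            pts = np.empty((n, 2))
            for k in range(config.nest_count):
                sel = which == k
                pts[sel] = _annulus_points(
                    rng, nest_centers[k], config.nest_radius_px,
                    1.5 * config.nest_radius_px, int(sel.sum()),
                )
        else:  # gc_blob — round-robin over blobs so each blob sees every GC type
            which = np.arange(n) % config.gc_count
            pts = np.empty((n, 2))
            for k in range(config.gc_count):
                sel = which == k
                pts[sel] = _disc_points(
                    rng, gc_centers[k], config.gc_radius_px, int(sel.sum())
                )
        xs.append(pts)
        phenos.extend([spec.name] * n)

    if not xs:
        cols = ["cell_id", "sample_id", "x_px", "y_px", "phenotype", *markers]
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    xy = np.vstack(xs)
    xy[:, 0] = np.clip(xy[:, 0], 0.0, np.nextafter(width, 0.0))
    xy[:, 1] = np.clip(xy[:, 1], 0.0, np.nextafter(height, 0.0))
    phenotype = np.asarray(phenos, dtype=object)
    n_cells = len(phenotype)

    log_mu = config.fingerprint_means.loc[phenotype, markers].to_numpy(float)
    mfi = np.exp(log_mu + rng.normal(0.0, config.noise_sd, size=log_mu.shape))

    out = pd.DataFrame(
        {
            "cell_id": [f"{config.sample_id}_{i:06d}" for i in range(n_cells)],
            "sample_id": config.sample_id,
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
            "phenotype": phenotype,
        }
    )
    out[markers] = mfi
    return out


def synthetic_fingerprints(
    phenotypes: Iterable[str],
    markers: Sequence[str] | None = None,
    *,
    separation: float = 3.0,
    baseline: float = 0.5,
    markers_per_phenotype: int = 3,
) -> pd.DataFrame:
    """Well-separated log-intensity fingerprints for simulation.

    Each phenotype is assigned a distinct block of ``markers_per_phenotype``
    markers (cycling through the panel) elevated by ``separation`` log units
    over the ``baseline``; deterministic.
    """
    phenotypes = list(phenotypes)
    if markers is None:
        markers = list(vocab.PHENOTYPIC_MARKERS)
    markers = list(markers)
    m = len(markers)
    if m < markers_per_phenotype:
        raise ValueError("marker panel smaller than markers_per_phenotype")
    fp = np.full((len(phenotypes), m), baseline)
    for i in range(len(phenotypes)):
        for j in range(markers_per_phenotype):
            fp[i, (markers_per_phenotype * i + j) % m] += separation
    return pd.DataFrame(fp, index=phenotypes, columns=markers)


def demo_tissue_config(seed: int, *, scale: float = 1.0,
                       separation: float = 3.0, noise_sd: float = 0.35,
                       sample_id: str = "S1") -> TissueSimConfig:
    """A realistic default sample: HLA-DR± melanoma nests, border-enriched
    immune infiltrate, one germinal-center blob, uniform background."""
    def n(x: int) -> int:
        return max(0, int(round(x * scale)))

    table = [
        PhenotypeSpec("HLADRneg_mel", n(3000), "nest"),
        PhenotypeSpec("HLADRpos_mel", n(400), "border"),
        PhenotypeSpec("Tcy", n(300), "border"),
        PhenotypeSpec("Th", n(250), "border"),
        PhenotypeSpec("Macroph", n(200), "border"),
        PhenotypeSpec("Macroph_CD163", n(150), "uniform"),
        PhenotypeSpec("BC", n(250), "gc_blob"),
        PhenotypeSpec("BC_GerminalCenter", n(120), "gc_blob"),
        PhenotypeSpec("fDC", n(60), "gc_blob"),
        PhenotypeSpec("NK", n(80), "uniform"),
        PhenotypeSpec("Stroma", n(150), "uniform"),
    ]
    phenos = [s.name for s in table]
    fp = synthetic_fingerprints(phenos, separation=separation)
    return TissueSimConfig(
        seed=seed,
        phenotype_table=table,
        fingerprint_means=fp,
        noise_sd=noise_sd,
        sample_id=sample_id,
    )


@dataclass
class CytokineSimConfig:
    """Two-group cytokine matrix with a known informative marker subset.

    ``effect_size`` is the standardized mean difference (in units of
    ``noise_sd``) between groups on the informative markers; uninformative
    markers are identically distributed in both groups.
    """

    seed: int
    n_per_group: int
    informative_set: Sequence[str]
    effect_size: float
    markers: Sequence[str] = field(default_factory=lambda: list(vocab.CYTOKINES))
    noise_sd: float = 1.0
    group_names: tuple[str, str] = ("HLA-DR-", "HLA-DR+")

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.informative_set) - set(self.markers)
        if unknown:
            raise ValueError(f"informative markers not in panel: {sorted(unknown)}")


def simulate_cytokines(config: CytokineSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a samples x markers MFI matrix and binary group labels.

    The second group's mean is shifted by ``effect_size * noise_sd`` on every
    informative marker. Seeded and reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = list(config.markers)
    n = 2 * config.n_per_group
    X = rng.normal(0.0, config.noise_sd, size=(n, len(markers)))
    informative = [markers.index(m) for m in config.informative_set]
    X[config.n_per_group:, informative] += config.effect_size * config.noise_sd
    index = [f"sample_{i + 1:02d}" for i in range(n)]
    labels = pd.Series(
        [config.group_names[0]] * config.n_per_group
        + [config.group_names[1]] * config.n_per_group,
        index=index,
        name="group",
    )
    return pd.DataFrame(X, index=index, columns=markers), labels
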