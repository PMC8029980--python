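"""End-to-end pipeline: phenotyping -> microdissection -> composition ->
neighborhood, with an independent cytokine-panel branch.

Each stage writes its artifact to the output directory; a manifest records
the effective configuration, its hash and the seed so a rerun with identical
inputs is bit-identical. A stage failure halts the run with the failing
stage named; artifacts of completed stages are retained.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io, microdissection, neighborhood, phenotyping
from .composition import composition_stats
from .panel import CytokinePanelLDA

log = logging.getLogger("histoplex")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # halt with the failing stage named
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


def run_pipeline(
    config: io.RunConfig,
    cells: pd.DataFrame,
    out_dir: str | Path,
    *,
    reference_fingerprints: pd.DataFrame | None = None,
    marker_columns: list[str] | None = None,
    cytokines: pd.DataFrame | None = None,
    cytokine_groups: pd.Series | None = None,
) -> dict[str, Path]:
    """Run all stages on one cell table; returns the artifact paths.

    ``reference_fingerprints`` (phenotype x marker, z-space) drive the
    cluster-annotation step; when omitted the table must already carry a
    ``phenotype`` column and the phenotyping stage only re-derives z-scores.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if marker_columns is None:
        skip = set(io.REQUIRED_COLUMNS) | set(io.OPTIONAL_COLUMNS)
        marker_columns = [c for c in cells.columns if c not in skip]

    @_stage("phenotyping")
    def _phenotype() -> pd.DataFrame:
        z = phenotyping.zscore_normalize(
            cells[marker_columns], trim=config.z_trim,
            by=cells["sample_id"],
        )
        out = cells.copy()
        if reference_fingerprints is not None:
            labels, _fp = phenotyping.consensus_phenotype(
                z,
                reference_fingerprints,
                n_clusters=config.n_clusters,
                subsample=config.subsample,
                seed=config.seed,
            )
            out["phenotype"] = labels
        elif "phenotype" not in out.columns:
            raise ValueError(
                "no reference fingerprints and no phenotype column supplied"
            )
        p = out_dir / "cells_phenotyped.csv"
        io.write_cell_table(out, p)
        artifacts["phenotyping"] = p
        return out

    labelled = _phenotype()

    @_stage("microdissection")
    def _dissect() -> tuple[pd.DataFrame, dict]:
        parts, areas = [], {}
        for sample, sub in labelled.groupby("sample_id", sort=True):
            grid = microdissection.tile_grid(sub, tile_px=config.tile_px)
            masks = {}
            try:
                masks["tumor"] = microdissection.tumor_mask(grid)
            except ValueError:
                pass
            try:
                masks["GC"] = microdissection.gc_mask(
                    grid,
                    fraction=config.gc_fraction,
                    min_tiles=config.min_object_tiles,
                )
            except ValueError:
                pass
            labelled_sub = microdissection.assign_regions(
                sub, masks, precedence=["GC", "tumor"] if masks else None
            )
            parts.append(labelled_sub)
            for name, m in masks.items():
                areas[(str(sample), name)] = m.area_mm2(config.resolution_um_per_px)
        out = pd.concat(parts).sort_index()
        p = out_dir / "cells_regions.csv"
        io.write_cell_table(out, p)
        artifacts["microdissection"] = p
        return out, areas

    regions, areas = _dissect()

    @_stage("composition")
    def _compose() -> pd.DataFrame:
        comp = composition_stats(
            regions[regions["region"] != "unassigned"],
            region_areas_mm2=areas or None,
        )
        p = out_dir / "composition.csv"
        comp.to_csv(p, index=False)
        artifacts["composition"] = p
        return comp

    _compose()

    @_stage("neighborhood")
    def _neighbors() -> pd.DataFrame:
        cfg = neighborhood.NeighborhoodConfig(
            radius_px=config.radius_px,
            n_permutations=config.n_permutations,
            strong_p=config.strong_p,
            moderate_p=config.moderate_p,
            seed=config.seed,
        )
        tidy = []
        per_region: dict[str, list] = {}
        for (sample, region), sub in regions.groupby(["sample_id", "region"]):
            if region == "unassigned":
                continue
            try:
                res = neighborhood.NeighborhoodAnalysis(
                    sub, cfg, sample_id=str(sample)
                ).fit()
            except ValueError:
                continue
            frame = res.to_frame()
            frame.insert(1, "region", region)
            tidy.append(frame)
            per_region.setdefault(str(region), []).append(res)
        out = pd.concat(tidy, ignore_index=True) if tidy else pd.DataFrame()
        p = out_dir / "interactions.csv"
        out.to_csv(p, index=False)
        artifacts["neighborhood"] = p
        for region, results in per_region.items():
            integ = neighborhood.integrate_samples(results)
            ip = out_dir / f"interactions_integrated_{region}.csv"
            integ.to_csv(ip)
            artifacts[f"neighborhood_integrated_{region}"] = ip
        return out

    _neighbors()

    if cytokines is not None:
        @_stage("cytokine_panel")
        def _panel() -> None:
            model = CytokinePanelLDA(cytokines, cytokine_groups)
            res = model.fit()
            p = out_dir / "panel_pareto.csv"
            pareto = res.pareto.copy()
            pareto["markers"] = pareto["markers"].map(lambda t: "|".join(t))
            pareto.to_csv(p, index=False)
            artifacts["cytokine_panel"] = p
            (out_dir / "panel_summary.txt").write_text(res.summary() + "\n")
            artifacts["cytokine_panel_summary"] = out_dir / "panel_summary.txt"

        _panel()

    manifest = io.write_manifest(
        out_dir / "manifest.json",
        config,
        {k: str(v.name) for k, v in artifacts.items()},
    )
    artifacts["manifest"] = manifest
    return artifacts
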