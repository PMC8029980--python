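"""Cell composition statistics and between-group comparisons.

Per (sample, region) the module reports, for each phenotype, the cell count,
the percentage of all cells, the percentage within its lineage (subtype
grouping: B, T, NK, dendritic, macrophage, melanoma, vasculature, ...), and
the density in cells/mm² when a region area is available. Regions are
compared between groups phenotype-by-phenotype with the two-sided Wilcoxon
rank-sum test — exact null for small groups, normal approximation with
continuity correction otherwise — unadjusted by default.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab


def composition_from_counts(
    counts: pd.Series,
    *,
    lineage: Mapping[str, str] | None = None,
    area_mm2: float | None = None,
) -> pd.DataFrame:
    """Composition table from per-phenotype counts.

    Returns one row per phenotype with ``count``, ``pct_overall``,
    ``pct_subtype`` (within the phenotype's lineage) and, when ``area_mm2``
    is given, ``density`` in cells/mm².
    """
    if lineage is None:
        lineage = vocab.LINEAGE
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    lin = pd.Series(
        {p: lineage.get(p, p) for p in counts.index}, name="lineage"
    )
    out = pd.DataFrame({"count": counts, "lineage": lin})
    out["pct_overall"] = 100.0 * out["count"] / total if total else 0.0
    subtype_totals = out.groupby("lineage")["count"].transform("sum")
    with np.errstate(invalid="ignore"):
        out["pct_subtype"] = 100.0 * out["count"] / subtype_totals
    if area_mm2 is not None:
        if area_mm2 <= 0:
            raise ValueError("area_mm2 must be positive")
        out["density"] = out["count"] / area_mm2
    out.index.name = "phenotype"
    return out


def composition_stats(
    cells: pd.DataFrame,
    region_areas_mm2: Mapping[tuple[str, str] | str, float] | None = None,
    *,
    groupby: Sequence[str] = ("sample_id", "region"),
    lineage: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tidy composition table, one row per group x phenotype.

    ``region_areas_mm2`` maps a group key — ``(sample_id, region)`` tuple or
    plain region name — to its area; densities are reported where an area is
    known and an error is raised when cells fall in a region that has no
    area while areas were supplied for others of the same sample.
    """
    groupby = list(groupby)
    if "region" in groupby and "region" not in cells.columns:
        raise ValueError("cells need a 'region' column; run assign_regions first")
    parts = []
    for key, sub in cells.groupby(groupby, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        area = None
        if region_areas_mm2 is not None:
            area = region_areas_mm2.get(tuple(key))
            if area is None and len(key) > 1:
                area = region_areas_mm2.get(key[-1])
            if area is None:
                raise ValueError(f"no area supplied for group {key}")
        counts = sub["phenotype"].value_counts().sort_index()
        tab = composition_from_counts(counts, lineage=lineage, area_mm2=area)
        tab = tab.reset_index()
        for name, val in zip(groupby, key):
            tab.insert(0, name, val)
        parts.append(tab)
    if not parts:
        return pd.DataFrame(
            columns=[*groupby, "phenotype", "count", "lineage", "pct_overall",
                     "pct_subtype"]
        )
    return pd.concat(parts, ignore_index=True)


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], *, exact_max_n: int = 10
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def compare_regions(
    composition: pd.DataFrame,
    groups: Mapping[str, str],
    *,
    metrics: Sequence[str] = ("pct_overall", "density"),
    exclude: Sequence[str] = vocab.EXCLUDED_DEFAULT,
    sample_col: str = "sample_id",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-phenotype two-group comparison of composition metrics.

    ``composition`` is a tidy table from :func:`composition_stats`;
    ``groups`` maps sample ids to one of two group labels. Excluded
    phenotypes (``other``, ``Stroma``, ``Epith`` by default) are dropped.
    P-values are unadjusted unless ``adjust="fdr_bh"``.
    """
    comp = composition[~composition["phenotype"].isin(set(exclude))]
    grp = comp[sample_col].map(dict(groups))
    if grp.isna().any():
        missing = sorted(comp.loc[grp.isna(), sample_col].unique())
        raise ValueError(f"samples with no group assignment: {missing}")
    levels = sorted(pd.unique(grp))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    n_per = grp.groupby(grp).apply(lambda s: comp.loc[s.index, sample_col].nunique())
    if (n_per < 2).any():
        raise ValueError("each group needs at least 2 samples")

    rows = []
    metrics = [m for m in metrics if m in comp.columns]
    for pheno, sub in comp.groupby("phenotype", sort=True):
        for metric in metrics:
            vals = sub.groupby(sample_col)[metric].sum()
            g = vals.index.map(dict(groups))
            a = vals[g == levels[0]].to_numpy()
            b = vals[g == levels[1]].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            rows.append(
                {
                    "phenotype": pheno,
                    "metric": metric,
                    "p_value": wilcoxon_ranksum(a, b),
                }
            )
    out = pd.DataFrame(rows)
    if adjust == "fdr_bh" and len(out):
        out["p_adjusted"] = stats.false_discovery_control(out["p_value"], method="bh")
    elif adjust is not None and adjust != "fdr_bh":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
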