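"""Marker normalization, consensus annotation, fingerprint propagation, gating.

The phenotyping stage mirrors a standard high-plex cyclic-IHC workflow:

1. per-marker z-score normalization with trimming to suppress outliers;
2. three independent clustering runs on a subsample, each annotated to
   phenotype names (the expert annotation step is an input here);
3. a 2-of-3 consensus vote per cell, disagreements labelled ``other``;
4. per-phenotype fingerprints (mean z-vector) propagate labels to the full
   dataset by minimum Euclidean distance;
5. marker gating on asinh-transformed intensities refines subtypes
   (PD-1-high helpers -> TFH, BCL6/BCL2 splits of B cells, HLA-DR split of
   melanoma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans


def zscore_normalize(
    mfi: pd.DataFrame,
    trim: float = 5.0,
    by: pd.Series | None = None,
) -> pd.DataFrame:
    """Standardize each marker column to mean 0 / unit spread, clip to ±trim.

    Uses the population standard deviation (ddof=0). Zero-spread columns map
    to all zeros. When ``by`` is given (e.g. the sample/core id), statistics
    are computed within each group — normalization then doubles as a
    batch-correction step across cores.
    """
    if mfi.empty:
        raise ValueError("empty intensity matrix")
    if trim <= 0:
        raise ValueError("trim must be positive")
    if by is not None:
        parts = []
        for _, idx in mfi.groupby(np.asarray(by)).groups.items():
            parts.append(zscore_normalize(mfi.loc[idx], trim=trim))
        return pd.concat(parts).loc[mfi.index]
    x = mfi.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[:, sd == 0] = 0.0
    np.clip(z, -trim, trim, out=z)
    return pd.DataFrame(z, index=mfi.index, columns=mfi.columns)


def consensus_annotate(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    labels_c: Sequence[str],
    *,
    disagreement_label: str = "other",
) -> np.ndarray:
    """2-of-3 majority vote over three annotated label vectors.

    A cell keeps the label on which at least two runs agree; if all three
    disagree it becomes ``other``. Invariant to the order of the inputs.
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    c = np.asarray(labels_c, dtype=object)
    if not (len(a) == len(b) == len(c)):
        raise ValueError("label vectors must have equal length")
    out = np.full(len(a), disagreement_label, dtype=object)
    ab = a == b
    ac = a == c
    bc = b == c
    out[ab | ac] = a[ab | ac]
    out[~(ab | ac) & bc] = b[~(ab | ac) & bc]
    return out


def fingerprints_from_labels(z: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """Per-phenotype fingerprint: mean z-score vector over labelled cells."""
    lab = pd.Series(np.asarray(labels, dtype=object), index=z.index, name="phenotype")
    fp = z.groupby(lab).mean()
    fp.index.name = "phenotype"
    return fp.sort_index()


def assign_by_fingerprint(
    z: pd.DataFrame | pd.Series | np.ndarray,
    fingerprints: pd.DataFrame,
) -> np.ndarray | str:
    """Nearest-fingerprint phenotype by Euclidean distance in z-space.

    Ties break to the lexicographically smallest phenotype name. Accepts a
    single z-vector (returns one label) or a cells x markers frame.
    """
    if len(fingerprints) == 0:
        raise ValueError("need at least one fingerprint")
    fp = fingerprints.sort_index()
    single = isinstance(z, pd.Series) or (
        isinstance(z, np.ndarray) and z.ndim == 1
    )
    if isinstance(z, pd.DataFrame) or isinstance(z, pd.Series):
        missing = set(fp.columns) - set(z.index if single else z.columns)
        if missing:
            raise ValueError(f"z-vector missing fingerprint markers: {sorted(missing)}")
        zv = (z[fp.columns] if not single else z[list(fp.columns)]).to_numpy(float)
    else:
        zv = np.asarray(z, dtype=float)
        if zv.shape[-1] != fp.shape[1]:
            raise ValueError("marker mismatch between vector and fingerprints")
    zv = np.atleast_2d(zv)
    d = cdist(zv, fp.to_numpy(float))
    labels = fp.index.to_numpy(object)[d.argmin(axis=1)]
    return labels[0] if single else labels


@dataclass
class GatingRule:
    """One manual gate refining a parent phenotype into child labels.

    Positivity of each marker is decided on asinh(mfi / cofactor) against a
    per-marker threshold resolved on the parent population:

    - a float: used as-is;
    - ``"q<p>"`` (e.g. ``"q90"``): that percentile of the parent population,
      for "high" gates;
    - ``"split"``: midpoint of an exact 2-class 1-D partition (minimum
      within-class sum of squares), for +/- gates.

    ``children`` maps the tuple of per-marker positivity outcomes to the
    child label; every outcome must map to exactly one child.
    """

    parent: str
    markers: tuple[str, ...]
    children: Mapping[tuple[bool, ...], str]
    thresholds: Mapping[str, float | str] = field(default_factory=dict)
    cofactor: float = 1.0

    def validate(self) -> None:
        want = 2 ** len(self.markers)
        if len(self.children) != want:
            raise ValueError(
                f"gate on {len(self.markers)} markers needs {want} outcomes, "
                f"got {len(self.children)}"
            )


def two_class_split(values: np.ndarray) -> float:
    """Midpoint of the optimal 2-class split of 1-D data (exact k=2 k-means)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return float(v[-1]) if n else 0.0
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    best_cost, best_i = np.inf, 1
    for i in range(1, n):  # left = v[:i], right = v[i:]
        sl, sr = csum[i - 1], csum[-1] - csum[i - 1]
        ql, qr = csq[i - 1], csq[-1] - csq[i - 1]
        cost = (ql - sl**2 / i) + (qr - sr**2 / (n - i))
        if cost < best_cost - 1e-12:
            best_cost, best_i = cost, i
    return float((v[best_i - 1] + v[best_i]) / 2.0)


def _resolve_threshold(spec: float | str, parent_vals: np.ndarray) -> float:
    if isinstance(spec, str):
        if spec == "split":
            return two_class_split(parent_vals)
        if spec.startswith("q"):
            return float(np.percentile(parent_vals, float(spec[1:])))
        raise ValueError(f"unknown threshold spec {spec!r}")
    return float(spec)


def gate_subtypes(
    cells: pd.DataFrame,
    rules: Sequence[GatingRule],
    *,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Apply gating rules; cells whose parent matches no rule are unchanged.

    Total cell count is conserved. Raises if a rule references a marker
    column absent from the table or a parent phenotype not present.
    """
    out = cells.copy()
    for rule in rules:
        rule.validate()
        for m in rule.markers:
            if m not in out.columns:
                raise KeyError(f"gating rule references unknown marker {m!r}")
        sel = out[phenotype_col].to_numpy(object) == rule.parent
        if not sel.any():
            raise ValueError(
                f"gating rule parent {rule.parent!r} not present in the table"
            )
        pos = []
        for m in rule.markers:
            vals = np.arcsinh(out.loc[sel, m].to_numpy(float) / rule.cofactor)
            thr = _resolve_threshold(rule.thresholds.get(m, "split"), vals)
            pos.append(vals > thr)
        outcome = list(zip(*pos))
        out.loc[sel, phenotype_col] = [rule.children[o] for o in outcome]
    return out


def default_gating_rules() -> list[GatingRule]:
    """The three standard refinement gates.

    - T helpers with high PD-1 (90th percentile gate) become TFH;
    - B cells split on BCL6/BCL2: BCL6+/BCL2- germinal center, BCL6+/BCL2+
      early germinal center, BCL6- stay BC;
    - melanoma splits on HLA-DR into HLADRpos_mel / HLADRneg_mel.
    """
    return [
        GatingRule(
            parent="Th",
            markers=("PD1",),
            children={(True,): "TFH", (False,): "Th"},
            thresholds={"PD1": "q90"},
        ),
        GatingRule(
            parent="BC",
            markers=("BCL6", "BCL2"),
            children={
                (True, False): "BC_GerminalCenter",
                (True, True): "BC_EarlyGerminalCenter",
                (False, False): "BC",
                (False, True): "BC",
            },
        ),
        GatingRule(
            parent="Melanoma",
            markers=("HLA-DR",),
            children={(True,): "HLADRpos_mel", (False,): "HLADRneg_mel"},
        ),
    ]


def subsample_cells(
    z: pd.DataFrame, n: int = 25000, seed: int = 0
) -> pd.DataFrame:
    """Uniform subsample without replacement (all cells if fewer than n)."""
    if len(z) <= n:
        return z
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(z), size=n, replace=False)
    return z.iloc[np.sort(idx)]


def cluster_runs(
    z: pd.DataFrame,
    n_clusters: int,
    seed: int = 0,
    n_runs: int = 3,
) -> list[np.ndarray]:
    """Default pluggable clustering: k-means run ``n_runs`` times with
    distinct seeds. Returns raw cluster-id vectors (one per run); any other
    per-cell label vectors may be substituted."""
    x = z.to_numpy(float)
    out = []
    for r in range(n_runs):
        km = KMeans(n_clusters=n_clusters, n_init=5, random_state=seed + r)
        out.append(km.fit_predict(x))
    return out


def annotate_clusters(
    z: pd.DataFrame,
    cluster_ids: np.ndarray,
    reference_fingerprints: pd.DataFrame,
) -> np.ndarray:
    """Map raw cluster ids to phenotype names via nearest reference fingerprint.

    Stands in for the expert cluster-annotation step: each cluster's centroid
    (mean z) is labelled with the closest reference phenotype.
    """
    centroids = z.groupby(np.asarray(cluster_ids)).mean()
    names = assign_by_fingerprint(centroids, reference_fingerprints)
    mapping = dict(zip(centroids.index, names))
    return np.asarray([mapping[c] for c in cluster_ids], dtype=object)


def consensus_phenotype(
    z: pd.DataFrame,
    reference_fingerprints: pd.DataFrame,
    *,
    n_clusters: int | None = None,
    subsample: int = 25000,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full phenotyping path: subsample, three clustering runs, consensus,
    fingerprints from the consensus, propagation to all cells.

    By default the runs overcluster at twice the number of reference
    phenotypes — k-means at k equal to the phenotype count tends to merge
    rare populations, and annotation folds split clusters back together.
    Returns ``(labels for all cells, consensus fingerprints)``.
    """
    if n_clusters is None:
        n_clusters = 2 * len(reference_fingerprints)
    sub = subsample_cells(z, subsample, seed)
    runs = cluster_runs(sub, n_clusters=n_clusters, seed=seed)
    annotated = [annotate_clusters(sub, r, reference_fingerprints) for r in runs]
    consensus = consensus_annotate(*annotated)
    keep = consensus != "other"
    fingerprints = fingerprints_from_labels(sub.loc[keep], consensus[keep])
    labels = assign_by_fingerprint(z, fingerprints)
    return labels, fingerprints
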