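"""Exhaustive cytokine-panel selection with LOOCV linear discriminant analysis.

Given a samples x markers MFI matrix with a binary group label, every marker
subset of every size k = 1..M is scored by leave-one-out cross-validated
two-class LDA: marker z-score normalization is fitted on each training fold
only (no leakage into the held-out sample), priors are equal, and a small
ridge term stabilizes the pooled covariance. Per size, the best panel
maximizes LOOCV accuracy; ties are broken by minimal residual probability
(the summed complement of the posterior assigned to the true class over
held-out folds), then lexicographically. The optimal panel size is the elbow
of the per-size best-accuracy front: the size with maximum perpendicular
distance to the chord joining the first and last front points, ties going to
the smallest size.

The LDA discriminant is evaluated in closed form (pooled-covariance solve,
equal priors) so the 2^M - 1 subset sweep stays fast; a test suite verifies
fold-by-fold agreement with scikit-learn's LinearDiscriminantAnalysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit


# ---------------------------------------------------------------------------
# closed-form LOOCV machinery


@dataclass
class _FoldCache:
    """Per-dataset precomputation shared by all panels.

    For each left-out sample i the full-panel training statistics are cached:
    normalized data, class means, their sum/difference and the pooled
    (equal-prior, biased) covariance. A panel evaluation then reduces to a
    batched k x k solve across folds.
    """

    z_test: np.ndarray      # (n, M) held-out sample, fold-normalized
    mean_diff: np.ndarray   # (n, M) mu1 - mu0 on the training fold
    mean_sum: np.ndarray    # (n, M) mu1 + mu0
    sigma: np.ndarray       # (n, M, M) pooled covariance of the training fold
    y: np.ndarray           # (n,) class codes 0/1
    ridge: float


def _normalize_loo(X: np.ndarray) -> np.ndarray:
    """Z per fold: column stats from the n-1 training rows (population SD)."""
    n, m = X.shape
    s = X.sum(axis=0)
    q = (X**2).sum(axis=0)
    Z = np.empty((n, n, m))
    for i in range(n):
        mu = (s - X[i]) / (n - 1)
        var = (q - X[i] ** 2) / (n - 1) - mu**2
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            zi = (X - mu) / sd
        zi[:, sd == 0] = 0.0
        Z[i] = zi
    return Z


def _prepare(X: np.ndarray, y: np.ndarray, *, normalize: str = "fold",
             ridge: float = 1e-6) -> _FoldCache:
    n, m = X.shape
    if normalize == "fold":
        Z = _normalize_loo(X)
    elif normalize == "global":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            zg = (X - mu) / sd
        zg[:, sd == 0] = 0.0
        Z = np.broadcast_to(zg, (n, n, m)).copy()
    elif normalize == "none":
        Z = np.broadcast_to(X, (n, n, m)).copy()
    else:
        raise ValueError(f"unknown normalization {normalize!r}")

    z_test = np.empty((n, m))
    mean_diff = np.empty((n, m))
    mean_sum = np.empty((n, m))
    sigma = np.empty((n, m, m))
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        zt = Z[i][train]
        yt = y[train]
        if (yt == 0).sum() == 0 or (yt == 1).sum() == 0:
            raise ValueError("a training fold has an empty class")
        mu0 = zt[yt == 0].mean(axis=0)
        mu1 = zt[yt == 1].mean(axis=0)
        c0 = np.cov(zt[yt == 0].T, bias=True).reshape(m, m)
        c1 = np.cov(zt[yt == 1].T, bias=True).reshape(m, m)
        sigma[i] = 0.5 * c0 + 0.5 * c1  # equal priors
        mean_diff[i] = mu1 - mu0
        mean_sum[i] = mu1 + mu0
        z_test[i] = Z[i][i]
    return _FoldCache(z_test, mean_diff, mean_sum, sigma, y, ridge)


def _panel_scores(cache: _FoldCache, ix: np.ndarray) -> np.ndarray:
    """Held-out log-odds (class 1 vs 0) per fold for one marker subset."""
    k = len(ix)
    S = cache.sigma[:, ix][:, :, ix] + cache.ridge * np.eye(k)
    d = cache.mean_diff[:, ix]
    w = np.linalg.solve(S, d[..., None])[..., 0]
    b = -0.5 * np.einsum("nk,nk->n", cache.mean_sum[:, ix], w)
    return np.einsum("nk,nk->n", cache.z_test[:, ix], w) + b


def _panel_metrics(cache: _FoldCache, ix: np.ndarray) -> tuple[float, float]:
    scores = _panel_scores(cache, ix)
    pred = (scores > 0).astype(int)
    accuracy = float((pred == cache.y).mean())
    p_true = expit(np.where(cache.y == 1, scores, -scores))
    residual = float(np.sum(1.0 - p_true))
    return accuracy, residual


def _lda_weights(X: np.ndarray, y: np.ndarray, *, ridge: float = 1e-6
                 ) -> tuple[np.ndarray, float]:
    """Equal-prior LDA direction and intercept on z-scored data (all samples)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (X - mu) / sd
    z[:, sd == 0] = 0.0
    m = X.shape[1]
    mu0 = z[y == 0].mean(axis=0)
    mu1 = z[y == 1].mean(axis=0)
    c0 = np.cov(z[y == 0].T, bias=True).reshape(m, m)
    c1 = np.cov(z[y == 1].T, bias=True).reshape(m, m)
    sigma = 0.5 * c0 + 0.5 * c1 + ridge * np.eye(m)
    w = np.linalg.solve(sigma, mu1 - mu0)
    b = -0.5 * float((mu1 + mu0) @ w)
    return w, b


# ---------------------------------------------------------------------------
# public operations


def loocv_lda(
    X: pd.DataFrame,
    groups: Sequence[str],
    panel: Sequence[str],
    *,
    normalize: str = "fold",
    ridge: float = 1e-6,
) -> tuple[float, float, pd.Series]:
    """LOOCV accuracy, residual probability and discriminant weights of a panel.

    Each sample is held out once; a two-class LDA with equal priors is fitted
    on the rest (z-scores fitted on the training fold) and the held-out
    sample predicted. The returned weights come from a fit on all samples.
    """
    panel = list(panel)
    if len(panel) < 1:
        raise ValueError("panel must contain at least one marker")
    missing = set(panel) - set(X.columns)
    if missing:
        raise ValueError(f"panel markers absent from the matrix: {sorted(missing)}")
    y, _ = _encode_groups(groups)
    cache = _prepare(X[panel].to_numpy(float), y, normalize=normalize, ridge=ridge)
    accuracy, residual = _panel_metrics(cache, np.arange(len(panel)))
    w, _b = _lda_weights(X[panel].to_numpy(float), y, ridge=ridge)
    return accuracy, residual, pd.Series(w, index=panel, name="weight")


def _encode_groups(groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    g = pd.Series(list(groups))
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    y = (g == levels[1]).to_numpy(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 samples")
    return y, levels


def exhaustive_panel_search(
    X: pd.DataFrame,
    groups: Sequence[str],
    *,
    max_size: int | None = None,
    normalize: str = "fold",
    ridge: float = 1e-6,
    marker_cap: int = 20,
    allow_large: bool = False,
) -> pd.DataFrame:
    """Best panel per size k = 1..M over all C(M, k) marker subsets.

    Returns one row per size with the winning marker tuple, its LOOCV
    accuracy, residual probability and the number of panels evaluated.
    Ties on accuracy break to minimal residual probability, remaining ties
    to the lexicographically smallest marker tuple; fully deterministic.
    """
    markers = sorted(X.columns)
    m = len(markers)
    if m > marker_cap and not allow_large:
        raise ValueError(
            f"{m} markers exceed the exhaustive-search cap ({marker_cap}); "
            "pass allow_large=True to override"
        )
    y, _ = _encode_groups(groups)
    cache = _prepare(X[markers].to_numpy(float), y, normalize=normalize, ridge=ridge)
    max_size = m if max_size is None else min(max_size, m)

    rows = []
    for k in range(1, max_size + 1):
        best: tuple[float, float, tuple[str, ...]] | None = None
        n_eval = 0
        for combo in combinations(range(m), k):
            ix = np.asarray(combo)
            acc, resid = _panel_metrics(cache, ix)
            n_eval += 1
            names = tuple(markers[i] for i in combo)
            if (
                best is None
                or acc > best[0] + 1e-12
                or (abs(acc - best[0]) <= 1e-12 and resid < best[1] - 1e-12)
            ):
                best = (acc, resid, names)
        assert best is not None
        rows.append(
            {
                "size": k,
                "markers": best[2],
                "accuracy": best[0],
                "residual_probability": best[1],
                "n_evaluated": n_eval,
            }
        )
    return pd.DataFrame(rows)


def elbow_select(
    accuracies: Sequence[float], sizes: Sequence[int] | None = None
) -> int:
    """Optimal panel size on the per-size best-accuracy front.

    Returns the size with maximum perpendicular distance to the chord from
    the first to the last front point; ties (including a perfectly linear
    front) go to the smallest size — the simplest model that explains the
    data.
    """
    acc = np.asarray(accuracies, dtype=float)
    if len(acc) < 3:
        raise ValueError("elbow selection needs at least 3 panel sizes")
    s = np.arange(1, len(acc) + 1) if sizes is None else np.asarray(sizes, float)
    p0 = np.array([s[0], acc[0]])
    p1 = np.array([s[-1], acc[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return int(s[0])
    rel = np.c_[s - p0[0], acc - p0[1]]
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    best = np.flatnonzero(dist >= dist.max() - 1e-12)[0]
    return int(s[best])


# ---------------------------------------------------------------------------
# Model / Results interface


@dataclass
class PanelSearchResults:
    """Results of the exhaustive LOOCV-LDA panel search.

    ``pareto`` is the per-size front (best panel, accuracy, residual
    probability); ``selected_size``/``selected_panel`` come from the elbow
    criterion; ``weights`` are the discriminant weights of the selected panel
    fitted on all samples; ``scores`` the per-sample discriminant (LD1)
    values and ``predictions`` the per-sample LOOCV-free predicted labels.
    """

    pareto: pd.DataFrame
    selected_size: int
    selected_panel: tuple[str, ...]
    selected_accuracy: float
    selected_residual: float
    weights: pd.Series
    intercept: float
    scores: pd.Series
    predictions: pd.Series
    groups: pd.Series
    group_levels: list[str]

    def summary(self) -> str:
        lines = [
            "Exhaustive LOOCV-LDA panel search",
            "=" * 48,
            f"samples:         {len(self.groups)} "
            f"({(self.groups == self.group_levels[0]).sum()} {self.group_levels[0]}, "
            f"{(self.groups == self.group_levels[1]).sum()} {self.group_levels[1]})",
            f"markers:         {int(self.pareto['size'].max())}",
            f"panels evaluated:{int(self.pareto['n_evaluated'].sum()):>7}",
            "",
            "size  accuracy  resid.prob  best panel",
        ]
        for _, r in self.pareto.iterrows():
            mark = " <- selected" if r["size"] == self.selected_size else ""
            lines.append(
                f"{int(r['size']):>4}  {r['accuracy']:8.3f}  {r['residual_probability']:10.3f}  "
                f"{', '.join(r['markers'])}{mark}"
            )
        lines += [
            "",
            f"selected size:   {self.selected_size} (elbow criterion)",
            f"selected panel:  {', '.join(self.selected_panel)}",
            f"LOOCV accuracy:  {self.selected_accuracy:.3f}",
            "discriminant weights (z-scored inputs):",
        ]
        for mkr, w in self.weights.items():
            lines.append(f"  {mkr:>8}: {w:+.3f}")
        return "\n".join(lines)

    def plot_front(self, ax=None):
        """Accuracy and residual probability per panel size (Pareto front)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.pareto["size"], self.pareto["accuracy"], "o-",
                label="LOOCV accuracy")
        ax2 = ax.twinx()
        ax2.plot(self.pareto["size"], self.pareto["residual_probability"],
                 "s--", color="tab:orange", label="residual probability")
        ax.axvline(self.selected_size, color="grey", ls=":")
        ax.set_xlabel("panel size")
        ax.set_ylabel("LOOCV accuracy")
        ax2.set_ylabel("residual probability")
        return ax


class CytokinePanelLDA:
    """Two-group cytokine-panel model (exhaustive LDA subset selection).

    Parameters
    ----------
    X : samples x markers MFI matrix (DataFrame).
    groups : per-sample binary group label, aligned with ``X``.
    normalize : ``"fold"`` fits z-scores inside each LOOCV training fold
        (default, leakage-free); ``"global"`` normalizes once on all samples.
    ridge : ridge term added to the pooled covariance for near-singular fits.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        groups: Sequence[str],
        *,
        normalize: str = "fold",
        ridge: float = 1e-6,
    ) -> None:
        if X.isna().any().any():
            raise ValueError("MFI matrix contains missing values")
        self.X = X
        self.groups = pd.Series(list(groups), index=X.index, name="group")
        self.normalize = normalize
        self.ridge = ridge
        self._y, self.group_levels = _encode_groups(self.groups)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_col: str = "group", **kwargs
    ) -> "CytokinePanelLDA":
        markers = [c for c in df.columns if c != group_col]
        return cls(df[markers], df[group_col], **kwargs)

    def loocv(self, panel: Sequence[str]) -> tuple[float, float, pd.Series]:
        return loocv_lda(
            self.X, self.groups, panel, normalize=self.normalize, ridge=self.ridge
        )

    def fit(self, *, max_size: int | None = None,
            allow_large: bool = False) -> PanelSearchResults:
        """Run the exhaustive search, select the elbow size, fit final weights."""
        pareto = exhaustive_panel_search(
            self.X,
            self.groups,
            max_size=max_size,
            normalize=self.normalize,
            ridge=self.ridge,
            allow_large=allow_large,
        )
        size = elbow_select(pareto["accuracy"], pareto["size"])
        row = pareto.loc[pareto["size"] == size].iloc[0]
        panel = list(row["markers"])
        w, b = _lda_weights(self.X[panel].to_numpy(float), self._y, ridge=self.ridge)

        xp = self.X[panel].to_numpy(float)
        mu = xp.mean(axis=0)
        sd = xp.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (xp - mu) / sd
        z[:, sd == 0] = 0.0
        scores = z @ w + b
        pred = np.where(scores > 0, self.group_levels[1], self.group_levels[0])
        return PanelSearchResults(
            pareto=pareto,
            selected_size=size,
            selected_panel=tuple(panel),
            selected_accuracy=float(row["accuracy"]),
            selected_residual=float(row["residual_probability"]),
            weights=pd.Series(w, index=panel, name="weight"),
            intercept=b,
            scores=pd.Series(scores, index=self.X.index, name="LD1"),
            predictions=pd.Series(pred, index=self.X.index, name="predicted"),
            groups=self.groups,
            group_levels=self.group_levels,
        )
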