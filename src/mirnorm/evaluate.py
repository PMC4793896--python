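"""Evaluation of normalization performance and PCA-based validation.

Two independent checks are provided:

* **CV reduction** — the per-detector coefficient of variation (linear
  scale) is compared between raw RQs and each normalization scheme via
  empirical cumulative distributions on a shared grid; a left-shifted
  (pointwise dominating) curve means reduced variability.
* **PCA validation** — detectors are the observations.  On autoscaled data
  (per-detector standardized log10 RQ, ``ARQ``) a PC1 vs PC2 plot groups
  miRNAs by variability: stable candidates cluster tightly at the narrow
  end of a funnel-shaped cloud.  On unscaled log10 data PC1 mostly carries
  expression level, so PC2/PC3 are the informative components.  The
  separation statistic quantifies "funnel-like" clustering as the ratio of
  within-set mean centroid distances (stable set / variable set); values
  below 1 indicate the stable set is the tighter cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .preprocess import RQMatrix


def _frame(mat) -> pd.DataFrame:
    return mat.rq if isinstance(mat, RQMatrix) else mat


def cv_per_detector(mat) -> pd.Series:
    """Sample SD divided by mean, per detector row, on the linear scale."""
    frame = _frame(mat)
    vals = frame.to_numpy(dtype=float)
    if (vals[np.isfinite(vals)] <= 0).any():
        raise InputError("CV evaluation expects positive values")
    mean = frame.mean(axis=1)
    if (mean == 0).any():
        raise InputError("zero-mean row encountered")
    out = frame.std(axis=1, ddof=1) / mean
    out.name = "cv"
    return out


@dataclass
class EvaluationReport:
    """CV vectors, ECDFs, medians and dominance flags per scheme."""

    cv: pd.DataFrame            # detectors x schemes (first column: raw)
    grid: np.ndarray
    ecdf: pd.DataFrame          # grid points x schemes
    median_cv: pd.Series
    fraction_reduced: pd.Series  # fraction of detectors with CV < raw
    dominates: dict[str, bool] = field(default_factory=dict)


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    v = np.sort(values)
    return np.searchsorted(v, grid, side="right") / len(v)


def cv_reduction_summary(raw, normalized: dict[str, pd.DataFrame], grid_size: int = 100) -> EvaluationReport:
    """Compare CV distributions of normalized matrices against raw.

    All matrices must cover the same detectors.  ECDFs are evaluated on a
    shared grid spanning the pooled CV range; a scheme *dominates* raw when
    its ECDF is >= the raw ECDF at every grid point (its curve lies left).
    """
    raw_frame = _frame(raw)
    cvs = {"raw": cv_per_detector(raw_frame)}
    for name, mat in normalized.items():
        frame = _frame(mat)
        if set(frame.index) != set(raw_frame.index):
            raise InputError(f"scheme {name!r} covers a different detector set")
        cvs[name] = cv_per_detector(frame).reindex(raw_frame.index)
    cv_tab = pd.DataFrame(cvs)
    pooled = cv_tab.to_numpy().ravel()
    grid = np.linspace(pooled.min(), pooled.max(), grid_size)
    ecdf = pd.DataFrame(
        {name: _ecdf_on_grid(col.to_numpy(), grid) for name, col in cv_tab.items()},
        index=grid,
    )
    ecdf.index.name = "cv_grid"
    dominates = {
        name: bool((ecdf[name] >= ecdf["raw"]).all()) for name in normalized
    }
    fraction_reduced = pd.Series(
        {name: float((cv_tab[name] < cv_tab["raw"]).mean()) for name in normalized},
        name="fraction_reduced",
    )
    return EvaluationReport(
        cv=cv_tab,
        grid=grid,
        ecdf=ecdf,
        median_cv=cv_tab.median(axis=0).rename("median_cv"),
        fraction_reduced=fraction_reduced,
        dominates=dominates,
    )


# ---------------------------------------------------------------------------
# autoscaling and PCA
# ---------------------------------------------------------------------------

def autoscale(rq) -> pd.DataFrame:
    """Per-detector standardized log10 RQ (ARQ): row mean 0, sample SD 1.

    Rows whose log10 values are constant (zero SD) carry no profile
    information and are excluded with a warning.
    """
    frame = _frame(rq)
    vals = frame.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals <= 0).any():
        raise InputError("autoscaling requires a complete, positive matrix")
    logv = np.log10(frame)
    sd = logv.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise DataError("all detector rows are constant; nothing to autoscale")
    if constant.any():
        warnings.warn(
            "excluded constant detector row(s) from autoscaling: "
            + ", ".join(map(str, frame.index[constant])),
            stacklevel=2,
        )
    kept = logv.loc[~constant]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)


@dataclass
class PCAResult:
    scores: pd.DataFrame      # detectors (observations) x components
    loadings: pd.DataFrame    # samples (variables) x components
    explained_variance_ratio: pd.Series


def pca(mat: pd.DataFrame, scaled: bool = True) -> PCAResult:
    """Principal components of detector profiles via SVD.

    Detectors are the observations (the points of the validation plots);
    samples are the variables.  The input should be log10 RQ (unscaled
    analysis) or ARQ (autoscaled analysis).  Sign convention: each
    component's loading vector has a non-negative entry of largest absolute
    value, making results deterministic.
    """
    from sklearn.decomposition import PCA as _PCA

    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise InputError("PCA requires at least 2 detectors and 2 samples")
    if (mat.std(axis=1, ddof=0) > 0).sum() < 2:
        raise DataError("fewer than 2 non-constant detectors")
    k = min(mat.shape)
    model = _PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(mat.to_numpy(dtype=float))
    components = model.components_  # k x n_samples
    for c in range(k):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=mat.index, columns=names),
        loadings=pd.DataFrame(components.T, index=mat.columns, columns=names),
        explained_variance_ratio=pd.Series(
            model.explained_variance_ratio_, index=names, name="explained_variance_ratio"
        ),
    )


def stability_separation(
    scores: pd.DataFrame,
    top_set: list[str],
    bottom_set: list[str],
    components: tuple[str, str] = ("PC1", "PC2"),
) -> float:
    """Within-set spread ratio of the stable vs variable detector clouds.

    ``(mean distance of top-set points from the top-set centroid) /
    (mean distance of bottom-set points from the bottom-set centroid)``
    in the plane of the chosen components (PC1-PC2 for autoscaled data,
    PC2-PC3 for unscaled).  Values < 1 mean the designated stable set forms
    the tighter cluster.  Returns ``inf`` when only the bottom set is
    degenerate and ``nan`` when both sets collapse to points.
    """
    if not top_set or not bottom_set:
        raise InputError("both detector sets must be non-empty")
    if set(top_set) & set(bottom_set):
        raise InputError("top and bottom sets must be disjoint")
    missing = [d for d in list(top_set) + list(bottom_set) if d not in scores.index]
    if missing:
        raise InputError(f"detector(s) absent from scores: {', '.join(missing)}")

    def spread(dets: list[str]) -> float:
        pts = scores.loc[list(dets), list(components)].to_numpy(dtype=float)
        centroid = pts.mean(axis=0)
        return float(np.linalg.norm(pts - centroid, axis=1).mean())

    top, bottom = spread(top_set), spread(bottom_set)
    if bottom == 0:
        return float("nan") if top == 0 else float("inf")
    return top / bottom


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_cv_ecdf(report: EvaluationReport, path: str) -> None:
    """Cumulative CV distribution per scheme (left-shifted = less variable)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in report.ecdf.columns:
        ax.step(report.ecdf.index, report.ecdf[name], where="post", label=name)
    ax.set_xlabel("CV")
    ax.set_ylabel("cumulative fraction of detectors")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(result: PCAResult, path: str, top_set=(), bottom_set=(), components=("PC1", "PC2")) -> None:
    """Scatter of detector scores with stable/variable sets highlighted."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = components
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.scores[x], result.scores[y], s=12, c="grey", label="other")
    if len(top_set):
        ax.scatter(result.scores.loc[list(top_set), x], result.scores.loc[list(top_set), y],
                   s=20, c="tab:blue", label="most stable")
    if len(bottom_set):
        ax.scatter(result.scores.loc[list(bottom_set), x], result.scores.loc[list(bottom_set), y],
                   s=20, c="tab:red", label="most variable")
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"{x} ({evr[x]:.0%})")
    ax.set_ylabel(f"{y} ({evr[y]:.0%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
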