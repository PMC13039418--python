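"""Single-cell expression landscape.

Builds the cells × markers matrix (nuclear mean by default, cell-region
mean for cytosolic markers such as P16), restricts it to representative
ROIs, and runs the z-score → PCA (retain the minimal axes explaining the
requested variance fraction, default 95 %) → K-means clustering workflow.
Marker positivity calls (manual, quantile or automatic bimodal thresholds)
drive the endocrine subtype partition (Insulin+ / Glucagon+ / SST28+ /
negative) and co-occurrence statistics between marker pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.proportion import proportion_confint

from .errors import CapacityError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "select_rois",
    "assign_rois",
    "build_expression_matrix",
    "ClusterModel",
    "cluster_cells",
    "embed_2d",
    "PositivityCall",
    "call_positivity",
    "cooccurrence_stats",
]

ENDOCRINE_MARKERS = ("Insulin", "Glucagon", "SST28")


# ---------------------------------------------------------------------------
# ROI selection


def select_rois(
    image_shape: tuple[int, int],
    n_rois: int,
    roi_size_px: int = 2000,
    artifact_mask: np.ndarray | None = None,
    seed: int = 0,
    jitter_px: int = 0,
) -> list[tuple[int, int, int]]:
    """Pick ``n_rois`` non-overlapping square ROIs avoiding masked regions.

    Deterministic greedy packing: candidate top-left corners are scanned
    row-major (stride = a quarter ROI side) with optional seeded jitter; a
    candidate is accepted if fully in bounds, free of artifact-mask pixels
    and disjoint from every accepted ROI.  Returns (row, col, size) tuples.
    """
    h, w = image_shape
    s = int(roi_size_px)
    if s < 1 or n_rois < 1:
        raise ValidationError("roi_size_px and n_rois must be positive")
    if artifact_mask is not None and artifact_mask.shape != (h, w):
        raise ValidationError("artifact mask shape mismatch")
    rng = np.random.default_rng(seed)
    stride = max(s // 4, 1)
    taken: list[tuple[int, int, int]] = []
    for r0 in range(0, h - s + 1, stride):
        for c0 in range(0, w - s + 1, stride):
            r, c = r0, c0
            if jitter_px > 0:
                r = int(np.clip(r + rng.integers(-jitter_px, jitter_px + 1),
                                0, h - s))
                c = int(np.clip(c + rng.integers(-jitter_px, jitter_px + 1),
                                0, w - s))
            if any(
                r < tr + ts and tr < r + s and c < tc + ts and tc < c + s
                for tr, tc, ts in taken
            ):
                continue
            if artifact_mask is not None and artifact_mask[r : r + s, c : c + s].any():
                continue
            taken.append((r, c, s))
            if len(taken) == n_rois:
                return taken
    raise CapacityError(
        f"could only place {len(taken)}/{n_rois} ROIs of side {s} px"
    )


def assign_rois(
    cells: pd.DataFrame, rois: list[tuple[int, int, int]]
) -> pd.Series:
    """ROI index per cell by centroid containment; −1 if in no ROI."""
    roi_id = np.full(len(cells), -1)
    rr = cells["centroid_row"].to_numpy()
    cc = cells["centroid_col"].to_numpy()
    for k, (r, c, s) in enumerate(rois):
        inside = (rr >= r) & (rr < r + s) & (cc >= c) & (cc < c + s)
        roi_id[inside & (roi_id < 0)] = k
    return pd.Series(roi_id, index=cells.index, name="roi_id")


# ---------------------------------------------------------------------------
# Expression matrix


def build_expression_matrix(
    cells: pd.DataFrame,
    markers: list[str],
    marker_localization: dict[str, str] | None = None,
    rois: list[tuple[int, int, int]] | None = None,
) -> pd.DataFrame:
    """Cells × markers matrix from the feature table.

    Each marker column is the nuclear mean (``<m>_nuc_mean``) unless the
    marker is flagged ``"cell"`` in ``marker_localization`` (cytosolic
    staining), in which case the cell-region mean is used.  If ``rois`` is
    given, rows are restricted to cells inside an ROI and a ``roi_id``
    column records the source ROI.
    """
    marker_localization = marker_localization or {}
    frame = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    for m in markers:
        loc = marker_localization.get(m, "nuclear")
        if loc not in ("nuclear", "cell"):
            raise ConfigurationError(f"marker {m!r}: bad localization {loc!r}")
        col = f"{m}_nuc_mean" if loc == "nuclear" else f"{m}_cell_mean"
        if col not in cells.columns:
            raise ConfigurationError(f"marker {m!r}: column {col!r} missing")
        frame[m] = cells[col].to_numpy(dtype=float)
    if rois is not None:
        frame["roi_id"] = assign_rois(cells, rois).to_numpy()
        frame = frame[frame["roi_id"] >= 0].reset_index(drop=True)
    if frame[markers].isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return frame


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterModel:
    """Frozen parameters of the z-score → PCA → K-means workflow."""

    markers: list[str]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray  # (n_retained, n_markers)
    explained_variance_ratio: np.ndarray
    explained_variance_ratio_full: np.ndarray
    n_components: int
    centroids: np.ndarray  # (k, n_retained)
    k: int
    seed: int

    def zscore(self, x: np.ndarray) -> np.ndarray:
        sds = np.where(self.sds > 0, self.sds, 1.0)
        return (x - self.means) / sds

    def reduce(self, x: np.ndarray) -> np.ndarray:
        return self.zscore(x) @ self.components.T


def cluster_cells(
    matrix: pd.DataFrame,
    markers: list[str] | None = None,
    var_frac: float = 0.95,
    k: int = 20,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[ClusterModel, pd.Series, pd.DataFrame, pd.Series]:
    """z-score each marker, project onto the minimal set of principal axes
    explaining ≥ ``var_frac`` of the variance, and K-means the result.

    Returns (model, assignments, profile, occurrence): ``profile`` is the
    per-cluster mean z-scored marker vector (the heatmap data) and
    ``occurrence`` the fraction of cells in each cluster (sums to 1).
    Deterministic given ``seed``; best of ``n_init`` k-means++ restarts.
    """
    if markers is None:
        markers = [c for c in matrix.columns if c not in ("cell_id", "roi_id")]
    if not markers:
        raise ValidationError("need at least one marker")
    x = matrix[markers].to_numpy(dtype=float)
    n = len(x)
    if k > n:
        raise ValidationError(f"k={k} exceeds number of cells {n}")
    if not 0 < var_frac <= 1:
        raise ValidationError("var_frac must be in (0, 1]")
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    z = (x - means) / np.where(sds > 0, sds, 1.0)
    n_comp_max = min(z.shape)
    pca = PCA(n_components=n_comp_max, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_retained = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    n_retained = min(n_retained, n_comp_max)
    reduced = scores[:, :n_retained]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(reduced)
    model = ClusterModel(
        markers=list(markers),
        means=means,
        sds=sds,
        components=pca.components_[:n_retained],
        explained_variance_ratio=pca.explained_variance_ratio_[:n_retained],
        explained_variance_ratio_full=pca.explained_variance_ratio_,
        n_components=n_retained,
        centroids=km.cluster_centers_,
        k=k,
        seed=seed,
    )
    assignments = pd.Series(labels, index=matrix.index, name="cluster")
    profile = pd.DataFrame(
        [z[labels == c].mean(axis=0) if (labels == c).any() else np.zeros(len(markers))
         for c in range(k)],
        columns=markers,
    )
    profile.index.name = "cluster"
    occ = pd.Series(
        np.bincount(labels, minlength=k) / n, name="occurrence"
    )
    return model, assignments, profile, occ


def embed_2d(reduced: np.ndarray, seed: int = 0) -> np.ndarray:
    """2D embedding of the PCA-reduced features for visualization.

    Uses UMAP when available (and n is large enough for its neighbourhood
    graph); otherwise falls back to the first two reduced components with a
    logged notice.  The fallback pads a single-axis input with zeros.
    """
    reduced = np.asarray(reduced, dtype=float)
    n = len(reduced)
    if n >= 10:
        try:
            import umap

            nn = min(15, n - 1)
            emb = umap.UMAP(
                n_components=2, n_neighbors=nn, random_state=seed
            ).fit_transform(reduced)
            return np.asarray(emb)
        except ImportError:
            logger.info("umap-learn not installed; using first two principal axes")
    else:
        logger.info("too few points for UMAP; using first two principal axes")
    if reduced.shape[1] >= 2:
        return reduced[:, :2].copy()
    return np.column_stack([reduced[:, 0], np.zeros(n)])


# ---------------------------------------------------------------------------
# Positivity and co-occurrence


@dataclass
class PositivityCall:
    """Boolean positivity per cell and marker, plus derived subtypes."""

    calls: pd.DataFrame  # boolean, one column per marker
    thresholds: dict[str, float]
    subtype: pd.Series  # Insulin+ / Glucagon+ / SST28+ / negative


def _resolve_threshold(values: np.ndarray, spec) -> float:
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        return float(spec)
    if spec == "otsu":
        logv = np.log1p(np.maximum(values, 0.0))
        if np.ptp(logv) == 0:
            return float(np.expm1(logv[0]))
        return float(np.expm1(threshold_otsu(logv)))
    if isinstance(spec, dict) and set(spec) == {"quantile"}:
        q = spec["quantile"]
        if not 0 <= q <= 1:
            raise ConfigurationError("quantile must be in [0, 1]")
        return float(np.quantile(values, q))
    raise ConfigurationError(f"unknown threshold spec {spec!r}")


def call_positivity(
    matrix: pd.DataFrame,
    threshold_spec: dict,
    endocrine_markers: tuple[str, ...] = ENDOCRINE_MARKERS,
) -> PositivityCall:
    """Positivity calls per marker and the endocrine subtype partition.

    ``threshold_spec`` maps marker → manual value, ``"otsu"`` (automatic
    bimodal threshold on log intensities) or ``{"quantile": q}``.  A cell
    is positive when its value exceeds the threshold.  The subtype is the
    positive endocrine marker; multi-positive cells take the marker with
    the highest z-score, cells positive for none are "negative".
    """
    calls = {}
    thresholds = {}
    for m, spec in threshold_spec.items():
        if m not in matrix.columns:
            raise ConfigurationError(f"marker {m!r} not in expression matrix")
        v = matrix[m].to_numpy(dtype=float)
        thr = _resolve_threshold(v, spec)
        thresholds[m] = thr
        calls[m] = v > thr
    calls_df = pd.DataFrame(calls, index=matrix.index)

    present = [m for m in endocrine_markers if m in calls_df.columns]
    n = len(matrix)
    subtype = np.array(["negative"] * n, dtype=object)
    if present:
        zcols = {}
        for m in present:
            v = matrix[m].to_numpy(dtype=float)
            sd = v.std()
            zcols[m] = (v - v.mean()) / (sd if sd > 0 else 1.0)
        zmat = np.column_stack([zcols[m] for m in present])
        posmat = calls_df[present].to_numpy()
        any_pos = posmat.any(axis=1)
        masked = np.where(posmat, zmat, -np.inf)
        best = np.argmax(masked, axis=1)
        labels = np.array([f"{m}+" for m in present], dtype=object)
        subtype[any_pos] = labels[best[any_pos]]
    return PositivityCall(
        calls=calls_df,
        thresholds=thresholds,
        subtype=pd.Series(subtype, index=matrix.index, name="subtype"),
    )


@dataclass
class CooccurrenceResult:
    fraction: float  # P(y+ | x+); NaN if no x-positive cells
    n_x_positive: int
    n_xy_positive: int
    ci_low: float
    ci_high: float
    group_means: pd.DataFrame | None = None  # 2×2 means of a quantitative marker


def cooccurrence_stats(
    calls: PositivityCall,
    marker_x: str,
    marker_y: str,
    values: pd.Series | None = None,
) -> CooccurrenceResult:
    """Fraction of x-positive cells that are y-positive, with Wilson 95 % CI.

    If ``values`` (a quantitative per-cell marker, background-corrected) is
    given, also reports the mean and group size in the four (x±, y±)
    groups.  With no x-positive cell the fraction is reported missing
    (NaN, n = 0) rather than raising.
    """
    for m in (marker_x, marker_y):
        if m not in calls.calls.columns:
            raise ConfigurationError(f"no positivity calls for marker {m!r}")
    x = calls.calls[marker_x].to_numpy()
    y = calls.calls[marker_y].to_numpy()
    n_x = int(x.sum())
    n_xy = int((x & y).sum())
    if n_x == 0:
        frac, lo, hi = np.nan, np.nan, np.nan
    else:
        frac = n_xy / n_x
        lo, hi = proportion_confint(n_xy, n_x, alpha=0.05, method="wilson")
    groups = None
    if values is not None:
        v = np.asarray(values, dtype=float)
        rows = []
        for xs, ys, name in [
            (False, False, f"{marker_x}-/{marker_y}-"),
            (True, False, f"{marker_x}+/{marker_y}-"),
            (False, True, f"{marker_x}-/{marker_y}+"),
            (True, True, f"{marker_x}+/{marker_y}+"),
        ]:
            m = (x == xs) & (y == ys)
            rows.append(
                {
                    "group": name,
                    "n": int(m.sum()),
                    "mean": float(v[m].mean()) if m.any() else np.nan,
                    "sem": float(stats.sem(v[m])) if m.sum() > 1 else np.nan,
                }
            )
        groups = pd.DataFrame(rows)
    return CooccurrenceResult(
        fraction=float(frac) if not np.isnan(frac) else np.nan,
        n_x_positive=n_x,
        n_xy_positive=n_xy,
        ci_low=float(lo) if not np.isnan(lo) else np.nan,
        ci_high=float(hi) if not np.isnan(hi) else np.nan,
        group_means=groups,
    )
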