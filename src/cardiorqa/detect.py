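"""Stable-rotor detection and arrhythmia-class feature analysis.

A spatially pinned rotor keeps nearby tissue in a near-periodic pattern for
most of the analysis window, which shows up jointly as a very long longest
diagonal line (Lmax) and a high mean diagonal length (Lmean) in the per-site
recurrence plots.  The detector thresholds both maps (defaults Lmax >= 800
samples and Lmean > 15 on 1-s, 1000 Hz traces) and labels 8-connected
components.

For whole-simulation classification, each metric map is summarised by its
spatial mean and its Moran's I, giving an interpretable low-dimensional
feature space in which the four arrhythmia classes separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .spatial import MetricMap, compute_metric_maps, moore_weights, morans_i

__all__ = ["RotorMask", "detect_stable_rotors", "extract_feature_vector",
           "features_dataframe", "check_class_separation", "cluster_features",
           "resolution_degradation_study", "DEFAULT_FEATURE_METRICS"]

DEFAULT_FEATURE_METRICS = ("REC", "RATIO", "DET", "DIV", "Lmax", "Lmean",
                           "ENTR", "LAM", "Vmax", "Vmean", "OI1", "OI2",
                           "eigen1", "eigen2", "ApEnt", "SampEnt")

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class RotorMask:
    mask: np.ndarray               # bool grid of detected sites
    labels: np.ndarray             # connected-component labels (0 = none)
    centroids: list[tuple[float, float]]   # (row, col) per component
    thr_lmax: float
    thr_lmean: float
    spacing_mm: float

    @property
    def n_components(self) -> int:
        return len(self.centroids)


def detect_stable_rotors(lmax_map: MetricMap, lmean_map: MetricMap,
                         thr_lmax: float = 800.0,
                         thr_lmean: float = 15.0) -> RotorMask:
    """Joint-threshold detector for spatially pinned rotor tips.

    A site is flagged when Lmax >= thr_lmax AND Lmean > thr_lmean; flagged
    sites are grouped into 8-connected components with centroids in grid
    coordinates.
    """
    if lmax_map.shape != lmean_map.shape:
        raise ValueError("Lmax and Lmean maps must be congruent")
    valid = lmax_map.valid & lmean_map.valid
    with np.errstate(invalid="ignore"):
        mask = valid & (lmax_map.values >= thr_lmax) \
            & (lmean_map.values > thr_lmean)
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    cents = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    return RotorMask(mask=mask, labels=labels,
                     centroids=[(float(r), float(c)) for r, c in cents],
                     thr_lmax=thr_lmax, thr_lmean=thr_lmean,
                     spacing_mm=lmax_map.spacing_mm)


def extract_feature_vector(maps: dict[str, MetricMap],
                           metrics: tuple[str, ...] | None = None,
                           smooth_first: bool = False) -> dict[str, float]:
    """(spatial mean, Moran's I) per metric map.

    Moran's I is computed on the unsmoothed maps unless ``smooth_first``;
    undefined values (constant maps) propagate as nan.
    """
    from .spatial import smooth_map
    if metrics is None:
        metrics = tuple(maps.keys())
    feats: dict[str, float] = {}
    weights_cache: dict[bytes, object] = {}
    for name in metrics:
        if name not in maps:
            feats[f"{name}_mean"] = np.nan
            feats[f"{name}_moran"] = np.nan
            continue
        mp = maps[name]
        if smooth_first:
            mp = smooth_map(mp)
        vals = mp.valid_values()
        vals = vals[np.isfinite(vals)]
        feats[f"{name}_mean"] = float(vals.mean()) if vals.size else np.nan
        key = mp.valid.tobytes()
        if key not in weights_cache:
            weights_cache[key] = moore_weights(*mp.shape, valid=mp.valid)
        try:
            feats[f"{name}_moran"] = morans_i(mp, weights_cache[key])
        except ValueError:
            feats[f"{name}_moran"] = np.nan
    return feats


def features_dataframe(rows: list[dict], labels: list[str] | None = None
                       ) -> pd.DataFrame:
    """Tidy one-row-per-simulation feature table (``class`` column last)."""
    df = pd.DataFrame(rows)
    df["class"] = labels if labels is not None else "unknown"
    return df


def check_class_separation(features: pd.DataFrame,
                           metric_pair: tuple[str, str]) -> pd.DataFrame:
    """Pairwise convex-hull disjointness + silhouette in a 2-D feature plane.

    ``features`` needs the two feature columns and a ``class`` column with
    >= 2 classes of >= 2 members each.  Returns one row per class pair with
    columns ``class_a``, ``class_b``, ``disjoint`` and ``silhouette``.
    """
    from itertools import combinations
    from shapely.geometry import MultiPoint
    from sklearn.metrics import silhouette_score

    fx, fy = metric_pair
    df = features.dropna(subset=[fx, fy])
    counts = df["class"].value_counts()
    classes = [c for c in counts.index if counts[c] >= 2]
    if len(classes) < 2:
        raise ValueError("need at least two classes with >= 2 members")
    rows = []
    for a, b in combinations(sorted(classes), 2):
        pa = df.loc[df["class"] == a, [fx, fy]].to_numpy()
        pb = df.loc[df["class"] == b, [fx, fy]].to_numpy()
        # scale jointly so hull geometry is not dominated by one axis
        both = np.vstack([pa, pb])
        scale = both.std(axis=0)
        scale[scale == 0] = 1.0
        ha = MultiPoint(list(map(tuple, pa / scale))).convex_hull
        hb = MultiPoint(list(map(tuple, pb / scale))).convex_hull
        disjoint = not ha.intersects(hb)
        lab = np.array([0] * len(pa) + [1] * len(pb))
        sil = float(silhouette_score(both / scale, lab))
        rows.append({"class_a": a, "class_b": b, "disjoint": disjoint,
                     "silhouette": sil})
    return pd.DataFrame(rows)


def cluster_features(features: pd.DataFrame, k: int,
                     feature_cols: list[str] | None = None,
                     seed: int = 0) -> tuple[np.ndarray, float | None]:
    """k-means on z-scored features; labels aligned to known classes.

    Returns ``(labels, accuracy)``; accuracy is the best label-permutation
    agreement (Hungarian matching) with the ``class`` column, or None when no
    ground truth is present.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans
    from sklearn.preprocessing import StandardScaler

    if feature_cols is None:
        feature_cols = [c for c in features.columns if c != "class"]
    X = features[feature_cols].to_numpy(dtype=float)
    X = X[:, np.all(np.isfinite(X), axis=0)]
    if len(X) < k:
        raise ValueError("fewer points than clusters")
    Xs = StandardScaler().fit_transform(X)
    labels = KMeans(n_clusters=k, random_state=seed, n_init=10
                    ).fit_predict(Xs)
    acc = None
    if "class" in features.columns \
            and not (features["class"] == "unknown").all():
        truth, classes = pd.factorize(features["class"])
        n_true = len(classes)
        conf = np.zeros((k, n_true))
        for lab, t in zip(labels, truth):
            conf[lab, t] += 1
        r, c = linear_sum_assignment(-conf)
        acc = conf[r, c].sum() / len(labels)
    return labels, acc


def resolution_degradation_study(recording, strides: list[int],
                                 window_ms=None,
                                 metrics: tuple[str, ...] = ("REC", "DET"),
                                 **map_kwargs) -> pd.DataFrame:
    """Recompute the feature vector at coarser site spacings.

    For each stride, traces are re-extracted from the recording at that
    spatial subsampling, metric maps recomputed and summarised; one row per
    stride, with a ``spacing_mm`` column.
    """
    from .sim import extract_traces
    rows = []
    for stride in strides:
        tg = extract_traces(recording, stride, window_ms)
        if min(tg.shape) < 2:
            raise ValueError(f"stride {stride} leaves fewer than 2x2 sites")
        maps = compute_metric_maps(tg, measures=metrics, **map_kwargs)
        feats = extract_feature_vector(maps)
        feats["stride"] = stride
        feats["spacing_mm"] = tg.spacing_mm
        rows.append(feats)
    return pd.DataFrame(rows)
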