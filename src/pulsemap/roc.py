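"""Observer-mask comparison: ROC sweep, ideal threshold, critical amplitude.

An observer outlines the pulsating areas on a full-resolution frame.
The binary outline is reduced 5:1 to the cluster grid (a cluster is
pulsatile if *any* of its 25 pixels is inside the outline) and compared
with the automated amplitude map: at each integer threshold 0..40 a
cluster is called pulsatile when its amplitude is strictly greater than
the threshold, yielding per-threshold confusion counts, an empirical
ROC curve and its area, the ideal threshold (maximum sensitivity x
specificity product), and the per-region critical amplitudes — the
threshold ceilings above which an observer-outlined region would be
missed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .amplitude import AmplitudeMap

__all__ = [
    "ObserverMask",
    "ConfusionCounts",
    "RocResult",
    "downscale_mask",
    "segment",
    "confusion",
    "rates",
    "auc_empirical",
    "roc_sweep",
    "ideal_threshold",
    "critical_amplitude",
    "cohens_kappa",
]

THRESHOLDS = np.arange(0, 41)  # integer amplitude scale 0:40


@dataclass
class ObserverMask:
    """One observer's pulsation annotation, full-resolution and 5:1 reduced."""

    full: np.ndarray
    clusters: np.ndarray
    observer_id: str = "observer"


@dataclass
class ConfusionCounts:
    threshold: int
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class RocResult:
    """Full observer-vs-map comparison over the 0..40 threshold sweep."""

    counts: list
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ideal_threshold: int
    regions: list  # (region_id, n_clusters, max_amplitude)
    critical_amplitude: float
    observer_id: str = "observer"
    degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "threshold": [c.threshold for c in self.counts],
                "TP": [c.tp for c in self.counts],
                "FP": [c.fp for c in self.counts],
                "FN": [c.fn for c in self.counts],
                "TN": [c.tn for c in self.counts],
                "tpr": self.tpr,
                "fpr": self.fpr,
            }
        )


def downscale_mask(mask: np.ndarray, cluster_size: int = 5,
                   grid_shape: tuple[int, int] | None = None) -> np.ndarray:
    """5:1 OR-pooling: a cluster is pulsatile if any of its pixels is.

    The tiling matches the amplitude grid (anchored at pixel (0, 0),
    trailing remainder dropped).  ``grid_shape``, when given, is checked
    against the pooled result.
    """
    mask = np.asarray(mask)
    s = cluster_size
    nr, nc = mask.shape[0] // s, mask.shape[1] // s
    if nr == 0 or nc == 0:
        raise ValueError(f"mask {mask.shape} smaller than one {s}x{s} cluster")
    pooled = (mask[: nr * s, : nc * s].reshape(nr, s, nc, s) > 0).any(axis=(1, 3))
    if grid_shape is not None and pooled.shape != tuple(grid_shape):
        raise ValueError(
            f"mask pools to {pooled.shape}, amplitude grid is {tuple(grid_shape)}"
        )
    return pooled.astype(np.uint8)


def segment(amap: AmplitudeMap | np.ndarray, threshold: float) -> np.ndarray:
    """Binary detection grid: amplitude strictly greater than threshold.

    Equality with the threshold counts as non-pulsatile.
    """
    amp = amap.amplitude if isinstance(amap, AmplitudeMap) else np.asarray(amap)
    return (amp > threshold).astype(np.uint8)


def confusion(segmented: np.ndarray, observer: np.ndarray,
              threshold: int) -> ConfusionCounts:
    """Element-wise 2x2 cross-tabulation of detection vs observer grading."""
    pred = np.asarray(segmented) > 0
    truth = np.asarray(observer) > 0
    if pred.shape != truth.shape:
        raise ValueError(f"grid shapes differ: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        threshold=threshold,
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def rates(counts: ConfusionCounts) -> dict:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN); NaN with a flag when undefined."""
    out = {"tpr": np.nan, "fpr": np.nan, "undefined": False}
    if counts.tp + counts.fn > 0:
        out["tpr"] = counts.tp / (counts.tp + counts.fn)
    else:
        out["undefined"] = True
    if counts.fp + counts.tn > 0:
        out["fpr"] = counts.fp / (counts.fp + counts.tn)
    else:
        out["undefined"] = True
    out["sensitivity"] = out["tpr"]
    out["specificity"] = 1.0 - out["fpr"]
    return out


def auc_empirical(fpr: np.ndarray, tpr: np.ndarray) -> tuple[float, bool]:
    """Trapezoidal area under the empirical ROC curve.

    Points are augmented with the (0,0) and (1,1) anchors and sorted
    into sweep order (both rates are non-increasing in threshold, so
    sorting by (fpr, tpr) recovers it).  Duplicate-FPR points form
    vertical segments of zero width, so the trapezoid rule integrates
    the swept staircase exactly.  Returns ``(auc, degenerate)``; the
    flag marks a curve whose distinct points collapsed to the anchors
    alone (chance diagonal).
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    ok = np.isfinite(fpr) & np.isfinite(tpr)
    pts = np.column_stack([np.append(fpr[ok], [0.0, 1.0]),
                           np.append(tpr[ok], [0.0, 1.0])])
    if len(pts) < 2:
        raise ValueError("need at least 2 ROC points")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    x, y = pts[order, 0], pts[order, 1]
    degenerate = np.unique(pts, axis=0).shape[0] <= 2
    return float(np.trapezoid(y, x)), bool(degenerate)


def ideal_threshold(tpr: np.ndarray, fpr: np.ndarray,
                    thresholds: np.ndarray = THRESHOLDS) -> int:
    """Integer threshold maximising sensitivity x specificity; ties -> lowest."""
    sens = np.asarray(tpr, dtype=float)
    spec = 1.0 - np.asarray(fpr, dtype=float)
    product = sens * spec
    if not np.any(np.isfinite(product)):
        raise ValueError("no threshold has defined sensitivity and specificity")
    product = np.where(np.isfinite(product), product, -np.inf)
    return int(thresholds[int(np.argmax(product))])


def critical_amplitude(amap: AmplitudeMap | np.ndarray,
                       observer: np.ndarray) -> tuple[list, float]:
    """Per-region and eye-level critical amplitudes.

    Regions are 8-connected components of the observer cluster grid.  A
    region's critical amplitude is the maximum map amplitude it contains
    — the ceiling above which a threshold would miss the region
    entirely.  The eye-level value is the minimum over regions: the
    lowest such ceiling.  Returns ``(regions, eye_level)`` with regions
    as ``(region_id, n_clusters, max_amplitude)``; empty mask gives
    ``([], nan)``.
    """
    amp = amap.amplitude if isinstance(amap, AmplitudeMap) else np.asarray(amap)
    truth = np.asarray(observer) > 0
    if amp.shape != truth.shape:
        raise ValueError(f"grid shapes differ: {amp.shape} vs {truth.shape}")
    labels, n = ndimage.label(truth, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return [], float("nan")
    regions = []
    for rid in range(1, n + 1):
        sel = labels == rid
        regions.append((rid, int(sel.sum()), float(amp[sel].max())))
    eye_level = min(r[2] for r in regions)
    return regions, eye_level


def cohens_kappa(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Cohen's kappa between two observers' binary cluster grids.

    ``(p_o - p_e) / (1 - p_e)`` with marginal-product chance agreement;
    NaN when both gradings are constant (p_e = 1).
    """
    a = np.asarray(mask_a).ravel() > 0
    b = np.asarray(mask_b).ravel() > 0
    if a.shape != b.shape:
        raise ValueError("masks must have identical shapes")
    n = a.size
    p_o = np.mean(a == b)
    p_yes = a.mean() * b.mean()
    p_no = (1 - a.mean()) * (1 - b.mean())
    p_e = p_yes + p_no
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return float((p_o - p_e) / (1 - p_e))


def roc_sweep(amap: AmplitudeMap | np.ndarray, observer: np.ndarray,
              observer_id: str = "observer",
              thresholds: np.ndarray = THRESHOLDS) -> RocResult:
    """Full comparison of an amplitude map against one observer grid."""
    amp = amap.amplitude if isinstance(amap, AmplitudeMap) else np.asarray(amap)
    counts = [confusion(segment(amp, t), observer, int(t)) for t in thresholds]
    r = [rates(c) for c in counts]
    tpr = np.array([x["tpr"] for x in r])
    fpr = np.array([x["fpr"] for x in r])
    auc, degenerate = auc_empirical(fpr, tpr)
    ideal = ideal_threshold(tpr, fpr, thresholds)
    regions, eye_level = critical_amplitude(amp, observer)
    return RocResult(
        counts=counts, tpr=tpr, fpr=fpr, auc=auc, ideal_threshold=ideal,
        regions=regions, critical_amplitude=eye_level,
        observer_id=observer_id, degenerate=degenerate,
    )
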