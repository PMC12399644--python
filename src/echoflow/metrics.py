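"""Region-similarity and temporal-consistency metrics.

Two consistency measures for video segmentation:

* ``TC`` — for each pair of adjacent-frame masks, both contours are
  resampled to ``n_pts`` points, described by shape-context histograms
  (log-polar, 5 radial × 12 angular bins, radii normalized by the mean
  pairwise distance), and aligned by an order-preserving cyclic DTW over the
  χ² distances; the pair cost is the mean cost per matched point.  The
  video score is the mean over adjacent pairs, the dataset score the mean
  over videos.  Lower is more stable; a static sequence scores 0.
* ``TCD`` — mean absolute difference of per-frame ground-truth Dice between
  adjacent frames, averaged per video and then over videos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is pre-installed
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]

__all__ = [
    "ContourSet",
    "DiceSeries",
    "dice",
    "iou",
    "mask_to_contours",
    "shape_context",
    "chi2_distance_matrix",
    "dtw_align",
    "tc_pair",
    "tc_video",
    "tc_dataset",
    "tcd",
    "SC_RADIAL_BINS",
    "SC_ANGULAR_BINS",
    "DEFAULT_N_PTS",
]

SC_RADIAL_BINS = 5
SC_ANGULAR_BINS = 12
DEFAULT_N_PTS = 100


@dataclass
class ContourSet:
    """Closed contours as ordered sub-pixel vertex arrays, largest first."""

    contours: list  # list of (n_pts, 2) float arrays
    empty: bool = False

    @property
    def main(self) -> np.ndarray:
        if self.empty:
            raise ValueError("empty contour set")
        return self.contours[0]


@dataclass
class DiceSeries:
    """Per-frame dice values for one or more videos."""

    values: list  # list of 1-D arrays, one per video

    def __post_init__(self):
        self.values = [np.asarray(v, dtype=np.float64) for v in self.values]
        for v in self.values:
            if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
                raise ValueError("dice values must lie in [0, 1]")


# -- region similarity -----------------------------------------------------

def dice(mask_a: np.ndarray, mask_b: np.ndarray, class_id: int | None = None) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); both-empty → 1.0."""
    a, b = _binarize(mask_a, mask_b, class_id)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(mask_a: np.ndarray, mask_b: np.ndarray, class_id: int | None = None) -> float:
    """Intersection over union; both-empty → 1.0."""
    a, b = _binarize(mask_a, mask_b, class_id)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _binarize(a, b, class_id):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if class_id is not None:
        return a == class_id, b == class_id
    return a.astype(bool), b.astype(bool)


# -- contours and descriptors ---------------------------------------------

def mask_to_contours(mask: np.ndarray, class_id: int | None = None,
                     n_pts: int = DEFAULT_N_PTS) -> ContourSet:
    """Marching-squares iso-contours at 0.5, arc-length resampled to n_pts.

    Components are ordered by enclosed perimeter (largest first).  An empty
    mask yields a flagged empty set.
    """
    mask = np.asarray(mask)
    binary = (mask == class_id) if class_id is not None else mask.astype(bool)
    if not binary.any():
        return ContourSet(contours=[], empty=True)
    # pad so structures touching the border still close
    padded = np.pad(binary.astype(float), 1)
    raw = measure.find_contours(padded, 0.5)
    resampled = []
    for contour in raw:
        pts = contour - 1.0  # undo padding offset
        resampled.append(_resample_closed(pts, n_pts))
    resampled.sort(key=lambda c: -_perimeter(c))
    return ContourSet(contours=resampled)


def _perimeter(points: np.ndarray) -> float:
    closed = np.vstack([points, points[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def _resample_closed(points: np.ndarray, n_pts: int) -> np.ndarray:
    """Equispaced-in-arc-length resampling of a closed polyline."""
    pts = np.asarray(points, dtype=np.float64)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) == 0:
        raise ValueError("degenerate contour")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        # single-pixel mask: marching squares still gives a tiny diamond,
        # but guard against fully coincident vertices
        return np.repeat(pts[:1], n_pts, axis=0)
    targets = np.linspace(0.0, total, n_pts, endpoint=False)
    out = np.empty((n_pts, 2))
    out[:, 0] = np.interp(targets, arclen, closed[:, 0])
    out[:, 1] = np.interp(targets, arclen, closed[:, 1])
    return out


def shape_context(contour, n_radial: int = SC_RADIAL_BINS,
                  n_angular: int = SC_ANGULAR_BINS) -> np.ndarray:
    """Per-point log-polar histograms of the relative positions of all others.

    Radii are normalized by the mean pairwise distance (scale invariance);
    relative coordinates give translation invariance.  Rows sum to 1.
    """
    pts = contour.main if isinstance(contour, ContourSet) else np.asarray(contour)
    n = len(pts)
    if n < 3:
        raise ValueError("shape context needs at least 3 points")
    diff = pts[None, :, :] - pts[:, None, :]  # (n, n, 2)
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    mean_dist = dist[off].mean()
    if mean_dist <= 0:
        raise ValueError("all contour points coincide")
    r = np.round(dist / mean_dist, 9)  # snap float jitter off bin edges
    # standard shape-context radial range [1/8, 2] in log space
    r_edges = np.logspace(np.log10(0.125), np.log10(2.0), n_radial + 1)
    r_bin = np.clip(np.searchsorted(r_edges, r, side="right") - 1, 0, n_radial - 1)
    theta = np.arctan2(diff[..., 0], diff[..., 1]) % (2 * np.pi)
    t_bin = np.floor(np.round(theta / (2 * np.pi) * n_angular, 9)).astype(int)
    t_bin = np.clip(t_bin, 0, n_angular - 1)
    flat = r_bin * n_angular + t_bin
    hist = np.zeros((n, n_radial * n_angular))
    for i in range(n):
        hist[i] = np.bincount(flat[i][off[i]], minlength=n_radial * n_angular)
    hist /= hist.sum(axis=1, keepdims=True)
    return hist


def chi2_distance_matrix(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """χ² distance between all descriptor pairs: 0.5·Σ (a−b)²/(a+b)."""
    a = desc_a[:, None, :]
    b = desc_b[None, :, :]
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, (a - b) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
    return 0.5 * terms.sum(axis=-1)


# -- DTW -------------------------------------------------------------------

@njit(cache=True)
def _dtw_cost_path(C):  # pragma: no cover - exercised via tc_pair
    n, m = C.shape
    INF = 1e300
    D = np.empty((n, m))
    L = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            c = C[i, j]
            if i == 0 and j == 0:
                D[i, j] = c
                L[i, j] = 1
                continue
            best = INF
            bl = 0
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
                bl = L[i - 1, j - 1]
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
                bl = L[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
                bl = L[i, j - 1]
            D[i, j] = c + best
            L[i, j] = bl + 1
    return D[n - 1, m - 1], L[n - 1, m - 1]


@njit(cache=True)
def _cyclic_dtw(C):  # pragma: no cover - exercised via tc_pair
    n, m = C.shape
    best_cost = 1e300
    best_len = 1
    rolled = np.empty_like(C)
    for shift in range(m):
        for j in range(m):
            rolled[:, j] = C[:, (j + shift) % m]
        cost, length = _dtw_cost_path(rolled)
        if cost < best_cost - 1e-15 or (
            abs(cost - best_cost) <= 1e-15 and length > best_len
        ):
            best_cost = cost
            best_len = length
    return best_cost, best_len


def dtw_align(cost_matrix: np.ndarray, cyclic: bool = True):
    """Minimal monotone alignment cost and matched-pair count.

    With ``cyclic=True`` the best start-offset rotation of the second
    sequence is used (contours have no canonical starting vertex).
    """
    C = np.ascontiguousarray(cost_matrix, dtype=np.float64)
    if C.ndim != 2 or C.size == 0:
        raise ValueError("cost matrix must be 2-D and non-empty")
    if cyclic:
        return _cyclic_dtw(C)
    return _dtw_cost_path(C)


# -- the TC metric ---------------------------------------------------------

def tc_pair(mask_a: np.ndarray, mask_b: np.ndarray, class_id: int | None = None,
            n_pts: int = DEFAULT_N_PTS) -> float:
    """Temporal-stability cost between two masks (mean cost per matched point).

    Contours → shape contexts → χ² distances → cyclic order-preserving DTW.
    Raises if either mask is empty (callers skip and tally such pairs).
    """
    ca = mask_to_contours(mask_a, class_id, n_pts)
    cb = mask_to_contours(mask_b, class_id, n_pts)
    if ca.empty or cb.empty:
        raise ValueError("empty mask in tc_pair")
    da = shape_context(ca.main)
    db = shape_context(cb.main)
    C = chi2_distance_matrix(da, db)
    cost, length = dtw_align(C, cyclic=True)
    return float(cost / length)


def tc_video(masks, class_id: int | None = None,
             n_pts: int = DEFAULT_N_PTS) -> tuple[float, int]:
    """Mean adjacent-pair cost over a mask sequence.

    Returns ``(tc, n_empty_pairs)``: pairs touching an empty mask are
    excluded from the mean and tallied instead of silently hiding them.
    """
    masks = [np.asarray(m) for m in masks]
    if len(masks) < 2:
        raise ValueError("tc_video needs at least 2 frames")
    costs, n_empty = [], 0
    for a, b in zip(masks[:-1], masks[1:]):
        try:
            costs.append(tc_pair(a, b, class_id, n_pts))
        except ValueError:
            n_empty += 1
    if n_empty:
        warnings.warn(f"{n_empty} adjacent pairs skipped (empty mask)",
                      stacklevel=2)
    tc = float(np.mean(costs)) if costs else float("nan")
    return tc, n_empty


def tc_dataset(videos, class_id: int | None = None,
               n_pts: int = DEFAULT_N_PTS) -> float:
    """Mean of per-video TC over a collection of mask sequences."""
    scores = []
    for masks in videos:
        tc, _ = tc_video(masks, class_id, n_pts)
        if np.isfinite(tc):
            scores.append(tc)
    if not scores:
        raise ValueError("no video produced a finite TC")
    return float(np.mean(scores))


def tcd(series: DiceSeries) -> float:
    """Mean absolute adjacent-frame dice change, per video then over videos."""
    if isinstance(series, (list, tuple)):
        series = DiceSeries(values=list(series))
    per_video = []
    for v in series.values:
        if len(v) < 2:
            raise ValueError("each video needs at least 2 frames for TCD")
        per_video.append(float(np.mean(np.abs(np.diff(v)))))
    return float(np.mean(per_video))
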