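"""Cardiac-cycle phase detection and keypoint-based dimension measurement.

Phase detection follows the standard pipeline: per-frame LV area curve →
Savitzky–Golay smoothing (width 13, order 3) → peak detection; local maxima
of the smoothed curve are end-diastole (ED) frames and local minima are
end-systole (ES).  Detected phases are matched to ground truth within a
±10-frame window.

Measurements come from keypoint heatmaps: the score-weighted centroid of
pixels above a 0.3 confidence threshold gives each endpoint, and the
dimension is the endpoint distance times the pixel spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .phantom import AreaCurve

__all__ = [
    "PhaseSet",
    "MeasurementResult",
    "lv_area_series",
    "savgol_smooth",
    "detect_phases",
    "phase_mae",
    "heatmap_to_point",
    "measure_dimension",
    "measure_from_heatmaps",
    "HEATMAP_THRESHOLD",
    "MATCH_WINDOW",
]

HEATMAP_THRESHOLD = 0.3
MATCH_WINDOW = 10
_LINE_NAMES = ("IVS", "LVID", "LVPW")


@dataclass
class PhaseSet:
    """Detected ED (peak) and ES (valley) frame indices, sorted."""

    ed: list
    es: list

    def __post_init__(self):
        self.ed = sorted(int(i) for i in self.ed)
        self.es = sorted(int(i) for i in self.es)


@dataclass
class MeasurementResult:
    """Per-line endpoints (px, sub-pixel) and length (mm)."""

    points: dict  # name -> (begin, end) or None
    lengths_mm: dict  # name -> float or None


def lv_area_series(labels: np.ndarray, lv_class: int, mm_per_px: float = 1.0,
                   frame_rate: float | None = None) -> AreaCurve:
    """Per-frame LV pixel count × mm_per_px² from full-video label maps."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("expected a (n_frames, h, w) label stack")
    counts = (labels == lv_class).sum(axis=(1, 2)).astype(np.float64)
    return AreaCurve(values=counts * mm_per_px**2, frame_rate=frame_rate)


def savgol_smooth(curve: AreaCurve, width: int = 13, order: int = 3) -> AreaCurve:
    """Savitzky–Golay least-squares smoothing (edges by truncated-window fit).

    A curve shorter than ``width`` falls back to the largest feasible odd
    width with a warning; curves too short for the polynomial order are
    returned unchanged.
    """
    if width % 2 == 0 or width <= order:
        raise ValueError("width must be odd and greater than the order")
    values = np.asarray(curve.values, dtype=np.float64)
    n = len(values)
    if n < width:
        fallback = n if n % 2 == 1 else n - 1
        if fallback <= order:
            warnings.warn("curve too short to smooth; returning unchanged",
                          stacklevel=2)
            return AreaCurve(values=values.copy(), frame_rate=curve.frame_rate)
        warnings.warn(
            f"curve of length {n} shorter than filter width {width}; "
            f"using width {fallback}", stacklevel=2)
        width = fallback
    smoothed = savgol_filter(values, window_length=width, polyorder=order,
                             mode="interp")
    return AreaCurve(values=np.maximum(smoothed, 0.0), frame_rate=curve.frame_rate)


def _min_separation(values: np.ndarray) -> int:
    """max(4, ⌊0.5·median cycle estimate⌋), cycle estimated from rough peaks."""
    rough, _ = find_peaks(values, distance=4)
    if len(rough) >= 2:
        est = float(np.median(np.diff(rough)))
    else:
        valleys, _ = find_peaks(-values, distance=4)
        est = float(np.median(np.diff(valleys))) if len(valleys) >= 2 else 0.0
    return max(4, int(np.floor(0.5 * est)))


def detect_phases(curve: AreaCurve) -> PhaseSet:
    """Peaks → ED, valleys → ES on a (smoothed) area curve.

    Minimum peak separation is max(4, half the estimated cycle length);
    plateau ties resolve to the leftmost index.  A monotone curve yields an
    empty (flagged) phase set.
    """
    values = np.asarray(curve.values, dtype=np.float64)
    if len(values) < 3:
        return PhaseSet(ed=[], es=[])
    sep = _min_separation(values)
    _, ed_props = find_peaks(values, distance=sep, plateau_size=1)
    _, es_props = find_peaks(-values, distance=sep, plateau_size=1)
    ed = ed_props["left_edges"]  # plateau ties resolve to the leftmost index
    es = es_props["left_edges"]
    if len(ed) == 0 and len(es) == 0:
        warnings.warn("no extrema detected (monotone or flat curve)",
                      stacklevel=2)
    return PhaseSet(ed=list(ed), es=list(es))


def phase_mae(pred, gt, window: int = MATCH_WINDOW):
    """Greedy nearest one-to-one matching of predicted to GT indices.

    Accepts PhaseSet pairs (ED matched to ED, ES to ES) or plain index
    lists.  Returns ``(mae, n_matched, n_missed_gt, n_spurious)``; MAE is
    over matched pairs only, unmatched counts are reported separately.
    """
    if isinstance(pred, PhaseSet) and isinstance(gt, PhaseSet):
        r_ed = _match_one(pred.ed, gt.ed, window)
        r_es = _match_one(pred.es, gt.es, window)
        errors = r_ed[0] + r_es[0]
        mae = float(np.mean(errors)) if errors else float("nan")
        return (mae, len(errors), r_ed[2] + r_es[2], r_ed[3] + r_es[3])
    errors, matched, missed, spurious = _match_one(list(pred), list(gt), window)
    mae = float(np.mean(errors)) if errors else float("nan")
    return mae, matched, missed, spurious


def _match_one(pred: list, gt: list, window: int):
    candidates = sorted(
        ((abs(p - g), i, j) for i, p in enumerate(pred) for j, g in enumerate(gt)
         if abs(p - g) <= window),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_p, used_g = set(), set()
    errors = []
    for d, i, j in candidates:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        errors.append(float(d))
    return errors, len(errors), len(gt) - len(used_g), len(pred) - len(used_p)


def heatmap_to_point(heatmap: np.ndarray,
                     threshold: float = HEATMAP_THRESHOLD):
    """Score-weighted centroid of supra-threshold pixels, or None.

    Pixels scoring below ``threshold`` are ignored; if none remain, the
    point is unavailable (structure not confidently visible).
    """
    hm = np.asarray(heatmap, dtype=np.float64)
    if hm.min() < -1e-9 or hm.max() > 1 + 1e-9:
        raise ValueError("heatmap values must lie in [0, 1]")
    mask = hm >= threshold
    if not mask.any():
        return None
    rr, cc = np.nonzero(mask)
    w = hm[rr, cc]
    return (float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum()))


def measure_dimension(p_begin, p_end, mm_per_px: float) -> float:
    """Euclidean endpoint distance × pixel spacing (mm)."""
    if p_begin is None or p_end is None:
        raise ValueError("both endpoints are required")
    d = np.linalg.norm(np.asarray(p_end, float) - np.asarray(p_begin, float))
    return float(d * mm_per_px)


def measure_from_heatmaps(maps: np.ndarray, mm_per_px: float,
                          threshold: float = HEATMAP_THRESHOLD) -> MeasurementResult:
    """Decode a 6-channel heatmap stack into the three line measurements."""
    maps = np.asarray(maps)
    if maps.shape[0] != 6:
        raise ValueError("expected 6 heatmap channels (begin/end × 3 lines)")
    points, lengths = {}, {}
    for k, name in enumerate(_LINE_NAMES):
        p0 = heatmap_to_point(maps[2 * k], threshold)
        p1 = heatmap_to_point(maps[2 * k + 1], threshold)
        if p0 is None or p1 is None:
            points[name] = None
            lengths[name] = None
        else:
            points[name] = (p0, p1)
            lengths[name] = measure_dimension(p0, p1, mm_per_px)
    return MeasurementResult(points=points, lengths_mm=lengths)
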