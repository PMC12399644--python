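"""Synthetic beating-heart phantom.

Generates echo-like grayscale videos with full ground truth: dense label
maps for seven structures (background, LA, IVS, LVPW, LV, RV, RVAW),
constructed ED/ES frame indices, measurement-line keypoints and the
per-cycle period schedule.  Everything is analytic, so every other module
has an exact oracle to train and test against without any download.

Geometry
--------
The LV cavity is an ellipse whose semiaxes scale by ``s(t) = 1 + a·g(φ)``,
where ``g`` is an asymmetric raised cosine with a single maximum (ED, g=+1)
and minimum (ES, g=−1) per cycle — systole occupies a fraction
``SYSTOLE_FRACTION`` of the cycle, mimicking the faster contraction of real
hearts.  IVS/LVPW are constant-thickness half-shells hugging the scaled LV
boundary; RV (with its anterior-wall shell) and LA are nearby ellipses
deforming coherently.  Frames are the structure intensity map multiplied by
gamma-distributed speckle.  The LV is painted last, so its rendered pixel
set is exactly the analytic ellipse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomConfig",
    "VideoClip",
    "PhantomAnnotation",
    "SampledClip",
    "AreaCurve",
    "CLASS_NAMES",
    "SYSTOLE_FRACTION",
    "SEGMENT_NAMES",
    "pulsation_waveform",
    "generate_phantom",
    "sample_clip",
    "gt_area_curve",
    "write_phantom",
    "load_phantom",
]

CLASS_NAMES = ("background", "LA", "IVS", "LVPW", "LV", "RV", "RVAW")
LV_CLASS = 4
SEGMENT_NAMES = ("IVS", "LVID", "LVPW")
# systole occupies slightly less than half the cycle (faster contraction);
# 0.45 keeps the raised-cosine asymmetric while mild enough that a 13/3
# Savitzky-Golay fit preserves the discrete extrema at the default period
SYSTOLE_FRACTION = 0.45

# base intensities before speckle (blood pools dark, myocardium bright)
_INTENSITY = {0: 0.12, 1: 0.25, 2: 0.75, 3: 0.70, 4: 0.20, 5: 0.24, 6: 0.65}


@dataclass
class PhantomConfig:
    image_size: tuple[int, int] = (64, 64)
    n_frames: int = 40
    base_period: int = 20
    pulsation_amplitude: float = 0.2
    n_classes: int = 7
    speckle_strength: float = 0.3
    arrhythmia: bool = False
    period_jitter: float = 0.2
    mm_per_px: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pulsation_amplitude < 0.5):
            raise ValueError("pulsation_amplitude must be in [0, 0.5)")
        if self.base_period < 4:
            raise ValueError("base_period must be at least 4 frames")
        if self.n_frames < self.base_period:
            raise ValueError("n_frames must cover at least one cycle")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be non-negative")
        if self.n_classes < 2 or self.n_classes > 7:
            raise ValueError("n_classes must be between 2 and 7")


@dataclass
class VideoClip:
    """Frame stack with normalized, strictly increasing times in [0, 1]."""

    frames: np.ndarray  # (n, h, w) float in [0, 1]
    times: np.ndarray  # (n,) strictly increasing within [0, 1]
    mm_per_px: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frame count must equal number of timesteps")
        if self.times.size and (
            np.any(np.diff(self.times) <= 0)
            or self.times[0] < -1e-12
            or self.times[-1] > 1 + 1e-12
        ):
            raise ValueError("times must be strictly increasing within [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class PhantomAnnotation:
    labels: np.ndarray  # (n, h, w) int
    ed_frames: list[int]
    es_frames: list[int]
    segments: dict[int, dict[str, tuple[tuple[float, float], tuple[float, float]]]]
    cycle_schedule: list[float]
    mm_per_px: float = 1.0
    scale: np.ndarray | None = None  # analytic s(t) per frame, for oracles


@dataclass
class AreaCurve:
    values: np.ndarray  # per-frame area
    frame_rate: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("areas must be non-negative")


def pulsation_waveform(phase: np.ndarray) -> np.ndarray:
    """Asymmetric raised cosine g(φ): +1 at φ=0 (ED), −1 at φ=SYSTOLE_FRACTION (ES).

    C¹-smooth, periodic with period 1, one max and one min per cycle.
    """
    phi = np.mod(phase, 1.0)
    f = SYSTOLE_FRACTION
    return np.where(
        phi < f,
        np.cos(np.pi * phi / f),
        -np.cos(np.pi * (phi - f) / (1.0 - f)),
    )


def _cycle_layout(config: PhantomConfig, rng: np.random.Generator):
    """Per-frame phase plus constructed ED/ES indices and period schedule."""
    ed_offset = max(1, int(round(0.3 * config.base_period)))
    periods: list[float] = []
    ed_times = [float(ed_offset)]
    # cover [0, n_frames] with cycles; the segment before the first ED reuses
    # the first cycle's period
    while ed_times[-1] < config.n_frames:
        if config.arrhythmia:
            jit = config.period_jitter * rng.uniform(-1.0, 1.0)
            p = max(4.0, round(config.base_period * (1.0 + jit)))
        else:
            p = float(config.base_period)
        periods.append(p)
        ed_times.append(ed_times[-1] + p)

    j = np.arange(config.n_frames, dtype=np.float64)
    phase = np.empty_like(j)
    # before the first ED: extrapolate backwards with the first period
    first = j < ed_times[0]
    phase[first] = (j[first] - ed_times[0]) / periods[0]
    for k, p in enumerate(periods):
        lo, hi = ed_times[k], ed_times[k] + p
        sel = (j >= lo) & (j < hi)
        phase[sel] = (j[sel] - lo) / p

    ed_frames = [int(t) for t in ed_times if 0 <= t < config.n_frames]
    es_frames = []
    s_wave = pulsation_waveform(phase)
    for k, p in enumerate(periods):
        lo = int(ed_times[k])
        hi = min(int(ed_times[k] + p), config.n_frames)
        # only cycles whose analytic minimum lies inside the video
        if ed_times[k] + SYSTOLE_FRACTION * p < config.n_frames - 0.5 and lo < hi:
            es_frames.append(lo + int(np.argmin(s_wave[lo:hi])))
    return phase, ed_frames, es_frames, periods


def _ellipse_mask(h, w, cr, cc, ar, ac):
    rr, cols = np.ogrid[:h, :w]
    return ((rr - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0


def _geometry(config: PhantomConfig):
    h, w = config.image_size
    return {
        "lv_center": (0.56 * h, 0.46 * w),
        "lv_axes": (0.155 * h, 0.225 * w),  # (row semiaxis, col semiaxis)
        "ivs_th": max(2.0, 0.055 * h),
        "pw_th": max(2.0, 0.05 * h),
        "rvaw_th": max(1.5, 0.035 * h),
        "rv_axes": (0.075 * h, 0.16 * w),
        "la_center": (0.62 * h, 0.82 * w),
        "la_axes": (0.11 * h, 0.10 * w),
    }


def _render_frame(config: PhantomConfig, s: float):
    """Rasterize label map for a single frame at LV scale factor ``s``."""
    h, w = config.image_size
    g = _geometry(config)
    cr, cc = g["lv_center"]
    ar, ac = g["lv_axes"]
    a1, b1 = ar * s, ac * s

    labels = np.zeros((h, w), dtype=np.int64)
    rows = np.arange(h)[:, None]

    def paint(mask, cls):
        if cls < config.n_classes:
            labels[mask] = cls

    # LA: antiphase accessory chamber (fills during ventricular systole)
    sa = 1.0 - 0.5 * (s - 1.0)
    lar, lac = g["la_center"]
    paint(_ellipse_mask(h, w, lar, lac, g["la_axes"][0] * sa, g["la_axes"][1] * sa), 1)

    # RV sits above the IVS; deforms coherently (60 % of the LV excursion)
    srv = 1.0 + 0.6 * (s - 1.0)
    rv_ar, rv_ac = g["rv_axes"][0] * srv, g["rv_axes"][1] * srv
    rv_cr = cr - a1 - g["ivs_th"] - rv_ar - 1.0
    rv_cc = cc + 0.04 * w
    rvaw = _ellipse_mask(h, w, rv_cr, rv_cc, rv_ar + g["rvaw_th"], rv_ac + g["rvaw_th"])
    rvaw &= ~_ellipse_mask(h, w, rv_cr, rv_cc, rv_ar, rv_ac)
    rvaw &= rows < rv_cr
    paint(rvaw, 6)
    paint(_ellipse_mask(h, w, rv_cr, rv_cc, rv_ar, rv_ac), 5)

    # myocardial shells: constant thickness outside the scaled LV boundary
    shell_ivs = _ellipse_mask(h, w, cr, cc, a1 + g["ivs_th"], b1 + g["ivs_th"])
    shell_pw = _ellipse_mask(h, w, cr, cc, a1 + g["pw_th"], b1 + g["pw_th"])
    lv = _ellipse_mask(h, w, cr, cc, a1, b1)
    paint(shell_ivs & ~lv & (rows < cr), 2)
    paint(shell_pw & ~lv & (rows >= cr), 3)
    paint(lv, 4)  # LV last: rendered pixels = analytic ellipse exactly
    return labels


def _segments_for_frame(config: PhantomConfig, s: float):
    """Measurement keypoints on the vertical line through the LV centre."""
    g = _geometry(config)
    cr, cc = g["lv_center"]
    a1 = g["lv_axes"][0] * s
    top, bot = cr - a1, cr + a1
    return {
        "IVS": ((top - g["ivs_th"], cc), (top, cc)),
        "LVID": ((top, cc), (bot, cc)),
        "LVPW": ((bot, cc), (bot + g["pw_th"], cc)),
    }


def generate_phantom(config: PhantomConfig):
    """Render a phantom video and its full ground-truth annotation.

    Deterministic for a fixed config+seed (bitwise).
    """
    rng = np.random.default_rng(config.seed)
    phase, ed_frames, es_frames, periods = _cycle_layout(config, rng)
    s = 1.0 + config.pulsation_amplitude * pulsation_waveform(phase)

    h, w = config.image_size
    n = config.n_frames
    labels = np.empty((n, h, w), dtype=np.int64)
    frames = np.empty((n, h, w), dtype=np.float64)
    lut = np.array([_INTENSITY[c] for c in range(7)])
    for j in range(n):
        labels[j] = _render_frame(config, float(s[j]))
        intensity = lut[labels[j]]
        if config.speckle_strength > 0:
            k = 1.0 / config.speckle_strength**2
            noise = rng.gamma(shape=k, scale=1.0 / k, size=(h, w))
            frame = intensity * noise
        else:
            frame = intensity.copy()
        frames[j] = np.clip(frame, 0.0, 1.0)

    times = np.arange(n) / max(n - 1, 1)
    clip = VideoClip(frames=frames, times=times, mm_per_px=config.mm_per_px)
    segments = {j: _segments_for_frame(config, float(s[j])) for j in range(n)}
    ann = PhantomAnnotation(
        labels=labels,
        ed_frames=ed_frames,
        es_frames=es_frames,
        segments=segments,
        cycle_schedule=list(periods),
        mm_per_px=config.mm_per_px,
        scale=s,
    )
    return clip, ann


@dataclass
class SampledClip:
    """A training/eval sample: sparse inputs plus dense supervision targets."""

    frames: np.ndarray  # (n_input, h, w)
    tau: np.ndarray  # (n_input,) uniform nodes in [0, 1]
    target_times: np.ndarray  # S: (2*n_input - 1,) uniform nodes
    frame_indices: np.ndarray  # original indices of the input frames
    target_indices: np.ndarray  # original indices of every spanned frame
    recon_targets: np.ndarray  # (|S|, h, w) real frames at S
    labeled_node: int  # index into S of the annotated node
    label: np.ndarray  # (h, w) segmentation at the annotated frame
    labeled_frame: int  # original index of the annotated frame
    segments: dict | None = None
    mm_per_px: float = 1.0


def sample_clip(video: VideoClip, annotation: PhantomAnnotation,
                labeled_frame: int, n_input: int = 4, stride: int = 2,
                policy: str = "eval",
                rng: np.random.Generator | None = None) -> SampledClip:
    """Draw a sparse input window around an annotated frame.

    ``policy='eval'`` pins the labeled frame to the last input; ``'train'``
    places it uniformly at random among the inputs (pass ``rng`` for
    reproducibility).  Input times are ``n_input`` uniform nodes in [0, 1];
    the target times ``S`` are the ``2·n_input − 1`` uniform nodes covering
    every spanned frame.
    """
    if n_input < 1:
        raise ValueError("n_input must be >= 1")
    if policy not in ("eval", "train"):
        raise ValueError(f"unknown policy {policy!r}")
    n = video.n_frames
    span = 1 + stride * (n_input - 1)
    if span > n:
        raise ValueError(f"window of {span} frames does not fit in video of {n}")
    if not (0 <= labeled_frame < n):
        raise ValueError("annotated frame outside the video")

    if n_input == 1:
        pos = 0
    elif policy == "eval":
        pos = n_input - 1
    else:
        if rng is None:
            rng = np.random.default_rng()
        lo = max(0, n_input - 1 - (n - 1 - labeled_frame) // stride)
        hi = min(n_input - 1, labeled_frame // stride)
        if lo > hi:
            raise ValueError("annotated frame outside any feasible window")
        pos = int(rng.integers(lo, hi + 1))
    start = labeled_frame - stride * pos
    if start < 0 or start + stride * (n_input - 1) >= n:
        raise ValueError("annotated frame outside the sampling window")

    frame_idx = start + stride * np.arange(n_input)
    if n_input > 1:
        # S covers every spanned frame at half the input stride
        half = stride / 2.0
        target_idx = start + np.round(np.arange(2 * n_input - 1) * half).astype(int)
        tau = np.arange(n_input) / (n_input - 1)
        s_nodes = np.arange(2 * n_input - 1) / (2 * n_input - 2)
    else:
        target_idx = np.array([start])
        tau = np.array([0.0])
        s_nodes = np.array([0.0])

    labeled_node = int(np.where(target_idx == labeled_frame)[0][0])
    return SampledClip(
        frames=video.frames[frame_idx],
        tau=tau,
        target_times=s_nodes,
        frame_indices=frame_idx,
        target_indices=target_idx,
        recon_targets=video.frames[target_idx],
        labeled_node=labeled_node,
        label=annotation.labels[labeled_frame],
        labeled_frame=labeled_frame,
        segments=annotation.segments.get(labeled_frame),
        mm_per_px=video.mm_per_px,
    )


def gt_area_curve(annotation: PhantomAnnotation, lv_class: int = LV_CLASS,
                  mm_per_px: float | None = None) -> AreaCurve:
    """Per-frame LV pixel count × mm_per_px² from the ground-truth labels."""
    import warnings

    if mm_per_px is None:
        mm_per_px = annotation.mm_per_px
    counts = (annotation.labels == lv_class).sum(axis=(1, 2)).astype(np.float64)
    if counts.max() == 0:
        warnings.warn(f"class {lv_class} absent from all label maps", stacklevel=2)
    return AreaCurve(values=counts * mm_per_px**2)


# -- disk round-trip (plain-text / PNG, for the CLI) -----------------------

def write_phantom(out_dir, clip: VideoClip, ann: PhantomAnnotation) -> None:
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    for j in range(clip.n_frames):
        iio.imwrite(out / "frames" / f"{j:04d}.png",
                    (clip.frames[j] * 255).round().astype(np.uint8))
        iio.imwrite(out / "labels" / f"{j:04d}.png",
                    ann.labels[j].astype(np.uint8))
    meta = {
        "times": clip.times.tolist(),
        "mm_per_px": clip.mm_per_px,
        "ed_frames": ann.ed_frames,
        "es_frames": ann.es_frames,
        "cycle_schedule": ann.cycle_schedule,
        "segments": {
            str(j): {name: [list(p0), list(p1)] for name, (p0, p1) in segs.items()}
            for j, segs in ann.segments.items()
        },
    }
    (out / "annotation.json").write_text(json.dumps(meta, indent=2))


def load_phantom(out_dir):
    import imageio.v3 as iio

    out = Path(out_dir)
    meta = json.loads((out / "annotation.json").read_text())
    frame_files = sorted((out / "frames").glob("*.png"))
    frames = np.stack([iio.imread(f).astype(np.float64) / 255.0 for f in frame_files])
    labels = np.stack([iio.imread(f).astype(np.int64)
                       for f in sorted((out / "labels").glob("*.png"))])
    clip = VideoClip(frames=frames, times=np.asarray(meta["times"]),
                     mm_per_px=meta["mm_per_px"])
    segments = {
        int(j): {name: (tuple(p0), tuple(p1)) for name, (p0, p1) in segs.items()}
        for j, segs in meta["segments"].items()
    }
    ann = PhantomAnnotation(
        labels=labels,
        ed_frames=list(meta["ed_frames"]),
        es_frames=list(meta["es_frames"]),
        segments=segments,
        cycle_schedule=list(meta["cycle_schedule"]),
        mm_per_px=meta["mm_per_px"],
    )
    return clip, ann
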