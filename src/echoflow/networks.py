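"""Convolutional encoder/decoders and the full continuous-time video model.

The model is an encoder–decoder with a latent-ODE bottleneck:

* a shared convolutional encoder (four conv pairs, three 2×2 max-poolings)
  embeds every input frame at 1/8 resolution;
* a backward-in-time ODE-RNN produces the clip dynamics code ``D`` and the
  initial latent state ``h_s0``;
* one adaptive forward solve with dense output yields latent states at all
  requested target times ``S``;
* each latent state is decoded twice — a reconstruction decoder produces a
  3-channel image, and a target decoder (fed skip connections *from the
  reconstruction decoder*, not the encoder) produces segmentation logits or
  keypoint heatmaps.

A small per-frame U-Net-style baseline (encoder skips, no temporal model)
is included purely as the consistency comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Conv2d, Module, Tensor, concat, maxpool2x2, relu,
                       upsample2x)
from .ode import (DerivativeNet, LatentODEEncoder, OdeSolveConfig,
                  odeint_dense)
from .phantom import VideoClip

__all__ = [
    "EncoderConfig",
    "SegmentationSequence",
    "HeatmapSet",
    "Encoder",
    "ReconstructionDecoder",
    "TargetDecoder",
    "EchoODEModel",
    "BaselineSegmenter",
    "N_HEATMAPS",
]

N_HEATMAPS = 6  # begin/end for IVS, LVID, LVPW


@dataclass
class EncoderConfig:
    channel_pairs: tuple = ((32, 32), (64, 64), (128, 128), (256, 256))
    kernel: int = 3
    width_scale: int = 1

    def __post_init__(self):
        if len(self.channel_pairs) != 4:
            raise ValueError("encoder has exactly 4 stages")
        if self.width_scale < 1:
            raise ValueError("width_scale must be >= 1")

    @property
    def widths(self) -> list[tuple[int, int]]:
        return [
            (max(c1 // self.width_scale, 2), max(c2 // self.width_scale, 2))
            for c1, c2 in self.channel_pairs
        ]

    @property
    def bottleneck_channels(self) -> int:
        return self.widths[-1][1]


@dataclass
class SegmentationSequence:
    """Per-timestep class probabilities and argmax label maps."""

    probs: np.ndarray  # (|S|, n_classes, h, w), softmax-normalized
    labels: np.ndarray  # (|S|, h, w) int
    times: np.ndarray  # S

    def __post_init__(self):
        if self.probs.shape[0] != len(self.times):
            raise ValueError("one probability map per target time required")


@dataclass
class HeatmapSet:
    maps: np.ndarray  # (|S|, 6, h, w) in [0, 1]
    times: np.ndarray


class Encoder(Module):
    """Four conv pairs with ReLU, 2×2 max-pooling between stages."""

    def __init__(self, c_in: int, config: EncoderConfig, rng: np.random.Generator):
        self.stages = []
        c = c_in
        for c1, c2 in config.widths:
            self.stages.append(
                [Conv2d(c, c1, config.kernel, rng), Conv2d(c1, c2, config.kernel, rng)]
            )
            c = c2
        self.config = config

    def __call__(self, x: Tensor):
        feats = []
        for i, (conv1, conv2) in enumerate(self.stages):
            if i > 0:
                x = maxpool2x2(x)
            x = relu(conv2(relu(conv1(x))))
            feats.append(x)
        return feats[-1], feats


class _UpStage(Module):
    """×2 nearest upsample, optional same-resolution skip concat, two convs."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        self.conv1 = Conv2d(c_in, c_out, kernel, rng)
        self.conv2 = Conv2d(c_out, c_out, kernel, rng)

    def __call__(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        x = upsample2x(x)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(
                    f"skip resolution {skip.shape} incompatible with {x.shape}"
                )
            x = concat([x, skip], axis=1)
        return relu(self.conv2(relu(self.conv1(x))))


class ReconstructionDecoder(Module):
    """Mirrors the encoder in reverse; keeps per-stage features for skips."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 c_out: int = 3):
        widths = config.widths
        chans = [widths[3][1], widths[2][1], widths[1][1], widths[0][1]]
        self.up = [
            _UpStage(chans[i], chans[i + 1], config.kernel, rng) for i in range(3)
        ]
        self.head = Conv2d(chans[3], c_out, 1, rng)

    def __call__(self, h: Tensor):
        feats = []
        x = h
        for stage in self.up:
            x = stage(x)
            feats.append(x)  # resolutions 1/4, 1/2, 1 of the input
        return self.head(x), feats


class TargetDecoder(Module):
    """Task decoder; concatenates reconstruction-decoder features per stage."""

    def __init__(self, config: EncoderConfig, n_out: int,
                 rng: np.random.Generator, use_skips: bool = True):
        widths = config.widths
        chans = [widths[3][1], widths[2][1], widths[1][1], widths[0][1]]
        self.use_skips = use_skips
        self.up = []
        for i in range(3):
            c_in = chans[i] + (chans[i + 1] if use_skips else 0)
            self.up.append(_UpStage(c_in, chans[i + 1], config.kernel, rng))
        self.head = Conv2d(chans[3], n_out, 1, rng)

    def __call__(self, h: Tensor, skips: list[Tensor] | None = None) -> Tensor:
        if self.use_skips and skips is None:
            raise ValueError("skip features required by a skip-enabled decoder")
        x = h
        for i, stage in enumerate(self.up):
            x = stage(x, skips[i] if self.use_skips else None)
        return self.head(x)


class EchoODEModel(Module):
    """Full continuous-time video network.

    ``mode`` selects the task head: ``'segmentation'`` (n_classes softmax
    channels) or ``'measurement'`` (6 sigmoid heatmap channels).
    """

    def __init__(self, n_classes: int = 7, mode: str = "segmentation",
                 encoder_config: EncoderConfig | None = None,
                 solve_config: OdeSolveConfig | None = None,
                 use_skips: bool = True, use_reconstruction: bool = True,
                 seed: int = 0):
        if mode not in ("segmentation", "measurement"):
            raise ValueError(f"unknown mode {mode!r}")
        rng = np.random.default_rng(seed)
        self.encoder_config = encoder_config or EncoderConfig()
        self.solve_config = solve_config or OdeSolveConfig()
        self.mode = mode
        self.n_classes = n_classes
        self.use_reconstruction = use_reconstruction
        c_lat = self.encoder_config.bottleneck_channels
        self.encoder = Encoder(3, self.encoder_config, rng)
        self.latent_encoder = LatentODEEncoder(c_lat, c_lat, rng)
        self.f_dec = DerivativeNet(c_lat, c_lat, rng)
        self.recon_decoder = ReconstructionDecoder(self.encoder_config, rng)
        n_out = n_classes if mode == "segmentation" else N_HEATMAPS
        self.target_decoder = TargetDecoder(
            self.encoder_config, n_out, rng,
            use_skips=use_skips and use_reconstruction,
        )

    # -- pieces -----------------------------------------------------------
    def encode_frames(self, frames: np.ndarray) -> list[Tensor]:
        """frames: (n, T, h, w) grayscale in [0,1] → per-time bottleneck feats."""
        frames = _pad_to_multiple_of_8(frames)
        n, T = frames.shape[:2]
        feats = []
        for t in range(T):
            x = Tensor(np.repeat(frames[:, t][:, None], 3, axis=1))
            bottleneck, _ = self.encoder(x)
            feats.append(bottleneck)
        return feats

    def forward(self, frames: np.ndarray, tau, S):
        """Run the full pipeline on a batch of clips.

        frames: (n_batch, n_input, h, w); tau: input times; S: target times.
        Returns (reconstructions, task_outputs): lists over S of Tensors
        ((n,3,h,w) images and (n,n_out,h,w) raw logits).
        """
        S = [float(s) for s in S]
        feats = self.encode_frames(frames)
        dyn, h0 = self.latent_encoder(feats, tau, self.solve_config)
        f = self.f_dec.bind(dyn.D)
        states = odeint_dense(lambda t, y: f(y), h0.h, 0.0, S, self.solve_config)
        recons, outputs = [], []
        for st in states:
            if self.use_reconstruction:
                img, skips = self.recon_decoder(st)
            else:
                img, skips = None, None
            recons.append(img)
            outputs.append(self.target_decoder(st, skips))
        return recons, outputs

    # -- inference --------------------------------------------------------
    def predict(self, clip_frames: np.ndarray, tau, S):
        """Inference on one clip; returns task output + reconstructions."""
        h, w = clip_frames.shape[-2:]
        recons, outputs = self.forward(clip_frames[None], tau, S)
        raw = np.stack([o.data[0] for o in outputs])[..., :h, :w]
        times = np.asarray(S, dtype=np.float64)
        if self.mode == "segmentation":
            probs = _np_softmax(raw, axis=1)
            seq = SegmentationSequence(
                probs=probs, labels=probs.argmax(axis=1), times=times
            )
        else:
            seq = HeatmapSet(maps=_np_sigmoid(raw), times=times)
        rec = (
            np.stack([r.data[0] for r in recons])[..., :h, :w]
            if self.use_reconstruction else None
        )
        return seq, rec

    def predict_video(self, video: VideoClip, n_input: int = 4, stride: int = 2):
        """Segment a whole video with sliding dense-output windows."""
        n = video.n_frames
        span = 1 + stride * (n_input - 1)
        if span > n:
            raise ValueError("video shorter than one input window")
        tau = np.arange(n_input) / max(n_input - 1, 1)
        S = np.arange(2 * n_input - 1) / max(2 * n_input - 2, 1)
        out_probs = [None] * n
        start = 0
        while True:
            idx = start + stride * np.arange(n_input)
            seq, _ = self.predict(video.frames[idx], tau, S)
            target_idx = start + np.arange(2 * n_input - 1)
            for k, j in enumerate(target_idx):
                out_probs[j] = seq.probs[k]
            if start + span >= n:
                break
            start = min(start + span - 1, n - span)
        probs = np.stack(out_probs)
        return SegmentationSequence(
            probs=probs, labels=probs.argmax(axis=1), times=video.times
        )


class BaselineSegmenter(Module):
    """Per-frame U-Net-style segmenter (encoder skips, no temporal model)."""

    def __init__(self, n_classes: int = 7,
                 encoder_config: EncoderConfig | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder_config = encoder_config or EncoderConfig()
        self.n_classes = n_classes
        widths = self.encoder_config.widths
        self.encoder = Encoder(3, self.encoder_config, rng)
        chans = [widths[3][1], widths[2][1], widths[1][1], widths[0][1]]
        self.up = []
        for i in range(3):
            self.up.append(
                _UpStage(chans[i] + chans[i + 1], chans[i + 1],
                         self.encoder_config.kernel, rng)
            )
        self.head = Conv2d(chans[3], n_classes, 1, rng)

    def forward(self, frames: np.ndarray) -> Tensor:
        """frames: (n, h, w) → logits (n, n_classes, h, w)."""
        frames = _pad_to_multiple_of_8(frames[:, None])[:, 0]
        x = Tensor(np.repeat(frames[:, None], 3, axis=1))
        bottleneck, enc_feats = self.encoder(x)
        y = bottleneck
        for i, stage in enumerate(self.up):
            y = stage(y, enc_feats[2 - i])  # encoder feature at matching res
        return self.head(y)

    def predict(self, frames: np.ndarray) -> SegmentationSequence:
        h, w = frames.shape[-2:]
        logits = self.forward(frames).data[..., :h, :w]
        probs = _np_softmax(logits, axis=1)
        times = np.arange(frames.shape[0], dtype=np.float64)
        times = times / max(len(times) - 1, 1)
        return SegmentationSequence(probs=probs, labels=probs.argmax(axis=1),
                                    times=times)


def _pad_to_multiple_of_8(frames: np.ndarray) -> np.ndarray:
    h, w = frames.shape[-2:]
    ph, pw = (-h) % 8, (-w) % 8
    if ph or pw:
        pad = [(0, 0)] * (frames.ndim - 2) + [(0, ph), (0, pw)]
        frames = np.pad(frames, pad, mode="edge")
    return frames


def _np_softmax(x, axis):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _np_sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
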