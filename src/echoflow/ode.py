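"""Continuous-time machinery.

Contains the ConvGRU cell, the dynamics-conditioned derivative network, an
adaptive Dormand–Prince 4(5) integrator with dense output, and the
backward-in-time latent-ODE encoder that turns a sequence of per-frame
features into a per-clip dynamics code ``D`` and an initial latent state.

The integrator operates on :class:`~echoflow.autodiff.Tensor` states, so
gradients flow through every accepted solver step and every dense-output
interpolation (discretize-then-optimize).  Step-size control runs on
detached values and therefore does not enter the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Conv2d, Module, Tensor, concat, sigmoid, tanh

__all__ = [
    "LatentState",
    "DynamicsInfo",
    "OdeSolveConfig",
    "IntegrationFailure",
    "odeint_dense",
    "ode_integrate",
    "ConvGRUCell",
    "DerivativeNet",
    "EncoderDerivativeNet",
    "LatentODEEncoder",
]


@dataclass
class LatentState:
    """Spatial latent grid ``h`` tagged with its time in [0, 1]."""

    h: Tensor
    t: float = 0.0


@dataclass
class DynamicsInfo:
    """Per-clip dynamics code at the latent resolution."""

    D: Tensor


@dataclass
class OdeSolveConfig:
    method: str = "dopri5"
    rtol: float = 1e-4
    atol: float = 1e-4
    epsilon: float = 0.01
    adjoint: bool = False
    max_steps: int = 2000

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("rtol and atol must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.method != "dopri5":
            raise ValueError(f"unsupported solver method {self.method!r}")
        if self.adjoint:
            raise NotImplementedError(
                "only direct backprop through the solver is implemented"
            )


class IntegrationFailure(RuntimeError):
    """Adaptive step size underflow; carries the time reached."""

    def __init__(self, t_reached: float):
        super().__init__(f"ODE solver step size underflow at t={t_reached:.6g}")
        self.t_reached = t_reached


# Dormand–Prince 4(5) tableau.
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = [
    [],
    [1 / 5],
    [3 / 40, 9 / 40],
    [44 / 45, -56 / 15, 32 / 9],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
]
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200,
                187 / 2100, 1 / 40])
_E = _B5 - _B4
# Dense-output coefficients (Hairer, Nørsett & Wanner, DOPRI5 continuous ext.)
_D = np.array([
    -12715105075.0 / 11282082432.0,
    0.0,
    87487479700.0 / 32700410799.0,
    -10690763975.0 / 1880347072.0,
    701980252875.0 / 199316789632.0,
    -1453857185.0 / 822651844.0,
    69997945.0 / 29380423.0,
])


def _lincomb(terms):
    """Sum of coeff*Tensor pairs, skipping exact zeros."""
    out = None
    for c, t in terms:
        if c == 0.0:
            continue
        piece = t * c
        out = piece if out is None else out + piece
    if out is None:
        raise ValueError("empty linear combination")
    return out


def _error_norm(e, y0, y1, rtol, atol):
    scale = atol + rtol * np.maximum(np.abs(y0), np.abs(y1))
    return float(np.sqrt(np.mean((e / scale) ** 2)))


def _dense_eval(theta, h, y0, y1, ks):
    """4th-order continuous extension of an accepted dopri5 step."""
    ydiff = y1 - y0
    bspl = ks[0] * h - ydiff
    r4 = ydiff - ks[6] * h - bspl
    r5 = _lincomb([(h * d, k) for d, k in zip(_D, ks)])
    return y0 + (
        (bspl + ((r4 + r5 * (1.0 - theta)) * theta)) * (1.0 - theta) + ydiff
    ) * theta


def odeint_dense(f, y0: Tensor, t0: float, targets, config: OdeSolveConfig):
    """Integrate ``dy/dt = f(t, y)`` from ``t0``, returning states at ``targets``.

    One adaptive solve; intermediate targets are filled in by dense-output
    interpolation of the accepted steps.  ``targets`` must be sorted away
    from ``t0`` (ascending for forward, descending for backward solves).
    """
    targets = [float(t) for t in targets]
    if not targets:
        return []
    diffs = np.diff(targets)
    if not (np.all(diffs >= 0) or np.all(diffs <= 0)):
        raise ValueError("targets must be monotonically sorted")
    t_end = targets[-1]
    direction = np.sign(t_end - t0)
    for t in targets:
        if direction * (t - t0) < -1e-12:
            raise ValueError("targets must lie on one side of t0")

    outputs: dict[int, Tensor] = {}
    pending = sorted(range(len(targets)), key=lambda i: direction * targets[i]) \
        if direction != 0 else list(range(len(targets)))
    pending = [i for i in pending]
    # exact hit at the starting time
    remaining = []
    for i in pending:
        if abs(targets[i] - t0) <= 1e-12:
            outputs[i] = y0
        else:
            remaining.append(i)
    pending = remaining
    if not pending:
        return [outputs[i] for i in range(len(targets))]
    if direction == 0:
        direction = 1.0

    span = abs(t_end - t0)
    h = direction * max(span / 10.0, 1e-6)
    t, y = t0, y0
    k1 = f(t, y)
    rtol, atol = config.rtol, config.atol

    for _ in range(config.max_steps):
        if not pending:
            break
        # never overshoot the last requested time
        if direction * (t + h - t_end) > 0:
            h = t_end - t
        if abs(h) < 1e-14 * max(1.0, abs(t)):
            raise IntegrationFailure(t)
        ks = [k1]
        for i in range(1, 7):
            yi = y + _lincomb([(h * a, k) for a, k in zip(_A[i], ks)])
            ks.append(f(t + _C[i] * h, yi))
        y1 = y + _lincomb([(h * b, k) for b, k in zip(_B5, ks)])
        err_vec = sum(h * e * k.data for e, k in zip(_E, ks) if e != 0.0)
        err = _error_norm(err_vec, y.data, y1.data, rtol, atol)
        if err <= 1.0:  # accept
            t_new = t + h
            still = []
            for i in pending:
                s = targets[i]
                if direction * (s - t_new) <= 1e-12:
                    theta = (s - t) / h
                    if abs(theta - 1.0) < 1e-12:
                        outputs[i] = y1
                    else:
                        outputs[i] = _dense_eval(theta, h, y, y1, ks)
                else:
                    still.append(i)
            pending = still
            t, y = t_new, y1
            k1 = ks[6]  # FSAL
        factor = 0.9 * (err + 1e-16) ** (-0.2)
        h = h * min(10.0, max(0.2, factor))
    if pending:
        raise IntegrationFailure(t)
    return [outputs[i] for i in range(len(targets))]


def ode_integrate(f, h0: LatentState, t0: float, targets,
                  config: OdeSolveConfig | None = None) -> list[LatentState]:
    """Latent-state wrapper around :func:`odeint_dense`."""
    config = config or OdeSolveConfig()
    states = odeint_dense(lambda t, y: f(y), h0.h, t0, targets, config)
    return [LatentState(h=s, t=float(tt)) for s, tt in zip(states, targets)]


class ConvGRUCell(Module):
    """Convolutional GRU: h' = (1-z)⊙h + z⊙h̃ with 3×3 gate convolutions."""

    def __init__(self, c_hidden: int, c_input: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.conv_z = Conv2d(c_hidden + c_input, c_hidden, kernel, rng)
        self.conv_r = Conv2d(c_hidden + c_input, c_hidden, kernel, rng)
        self.conv_h = Conv2d(c_hidden + c_input, c_hidden, kernel, rng)

    def __call__(self, h: Tensor, x: Tensor) -> Tensor:
        if h.shape[2:] != x.shape[2:]:
            raise ValueError(f"spatial mismatch: h {h.shape} vs x {x.shape}")
        hx = concat([h, x], axis=1)
        z = sigmoid(self.conv_z(hx))
        r = sigmoid(self.conv_r(hx))
        cand = tanh(self.conv_h(concat([r * h, x], axis=1)))
        return (1.0 - z) * h + z * cand


def conv_gru_update(cell: ConvGRUCell, h: LatentState, x_feat: Tensor) -> LatentState:
    return LatentState(h=cell(h.h, x_feat), t=h.t)


class DerivativeNet(Module):
    """Dynamics-conditioned derivative: concat(h, D) → conv–tanh–conv–tanh–conv.

    Autonomous (no explicit time input); the final convolution is
    zero-initialized so an untrained model starts as the identity flow.
    """

    def __init__(self, c_state: int, c_dyn: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.conv1 = Conv2d(c_state + c_dyn, c_state, kernel, rng)
        self.conv2 = Conv2d(c_state, c_state, kernel, rng)
        self.conv3 = Conv2d(c_state, c_state, kernel, rng, zero_init=True)

    def __call__(self, h: Tensor, D: Tensor) -> Tensor:
        if D is None:
            raise ValueError("dynamics code D is required by the derivative net")
        if h.shape[2:] != D.shape[2:]:
            raise ValueError(f"spatial mismatch: h {h.shape} vs D {D.shape}")
        x = concat([h, D], axis=1)
        return self.conv3(tanh(self.conv2(tanh(self.conv1(x)))))

    def bind(self, D: Tensor):
        return lambda h: self(h, D)


class EncoderDerivativeNet(Module):
    """Encoder-side derivative f_enc(h): three convolutions on h alone."""

    def __init__(self, c_state: int, rng: np.random.Generator, kernel: int = 3):
        self.conv1 = Conv2d(c_state, c_state, kernel, rng)
        self.conv2 = Conv2d(c_state, c_state, kernel, rng)
        self.conv3 = Conv2d(c_state, c_state, kernel, rng, zero_init=True)

    def __call__(self, h: Tensor) -> Tensor:
        return self.conv3(tanh(self.conv2(tanh(self.conv1(h)))))


class LatentODEEncoder(Module):
    """Backward-in-time ODE-RNN over encoded frame features.

    Runs from the last frame to the first: the hidden state is seeded with
    zeros at t_n + ε, integrated down to t_n, GRU-updated with that frame's
    features, then alternately integrated to the previous node and updated,
    ending at the earliest frame.  The final hidden state is the dynamics
    code ``D``; a single convolution of ``D`` gives the initial decoder
    state ``h_s0``.
    """

    def __init__(self, c_feat: int, c_lat: int, rng: np.random.Generator):
        self.f_enc = EncoderDerivativeNet(c_lat, rng)
        self.gru = ConvGRUCell(c_lat, c_feat, rng)
        self.to_h0 = Conv2d(c_lat, c_lat, 3, rng)
        self.c_lat = c_lat

    def __call__(self, frame_feats: list[Tensor], times,
                 config: OdeSolveConfig | None = None):
        if len(frame_feats) == 0:
            raise ValueError("latent ODE encoder needs at least one frame")
        times = [float(t) for t in times]
        if len(times) != len(frame_feats):
            raise ValueError("times and features must have equal length")
        config = config or OdeSolveConfig()
        n_batch, _, hh, ww = frame_feats[-1].shape
        h = Tensor(np.zeros((n_batch, self.c_lat, hh, ww)))
        t_cur = times[-1] + config.epsilon
        for i in range(len(frame_feats) - 1, -1, -1):
            (h,) = odeint_dense(lambda t, y: self.f_enc(y), h, t_cur,
                                [times[i]], config)
            h = self.gru(h, frame_feats[i])
            t_cur = times[i]
        D = h
        h_s0 = self.to_h0(D)
        return DynamicsInfo(D=D), LatentState(h=h_s0, t=0.0)
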