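"""Feature fusion and the weekly LSTM over venue feature sequences.

Each week's LSTM input fuses the raw venue features with the graph-convolved
ones, X_p^t = delta * X^t + (1 - alpha) * H^t; the recurrence is a standard
LSTM cell with forget/input/output gates shared across venues and tiles.
All functions accept (n, d) matrices (one row per venue) or 1-D vectors, as
plain arrays or autograd Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_array, concat, sigmoid, tanh


@dataclass
class FusionParams:
    """Mixing weights of raw vs convolved features: delta*X + (1-alpha)*H."""

    delta: float = 0.5
    alpha: float = 0.5

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class LstmParams:
    """Gate weights over the concatenation [x, h_{t-1}].

    Every ``W_*`` has shape (input + hidden, hidden); biases have shape
    (hidden,).  ``W_g``/``b_C`` parameterize the candidate cell update.
    """

    W_F: np.ndarray | Tensor
    W_I: np.ndarray | Tensor
    W_O: np.ndarray | Tensor
    W_g: np.ndarray | Tensor
    b_F: np.ndarray | Tensor
    b_I: np.ndarray | Tensor
    b_O: np.ndarray | Tensor
    b_C: np.ndarray | Tensor

    @property
    def hidden_size(self) -> int:
        return as_array(self.W_F).shape[1]

    @property
    def input_size(self) -> int:
        return as_array(self.W_F).shape[0] - self.hidden_size

    @classmethod
    def init(cls, input_size: int, hidden_size: int,
             rng: np.random.Generator | None = None) -> "LstmParams":
        rng = rng or np.random.default_rng(0)
        fan_in = input_size + hidden_size
        lim = 1.0 / np.sqrt(fan_in)

        def w():
            return rng.uniform(-lim, lim, (fan_in, hidden_size))

        return cls(
            W_F=w(), W_I=w(), W_O=w(), W_g=w(),
            b_F=np.zeros(hidden_size), b_I=np.zeros(hidden_size),
            b_O=np.zeros(hidden_size), b_C=np.zeros(hidden_size),
        )


@dataclass
class LstmState:
    """Hidden and cell vectors (rows when the batch is a matrix)."""

    h: np.ndarray | Tensor
    C: np.ndarray | Tensor

    @classmethod
    def zeros(cls, n: int, hidden_size: int) -> "LstmState":
        return cls(h=np.zeros((n, hidden_size)), C=np.zeros((n, hidden_size)))


def fuse(X_t, H_gcn, params: FusionParams):
    """Weighted sum of raw and convolved features (equal shapes required)."""
    if as_array(X_t).shape != as_array(H_gcn).shape:
        raise ValueError("raw and convolved features must share a shape")
    return params.delta * X_t + (1.0 - params.alpha) * H_gcn


def lstm_cell(x, state: LstmState, params: LstmParams) -> LstmState:
    """One LSTM step.

    F, I, O are sigmoid gates of affine maps of [x, h_{t-1}];
    C_t = F * C_{t-1} + I * tanh(W_g [x, h] + b_C); h_t = O * tanh(C_t).
    """
    squeeze = False
    if not isinstance(x, Tensor) and np.asarray(x).ndim == 1:
        x = np.asarray(x, dtype=float)[None, :]
        state = LstmState(h=np.atleast_2d(as_array(state.h)), C=np.atleast_2d(as_array(state.C)))
        squeeze = True
    if not isinstance(x, Tensor) and not np.all(np.isfinite(as_array(x))):
        raise ValueError("non-finite LSTM input")
    xh = concat([x, state.h], axis=1)
    F = sigmoid(xh @ params.W_F + params.b_F)
    I = sigmoid(xh @ params.W_I + params.b_I)
    O = sigmoid(xh @ params.W_O + params.b_O)
    g = tanh(xh @ params.W_g + params.b_C)
    C = F * state.C + I * g
    h = O * tanh(C)
    if squeeze:
        return LstmState(h=as_array(h)[0], C=as_array(C)[0])
    return LstmState(h=h, C=C)


def lstm_forward(series, params: LstmParams, state: LstmState | None = None
                 ) -> tuple[np.ndarray | Tensor, list[LstmState]]:
    """Run the cell over a weekly series; returns (h_T, all states).

    ``series`` is a sequence of (n, input) matrices, one per week, applied in
    order from a zero initial state unless ``state`` is given.
    """
    series = list(series)
    if not series:
        raise ValueError("empty input series")
    first = as_array(series[0])
    n = first.shape[0] if first.ndim == 2 else 1
    if state is None:
        state = LstmState.zeros(n, params.hidden_size)
    states: list[LstmState] = []
    for x in series:
        state = lstm_cell(x, state, params)
        states.append(state)
    return state.h, states
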