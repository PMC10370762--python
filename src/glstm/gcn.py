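"""First-order spectral graph convolution over tile graphs.

The propagation operator is the symmetric normalized adjacency with
self-loops, D^{-1/2} (A + I) D^{-1/2}; stacking layers
H^{(l+1)} = ReLU(A_norm H^{(l)} W^{(l)} + b^{(l)}) lets each venue see its
l-hop neighborhood.  Functions run on plain arrays or autograd Tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import as_array, relu


@dataclass
class GcnParams:
    """Weight/bias chain of the stacked convolution layers."""

    weights: list
    biases: list

    def __post_init__(self):
        if len(self.weights) < 1:
            raise ValueError("need at least one layer")
        if len(self.biases) != len(self.weights):
            raise ValueError("one bias per layer required")
        for i in range(len(self.weights) - 1):
            if as_array(self.weights[i]).shape[1] != as_array(self.weights[i + 1]).shape[0]:
                raise ValueError("layer shapes do not chain")

    @classmethod
    def init(cls, dims: list[int], rng: np.random.Generator | None = None) -> "GcnParams":
        """Uniform +-1/sqrt(fan_in) initialization for dims[0] -> ... -> dims[-1]."""
        rng = rng or np.random.default_rng(0)
        ws, bs = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            lim = 1.0 / np.sqrt(d_in)
            ws.append(rng.uniform(-lim, lim, (d_in, d_out)))
            bs.append(np.zeros(d_out))
        return cls(weights=ws, biases=bs)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalized adjacency with self-loops.

    Returns D^{-1/2} (A + I) D^{-1/2} with D = diag(rowsum(A + I)).  The
    result is symmetric and has spectral radius at most 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    # dividing by sqrt(d_i * d_j) keeps simple rationals (e.g. the 2-node
    # graph's 1/2) exact, unlike multiplying two separate square roots
    return A_hat / np.sqrt(np.outer(d, d))


def gcn_layer(H, A_norm: np.ndarray, W, b):
    """One convolution layer: ReLU(A_norm H W + b)."""
    if as_array(H).shape[1] != as_array(W).shape[0]:
        raise ValueError("feature/weight shapes do not conform")
    return relu(A_norm @ (H @ W) + b)


def gcn_forward(X, A: np.ndarray, params: GcnParams, A_norm: np.ndarray | None = None):
    """Stacked convolution of node features ``X`` over adjacency ``A``.

    ``A_norm`` may be passed to reuse a cached normalized adjacency; it must
    equal ``normalized_adjacency(A)``.
    """
    if A_norm is None:
        A_norm = normalized_adjacency(A)
    H = X
    for W, b in zip(params.weights, params.biases):
        H = gcn_layer(H, A_norm, W, b)
    return H
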