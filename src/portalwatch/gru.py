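"""A small stack of gated recurrent units for metric-stream classification.

The network maps the 4-metric stream of a delivery to a per-segment scalar
output y in (-1, 1), with y > 0 signifying an error and y < 0 a normal
delivery.  The fixed default topology is four GRU layers of 4, 8, 4 and 1
units; the output is the raw hidden state of the final single-unit layer,
which the tanh candidate activation and convex gate mixing already confine
to (-1, 1).

Each layer follows the standard GRU cell (update gate z, reset gate r,
candidate state h~, all with biases):

    z  = sigmoid(Wz x + Uz h + bz)
    r  = sigmoid(Wr x + Ur h + br)
    h~ = tanh(W x + U (r * h) + bh)
    h' = z * h + (1 - z) * h~

All hidden states start at zero.  The "primary" weights — the candidate
input matrices W of every layer, excluding the recurrent (hidden-state)
matrices, the gate weights and all biases — are the set penalised by the
L2 regulariser during training.

Weights are stored as flat parameter vectors for the derivative-free
optimiser; :func:`forward_batch` evaluates many streams at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .simulate import ValidationError

DEFAULT_TOPOLOGY = (4, 4, 8, 4, 1)  # input size then units per layer
DEFAULT_INPUT_SCALE = 0.1  # metric % / 10 before entering the network

_GATE_NAMES = ("w_z", "u_z", "b_z", "w_r", "u_r", "b_r", "w_h", "u_h", "b_h")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


@dataclass
class GRULayerWeights:
    """All gate/candidate matrices and biases for one GRU layer."""

    w_z: np.ndarray
    u_z: np.ndarray
    b_z: np.ndarray
    w_r: np.ndarray
    u_r: np.ndarray
    b_r: np.ndarray
    w_h: np.ndarray  # candidate input matrix (the "primary" weights)
    u_h: np.ndarray  # candidate recurrent matrix
    b_h: np.ndarray

    def __post_init__(self) -> None:
        n_h, n_in = self.w_z.shape
        for name in _GATE_NAMES:
            a = getattr(self, name)
            want = (
                (n_h, n_in) if name.startswith("w") else (n_h, n_h) if name.startswith("u") else (n_h,)
            )
            if a.shape != want:
                raise ValidationError(f"layer weight {name} has shape {a.shape}, expected {want}")

    @property
    def n_in(self) -> int:
        return self.w_z.shape[1]

    @property
    def n_units(self) -> int:
        return self.w_z.shape[0]

    @property
    def param_count(self) -> int:
        return sum(getattr(self, n).size for n in _GATE_NAMES)

    @property
    def primary_count(self) -> int:
        return self.w_h.size


@dataclass
class RNNWeights:
    """Weights for the full GRU stack, addressable as a flat vector."""

    layers: list[GRULayerWeights]

    @property
    def topology(self) -> tuple[int, ...]:
        return (self.layers[0].n_in, *(l.n_units for l in self.layers))

    @property
    def total_count(self) -> int:
        return sum(l.param_count for l in self.layers)

    @property
    def layer_counts(self) -> tuple[int, ...]:
        return tuple(l.param_count for l in self.layers)

    @property
    def primary_count(self) -> int:
        return sum(l.primary_count for l in self.layers)

    # -- flat-vector view (parameter order: per layer, gates in _GATE_NAMES order)
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [getattr(l, n).ravel() for l in self.layers for n in _GATE_NAMES]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, topology: Sequence[int] = DEFAULT_TOPOLOGY) -> "RNNWeights":
        vec = np.asarray(vec, dtype=float)
        if vec.size != _count_for(topology):
            raise ValidationError(
                f"vector length {vec.size} does not match topology {tuple(topology)}"
            )
        layers = []
        pos = 0
        for n_in, n_h in zip(topology[:-1], topology[1:]):
            arrays = {}
            for name in _GATE_NAMES:
                shape = (n_h, n_in) if name.startswith("w") else (n_h, n_h) if name.startswith("u") else (n_h,)
                size = int(np.prod(shape))
                arrays[name] = vec[pos : pos + size].reshape(shape).copy()
                pos += size
            layers.append(GRULayerWeights(**arrays))
        if pos != vec.size:
            raise ValidationError(
                f"vector length {vec.size} does not match topology {tuple(topology)}"
            )
        return cls(layers)

    def primary_mask(self) -> np.ndarray:
        """Boolean mask over the flat vector marking the candidate input matrices."""
        parts = []
        for l in self.layers:
            for name in _GATE_NAMES:
                parts.append(np.full(getattr(l, name).size, name == "w_h"))
        return np.concatenate(parts)

    @classmethod
    def zeros(cls, topology: Sequence[int] = DEFAULT_TOPOLOGY) -> "RNNWeights":
        n = _count_for(topology)
        return cls.from_vector(np.zeros(n), topology)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        scale: float = 0.5,
        topology: Sequence[int] = DEFAULT_TOPOLOGY,
        update_bias: float = 0.0,
    ) -> "RNNWeights":
        """Small random initial weights, uniform in +/- scale.

        ``update_bias`` is added to every update-gate bias, starting the
        cells in a longer-memory regime (the update gate initially favours
        carrying the hidden state, analogous to the positive forget-gate
        bias initialisation customary for LSTMs); positive values help the
        network learn to integrate evidence over many segments.
        """
        n = _count_for(topology)
        vec = rng.uniform(-scale, scale, size=n)
        if update_bias != 0.0:
            w = cls.from_vector(vec, topology)
            for layer in w.layers:
                layer.b_z += update_bias
            return w
        return cls.from_vector(vec, topology)


def _count_for(topology: Sequence[int]) -> int:
    return sum(
        3 * (h * i + h * h + h) for i, h in zip(topology[:-1], topology[1:])
    )


def gru_step(x: np.ndarray, h: np.ndarray, layer: GRULayerWeights) -> np.ndarray:
    """One GRU update: hidden state h advanced by one time step on input x."""
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if x.shape != (layer.n_in,) or h.shape != (layer.n_units,):
        raise ValidationError(
            f"expected x of shape ({layer.n_in},) and h of shape ({layer.n_units},)"
        )
    z = _sigmoid(layer.w_z @ x + layer.u_z @ h + layer.b_z)
    r = _sigmoid(layer.w_r @ x + layer.u_r @ h + layer.b_r)
    h_tilde = np.tanh(layer.w_h @ x + layer.u_h @ (r * h) + layer.b_h)
    return z * h + (1.0 - z) * h_tilde


def forward(
    stream, weights: RNNWeights, input_scale: float = DEFAULT_INPUT_SCALE
) -> np.ndarray:
    """Output trace y(s) of the network over one metric stream.

    ``stream`` may be a :class:`~portalwatch.metrics.MetricStream` or a
    plain (length, n_in) array.  Hidden states start at zero; at each time
    step the scaled metric 4-vector feeds layer 1 and each layer's new
    hidden state feeds the next layer at the same step.  The returned trace
    is the final layer's scalar hidden state, strictly inside (-1, 1).
    """
    values = getattr(stream, "values", stream)
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValidationError("stream must be 2-D (length, n_in)")
    return forward_batch(X[None, :, :], weights, input_scale)[0]


def _layer_tables(topology: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shapes and flat-vector offsets of every gate array (kernel support)."""
    n_ins = np.array(topology[:-1], dtype=np.int64)
    n_hs = np.array(topology[1:], dtype=np.int64)
    offsets = np.zeros((len(n_hs), 9), dtype=np.int64)
    pos = 0
    for l, (ni, nh) in enumerate(zip(n_ins, n_hs)):
        for g, name in enumerate(_GATE_NAMES):
            offsets[l, g] = pos
            pos += nh * ni if name.startswith("w") else nh * nh if name.startswith("u") else nh
    return n_ins, n_hs, offsets


try:
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _stack_forward_kernel(X, vec, n_ins, n_hs, offsets):  # pragma: no cover
        B, L, n0 = X.shape
        n_layers = n_hs.shape[0]
        max_h = 0
        for l in range(n_layers):
            if n_hs[l] > max_h:
                max_h = int(n_hs[l])
        max_w = max_h if max_h > n0 else n0
        H = np.zeros((n_layers, B, max_h))
        inp = np.zeros(max_w)
        z = np.zeros(max_h)
        r = np.zeros(max_h)
        rh = np.zeros(max_h)
        Y = np.empty((B, L))
        for b in range(B):
            for l in range(n_layers):
                for j in range(max_h):
                    H[l, b, j] = 0.0
        for t in range(L):
            for b in range(B):
                for j in range(n0):
                    inp[j] = X[b, t, j]
                for l in range(n_layers):
                    ni = n_ins[l]
                    nh = n_hs[l]
                    o = offsets[l]
                    # gates
                    for i in range(nh):
                        az = vec[o[2] + i]
                        ar = vec[o[5] + i]
                        for j in range(ni):
                            xj = inp[j]
                            az += vec[o[0] + i * ni + j] * xj
                            ar += vec[o[3] + i * ni + j] * xj
                        for j in range(nh):
                            hj = H[l, b, j]
                            az += vec[o[1] + i * nh + j] * hj
                            ar += vec[o[4] + i * nh + j] * hj
                        z[i] = 1.0 / (1.0 + np.exp(-az))
                        r[i] = 1.0 / (1.0 + np.exp(-ar))
                    for j in range(nh):
                        rh[j] = r[j] * H[l, b, j]
                    # candidate and state update
                    for i in range(nh):
                        ah = vec[o[8] + i]
                        for j in range(ni):
                            ah += vec[o[6] + i * ni + j] * inp[j]
                        for j in range(nh):
                            ah += vec[o[7] + i * nh + j] * rh[j]
                        h_tilde = np.tanh(ah)
                        H[l, b, i] = z[i] * H[l, b, i] + (1.0 - z[i]) * h_tilde
                    for i in range(nh):
                        inp[i] = H[l, b, i]
                Y[b, t] = H[n_layers - 1, b, 0]
        return Y

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def forward_batch(
    X: np.ndarray, weights: RNNWeights, input_scale: float = DEFAULT_INPUT_SCALE
) -> np.ndarray:
    """Vectorised forward pass over a batch of streams.

    ``X`` has shape (batch, length, n_in); returns y of shape
    (batch, length) — the final layer's scalar output per time step.
    """
    X = np.asarray(X, dtype=float) * input_scale
    B, L, n_in = X.shape
    if n_in != weights.topology[0]:
        raise ValidationError("input dimension does not match network topology")
    if _HAVE_NUMBA:
        n_ins, n_hs, offsets = _layer_tables(weights.topology)
        return _stack_forward_kernel(
            np.ascontiguousarray(X), weights.to_vector(), n_ins, n_hs, offsets
        )
    # fuse the update/reset gate transforms into single matmuls per step
    fused = []
    for layer in weights.layers:
        n_h = layer.n_units
        w_zr = np.vstack([layer.w_z, layer.w_r]).T.copy()
        u_zr = np.vstack([layer.u_z, layer.u_r]).T.copy()
        b_zr = np.concatenate([layer.b_z, layer.b_r])
        fused.append((w_zr, u_zr, b_zr, layer.w_h.T.copy(), layer.u_h.T.copy(), layer.b_h, n_h))
    hs = [np.zeros((B, l.n_units)) for l in weights.layers]
    y = np.empty((B, L))
    for t in range(L):
        inp = X[:, t, :]
        for k, (w_zr, u_zr, b_zr, w_h, u_h, b_h, n_h) in enumerate(fused):
            h = hs[k]
            zr = _sigmoid(inp @ w_zr + h @ u_zr + b_zr)
            z = zr[:, :n_h]
            r = zr[:, n_h:]
            h_tilde = np.tanh(inp @ w_h + (r * h) @ u_h + b_h)
            h = z * h + (1.0 - z) * h_tilde
            hs[k] = h
            inp = h
        y[:, t] = hs[-1][:, 0]
    return y


def make_batch_forward(
    X: np.ndarray,
    topology: Sequence[int] = DEFAULT_TOPOLOGY,
    input_scale: float = DEFAULT_INPUT_SCALE,
):
    """Pre-bind a batch of streams: returns ``f(vec) -> Y`` over flat vectors.

    Used by the derivative-free optimiser, which evaluates thousands of
    weight vectors against a fixed training batch.
    """
    Xs = np.ascontiguousarray(np.asarray(X, dtype=float) * input_scale)
    if _HAVE_NUMBA:
        n_ins, n_hs, offsets = _layer_tables(topology)

        def f(vec: np.ndarray) -> np.ndarray:
            return _stack_forward_kernel(Xs, np.ascontiguousarray(vec), n_ins, n_hs, offsets)

    else:

        def f(vec: np.ndarray) -> np.ndarray:
            return forward_batch(X, RNNWeights.from_vector(vec, topology), input_scale)

    return f


def l2_penalty(
    weights: RNNWeights, lam: float = 40.0, denominator: str = "primary"
) -> float:
    """L2 regularisation term (lambda / 2W) * sum of squared primary weights.

    Only the candidate input matrices (the "primary" weights) enter the sum;
    recurrent, gate and bias weights are exempt.  ``W`` in the denominator is
    the number of primary weights by default (``denominator="total"`` uses
    the full parameter count instead).
    """
    mask = weights.primary_mask()
    if not mask.any():
        raise ValidationError("primary weight set is empty")
    sq = float(np.sum(weights.to_vector()[mask] ** 2))
    W = int(mask.sum()) if denominator == "primary" else weights.total_count
    return lam / (2.0 * W) * sq


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _checksum(vec: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(vec, dtype="<f8").tobytes()).hexdigest()


def save_weights(
    weights: RNNWeights,
    path: str | Path,
    input_scale: float = DEFAULT_INPUT_SCALE,
    extra: dict | None = None,
) -> Path:
    """Write weights to JSON: topology header, flat weight list, checksum.

    The input preprocessing scale travels with the weights so a saved model
    is self-contained.  Round trips are bit-exact (floats serialised via
    Python repr, which round-trips IEEE doubles).
    """
    vec = weights.to_vector()
    doc = {
        "format": "portalwatch-gru-weights",
        "version": 1,
        "topology": list(weights.topology),
        "input_scale": input_scale,
        "checksum": _checksum(vec),
        "weights": vec.tolist(),
    }
    if extra:
        doc["extra"] = extra
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return path


def load_weights(
    path: str | Path, topology: Sequence[int] = DEFAULT_TOPOLOGY
) -> tuple[RNNWeights, float]:
    """Read weights from JSON, verifying topology and checksum."""
    doc = json.loads(Path(path).read_text())
    if tuple(doc["topology"]) != tuple(topology):
        raise ValidationError(
            f"topology mismatch: file has {doc['topology']}, expected {list(topology)}"
        )
    vec = np.array(doc["weights"], dtype=float)
    if _checksum(vec) != doc["checksum"]:
        raise ValidationError("weight checksum mismatch")
    return RNNWeights.from_vector(vec, topology), float(doc.get("input_scale", DEFAULT_INPUT_SCALE))
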