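"""Shared deep-autoencoder machinery (numpy, hand-derived gradients).

Both the structural network embedding and the stacked-autoencoder
similarity compression are mirrored dense autoencoders trained with Adam on
a (possibly penalty-weighted) reconstruction objective; the embedding
additionally carries a Laplacian first-order term on the code layer.  This
module implements the common forward pass, analytic backward pass and
optimizer; the public faces live in :mod:`mdlink.sdne` and
:mod:`mdlink.fusion`.

Weight convention: layer k maps ``A_{k-1} -> act(A_{k-1} @ W_k.T + b_k)``
with ``W_k`` of shape ``(d_k, d_{k-1})``.  The decoder mirrors the encoder
dimensions; its last layer may use a different output activation (sigmoid
for binary adjacency rows, identity for real-valued similarity rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACT = {
    "sigmoid": (_sigmoid, lambda z, a: a * (1.0 - a)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
}


@dataclass
class AutoencoderState:
    """Encoder weights ``W, b`` and mirrored decoder weights ``W_hat, b_hat``."""

    W: list[np.ndarray]
    b: list[np.ndarray]
    W_hat: list[np.ndarray]
    b_hat: list[np.ndarray]
    activation: str = "sigmoid"
    output_activation: str = "sigmoid"

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b, *self.W_hat, *self.b_hat]


def init_state(
    layer_dims: list[int],
    rng: np.random.Generator,
    activation: str = "sigmoid",
    output_activation: str = "sigmoid",
) -> AutoencoderState:
    """Glorot-uniform initialisation of a mirrored autoencoder.

    ``layer_dims`` runs input -> ... -> code; the decoder mirrors it back.
    """
    if len(layer_dims) < 2:
        raise ValueError("need at least input and code dimensions")
    for name in (activation, output_activation):
        if name not in _ACT:
            raise ValueError(f"unknown activation {name!r}")

    def glorot(d_out: int, d_in: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (d_in + d_out))
        return rng.uniform(-lim, lim, size=(d_out, d_in))

    enc_pairs = list(zip(layer_dims[1:], layer_dims[:-1]))
    dec_dims = layer_dims[::-1]
    dec_pairs = list(zip(dec_dims[1:], dec_dims[:-1]))
    return AutoencoderState(
        W=[glorot(o, i) for o, i in enc_pairs],
        b=[np.zeros(o) for o, _ in enc_pairs],
        W_hat=[glorot(o, i) for o, i in dec_pairs],
        b_hat=[np.zeros(o) for o, _ in dec_pairs],
        activation=activation,
        output_activation=output_activation,
    )


def encode(X: np.ndarray, state: AutoencoderState) -> np.ndarray:
    """Forward pass through the encoder only; rows of X map to code rows."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != state.W[0].shape[1]:
        raise ValueError(
            f"input width {X.shape[1]} != first-layer width {state.W[0].shape[1]}"
        )
    act, _ = _ACT[state.activation]
    A = X
    for W, b in zip(state.W, state.b):
        A = act(A @ W.T + b)
    return A


def _forward(X: np.ndarray, state: AutoencoderState):
    """Full forward pass; caches pre-activations and outputs per layer."""
    act, _ = _ACT[state.activation]
    out_act, _ = _ACT[state.output_activation]
    Zs_e, As_e = [], [X]
    A = X
    for W, b in zip(state.W, state.b):
        Z = A @ W.T + b
        A = act(Z)
        Zs_e.append(Z)
        As_e.append(A)
    Zs_d, As_d = [], [A]
    n_dec = len(state.W_hat)
    for k, (W, b) in enumerate(zip(state.W_hat, state.b_hat)):
        Z = A @ W.T + b
        A = out_act(Z) if k == n_dec - 1 else act(Z)
        Zs_d.append(Z)
        As_d.append(A)
    return Zs_e, As_e, Zs_d, As_d


def reconstruct(X: np.ndarray, state: AutoencoderState):
    """Return (code Y, reconstruction Xhat) for input rows X."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    _, As_e, _, As_d = _forward(X, state)
    return As_e[-1], As_d[-1]


def penalty_matrix(X: np.ndarray, beta: float) -> np.ndarray:
    """Reconstruction penalty: ``beta`` where an entry is nonzero, else 1."""
    if beta < 1.0:
        raise ValueError(f"beta must be >= 1, got {beta}")
    return np.where(X > 0, beta, 1.0)


def weighted_reconstruction_loss(
    X: np.ndarray, X_hat: np.ndarray, beta: float = 1.0
) -> float:
    """Squared Frobenius error with nonzero entries up-weighted by beta."""
    X = np.asarray(X, dtype=np.float64)
    X_hat = np.asarray(X_hat, dtype=np.float64)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    B = penalty_matrix(X, beta)
    return float(np.sum(((X_hat - X) * B) ** 2))


def laplacian_loss(Y: np.ndarray, S: np.ndarray) -> float:
    """Sum over ordered pairs of ``S_ij * ||y_i - y_j||^2`` (>= 0)."""
    Y = np.asarray(Y, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if Y.shape[0] != S.shape[0] or S.shape[0] != S.shape[1]:
        raise ValueError("embedding row count must match adjacency size")
    deg = S.sum(axis=1)
    # sum_ij S_ij ||y_i - y_j||^2 = 2 tr(Y' (D - S) Y)
    return float(2.0 * (np.sum(deg[:, None] * Y * Y) - np.sum((S @ Y) * Y)))


def regularization_loss(state: AutoencoderState) -> float:
    """Half the summed squared Frobenius norms of all weight matrices."""
    return 0.5 * float(
        sum(np.sum(W**2) for W in state.W) + sum(np.sum(W**2) for W in state.W_hat)
    )


def total_loss(
    X: np.ndarray,
    S: np.ndarray | None,
    state: AutoencoderState,
    alpha: float,
    beta: float,
    nu: float,
) -> float:
    """Weighted reconstruction + alpha * Laplacian + nu * regularisation."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y, X_hat = reconstruct(X, state)
    loss = weighted_reconstruction_loss(X, X_hat, beta)
    if alpha > 0.0 and S is not None:
        loss += alpha * laplacian_loss(Y, S)
    if nu > 0.0:
        loss += nu * regularization_loss(state)
    return loss


def loss_and_grads(
    X: np.ndarray,
    S: np.ndarray | None,
    state: AutoencoderState,
    alpha: float,
    beta: float,
    nu: float,
):
    """Analytic gradients of :func:`total_loss` w.r.t. every parameter.

    Returns ``(loss, grads)`` with ``grads`` ordered like ``state.params()``.
    ``S`` is the adjacency sub-block for the rows of ``X`` (or None when no
    first-order term is used).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    act, dact = _ACT[state.activation]
    out_act, out_dact = _ACT[state.output_activation]
    Zs_e, As_e, Zs_d, As_d = _forward(X, state)
    Y, X_hat = As_e[-1], As_d[-1]

    B = penalty_matrix(X, beta)
    loss = float(np.sum(((X_hat - X) * B) ** 2))
    if alpha > 0.0 and S is not None:
        loss += alpha * laplacian_loss(Y, S)
    if nu > 0.0:
        loss += nu * regularization_loss(state)

    gW = [np.zeros_like(W) for W in state.W]
    gb = [np.zeros_like(b) for b in state.b]
    gWh = [np.zeros_like(W) for W in state.W_hat]
    gbh = [np.zeros_like(b) for b in state.b_hat]

    # decoder backward
    dA = 2.0 * (X_hat - X) * B * B
    n_dec = len(state.W_hat)
    for k in range(n_dec - 1, -1, -1):
        d = out_dact if k == n_dec - 1 else dact
        dZ = dA * d(Zs_d[k], As_d[k + 1])
        gWh[k] = dZ.T @ As_d[k]
        gbh[k] = dZ.sum(axis=0)
        dA = dZ @ state.W_hat[k]

    # first-order (Laplacian) term acts on the code layer
    if alpha > 0.0 and S is not None:
        S = np.asarray(S, dtype=np.float64)
        L = np.diag(S.sum(axis=1)) - S
        dA = dA + alpha * 4.0 * (L @ Y)

    # encoder backward
    for k in range(len(state.W) - 1, -1, -1):
        dZ = dA * dact(Zs_e[k], As_e[k + 1])
        gW[k] = dZ.T @ As_e[k]
        gb[k] = dZ.sum(axis=0)
        dA = dZ @ state.W[k]

    if nu > 0.0:
        gW = [g + nu * W for g, W in zip(gW, state.W)]
        gWh = [g + nu * W for g, W in zip(gWh, state.W_hat)]

    return loss, [*gW, *gb, *gWh, *gbh]


@dataclass
class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    X: np.ndarray,
    S: np.ndarray | None,
    state: AutoencoderState,
    *,
    alpha: float,
    beta: float,
    nu: float,
    learning_rate: float,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch Adam training; mutates ``state`` in place.

    Falls back to full batch when the data is smaller than ``batch_size``.
    Returns the full-data total loss recorded after each epoch.  Raises if
    the loss goes non-finite, naming the epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    bs = min(batch_size, n)
    opt = Adam(lr=learning_rate)
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            Sb = S[np.ix_(idx, idx)] if S is not None else None
            _, grads = loss_and_grads(X[idx], Sb, state, alpha, beta, nu)
            # per-row gradient scale keeps Adam step sizes batch-invariant
            # (the loss itself stays the paper-scale sum)
            inv = 1.0 / len(idx)
            opt.step(state.params(), [g * inv for g in grads])
        epoch_loss = total_loss(X, S, state, alpha, beta, nu)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(epoch_loss)
    return history
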