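"""Structural deep network embedding (SDNE) of the association network.

SDNE trains a mirrored deep autoencoder on the rows of the network adjacency
matrix.  The reconstruction objective (second-order proximity, with nonzero
adjacency entries up-weighted by ``beta``) makes nodes with similar
neighbourhoods embed nearby; a Laplacian penalty on the code layer
(first-order proximity, weighted by ``alpha``) pulls directly connected
nodes together.  The code layer — 128 units by default — is each node's
"behaviour" feature vector.

The combined objective is

    L = || (X_hat - X) o B ||_F^2  +  alpha * sum_ij s_ij ||y_i - y_j||^2
        + nu * L_reg,

with ``L_reg`` half the summed squared Frobenius norms of all weights.
The paper-facing loss terms are exposed individually so they can be checked
against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autoencoder as ae
from ._autoencoder import AutoencoderState, encode  # re-export  # noqa: F401
from .network import HeteroNetwork

EMBEDDING_DIM = 128


@dataclass
class SdneConfig:
    """Hyperparameters of the embedding.

    ``layer_dims`` are the encoder sizes after the input layer (the input
    width is the node count, known only once the network is seen); the last
    entry is the embedding dimension.  ``alpha`` weights the first-order
    Laplacian term, ``beta >= 1`` up-weights reconstruction of nonzero
    adjacency entries, ``nu`` weights L2 regularisation of the weights.
    """

    alpha: float = 0.05
    nu: float = 1e-4
    beta: float = 5.0
    layer_dims: tuple[int, ...] = (512, EMBEDDING_DIM)
    activation: str = "sigmoid"
    learning_rate: float = 0.005
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.nu < 0:
            raise ValueError("alpha and nu must be non-negative")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


@dataclass
class SdneResult:
    """Fitted embedding: per-node vectors plus the trained state."""

    embeddings: dict[tuple[str, str], np.ndarray]
    state: AutoencoderState
    loss_history: list[float] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        return np.array(list(self.embeddings.values()))


def first_order_loss(Y: np.ndarray, s: np.ndarray) -> float:
    """Laplacian penalty: sum over ordered pairs of s_ij ||y_i - y_j||^2."""
    return ae.laplacian_loss(Y, s)


def second_order_loss(X: np.ndarray, X_hat: np.ndarray, beta: float) -> float:
    """Penalised reconstruction error ||(X_hat - X) o B||_F^2 with
    b_ij = beta where x_ij > 0 else 1."""
    return ae.weighted_reconstruction_loss(X, X_hat, beta)


def reg_loss(state: AutoencoderState) -> float:
    """0.5 * sum_k (||W^(k)||_F^2 + ||W_hat^(k)||_F^2)."""
    return ae.regularization_loss(state)


def total_loss(
    X: np.ndarray,
    X_hat: np.ndarray,
    Y: np.ndarray,
    s: np.ndarray,
    cfg: SdneConfig,
    state: AutoencoderState | None = None,
) -> float:
    """L_2nd + alpha * L_1st + nu * L_reg (L_reg only when a state is given)."""
    loss = second_order_loss(X, X_hat, cfg.beta) + cfg.alpha * first_order_loss(Y, s)
    if state is not None and cfg.nu > 0:
        loss += cfg.nu * reg_loss(state)
    return loss


def fit_sdne(net: HeteroNetwork, cfg: SdneConfig) -> SdneResult:
    """Train the embedding on a network's adjacency matrix.

    Each node's adjacency row is both the input and the reconstruction
    target.  Training is mini-batch Adam (full-batch for networks smaller
    than the batch size); the first-order term uses the adjacency sub-block
    of each batch.  With ``epochs = 0`` the untrained forward pass is
    returned.  Deterministic given ``cfg.seed``.
    """
    if len(net.nodes) == 0:
        raise ValueError("empty network")
    X = net.adjacency.astype(np.float64)
    S = X  # adjacency doubles as the first-order weight matrix
    rng = np.random.default_rng(cfg.seed)
    layer_dims = [X.shape[0], *cfg.layer_dims]
    state = ae.init_state(
        layer_dims, rng, activation=cfg.activation, output_activation="sigmoid"
    )
    history = ae.train(
        X, S, state,
        alpha=cfg.alpha, beta=cfg.beta, nu=cfg.nu,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, rng=rng,
    )
    Y = encode(X, state)
    embeddings = {
        (n.node_type, n.node_id): Y[i] for i, n in enumerate(net.nodes)
    }
    return SdneResult(embeddings=embeddings, state=state, loss_history=history)
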