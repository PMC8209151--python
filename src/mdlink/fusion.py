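"""Feature fusion: compressed attribute vectors + behaviour embeddings.

Attribute similarity rows (miRNA sequence similarity, disease semantic
similarity) are compressed to 64 dimensions by a stacked autoencoder, then
concatenated with the 128-dimensional behaviour embeddings into the
384-long pair descriptor

    FD(i, j) = [M_b(i) | M_sim(i) | D_b(j) | D_sim(j)]

with fixed block boundaries (0, 128, 192, 320, 384).  Negative training
pairs are sampled uniformly from unknown miRNA-disease pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _autoencoder as ae
from .network import LabeledPairSet
from .sdne import EMBEDDING_DIM

ATTR_DIM = 64
DESCRIPTOR_LEN = 2 * (EMBEDDING_DIM + ATTR_DIM)  # 384
#: slice boundaries of [M_b, M_sim, D_b, D_sim] in the fused descriptor
BLOCK_BOUNDS = (0, 128, 192, 320, 384)


@dataclass
class CompressConfig:
    """Stacked-autoencoder settings for similarity-row compression."""

    hidden_dim: int = 256
    target_dim: int = ATTR_DIM
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0


def compress_similarity(
    matrix: pd.DataFrame,
    cfg: CompressConfig | None = None,
    fit_ids: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Compress each row of a similarity matrix to ``target_dim`` values.

    A mirrored autoencoder (n -> hidden -> target, sigmoid hidden units,
    linear output so negative similarities are reconstructable) is trained
    to reconstruct the rows, and the encoder output is returned per entity.
    ``fit_ids`` restricts which rows the autoencoder is *trained* on (e.g.
    entities of the training fold); the encoder is applied to all rows.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or CompressConfig()
    X = np.asarray(matrix.values, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("similarity matrix has non-finite entries")
    ids = list(matrix.index)
    if fit_ids is not None:
        keep = [i for i, eid in enumerate(ids) if eid in set(fit_ids)]
        if not keep:
            raise ValueError("fit_ids matches no row of the matrix")
        X_fit = X[keep]
    else:
        X_fit = X
    # column-wise z-scoring (on the fitted rows) gives the autoencoder a
    # high-contrast target; raw similarity rows cluster tightly around
    # their mean and reconstruct trivially, losing the row structure
    mu = X_fit.mean(axis=0)
    sd = X_fit.std(axis=0) + 1e-8
    X = (X - mu) / sd
    X_fit = (X_fit - mu) / sd
    rng = np.random.default_rng(cfg.seed)
    state = ae.init_state(
        [X.shape[1], cfg.hidden_dim, cfg.target_dim],
        rng,
        activation="sigmoid",
        output_activation="identity",
    )
    ae.train(
        X_fit, None, state,
        alpha=0.0, beta=1.0, nu=0.0,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        batch_size=cfg.batch_size, rng=rng,
    )
    codes = ae.encode(X, state)
    return {eid: codes[i] for i, eid in enumerate(ids)}


def build_descriptor(
    mi: str,
    dj: str,
    behavior: dict[tuple[str, str], np.ndarray],
    attr_m: dict[str, np.ndarray],
    attr_d: dict[str, np.ndarray],
) -> np.ndarray:
    """Concatenate [M_b(i), M_sim(i), D_b(j), D_sim(j)] for one pair."""
    try:
        mb = behavior[("miRNA", mi)]
    except KeyError:
        raise KeyError(f"no behaviour embedding for miRNA {mi!r}") from None
    try:
        db = behavior[("disease", dj)]
    except KeyError:
        raise KeyError(f"no behaviour embedding for disease {dj!r}") from None
    if mi not in attr_m:
        raise KeyError(f"no attribute vector for miRNA {mi!r}")
    if dj not in attr_d:
        raise KeyError(f"no attribute vector for disease {dj!r}")
    fd = np.concatenate([mb, attr_m[mi], db, attr_d[dj]])
    if fd.shape[0] != DESCRIPTOR_LEN:
        raise ValueError(
            f"descriptor length {fd.shape[0]} != {DESCRIPTOR_LEN}; "
            "component dimensions are inconsistent"
        )
    return fd


def sample_negatives(
    positives: list[tuple[str, str]],
    mirna_ids: list[str],
    disease_ids: list[str],
    n_samples: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Uniform sample of unknown pairs, disjoint from positives/exclusions."""
    forbidden = set(positives) | (exclude or set())
    universe = [
        (m, d)
        for m in sorted(mirna_ids)
        for d in sorted(disease_ids)
        if (m, d) not in forbidden
    ]
    if n_samples > len(universe):
        raise ValueError(
            f"requested {n_samples} negatives but only {len(universe)} "
            "unknown pairs are available"
        )
    idx = rng.choice(len(universe), size=n_samples, replace=False)
    return [universe[i] for i in sorted(idx)]


def build_dataset(
    positives: LabeledPairSet,
    mirna_ids: list[str],
    disease_ids: list[str],
    behavior: dict[tuple[str, str], np.ndarray],
    attr_m: dict[str, np.ndarray],
    attr_d: dict[str, np.ndarray],
    ratio: float = 1.0,
    seed: int = 0,
    exclude: set[tuple[str, str]] | None = None,
):
    """Labelled descriptor matrix: positives plus sampled negatives.

    Negatives are drawn uniformly without replacement from pairs that are
    neither positives nor in ``exclude`` (used to keep test negatives out of
    training), at ``ratio`` times the positive count.  Rows are shuffled;
    everything is deterministic given ``seed``.

    Returns ``(X, y, pairs)`` with X of shape (n, 384).
    """
    pos = positives.positives()
    if not pos:
        raise ValueError("no positive pairs")
    rng = np.random.default_rng(seed)
    n_neg = int(round(ratio * len(pos)))
    all_pos = {(m, d) for m, d, lab in positives.pairs if lab == 1}
    neg = sample_negatives(
        sorted(all_pos), mirna_ids, disease_ids, n_neg, rng, exclude=exclude
    )
    pairs = [(m, d, 1) for m, d in pos] + [(m, d, 0) for m, d in neg]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    X = np.array([build_descriptor(m, d, behavior, attr_m, attr_d) for m, d, _ in pairs])
    y = np.array([lab for _, _, lab in pairs], dtype=int)
    return X, y, [(m, d) for m, d, _ in pairs]
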