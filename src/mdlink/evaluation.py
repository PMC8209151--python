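"""Leakage-controlled five-fold cross validation and candidate ranking.

Known miRNA-disease pairs are partitioned into five folds.  For each fold
the test-fold edges are removed from the association network *before* the
embedding is computed, so behaviour features never see test labels; train
and test negatives are disjoint samples of unknown pairs.  Metrics follow
the standard confusion-matrix definitions plus a rank-based (Mann-Whitney)
AUC with tie correction and average-precision AUPR.

Case-study mode trains on all known pairs and ranks, for one disease, every
miRNA not already associated with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .cgr import similarity_matrix
from .classifiers import CnnConfig, make_classifier
from .fusion import (
    CompressConfig,
    build_dataset,
    build_descriptor,
    compress_similarity,
    sample_negatives,
)
from .network import HeteroNetwork, LabeledPairSet, NodeRef, remove_md_edges
from .sdne import SdneConfig, fit_sdne
from .semantics import dags_with_fallback, disease_similarity_matrix

logger = logging.getLogger(__name__)

#: column blocks of the 384-long descriptor selected by each feature mode
FEATURE_SLICES = {
    "fused": [(0, 384)],
    "behavior": [(0, 128), (192, 320)],
    "attributes": [(128, 192), (320, 384)],
}


def select_features(X: np.ndarray, mode: str) -> np.ndarray:
    """Column subset of the fused descriptor for an ablation mode."""
    if mode not in FEATURE_SLICES:
        raise ValueError(f"unknown feature mode {mode!r}")
    return np.hstack([X[:, a:b] for a, b in FEATURE_SLICES[mode]])


# ---------------------------------------------------------------------------
# fold construction


@dataclass(frozen=True)
class FoldSplit:
    """Partition of the positive pairs into disjoint test folds."""

    positives: tuple[tuple[str, str], ...]
    folds: tuple[tuple[int, ...], ...]

    def test_pairs(self, f: int) -> list[tuple[str, str]]:
        return [self.positives[i] for i in self.folds[f]]

    def train_pairs(self, f: int) -> list[tuple[str, str]]:
        test = set(self.folds[f])
        return [p for i, p in enumerate(self.positives) if i not in test]


def five_fold_split(
    positives: LabeledPairSet | Sequence[tuple[str, str]],
    seed: int,
    n_folds: int = 5,
) -> FoldSplit:
    """Random disjoint partition into ``n_folds`` subsets (sizes differ <=1)."""
    if isinstance(positives, LabeledPairSet):
        pairs = positives.positives()
    else:
        pairs = list(positives)
    if len(pairs) < n_folds:
        raise ValueError(f"need >= {n_folds} positives, got {len(pairs)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = tuple(tuple(int(i) for i in chunk) for chunk in np.array_split(order, n_folds))
    return FoldSplit(positives=tuple(pairs), folds=folds)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricSet:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "sen": self.sen, "spec": self.spec,
            "prec": self.prec, "mcc": self.mcc, "auc": self.auc,
            "aupr": self.aupr,
        }


def rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (ties count 0.5)."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)  # average ranks resolve ties as 0.5
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Confusion-matrix metrics at ``threshold`` plus AUC and AUPR.

    MCC with a zero denominator (degenerate confusion matrix) is defined
    as 0.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    auc = rank_auc(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    return MetricSet(
        tp=tp, fp=fp, tn=tn, fn=fn, acc=acc, sen=sen, spec=spec,
        prec=prec, mcc=float(mcc), auc=auc, aupr=aupr,
    )


# ---------------------------------------------------------------------------
# cross validation


@dataclass
class CvConfig:
    """Everything the CV harness needs beyond the data itself."""

    sdne: SdneConfig = field(default_factory=SdneConfig)
    compress: CompressConfig = field(default_factory=CompressConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    classifier: str = "cnn"
    neg_ratio: float = 1.0
    n_folds: int = 5
    threshold: float = 0.5
    feature_mode: str = "fused"

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.feature_mode not in FEATURE_SLICES:
            raise ValueError(f"unknown feature mode {self.feature_mode!r}")


@dataclass
class CvResult:
    fold_metrics: list[MetricSet]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, std)
    audit: list[dict[str, bool]]
    config: CvConfig
    seed: int

    @property
    def mean_auc(self) -> float:
        return self.summary["auc"][0]


def _summarize(fold_metrics: list[MetricSet]) -> dict[str, tuple[float, float]]:
    keys = fold_metrics[0].as_dict().keys()
    out = {}
    for k in keys:
        vals = np.array([m.as_dict()[k] for m in fold_metrics])
        out[k] = (float(vals.mean()), float(vals.std()))
    return out


def _audit_fold(
    net_masked: HeteroNetwork,
    test_pos: list[tuple[str, str]],
    train_rows: list[tuple[str, str]],
    test_rows: list[tuple[str, str]],
) -> dict[str, bool]:
    """Leakage audit: no test positive in the embedded network or train rows,
    and train/test row sets disjoint.  Raises on violation."""
    masked_ok = all(
        net_masked.adjacency[
            net_masked.index_of(NodeRef("miRNA", m)),
            net_masked.index_of(NodeRef("disease", d)),
        ] == 0
        for m, d in test_pos
    )
    train_set = set(train_rows)
    disjoint_ok = not train_set & set(test_rows)
    no_test_pos_in_train = not train_set & set(test_pos)
    audit = {
        "masked_ok": masked_ok,
        "train_test_disjoint": disjoint_ok,
        "no_test_positive_in_train": no_test_pos_in_train,
    }
    if not all(audit.values()):
        raise RuntimeError(f"leakage audit failed: {audit}")
    return audit


def run_cv(
    net: HeteroNetwork,
    seqs: Mapping[str, str],
    mesh_table: Mapping[str, Sequence[str]],
    positives: LabeledPairSet,
    config: CvConfig,
    seed: int,
) -> CvResult:
    """Five-fold cross validation with per-fold network masking.

    Per fold: test-fold miRNA-disease edges are removed from the network
    before the embedding is fitted; attribute compression is fitted on rows
    of training-fold entities; train/test negatives are disjoint samples of
    unknown pairs at ``neg_ratio``; the classifier sees training rows only.
    Returns per-fold metrics and their mean/std summary.
    """
    mirna_ids = sorted(n.node_id for n in net.nodes_of_type("miRNA"))
    disease_ids = sorted(n.node_id for n in net.nodes_of_type("disease"))

    # attribute similarity is label-free; computed once for all folds
    msim = similarity_matrix({k: seqs[k] for k in mirna_ids if k in seqs})
    dags = dags_with_fallback(mesh_table, disease_ids)
    dsim = disease_similarity_matrix({d: dags[d] for d in disease_ids})

    split = five_fold_split(positives, seed=seed, n_folds=config.n_folds)
    all_pos = set(split.positives)
    master = np.random.default_rng(seed)
    fold_seeds = master.integers(0, 2**31 - 1, size=(config.n_folds, 4))

    fold_metrics: list[MetricSet] = []
    audits: list[dict[str, bool]] = []
    for f in range(config.n_folds):
        test_pos = split.test_pairs(f)
        train_pos = split.train_pairs(f)
        if not test_pos:
            raise RuntimeError(f"fold {f} has an empty test set")
        s_embed, s_compress, s_neg, s_clf = (int(s) for s in fold_seeds[f])

        net_f = remove_md_edges(net, test_pos)
        emb = fit_sdne(net_f, replace(config.sdne, seed=s_embed)).embeddings

        train_mirnas = sorted({m for m, _ in train_pos})
        train_diseases = sorted({d for _, d in train_pos})
        attr_m = compress_similarity(
            msim, replace(config.compress, seed=s_compress), fit_ids=train_mirnas
        )
        attr_d = compress_similarity(
            dsim, replace(config.compress, seed=s_compress + 1),
            fit_ids=train_diseases,
        )

        rng = np.random.default_rng(s_neg)
        n_test_neg = int(round(config.neg_ratio * len(test_pos)))
        test_neg = sample_negatives(
            sorted(all_pos), mirna_ids, disease_ids, n_test_neg, rng
        )
        train_set = LabeledPairSet(tuple((m, d, 1) for m, d in train_pos))
        X_tr, y_tr, train_rows = build_dataset(
            train_set, mirna_ids, disease_ids, emb, attr_m, attr_d,
            ratio=config.neg_ratio, seed=s_neg + 1,
            exclude=set(test_pos) | set(test_neg),
        )

        test_rows = list(test_pos) + list(test_neg)
        audits.append(_audit_fold(net_f, test_pos, train_rows, test_rows))

        X_te = np.array(
            [build_descriptor(m, d, emb, attr_m, attr_d) for m, d in test_rows]
        )
        y_te = np.array([1] * len(test_pos) + [0] * len(test_neg))

        X_tr_m = select_features(X_tr, config.feature_mode)
        X_te_m = select_features(X_te, config.feature_mode)
        clf = make_classifier(
            config.classifier, X_tr_m.shape[1], seed=s_clf, cnn_cfg=config.cnn
        )
        clf.fit(X_tr_m, y_tr)
        scores = clf.predict_proba(X_te_m)
        fold_metrics.append(compute_metrics(y_te, scores, config.threshold))
        logger.info("fold %d: AUC=%.4f", f, fold_metrics[-1].auc)

    return CvResult(
        fold_metrics=fold_metrics,
        summary=_summarize(fold_metrics),
        audit=audits,
        config=config,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# case-study mode


class RankedCandidate(NamedTuple):
    mirna_id: str
    score: float
    rank: int


@dataclass
class FittedPipeline:
    """Pipeline trained on all known pairs, ready to score unknown pairs."""

    embeddings: dict[tuple[str, str], np.ndarray]
    attr_m: dict[str, np.ndarray]
    attr_d: dict[str, np.ndarray]
    classifier: object
    feature_mode: str
    known: set[tuple[str, str]]
    mirna_ids: list[str]
    disease_ids: list[str]


def fit_full(
    net: HeteroNetwork,
    seqs: Mapping[str, str],
    mesh_table: Mapping[str, Sequence[str]],
    positives: LabeledPairSet,
    config: CvConfig,
    seed: int,
) -> FittedPipeline:
    """Train on *all* known associations (case-study mode, no masking)."""
    mirna_ids = sorted(n.node_id for n in net.nodes_of_type("miRNA"))
    disease_ids = sorted(n.node_id for n in net.nodes_of_type("disease"))
    msim = similarity_matrix({k: seqs[k] for k in mirna_ids if k in seqs})
    dags = dags_with_fallback(mesh_table, disease_ids)
    dsim = disease_similarity_matrix({d: dags[d] for d in disease_ids})
    master = np.random.default_rng(seed)
    s_embed, s_compress, s_neg, s_clf = (
        int(s) for s in master.integers(0, 2**31 - 1, size=4)
    )
    emb = fit_sdne(net, replace(config.sdne, seed=s_embed)).embeddings
    attr_m = compress_similarity(
        msim, replace(config.compress, seed=s_compress)
    )
    attr_d = compress_similarity(
        dsim, replace(config.compress, seed=s_compress + 1)
    )
    X, y, _rows = build_dataset(
        positives, mirna_ids, disease_ids, emb, attr_m, attr_d,
        ratio=config.neg_ratio, seed=s_neg,
    )
    Xm = select_features(X, config.feature_mode)
    clf = make_classifier(
        config.classifier, Xm.shape[1], seed=s_clf, cnn_cfg=config.cnn
    )
    clf.fit(Xm, y)
    return FittedPipeline(
        embeddings=emb, attr_m=attr_m, attr_d=attr_d, classifier=clf,
        feature_mode=config.feature_mode,
        known={(m, d) for m, d, lab in positives.pairs if lab == 1},
        mirna_ids=mirna_ids, disease_ids=disease_ids,
    )


def rank_candidates(
    pipeline: FittedPipeline, disease_id: str, k: int = 50
) -> list[RankedCandidate]:
    """Top-k candidate miRNAs for a disease, by descending score.

    Scores every miRNA not already known to be associated with the disease;
    ties break lexicographically by miRNA id.  If fewer than ``k``
    candidates exist the full pool is returned (logged).
    """
    if disease_id not in pipeline.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    candidates = [
        m for m in pipeline.mirna_ids if (m, disease_id) not in pipeline.known
    ]
    if not candidates:
        return []
    X = np.array(
        [
            build_descriptor(
                m, disease_id, pipeline.embeddings,
                pipeline.attr_m, pipeline.attr_d,
            )
            for m in candidates
        ]
    )
    scores = pipeline.classifier.predict_proba(
        select_features(X, pipeline.feature_mode)
    )
    order = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    if k > len(order):
        logger.info(
            "requested top-%d but only %d candidates exist", k, len(order)
        )
    return [
        RankedCandidate(m, float(s), i + 1)
        for i, (m, s) in enumerate(order[:k])
    ]
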