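"""Evaluation protocols for barcode embeddings.

Four protocols measure representation quality:

- **Fine-tuning** (closed world): the full encoder plus a linear head is
  trained on Seen-train, model-selected on Seen-val, and scored on
  Seen-test at species rank.
- **Linear probe** (closed world): a multinomial linear classifier on
  frozen embeddings.
- **1-NN probe** (open world): each query embedding takes the label of its
  nearest reference embedding under cosine similarity, at any taxonomic
  rank — with Seen-train as reference and Unseen as query, this measures
  generalization to species never observed, within known genera.
- **Zero-shot BIN clustering**: embeddings are agglomeratively clustered
  (cosine distance, average linkage) into as many clusters as there are
  distinct BINs; accuracy is scored under the optimal one-to-one
  cluster-to-BIN matching (Hungarian assignment), with adjusted mutual
  information as a second view.

Accuracy and macro-averaged F1 are reported throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_mutual_info_score, f1_score

from barcodelm import autodiff as ad
from barcodelm.encoder import TransformerEncoder, embed_records, pool_embedding


@dataclass
class ProbeReport:
    task: str
    rank: str | None
    accuracy: float
    macro_f1: float | None = None
    ami: float | None = None
    n_query: int = 0
    n_reference: int | None = None
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def macro_f1(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Unweighted mean of per-class F1 over the classes present in the truth.

    A class never predicted contributes F1 = 0.
    """
    if len(true_labels) == 0:
        raise ValueError("empty input")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    classes = sorted(set(true_labels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            f1_score(
                list(true_labels),
                list(predicted_labels),
                labels=classes,
                average="macro",
                zero_division=0,
            )
        )


def _check_embeddings(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite entries")
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = int(np.nonzero(norms == 0)[0][0])
        raise ValueError(f"{name} row {bad} has zero norm; cosine undefined")


def knn_probe(
    ref_embeddings: np.ndarray,
    ref_labels: Sequence,
    query_embeddings: np.ndarray,
    query_labels: Sequence,
    rank: str = "genus",
    k: int = 1,
) -> ProbeReport:
    """1-NN classification by cosine similarity against a reference set.

    Ties are broken toward the lowest reference index, so results are
    deterministic. ``rank`` is descriptive metadata (the labels passed in
    are already at the desired rank).
    """
    if k != 1:
        raise NotImplementedError("only 1-NN probing is supported")
    ref = np.asarray(ref_embeddings, dtype=np.float64)
    query = np.asarray(query_embeddings, dtype=np.float64)
    if ref.shape[1] != query.shape[1]:
        raise ValueError("embedding dimensions differ between reference and query")
    _check_embeddings(ref, "reference embeddings")
    _check_embeddings(query, "query embeddings")
    ref_unit = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    query_unit = query / np.linalg.norm(query, axis=1, keepdims=True)
    sims = query_unit @ ref_unit.T
    nearest = sims.argmax(axis=1)  # argmax returns the lowest index on ties
    ref_labels = np.asarray(list(ref_labels))
    predictions = ref_labels[nearest]
    truth = np.asarray(list(query_labels))
    return ProbeReport(
        task="knn_probe",
        rank=rank,
        accuracy=float((predictions == truth).mean()),
        macro_f1=macro_f1(list(truth), list(predictions)),
        n_query=len(truth),
        n_reference=len(ref_labels),
        config={"k": k, "similarity": "cosine"},
    )


def linear_probe(
    embeddings_train: np.ndarray,
    labels_train: Sequence,
    embeddings_test: np.ndarray,
    labels_test: Sequence,
    rank: str = "species",
    max_iter: int = 500,
) -> ProbeReport:
    """Multinomial linear classifier on frozen embeddings (no hidden layers)."""
    train = np.asarray(embeddings_train)
    test = np.asarray(embeddings_test)
    if train.shape[1] != test.shape[1]:
        raise ValueError("embedding dimensions differ between train and test")
    clf = LogisticRegression(penalty=None, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence at the iteration cap
        clf.fit(train, list(labels_train))
        predictions = clf.predict(test)
    truth = np.asarray(list(labels_test))
    return ProbeReport(
        task="linear_probe",
        rank=rank,
        accuracy=float((predictions == truth).mean()),
        macro_f1=macro_f1(list(truth), list(predictions)),
        n_query=len(truth),
        n_reference=train.shape[0],
        config={"max_iter": max_iter},
    )


def zsc_probe(embeddings: np.ndarray, bin_labels: Sequence) -> ProbeReport:
    """Zero-shot BIN reconstruction by agglomerative clustering.

    Embeddings are clustered (cosine distance, average linkage) into
    exactly the number of distinct BINs; accuracy is the fraction of
    records correctly assigned under the accuracy-maximizing one-to-one
    cluster-to-BIN matching. Invariant to record order and BIN renaming.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(list(bin_labels))
    if np.any(labels == None) or any(l == "" for l in labels):  # noqa: E711
        raise ValueError("every record must carry a BIN label")
    bins, bin_idx = np.unique(labels, return_inverse=True)
    n_bins = len(bins)
    if n_bins < 2:
        raise ValueError("zero-shot clustering needs at least 2 distinct BINs")
    if x.shape[0] < n_bins:
        raise ValueError(f"fewer records ({x.shape[0]}) than BINs ({n_bins})")
    _check_embeddings(x, "embeddings")
    clusterer = AgglomerativeClustering(
        n_clusters=n_bins, metric="cosine", linkage="average"
    )
    cluster_idx = clusterer.fit_predict(x)
    # contingency table, then Hungarian matching for max agreement
    table = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(table, (cluster_idx, bin_idx), 1)
    rows, cols = linear_sum_assignment(-table)
    n_correct = int(table[rows, cols].sum())
    mapping = dict(zip(rows, cols))
    predictions = bins[[mapping[c] for c in cluster_idx]]
    return ProbeReport(
        task="zsc_probe",
        rank=None,
        accuracy=n_correct / x.shape[0],
        macro_f1=macro_f1(list(labels), list(predictions)),
        ami=float(adjusted_mutual_info_score(bin_idx, cluster_idx)),
        n_query=x.shape[0],
        config={"n_clusters": n_bins, "metric": "cosine", "linkage": "average"},
    )


def finetune_and_score(
    model: TransformerEncoder,
    tokenizer,
    train_records: Sequence,
    val_records: Sequence,
    test_records: Sequence,
    rank: str = "species",
    epochs: int = 5,
    batch_size: int = 32,
    max_lr: float = 1e-3,
    seed: int = 0,
) -> ProbeReport:
    """Fine-tune the full encoder plus a linear head, then score on test.

    The head acts on the mean-pooled embedding. The checkpoint (backbone +
    head) with the best validation accuracy across epochs is the one
    scored on the test set. Labels in val/test must all occur in train
    (closed-world contract).
    """
    def get_label(rec):
        label = rec.taxonomy.get(rank)
        if label is None:
            raise ValueError(f"record {rec.record_id!r} lacks a {rank} label")
        return label

    train_labels = [get_label(r) for r in train_records]
    classes = sorted(set(train_labels))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    for name, recs in (("validation", val_records), ("test", test_records)):
        missing = {get_label(r) for r in recs} - set(classes)
        if missing:
            raise ValueError(
                f"{name} labels absent from training set: {sorted(missing)[:5]}"
            )
    if len(classes) == 1:
        warnings.warn("single-class fine-tuning: accuracy is trivially 1.0", stacklevel=2)

    rng = np.random.default_rng(seed)
    d = model.config.model_dim
    head_w = ad.parameter(rng.normal(0, 0.02, (d, len(classes))).astype(np.float32))
    head_b = ad.parameter(np.zeros(len(classes), dtype=np.float32))
    params = model.parameters() + [head_w, head_b]
    opt = ad.AdamW(params, lr=max_lr, weight_decay=1e-5)

    y_train = np.array([class_to_idx[l] for l in train_labels])
    n = len(train_records)
    steps_per_epoch = (n + batch_size - 1) // batch_size
    total_steps = steps_per_epoch * epochs

    def predict(records) -> np.ndarray:
        out = []
        for start in range(0, len(records), 64):
            chunk = records[start : start + 64]
            batch = tokenizer.batch([r.sequence for r in chunk])
            pooled = pool_embedding(model.encode(batch).data, batch.validity_mask)
            out.append(np.asarray(pooled @ head_w.data + head_b.data).argmax(axis=1))
        return np.concatenate(out)

    y_val = np.array([class_to_idx[get_label(r)] for r in val_records])
    best = {"acc": -1.0, "state": None}
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = tokenizer.batch([train_records[i].sequence for i in idx])
            hidden = model.encode(batch)
            pooled = pool_embedding(hidden, batch.validity_mask)
            logits = pooled @ head_w + head_b
            weights = np.full(len(idx), 1.0 / len(idx))
            loss = ad.weighted_cross_entropy(logits, y_train[idx], weights)
            opt.zero_grad()
            loss.backward()
            ad.clip_grad_norm(params, 1.0)
            opt.lr = ad.one_cycle_lr(step, total_steps, max_lr)
            opt.step()
            step += 1
        val_acc = float((predict(val_records) == y_val).mean())
        if val_acc > best["acc"]:
            best = {
                "acc": val_acc,
                "state": [p.data.copy() for p in params],
            }
    if best["state"] is not None:
        for p, state in zip(params, best["state"]):
            p.data = state
    y_test = np.array([class_to_idx[get_label(r)] for r in test_records])
    pred_test = predict(test_records)
    idx_to_class = {i: c for c, i in class_to_idx.items()}
    return ProbeReport(
        task="finetune",
        rank=rank,
        accuracy=float((pred_test == y_test).mean()),
        macro_f1=macro_f1(
            [idx_to_class[i] for i in y_test], [idx_to_class[i] for i in pred_test]
        ),
        n_query=len(test_records),
        n_reference=len(train_records),
        config={"epochs": epochs, "max_lr": max_lr, "val_accuracy": best["acc"]},
    )


__all__ = [
    "ProbeReport",
    "macro_f1",
    "knn_probe",
    "linear_probe",
    "zsc_probe",
    "finetune_and_score",
    "embed_records",
]
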