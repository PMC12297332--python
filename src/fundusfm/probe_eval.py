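"""Downstream adaptation protocol: linear probing on frozen embeddings, 2-D
projections (PCA / UMAP and sensitivity variants), 2-D probes, external
transportability, and the non-trivial-class filter.

Linear probing fits an L2-penalised logistic regression (scikit-learn
defaults, maximum iterations raised to 20,000) on embeddings standardised to
zero mean and unit variance, with standardisation parameters estimated on the
training set only. A binary probe over d-dimensional embeddings has d + 1
parameters (weights plus intercept; 385 at d = 384). Graded targets named in
``EvalProtocol.multinomial_targets`` get a single multinomial fit, with
per-grade AUCs derived one-vs-rest from the predicted probabilities.

Projections are fit on the training set only and applied to unseen rows; UMAP
runs single-threaded with a fixed random_state so it is deterministic, and
uses cosine distance by default. Classifiers on the 2-D projections
(single-target logistic regression without rescaling, and KNN with k = 5)
quantify how well a projection separates the classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "EvalProtocol",
    "LinearProbe",
    "Projection",
    "fit_linear_probe",
    "cosine_affinity",
    "fit_projection",
    "probe_2d",
    "transport_evaluate",
    "select_nontrivial_classes",
]


@dataclass(frozen=True)
class EvalProtocol:
    max_iterations: int = 20_000
    standardize_full_vectors: bool = True  # scaler fit on train only
    multinomial_targets: tuple[str, ...] = ("dr_grade", "edema_grade", "grade")
    knn_k: int = 5
    projection_dim: int = 2
    umap_metric: str = "cosine"
    pca_precomponents: int = 100
    trivial_auc_threshold: float = 0.95

    def __post_init__(self):
        if not 0.0 < self.trivial_auc_threshold <= 1.0:
            raise ValueError("trivial_auc_threshold must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def _values(emb) -> np.ndarray:
    return np.asarray(getattr(emb, "values", emb), dtype=np.float64)


class LinearProbe:
    """A fitted standardiser + logistic probe over frozen embeddings."""

    def __init__(self, scaler, clf, classes, multinomial: bool, target: str):
        self.scaler = scaler
        self.clf = clf
        self.classes = classes
        self.multinomial = multinomial
        self.target = target

    @property
    def n_parameters(self) -> int:
        """Weights plus intercepts actually fitted (d + 1 per binary target)."""
        return int(self.clf.coef_.size + self.clf.intercept_.size)

    def _transform(self, emb) -> np.ndarray:
        x = _values(emb)
        if self.scaler is not None:
            if x.shape[1] != self.scaler.mean_.shape[0]:
                raise ValueError(
                    f"embedding dimension {x.shape[1]} does not match the "
                    f"fitted probe ({self.scaler.mean_.shape[0]})"
                )
            x = self.scaler.transform(x)
        return x

    def predict_proba(self, emb) -> np.ndarray:
        return self.clf.predict_proba(self._transform(emb))

    def auc(self, emb, labels):
        """Test AUC: a float for a binary probe, a per-class dict (one-vs-rest
        from the multinomial probabilities) otherwise."""
        proba = self.predict_proba(emb)
        labels = np.asarray(labels)
        if not self.multinomial:
            return float(roc_auc_score(labels == self.classes[1], proba[:, 1]))
        out = {}
        for j, cls in enumerate(self.classes):
            y = labels == cls
            if 0 < y.sum() < len(y):
                out[cls] = float(roc_auc_score(y, proba[:, j]))
        return out


def fit_linear_probe(train, labels, protocol: EvalProtocol | None = None,
                     target: str = "") -> LinearProbe:
    """Fit the linear probe on training embeddings only. Binary targets get a
    binary fit; targets named in `protocol.multinomial_targets` (or any target
    with more than two classes) get a single multinomial fit."""
    protocol = protocol or EvalProtocol()
    x = _values(train)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"target {target or 'label'!r} has a single class in train")
    scaler = None
    if protocol.standardize_full_vectors:
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    multinomial = classes.size > 2
    clf = LogisticRegression(max_iter=protocol.max_iterations)
    clf.fit(x, y)
    return LinearProbe(scaler, clf, classes, multinomial, target)


def cosine_affinity(a, b) -> float:
    """Dot product normalised by the product of magnitudes, in [-1, 1]."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine affinity undefined for the zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


class Projection:
    """A 2-D transform fit on training embeddings only."""

    def __init__(self, steps, method: str):
        self.steps = steps
        self.method = method

    def transform(self, emb) -> np.ndarray:
        x = _values(emb)
        for step in self.steps:
            x = step.transform(x)
        return np.asarray(x, dtype=np.float64)


def fit_projection(train, method: str = "pca", metric: str = "cosine",
                   seed: int = 0, protocol: EvalProtocol | None = None) -> Projection:
    """Fit a 2-D projection: 'pca', 'umap', or 'pca100+umap' (UMAP on the
    first 100 principal components, a sensitivity variant). Deterministic
    given the seed; UMAP runs single-threaded."""
    protocol = protocol or EvalProtocol()
    x = _values(train)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 rows to fit a projection")
    if method == "pca":
        if metric != "euclidean":
            warnings.warn("PCA ignores the distance metric", stacklevel=2)
        pca = PCA(n_components=protocol.projection_dim, random_state=seed).fit(x)
        return Projection([pca], method)
    import umap  # deferred: numba compilation is slow at import time

    steps = []
    if method == "pca100+umap":
        k = min(protocol.pca_precomponents, x.shape[0], x.shape[1])
        pre = PCA(n_components=k, random_state=seed).fit(x)
        steps.append(pre)
        x = pre.transform(x)
    elif method != "umap":
        raise ValueError(f"unknown projection method {method!r}")
    reducer = umap.UMAP(n_components=protocol.projection_dim, metric=metric,
                        random_state=seed, n_jobs=1).fit(x)
    steps.append(reducer)
    return Projection(steps, method)


def probe_2d(train_2d, train_labels, test_2d, test_labels,
             protocol: EvalProtocol | None = None) -> dict[str, float]:
    """AUCs of a single binary logistic probe (no rescaling) and a KNN probe
    (k = knn_k) fitted on 2-D projected training points."""
    protocol = protocol or EvalProtocol()
    xtr = np.asarray(train_2d, dtype=np.float64)
    xte = np.asarray(test_2d, dtype=np.float64)
    ytr = np.asarray(train_labels).astype(int)
    yte = np.asarray(test_labels).astype(int)
    if np.unique(yte).size < 2:
        raise ValueError("test set lacks both classes")
    lr = LogisticRegression(max_iter=protocol.max_iterations).fit(xtr, ytr)
    knn = KNeighborsClassifier(n_neighbors=protocol.knn_k).fit(xtr, ytr)
    return {
        "logistic": float(roc_auc_score(yte, lr.predict_proba(xte)[:, 1])),
        "knn": float(roc_auc_score(yte, knn.predict_proba(xte)[:, 1])),
    }


def transport_evaluate(fitted, emb_b, labels_b):
    """Apply objects fitted on dataset A — a LinearProbe, or a (Projection,
    2-D classifier) pair — to dataset B without any refitting. Returns the
    AUC table the frozen pipeline produces on B."""
    if isinstance(fitted, LinearProbe):
        return fitted.auc(emb_b, labels_b)
    projection, clf = fitted
    coords = projection.transform(emb_b)
    labels_b = np.asarray(labels_b).astype(int)
    return float(roc_auc_score(labels_b, clf.predict_proba(coords)[:, 1]))


def select_nontrivial_classes(auc_table, threshold: float = 0.95) -> list:
    """Keep a class iff at least one model scores strictly below the
    threshold on it (exactly-threshold classes are dropped). Dropped classes
    stay in evaluation sets as negatives; this only selects which classes are
    reported as targets.

    `auc_table`: DataFrame (classes x models) or mapping class -> per-model
    AUCs.
    """
    import pandas as pd

    if isinstance(auc_table, pd.DataFrame):
        rows = auc_table.iterrows()
    else:
        rows = auc_table.items()
    kept = []
    for cls, aucs in rows:
        if float(np.min(np.asarray(aucs, dtype=float))) < threshold:
            kept.append(cls)
    return kept
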