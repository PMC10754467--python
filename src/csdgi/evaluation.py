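"""Classification/clustering metrics, subtype-number estimation, and the
gene-set benchmarking harness.

Supervised gene sets are scored with accuracy and F1 (SVM and random-forest
classifiers under cross-validation); clustering quality is reported as the
adjusted Rand index only, since mapping cluster labels onto classes is
ambiguous.  The number of subtypes is estimated from the within-cluster
sum-of-squares (WSS) curve of k-means with an elbow rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .matrix_io import ExpressionMatrix

__all__ = [
    "ConfusionCounts",
    "WSSCurve",
    "classification_metrics",
    "adjusted_rand_index",
    "wss_curve",
    "benchmark_gene_set",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts are all zero")


@dataclass
class WSSCurve:
    k_values: list[int]
    wss: list[float]
    chosen_k: int


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Undefined ratios (zero denominator) are reported as NaN; F1 with
    precision + recall = 0 is reported as 0 by convention.
    """
    total = c.tp + c.tn + c.fp + c.fn
    accuracy = (c.tp + c.tn) / total
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else float("nan")
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    ARI = (Index - E[Index]) / (MaxIndex - E[Index]) with the pair counts
    taken from the contingency table under the permutation model.  1 for
    identical partitions (up to relabeling), ~0 for independent labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_nij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    n_pairs = comb(a.size, 2)
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial: define ARI = 1
        return 1.0
    return float((sum_nij - expected) / (max_index - expected))


def wss_curve(
    X: ExpressionMatrix | np.ndarray,
    k_max: int = 10,
    restarts: int = 10,
    seed: int = 0,
) -> WSSCurve:
    """Best-over-restarts k-means WSS for k = 1..k_max, plus the elbow k.

    The elbow maximizes the second difference wss[k-1] - 2 wss[k] + wss[k+1]
    over interior k; callers may override the choice after inspecting the
    curve (the reference analyses picked k from the plot).
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    m = V.shape[0]
    if k_max >= m:
        raise ValueError(f"k_max={k_max} must be smaller than the cell count {m}")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    wss = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed + k)
        km.fit(V)
        wss.append(float(km.inertia_))
    if k_max < 3:
        chosen = 1 if k_max == 1 else (2 if wss[0] > 2 * wss[1] else 1)
    else:
        second_diff = [
            wss[k - 2] - 2.0 * wss[k - 1] + wss[k] for k in range(2, k_max)
        ]
        chosen = int(np.argmax(second_diff)) + 2
    return WSSCurve(list(range(1, k_max + 1)), wss, chosen)


def _f1_binary_or_macro(y) -> str:
    return "f1" if len(np.unique(y)) == 2 else "f1_macro"


def benchmark_gene_set(
    X: ExpressionMatrix,
    true_groups,
    gene_sets: dict[str, list[str]],
    sizes: list[int] | None = None,
    seed: int = 0,
    n_repeats: int = 10,
    cv_folds: int = 3,
) -> pd.DataFrame:
    """Score ranked gene sets by how well their top-`size` genes separate
    the true groups.

    For each method and size: cross-validated accuracy and F1 with SVM and
    random-forest classifiers, and clustering ARI with k-means and a
    Gaussian mixture, averaged over ``n_repeats`` seeded repetitions.
    Returns a tidy DataFrame (method, size, model, metric, value).
    """
    sizes = sizes or [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
    y = np.asarray(true_groups)
    _, y_enc = np.unique(y, return_inverse=True)
    n_classes = len(np.unique(y_enc))
    rows = []
    for method, genes in gene_sets.items():
        if max(sizes) > len(genes):
            raise ValueError(
                f"size {max(sizes)} exceeds the {len(genes)} genes of {method!r}"
            )
        for size in sizes:
            sub = X.subset_genes(genes[:size])
            V = sub.values
            accs: dict[str, list[float]] = {}
            for rep in range(n_repeats):
                rs = seed + 7919 * rep
                cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rs)
                for name, clf in (
                    ("svm", SVC(kernel="rbf", random_state=rs)),
                    ("rf", RandomForestClassifier(n_estimators=100, random_state=rs)),
                ):
                    acc = cross_val_score(clf, V, y_enc, cv=cv, scoring="accuracy")
                    f1 = cross_val_score(clf, V, y_enc, cv=cv, scoring=_f1_binary_or_macro(y_enc))
                    accs.setdefault((name, "accuracy"), []).append(acc.mean())
                    accs.setdefault((name, "f1"), []).append(f1.mean())
                km = KMeans(n_clusters=n_classes, n_init=5, random_state=rs).fit_predict(V)
                gmm = GaussianMixture(
                    n_components=n_classes, random_state=rs, reg_covar=1e-4
                ).fit_predict(V)
                accs.setdefault(("kmeans", "ari"), []).append(adjusted_rand_index(y_enc, km))
                accs.setdefault(("gmm", "ari"), []).append(adjusted_rand_index(y_enc, gmm))
            for (mdl, metric), vals in accs.items():
                rows.append(
                    {
                        "method": method,
                        "size": size,
                        "model": mdl,
                        "metric": metric,
                        "value": float(np.mean(vals)),
                    }
                )
    return pd.DataFrame(rows)
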