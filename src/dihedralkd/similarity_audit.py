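"""Generalization audit: dihedral-similarity binning of training data.

The audit asks why a structure-based predictor holds up on unseen
sequences: cluster the test items by their dihedral-angle vectors
(k-means, k=9 by default), pick the member closest to each centroid as
the cluster representative, bin the training pairs by cosine similarity
of their dihedral vectors to that representative, and measure how far the
model's predictions for the cluster sit from each bin's empirical binding
rate (an RMSE per bin).  If structure drives the predictions, the
discrepancy shrinks as similarity rises.

The audit runs identically for CDR3b or peptide vectors — pass whichever
entity's dihedral matrices you want to stratify by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dihedral import DihedralMatrix

__all__ = [
    "AuditBin",
    "AuditResult",
    "dihedral_vector",
    "cluster_test_items",
    "similarity_bins",
    "bin_rmse",
    "run_audit",
]

DEFAULT_K = 9
DEFAULT_N_BINS = 5


def dihedral_vector(m: DihedralMatrix, pad_rows: int = 17) -> np.ndarray:
    """Row-major flattening of the zero-padded (pad_rows x 2) angle matrix."""
    if m.n_rows > pad_rows:
        raise ValueError(
            f"sequence exceeds configured maximum: {m.n_rows} rows > {pad_rows}"
        )
    out = np.zeros((pad_rows, 2), dtype=float)
    out[: m.n_rows] = m.angles
    return out.ravel()


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0 (with a warning) when either vector is zero."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("zero vector in cosine similarity; returning 0", stacklevel=2)
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def cluster_test_items(
    vectors: list[np.ndarray] | np.ndarray, k: int = DEFAULT_K, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means partition of dihedral vectors.

    Returns ``(labels, representative_indices)`` where the representative
    of a cluster is the member closest (Euclidean) to its centroid.
    """
    x = np.asarray(vectors, dtype=float)
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("too few distinct items for the requested cluster count")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        d = np.linalg.norm(x[members] - km.cluster_centers_[c], axis=1)
        reps[c] = members[np.argmin(d)]
    return labels, reps


def similarity_bins(
    representative: np.ndarray,
    train: list[tuple[np.ndarray, int]],
    edges,
) -> list[tuple[tuple[float, float], list[int]]]:
    """Assign training items to cosine-similarity intervals.

    Intervals are half-open [e_i, e_{i+1}) except the last, which is
    closed, so every similarity in [edges[0], edges[-1]] lands somewhere.
    Returns ``[(interval, labels_in_bin), ...]`` in ascending order.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be an ascending list with >= 2 entries")
    bins: list[list[int]] = [[] for _ in range(edges.size - 1)]
    for vec, label in train:
        s = cosine(representative, vec)
        if s < edges[0] or s > edges[-1]:
            continue
        idx = min(int(np.searchsorted(edges, s, side="right")) - 1, edges.size - 2)
        bins[max(idx, 0)].append(int(label))
    return [
        ((float(edges[i]), float(edges[i + 1])), bins[i])
        for i in range(edges.size - 1)
    ]


def bin_rmse(test_cluster_probs, train_bin_labels) -> float:
    """Root-mean-square gap between cluster predictions and a bin's binding rate.

    The training bin is summarised by its empirical binding rate; the
    RMSE is sqrt(mean_i (p_i - rate)^2) over the cluster's predicted
    probabilities. In [0, 1] for probability inputs.
    """
    probs = np.asarray(test_cluster_probs, dtype=float)
    labels = np.asarray(train_bin_labels, dtype=float)
    if probs.size == 0 or labels.size == 0:
        raise ValueError("both the test cluster and the training bin must be non-empty")
    rate = float(np.mean(labels))
    return float(np.sqrt(np.mean((probs - rate) ** 2)))


@dataclass(frozen=True)
class AuditBin:
    low: float
    high: float
    n_train: int
    rmse: float | None  # None for an empty bin


@dataclass
class AuditResult:
    entity: str  # "cdr3b" or "peptide"
    k: int
    representatives: list[int] = field(default_factory=list)  # test indices
    bins: list[list[AuditBin]] = field(default_factory=list)  # per representative

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep_id, (rep_idx, rep_bins) in enumerate(
            zip(self.representatives, self.bins)
        ):
            for b in rep_bins:
                rows.append(
                    {
                        "entity": self.entity,
                        "representative_id": rep_id,
                        "representative_test_index": rep_idx,
                        "bin_low": b.low,
                        "bin_high": b.high,
                        "n_train": b.n_train,
                        "rmse": b.rmse,
                    }
                )
        return pd.DataFrame(rows)

    def monotone_nonincreasing_count(self, tol: float = 1e-9) -> int:
        """Representatives whose RMSE never rises across ascending bins."""
        count = 0
        for rep_bins in self.bins:
            vals = [b.rmse for b in rep_bins if b.rmse is not None]
            if len(vals) >= 2 and all(
                later <= earlier + tol for earlier, later in zip(vals, vals[1:])
            ):
                count += 1
        return count

    def decreasing_trend_count(self) -> int:
        """Representatives with a falling RMSE-vs-similarity trend.

        Bin-level RMSEs are sampling-noisy, so the qualitative
        "discrepancy shrinks as similarity rises" pattern is scored as a
        strictly negative Spearman rank correlation between bin order and
        RMSE (missing bins skipped), not as strict pairwise monotonicity.
        """
        from scipy.stats import spearmanr

        count = 0
        for rep_bins in self.bins:
            vals = [b.rmse for b in rep_bins if b.rmse is not None]
            if len(vals) >= 2:
                rho = spearmanr(np.arange(len(vals)), vals).statistic
                if np.isfinite(rho) and rho < 0:
                    count += 1
        return count


def run_audit(
    test_vectors,
    test_probs,
    train_vectors,
    train_labels,
    entity: str = "cdr3b",
    k: int = DEFAULT_K,
    n_bins: int = DEFAULT_N_BINS,
    edges=None,
    seed: int = 0,
) -> AuditResult:
    """Full audit: cluster test items, bin training data, score discrepancy.

    ``edges`` overrides the default per-representative equal-width bins
    spanning the observed similarity range.
    """
    test_vectors = np.asarray(test_vectors, dtype=float)
    test_probs = np.asarray(test_probs, dtype=float)
    train_pairs = list(zip(np.asarray(train_vectors, dtype=float),
                           np.asarray(train_labels, dtype=int)))
    labels_arr, reps = cluster_test_items(test_vectors, k=k, seed=seed)
    result = AuditResult(entity=entity, k=k, representatives=[int(r) for r in reps])
    for c, rep_idx in enumerate(reps):
        rep_vec = test_vectors[rep_idx]
        cluster_probs = test_probs[labels_arr == c]
        if edges is None:
            sims = [cosine(rep_vec, v) for v, _ in train_pairs]
            lo, hi = float(np.min(sims)), float(np.max(sims))
            if hi - lo < 1e-12:
                hi = lo + 1e-12
            rep_edges = np.linspace(lo, hi, n_bins + 1)
        else:
            rep_edges = np.asarray(edges, dtype=float)
        rep_bins = []
        for (low, high), bin_labels in similarity_bins(rep_vec, train_pairs, rep_edges):
            rmse = bin_rmse(cluster_probs, bin_labels) if bin_labels else None
            rep_bins.append(
                AuditBin(low=low, high=high, n_train=len(bin_labels), rmse=rmse)
            )
        result.bins.append(rep_bins)
    return result
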