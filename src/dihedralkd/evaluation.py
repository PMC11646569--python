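"""AUC and stratified performance summaries.

AUC is the Mann-Whitney rank statistic: the probability that a random
positive outscores a random negative, ties counted 1/2.  Evaluation
reports the overall AUC, seen/unseen-stratum AUCs, and the spread over k
random test subsets (mean +/- sd), mirroring how binding predictors are
usually benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import PairRecord, split_seen_unseen

__all__ = ["EvalReport", "StratumResult", "auc", "evaluate"]


def auc(scores, labels) -> float:
    """Rank-statistic AUC with the 0.5 tie convention.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as half. Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one of each class")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 per pair
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass(frozen=True)
class StratumResult:
    auc: float | None  # None when the stratum is degenerate
    n_pos: int
    n_neg: int


@dataclass
class EvalReport:
    auc: float
    n_pos: int
    n_neg: int
    per_stratum: dict[str, StratumResult] = field(default_factory=dict)
    per_subset: list[float] = field(default_factory=list)

    @property
    def subset_mean(self) -> float | None:
        return float(np.mean(self.per_subset)) if self.per_subset else None

    @property
    def subset_sd(self) -> float | None:
        return float(np.std(self.per_subset, ddof=1)) if len(self.per_subset) > 1 else None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "per_stratum": {
                k: {"auc": v.auc, "n_pos": v.n_pos, "n_neg": v.n_neg}
                for k, v in self.per_stratum.items()
            },
            "per_subset": self.per_subset,
            "subset_mean": self.subset_mean,
            "subset_sd": self.subset_sd,
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat CSV view: one row per stratum/subset."""
        rows = [{"scope": "overall", "auc": self.auc,
                 "n_pos": self.n_pos, "n_neg": self.n_neg}]
        for name, s in self.per_stratum.items():
            rows.append({"scope": f"stratum:{name}", "auc": s.auc,
                         "n_pos": s.n_pos, "n_neg": s.n_neg})
        for i, a in enumerate(self.per_subset):
            rows.append({"scope": f"subset:{i}", "auc": a,
                         "n_pos": None, "n_neg": None})
        return pd.DataFrame(rows)


def _stratum(scores, labels) -> StratumResult:
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return StratumResult(auc=None, n_pos=n_pos, n_neg=n_neg)
    return StratumResult(auc=auc(scores, labels), n_pos=n_pos, n_neg=n_neg)


def evaluate(
    scores,
    test: list[PairRecord],
    train_peptides: set[str],
    k_subsets: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Overall + seen/unseen + subset AUCs for a scored test set.

    ``scores`` aligns positionally with ``test``. Strata follow the
    seen/unseen peptide rule against ``train_peptides``; a degenerate
    stratum is reported with counts and a None AUC, never an exception.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(test):
        raise ValueError("scores and test records length mismatch")
    labels = np.array([r.label for r in test])
    report = EvalReport(
        auc=auc(scores, labels),
        n_pos=int(np.sum(labels == 1)),
        n_neg=int(np.sum(labels == 0)),
    )

    fake_train = [
        PairRecord(cdr3b="ACDEF", peptide=p, label=1) for p in train_peptides
    ]
    annotated = split_seen_unseen(test, fake_train)
    for name in ("seen", "unseen"):
        mask = np.array([r.stratum == name for r in annotated])
        report.per_stratum[name] = _stratum(scores[mask], labels[mask])

    if k_subsets >= 1 and k_subsets <= len(test):
        indexed = list(range(len(test)))
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(indexed))
        for j in range(k_subsets):
            idx = order[j::k_subsets]
            res = _stratum(scores[idx], labels[idx])
            if res.auc is not None:
                report.per_subset.append(res.auc)
    return report
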