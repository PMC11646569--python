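"""Pair tables: loading, negative-pair construction, seen/unseen logic.

A dataset row is one (CDR3b sequence, peptide sequence, binary label)
record.  Binding pairs come from experimental sources; non-binding pairs
are constructed by randomly combining CDR3b sequences with wildtype
(self) peptides, on the assumption that TCRs are tolerant to self.
A test peptide is "seen" when its sequence occurs anywhere in training,
"unseen" otherwise — CDR3b identity plays no role in the stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PairRecord",
    "load_pairs",
    "save_pairs",
    "generate_nonbinding",
    "split_seen_unseen",
    "random_subsets",
    "dedupe_pairs",
]

logger = logging.getLogger(__name__)

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
MAX_SEQ_LEN = 19  # so l-2 fits the default pad_rows of 17


@dataclass(frozen=True)
class PairRecord:
    cdr3b: str
    peptide: str
    label: int
    source_tag: str = ""
    stratum: str = "unknown"  # seen | unseen | unknown

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        for name, seq in (("cdr3b", self.cdr3b), ("peptide", self.peptide)):
            if not seq:
                raise ValueError(f"{name} sequence is empty")
            if len(seq) > MAX_SEQ_LEN:
                raise ValueError(f"{name} sequence longer than {MAX_SEQ_LEN}")


def _valid_seq(seq: str) -> bool:
    return bool(seq) and len(seq) <= MAX_SEQ_LEN and set(seq) <= VALID_AA


def load_pairs(path_or_buffer, source_tag: str = "") -> list[PairRecord]:
    """Read a pair CSV (header ``cdr3b,peptide,label[,source_tag]``).

    Extra columns are tolerated; records with characters outside the
    amino-acid alphabet (or over-long sequences) are dropped with a
    logged count.
    """
    df = pd.read_csv(path_or_buffer, dtype={"cdr3b": str, "peptide": str})
    required = {"cdr3b", "peptide", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pair CSV missing columns: {sorted(missing)}")
    records: list[PairRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        cdr3b = str(row.cdr3b).strip().upper()
        peptide = str(row.peptide).strip().upper()
        if not (_valid_seq(cdr3b) and _valid_seq(peptide)):
            dropped += 1
            continue
        tag = str(getattr(row, "source_tag", "") or source_tag)
        records.append(
            PairRecord(cdr3b=cdr3b, peptide=peptide, label=int(row.label), source_tag=tag)
        )
    if dropped:
        logger.warning("dropped %d records with invalid sequences", dropped)
    return records


def save_pairs(records: list[PairRecord], path_or_buffer) -> None:
    pd.DataFrame(
        {
            "cdr3b": [r.cdr3b for r in records],
            "peptide": [r.peptide for r in records],
            "label": [r.label for r in records],
            "source_tag": [r.source_tag for r in records],
        }
    ).to_csv(path_or_buffer, index=False)


def generate_nonbinding(
    cdr3b_pool: list[str],
    wildtype_peptides: list[str],
    n: int,
    exclude: set[tuple[str, str]] | None = None,
    seed: int = 0,
) -> list[PairRecord]:
    """Sample ``n`` distinct non-binding pairs.

    Pairs are drawn uniformly without replacement from the Cartesian
    product ``cdr3b_pool x wildtype_peptides`` minus ``exclude``, each
    labelled 0. Deterministic for a fixed seed.
    """
    exclude = exclude or set()
    cdr3bs = sorted(set(cdr3b_pool))
    peptides = sorted(set(wildtype_peptides))
    total = len(cdr3bs) * len(peptides)
    n_excluded = sum(
        1 for c, p in exclude if c in set(cdr3bs) and p in set(peptides)
    )
    if n > total - n_excluded:
        raise ValueError(
            f"insufficient unique combinations: requested {n}, "
            f"available {total - n_excluded}"
        )
    rng = np.random.default_rng(seed)
    def _pair(flat: int) -> tuple[str, str]:
        return cdr3bs[flat // len(peptides)], peptides[flat % len(peptides)]

    if total <= 1_000_000:
        # Small product: enumerate the allowed set and sample exactly.
        allowed = [f for f in range(total) if _pair(f) not in exclude]
        idx = rng.choice(len(allowed), size=n, replace=False)
        chosen = [_pair(allowed[i]) for i in idx]
    else:
        # Huge product: draw flat indices with rejection of duplicates
        # and exclusions (n is tiny relative to the product here).
        chosen = []
        seen: set[tuple[str, str]] = set(exclude)
        while len(chosen) < n:
            for flat in rng.integers(0, total, size=max(2 * (n - len(chosen)), 16)):
                pair = _pair(int(flat))
                if pair in seen:
                    continue
                seen.add(pair)
                chosen.append(pair)
                if len(chosen) == n:
                    break
    return [
        PairRecord(cdr3b=c, peptide=p, label=0, source_tag="generated-nonbinding")
        for c, p in chosen
    ]


def split_seen_unseen(
    test: list[PairRecord], train: list[PairRecord]
) -> list[PairRecord]:
    """Annotate test records with the seen/unseen stratum.

    A record is "seen" iff its peptide sequence occurs in any training
    record (with any CDR3b, any label); otherwise "unseen". Depends only
    on the peptide-string sets, hence idempotent.
    """
    train_peptides = {r.peptide for r in train}
    return [
        replace(r, stratum="seen" if r.peptide in train_peptides else "unseen")
        for r in test
    ]


def random_subsets(
    data: list[PairRecord], k: int, seed: int = 0
) -> list[list[PairRecord]]:
    """Randomly partition ``data`` into k disjoint subsets of near-equal size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(data):
        raise ValueError("more subsets than records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    return [[data[i] for i in order[j::k]] for j in range(k)]


def dedupe_pairs(records: list[PairRecord]) -> list[PairRecord]:
    """Collapse duplicate (cdr3b, peptide) pairs.

    A label conflict resolves to 1 with a logged warning: positive binding
    evidence overrides an assumed negative.
    """
    by_pair: dict[tuple[str, str], PairRecord] = {}
    conflicts = 0
    for r in records:
        key = (r.cdr3b, r.peptide)
        prev = by_pair.get(key)
        if prev is None:
            by_pair[key] = r
        elif prev.label != r.label:
            conflicts += 1
            by_pair[key] = prev if prev.label == 1 else r
    if conflicts:
        logger.warning("resolved %d label conflicts in favour of binding", conflicts)
    return list(by_pair.values())
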