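"""Seed-controlled synthetic fixtures with a planted structural binding rule.

Real inputs to the binding predictor are structure predictions for CDR3b
loops and peptides plus experimentally curated pair labels.  To make
every stage testable at desk scale, this module emulates those inputs:

* ``n_motifs`` binder archetypes, each a matched (peptide profile, CDR3b
  profile) pair of phi/psi matrices drawn uniformly on the angle torus;
* a pair is a binder iff its peptide profile derives from an archetype
  AND its CDR3b profile derives from that archetype's partner (both with
  wrapped-Gaussian angular noise) — so the model must read all four input
  columns to separate classes;
* non-binders mix background (uniform-angle) profiles with unmatched or
  missing motifs;
* peptides form a reusable pool (as in real data, where few unique
  peptides pair with many receptors); a configurable fraction of the pool
  is reserved for the test split only, giving a genuine unseen stratum;
* sequences are random unique amino-acid strings — decorative for the
  model, but they drive the seen/unseen bookkeeping exactly as real
  sequences do;
* structures are realised through :func:`~dihedralkd.dihedral.build_backbone`,
  so reading a written fixture bundle reproduces every dihedral matrix.

With zero noise the classes are perfectly separable (Bayes AUC 1); rising
noise degrades attainable AUC monotonically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import PairRecord, load_pairs, save_pairs
from .dihedral import DihedralMatrix, build_backbone
from .featurize import FeaturizeConfig, PairedInput, assemble_input
from .structure_io import BackboneChain, read_backbone, write_backbone

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    n_pairs: int = 2000
    n_motifs: int = 8
    angular_noise_sd: float = 20.0  # degrees, wrapped-Gaussian on the circle
    binder_fraction: float = 0.5
    cdr3b_length_range: tuple[int, int] = (10, 18)  # inclusive, within [8, 19]
    peptide_length_range: tuple[int, int] = (8, 11)
    unseen_fraction: float = 0.3  # of pool peptides reserved for test only
    test_fraction: float = 0.3
    #: fraction of non-binders that reuse a motif profile on one side
    #: (hard negatives forcing the model to read both partners); the rest
    #: draw both profiles from the uniform background. Set to 0 for data
    #: where single-entity similarity alone predicts the label, e.g. when
    #: demonstrating the similarity audit.
    hard_negative_fraction: float = 0.75
    #: label rule. "paired" (default): a pair binds iff peptide AND CDR3b
    #: derive from a matched archetype pair. "receptor_only": every CDR3b
    #: derives from an archetype and the label is a fixed property of
    #: that archetype alone (half the archetypes bind) — labels are then
    #: a deterministic function of the CDR3b dihedral vector, the setting
    #: the similarity audit presumes.
    label_rule: str = "paired"
    n_peptides: int | None = None  # default: max(24, n_pairs // 25)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.binder_fraction < 1:
            raise ValueError("binder_fraction must lie in (0, 1)")
        if not 0 < self.unseen_fraction < 1:
            raise ValueError("unseen_fraction must lie in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0.0 <= self.hard_negative_fraction <= 1.0:
            raise ValueError("hard_negative_fraction must lie in [0, 1]")
        if self.label_rule not in ("paired", "receptor_only"):
            raise ValueError("label_rule must be 'paired' or 'receptor_only'")
        if self.label_rule == "receptor_only" and self.n_motifs < 2:
            raise ValueError("receptor_only labels need at least 2 motifs")
        for name, (lo, hi), bound in (
            ("cdr3b_length_range", self.cdr3b_length_range, (8, 19)),
            ("peptide_length_range", self.peptide_length_range, (8, 11)),
        ):
            if lo > hi or lo < bound[0] or hi > bound[1]:
                raise ValueError(f"{name} must be within {bound}")

    @property
    def pool_size(self) -> int:
        return self.n_peptides if self.n_peptides is not None else max(
            24, self.n_pairs // 25
        )


def _wrap(a):
    return -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)


@dataclass
class SimulatedDataset:
    config: SimConfig
    train: list[PairRecord]
    test: list[PairRecord]
    profiles: dict[str, DihedralMatrix]  # sequence -> (l-2, 2) angles
    truth: dict

    def structure(self, sequence: str) -> BackboneChain:
        """Realise one sequence's profile as backbone coordinates."""
        m = self.profiles[sequence]
        return build_backbone(sequence, m.phi, m.psi)

    def structures(self) -> dict[str, BackboneChain]:
        return {seq: self.structure(seq) for seq in self.profiles}

    def paired_inputs(
        self, split: str = "train", config: FeaturizeConfig = FeaturizeConfig()
    ) -> tuple[list[PairedInput], np.ndarray]:
        """Featurize one split straight from the stored dihedral profiles."""
        records = {"train": self.train, "test": self.test}[split]
        inputs = [
            assemble_input(
                self.profiles[r.cdr3b], self.profiles[r.peptide],
                pad_rows=config.pad_rows, normalize=config.normalize,
            )
            for r in records
        ]
        return inputs, np.array([r.label for r in records])


def _random_sequence(rng, length: int, taken: set[str]) -> str:
    for _ in range(1000):
        seq = "".join(rng.choice(list(_AA), size=length))
        if seq not in taken:
            taken.add(seq)
            return seq
    raise RuntimeError("could not draw a unique sequence")


def _noisy(arch: np.ndarray, sd: float, rng) -> np.ndarray:
    return _wrap(arch + rng.normal(0.0, sd, size=arch.shape)) if sd > 0 else arch.copy()


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """Draw a complete labelled train/test dataset with planted structure."""
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()
    sd = config.angular_noise_sd

    # Archetypes: matched (peptide, cdr3b) profile pairs.
    arch_pep, arch_cdr = [], []
    for _ in range(config.n_motifs):
        lp = int(rng.integers(config.peptide_length_range[0],
                              config.peptide_length_range[1] + 1))
        lc = int(rng.integers(config.cdr3b_length_range[0],
                              config.cdr3b_length_range[1] + 1))
        arch_pep.append(_wrap(rng.uniform(-180.0, 180.0, size=(lp - 2, 2))))
        arch_cdr.append(_wrap(rng.uniform(-180.0, 180.0, size=(lc - 2, 2))))

    # Peptide pool: half motif-derived, half background; unseen subset
    # stratified over both kinds so each stratum contains binder peptides.
    pool_size = config.pool_size
    n_motif_peps = pool_size // 2
    profiles: dict[str, DihedralMatrix] = {}
    pool: list[dict] = []
    for i in range(pool_size):
        if i < n_motif_peps:
            motif = i % config.n_motifs
            angles = _noisy(arch_pep[motif], sd, rng)
        else:
            motif = -1  # background
            lp = int(rng.integers(config.peptide_length_range[0],
                                  config.peptide_length_range[1] + 1))
            angles = _wrap(rng.uniform(-180.0, 180.0, size=(lp - 2, 2)))
        seq = _random_sequence(rng, angles.shape[0] + 2, taken)
        profiles[seq] = DihedralMatrix(angles=angles, source_length=angles.shape[0] + 2)
        pool.append({"sequence": seq, "motif": motif})

    def _mark_unseen(entries):
        n_unseen = round(config.unseen_fraction * len(entries))
        if 0 < config.unseen_fraction and n_unseen == 0:
            n_unseen = 1
        order = rng.permutation(len(entries))
        for j, idx in enumerate(order):
            entries[idx]["unseen"] = j < n_unseen

    motif_entries = [p for p in pool if p["motif"] >= 0]
    bg_entries = [p for p in pool if p["motif"] < 0]
    _mark_unseen(motif_entries)
    _mark_unseen(bg_entries)
    seen_pool = [p for p in pool if not p["unseen"]]
    if not any(p["motif"] >= 0 for p in seen_pool):
        raise ValueError("infeasible config: no training-eligible motif peptide")

    def _new_cdr3b(angles: np.ndarray) -> str:
        seq = _random_sequence(rng, angles.shape[0] + 2, taken)
        profiles[seq] = DihedralMatrix(angles=angles, source_length=angles.shape[0] + 2)
        return seq

    def _background_cdr_angles() -> np.ndarray:
        lc = int(rng.integers(config.cdr3b_length_range[0],
                              config.cdr3b_length_range[1] + 1))
        return _wrap(rng.uniform(-180.0, 180.0, size=(lc - 2, 2)))

    # Half the receptor archetypes bind under the receptor_only rule.
    motif_labels = np.zeros(config.n_motifs, dtype=int)
    motif_labels[rng.permutation(config.n_motifs)[: (config.n_motifs + 1) // 2]] = 1

    def _make_pairs_receptor_only(n: int, peptide_pool: list[dict],
                                  tag: str) -> list[PairRecord]:
        n_bind = round(config.binder_fraction * n)
        by_label = {
            1: np.nonzero(motif_labels == 1)[0],
            0: np.nonzero(motif_labels == 0)[0],
        }
        records = []
        for i in range(n):
            label = 1 if i < n_bind else 0
            m = int(rng.choice(by_label[label]))
            pep = peptide_pool[rng.integers(len(peptide_pool))]
            cdr = _new_cdr3b(_noisy(arch_cdr[m], sd, rng))
            records.append(
                PairRecord(cdr3b=cdr, peptide=pep["sequence"], label=label,
                           source_tag=tag)
            )
        order = rng.permutation(len(records))
        return [records[i] for i in order]

    def _make_pairs(n: int, peptide_pool: list[dict], tag: str) -> list[PairRecord]:
        if config.label_rule == "receptor_only":
            return _make_pairs_receptor_only(n, peptide_pool, tag)
        n_bind = round(config.binder_fraction * n)
        motif_peps = [p for p in peptide_pool if p["motif"] >= 0]
        bg_peps = [p for p in peptide_pool if p["motif"] < 0]
        if not motif_peps or not bg_peps:
            raise ValueError("infeasible config: peptide pool lacks a class")
        records = []
        for i in range(n):
            if i < n_bind:
                pep = motif_peps[rng.integers(len(motif_peps))]
                cdr = _new_cdr3b(_noisy(arch_cdr[pep["motif"]], sd, rng))
                label = 1
            else:
                if rng.uniform() < config.hard_negative_fraction:
                    scheme = int(rng.choice([0, 1, 3]))
                else:
                    scheme = 2
                if scheme == 3 and config.n_motifs < 2:
                    scheme = 0
                if scheme == 0:  # motif peptide, background receptor
                    pep = motif_peps[rng.integers(len(motif_peps))]
                    cdr = _new_cdr3b(_background_cdr_angles())
                elif scheme == 1:  # background peptide, motif receptor
                    pep = bg_peps[rng.integers(len(bg_peps))]
                    m = int(rng.integers(config.n_motifs))
                    cdr = _new_cdr3b(_noisy(arch_cdr[m], sd, rng))
                elif scheme == 2:  # background peptide, background receptor
                    pep = bg_peps[rng.integers(len(bg_peps))]
                    cdr = _new_cdr3b(_background_cdr_angles())
                else:  # motif peptide, mismatched-motif receptor
                    pep = motif_peps[rng.integers(len(motif_peps))]
                    wrong = (pep["motif"] + 1 + int(
                        rng.integers(config.n_motifs - 1))) % config.n_motifs
                    cdr = _new_cdr3b(_noisy(arch_cdr[wrong], sd, rng))
                label = 0
            records.append(
                PairRecord(cdr3b=cdr, peptide=pep["sequence"], label=label,
                           source_tag=tag)
            )
        order = rng.permutation(len(records))
        return [records[i] for i in order]

    n_test = round(config.test_fraction * config.n_pairs)
    n_train = config.n_pairs - n_test
    train = _make_pairs(n_train, seen_pool, "synthetic-train")
    test = _make_pairs(n_test, pool, "synthetic-test")

    truth = {
        "config": asdict(config),
        "archetypes": {
            "peptide": [a.tolist() for a in arch_pep],
            "cdr3b": [a.tolist() for a in arch_cdr],
        },
        "peptide_pool": [
            {"sequence": p["sequence"], "motif": p["motif"], "unseen": p["unseen"]}
            for p in pool
        ],
        "motif_labels": motif_labels.tolist(),
    }
    return SimulatedDataset(config=config, train=train, test=test,
                            profiles=profiles, truth=truth)


def write_fixture_bundle(dataset: SimulatedDataset, directory) -> None:
    """Materialise the dataset on disk.

    Layout: ``structures/<sequence>.pdb`` (one backbone per unique
    sequence, built from its profile), ``train.csv``, ``test.csv`` and
    ``truth.json`` (archetypes, pool assignments, config echo).
    """
    directory = Path(directory)
    (directory / "structures").mkdir(parents=True, exist_ok=True)
    for seq in sorted(dataset.profiles):
        write_backbone(dataset.structure(seq), directory / "structures" / f"{seq}.pdb")
    save_pairs(dataset.train, directory / "train.csv")
    save_pairs(dataset.test, directory / "test.csv")
    (directory / "truth.json").write_text(json.dumps(dataset.truth, indent=2))


def read_fixture_bundle(directory):
    """Load a written bundle: (train records, test records, structures)."""
    directory = Path(directory)
    train = load_pairs(directory / "train.csv")
    test = load_pairs(directory / "test.csv")
    structures = {
        p.stem: read_backbone(str(p))
        for p in sorted((directory / "structures").glob("*.pdb"))
    }
    return train, test, structures
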