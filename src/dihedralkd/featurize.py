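"""Assemble (CDR3b, peptide) dihedral matrices into the fixed-size model input.

The model consumes a pad_rows x 4 matrix: columns 0-1 are the CDR3b
(phi, psi) rows, columns 2-3 the peptide's, each block top-aligned and
zero-padded to pad_rows (default 17, sized for the longest supported
sequences).  With normalisation on (the default) angles are divided by
180 so every entry lies in (-1, 1]; padding stays exactly 0 either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dihedral import DihedralMatrix, phi_psi
from .structure_io import BackboneChain

__all__ = ["PairedInput", "FeaturizeConfig", "assemble_input", "featurize_pair"]

DEFAULT_PAD_ROWS = 17


@dataclass(frozen=True)
class FeaturizeConfig:
    pad_rows: int = DEFAULT_PAD_ROWS
    normalize: bool = True


@dataclass(frozen=True)
class PairedInput:
    """pad_rows x 4 feature matrix for one CDR3b-peptide pair.

    ``cdr3b_rows`` / ``peptide_rows`` record how many leading rows of each
    column block are real angles; everything below is zero padding.
    """

    matrix: np.ndarray
    cdr3b_rows: int
    peptide_rows: int
    normalized: bool = True

    @property
    def pad_rows(self) -> int:
        return self.matrix.shape[0]

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Recover the two (rows x 2) angle blocks in degrees."""
        scale = 180.0 if self.normalized else 1.0
        return (
            self.matrix[: self.cdr3b_rows, 0:2] * scale,
            self.matrix[: self.peptide_rows, 2:4] * scale,
        )


def assemble_input(
    cdr3b: DihedralMatrix,
    peptide: DihedralMatrix,
    pad_rows: int = DEFAULT_PAD_ROWS,
    normalize: bool = True,
) -> PairedInput:
    """Concatenate two dihedral matrices side by side and zero-pad.

    Raises ValueError if either matrix has more rows than ``pad_rows``.
    """
    for name, m in (("cdr3b", cdr3b), ("peptide", peptide)):
        if m.n_rows > pad_rows:
            raise ValueError(
                f"sequence exceeds configured maximum: {name} has "
                f"{m.n_rows} rows > pad_rows={pad_rows}"
            )
    out = np.zeros((pad_rows, 4), dtype=float)
    out[: cdr3b.n_rows, 0:2] = cdr3b.angles
    out[: peptide.n_rows, 2:4] = peptide.angles
    if normalize:
        out /= 180.0
    return PairedInput(
        matrix=out,
        cdr3b_rows=cdr3b.n_rows,
        peptide_rows=peptide.n_rows,
        normalized=normalize,
    )


def featurize_pair(
    cdr3b_structure: BackboneChain,
    peptide_structure: BackboneChain,
    config: FeaturizeConfig = FeaturizeConfig(),
) -> PairedInput:
    """Backbone structures -> model input (phi/psi extraction + assembly)."""
    return assemble_input(
        phi_psi(cdr3b_structure),
        phi_psi(peptide_structure),
        pad_rows=config.pad_rows,
        normalize=config.normalize,
    )


def stack_inputs(inputs: list[PairedInput]) -> np.ndarray:
    """Batch PairedInputs into an (n, pad_rows, 4, 1) float32 tensor."""
    if not inputs:
        raise ValueError("no inputs to stack")
    return np.stack([p.matrix for p in inputs]).astype(np.float32)[..., None]
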