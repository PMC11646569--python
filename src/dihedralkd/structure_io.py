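"""Read and write single-chain backbone structures in PDB format.

The binding predictor consumes one polypeptide chain per PDB file (the
CDR3b loop or the peptide), and only needs the backbone N/CA/C atoms from
which the phi/psi torsions are computed.  This module houses the
:class:`BackboneChain` container, a reader built on Bio.PDB, and a writer
emitting standard fixed-column ATOM records so that synthetic fixtures can
round-trip through the same path as externally predicted structures.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

__all__ = [
    "BackboneChain",
    "ChainError",
    "read_backbone",
    "write_backbone",
    "CHAIN_BREAK_MAX_CN",
]

#: C(i)-N(i+1) distances above this (Angstrom) are treated as chain breaks.
#: A peptide bond is ~1.33 A; 2.5 A flags gaps without false positives.
CHAIN_BREAK_MAX_CN = 2.5

BACKBONE_ATOMS = ("N", "CA", "C")


class ChainError(ValueError):
    """Raised for structurally invalid or unusable chains."""


@dataclass
class Residue:
    name: str  # 3-letter residue code
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray


@dataclass
class BackboneChain:
    """Ordered backbone (N, CA, C) coordinates for one polypeptide chain.

    Residue order follows record order in the source file; residue
    numbering and insertion codes are irrelevant to the dihedral math and
    are not retained.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """1-letter sequence; non-standard residues map to 'X'."""
        return "".join(
            seq1(r.name, undef_code="X") or "X" for r in self.residues
        )

    def coords(self) -> np.ndarray:
        """(l, 3, 3) array: residue x (N, CA, C) x (x, y, z)."""
        return np.array([[r.n, r.ca, r.c] for r in self.residues], dtype=float)

    def validate(self) -> None:
        """Enforce the invariants needed for dihedral extraction.

        Raises :class:`ChainError` on <3 residues, non-finite coordinates,
        or a C(i)-N(i+1) distance exceeding the chain-break threshold.
        """
        if len(self.residues) < 3:
            raise ChainError("chain too short for dihedral extraction")
        xyz = self.coords()
        if not np.all(np.isfinite(xyz)):
            raise ChainError("non-finite backbone coordinates")
        gaps = np.linalg.norm(xyz[1:, 0] - xyz[:-1, 2], axis=1)
        bad = np.nonzero(gaps >= CHAIN_BREAK_MAX_CN)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise ChainError(f"chain break between {i} and {i + 1}")


def read_backbone(
    pdb_source,
    chain_selector: str | None = None,
    *,
    validate: bool = True,
) -> BackboneChain:
    """Parse PDB text into a :class:`BackboneChain`.

    Parameters
    ----------
    pdb_source : str, path, or text stream
        PDB-format content. A string containing newlines is treated as
        literal PDB text, anything else as a path.
    chain_selector : str, optional
        Chain id to extract. Default: the only chain present (error if the
        first model holds several chains).
    validate : bool
        Check chain invariants (length, chain breaks) after reading.

    Only the first model is read; additional models are ignored with a
    warning. Alternate locations resolve to the highest-occupancy
    conformer (Bio.PDB's default). A residue missing any of N/CA/C is an
    error — incomplete backbones cannot yield phi/psi rows.
    """
    if isinstance(pdb_source, str) and "\n" in pdb_source:
        handle: io.TextIOBase | str = io.StringIO(pdb_source)
    else:
        handle = pdb_source
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("chain", handle)
    models = list(structure)
    if not models:
        raise ChainError("no model found in PDB input")
    if len(models) > 1:
        warnings.warn("multiple models present; using the first", stacklevel=2)
    model = models[0]
    chains = {ch.id: ch for ch in model}
    if chain_selector is None:
        if len(chains) != 1:
            raise ChainError(
                f"chain selector required: file has chains {sorted(chains)}"
            )
        chain = next(iter(chains.values()))
    else:
        if chain_selector not in chains:
            raise ChainError(f"chain not found: {chain_selector!r}")
        chain = chains[chain_selector]

    residues: list[Residue] = []
    for idx, res in enumerate(chain, start=1):
        if res.id[0].strip():  # skip waters / heteroatoms
            continue
        atoms = {}
        for name in BACKBONE_ATOMS:
            if name not in res:
                raise ChainError(f"incomplete backbone at residue {idx}")
            atom = res[name]
            if atom.is_disordered():
                atom = max(atom, key=lambda a: a.get_occupancy() or 0.0)
            atoms[name] = np.asarray(atom.get_coord(), dtype=float)
        residues.append(Residue(res.get_resname(), atoms["N"], atoms["CA"], atoms["C"]))

    out = BackboneChain(chain_id=chain.id, residues=residues)
    if validate:
        out.validate()
    return out


_ATOM_FMT = (
    "ATOM  {serial:>5d}  {name:<3s}{resname:>4s} {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {element:>2s}\n"
)


def write_backbone(chain: BackboneChain, destination, *, validate: bool = True) -> None:
    """Emit the chain as wwPDB v3.3 ATOM records (plus TER/END).

    Coordinates are written to 3 decimals, so a read/write round trip
    reproduces them to 1e-3 A and the sequence exactly.
    ``validate=False`` skips the invariant check (deliberately broken
    test fixtures).
    """
    if validate:
        chain.validate()

    def _emit(fh) -> None:
        serial = 1
        for resseq, res in enumerate(chain.residues, start=1):
            for name, xyz in zip(BACKBONE_ATOMS, (res.n, res.ca, res.c)):
                fh.write(
                    _ATOM_FMT.format(
                        serial=serial,
                        name=name,
                        resname=res.name,
                        chain=(chain.chain_id or "A")[0],
                        resseq=resseq,
                        x=xyz[0],
                        y=xyz[1],
                        z=xyz[2],
                        occ=1.00,
                        bfac=0.00,
                        element=name[0],
                    )
                )
                serial += 1
        fh.write("TER\nEND\n")

    if hasattr(destination, "write"):
        _emit(destination)
    else:
        with open(destination, "w") as fh:
            _emit(fh)
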