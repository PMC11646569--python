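"""Backbone torsion angles: extraction and reconstruction.

phi (torsion about N-CA, atoms C(i-1)-N(i)-CA(i)-C(i)) and psi (torsion
about CA-C, atoms N(i)-CA(i)-C(i)-N(i+1)) are the features the binding
model consumes.  The first and last residues of a chain rotate freely, so
both of their angles are excluded: an l-residue chain yields an
(l-2) x 2 matrix, row r describing residue r+2 (1-based).

The inverse operation, :func:`build_backbone`, places N/CA/C atoms by
internal-coordinate chain extension (NeRF) with ideal bond geometry and a
fixed trans omega, so prescribed phi/psi profiles can be realised as
coordinates and recovered exactly — the round trip underpinning all
synthetic fixtures.

All angles are in degrees in (-180, 180], IUPAC sign convention
(cis = 0, trans = 180, right-handed positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import BackboneChain, ChainError, Residue

__all__ = [
    "DihedralMatrix",
    "torsion",
    "phi_psi",
    "build_backbone",
    "BondGeometry",
    "IDEAL_GEOMETRY",
]

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass(frozen=True)
class DihedralMatrix:
    """(l-2) x 2 table of (phi, psi) in degrees for one chain.

    Row r (0-based) holds the angles of residue r+2 in 1-based chain
    numbering; ``source_length`` is l, the residue count of the
    originating chain.
    """

    angles: np.ndarray
    source_length: int

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("angles must be an (l-2) x 2 array")
        if a.shape[0] != self.source_length - 2:
            raise ValueError("row count must equal source_length - 2")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        if np.any(a <= -180.0) or np.any(a > 180.0):
            raise ValueError("angles must lie in (-180, 180]")
        object.__setattr__(self, "angles", a)

    @property
    def n_rows(self) -> int:
        return self.angles.shape[0]

    @property
    def phi(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def psi(self) -> np.ndarray:
        return self.angles[:, 1]

    def to_frame(self) -> pd.DataFrame:
        """CSV-friendly view: residue_index (1-based), phi_deg, psi_deg."""
        return pd.DataFrame(
            {
                "residue_index": np.arange(2, self.source_length),
                "phi_deg": self.phi,
                "psi_deg": self.psi,
            }
        )


def _wrap_degrees(a):
    """Map angles to (-180, 180]; -180 goes to +180."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    With b1 = p2-p1, b2 = p3-p2, b3 = p4-p3:

        angle = atan2( ((b1 x b2) x (b2 x b3)) . b2_hat ,
                       (b1 x b2) . (b2 x b3) )

    Returns a value in (-180, 180]; trans is +180. Raises ChainError when
    either atom triplet is collinear (the planes are undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 == 0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ChainError("degenerate dihedral")
    m = np.cross(n1, n2)
    y = float(np.dot(m, b2 / norm_b2))
    x = float(np.dot(n1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return float(_wrap_degrees(ang))


def phi_psi(chain: BackboneChain) -> DihedralMatrix:
    """Interior-residue (phi, psi) matrix of a backbone chain.

    For residue i (1-based, 2 <= i <= l-1):
    phi(i) = torsion(C(i-1), N(i), CA(i), C(i)),
    psi(i) = torsion(N(i), CA(i), C(i), N(i+1)).
    """
    l = len(chain)
    if l < 3:
        raise ChainError("chain too short for dihedral extraction")
    xyz = chain.coords()  # (l, 3[N,CA,C], 3)
    rows = np.empty((l - 2, 2), dtype=float)
    for r, i in enumerate(range(1, l - 1)):  # 0-based interior index
        rows[r, 0] = torsion(xyz[i - 1, 2], xyz[i, 0], xyz[i, 1], xyz[i, 2])
        rows[r, 1] = torsion(xyz[i, 0], xyz[i, 1], xyz[i, 2], xyz[i + 1, 0])
    return DihedralMatrix(angles=rows, source_length=l)


@dataclass(frozen=True)
class BondGeometry:
    """Ideal backbone internal coordinates (Angstrom / degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    ang_c_n_ca: float = 121.7
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    omega: float = 180.0


IDEAL_GEOMETRY = BondGeometry()

# Terminal torsions (psi of residue 1, phi of residue l) are excluded from
# the feature matrices but still needed to place atoms; any fixed value
# works, extended-strand-like defaults keep built chains open.
_TERMINAL_PSI = 140.0
_TERMINAL_PHI = -140.0


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position atom d given the three preceding atoms.

    d is at distance ``bond`` from c, with angle b-c-d = ``angle_deg`` and
    torsion a-b-c-d = ``torsion_deg`` (same sign convention as
    :func:`torsion`).
    """
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor), bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    sequence: str,
    phi,
    psi,
    geometry: BondGeometry = IDEAL_GEOMETRY,
    chain_id: str = "A",
) -> BackboneChain:
    """Construct backbone coordinates realising prescribed phi/psi.

    ``phi`` and ``psi`` list the interior-residue angles (length l-2 for
    an l-letter sequence); omega is fixed trans. The construction is the
    exact inverse of :func:`phi_psi`:
    ``phi_psi(build_backbone(s, phi, psi))`` recovers the inputs to
    floating-point precision.
    """
    l = len(sequence)
    if l < 3:
        raise ChainError("sequence must have at least 3 residues")
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (l - 2,) or psi.shape != (l - 2,):
        raise ValueError("angle list length must be l-2")
    g = geometry

    # phi_full[i], psi_full[i] for 0-based residue i; terminals fixed.
    phi_full = np.concatenate(([_TERMINAL_PHI], phi, [_TERMINAL_PHI]))
    psi_full = np.concatenate(([_TERMINAL_PSI], psi, [_TERMINAL_PSI]))

    coords = np.zeros((l, 3, 3), dtype=float)
    # Seed frame: N0 at origin, CA0 on +x, C0 in the xy-plane.
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (g.n_ca, 0.0, 0.0)
    ang = np.radians(g.ang_n_ca_c)
    coords[0, 2] = coords[0, 1] + g.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, l):
        n_prev, ca_prev, c_prev = coords[i - 1]
        n_i = _place(n_prev, ca_prev, c_prev, g.c_n, g.ang_ca_c_n, psi_full[i - 1])
        ca_i = _place(ca_prev, c_prev, n_i, g.n_ca, g.ang_c_n_ca, g.omega)
        c_i = _place(c_prev, n_i, ca_i, g.ca_c, g.ang_n_ca_c, phi_full[i])
        coords[i] = (n_i, ca_i, c_i)

    residues = [
        Residue(_AA3.get(aa.upper(), "UNK"), coords[i, 0], coords[i, 1], coords[i, 2])
        for i, aa in enumerate(sequence)
    ]
    return BackboneChain(chain_id=chain_id, residues=residues)
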