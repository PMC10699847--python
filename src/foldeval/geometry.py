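"""Coordinate-level primitives for protein structure analysis.

Everything downstream — torsion losses, frame-aligned point error,
chi-accuracy — reduces to a handful of operations on atomic coordinates:
signed dihedral angles, residue-specific chi extraction, and per-residue
backbone rigid frames.

Conventions
-----------
* All angles are in radians internally, normalized to (-pi, pi].
  Dihedrals follow IUPAC: cis = 0, trans = pi.
* Backbone frames use the Gram-Schmidt construction on (N, CA, C) with
  the origin at CA: the first axis points from CA to C, the second is the
  CA->N direction orthogonalized against the first, the third completes a
  right-handed basis.  The rotation maps local coordinates to global ones.
* Chi angles chi1..chi4 are defined by the standard rotamer-convention
  atom quadruples (e.g. ARG chi1 = N-CA-CB-CG).  Residues whose terminal
  chi is ambiguous under a 180-degree flip of a symmetric end group
  (ASP chi2, GLU chi3, PHE/TYR chi2) carry a symmetry flag so callers can
  choose raw or symmetry-corrected differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "STANDARD_AA3",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "CHI_ATOMS",
    "CHI_PI_SYMMETRIC",
    "NONSTANDARD_PARENT",
    "ResidueModel",
    "StructureModel",
    "RigidFrame",
    "TorsionSet",
    "wrap_angle",
    "circular_difference",
    "dihedral",
    "extract_chi",
    "extract_torsions",
    "build_frame",
    "backbone_frames",
    "apply_rigid",
]

# ---------------------------------------------------------------------------
# Amino-acid tables

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)

# Common nonstandard residues with an unambiguous standard parent.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

# chi-defining atom quadruples per residue type (standard rotamer convention).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

# (residue, chi index 0-based) pairs whose chi is pi-periodic because the
# terminal group is two-fold symmetric.
CHI_PI_SYMMETRIC: dict[str, int] = {"ASP": 1, "GLU": 2, "PHE": 1, "TYR": 1}


# ---------------------------------------------------------------------------
# Angle helpers

def wrap_angle(angle):
    """Wrap angle(s) to (-pi, pi]; values already in range pass through
    exactly (no modulo round-off)."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    out = np.where((a > -np.pi) & (a <= np.pi), a, wrapped)
    return out if out.ndim else float(out)


def circular_difference(a, b):
    """Signed circular difference a - b wrapped to (-pi, pi]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class ResidueModel:
    """One residue: 3-letter code, author index, and named atom coordinates (A)."""

    name: str
    index: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.name = self.name.upper()
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}
        for atom_name, xyz in self.atoms.items():
            if xyz.shape != (3,):
                raise ValidationError(
                    f"atom {atom_name!r} of residue {self.name}{self.index}: "
                    f"expected a 3-vector, got shape {xyz.shape}")
            if not np.all(np.isfinite(xyz)):
                raise ValidationError(
                    f"atom {atom_name!r} of residue {self.name}{self.index}: "
                    "non-finite coordinates")

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA3

    @property
    def is_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    def atom(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name]
        except KeyError:
            raise KeyError(
                f"residue {self.name}{self.index} has no atom {name!r}") from None


@dataclass
class StructureModel:
    """An ordered single-chain protein model.

    ``sequence`` is derived from residue names; nonstandard residues with a
    known parent contribute the parent's letter, others contribute 'X'.
    """

    residues: list[ResidueModel]
    chain_id: str = "A"

    @property
    def sequence(self) -> str:
        letters = []
        for r in self.residues:
            name = NONSTANDARD_PARENT.get(r.name, r.name)
            letters.append(THREE_TO_ONE.get(name, "X"))
        return "".join(letters)

    def __len__(self) -> int:
        return len(self.residues)

    def coordinates(self, atom_names=("N", "CA", "C")) -> np.ndarray:
        """Stacked coordinates of the named atoms, residue-major order."""
        rows = [r.atom(a) for r in self.residues for a in atom_names if a in r.atoms]
        return np.array(rows, dtype=float)

    def cb_coordinates(self) -> np.ndarray:
        """Per-residue CB coordinates with CA fallback (GLY has no CB)."""
        out = np.empty((len(self.residues), 3))
        for i, r in enumerate(self.residues):
            out[i] = r.atoms.get("CB", r.atoms.get("CA"))
            if out[i] is None or not np.all(np.isfinite(out[i])):
                raise ValidationError(
                    f"residue {r.name}{r.index} has neither CB nor CA")
        return out


@dataclass
class RigidFrame:
    """A rigid transform: 3x3 rotation plus translation, x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    _ORTHO_TOL = 1e-6

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("RigidFrame needs a 3x3 rotation and 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > self._ORTHO_TOL:
            raise ValidationError(f"rotation not orthonormal (max dev {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation has determinant -1 (improper)")

    @classmethod
    def identity(cls) -> "RigidFrame":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidFrame":
        r_inv = self.rotation.T
        return RigidFrame(r_inv, -r_inv @ self.translation)

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        """self applied after other: (self @ other)(x) = self(other(x))."""
        return RigidFrame(self.rotation @ other.rotation,
                          self.rotation @ other.translation + self.translation)


@dataclass
class TorsionSet:
    """Per-residue chi1..chi4 angles with availability and symmetry masks.

    ``chi[i, k]`` is only meaningful where ``mask[i, k]`` is True; masked
    entries are zero-filled but must never be read.  ``symmetric[i, k]``
    marks pi-periodic angles.
    """

    chi: np.ndarray        # (n, 4) radians, in (-pi, pi]
    mask: np.ndarray       # (n, 4) bool
    symmetric: np.ndarray  # (n, 4) bool

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.symmetric = np.asarray(self.symmetric, dtype=bool)
        if not (self.chi.shape == self.mask.shape == self.symmetric.shape):
            raise ValidationError("chi/mask/symmetric shapes differ")
        if self.chi.ndim != 2 or self.chi.shape[1] != 4:
            raise ValidationError("TorsionSet arrays must have shape (n, 4)")
        live = self.chi[self.mask]
        if live.size and (np.any(live <= -np.pi - 1e-9) or np.any(live > np.pi + 1e-9)):
            raise ValidationError("chi angles must lie in (-pi, pi]")

    @property
    def n_residues(self) -> int:
        return self.chi.shape[0]


# ---------------------------------------------------------------------------
# Operations

_DEGENERACY_TOL = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of the four points, IUPAC convention.

    Looking down the p2->p3 bond, the angle is between the half-plane
    containing p1 and the half-plane containing p4; eclipsed (cis) is 0,
    anti (trans) is pi.  Returns radians in (-pi, pi].

    Raises
    ------
    GeometryError
        If any bond vector is (near) zero-length or three consecutive
        points are collinear, where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for i, b in enumerate((b1, b2, b3), 1):
        if np.dot(b, b) < _DEGENERACY_TOL**2:
            raise GeometryError(f"zero-length bond vector b{i}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < _DEGENERACY_TOL * np.linalg.norm(b1) * b2n:
        raise GeometryError("p1, p2, p3 are collinear; torsion undefined")
    if np.linalg.norm(n2) < _DEGENERACY_TOL * np.linalg.norm(b3) * b2n:
        raise GeometryError("p2, p3, p4 are collinear; torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    angle = math.atan2(y, x)
    # standard convention gives trans = +/-pi; normalize to (-pi, pi]
    return wrap_angle(angle)


def extract_chi(residue: ResidueModel):
    """Chi1..chi4 of one residue from the standard atom quadruples.

    Returns ``(chi, mask, symmetric)``: three length-4 arrays.  A chi is
    unavailable (mask False, angle 0) when the residue type lacks it or a
    defining atom is missing; missing atoms emit a UserWarning rather than
    silently zero-filling.
    """
    name = NONSTANDARD_PARENT.get(residue.name, residue.name)
    if name not in STANDARD_AA3:
        raise ValidationError(f"residue {residue.name} is not a standard amino acid "
                              "and has no standard parent")
    chi = np.zeros(4)
    mask = np.zeros(4, dtype=bool)
    symmetric = np.zeros(4, dtype=bool)
    quadruples = CHI_ATOMS[name]
    sym_idx = CHI_PI_SYMMETRIC.get(name)
    for k, quad in enumerate(quadruples):
        missing = [a for a in quad if a not in residue.atoms]
        if missing:
            warnings.warn(
                f"residue {residue.name}{residue.index}: chi{k + 1} atoms "
                f"{missing} missing; flagged unavailable", stacklevel=2)
            break  # chi_{k+1}.. are undefined once the chain is broken
        chi[k] = dihedral(*(residue.atoms[a] for a in quad))
        mask[k] = True
        if sym_idx == k:
            symmetric[k] = True
    return chi, mask, symmetric


def extract_torsions(structure: StructureModel) -> TorsionSet:
    """TorsionSet over all residues of a structure (skips nothing; residues
    without side-chain torsions simply have an all-False mask row)."""
    n = len(structure)
    chi = np.zeros((n, 4))
    mask = np.zeros((n, 4), dtype=bool)
    sym = np.zeros((n, 4), dtype=bool)
    for i, res in enumerate(structure.residues):
        chi[i], mask[i], sym[i] = extract_chi(res)
    return TorsionSet(chi, mask, sym)


def build_frame(n, ca, c) -> RigidFrame:
    """Backbone rigid frame from N, CA, C coordinates.

    Gram-Schmidt with CA origin: e1 = unit(C - CA); e2 = unit component of
    (N - CA) orthogonal to e1; e3 = e1 x e2.  The returned frame maps local
    coordinates to global ones, so ``frame.inverse()`` expresses global
    points in the residue's local system (CA at the origin, C on +x, N in
    the xy-plane with positive y).
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    if not all(np.all(np.isfinite(p)) for p in (n, ca, c)):
        raise GeometryError("non-finite backbone coordinates")
    v1 = c - ca
    v2 = n - ca
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < _DEGENERACY_TOL or n2 < _DEGENERACY_TOL:
        raise GeometryError("coincident backbone atoms; frame undefined")
    e1 = v1 / n1
    u2 = v2 - np.dot(v2, e1) * e1
    u2n = np.linalg.norm(u2)
    if u2n < 1e-8 * n2:
        raise GeometryError("collinear N, CA, C; frame undefined")
    e2 = u2 / u2n
    e3 = np.cross(e1, e2)
    return RigidFrame(np.stack([e1, e2, e3], axis=1), ca)


def backbone_frames(structure: StructureModel) -> list[RigidFrame]:
    """One backbone frame per residue; requires complete N/CA/C."""
    frames = []
    for r in structure.residues:
        if not r.is_complete_backbone:
            raise ValidationError(
                f"residue {r.name}{r.index} lacks a complete N/CA/C backbone")
        frames.append(build_frame(r.atom("N"), r.atom("CA"), r.atom("C")))
    return frames


def apply_rigid(frame: RigidFrame, points) -> np.ndarray:
    """Apply y = R x + t to one point or a stack of points (last axis 3)."""
    pts = np.asarray(points, dtype=float)
    return pts @ frame.rotation.T + frame.translation
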