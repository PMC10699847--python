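"""Deterministic synthetic protein fixtures.

Builds small peptides from ideal internal coordinates (bond lengths,
bond angles, canonical phi/psi) with side chains grown along each
residue's chi-defining atom chain, the chi angles drawn uniformly from a
seeded generator.  Two perturbation operators create matched
"prediction" structures with known ground truth: ``perturb_chi`` rotates
side-chain torsions by wrapped-Gaussian noise and reports the exact
angular deltas, ``perturb_rigid`` jitters per-residue positions to a
target displacement scale.  Everything is a pure function of its
arguments and seed, so every loss and metric in the package is testable
without downloading a single structure.

The geometry tables are generic stereochemistry constants; the peptides
are idealized (no clash relief, no rotamer statistics) and exist to
exercise the math, not to mimic real conformational ensembles.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .geometry import (CHI_ATOMS, ONE_TO_THREE, ResidueModel, StructureModel,
                       extract_torsions, wrap_angle)

__all__ = [
    "CANONICAL_PHI_PSI",
    "place_atom",
    "make_peptide",
    "perturb_chi",
    "perturb_rigid",
    "write_pdb",
]

# Canonical backbone torsions (degrees) per conformation.
CANONICAL_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
}

# Ideal backbone internal coordinates (lengths in A, angles in degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
# CB placement: bonded to CA, angle C-CA-CB, improper torsion N-C-CA-CB.
_B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB = 1.530, 110.1, 122.6
# Generic side-chain extension geometry by element of the placed atom.
_SC_BOND = {"C": 1.52, "O": 1.43, "N": 1.47, "S": 1.81}
_SC_ANGLE = 111.0


def place_atom(a, b, c, bond_length: float, bond_angle_deg: float,
               torsion_rad: float) -> np.ndarray:
    """Position a new atom d bonded to c with the given b-c-d angle and
    a-b-c-d torsion (natural-extension / NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValidationError("collinear reference atoms in placement")
    n /= nn
    m = np.cross(n, bc)
    ang = np.deg2rad(bond_angle_deg)
    d_local = np.array([-bond_length * np.cos(ang),
                        bond_length * np.sin(ang) * np.cos(torsion_rad),
                        bond_length * np.sin(ang) * np.sin(torsion_rad)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_peptide(sequence: str, conformation: str = "helix",
                 seed: int = 0) -> StructureModel:
    """Build an idealized peptide with randomized side-chain torsions.

    Backbone phi/psi are the canonical values for ``conformation``
    (helix: -57/-47, extended: -139/135), omega is trans.  Side chains
    contain exactly the chi-defining chain atoms (plus CB and O), their
    chi angles drawn uniformly from (-pi, pi] with the seeded generator —
    re-extract them with :func:`foldeval.geometry.extract_torsions`.
    """
    if conformation not in CANONICAL_PHI_PSI:
        raise ValidationError(
            f"unknown conformation {conformation!r}; "
            f"choose from {sorted(CANONICAL_PHI_PSI)}")
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValidationError("empty sequence")
    bad = [ch for ch in sequence if ch not in ONE_TO_THREE]
    if bad:
        raise ValidationError(f"invalid amino-acid letters: {bad}")
    phi, psi = (np.deg2rad(v) for v in CANONICAL_PHI_PSI[conformation])
    omega = np.pi
    rng = np.random.default_rng(seed)

    residues: list[ResidueModel] = []
    prev_n = prev_ca = prev_c = None
    for i, letter in enumerate(sequence):
        name = ONE_TO_THREE[letter]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = np.deg2rad(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi)
            ca = place_atom(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, omega)
            c = place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        atoms = {"N": n, "CA": ca, "C": c}
        atoms["O"] = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi - np.pi)
        if name != "GLY":
            atoms["CB"] = place_atom(n, c, ca, _B_CA_CB, _A_C_CA_CB,
                                     np.deg2rad(_T_N_C_CA_CB))
        for quad in CHI_ATOMS[name]:
            chi = wrap_angle(rng.uniform(-np.pi, np.pi))
            a3, b3, c3, d3 = quad
            elem = d3[0]
            atoms[d3] = place_atom(atoms[a3], atoms[b3], atoms[c3],
                                   _SC_BOND.get(elem, 1.52), _SC_ANGLE, chi)
        residues.append(ResidueModel(name=name, index=i + 1, atoms=atoms))
        prev_n, prev_ca, prev_c = n, ca, c
    return StructureModel(residues=residues, chain_id="A")


def perturb_chi(structure: StructureModel, sigma_deg, seed: int = 0):
    """Rotate every available chi by wrapped-Gaussian noise.

    ``sigma_deg`` is a scalar or length-4 per-chi noise scale in degrees.
    Atoms distal to each rotated bond move rigidly, so upstream and
    downstream torsions are untouched by each rotation.  Returns
    ``(perturbed, deltas)`` where ``deltas[i, k]`` is the exact circular
    difference original - perturbed in radians (zero where chi_k is
    unavailable), obtained by re-extracting torsions from both structures.
    """
    sigma = np.broadcast_to(np.deg2rad(np.asarray(sigma_deg, dtype=float)), (4,))
    rng = np.random.default_rng(seed)
    new_residues = []
    for res in structure.residues:
        atoms = {k: v.copy() for k, v in res.atoms.items()}
        quads = CHI_ATOMS.get(res.name, [])
        for k, quad in enumerate(quads):
            if any(a not in atoms for a in quad):
                break
            if sigma[k] == 0.0:
                continue
            delta = rng.normal(0.0, sigma[k])
            _, b, c, _ = quad
            axis = atoms[c] - atoms[b]
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(axis * delta)
            pivot = atoms[c]
            # distal atoms: the d-atoms of this and all later chi quadruples
            for later in quads[k:]:
                d_name = later[3]
                if d_name in atoms:
                    atoms[d_name] = pivot + rot.apply(atoms[d_name] - pivot)
        new_residues.append(ResidueModel(name=res.name, index=res.index,
                                         atoms=atoms,
                                         insertion_code=res.insertion_code))
    perturbed = StructureModel(residues=new_residues,
                               chain_id=structure.chain_id)
    t0 = extract_torsions(structure)
    t1 = extract_torsions(perturbed)
    deltas = np.where(t0.mask, wrap_angle(t0.chi - t1.chi), 0.0)
    return perturbed, deltas


def perturb_rigid(structure: StructureModel, rmsd_target: float,
                  seed: int = 0) -> StructureModel:
    """Jitter each residue rigidly toward a target displacement scale.

    Every residue gets an independent random translation with RMS norm
    ``rmsd_target`` plus a small random rotation about its CA (angle
    scale 0.1 rad per A of target), so backbone frames decorrelate from
    the original and frame-aligned errors grow with the target.
    ``rmsd_target = 0`` returns an identical copy.
    """
    if rmsd_target < 0:
        raise ValidationError("rmsd_target must be non-negative")
    rng = np.random.default_rng(seed)
    sigma_t = rmsd_target / np.sqrt(3.0)
    sigma_r = 0.1 * rmsd_target
    new_residues = []
    for res in structure.residues:
        shift = rng.normal(0.0, sigma_t, size=3) if sigma_t > 0 else np.zeros(3)
        if sigma_r > 0:
            rotvec = rng.normal(0.0, sigma_r, size=3)
            rot = Rotation.from_rotvec(rotvec)
        else:
            rot = Rotation.identity()
        ca = res.atoms.get("CA", np.zeros(3))
        atoms = {name: ca + rot.apply(xyz - ca) + shift
                 for name, xyz in res.atoms.items()}
        new_residues.append(ResidueModel(name=res.name, index=res.index,
                                         atoms=atoms,
                                         insertion_code=res.insertion_code))
    return StructureModel(residues=new_residues, chain_id=structure.chain_id)


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB-format file for fixture structures (ATOM
    records only; enough for :func:`foldeval.io_formats.read_structure`)."""
    order = ["N", "CA", "C", "O", "CB"]
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            names = [a for a in order if a in res.atoms]
            names += [a for a in res.atoms if a not in order]
            for atom_name in names:
                x, y, z = res.atoms[atom_name]
                elem = atom_name[0]
                name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name_field:4s} {res.name:>3s} "
                    f"{structure.chain_id}{res.index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n")
                serial += 1
        fh.write("END\n")
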