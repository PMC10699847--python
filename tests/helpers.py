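"""Independent oracles and small utilities shared by the test modules.

These are deliberately coded from different constructions than the
library: the dihedral oracle uses the projection-onto-bond-normal-plane
construction instead of the two-normal cross product, and the alignment
quality oracle enumerates pairs with a plain nested loop over explicit
distance computations.
"""

import math

import numpy as np


def dihedral_oracle(p1, p2, p3, p4) -> float:
    """Signed torsion via the bond-perpendicular projection construction."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    x = float(np.dot(u, v))
    y = float(np.dot(np.cross(u, v), axis))
    return math.atan2(y, x)


def alignment_quality_oracle(native, template, pairs, min_sep=4,
                             native_cutoff=8.0, sim_threshold=3.0):
    """Brute-force contact-agreement ratio over all native residue pairs."""
    mapping = dict(pairs)
    cb_nat = [r.atoms.get("CB", r.atoms.get("CA")) for r in native.residues]
    cb_tmp = [r.atoms.get("CB", r.atoms.get("CA")) for r in template.residues]
    idx = [r.index for r in native.residues]
    collected = similar = 0
    n = len(native.residues)
    for i in range(n):
        for j in range(n):
            if j <= i or abs(idx[i] - idx[j]) < min_sep:
                continue
            d_nat = math.dist(cb_nat[i], cb_nat[j])
            if d_nat >= native_cutoff:
                continue
            collected += 1
            if (i + 1) in mapping and (j + 1) in mapping:
                d_tmp = math.dist(cb_tmp[mapping[i + 1] - 1],
                                  cb_tmp[mapping[j + 1] - 1])
                if abs(d_nat - d_tmp) < sim_threshold:
                    similar += 1
    return collected, similar


def random_rigid(rng):
    """A uniformly random proper rigid transform as (R, t)."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
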