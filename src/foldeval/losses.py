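"""Training-loss components for structure-prediction models.

Implements the modified losses as pure functions of coordinates, torsions
and probability tables — no network, no gradients:

* sequentially conditioned side-chain torsion loss: the error of chi_k is
  propagated down the chain through a "pre-torsion" recursion, so a wrong
  chi1 inflates the charged error of a correctly predicted chi2;
* frame-aligned point error (FAPE) with a 10 A clamp, and its
  distogram-weighted variant where each (frame i, atom j) term is scaled
  by a sigmoid weight of the mode Cb-Cb distance d_ij;
* 8-state secondary-structure cross-entropy;
* a side-chain confidence score s_i = 1 / (1 + (delta_i / delta0)^2) on
  the chi1 error, discretized into 50 bins, with its cross-entropy loss;
* the combined weighted objective over these plus six caller-supplied
  auxiliary loss scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import RigidFrame, TorsionSet, circular_difference

__all__ = [
    "DSSP8_ALPHABET",
    "DEFAULT_OTHER_WEIGHTS",
    "FapeConfig",
    "ConfidenceConfig",
    "LossWeights",
    "angle_unit_vector",
    "chi_error",
    "chi_differences",
    "pre_torsion_errors",
    "chi_error_table",
    "angle_loss",
    "fape",
    "fape_weight",
    "weighted_fape",
    "secondary_structure_loss",
    "side_chain_confidence",
    "bin_confidence",
    "sc_confidence_loss",
    "combined_loss",
]

DSSP8_ALPHABET = "HGIEBTS-"

#: Published default weights for the six auxiliary losses
#: (L_aux, L_dist, L_msa, L_conf, L_exp_resolved, L_vio).
DEFAULT_OTHER_WEIGHTS = (0.5, 0.3, 2.0, 0.01, 0.01, 1.0)

_PROB_FLOOR = 1e-8
_SIMPLEX_TOL = 1e-6


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class FapeConfig:
    """FAPE hyperparameters.

    clamp
        Cutoff in A above which per-pair errors saturate (default 10).
    v, h
        Sigmoid inflection distance (A) and additive offset of the
        distance weight w = sigmoid(2 (v - d)) + h; published values
        v = 12.0, h = 1.5.
    normalize_by_weight_sum
        If True the weighted variant divides by the weight sum instead of
        the pair count.
    length_scale
        Optional divisor applied to the clamped per-pair errors (off by
        default; the loss is used exactly as printed).
    """

    clamp: float = 10.0
    v: float = 12.0
    h: float = 1.5
    weighted: bool = True
    normalize_by_weight_sum: bool = False
    length_scale: float | None = None

    def __post_init__(self) -> None:
        if self.clamp <= 0:
            raise ValidationError("clamp must be positive")
        if self.h < 0:
            raise ValidationError("h must be non-negative")
        if self.length_scale is not None and self.length_scale <= 0:
            raise ValidationError("length_scale must be positive if set")


@dataclass
class ConfidenceConfig:
    """Side-chain confidence settings: reference angle delta0 (degrees,
    default 12) and the number of uniform bins over [0, 1] (default 50)."""

    delta0_deg: float = 12.0
    n_bins: int = 50

    def __post_init__(self) -> None:
        if self.delta0_deg <= 0:
            raise ValidationError("delta0 must be positive")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")

    @property
    def delta0_rad(self) -> float:
        return float(np.deg2rad(self.delta0_deg))


@dataclass
class LossWeights:
    """Weights of the combined objective.

    c1..c4 scale the torsion, weighted-FAPE, secondary-structure and
    side-chain-confidence terms.  Their published values live in
    supplementary material that is not part of the main text, so the
    library defaults them to 1.0 each — these are NOT the trained model's
    values and exist only to make the aggregator runnable.  c_others are
    the published defaults for the six auxiliary losses.
    """

    c1: float = 1.0
    c2: float = 1.0
    c3: float = 1.0
    c4: float = 1.0
    c_others: tuple = field(default_factory=lambda: DEFAULT_OTHER_WEIGHTS)

    def __post_init__(self) -> None:
        self.c_others = tuple(float(c) for c in self.c_others)
        if len(self.c_others) != 6:
            raise ValidationError("c_others must have exactly 6 entries")
        if any(c < 0 for c in (self.c1, self.c2, self.c3, self.c4, *self.c_others)):
            raise ValidationError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# Torsion-angle loss

def angle_unit_vector(chi):
    """(cos chi, sin chi) unit vector(s); last axis has length 2."""
    chi = np.asarray(chi, dtype=float)
    if not np.all(np.isfinite(chi)):
        raise ValidationError("angle must be finite")
    return np.stack([np.cos(chi), np.sin(chi)], axis=-1)


def chi_error(alpha_true, alpha_pred):
    """Euclidean distance between two angle unit vectors, in [0, 2].

    For a circular difference Delta this is the chord length
    2 sin(|Delta| / 2): 0 for identical angles, 2 for angles pi apart.
    """
    at = np.asarray(alpha_true, dtype=float)
    ap = np.asarray(alpha_pred, dtype=float)
    if at.shape[-1] != 2 or ap.shape != at.shape:
        raise ValidationError("angle vectors must have matching shape (..., 2)")
    return np.linalg.norm(at - ap, axis=-1)


def chi_differences(torsions_true: TorsionSet, torsions_pred: TorsionSet,
                    symmetry_correct: bool = True) -> np.ndarray:
    """Per-residue per-chi circular differences true - pred, (n, 4).

    Where ``symmetry_correct`` is on, pi-periodic chis (two-fold symmetric
    end groups) take the smaller of the raw difference and its pi-flip.
    Masked entries are zero.
    """
    _check_masks(torsions_true, torsions_pred)
    delta = circular_difference(torsions_true.chi, torsions_pred.chi)
    if symmetry_correct:
        flipped = circular_difference(torsions_true.chi, torsions_pred.chi + np.pi)
        use_flip = torsions_true.symmetric & (np.abs(flipped) < np.abs(delta))
        delta = np.where(use_flip, flipped, delta)
    return np.where(torsions_true.mask, delta, 0.0)


def pre_torsion_errors(e, mask):
    """Sequential error propagation down the chi chain of one residue.

    Given raw errors E_k in [0, 2] for k = 1..4, returns the conditioned
    errors via E~_1 = E_1 and E~_k = E~_{k-1} + E_k - E~_{k-1} E_k / 2.
    The map (a, b) -> a + b - ab/2 keeps [0, 2] invariant, is monotone in
    both arguments and dominates both, with 2 an absorbing state: once an
    angle is maximally wrong, everything downstream is too.

    ``mask`` must be a prefix pattern (chi_k available implies chi_{k-1}
    available); unavailable positions are returned as 0 and must be
    excluded from any later sum.
    """
    e = np.asarray(e, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if e.shape != (4,) or mask.shape != (4,):
        raise ValidationError("expected length-4 error and mask arrays")
    if np.any((e < -1e-12) | (e > 2 + 1e-12)):
        raise ValidationError("chi errors must lie in [0, 2]")
    n_avail = int(mask.sum())
    if not np.array_equal(mask, np.arange(4) < n_avail):
        raise ValidationError(f"mask {mask.tolist()} is not a prefix pattern")
    out = np.zeros(4)
    prev = 0.0
    for k in range(n_avail):
        prev = e[k] if k == 0 else prev + e[k] - prev * e[k] / 2.0
        out[k] = prev
    return out


def chi_error_table(torsions_true: TorsionSet, torsions_pred: TorsionSet,
                    symmetry_correct: bool = False):
    """Raw and sequentially conditioned chi errors for every residue.

    Returns ``(e, e_tilde, mask)``, each (n, 4); entries are zero outside
    the mask.
    """
    delta = chi_differences(torsions_true, torsions_pred, symmetry_correct)
    e = np.where(torsions_true.mask, 2.0 * np.abs(np.sin(delta / 2.0)), 0.0)
    e_tilde = np.zeros_like(e)
    for i in range(e.shape[0]):
        e_tilde[i] = pre_torsion_errors(e[i], torsions_true.mask[i])
    return e, e_tilde, torsions_true.mask


def angle_loss(torsions_true: TorsionSet, torsions_pred: TorsionSet,
               symmetry_correct: bool = False) -> float:
    """Sequentially conditioned torsion loss.

    Sums E_chi1 plus the conditioned errors E~_chi2..E~_chi4 over the
    residues possessing each chi, divided by the total residue count N.
    Symmetry correction is off by default here (the training-time choice
    for pi-ambiguous chis is a caller decision; see ``chi_differences``).
    """
    _, e_tilde, mask = chi_error_table(torsions_true, torsions_pred,
                                       symmetry_correct)
    n = torsions_true.n_residues
    if n == 0:
        raise ValidationError("empty torsion set")
    return float(np.sum(e_tilde[mask]) / n)


def _check_masks(a: TorsionSet, b: TorsionSet) -> None:
    if a.n_residues != b.n_residues:
        raise ValidationError(
            f"residue count mismatch: {a.n_residues} vs {b.n_residues}")
    if not np.array_equal(a.mask, b.mask):
        raise ValidationError("torsion availability masks differ")


# ---------------------------------------------------------------------------
# FAPE

def fape(frames_pred, points_pred, frames_true, points_true,
         cfg: FapeConfig | None = None):
    """Frame-aligned point error.

    Expresses every atom j in the local frame of every residue i, for the
    prediction and the truth separately, and clamps the per-pair distance
    between the two local positions.  Returns ``(matrix, scalar)``: the
    (n_frames, n_points) clamped error matrix and its unweighted mean.
    The scalar is invariant under independent global rigid motions of the
    predicted and of the true pair.
    """
    cfg = cfg or FapeConfig()
    pp = np.atleast_2d(np.asarray(points_pred, dtype=float))
    pt = np.atleast_2d(np.asarray(points_true, dtype=float))
    if len(frames_pred) != len(frames_true):
        raise ValidationError("frame count mismatch between prediction and truth")
    if pp.shape != pt.shape:
        raise ValidationError("point count mismatch between prediction and truth")
    local_pred = _local_coords(frames_pred, pp)
    local_true = _local_coords(frames_true, pt)
    err = np.linalg.norm(local_pred - local_true, axis=-1)
    err = np.minimum(err, cfg.clamp)
    if cfg.length_scale is not None:
        err = err / cfg.length_scale
    return err, float(err.mean())


def _local_coords(frames, points: np.ndarray) -> np.ndarray:
    """(n_frames, n_points, 3) local coordinates R_i^T (x_j - t_i)."""
    rot = np.stack([f.rotation for f in frames])        # (n, 3, 3)
    trans = np.stack([f.translation for f in frames])   # (n, 3)
    return np.einsum("nba,jb->nja", rot, points) - np.einsum(
        "nba,nb->na", rot, trans)[:, None, :]


def fape_weight(d, cfg: FapeConfig | None = None):
    """Distance weight w = 1 / (1 + exp(-2 (v - d))) + h.

    Strictly decreasing in d, bounded in (h, 1 + h); equals 0.5 + h at the
    inflection d = v and tends to h as d grows: distant residue pairs are
    down-weighted toward the floor h, close pairs count up to 1 + h.
    """
    cfg = cfg or FapeConfig()
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    with np.errstate(over="ignore"):
        w = 1.0 / (1.0 + np.exp(-2.0 * (cfg.v - d))) + cfg.h
    return w if w.ndim else float(w)


def weighted_fape(frames_pred, points_pred, frames_true, points_true,
                  mode_distances, point_residues=None,
                  cfg: FapeConfig | None = None) -> float:
    """Distogram-weighted FAPE.

    Each per-pair FAPE term for frame i and atom j is multiplied by
    w(d_{i, r(j)}), where r(j) is the residue owning atom j and d is the
    mode (argmax-probability) Cb-Cb distance matrix from a distogram.
    Self-pairs use the zero diagonal of d, hence the maximal weight.

    ``point_residues`` maps each point to its residue index; identity
    (one point per residue, in order) when omitted.  Aggregation is the
    plain mean of weighted terms, or weighted mean when
    ``cfg.normalize_by_weight_sum`` is set.
    """
    cfg = cfg or FapeConfig()
    d = np.asarray(mode_distances, dtype=float)
    n = len(frames_pred)
    if d.shape != (n, n):
        raise ValidationError(
            f"mode-distance matrix shape {d.shape} does not match {n} frames")
    err, _ = fape(frames_pred, points_pred, frames_true, points_true, cfg)
    n_points = err.shape[1]
    if point_residues is None:
        if n_points != n:
            raise ValidationError(
                "point_residues required when points do not map 1:1 to residues")
        point_residues = np.arange(n)
    point_residues = np.asarray(point_residues, dtype=int)
    if point_residues.shape != (n_points,):
        raise ValidationError("point_residues must give one residue per point")
    if np.any((point_residues < 0) | (point_residues >= n)):
        raise ValidationError("point_residues indices out of range")
    w = fape_weight(d[:, point_residues], cfg)  # (n_frames, n_points)
    if cfg.normalize_by_weight_sum:
        return float(np.sum(w * err) / np.sum(w))
    return float(np.mean(w * err))


# ---------------------------------------------------------------------------
# Secondary structure

def secondary_structure_loss(true_labels, pred_probs) -> float:
    """Mean 8-state secondary-structure cross-entropy.

    ``true_labels`` is a string (or sequence) over the DSSP 8-state
    alphabet H, G, I, E, B, T, S, '-'; ``pred_probs`` is (n, 8) with rows
    on the simplex, columns in alphabet order.  Probabilities are floored
    at 1e-8 before the log.
    """
    labels = list(true_labels)
    probs = np.asarray(pred_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != len(DSSP8_ALPHABET):
        raise ValidationError(f"pred_probs must be (n, {len(DSSP8_ALPHABET)})")
    if len(labels) != probs.shape[0]:
        raise ValidationError("label count does not match probability rows")
    idx = []
    for i, lab in enumerate(labels):
        if lab not in DSSP8_ALPHABET:
            raise ValidationError(
                f"invalid secondary-structure label {lab!r} at position {i + 1}")
        idx.append(DSSP8_ALPHABET.index(lab))
    _check_simplex(probs)
    p = np.maximum(probs[np.arange(len(labels)), idx], _PROB_FLOOR)
    return float(-np.mean(np.log(p)))


def _check_simplex(probs: np.ndarray) -> None:
    sums = probs.sum(axis=1)
    if np.any(probs < -1e-12) or np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"probability row {bad} is not on the simplex (sum {sums[bad]:.6g})")


# ---------------------------------------------------------------------------
# Side-chain confidence

def side_chain_confidence(delta, delta0: float | None = None):
    """Per-residue side-chain confidence s = 1 / (1 + (delta / delta0)^2).

    ``delta`` is the chi1 difference in radians (wrapped circularly);
    ``delta0`` the reference angle in radians (default: 12 degrees).
    s is 1 at a perfect chi1, 0.5 at |delta| = delta0, and decays
    quadratically beyond.
    """
    if delta0 is None:
        delta0 = ConfidenceConfig().delta0_rad
    if delta0 <= 0:
        raise ValidationError("delta0 must be positive")
    d = circular_difference(np.asarray(delta, dtype=float), 0.0)
    s = 1.0 / (1.0 + (d / delta0) ** 2)
    return s if np.ndim(s) else float(s)


def bin_confidence(s, n_bins: int = 50):
    """Discretize a confidence value into uniform bins over [0, 1].

    Bins are half-open [lo, hi) except the last, which is closed so that
    s = 1 lands in bin n_bins - 1.  Returns ``(index, one_hot)``.
    """
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValidationError(f"confidence {s} outside [0, 1]")
    idx = min(int(np.floor(s * n_bins)), n_bins - 1)
    one_hot = np.zeros(n_bins)
    one_hot[idx] = 1.0
    return idx, one_hot


def sc_confidence_loss(true_s, pred_probs, mask=None, n_bins: int = 50) -> float:
    """Cross-entropy between binned true confidences and predicted bin
    probabilities, averaged over residues with an available chi1.

    ``mask`` selects the residues that possess chi1 (all residues when
    omitted); an all-masked input is an error, not a zero.
    """
    s = np.asarray(true_s, dtype=float)
    probs = np.asarray(pred_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != n_bins:
        raise ValidationError(f"pred_probs must be (n, {n_bins})")
    if s.shape != (probs.shape[0],):
        raise ValidationError("true_s length does not match probability rows")
    mask = np.ones(s.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if mask.shape != s.shape:
        raise ValidationError("mask length mismatch")
    if not mask.any():
        raise ValidationError("no residue has an available chi1")
    _check_simplex(probs[mask])
    bins = np.array([bin_confidence(x, n_bins)[0] for x in s[mask]])
    p = np.maximum(probs[mask][np.arange(mask.sum()), bins], _PROB_FLOOR)
    return float(-np.mean(np.log(p)))


# ---------------------------------------------------------------------------
# Combined objective

def combined_loss(l_angle: float, l_wfape: float, l_secondary: float,
                  l_sc: float, l_others=(0.0,) * 6,
                  weights: LossWeights | None = None) -> float:
    """Weighted sum c1 L_angle + c2 L_WFAPE + c3 L_secondary + c4 L_sc +
    c . L_others.  The six auxiliary losses are caller-supplied scalars in
    the order (aux, dist, msa, conf, exp_resolved, violation)."""
    weights = weights or LossWeights()
    comps = np.array([l_angle, l_wfape, l_secondary, l_sc, *l_others], dtype=float)
    if comps.shape != (10,):
        raise ValidationError("l_others must have exactly 6 entries")
    if not np.all(np.isfinite(comps)):
        raise ValidationError("loss components must be finite")
    if np.any(comps < 0):
        raise ValidationError("loss components must be non-negative")
    c = np.array([weights.c1, weights.c2, weights.c3, weights.c4,
                  *weights.c_others])
    return float(np.dot(c, comps))
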