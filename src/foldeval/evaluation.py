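"""Assessment statistics for predicted protein structures.

Four evaluators:

* ``chi_accuracy`` — the fraction of residues whose chi_k is reproduced
  to within a tolerance (10 degrees by convention), the standard
  side-chain correctness criterion;
* ``sequence_confidence`` — the mean side-chain confidence score over a
  sequence;
* ``alignment_quality`` — a template/alignment quality ratio: of the
  native residue pairs in contact (sequence separation > 3, distance
  < 8 A), the fraction whose distance is preserved (within 3 A) at the
  aligned template positions, unaligned pairs counting as failures;
* ``z_scores`` / ``assessor_sum_z`` — CASP-style standardized scores per
  (domain, metric) across predicting groups, and their weighted
  aggregation over ten assessment metrics:

      sum Z = 1/6 (GDT-HA + reLLG + ASE)
            + 1/16 (LDDT + AA + SG + SCerror)
            + 1/12 (Molprobity + BBerror + DipDiff)

  The weights sum to exactly 1, so a group one standard deviation above
  the mean in every metric of every domain scores the domain count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedResultError, ValidationError
from .geometry import StructureModel, TorsionSet
from .losses import ConfidenceConfig, chi_differences, side_chain_confidence

__all__ = [
    "ASSESSOR_METRIC_WEIGHTS",
    "LOWER_IS_BETTER",
    "PairAlignment",
    "MetricTable",
    "ZScoreConfig",
    "chi_accuracy",
    "sequence_confidence",
    "alignment_quality",
    "z_scores",
    "assessor_sum_z",
    "rank_groups",
]

#: The ten assessment metrics of the sum-Z formula and their weights.
ASSESSOR_METRIC_WEIGHTS = {
    "GDT-HA": 1 / 6, "reLLG": 1 / 6, "ASE": 1 / 6,
    "LDDT": 1 / 16, "AA": 1 / 16, "SG": 1 / 16, "SCerror": 1 / 16,
    "Molprobity": 1 / 12, "BBerror": 1 / 12, "DipDiff": 1 / 12,
}

#: Metrics where a smaller raw value means a better model; their Z-scores
#: are computed on the negated values so that higher Z is always better.
LOWER_IS_BETTER = frozenset({"SCerror", "Molprobity", "BBerror", "DipDiff"})

_METRIC_ALIASES = {"Molprb": "Molprobity", "MolPrb": "Molprobity"}


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class PairAlignment:
    """Matched positions of a pairwise alignment, 1-based over the
    ungapped sequences; both columns strictly increasing (no crossings)."""

    pairs: list[tuple[int, int]]
    query_length: int
    template_length: int

    def __post_init__(self) -> None:
        self.pairs = [(int(q), int(t)) for q, t in self.pairs]
        prev_q = prev_t = 0
        for q, t in self.pairs:
            if q <= prev_q or t <= prev_t:
                raise ValidationError(
                    f"alignment pairs must be strictly increasing; saw ({q}, {t}) "
                    f"after ({prev_q}, {prev_t})")
            prev_q, prev_t = q, t
        if self.pairs:
            if self.pairs[-1][0] > self.query_length:
                raise ValidationError("query position exceeds query length")
            if self.pairs[-1][1] > self.template_length:
                raise ValidationError("template position exceeds template length")

    def query_to_template(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class MetricTable:
    """Raw (group, domain, metric) assessment values.

    ``orientation`` maps metric name -> True when higher is better; any
    metric absent from the map falls back to the built-in convention
    (SCerror, Molprobity, BBerror, DipDiff are lower-is-better).
    """

    rows: pd.DataFrame  # columns: group, domain, metric, value
    orientation: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"group", "domain", "metric", "value"}
        if not required.issubset(self.rows.columns):
            raise ValidationError(f"metric table needs columns {sorted(required)}")
        self.rows = self.rows.copy()
        self.rows["metric"] = self.rows["metric"].replace(_METRIC_ALIASES)
        dup = self.rows.duplicated(subset=["group", "domain", "metric"])
        if dup.any():
            first = self.rows[dup].iloc[0]
            raise ValidationError(
                f"duplicate entry for ({first['group']}, {first['domain']}, "
                f"{first['metric']})")
        if not np.all(np.isfinite(self.rows["value"].to_numpy(dtype=float))):
            raise ValidationError("metric values must be finite")

    def higher_is_better(self, metric: str) -> bool:
        metric = _METRIC_ALIASES.get(metric, metric)
        if metric in self.orientation:
            return self.orientation[metric]
        return metric not in LOWER_IS_BETTER


@dataclass
class ZScoreConfig:
    """Z-score computation settings.

    ``two_pass`` recomputes mean/sd after excluding first-pass outliers
    with Z < -2 (long-standing CASP practice); ``floor`` clips the final
    Z from below (default -2) so one catastrophic model cannot dominate a
    ranking downward.
    """

    floor: float = -2.0
    two_pass: bool = True

    def __post_init__(self) -> None:
        if self.floor > 0:
            raise ValidationError("Z floor must be <= 0")


# ---------------------------------------------------------------------------
# Torsion-level statistics

def chi_accuracy(torsions_true: TorsionSet, torsions_pred: TorsionSet,
                 k: int, threshold_deg: float = 10.0,
                 symmetry_correct: bool = True) -> float:
    """Fraction of residues possessing chi_k predicted within the
    threshold (strict inequality on the absolute circular difference,
    pi-symmetry-corrected where the residue's end group is two-fold
    symmetric)."""
    if k not in (1, 2, 3, 4):
        raise ValidationError("k must be 1..4")
    delta = chi_differences(torsions_true, torsions_pred, symmetry_correct)
    have = torsions_true.mask[:, k - 1]
    if not have.any():
        raise UndefinedResultError(f"no residue possesses chi{k}")
    within = np.abs(delta[have, k - 1]) < np.deg2rad(threshold_deg)
    return float(np.mean(within))


def sequence_confidence(torsions_true: TorsionSet, torsions_pred: TorsionSet,
                        delta0: float | None = None,
                        symmetry_correct: bool = True) -> float:
    """Mean side-chain confidence over residues with an available chi1.

    ``delta0`` is in radians (default: the 12-degree reference).
    """
    if delta0 is None:
        delta0 = ConfidenceConfig().delta0_rad
    delta = chi_differences(torsions_true, torsions_pred, symmetry_correct)
    have = torsions_true.mask[:, 0]
    if not have.any():
        raise UndefinedResultError("no residue possesses chi1")
    return float(np.mean(side_chain_confidence(delta[have, 0], delta0)))


# ---------------------------------------------------------------------------
# Template alignment quality

def alignment_quality(native: StructureModel, template: StructureModel,
                      aln: PairAlignment, min_sep: int = 4,
                      native_cutoff: float = 8.0,
                      sim_threshold: float = 3.0) -> float:
    """Fraction of native contact pairs whose distance the aligned
    template reproduces.

    Collects native residue pairs (i, j) with author-numbering separation
    |i - j| >= ``min_sep`` and Cb-Cb distance < ``native_cutoff``; a pair
    counts as similar when both positions are aligned and the template
    distance at the aligned positions differs from the native one by less
    than ``sim_threshold``.  Pairs with an unaligned endpoint stay in the
    denominator as failures, so short alignments are penalized.
    Distances use Cb with CA fallback for glycine.
    """
    if len(native) != aln.query_length:
        raise ValidationError(
            f"alignment query length {aln.query_length} does not match the "
            f"native structure ({len(native)} residues)")
    if len(template) != aln.template_length:
        raise ValidationError(
            f"alignment template length {aln.template_length} does not match "
            f"the template structure ({len(template)} residues)")
    cb_nat = native.cb_coordinates()
    cb_tmp = template.cb_coordinates()
    author = np.array([r.index for r in native.residues])
    q2t = aln.query_to_template()

    n = len(native)
    collected = 0
    similar = 0
    for i in range(n):
        for j in range(i + 1, n):
            if abs(author[j] - author[i]) < min_sep:
                continue
            d_nat = float(np.linalg.norm(cb_nat[i] - cb_nat[j]))
            if d_nat >= native_cutoff:
                continue
            collected += 1
            ti = q2t.get(i + 1)
            tj = q2t.get(j + 1)
            if ti is None or tj is None:
                continue
            d_tmp = float(np.linalg.norm(cb_tmp[ti - 1] - cb_tmp[tj - 1]))
            if abs(d_nat - d_tmp) < sim_threshold:
                similar += 1
    if collected == 0:
        raise UndefinedResultError(
            "no native residue pair satisfies the separation/distance filter")
    return similar / collected


# ---------------------------------------------------------------------------
# Z-scores and the assessor aggregation

def z_scores(table: MetricTable, cfg: ZScoreConfig | None = None) -> pd.DataFrame:
    """Standardized scores per (domain, metric) across groups.

    Orientation is flipped for lower-is-better metrics so that higher Z
    is always better.  With ``cfg.two_pass`` the mean and (population)
    standard deviation are recomputed after dropping first-pass Z < -2,
    and the final Z is floored at ``cfg.floor``.  A zero spread yields
    Z = 0 for every group.  Returns a DataFrame with columns
    group, domain, metric, z.
    """
    cfg = cfg or ZScoreConfig()
    out = []
    for (domain, metric), sub in table.rows.groupby(["domain", "metric"],
                                                    sort=False):
        values = sub["value"].to_numpy(dtype=float)
        if len(values) < 2:
            raise ValidationError(
                f"({domain}, {metric}): need >= 2 groups to standardize")
        x = values if table.higher_is_better(metric) else -values
        z = _standardize(x)
        if cfg.two_pass:
            keep = z >= -2.0
            z = _standardize(x, reference=x[keep] if keep.any() else x)
            z = np.maximum(z, cfg.floor)
        for g, zv in zip(sub["group"], z):
            out.append((g, domain, metric, float(zv)))
    return pd.DataFrame(out, columns=["group", "domain", "metric", "z"])


def _standardize(x: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    ref = x if reference is None else reference
    if ref.size < 2:
        return np.zeros_like(x)
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - float(np.mean(ref))) / sd


def assessor_sum_z(z_by_domain) -> float:
    """Weighted sum-Z over domains for one group.

    ``z_by_domain`` maps domain -> {metric -> Z} with the ten metrics of
    ``ASSESSOR_METRIC_WEIGHTS``.  Domains missing any metric are skipped
    with a warning; unknown metric names are an error.
    """
    total = 0.0
    for domain, metrics in z_by_domain.items():
        canon = {}
        for name, z in metrics.items():
            name = _METRIC_ALIASES.get(name, name)
            if name not in ASSESSOR_METRIC_WEIGHTS:
                raise ValidationError(
                    f"unknown assessor metric {name!r} in domain {domain!r}")
            canon[name] = float(z)
        missing = set(ASSESSOR_METRIC_WEIGHTS) - set(canon)
        if missing:
            warnings.warn(f"domain {domain!r} missing metrics {sorted(missing)}; "
                          "skipped", stacklevel=2)
            continue
        total += sum(w * canon[m] for m, w in ASSESSOR_METRIC_WEIGHTS.items())
    return float(total)


def rank_groups(table: MetricTable, cfg: ZScoreConfig | None = None) -> pd.DataFrame:
    """Sum-Z ranking of all groups in a metric table.

    Computes per-(domain, metric) Z-scores, aggregates them with the
    assessor weights per group, and returns a DataFrame sorted by
    descending sum Z with columns group, sum_z, n_domains.
    """
    z = z_scores(table, cfg)
    rows = []
    for group, sub in z.groupby("group", sort=False):
        by_domain: dict = {}
        for _, r in sub.iterrows():
            by_domain.setdefault(r["domain"], {})[r["metric"]] = r["z"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            total = assessor_sum_z(by_domain)
        complete = sum(1 for m in by_domain.values()
                       if set(ASSESSOR_METRIC_WEIGHTS) <= set(m))
        rows.append((group, total, complete))
    df = pd.DataFrame(rows, columns=["group", "sum_z", "n_domains"])
    return df.sort_values("sum_z", ascending=False, ignore_index=True)
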