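"""Discrimination statistics and ground-truthing evaluation.

Two validation modes share these statistics:

* cross-validation — withheld presences scored against withheld background;
* ground-truthing — model predictions at independently surveyed traps with
  true presence/absence outcomes.

AUC is the rank (Mann-Whitney) statistic; the classification threshold is
the score maximising sensitivity + specificity over the observed scores
("maximum accuracy" in the maxSSS sense); TSS = sensitivity + specificity
- 1 at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .raster import CovariateStack

__all__ = [
    "EvalStats",
    "auc",
    "max_accuracy_threshold",
    "tss",
    "evaluate_independent",
    "compare_validation",
]


@dataclass
class EvalStats:
    """Per-model validation statistics (one table row per species)."""

    auc_cross_mean: float | None = None
    auc_cross_sd: float | None = None
    auc_independent_mean: float | None = None
    auc_independent_sd: float | None = None
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    tss: float | None = None
    n_pos: int = 0
    n_neg: int = 0
    n_excluded: int = 0
    evaluable: bool = True
    notes: list[str] = field(default_factory=list)


def auc(pos_scores, neg_scores) -> float:
    """Rank AUC: P(random positive outscores random negative), ties half.

    Computed from the rank-sum in O(m log m); identical to the brute-force
    pair count [#(p > n) + 0.5 #(p = n)] / (|pos| |neg|).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def max_accuracy_threshold(pos_scores, neg_scores) -> tuple[float, float, float]:
    """Threshold from the observed scores maximising sensitivity + specificity.

    Prediction is "presence" iff score >= threshold; ties on the objective
    are broken by the smallest qualifying threshold.  Returns (threshold,
    sensitivity, specificity).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    cand = np.unique(np.concatenate([pos, neg]))
    # fraction of each group at or above each candidate threshold
    sens = 1.0 - np.searchsorted(np.sort(pos), cand, side="left") / pos.size
    spec = np.searchsorted(np.sort(neg), cand, side="left") / neg.size
    obj = sens + spec
    # smallest tau among ties, robust to float rounding of the fractions
    best = int(np.flatnonzero(obj >= obj.max() - 1e-9)[0])
    return float(cand[best]), float(sens[best]), float(spec[best])


def tss(sensitivity: float, specificity: float) -> float:
    """True Skill Statistic, sensitivity + specificity - 1, in [-1, 1]."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def _bootstrap_auc_sd(pos, neg, n_boot: int, seed: int) -> float:
    """Stratified bootstrap standard deviation of the AUC."""
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ps = pos[rng.integers(0, len(pos), len(pos))]
        ns = neg[rng.integers(0, len(neg), len(neg))]
        vals[b] = auc(ps, ns)
    return float(vals.std(ddof=1))


def evaluate_independent(
    results,
    survey: pd.DataFrame,
    species_id: str,
    stack: CovariateStack,
    scale: str = "cloglog",
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalStats:
    """Ground-truth a fitted model against trap-survey presence/absence.

    Each trap is mapped to its containing raster cell and scored by the
    model prediction there; records are *not* deduplicated by cell, so
    repeated traps in one cell each contribute a record.  Traps off the
    raster are excluded and counted.  AUC uncertainty is a seeded
    stratified bootstrap over records.
    """
    if species_id not in survey.columns:
        raise ValueError(f"survey has no outcome column for {species_id!r}")
    ok = stack.on_valid_cell(survey["x"].to_numpy(), survey["y"].to_numpy())
    n_excluded = int((~ok).sum())
    sub = survey.loc[ok]
    outcomes = sub[species_id].to_numpy().astype(int)
    stats = EvalStats(n_pos=int(outcomes.sum()),
                      n_neg=int((1 - outcomes).sum()),
                      n_excluded=n_excluded)
    if stats.n_pos == 0 or stats.n_neg == 0:
        stats.evaluable = False
        stats.notes.append("no presences or no absences after raster mapping")
        return stats
    scores = results.predict(stack=stack, xy=sub[["x", "y"]].to_numpy(), scale=scale)
    pos, neg = scores[outcomes == 1], scores[outcomes == 0]
    stats.auc_independent_mean = auc(pos, neg)
    stats.auc_independent_sd = _bootstrap_auc_sd(pos, neg, n_boot, seed)
    thr, sens, spec = max_accuracy_threshold(pos, neg)
    stats.threshold, stats.sensitivity, stats.specificity = thr, sens, spec
    stats.tss = tss(sens, spec)
    return stats


def compare_validation(cross: EvalStats, independent: EvalStats,
                       equivalence_band: float = 0.02) -> dict:
    """Cross-validation vs independent AUC, the ground-truthing gap.

    Returns delta = AUC_cross - AUC_independent and a qualitative category:
    'independent_lower' (delta > band), 'independent_higher' (delta <
    -band), else 'equivocal'.
    """
    if (not cross.evaluable or not independent.evaluable
            or cross.auc_cross_mean is None
            or independent.auc_independent_mean is None):
        return {"available": False, "delta_auc": None, "category": "unavailable"}
    delta = cross.auc_cross_mean - independent.auc_independent_mean
    if delta > equivalence_band:
        category = "independent_lower"
    elif delta < -equivalence_band:
        category = "independent_higher"
    else:
        category = "equivocal"
    return {"available": True, "delta_auc": float(delta), "category": category}
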