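"""Model tuning over feature classes and regularisation multipliers.

For every candidate (fc, rm) in the grid — by default {L, Q, LQ} x
{1..5}, 15 models — the candidate is fitted on each checkerboard training
bin and evaluated on the withheld bin (validation AUC against withheld
background, omission rate at the tenth percentile against withheld
presences), and once on all data for later prediction.  The top model is
chosen sequentially: lowest mean OR.10p, ties broken by highest mean
validation AUC, then by smaller rm, then by feature-class order L < Q < LQ.
AICc from the full-data fit is reported alongside as the alternative
selection criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import auc
from .maxent import FeatureSpec, MaxEnt, MaxEntResults
from .partition import PartitionAssignment
from .raster import CovariateStack

__all__ = [
    "CandidateResult",
    "TuningResult",
    "tune_grid",
    "omission_rate_10p",
    "select_sequential",
    "aicc",
]

DEFAULT_FCS = ("L", "Q", "LQ")
DEFAULT_RMS = (1.0, 2.0, 3.0, 4.0, 5.0)
_FC_ORDER = {"L": 0, "Q": 1, "LQ": 2}


@dataclass
class CandidateResult:
    """One (fc, rm) candidate with its cross-validation statistics."""

    fc: str
    rm: float
    results_full: MaxEntResults | None
    bin_auc: list[float | None]
    bin_or10: list[float | None]
    aicc: float | None
    notes: list[str] = field(default_factory=list)

    def _avail(self, values) -> list[float]:
        return [v for v in values if v is not None]

    @property
    def evaluable(self) -> bool:
        return len(self._avail(self.bin_auc)) > 0

    @property
    def auc_mean(self) -> float | None:
        v = self._avail(self.bin_auc)
        return float(np.mean(v)) if v else None

    @property
    def auc_sd(self) -> float | None:
        v = self._avail(self.bin_auc)
        return float(np.std(v, ddof=1)) if len(v) > 1 else None

    @property
    def or10_mean(self) -> float | None:
        v = self._avail(self.bin_or10)
        return float(np.mean(v)) if v else None

    @property
    def or10_sd(self) -> float | None:
        v = self._avail(self.bin_or10)
        return float(np.std(v, ddof=1)) if len(v) > 1 else None

    @property
    def ncoef(self) -> int | None:
        return self.results_full.ncoef if self.results_full is not None else None


@dataclass
class TuningResult:
    """All candidates of one tuning run, plus the selection."""

    candidates: list[CandidateResult]
    selected_index: int | None = None
    selection_trace: list[str] = field(default_factory=list)

    @property
    def selected(self) -> CandidateResult | None:
        return None if self.selected_index is None else self.candidates[self.selected_index]

    def table(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.candidates):
            rows.append({
                "fc": c.fc, "rm": c.rm, "ncoef": c.ncoef,
                "or10_mean": c.or10_mean, "or10_sd": c.or10_sd,
                "auc_mean": c.auc_mean, "auc_sd": c.auc_sd,
                "aicc": c.aicc,
                "selected": i == self.selected_index,
            })
        return pd.DataFrame(rows)


def omission_rate_10p(train_presence_scores, withheld_presence_scores) -> float:
    """Omission rate at the tenth percentile of training presence scores.

    The threshold drops the ceil(n/10) lowest-scoring training presences
    (so at least 90% of them score at or above it); the omission rate is
    the fraction of withheld presences scoring strictly below it.
    """
    train = np.sort(np.asarray(train_presence_scores, dtype=float))
    withheld = np.asarray(withheld_presence_scores, dtype=float)
    if train.size == 0 or withheld.size == 0:
        raise ValueError("need at least one training and one withheld score")
    k = -(-train.size // 10)  # ceil(n/10)
    tau = np.inf if k >= train.size else train[k]
    return float(np.mean(withheld < tau))


def tune_grid(
    occ_xy: np.ndarray,
    bg_xy: np.ndarray,
    partition: PartitionAssignment,
    stack: CovariateStack,
    fcs=DEFAULT_FCS,
    rms=DEFAULT_RMS,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    scale: str = "cloglog",
) -> TuningResult:
    """Fit and cross-validate the full fc x rm candidate grid.

    For each candidate and each bin b: train on bin != b (occurrences and
    background), score the withheld bin; also fit on all data.  Bins with
    fewer than two training or one withheld occurrence are flagged missing
    and the candidate's means are taken over the available bins.
    """
    occ_xy = np.asarray(occ_xy, dtype=float).reshape(-1, 2)
    bg_xy = np.asarray(bg_xy, dtype=float).reshape(-1, 2)
    if len(partition.occurrence_bins) != len(occ_xy):
        raise ValueError("partition does not cover the occurrences")
    if len(partition.background_bins) != len(bg_xy):
        raise ValueError("partition does not cover the background")

    candidates: list[CandidateResult] = []
    for fc in fcs:
        base_spec = FeatureSpec.from_background(stack, bg_xy, fc, rm=1.0)
        X_occ = base_spec.transform(stack, occ_xy)
        X_bg = base_spec.transform(stack, bg_xy)
        for rm in rms:
            spec = replace(base_spec, rm=float(rm))
            bin_auc: list[float | None] = []
            bin_or10: list[float | None] = []
            notes: list[str] = []
            for b in (1, 2):
                tr_occ = partition.occurrence_bins != b
                te_occ = ~tr_occ
                tr_bg = partition.background_bins != b
                te_bg = ~tr_bg
                if tr_occ.sum() < 2 or te_occ.sum() < 1 or te_bg.sum() < 1:
                    bin_auc.append(None)
                    bin_or10.append(None)
                    notes.append(f"bin {b}: too few occurrences, statistics missing")
                    warnings.warn(f"candidate fc={fc} rm={rm}: bin {b} unevaluable")
                    continue
                model = MaxEnt(X_occ[tr_occ], X_bg[tr_bg],
                               penalties=spec.default_penalties(int(tr_occ.sum())),
                               spec=spec)
                res = model.fit(tol=tol, max_iter=max_iter)
                train_scores = res.predict(X_occ[tr_occ], scale=scale)
                test_scores = res.predict(X_occ[te_occ], scale=scale)
                bg_scores = res.predict(X_bg[te_bg], scale=scale)
                bin_auc.append(auc(test_scores, bg_scores))
                bin_or10.append(omission_rate_10p(train_scores, test_scores))
            full = MaxEnt(X_occ, X_bg,
                          penalties=spec.default_penalties(len(occ_xy)),
                          spec=spec).fit(tol=tol, max_iter=max_iter)
            candidates.append(CandidateResult(
                fc, float(rm), full, bin_auc, bin_or10,
                aicc(full, X_occ), notes,
            ))
    result = TuningResult(candidates)
    select_sequential(result)
    return result


def select_sequential(result: TuningResult) -> CandidateResult:
    """Sequential top-model choice on the tuning table.

    Minimum mean OR.10p; ties by maximum mean validation AUC; remaining
    ties by smaller rm, then feature-class order L < Q < LQ.  Pure function
    of the statistics (permutation-invariant); the trace is logged on the
    result.
    """
    evaluable = [(i, c) for i, c in enumerate(result.candidates) if c.evaluable]
    if not evaluable:
        raise ValueError("no evaluable candidate to select from")
    key = lambda ic: (ic[1].or10_mean, -ic[1].auc_mean, ic[1].rm, _FC_ORDER[ic[1].fc])
    order = sorted(evaluable, key=key)
    best_i, best = order[0]
    result.selected_index = best_i
    result.selection_trace = [
        f"{len(evaluable)}/{len(result.candidates)} candidates evaluable",
        f"selected fc={best.fc} rm={best.rm:g} "
        f"(OR.10p={best.or10_mean:.4f}, AUC={best.auc_mean:.4f})",
    ]
    return best


def aicc(results: MaxEntResults, occ_features: np.ndarray) -> float | None:
    """Small-sample-corrected AIC of a full-data fit.

    The raw prediction is standardised to sum to one over the background
    sample (the model's normalising support); the log-likelihood is the sum
    of standardised log predictions at the occurrences; k is the nonzero
    coefficient count.  Undefined (None) when n <= k + 1.
    """
    n = occ_features.shape[0]
    k = results.ncoef
    if n <= k + 1:
        return None
    eta = np.asarray(occ_features, dtype=float) @ results.params
    lnl = float(np.sum(eta - results.log_norm))
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
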