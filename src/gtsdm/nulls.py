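"""Null-model significance testing for cross-validation performance.

A null model is fitted to localities sampled uniformly at random from the
study extent — as many as the real training fold contains — with the same
feature class, regularisation and background as the real model, and then
evaluated against the *real* withheld occurrences and background.  Repeating
this (100 iterations by default) yields an empirical distribution of the
validation AUC attainable with no ecological signal, against which the real
model's AUC can be placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import auc
from .maxent import FeatureSpec, MaxEnt
from .partition import PartitionAssignment
from .prep import StudyExtent
from .raster import CovariateStack

__all__ = ["NullDistribution", "run_null_models", "significance"]


@dataclass
class NullDistribution:
    """Empirical null AUC sample and the real model's placement.

    ``null_auc``/``real_auc`` are fold-mean statistics (the aggregate the
    study design reports).  ``fold_null_auc``/``fold_real_auc`` keep the
    per-checkerboard-fold values: the fold-mean placement is
    anti-conservative for calibration questions because the two real fold
    AUCs are strongly coupled while each null iteration averages two
    independent fits, so per-fold placement is the exchangeable comparison.
    """

    null_auc: np.ndarray
    n_iter: int
    n_failed: int
    real_auc: float
    seed: int
    fold_null_auc: dict[int, np.ndarray] = field(default_factory=dict)
    fold_real_auc: dict[int, float] = field(default_factory=dict)
    per_iteration: pd.DataFrame | None = field(default=None, repr=False)


def _sample_mask_cells(mask: np.ndarray, stack: CovariateStack, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    cells = np.flatnonzero(mask.ravel())
    chosen = rng.choice(cells, size=n, replace=True)
    row, col = np.unravel_index(chosen, stack.shape)
    cx, cy = stack.cell_center(row, col)
    x = cx + (rng.random(n) - 0.5) * stack.cell_size
    y = cy + (rng.random(n) - 0.5) * stack.cell_size
    return np.column_stack([x, y])


def run_null_models(
    occ_xy: np.ndarray,
    bg_xy: np.ndarray,
    partition: PartitionAssignment,
    extent: StudyExtent,
    stack: CovariateStack,
    fc: str = "L",
    rm: float = 1.0,
    n_iter: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    real_auc: float | None = None,
    real_fold_auc: dict[int, float] | None = None,
) -> NullDistribution:
    """Build the null AUC distribution for one model configuration.

    Per iteration and per checkerboard fold: sample as many random
    localities from the extent as the real training fold holds, fit with
    the same fc/rm/penalty settings against the same training background,
    score the real withheld occurrences against the withheld background,
    and average the two folds — exactly the real pipeline's statistic.
    Null localities are drawn from the extent restricted to the training
    fold's checkerboard blocks, mirroring how the real training data are
    spatially confined (random localities partitioned like the real ones);
    sampling them from the whole extent instead would make null models see
    withheld-area environments the real model never does, and the null AUC
    distribution would be too narrow.  A null fit that fails to converge is
    resampled once, then recorded as failed and excluded.  Deterministic
    given the seed.
    """
    occ_xy = np.asarray(occ_xy, dtype=float).reshape(-1, 2)
    bg_xy = np.asarray(bg_xy, dtype=float).reshape(-1, 2)
    if extent.n_cells == 0:
        raise ValueError("study extent is empty")
    spec = FeatureSpec.from_background(stack, bg_xy, fc, rm)
    X_occ = spec.transform(stack, occ_xy)
    X_bg = spec.transform(stack, bg_xy)

    # checkerboard bin of every grid cell, to confine null localities to
    # the training fold's blocks
    f = partition.aggregation_factor
    rows, cols = np.indices(stack.shape)
    cell_bins = 1 + ((rows // f + cols // f) % 2)

    folds = []
    for b in (1, 2):
        tr_occ = partition.occurrence_bins != b
        te_occ = ~tr_occ
        tr_bg = partition.background_bins != b
        te_bg = ~tr_bg
        if tr_occ.sum() < 2 or te_occ.sum() < 1:
            continue
        folds.append({
            "bin": b,
            "train_mask": extent.mask & (cell_bins != b),
            "n_train": int(tr_occ.sum()),
            "Xb_train": X_bg[tr_bg],
            "X_test_occ": X_occ[te_occ],
            "Xb_test": X_bg[te_bg],
            "penalties": spec.default_penalties(int(tr_occ.sum())),
            "X_train_occ": X_occ[tr_occ],
        })
    if not folds:
        raise ValueError("no evaluable checkerboard fold")

    fold_real: dict[int, float] = {}
    if real_fold_auc is not None and all(f["bin"] in real_fold_auc for f in folds):
        fold_real = {f["bin"]: float(real_fold_auc[f["bin"]]) for f in folds}
    else:
        for f in folds:
            res = MaxEnt(f["X_train_occ"], f["Xb_train"], penalties=f["penalties"],
                         spec=spec).fit(tol=tol, max_iter=max_iter)
            fold_real[f["bin"]] = auc(res.predict(f["X_test_occ"], scale="raw"),
                                      res.predict(f["Xb_test"], scale="raw"))
    if real_auc is None:
        real_auc = float(np.mean(list(fold_real.values())))

    rng = np.random.default_rng(seed)
    null_vals: list[float] = []
    fold_nulls: dict[int, list[float]] = {f["bin"]: [] for f in folds}
    rows = []
    n_failed = 0
    for it in range(n_iter):
        fold_vals = {}
        ok = True
        for f in folds:
            res = None
            for _ in range(2):  # one resample on non-convergence
                pts = _sample_mask_cells(f["train_mask"], stack, f["n_train"], rng)
                Xn = spec.transform(stack, pts)
                cand = MaxEnt(Xn, f["Xb_train"], penalties=f["penalties"],
                              spec=spec).fit(tol=tol, max_iter=max_iter)
                if cand.converged:
                    res = cand
                    break
            if res is None:
                ok = False
                break
            a = auc(res.predict(f["X_test_occ"], scale="raw"),
                    res.predict(f["Xb_test"], scale="raw"))
            fold_vals[f["bin"]] = a
            rows.append({"iteration": it, "fold": f["bin"], "null_auc": a,
                         "converged": True})
        if ok:
            null_vals.append(float(np.mean(list(fold_vals.values()))))
            for b, a in fold_vals.items():
                fold_nulls[b].append(a)
        else:
            n_failed += 1
            rows.append({"iteration": it, "fold": np.nan, "null_auc": np.nan,
                         "converged": False})
    return NullDistribution(
        np.asarray(null_vals), n_iter, n_failed, float(real_auc), seed,
        {b: np.asarray(v) for b, v in fold_nulls.items()}, fold_real,
        pd.DataFrame(rows),
    )


def significance(dist: NullDistribution, fold: int | None = None) -> dict:
    """Place the real AUC in the null distribution.

    Returns the add-one-corrected empirical p-value
    (1 + #{null >= real}) / (B + 1), the z-score (real - mean) / sd, and
    the percentile (fraction of nulls strictly below the real AUC).  The
    z-score is None when the null sample has zero spread.

    By default the fold-mean statistics are compared (the aggregate the
    study design reports).  Pass a checkerboard ``fold`` number for the
    per-fold placement, which is the exchangeable comparison under no
    signal (see :class:`NullDistribution`).
    """
    if fold is None:
        null = np.asarray(dist.null_auc, dtype=float)
        real = dist.real_auc
    else:
        null = np.asarray(dist.fold_null_auc[fold], dtype=float)
        real = dist.fold_real_auc[fold]
    if null.size == 0:
        raise ValueError("no successful null iteration")
    b = null.size
    p = (1 + int(np.sum(null >= real))) / (b + 1)
    sd = null.std(ddof=1) if b > 1 else 0.0
    z = None if sd == 0 else float((real - null.mean()) / sd)
    percentile = float(np.mean(null < real))
    return {"empirical_p": float(p), "z_score": z, "percentile_of_real": percentile,
            "n_successful": b, "n_failed": dist.n_failed}
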