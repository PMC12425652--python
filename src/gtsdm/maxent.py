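"""Presence-background maximum-entropy estimator.

The model is the Gibbs density over the background sample

    P(x) = exp(sum_j lambda_j f_j(x)) / sum_{b in background} exp(sum_j lambda_j f_j(b))

fitted by maximising the L1-penalised presence log-likelihood per presence
point

    l(lambda) = (1/m) sum_{i in presence} log P(x_i) - sum_j beta_j |lambda_j|,

the normalisation under which the default penalty schedule
beta_j = rm * beta_class(m) * s_j / sqrt(m) has its conventional strength,
a concave problem whose solution satisfies the usual subgradient (KKT)
conditions: |dl/dlambda_j| <= beta_j where lambda_j = 0 and
dl/dlambda_j = sign(lambda_j) beta_j elsewhere.  Features are min-max
scaled linear and quadratic transforms of the continuous covariates plus
one 0/1 indicator per categorical level; hinge, product and threshold
features are deliberately not implemented.

The solver is a deterministic active-set Newton method: at each outer step
the most KKT-violating features join the working set, a damped Newton step
is taken in the orthant given by the coefficient signs (coordinates that
would cross zero are truncated to zero), and a proximal-gradient step is
the fallback whenever the Newton step fails its line search.  Every
accepted step increases the penalised objective, and coefficients leave the
model exactly at zero, so the nonzero-coefficient count is well defined.

Organisation follows the statsmodels convention: :class:`MaxEnt` is built
from data, ``fit()`` returns a :class:`MaxEntResults` carrying estimates
and diagnostics, and prediction and plotting hang off the results object.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .raster import CATEGORICAL, CONTINUOUS, CovariateStack

__all__ = [
    "Feature",
    "FeatureSpec",
    "MaxEnt",
    "MaxEntResults",
    "build_features",
    "default_regularization",
]

LINEAR = "linear"
QUADRATIC = "quadratic"
INDICATOR = "indicator"

FEATURE_CLASSES = ("L", "Q", "LQ")

# Default per-class regularisation schedules: piecewise-linear interpolation
# of beta_class against the presence sample size, the canonical defaults for
# linear/quadratic and categorical feature sets.
_BETA_SCHEDULE = {
    "lq": (np.array([10.0, 30.0, 100.0]), np.array([1.0, 0.2, 0.05])),
    "categorical": (np.array([0.0, 10.0, 17.0]), np.array([0.65, 0.5, 0.25])),
}


@dataclass(frozen=True)
class Feature:
    """One model feature: a transform of a source layer."""

    name: str
    kind: str  # linear | quadratic | indicator
    layer: str
    level: int | None = None
    lo: float = 0.0   # background min of the source layer (continuous)
    hi: float = 1.0   # background max


@dataclass
class FeatureSpec:
    """Feature expansion of a covariate stack for one feature class.

    Scaling bounds and feature standard deviations come from the background
    sample the spec was built from; they are frozen so that training and
    projection use identical transforms.
    """

    feature_class: str
    rm: float
    features: list[Feature]
    background_sd: np.ndarray  # s_j over the background design
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}")
        if self.rm < 0:
            raise ValueError("regularisation multiplier must be >= 0")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    # -- construction ----------------------------------------------------

    @classmethod
    def from_background(
        cls,
        stack: CovariateStack,
        background_xy: np.ndarray,
        feature_class: str = "LQ",
        rm: float = 1.0,
        clamp: bool = True,
    ) -> "FeatureSpec":
        """Build the expansion with min-max bounds from the background."""
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}")
        background_xy = np.asarray(background_xy, dtype=float)
        vals = stack.extract(background_xy[:, 0], background_xy[:, 1])
        features: list[Feature] = []
        for k, lyr in enumerate(stack.layers):
            if lyr.kind == CONTINUOUS:
                lo, hi = float(vals[:, k].min()), float(vals[:, k].max())
                if lo == hi:
                    warnings.warn(f"layer {lyr.name!r} is constant over the background; dropped")
                    continue
                if feature_class in ("L", "LQ"):
                    features.append(Feature(lyr.name, LINEAR, lyr.name, None, lo, hi))
                if feature_class in ("Q", "LQ"):
                    features.append(Feature(f"{lyr.name}^2", QUADRATIC, lyr.name, None, lo, hi))
            else:
                for code in lyr.codes or ():
                    features.append(Feature(f"{lyr.name}={code}", INDICATOR, lyr.name, code))
        spec = cls(feature_class, rm, features, np.ones(len(features)), clamp)
        design = spec.transform(stack, background_xy)
        spec.background_sd = design.std(axis=0)
        return spec

    # -- design matrices -------------------------------------------------

    def transform(self, stack: CovariateStack, xy: np.ndarray,
                  clamp: bool | None = None) -> np.ndarray:
        """Feature matrix (n_points, n_features) for points on the stack."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        raw = stack.extract(xy[:, 0], xy[:, 1])
        return self._expand(raw, stack.layer_names, clamp)

    def transform_grid(self, stack: CovariateStack,
                       clamp: bool | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix over all valid cells.

        Returns (design, flat_indices) where ``flat_indices`` locates each
        design row in the ravelled grid.
        """
        ok = np.flatnonzero(stack.valid_mask.ravel())
        raw = np.column_stack([lyr.values.ravel()[ok] for lyr in stack.layers])
        return self._expand(raw, stack.layer_names, clamp), ok

    def _expand(self, raw: np.ndarray, layer_names: list[str],
                clamp: bool | None) -> np.ndarray:
        clamp = self.clamp if clamp is None else clamp
        col = {n: i for i, n in enumerate(layer_names)}
        out = np.empty((raw.shape[0], self.n_features))
        for j, f in enumerate(self.features):
            v = raw[:, col[f.layer]]
            if f.kind == INDICATOR:
                out[:, j] = (v == f.level).astype(float)
            else:
                z = (v - f.lo) / (f.hi - f.lo)
                if clamp:
                    z = np.clip(z, 0.0, 1.0)
                out[:, j] = z if f.kind == LINEAR else z ** 2
        return out

    # -- regularisation --------------------------------------------------

    def default_penalties(self, n_presence: int) -> np.ndarray:
        """Per-feature L1 penalties beta_j = rm * beta_class(n) * s_j / sqrt(n).

        ``beta_class`` is a non-increasing piecewise-linear interpolation in
        the presence sample size (separate schedules for linear/quadratic
        and categorical feature sets) and ``s_j`` the feature's standard
        deviation over the background sample.
        """
        if n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        beta = np.empty(self.n_features)
        for j, f in enumerate(self.features):
            key = "categorical" if f.kind == INDICATOR else "lq"
            xs, ys = _BETA_SCHEDULE[key]
            beta[j] = np.interp(n_presence, xs, ys)
        return self.rm * beta * self.background_sd / np.sqrt(n_presence)

    def to_dict(self) -> dict:
        return {
            "feature_class": self.feature_class,
            "rm": self.rm,
            "clamp": self.clamp,
            "features": [vars(f) | {} for f in self.features],
            "background_sd": self.background_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        feats = [Feature(**f) for f in d["features"]]
        return cls(d["feature_class"], d["rm"], feats, np.asarray(d["background_sd"]),
                   d.get("clamp", True))


def build_features(stack: CovariateStack, xy: np.ndarray, spec: FeatureSpec,
                   clamp: bool | None = None) -> np.ndarray:
    """Functional alias for :meth:`FeatureSpec.transform`."""
    return spec.transform(stack, xy, clamp)


def default_regularization(spec: FeatureSpec, n_presence: int) -> np.ndarray:
    """Functional alias for :meth:`FeatureSpec.default_penalties`."""
    return spec.default_penalties(n_presence)


# ---------------------------------------------------------------------------
# Solver internals
# ---------------------------------------------------------------------------

def _kkt_residual(lam: np.ndarray, grad: np.ndarray, beta: np.ndarray) -> float:
    at_zero = lam == 0
    r = np.where(at_zero,
                 np.maximum(np.abs(grad) - beta, 0.0),
                 np.abs(grad - np.sign(lam) * beta))
    return float(r.max()) if r.size else 0.0


def _soft_threshold(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class _PenalizedMaxent:
    """Maximise mean(Xp lam) - logsumexp(Xb lam) - beta'|lam|.

    This is the penalised presence log-likelihood per presence point (the
    canonical normalisation, under which the default beta schedule carries
    its usual strength); the maximiser is identical to the total-likelihood
    form with penalties scaled by the presence count.
    """

    def __init__(self, X_pres: np.ndarray, X_bg: np.ndarray, beta: np.ndarray):
        self.Xp = X_pres
        self.Xb = X_bg
        self.beta = beta
        self.m = X_pres.shape[0]
        self.s = X_pres.mean(axis=0)

    def value(self, lam: np.ndarray, eta_bg: np.ndarray) -> float:
        return float(self.s @ lam - logsumexp(eta_bg) - self.beta @ np.abs(lam))

    def grad_smooth(self, eta_bg: np.ndarray) -> np.ndarray:
        w = np.exp(eta_bg - logsumexp(eta_bg))
        return self.s - w @ self.Xb

    def solve(self, tol: float = 1e-6, max_iter: int = 10_000):
        p = self.Xb.shape[1]
        lam = np.zeros(p)
        eta = self.Xb @ lam
        obj = self.value(lam, eta)
        trace = [obj]
        step = 1.0
        converged = False
        it = 0
        while it < max_iter:
            it += 1
            grad = self.grad_smooth(eta)
            resid = _kkt_residual(lam, grad, self.beta)
            if resid <= tol:
                converged = True
                break
            new = self._newton_step(lam, eta, obj, grad, resid)
            if new is None:
                new, step = self._prox_step(lam, eta, obj, grad, step)
                if new is None:  # no improving step exists numerically
                    break
            lam, eta, obj = new
            trace.append(obj)
        grad = self.grad_smooth(eta)
        return lam, eta, obj, _kkt_residual(lam, grad, self.beta), it, converged, trace

    # -- orthant-wise damped Newton on the working set -------------------

    def _newton_step(self, lam, eta, obj, grad, resid):
        active = lam != 0
        viol = (~active) & (np.abs(grad) > self.beta)
        work = np.flatnonzero(active | viol)
        if work.size == 0:
            return None
        xi = np.sign(lam[work])
        zero = xi == 0
        xi[zero] = np.sign(grad[work[zero]])
        Xw = self.Xb[:, work]
        w = np.exp(eta - logsumexp(eta))
        a = w @ Xw
        H = Xw.T @ (Xw * w[:, None]) - np.outer(a, a)
        H[np.diag_indices_from(H)] += 1e-12 + 1e-12 * np.trace(H)
        rhs = grad[work] - xi * self.beta[work]
        try:
            d = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            d, *_ = np.linalg.lstsq(H, rhs, rcond=None)
        t = 1.0
        for _ in range(40):
            cand = lam.copy()
            cw = lam[work] + t * d
            cw[np.sign(cw) != xi] = 0.0  # orthant truncation
            cand[work] = cw
            eta_c = self.Xb @ cand
            obj_c = self.value(cand, eta_c)
            if obj_c > obj + 1e-15:
                return cand, eta_c, obj_c
            if t == 1.0 and obj_c >= obj - 1e-12 * max(1.0, abs(obj)):
                # near the optimum the objective change is below float
                # resolution; accept the full step if it tightens the KKT
                # residual instead
                grad_c = self.grad_smooth(eta_c)
                if _kkt_residual(cand, grad_c, self.beta) < 0.5 * resid:
                    return cand, eta_c, max(obj_c, obj)
            t *= 0.5
        return None

    # -- proximal-gradient fallback (monotone, backtracking) -------------

    def _prox_step(self, lam, eta, obj, grad, step):
        t = step * 4.0
        for _ in range(80):
            cand = _soft_threshold(lam + t * grad, t * self.beta)
            if np.array_equal(cand, lam):
                t *= 0.5
                continue
            eta_c = self.Xb @ cand
            obj_c = self.value(cand, eta_c)
            if obj_c > obj + 1e-14:
                return (cand, eta_c, obj_c), t
            t *= 0.5
        return None, step


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MaxEnt:
    """Presence-background maximum-entropy model.

    Parameters
    ----------
    presence_features, background_features : ndarray
        Design matrices (rows = points, columns = features) built on the
        same :class:`FeatureSpec`.
    penalties : ndarray, optional
        Per-feature L1 penalties; defaults to the spec's default schedule
        (requires ``spec``), or zeros when neither is given.
    spec : FeatureSpec, optional
        Needed for prediction on rasters/points and for default penalties.
    """

    def __init__(self, presence_features, background_features, penalties=None,
                 spec: FeatureSpec | None = None,
                 feature_names: list[str] | None = None):
        self.X_pres = np.asarray(presence_features, dtype=float)
        self.X_bg = np.asarray(background_features, dtype=float)
        if self.X_pres.ndim != 2 or self.X_bg.ndim != 2:
            raise ValueError("design matrices must be 2-D")
        if self.X_pres.shape[1] != self.X_bg.shape[1]:
            raise ValueError("presence and background feature counts differ")
        if self.X_pres.shape[0] < 2:
            raise ValueError("need at least two presence points")
        self.spec = spec
        if penalties is None:
            if spec is not None:
                penalties = spec.default_penalties(self.X_pres.shape[0])
            else:
                penalties = np.zeros(self.X_pres.shape[1])
        self.penalties = np.asarray(penalties, dtype=float)
        if (self.penalties < 0).any():
            raise ValueError("penalties must be >= 0")
        if feature_names is not None:
            self.feature_names = list(feature_names)
        elif spec is not None:
            self.feature_names = spec.feature_names
        else:
            self.feature_names = [f"f{j}" for j in range(self.X_pres.shape[1])]

    @classmethod
    def from_points(
        cls,
        stack: CovariateStack,
        presence_xy,
        background_xy,
        feature_class: str = "LQ",
        rm: float = 1.0,
        clamp: bool = True,
        spec: FeatureSpec | None = None,
        penalties=None,
    ) -> "MaxEnt":
        """Construct from coordinates on a covariate stack."""
        presence_xy = np.asarray(presence_xy, dtype=float).reshape(-1, 2)
        background_xy = np.asarray(background_xy, dtype=float).reshape(-1, 2)
        if spec is None:
            spec = FeatureSpec.from_background(stack, background_xy, feature_class, rm, clamp)
        Xp = spec.transform(stack, presence_xy)
        Xb = spec.transform(stack, background_xy)
        return cls(Xp, Xb, penalties=penalties, spec=spec)

    def fit(self, tol: float = 1e-6, max_iter: int = 10_000) -> "MaxEntResults":
        """Fit by active-set Newton with proximal-gradient fallback."""
        prob = _PenalizedMaxent(self.X_pres, self.X_bg, self.penalties)
        lam, eta, obj, resid, n_iter, converged, trace = prob.solve(tol, max_iter)
        if not converged:
            warnings.warn(
                f"maxent fit did not reach tol={tol:g} in {n_iter} iterations "
                f"(KKT residual {resid:.3g})"
            )
        return MaxEntResults(self, lam, eta, obj, resid, n_iter, converged, trace)


class MaxEntResults:
    """Fitted maximum-entropy model.

    Carries the coefficient vector, the training log-normaliser and entropy
    (needed for the cloglog transform), and solver diagnostics.
    """

    def __init__(self, model: MaxEnt, params: np.ndarray, eta_bg: np.ndarray,
                 objective: float, kkt_residual: float, n_iter: int,
                 converged: bool, objective_trace: list[float]):
        self.model = model
        self.params = params
        self.objective = objective
        self.kkt_residual = kkt_residual
        self.n_iter = n_iter
        self.converged = converged
        self.objective_trace = np.asarray(objective_trace)
        self.log_norm = float(logsumexp(eta_bg))
        w = np.exp(eta_bg - self.log_norm)
        self.entropy = float(-np.sum(w * np.log(np.maximum(w, 1e-300))))

    @property
    def ncoef(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.count_nonzero(self.params))

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    # -- prediction ------------------------------------------------------

    def _scores_from_eta(self, eta: np.ndarray, scale: str) -> np.ndarray:
        if scale == "raw":
            # cap the exponent: projection cells far outside the training
            # envelope would otherwise overflow float64
            return np.exp(np.minimum(eta - self.log_norm, 700.0))
        if scale == "cloglog":
            return -np.expm1(-np.exp(np.minimum(self.entropy + eta - self.log_norm, 700.0)))
        raise ValueError("scale must be 'raw' or 'cloglog'")

    def predict(self, features=None, *, stack: CovariateStack | None = None,
                xy=None, scale: str = "cloglog", clamp: bool | None = None) -> np.ndarray:
        """Suitability at points.

        Either pass a precomputed feature matrix, or ``stack`` and ``xy``
        (requires the model to carry a :class:`FeatureSpec`).  ``raw``
        scores are normalised over the *training* background (they sum to 1
        there); ``cloglog`` maps them monotonically into (0, 1).
        """
        if features is None:
            if stack is None or xy is None:
                raise ValueError("pass features, or stack and xy")
            if self.model.spec is None:
                raise ValueError("model has no FeatureSpec; pass features directly")
            features = self.model.spec.transform(stack, np.asarray(xy), clamp)
        eta = np.asarray(features, dtype=float) @ self.params
        return self._scores_from_eta(eta, scale)

    def predict_grid(self, stack: CovariateStack, scale: str = "cloglog",
                     clamp: bool | None = None) -> np.ndarray:
        """Suitability surface over the stack (NaN on nodata cells)."""
        if self.model.spec is None:
            raise ValueError("model has no FeatureSpec")
        design, flat = self.model.spec.transform_grid(stack, clamp)
        out = np.full(stack.shape[0] * stack.shape[1], np.nan)
        out[flat] = self._scores_from_eta(design @ self.params, scale)
        return out.reshape(stack.shape)

    def plot_prediction(self, stack: CovariateStack, scale: str = "cloglog", ax=None):
        """Quick-look suitability map (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        img = self.predict_grid(stack, scale)
        x0, y0 = stack.origin
        extent = (x0, x0 + stack.n_cols * stack.cell_size,
                  y0, y0 + stack.n_rows * stack.cell_size)
        im = ax.imshow(img, origin="upper", extent=extent, cmap="viridis")
        ax.figure.colorbar(im, ax=ax, label=f"suitability ({scale})")
        return ax

    # -- reporting -------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "coefficient": self.params,
            "penalty": self.model.penalties,
        })

    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence-background model",
            f"  presences: {self.model.X_pres.shape[0]}"
            f"   background: {self.model.X_bg.shape[0]}"
            f"   features: {len(self.params)}",
            f"  nonzero coefficients: {self.ncoef}"
            f"   converged: {self.converged}"
            f"   KKT residual: {self.kkt_residual:.2e}",
            f"  penalised log-likelihood: {self.objective:.4f}",
            "",
            f"  {'feature':<28}{'coef':>12}{'penalty':>12}",
        ]
        for name, lam, b in zip(self.feature_names, self.params, self.model.penalties):
            if lam != 0:
                lines.append(f"  {name:<28}{lam:>12.4f}{b:>12.4f}")
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        if self.model.spec is None:
            raise ValueError("serialisation requires a FeatureSpec")
        payload = {
            "spec": self.model.spec.to_dict(),
            "penalties": self.model.penalties.tolist(),
            "params": self.params.tolist(),
            "log_norm": self.log_norm,
            "entropy": self.entropy,
            "diagnostics": {
                "converged": self.converged,
                "n_iter": self.n_iter,
                "kkt_residual": self.kkt_residual,
                "objective": self.objective,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxEntResults":
        """Reload a serialised fit (sufficient for prediction/reporting;
        the original design matrices are not stored)."""
        payload = json.loads(Path(path).read_text())
        spec = FeatureSpec.from_dict(payload["spec"])
        model = MaxEnt.__new__(MaxEnt)
        model.spec = spec
        model.penalties = np.asarray(payload["penalties"], dtype=float)
        model.feature_names = spec.feature_names
        model.X_pres = np.zeros((0, spec.n_features))
        model.X_bg = np.zeros((0, spec.n_features))
        res = cls.__new__(cls)
        res.model = model
        res.params = np.asarray(payload["params"], dtype=float)
        diag = payload["diagnostics"]
        res.objective = diag["objective"]
        res.kkt_residual = diag["kkt_residual"]
        res.n_iter = diag["n_iter"]
        res.converged = diag["converged"]
        res.objective_trace = np.asarray([diag["objective"]])
        res.log_norm = payload["log_norm"]
        res.entropy = payload["entropy"]
        return res
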