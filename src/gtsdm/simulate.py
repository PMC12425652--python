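"""Synthetic landscapes, virtual species, biased samples and trap surveys.

This module generates data with the statistical structure the analysis
pipeline assumes, so the whole workflow — occurrence cleaning, penalised
maximum-entropy fitting, checkerboard cross-validation, ground-truthing
against trap surveys, null models — runs end-to-end with a known truth:

* spatially autocorrelated continuous covariates (kernel-smoothed Gaussian
  white noise) plus a multi-level categorical layer, on a metric grid;
* a virtual species whose suitability is a known function of the covariates,
  with the intercept calibrated to a target prevalence and occupancy drawn
  once per cell;
* presence-only records sampled from occupied cells, optionally through a
  spatial sampling-bias surface, emulating heterogeneously collected
  database records;
* standardised trap surveys (funnel or pitfall) with imperfect detection,
  yielding per-trap presence/absence outcomes.

Everything is a pure function of its arguments and a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit
from shapely.geometry import Point, box
from shapely.geometry.base import BaseGeometry

from .raster import CATEGORICAL, CONTINUOUS, CovariateStack, Layer
from .records import SURVEY_KEY_COLUMNS, OccurrenceSet

__all__ = [
    "VirtualSpecies",
    "InfeasibleSamplingError",
    "generate_landscape",
    "default_scene",
    "define_virtual_species",
    "sample_presence_records",
    "sample_bias_surface",
    "simulate_survey",
]


class InfeasibleSamplingError(RuntimeError):
    """No occupied cell has positive sampling weight."""


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Standard-normal white noise convolved with a Gaussian kernel."""
    field = rng.standard_normal(shape)
    if smoothness > 0:
        field = ndimage.gaussian_filter(field, sigma=smoothness, mode="reflect")
    return field


def generate_landscape(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size: float = 100.0,
    continuous_specs: list[tuple[str, float, float, float]] | None = None,
    categorical_spec: tuple[str, int, float] | None = ("landuse", 15, 3.0),
    nodata_fraction: float = 0.0,
) -> CovariateStack:
    """Generate an aligned covariate stack.

    Parameters
    ----------
    continuous_specs : list of (name, smoothness, mean, sd)
        Each entry yields a spatially autocorrelated Gaussian field with the
        requested marginal mean and standard deviation; ``smoothness`` is the
        kernel scale in cells (0 = white noise).
    categorical_spec : (name, n_levels, smoothness), optional
        A smooth latent field binned into ``n_levels`` contiguous,
        equal-frequency classes coded 0..n_levels-1.
    nodata_fraction : float
        Approximate fraction of cells masked as nodata, carved from the low
        tail of an independent smooth field (a contiguous blob, like a lake).
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if continuous_specs is None:
        continuous_specs = [(f"env{i}", 3.0, 0.0, 1.0) for i in range(1, 7)]
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    for name, smoothness, mean, sd in continuous_specs:
        if smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        if sd < 0:
            raise ValueError("sd must be >= 0")
        field = _smooth_field(rng, (n_rows, n_cols), smoothness)
        if sd == 0:
            vals = np.full((n_rows, n_cols), float(mean))
        else:
            # affine map to the requested marginal moments
            vals = (field - field.mean()) / field.std() * sd + mean
        layers.append(Layer(name, CONTINUOUS, vals))
    if categorical_spec is not None:
        name, n_levels, smoothness = categorical_spec
        if n_levels < 2:
            raise ValueError("categorical layer needs >= 2 levels")
        if n_levels > 256:
            raise ValueError("more than 256 categorical levels is not supported")
        field = _smooth_field(rng, (n_rows, n_cols), smoothness)
        edges = np.quantile(field, np.linspace(0, 1, n_levels + 1)[1:-1])
        codes = np.digitize(field, edges)
        layers.append(Layer(name, CATEGORICAL, codes.astype(float), tuple(range(n_levels))))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if nodata_fraction > 0:
        blob = _smooth_field(rng, (n_rows, n_cols), max(2.0, min(n_rows, n_cols) / 10))
        mask = blob < np.quantile(blob, nodata_fraction)
    return CovariateStack(cell_size, (0.0, 0.0), layers, mask)


def default_scene(seed: int) -> CovariateStack:
    """The default synthetic scene: 100x100 cells at 100 m, six continuous
    layers plus one 15-level categorical layer."""
    return generate_landscape(seed)


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------

@dataclass
class VirtualSpecies:
    """Ground-truth species defined on a covariate stack.

    The suitability of a valid cell is ``link(intercept + eta)`` where
    ``eta`` is a linear predictor on standardised continuous covariates
    (feature class L: linear terms; Q: squared terms; LQ: both) plus
    optional per-level categorical effects.  Occupancy is a single Bernoulli
    draw per cell at that suitability.
    """

    feature_class: str
    true_coefficients: np.ndarray
    intercept: float
    link: str
    suitability: np.ndarray        # (n_rows, n_cols), NaN on nodata
    occupancy: np.ndarray          # bool grid, False on nodata
    detection_prob: dict[str, float] = field(
        default_factory=lambda: {"funnel": 0.5, "pitfall": 0.7}
    )
    categorical_effects: dict[str, dict[int, float]] | None = None

    @property
    def realized_prevalence(self) -> float:
        ok = np.isfinite(self.suitability)
        return float(self.occupancy[ok].mean())


def _apply_link(link: str, eta: np.ndarray) -> np.ndarray:
    if link == "logistic":
        return expit(eta)
    if link == "cloglog":
        return 1.0 - np.exp(-np.exp(eta))
    raise ValueError(f"unknown link {link!r}")


def _truth_eta(stack: CovariateStack, feature_class: str, coefficients,
               categorical_effects=None) -> np.ndarray:
    """Linear predictor grid on standardised continuous covariates."""
    cont = [lyr for lyr in stack.layers if lyr.kind == CONTINUOUS]
    terms = []
    for lyr in cont:
        vals = lyr.values
        ok = stack.valid_mask
        mu, sd = vals[ok].mean(), vals[ok].std()
        z = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
        if feature_class in ("L", "LQ"):
            terms.append(z)
        if feature_class in ("Q", "LQ"):
            terms.append(z ** 2)
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != len(terms):
        raise ValueError(
            f"expected {len(terms)} coefficients for feature class "
            f"{feature_class!r} over {len(cont)} continuous layers, "
            f"got {len(coefficients)}"
        )
    eta = np.zeros(stack.shape)
    for c, t in zip(coefficients, terms):
        eta += c * t
    if categorical_effects:
        for name, effects in categorical_effects.items():
            lyr = stack.layer(name)
            for code, eff in effects.items():
                eta += np.where(lyr.values == code, eff, 0.0)
    return eta


def define_virtual_species(
    stack: CovariateStack,
    feature_class: str = "L",
    true_coefficients=(1.0, -1.0, 0.0, 0.0, 0.0, 0.0),
    target_prevalence: float = 0.3,
    link: str = "logistic",
    seed: int = 0,
    detection_prob: dict[str, float] | None = None,
    categorical_effects: dict[str, dict[int, float]] | None = None,
) -> VirtualSpecies:
    """Define a virtual species calibrated to a target prevalence.

    The intercept is solved by a monotone 1-D root find so that the mean
    suitability over valid cells equals ``target_prevalence`` to within
    1e-6; occupancy is then drawn once per cell, Bernoulli(suitability),
    deterministically for the given seed.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target_prevalence must lie in (0, 1)")
    if feature_class not in ("L", "Q", "LQ"):
        raise ValueError("feature_class must be one of L, Q, LQ")
    eta = _truth_eta(stack, feature_class, true_coefficients, categorical_effects)
    ok = stack.valid_mask

    def gap(c: float) -> float:
        return float(_apply_link(link, c + eta[ok]).mean()) - target_prevalence

    lo, hi = -10.0, 10.0
    while gap(lo) > 0:
        lo *= 2
    while gap(hi) < 0:
        hi *= 2
    intercept = brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16)
    suit = np.where(ok, _apply_link(link, intercept + eta), np.nan)
    rng = np.random.default_rng(seed)
    occ = (rng.random(stack.shape) < suit) & ok
    kwargs = {}
    if detection_prob is not None:
        bad = [m for m, p in detection_prob.items() if not 0 <= p <= 1]
        if bad:
            raise ValueError(f"detection probabilities out of [0,1] for {bad}")
        kwargs["detection_prob"] = dict(detection_prob)
    return VirtualSpecies(
        feature_class, np.asarray(true_coefficients, dtype=float), float(intercept),
        link, suit, occ, categorical_effects=categorical_effects, **kwargs
    )


# ---------------------------------------------------------------------------
# Presence-only sampling
# ---------------------------------------------------------------------------

def sample_bias_surface(stack: CovariateStack, seed: int, strength: float = 2.0,
                        smoothness: float = 5.0) -> np.ndarray:
    """A smooth positive sampling-effort surface, exp(strength * field).

    Emulates spatially uneven collection effort (roads, towns, favourite
    field sites); strength 0 gives uniform effort.
    """
    rng = np.random.default_rng(seed)
    field = _smooth_field(rng, stack.shape, smoothness)
    field = (field - field.mean()) / (field.std() or 1.0)
    return np.exp(strength * field)


def sample_presence_records(
    vs: VirtualSpecies,
    stack: CovariateStack,
    n: int,
    bias_surface: np.ndarray | None = None,
    seed: int = 0,
    species_id: str = "virtual",
) -> OccurrenceSet:
    """Draw presence-only records from occupied cells.

    Cells are drawn with replacement with probability proportional to
    occupancy x bias; the record is positioned uniformly within the chosen
    cell, so records carry continuous coordinates and downstream
    cell-assignment logic is exercised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    weights = vs.occupancy.astype(float)
    if bias_surface is not None:
        bias_surface = np.asarray(bias_surface, dtype=float)
        if bias_surface.shape != stack.shape:
            raise ValueError("bias surface shape does not match the stack")
        if not np.isfinite(bias_surface).all() or (bias_surface < 0).any():
            raise ValueError("bias weights must be finite and non-negative")
        weights = weights * bias_surface
    total = weights.sum()
    if n > 0 and total <= 0:
        raise InfeasibleSamplingError("no occupied cell with positive sampling weight")
    rng = np.random.default_rng(seed)
    if n == 0:
        return OccurrenceSet.from_points(species_id, np.empty((0, 2)), source="simulated")
    flat = rng.choice(weights.size, size=n, replace=True, p=weights.ravel() / total)
    row, col = np.unravel_index(flat, stack.shape)
    cx, cy = stack.cell_center(row, col)
    x = cx + (rng.random(n) - 0.5) * stack.cell_size
    y = cy + (rng.random(n) - 0.5) * stack.cell_size
    return OccurrenceSet.from_points(species_id, np.column_stack([x, y]), source="simulated")


# ---------------------------------------------------------------------------
# Trap surveys
# ---------------------------------------------------------------------------

def _as_geometry(poly) -> BaseGeometry:
    if isinstance(poly, BaseGeometry):
        return poly
    xmin, ymin, xmax, ymax = poly
    return box(xmin, ymin, xmax, ymax)


def simulate_survey(
    species: dict[str, VirtualSpecies] | VirtualSpecies,
    stack: CovariateStack,
    site_polygons,
    traps_per_site: int = 10,
    site_methods: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a standardised presence/absence trap survey.

    Traps are placed uniformly at random within each site polygon (points on
    nodata cells rejected); each trap yields, independently per species, a
    presence with probability occupancy(cell) x detection_prob(method).
    Sites whose polygon covers no valid cell are skipped with a warning and
    listed in the result's ``attrs['skipped_sites']``.
    """
    if traps_per_site < 1:
        raise ValueError("traps_per_site must be >= 1")
    if isinstance(species, VirtualSpecies):
        species = {"virtual": species}
    rng = np.random.default_rng(seed)
    rows = []
    skipped: list[str] = []
    for i, poly in enumerate(site_polygons):
        site_id = f"site{i:03d}"
        method = site_methods[i] if site_methods else ("pitfall" if i % 4 == 3 else "funnel")
        geom = _as_geometry(poly)
        xmin, ymin, xmax, ymax = geom.bounds
        placed = 0
        attempts = 0
        while placed < traps_per_site and attempts < 1000 * traps_per_site:
            attempts += 1
            x = xmin + rng.random() * (xmax - xmin)
            y = ymin + rng.random() * (ymax - ymin)
            if not geom.contains(Point(x, y)):
                continue
            if not bool(stack.on_valid_cell(x, y)[0]):
                continue
            row_i, col_i = stack.cell_index(x, y)
            rec = {
                "site": site_id,
                "trap": f"{site_id}-t{placed:03d}",
                "x": x,
                "y": y,
                "method": method,
            }
            for name, vs in species.items():
                p_det = vs.detection_prob.get(method, 0.0)
                occupied = bool(vs.occupancy[int(row_i), int(col_i)])
                rec[name] = int(occupied and rng.random() < p_det)
            rows.append(rec)
            placed += 1
        if placed == 0:
            warnings.warn(f"survey site {site_id} has no valid cells; skipped")
            skipped.append(site_id)
    df = pd.DataFrame(rows, columns=SURVEY_KEY_COLUMNS + list(species))
    df.attrs["skipped_sites"] = skipped
    return df


# ---------------------------------------------------------------------------
# On-disk synthetic study
# ---------------------------------------------------------------------------

def write_synthetic_inputs(
    out_dir,
    seed: int = 0,
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size: float = 100.0,
    species_params: dict[str, dict] | None = None,
    n_presence: int = 300,
    bias_strength: float = 0.0,
    n_sites: int = 19,
    traps_per_site: int = 20,
):
    """Generate and write a complete synthetic study to ``out_dir``.

    Produces a landscape (ASCII grids + stack.json), a multi-species
    occurrence CSV, a trap-survey CSV and a manifest recording the seed and
    parameters.  Returns (stack, {name: VirtualSpecies}, occurrence path,
    survey path).
    """
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    stack = generate_landscape(int(rng.integers(2**31)), n_rows, n_cols, cell_size)
    if species_params is None:
        species_params = {
            "vsp1": {"feature_class": "L",
                     "true_coefficients": (2.0, -1.0, 0.0, 0.0, 0.0, 0.0)},
            "vsp2": {"feature_class": "L",
                     "true_coefficients": (0.0, 0.0, 1.5, 0.0, -1.5, 0.0)},
        }
    species: dict[str, VirtualSpecies] = {}
    frames = []
    for name, params in species_params.items():
        vs = define_virtual_species(stack, seed=int(rng.integers(2**31)), **params)
        species[name] = vs
        bias = (sample_bias_surface(stack, int(rng.integers(2**31)), bias_strength)
                if bias_strength > 0 else None)
        occ = sample_presence_records(vs, stack, n_presence, bias,
                                      int(rng.integers(2**31)), species_id=name)
        df = occ.records.copy()
        df.insert(0, "species", name)
        frames.append(df)
    occ_path = out_dir / "occurrences.csv"
    pd.concat(frames, ignore_index=True)[["species", "x", "y", "date", "source"]].to_csv(
        occ_path, index=False
    )
    # survey sites: random rectangles over the landscape
    width = n_cols * cell_size
    height = n_rows * cell_size
    sites = []
    for _ in range(n_sites):
        w = 0.08 * width
        h = 0.08 * height
        x0 = rng.random() * (width - w)
        y0 = rng.random() * (height - h)
        sites.append((x0, y0, x0 + w, y0 + h))
    survey = simulate_survey(species, stack, sites, traps_per_site,
                             seed=int(rng.integers(2**31)))
    survey_path = out_dir / "survey.csv"
    from .records import write_survey_csv

    write_survey_csv(survey, survey_path)
    raster_dir = out_dir / "rasters"
    stack.write_ascii(raster_dir)
    manifest = {
        "seed": seed,
        "n_rows": n_rows, "n_cols": n_cols, "cell_size": cell_size,
        "n_presence": n_presence, "bias_strength": bias_strength,
        "n_sites": n_sites, "traps_per_site": traps_per_site,
        "species": {n: {"feature_class": s.feature_class,
                        "intercept": s.intercept,
                        "realized_prevalence": s.realized_prevalence}
                    for n, s in species.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return stack, species, occ_path, survey_path
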