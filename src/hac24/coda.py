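"""Regression of an outcome on pivot ilr coordinates, and translation of the
fitted coefficients into time-reallocation effect curves.

The coordinate model is

    E(Y) = b0 + b1*z1 + b2*z2 + b3*z3 + g'X,

with (z1, z2, z3) the pivot ilr coordinates of the person-level activity
composition under a chosen pivot basis.  Any two bases are orthogonal
rotations of each other, so fitted values, reallocation curves and contrasts
are basis-invariant; only the coordinatewise coefficients change meaning.

Effects of time reallocations:

* one-vs-remaining: raising the pivot part by a relative factor (1 + r)
  while shrinking the rest by a common (1 - s) moves only z1, by
  dz1 = sqrt((D-1)/D) * ln((1+r)/(1-s)); the effect is b1*dz1 with a
  delta-method CI from SE(b1).
* pairwise and general contrasts: map both compositions through the ilr,
  take dz = z(B) - z(A); the effect is dz'b with variance dz' Cov(b) dz.

Because the model is linear on the log-ratio scale, reallocation effects
are nonlinear and asymmetric in the minutes moved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import RegressionFit, complete_cases, covariate_design, fit_ols
from .composition import (PARTS, Composition, PivotBasis, close,
                          compositional_mean, ilr_contrast, one_vs_remaining_realloc,
                          pairwise_realloc, pivot_ilr, pivot_ilr_matrix)

logger = logging.getLogger(__name__)

Z_COLS = ("z1", "z2", "z3")


@dataclass
class CodaFit:
    """An ilr-coordinate regression plus the context needed for prediction."""

    fit: RegressionFit
    basis: PivotBasis
    baseline: Composition
    day_length: float
    ilr_bounds: np.ndarray   # (2, D-1) axis-aligned bounds of observed coordinates

    @property
    def z_names(self) -> list[str]:
        return [f"z{i + 1}" for i in range(self.basis.D - 1)]

    def beta_z(self) -> np.ndarray:
        return self.fit.params[self.z_names].to_numpy()

    def cov_z(self, which: str = "model") -> np.ndarray:
        cov = self.fit.cov_model if which == "model" else self.fit.cov_sandwich
        return cov.loc[self.z_names, self.z_names].to_numpy()


def fit_coda(person_table: pd.DataFrame,
             basis: PivotBasis | str,
             covariates: list[str] | None = None,
             outcome: str = "outcome",
             baseline: Composition | None = None) -> CodaFit:
    """OLS of the outcome on pivot ilr coordinates plus covariates.

    The person-level composition is closed from the four behavior columns
    (scale invariant: minutes and hours give the same fit).  The baseline
    composition for reallocation curves defaults to the sample compositional
    mean over the analysis rows.
    """
    if isinstance(basis, str):
        basis = PivotBasis.for_pivot(basis)
    covariates = covariates or []
    needed = [outcome, *PARTS, *covariates]
    data = complete_cases(person_table, needed)
    X_parts = data[list(PARTS)].to_numpy(dtype=float)
    if np.any(X_parts <= 0):
        raise ValueError("zero or negative behavior times; run "
                         "preprocess.impute_zeros first")
    comps = X_parts / X_parts.sum(axis=1, keepdims=True)
    Z = pivot_ilr_matrix(comps, basis)

    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for i in range(Z.shape[1]):
        X[f"z{i + 1}"] = Z[:, i]
    X = pd.concat([X, covariate_design(data, covariates)], axis=1)
    fit = fit_ols(data[outcome].to_numpy(), X, design_info={
        "basis": basis.order, "covariates": covariates, "outcome": outcome,
        "index": data.index,
    })
    if baseline is None:
        baseline = compositional_mean(comps, labels=PARTS)
    day_length = float(np.median(data["day_length_minutes"])) \
        if "day_length_minutes" in data else 1440.0
    bounds = np.vstack([Z.min(axis=0), Z.max(axis=0)])
    return CodaFit(fit, basis, baseline, day_length, bounds)


def pivot_summary(fits: dict[str, CodaFit],
                  cov: str = "model",
                  ci_level: float = 0.95) -> pd.DataFrame:
    """One row per behavior-vs-remaining pivot coefficient (z1 of each basis)."""
    idx_sets = {tuple(f.fit.design_info["index"]) for f in fits.values()}
    if len(idx_sets) != 1:
        raise ValueError("pivot fits were made on different samples")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for part, cf in fits.items():
        beta = cf.fit.coef("z1")
        se = math.sqrt(cf.fit.var("z1", which=cov))
        pval = 2.0 * stats.norm.sf(abs(beta / se))
        rows.append((f"{part} vs. remaining", beta, beta - z * se,
                     beta + z * se, pval, cf.fit.n))
    return pd.DataFrame(rows, columns=["pivot", "estimate", "ci_low",
                                       "ci_high", "p_value", "n"])


def fit_all_pivots(person_table: pd.DataFrame,
                   covariates: list[str] | None = None,
                   **kwargs) -> dict[str, CodaFit]:
    return {p: fit_coda(person_table, PivotBasis.for_pivot(p), covariates,
                        **kwargs) for p in PARTS}


# ---------------------------------------------------------------------------
# Reallocation curves
# ---------------------------------------------------------------------------

@dataclass
class ReallocCurve:
    """Pointwise effect curve over a grid of reallocated minutes."""

    delta_minutes: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline: Composition
    description: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_minutes": self.delta_minutes,
                             "estimate": self.estimate,
                             "ci_low": self.ci_low,
                             "ci_high": self.ci_high})


def _truncate_grid(grid: np.ndarray, ok: np.ndarray, what: str) -> np.ndarray:
    if not ok.all():
        logger.warning("%s: %d grid points outside the admissible range were "
                       "dropped", what, int((~ok).sum()))
    return grid[ok]


def one_vs_remaining_curve(fit: CodaFit,
                           part: str | None = None,
                           delta_grid: np.ndarray | None = None,
                           baseline: Composition | None = None,
                           cov: str = "model",
                           ci_level: float = 0.95) -> ReallocCurve:
    """Effect of moving Delta minutes into the pivot part while shrinking the
    remaining parts proportionally.

    Only the first coordinate moves: dz1 = sqrt((D-1)/D)*ln((1+r)/(1-s)), so
    the estimate is b1*dz1 with CI b1*dz1 +/- z * |dz1| * SE(b1).  The curve
    through Delta = 0 is exactly zero with a zero-width interval.
    """
    part = part or fit.basis.pivot
    if part != fit.basis.pivot:
        raise ValueError(f"fit's pivot is {fit.basis.pivot!r}; refit with "
                         f"basis for {part!r}")
    baseline = baseline or fit.baseline
    if delta_grid is None:
        delta_grid = np.linspace(-60.0, 60.0, 121)
    x1 = baseline.part(part)
    r_grid = np.asarray(delta_grid, dtype=float) / (x1 * fit.day_length)
    ok = (r_grid > -1.0) & (r_grid < (1.0 - x1) / x1)
    delta_grid = _truncate_grid(np.asarray(delta_grid, dtype=float), ok,
                                "one_vs_remaining_curve")
    r_grid = r_grid[ok]
    s_grid = r_grid * x1 / (1.0 - x1)
    D = baseline.D
    dz1 = math.sqrt((D - 1) / D) * np.log((1.0 + r_grid) / (1.0 - s_grid))
    beta1 = fit.fit.coef("z1")
    se1 = math.sqrt(fit.fit.var("z1", which=cov))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    est = beta1 * dz1
    halfwidth = z * np.abs(dz1) * se1
    return ReallocCurve(delta_grid, est, est - halfwidth, est + halfwidth,
                        baseline, f"{part} vs remaining (proportional)")


def pairwise_curve(fit: CodaFit,
                   from_part: str,
                   to_part: str,
                   delta_grid: np.ndarray | None = None,
                   baseline: Composition | None = None,
                   cov: str = "model",
                   ci_level: float = 0.95) -> ReallocCurve:
    """Effect of moving Delta minutes from one behavior to another, others
    fixed; estimate dz'b with a quadratic-form CI."""
    baseline = baseline or fit.baseline
    if delta_grid is None:
        delta_grid = np.linspace(-60.0, 60.0, 121)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if from_part == to_part:
        zeros = np.zeros_like(delta_grid)
        return ReallocCurve(delta_grid, zeros, zeros, zeros, baseline,
                            f"{from_part} -> {to_part}")
    base_min = {l: baseline.part(l) * fit.day_length for l in baseline.labels}
    ok = ((delta_grid < base_min[from_part])
          & (-delta_grid < base_min[to_part]))
    delta_grid = _truncate_grid(delta_grid, ok, "pairwise_curve")
    beta = fit.beta_z()
    V = fit.cov_z(which=cov)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    z0 = pivot_ilr(baseline, fit.basis).values
    est = np.empty_like(delta_grid)
    half = np.empty_like(delta_grid)
    for k, d in enumerate(delta_grid):
        if d == 0.0:
            est[k] = half[k] = 0.0
            continue
        new = pairwise_realloc(base_min, from_part, to_part, d)
        dz = pivot_ilr(new, fit.basis).values - z0
        est[k] = float(dz @ beta)
        half[k] = z * math.sqrt(float(dz @ V @ dz))
    return ReallocCurve(delta_grid, est, est - half, est + half, baseline,
                        f"{from_part} -> {to_part}")


def composition_contrast_effect(fit: CodaFit,
                                comp_a: Composition,
                                comp_b: Composition,
                                cov: str = "model",
                                ci_level: float = 0.95
                                ) -> tuple[float, tuple[float, float]]:
    """Estimated mean-outcome difference between profiles B and A: dz'b with
    a quadratic-form CI.  Warns when either profile's coordinates fall
    outside the observed coordinate bounding box (extrapolation guard)."""
    dz = ilr_contrast(comp_a, comp_b, fit.basis).values
    for name, c in (("A", comp_a), ("B", comp_b)):
        zc = pivot_ilr(c, fit.basis).values
        if np.any(zc < fit.ilr_bounds[0] - 1e-12) or \
           np.any(zc > fit.ilr_bounds[1] + 1e-12):
            logger.warning("composition %s lies outside the observed "
                           "coordinate range; the contrast extrapolates", name)
    beta = fit.beta_z()
    V = fit.cov_z(which=cov)
    est = float(dz @ beta)
    half = stats.norm.ppf(0.5 + ci_level / 2.0) * math.sqrt(float(dz @ V @ dz))
    return est, (est - half, est + half)


def plot_curves(curves: dict[str, ReallocCurve], path: str | None = None,
                ncols: int = 2):
    """Multi-panel reallocation-curve figure (one panel per curve)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(curves)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 3.2 * nrows),
                             squeeze=False)
    for ax, (name, cv) in zip(axes.ravel(), curves.items()):
        ax.fill_between(cv.delta_minutes, cv.ci_low, cv.ci_high, alpha=0.3)
        ax.plot(cv.delta_minutes, cv.estimate)
        ax.axhline(0.0, color="gray", lw=0.7)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("minutes reallocated")
        ax.set_ylabel("difference in mean outcome")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
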