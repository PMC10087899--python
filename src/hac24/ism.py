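"""Isotemporal substitution models (ISM) for time-use exposures.

An ISM regresses the outcome on all activity variables but one, plus the
total time per day and covariates:

    E(Y) = b0 + b1*Sit + b2*Stand + b3*Sleep + b4*Total + g'X   (step dropped)

With Total held, the coefficient of a retained activity is the estimated
difference in mean outcome per unit of time moved from the *dropped*
activity into that activity — the substitution effect.  Because the four
parameterizations (one per dropped activity) span the same column space,
their fitted values agree exactly and substitution tables are antisymmetric.

The total time per day varies slightly across persons (out-of-bed to
out-of-bed day definition), so an intercept and Total can coexist; with an
exactly constant Total only one of the two is identified, and the fit
refuses the redundant pair.

Besides the linear ISM this module provides stratified (subgroup) fits and
a penalized cubic-spline ISM with GCV-selected smoothing and Wald-type
tests per smooth term, for probing nonlinear substitution effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from ._regression import RegressionFit, complete_cases, covariate_design, fit_ols
from .composition import PARTS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Linear ISM
# ---------------------------------------------------------------------------

def fit_ism(person_table: pd.DataFrame,
            dropped_activity: str,
            covariates: list[str] | None = None,
            outcome: str = "outcome",
            total_col: str = "day_length_minutes",
            intercept: bool = True) -> RegressionFit:
    """Ordinary least squares of the outcome on the retained activities,
    total time, and covariates, with the named activity omitted.

    Both the classical and HC1 sandwich covariances are stored on the fit.
    Rows with missing outcome/activity/covariate values are excluded
    (complete-case analysis, logged).
    """
    if dropped_activity not in PARTS:
        raise ValueError(f"unknown activity {dropped_activity!r}")
    covariates = covariates or []
    retained = [p for p in PARTS if p != dropped_activity]
    needed = [outcome, *retained, total_col, *covariates]
    data = complete_cases(person_table, needed)

    total = data[total_col].to_numpy(dtype=float)
    total_constant = np.ptp(total) < 1e-9
    if total_constant and intercept:
        raise ValueError(
            "total time is constant across persons, so an intercept and the "
            "Total term are perfectly collinear; refit with intercept=False "
            "(the Total coefficient then plays the intercept's role)"
        )

    X = pd.DataFrame(index=data.index)
    if intercept:
        X["intercept"] = 1.0
    for p in retained:
        X[p] = data[p].astype(float)
    X["total"] = total
    cov_design = covariate_design(data, covariates)
    X = pd.concat([X, cov_design], axis=1)

    fit = fit_ols(data[outcome].to_numpy(), X, design_info={
        "dropped": dropped_activity,
        "retained": retained,
        "covariates": covariates,
        "outcome": outcome,
        "index": data.index,
    })
    return fit


@dataclass
class SubstitutionTable:
    """K x K substitution-effect table for a Delta-minute reallocation.

    Entry (row=i, col=j) is the estimated change in mean outcome when
    Delta min/day are moved from behavior i to behavior j; the diagonal is
    empty and the table is antisymmetric.
    """

    delta_minutes: float
    estimate: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n: int
    ci_level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: replaced, replacement, estimate, low, high."""
        rows = []
        for i in self.estimate.index:
            for j in self.estimate.columns:
                if i == j:
                    continue
                rows.append((i, j, self.estimate.loc[i, j],
                             self.ci_low.loc[i, j], self.ci_high.loc[i, j]))
        return pd.DataFrame(rows, columns=["replaced", "replacement",
                                           "estimate", "ci_low", "ci_high"])


def substitution_table(fits: dict[str, RegressionFit],
                       delta_minutes: float = 30.0,
                       cov: str = "model",
                       ci_level: float = 0.95) -> SubstitutionTable:
    """Assemble the substitution table from the four one-dropped fits.

    Moving time from behavior i into behavior j raises j while the omitted
    i absorbs the decrease, so the (row=i, col=j) entry is delta times the
    coefficient of activity j in the model that drops activity i.
    """
    if set(fits) != set(PARTS):
        raise ValueError(f"need one fit per dropped activity {PARTS}")
    ns = {f.n for f in fits.values()}
    idx = [tuple(f.design_info["index"]) for f in fits.values()]
    if len(ns) != 1 or len(set(idx)) != 1:
        raise ValueError("fits were made on different samples")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    est = pd.DataFrame(np.nan, index=PARTS, columns=PARTS)
    low = est.copy()
    high = est.copy()
    for i, fit in fits.items():          # model dropping i: moving i -> j
        for j in fit.design_info["retained"]:
            beta = fit.coef(j)
            se = np.sqrt(fit.var(j, which=cov))
            est.loc[i, j] = delta_minutes * beta
            low.loc[i, j] = delta_minutes * beta - z * abs(delta_minutes) * se
            high.loc[i, j] = delta_minutes * beta + z * abs(delta_minutes) * se
    return SubstitutionTable(delta_minutes, est, low, high,
                             n=next(iter(ns)), ci_level=ci_level)


def fit_all_isms(person_table: pd.DataFrame,
                 covariates: list[str] | None = None,
                 **kwargs) -> dict[str, RegressionFit]:
    """One ISM per dropped activity, on the shared complete-case sample."""
    covariates = covariates or []
    data = complete_cases(person_table,
                          [kwargs.get("outcome", "outcome"), *PARTS,
                           kwargs.get("total_col", "day_length_minutes"),
                           *covariates])
    return {p: fit_ism(data, p, covariates, **kwargs) for p in PARTS}


def subgroup_ism(person_table: pd.DataFrame,
                 split_col: str,
                 threshold: float,
                 covariates: list[str] | None = None,
                 delta_minutes: float = 30.0,
                 **kwargs) -> dict[str, SubstitutionTable]:
    """Separate ISMs in the strata split_col > threshold vs <= threshold.

    Differential estimates across strata signal a nonlinear substitution
    effect.  Returns a SubstitutionTable per stratum, keyed "above"/"below".
    """
    strata = {
        "above": person_table[person_table[split_col] > threshold],
        "below": person_table[person_table[split_col] <= threshold],
    }
    out = {}
    for name, sub in strata.items():
        if sub.empty:
            logger.warning("subgroup_ism: stratum %s (%s %s %g) is empty; "
                           "omitted", name, split_col,
                           ">" if name == "above" else "<=", threshold)
            continue
        fits = fit_all_isms(sub, covariates, **kwargs)
        out[name] = substitution_table(fits, delta_minutes)
        logger.info("subgroup_ism: stratum %s n=%d", name, out[name].n)
    if not out:
        raise ValueError("both strata are empty")
    return out


# ---------------------------------------------------------------------------
# Penalized-spline (nonlinear) ISM
# ---------------------------------------------------------------------------

def _spline_basis(x: np.ndarray, n_knots: int = 5
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cubic B-spline basis on `n_knots` equally spaced knots over the
    observed range, sum-to-zero constrained, with its curvature penalty.

    Returns (basis matrix, penalty, knot vector, constraint null-space Z).
    The raw basis contains the constant function; projecting onto the null
    space of the column-sum constraint removes it so the smooth is
    identifiable next to the model intercept.
    """
    a, b = float(np.min(x)), float(np.max(x))
    if b - a <= 0:
        raise ValueError("activity has no spread; cannot build a spline")
    inner = np.linspace(a, b, n_knots)
    t = np.concatenate([[a] * 3, inner, [b] * 3])
    nb = len(t) - 4
    B = BSpline.design_matrix(np.clip(x, a, b), t, 3).toarray()

    # curvature penalty: integral of products of second derivatives,
    # exact via 3-point Gauss-Legendre on each knot interval
    S = np.zeros((nb, nb))
    gauss_x, gauss_w = np.polynomial.legendre.leggauss(3)
    edges = np.unique(t)
    d2 = []
    for l in range(nb):
        c = np.zeros(nb)
        c[l] = 1.0
        d2.append(BSpline(t, c, 3).derivative(2))
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        nodes = mid + half * gauss_x
        vals = np.array([f(nodes) for f in d2])     # (nb, 3)
        S += half * (vals * gauss_w) @ vals.T
    S /= np.linalg.norm(S)                          # unit scale across smooths

    csum = B.sum(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(csum, full_matrices=True)
    Z = Vt[1:].T                                    # null space of the constraint
    return B @ Z, Z.T @ S @ Z, t, Z


@dataclass
class SplineIsmFit:
    """A penalized-spline ISM: linear in Total and covariates, smooth in
    each retained activity."""

    dropped: str
    retained: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray                 # penalized (Bayesian) covariance
    columns: list[str]
    blocks: dict[str, slice]             # coefficient block per smooth
    knots: dict[str, np.ndarray]
    null_Z: dict[str, np.ndarray]
    lambdas: dict[str, float]
    edf_total: float
    edf_smooth: dict[str, float]
    gcv: float
    sigma2: float
    n: int
    smooth_tests: pd.DataFrame = field(default=None)
    covariates: list[str] = field(default_factory=list)
    total_col: str = "day_length_minutes"

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        X = _spline_design(newdata, self)
        return X @ self.beta


def _spline_design(data: pd.DataFrame, fit: SplineIsmFit) -> np.ndarray:
    cols = [np.ones(len(data))]
    for p in fit.retained:
        t = fit.knots[p]
        x = np.clip(data[p].to_numpy(dtype=float), t[0], t[-1])
        B = BSpline.design_matrix(x, t, 3).toarray()
        cols.append(B @ fit.null_Z[p])
    cols.append(data[fit.total_col].to_numpy(dtype=float)[:, None])
    cov = covariate_design(data, fit.covariates)
    if cov.shape[1]:
        cols.append(cov.to_numpy(dtype=float))
    return np.hstack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])


LAMBDA_GRID = np.logspace(-4, 6, 61)


def spline_ism(person_table: pd.DataFrame,
               dropped_activity: str,
               covariates: list[str] | None = None,
               outcome: str = "outcome",
               total_col: str = "day_length_minutes",
               n_knots: int = 5,
               lambda_grid: np.ndarray = LAMBDA_GRID,
               sweeps: int = 2) -> SplineIsmFit:
    """Nonlinear ISM: each retained activity enters through a penalized cubic
    spline (5 equally spaced knots over its observed range) while Total stays
    linear; smoothing parameters minimize GCV = n*RSS/(n - edf)^2, searched
    coordinate-wise over a log-spaced grid.

    Per-smooth Wald-type tests use the penalized coefficient covariance with
    rank set to the rounded effective degrees of freedom of the smooth.
    """
    covariates = covariates or []
    retained = [p for p in PARTS if p != dropped_activity]
    data = complete_cases(person_table,
                          [outcome, *retained, total_col, *covariates])
    n = len(data)
    y = data[outcome].to_numpy(dtype=float)

    blocks: dict[str, slice] = {}
    knots: dict[str, np.ndarray] = {}
    null_Z: dict[str, np.ndarray] = {}
    pieces = [np.ones((n, 1))]
    pens = {}
    pos = 1
    for p in retained:
        x = data[p].to_numpy(dtype=float)
        if np.unique(x).size < n_knots + 2:
            raise ValueError(f"too few distinct {p!r} values for a "
                             f"{n_knots}-knot spline")
        Bc, Sc, t, Z = _spline_basis(x, n_knots)
        pieces.append(Bc)
        blocks[p] = slice(pos, pos + Bc.shape[1])
        pens[p] = Sc
        knots[p] = t
        null_Z[p] = Z
        pos += Bc.shape[1]
    pieces.append(data[total_col].to_numpy(dtype=float)[:, None])
    pos += 1
    cov = covariate_design(data, covariates)
    cov_names = list(cov.columns)
    if cov.shape[1]:
        pieces.append(cov.to_numpy(dtype=float))
    X = np.hstack(pieces)
    p_total = X.shape[1]
    XtX = X.T @ X
    Xty = X.T @ y

    def penalty(lams: dict[str, float]) -> np.ndarray:
        S = np.zeros((p_total, p_total))
        for q, lam in lams.items():
            sl = blocks[q]
            S[sl, sl] += lam * pens[q]
        return S

    def solve(lams: dict[str, float]):
        A = XtX + penalty(lams)
        try:
            H = np.linalg.inv(A)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular penalized system; try fewer knots") from err
        beta = H @ Xty
        edf = float(np.trace(H @ XtX))
        rss = float(np.sum((y - X @ beta) ** 2))
        gcv = n * rss / (n - edf) ** 2
        return beta, H, edf, rss, gcv

    lams = {p: 1.0 for p in retained}
    for _ in range(sweeps):
        for p in retained:
            best = min(lambda_grid,
                       key=lambda lam: solve({**lams, p: lam})[4])
            lams[p] = float(best)
    beta, H, edf, rss, gcv = solve(lams)
    sigma2 = rss / (n - edf)
    Vb = H * sigma2                       # penalized (Bayesian) covariance

    edf_mat = H @ XtX
    tests = []
    edf_smooth = {}
    for p in retained:
        sl = blocks[p]
        edf_j = float(np.trace(edf_mat[sl, sl]))
        edf_smooth[p] = edf_j
        bj = beta[sl]
        Vj = Vb[sl, sl]
        r = max(1, int(round(edf_j)))
        w, U = np.linalg.eigh(Vj)
        order = np.argsort(w)[::-1][:r]
        Vinv_r = (U[:, order] / w[order]) @ U[:, order].T
        T = float(bj @ Vinv_r @ bj)
        pval = float(stats.chi2.sf(T, df=r))
        tests.append((p, edf_j, T, r, pval))
    smooth_tests = pd.DataFrame(tests, columns=["activity", "edf", "wald",
                                                "rank", "p_value"])

    columns = (["intercept"]
               + [f"{p}_s{k}" for p in retained
                  for k in range(blocks[p].stop - blocks[p].start)]
               + ["total"] + cov_names)
    return SplineIsmFit(
        dropped=dropped_activity, retained=retained, beta=beta, cov_beta=Vb,
        columns=columns, blocks=blocks, knots=knots, null_Z=null_Z,
        lambdas=lams, edf_total=edf, edf_smooth=edf_smooth, gcv=gcv,
        sigma2=sigma2, n=n, smooth_tests=smooth_tests, covariates=covariates,
        total_col=total_col,
    )
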