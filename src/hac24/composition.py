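"""Compositional algebra for the 24-hour activity cycle.

A day's time use is a *composition*: a vector of non-negative parts
(sit, stand, step, sleep) carrying only relative information.  This module
provides closure, compositional descriptive statistics (compositional mean,
variation matrix), the isometric log-ratio transform in *pivot coordinates*,
the (r, s) one-vs-remaining time-reallocation arithmetic, pairwise
reallocations, James's multivariate test of equal mean vectors under unequal
covariances, and ternary scatter plots.

Pivot coordinates single one part out as the numerator of the first
coordinate,

    z_i = sqrt((D-i)/(D-i+1)) * ln( x_(i) / gmean(x_(i+1), ..., x_(D)) ),

so z1 contrasts the pivot part against the geometric mean of the rest.  All
logarithms are natural.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical ordering of the four activity behaviors
PARTS = ("sit", "stand", "step", "sleep")

CLOSURE_TOL = 1e-10


# ---------------------------------------------------------------------------
# Composition container and closure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """A closed composition: labelled proportions summing to one."""

    labels: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", props)
        if len(self.labels) != props.size:
            raise ValueError("labels and proportions differ in length")
        if np.any(props < 0):
            raise ValueError("proportions must be non-negative")
        total = props.sum()
        if abs(total - 1.0) > CLOSURE_TOL:
            logger.warning("composition off closure by %.3g; re-closing", total - 1.0)
            object.__setattr__(self, "proportions", props / total)

    @property
    def D(self) -> int:
        return len(self.labels)

    def part(self, label: str) -> float:
        return float(self.proportions[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.proportions.tolist()))

    def reorder(self, labels: Sequence[str]) -> "Composition":
        if sorted(labels) != sorted(self.labels):
            raise ValueError(f"labels {labels!r} do not match {self.labels!r}")
        idx = [self.labels.index(l) for l in labels]
        return Composition(tuple(labels), self.proportions[idx])


def close(amounts: Sequence[float] | np.ndarray,
          labels: Sequence[str] = PARTS) -> Composition:
    """Close a vector of non-negative amounts to proportions of the total.

    Only relative information survives: ``close(k * x) == close(x)`` for any
    k > 0 (scale invariance).
    """
    x = np.asarray(amounts, dtype=float)
    if np.any(x < 0):
        raise ValueError("amounts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot close an all-zero vector")
    return Composition(tuple(labels), x / total)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def _as_matrix(sample: Sequence[Composition] | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(sample, np.ndarray):
        X = np.asarray(sample, dtype=float)
        labels = tuple(f"p{i}" for i in range(X.shape[1]))
        return X, labels
    labels = sample[0].labels
    X = np.vstack([c.reorder(labels).proportions for c in sample])
    return X, labels


def compositional_mean(sample: Sequence[Composition] | np.ndarray,
                       labels: Sequence[str] | None = None) -> Composition:
    """Center of a compositional sample: closed vector of per-part geometric means."""
    X, lab = _as_matrix(sample)
    if labels is not None:
        lab = tuple(labels)
    if np.any(X <= 0):
        raise ValueError(
            "compositional mean requires strictly positive parts; "
            "see preprocess.impute_zeros for zero handling"
        )
    gm = np.exp(np.log(X).mean(axis=0))
    return close(gm, lab)


def variation_matrix(sample: Sequence[Composition] | np.ndarray,
                     labels: Sequence[str] | None = None) -> np.ndarray:
    """Pairwise log-ratio variances: T[i, j] = var(ln(x_i / x_j)).

    Entries near zero flag pairs of behaviors that are nearly proportional
    across the sample.
    """
    X, _ = _as_matrix(sample)
    if X.shape[0] < 2:
        raise ValueError("variation matrix needs at least two observations")
    if np.any(X <= 0):
        raise ValueError("variation matrix requires strictly positive parts")
    L = np.log(X)
    D = X.shape[1]
    T = np.zeros((D, D))
    for i in range(D):
        for j in range(i + 1, D):
            v = np.var(L[:, i] - L[:, j], ddof=1)
            T[i, j] = T[j, i] = v
    return T


# ---------------------------------------------------------------------------
# Pivot ilr coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PivotBasis:
    """An ordering of the part labels; the first label is the pivot numerator.

    The default ordering after the pivot keeps the remaining parts in the
    canonical (sit, stand, step, sleep) order.
    """

    order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.order) < 2:
            raise ValueError("a pivot basis needs at least two parts")
        if len(set(self.order)) != len(self.order):
            raise ValueError("pivot basis ordering must be a permutation")

    @property
    def pivot(self) -> str:
        return self.order[0]

    @property
    def D(self) -> int:
        return len(self.order)

    @classmethod
    def for_pivot(cls, pivot: str, labels: Sequence[str] = PARTS) -> "PivotBasis":
        """Basis with `pivot` first and the rest in their canonical order."""
        if pivot not in labels:
            raise ValueError(f"{pivot!r} not among {tuple(labels)!r}")
        rest = tuple(l for l in labels if l != pivot)
        return cls((pivot,) + rest)

    def contrast_matrix(self) -> np.ndarray:
        """The (D-1) x D orthonormal log-contrast matrix V with z = V @ ln(x),
        columns ordered as in ``self.order``."""
        D = self.D
        V = np.zeros((D - 1, D))
        for i in range(D - 1):
            c = math.sqrt((D - i - 1) / (D - i))
            V[i, i] = c
            V[i, i + 1:] = -c / (D - i - 1)
        return V


@dataclass(frozen=True)
class IlrVector:
    """D-1 pivot-coordinate values plus the basis that produced them."""

    values: np.ndarray
    basis: PivotBasis

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("ilr coordinates must be finite")
        if v.size != self.basis.D - 1:
            raise ValueError("coordinate length must be D-1")


def pivot_ilr(c: Composition, basis: PivotBasis) -> IlrVector:
    """Transform a strictly positive composition to pivot ilr coordinates."""
    x = c.reorder(basis.order).proportions
    if np.any(x <= 0):
        raise ValueError("pivot_ilr requires strictly positive parts; "
                         "see preprocess.impute_zeros")
    z = basis.contrast_matrix() @ np.log(x)
    return IlrVector(z, basis)


def pivot_ilr_matrix(X: np.ndarray, basis: PivotBasis,
                     labels: Sequence[str] = PARTS) -> np.ndarray:
    """Vectorised pivot ilr for an (n, D) matrix whose columns follow `labels`."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("pivot_ilr requires strictly positive parts")
    idx = [tuple(labels).index(l) for l in basis.order]
    return np.log(X[:, idx]) @ basis.contrast_matrix().T


def inverse_ilr(z: IlrVector | np.ndarray, basis: PivotBasis) -> Composition:
    """The unique strictly positive closed composition with the given coordinates."""
    v = z.values if isinstance(z, IlrVector) else np.asarray(z, dtype=float)
    V = basis.contrast_matrix()
    logx = V.T @ v  # clr representation (zero-sum) under this ordering
    x = np.exp(logx)
    comp = close(x, basis.order)
    return comp.reorder(sorted(basis.order, key=lambda l: _canonical_rank(l, basis)))


def _canonical_rank(label: str, basis: PivotBasis) -> int:
    try:
        return PARTS.index(label)
    except ValueError:
        return basis.order.index(label)


def ilr_contrast(a: Composition, b: Composition, basis: PivotBasis) -> IlrVector:
    """Coordinatewise difference pivot_ilr(b) - pivot_ilr(a).

    Paired with a fitted coordinate model, the dot product of this contrast
    with the coordinate coefficients is the estimated mean-outcome difference
    between two time-use profiles.
    """
    if sorted(a.labels) != sorted(b.labels):
        raise ValueError("compositions have mismatched part labels")
    za = pivot_ilr(a, basis).values
    zb = pivot_ilr(b, basis).values
    return IlrVector(zb - za, basis)


# ---------------------------------------------------------------------------
# Time-reallocation arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReallocationSpec:
    """A one-vs-remaining reallocation: the target part is scaled by (1 + r)
    and every remaining part by (1 - s), with s = r * x1 / (1 - x1) so the
    parts still sum to one.  Admissible range: -1 < r < (1 - x1) / x1."""

    baseline: Composition
    part: str
    r: float
    s: float
    x1: float

    def __post_init__(self) -> None:
        if abs(self.s - self.r * self.x1 / (1.0 - self.x1)) > 1e-12:
            raise ValueError("s does not satisfy s = r*x1/(1-x1)")
        if not (-1.0 < self.r < (1.0 - self.x1) / self.x1):
            raise ValueError(f"r={self.r:.4g} outside (-1, (1-x1)/x1)")


def one_vs_remaining_realloc(baseline: Composition, part: str,
                             delta_minutes: float,
                             day_length: float = 1440.0,
                             ) -> tuple[ReallocationSpec, Composition]:
    """Reallocate `delta_minutes` into `part`, proportionally out of the rest.

    The target part changes by a relative factor r = delta / (x1 * day_length);
    the remaining parts share a common relative decrease s = r * x1 / (1 - x1),
    which keeps their mutual ratios, and the closure, exact.
    """
    x1 = baseline.part(part)
    r = delta_minutes / (x1 * day_length)
    if not (-1.0 < r < (1.0 - x1) / x1):
        raise ValueError(
            f"delta={delta_minutes:g} min gives r={r:.4g} outside the "
            f"admissible range (-1, {(1.0 - x1) / x1:.4g}) for {part!r}"
        )
    s = r * x1 / (1.0 - x1)
    scale = np.where(np.array(baseline.labels) == part, 1.0 + r, 1.0 - s)
    new = close(baseline.proportions * scale, baseline.labels)
    return ReallocationSpec(baseline, part, r, s, x1), new


def pairwise_realloc(baseline_amounts: dict[str, float] | Composition,
                     from_part: str, to_part: str,
                     delta: float) -> Composition:
    """Move `delta` (same units as the amounts) from one part to another."""
    if isinstance(baseline_amounts, Composition):
        amounts = baseline_amounts.as_dict()
    else:
        amounts = dict(baseline_amounts)
    if delta >= amounts[from_part]:
        raise ValueError(
            f"delta={delta:g} would exhaust {from_part!r} "
            f"(baseline {amounts[from_part]:g})"
        )
    amounts[from_part] -= delta
    amounts[to_part] += delta
    labels = tuple(amounts)
    return close([amounts[l] for l in labels], labels)


# ---------------------------------------------------------------------------
# James's test of equal mean vectors (unequal covariances)
# ---------------------------------------------------------------------------

def james_test(groups: Sequence[np.ndarray],
               order: int = 2,
               permutations: int | None = None,
               seed: int | None = None) -> tuple[float, float]:
    """James's MANOVA-type test of equality of k mean vectors.

    Unlike Hotelling/Wilks procedures, the group covariance matrices are not
    assumed equal.  The statistic is

        J = sum_i (xbar_i - mu)' W_i (xbar_i - mu),
        W_i = n_i * S_i^{-1},  mu = W^{-1} sum_i W_i xbar_i,  W = sum_i W_i,

    referred to a chi-square with r = p(k-1) degrees of freedom via James's
    second-order series correction.  A seeded permutation fallback is
    available for small samples (``permutations`` resamples of group labels).

    Parameters
    ----------
    groups : sequence of (n_i, p) arrays, one per group.

    Returns
    -------
    (statistic, p_value)
    """
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(mats)
    if k < 2:
        raise ValueError("need at least two groups")
    p = mats[0].shape[1]
    for g in mats:
        if g.shape[1] != p:
            raise ValueError("groups differ in dimension")
        if g.shape[0] <= p:
            raise ValueError("each group needs n > p observations")

    stat = _james_statistic(mats)
    if permutations:
        rng = np.random.default_rng(seed)
        pooled = np.vstack(mats)
        sizes = [g.shape[0] for g in mats]
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(pooled.shape[0])
            parts, start = [], 0
            for n_i in sizes:
                parts.append(pooled[perm[start:start + n_i]])
                start += n_i
            if _james_statistic(parts) >= stat:
                count += 1
        return stat, (count + 1) / (permutations + 1)

    r = p * (k - 1)
    A, B = _james_correction_terms(mats)
    # Solve J = x * (1 + A + B x) for the equivalent chi-square quantile x.
    if B > 0:
        disc = (1.0 + A) ** 2 + 4.0 * B * stat
        x = (-(1.0 + A) + math.sqrt(disc)) / (2.0 * B)
    else:
        x = stat / (1.0 + A)
    pval = float(stats.chi2.sf(x, df=r))
    return stat, pval


def _james_statistic(mats: Sequence[np.ndarray]) -> float:
    p = mats[0].shape[1]
    Ws, means = [], []
    for g in mats:
        n_i = g.shape[0]
        S = np.cov(g, rowvar=False, ddof=1).reshape(p, p)
        try:
            Wi = n_i * np.linalg.inv(S)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular group covariance matrix") from err
        Ws.append(Wi)
        means.append(g.mean(axis=0))
    W = sum(Ws)
    mu = np.linalg.solve(W, sum(Wi @ m for Wi, m in zip(Ws, means)))
    return float(sum((m - mu) @ Wi @ (m - mu) for Wi, m in zip(Ws, means)))


def _james_correction_terms(mats: Sequence[np.ndarray]) -> tuple[float, float]:
    p = mats[0].shape[1]
    k = len(mats)
    r = p * (k - 1)
    Ws = []
    for g in mats:
        n_i = g.shape[0]
        S = np.cov(g, rowvar=False, ddof=1).reshape(p, p)
        Ws.append(n_i * np.linalg.inv(S))
    W = sum(Ws)
    Winv = np.linalg.inv(W)
    A = 0.0
    B = 0.0
    for g, Wi in zip(mats, Ws):
        n_i = g.shape[0]
        M = np.eye(p) - Winv @ Wi
        t1 = np.trace(M)
        t2 = np.trace(M @ M)
        A += t1 ** 2 / (n_i - 1)
        B += (t2 + t1 ** 2 / 2.0) / (n_i - 1)
    A /= 2.0 * r
    B /= r * (r + 2.0)
    return A, B


# ---------------------------------------------------------------------------
# Ternary plots
# ---------------------------------------------------------------------------

def barycentric_xy(subcomp: np.ndarray) -> np.ndarray:
    """Project closed 3-part rows (a, b, c) onto the unit-edge triangle with
    vertex order a -> (0, 0), b -> (1, 0), c -> (1/2, sqrt(3)/2)."""
    X = np.atleast_2d(np.asarray(subcomp, dtype=float))
    if X.shape[1] != 3:
        raise ValueError("ternary projection needs exactly three parts")
    X = X / X.sum(axis=1, keepdims=True)
    x = X[:, 1] + 0.5 * X[:, 2]
    y = (math.sqrt(3.0) / 2.0) * X[:, 2]
    return np.column_stack([x, y])


def ternary_plot(compositions: np.ndarray,
                 labels: Sequence[str] = PARTS,
                 color: np.ndarray | None = None,
                 path: str | None = None,
                 color_label: str = "outcome"):
    """Four leave-one-out ternary scatter panels for a 4-part sample.

    Each panel drops one behavior, closes the remaining three parts, and
    scatters them in barycentric coordinates, colored by the (diverging)
    outcome variable.  For a 3-part sample a single panel is drawn.

    Returns the matplotlib Figure; writes it to `path` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.atleast_2d(np.asarray(compositions, dtype=float))
    D = X.shape[1]
    if D == 3:
        panels = [(None, tuple(labels))]
    elif D == len(labels):
        panels = [(i, tuple(l for j, l in enumerate(labels) if j != i))
                  for i in range(D)]
    else:
        raise ValueError("compositions must have 3 parts, or match `labels`")

    n_panels = len(panels)
    ncols = 2 if n_panels > 1 else 1
    nrows = math.ceil(n_panels / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 4.5 * nrows))
    axes = np.atleast_1d(axes).ravel()
    tri_x = [0.0, 1.0, 0.5, 0.0]
    tri_y = [0.0, 0.0, math.sqrt(3.0) / 2.0, 0.0]
    for ax, (drop, keep) in zip(axes, panels):
        if drop is None:
            sub = X
        else:
            cols = [j for j in range(D) if j != drop]
            sub = X[:, cols]
        xy = barycentric_xy(sub)
        ax.plot(tri_x, tri_y, color="black", lw=0.8)
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=color, cmap="coolwarm", s=8,
                        alpha=0.7)
        ax.text(-0.02, -0.02, keep[0], ha="right", va="top")
        ax.text(1.02, -0.02, keep[1], ha="left", va="top")
        ax.text(0.5, math.sqrt(3.0) / 2.0 + 0.02, keep[2], ha="center",
                va="bottom")
        ax.set_aspect("equal")
        ax.axis("off")
        if color is not None:
            fig.colorbar(sc, ax=ax, label=color_label, shrink=0.75)
    for ax in axes[n_panels:]:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
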