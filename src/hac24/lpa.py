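"""Latent profile analysis with bias-adjusted distal-outcome association.

A latent profile model is a finite mixture of multivariate normals over
continuous activity indicators, each class with its own mean vector and
(by default) its own full covariance matrix.  Because the four closed
behaviors are linearly dependent, the indicators must be a strict subset
(drop one part — the default is to use the three waking behaviors) or ilr
coordinates.

After a model is chosen (multi-start EM; AIC/BIC/CAIC/aBIC/ICL-BIC,
entropy, bootstrap likelihood-ratio test), persons are modally assigned to
their highest-posterior class.  Modal assignment misclassifies, and the
estimated classification-error matrix D (P(assigned s | true k)) quantifies
by how much.  Regressing an external outcome on the assigned class as if it
were observed ("naive") attenuates class effects and understates standard
errors; the BCH weighted three-step estimator (weights from D^-1) and the
step-3 maximum-likelihood estimator (modal class treated as an indicator
with known error D) undo that bias.  Robust (sandwich) standard errors are
used throughout the distal step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._regression import covariate_design

logger = logging.getLogger(__name__)

COV_FLOOR = 1e-6  # eigenvalue floor for class covariance regularization


# ---------------------------------------------------------------------------
# Gaussian-mixture EM
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """A fitted finite mixture of multivariate normals."""

    K: int
    weights: np.ndarray                 # (K,)
    means: np.ndarray                   # (K, d)
    covariances: np.ndarray             # (K, d, d)
    posteriors: np.ndarray              # (n, K), rows sum to 1
    log_likelihood: float
    trace: np.ndarray                   # log-likelihood per EM iteration
    n_params: int
    n: int
    best_start_seed: int | None = None
    n_replications: int = 1             # starts reproducing the best loglik
    converged: bool = True
    indicator_names: tuple[str, ...] = ()

    def order_by(self, column: int) -> "MixtureFit":
        """Relabel classes by ascending class mean of the given indicator
        (reporting convention: low to high mean sitting time)."""
        order = np.argsort(self.means[:, column], kind="stable")
        return MixtureFit(
            K=self.K, weights=self.weights[order], means=self.means[order],
            covariances=self.covariances[order],
            posteriors=self.posteriors[:, order],
            log_likelihood=self.log_likelihood, trace=self.trace,
            n_params=self.n_params, n=self.n,
            best_start_seed=self.best_start_seed,
            n_replications=self.n_replications, converged=self.converged,
            indicator_names=self.indicator_names,
        )


def _log_mvn_pdf(Y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = Y.shape[1]
    L = np.linalg.cholesky(cov)
    diff = Y - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * math.log(2.0 * math.pi) + logdet + maha)


def _regularize(cov: np.ndarray, floor: float = COV_FLOOR) -> np.ndarray:
    w, U = np.linalg.eigh(cov)
    if w.min() >= floor:
        return cov
    w = np.maximum(w, floor)
    return (U * w) @ U.T


def _em(Y: np.ndarray, weights: np.ndarray, means: np.ndarray,
        covs: np.ndarray, max_iter: int, tol: float,
        covariance_type: str = "full"
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Plain EM from given starting values; log-likelihood is monotone by
    construction and recorded per iteration."""
    n, d = Y.shape
    K = weights.size
    trace = []
    ll_prev = -np.inf
    converged = False
    resp = None

    def e_step():
        logp = np.empty((n, K))
        for k in range(K):
            logp[:, k] = math.log(weights[k]) + _log_mvn_pdf(Y, means[k], covs[k])
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        return float(lse.sum()), np.exp(logp - lse[:, None])

    for _ in range(max_iter):
        ll, resp = e_step()
        trace.append(ll)
        if ll - ll_prev < tol * max(1.0, abs(ll)) and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise _EmptyClass
        weights = nk / n
        means = (resp.T @ Y) / nk[:, None]
        new_covs = np.empty_like(covs)
        eye = np.eye(d)
        for k in range(K):
            diff = Y - means[k]
            C = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            if covariance_type == "diagonal":
                C = np.diag(np.diag(C))
            # C is PSD by construction, so adding the floor bounds all
            # eigenvalues below by COV_FLOOR without an eigendecomposition
            new_covs[k] = C + COV_FLOOR * eye
        if covariance_type == "shared":
            pooled = np.tensordot(nk, new_covs, axes=1) / n
            new_covs = np.broadcast_to(pooled, covs.shape).copy()
        covs = new_covs
    if not converged:
        # re-sync posteriors/log-likelihood with the last M-step parameters
        ll, resp = e_step()
        trace.append(ll)
    return weights, means, covs, resp, np.array(trace), converged


class _EmptyClass(Exception):
    pass


def _n_params(K: int, d: int, covariance_type: str) -> int:
    if covariance_type == "full":
        cov_p = K * d * (d + 1) // 2
    elif covariance_type == "diagonal":
        cov_p = K * d
    elif covariance_type == "shared":
        cov_p = d * (d + 1) // 2
    else:
        raise ValueError(f"unknown covariance_type {covariance_type!r}")
    return (K - 1) + K * d + cov_p


def fit_lpa(indicators: pd.DataFrame | np.ndarray,
            K: int,
            n_starts: int = 160,
            max_iter: int = 250,
            tol: float = 1e-8,
            seed: int = 0,
            covariance_type: str = "full") -> MixtureFit:
    """Best-of-multi-start EM for a K-class latent profile model.

    Starting values: responsibilities seeded from random centroid draws
    (one start per random seed); the solution with the highest final
    log-likelihood wins, and the number of starts replicating that value
    (within 1e-4) is recorded — a check that the optimum is not a one-off.

    The indicators must not be the full set of closed compositional parts:
    the closure makes their covariance matrix rank-deficient.  Singular
    class covariances along the way are floored at eigenvalue 1e-6.
    """
    if isinstance(indicators, pd.DataFrame):
        names = tuple(indicators.columns)
        Y = indicators.to_numpy(dtype=float)
    else:
        Y = np.asarray(indicators, dtype=float)
        names = tuple(f"y{i}" for i in range(Y.shape[1]))
    n, d = Y.shape
    _check_not_closed(Y, names)
    if K == 1:
        mean = Y.mean(axis=0, keepdims=True)
        cov = np.cov(Y, rowvar=False, ddof=0).reshape(1, d, d)
        ll = float(_log_mvn_pdf(Y, mean[0], _regularize(cov[0])).sum())
        return MixtureFit(1, np.ones(1), mean, cov, np.ones((n, 1)), ll,
                          np.array([ll]), _n_params(1, d, covariance_type), n,
                          indicator_names=names)

    master = np.random.SeedSequence(seed)
    best = None
    best_ll = -np.inf
    lls = []
    base_cov = _regularize(np.cov(Y, rowvar=False, ddof=0))
    for start_idx, child in enumerate(master.spawn(n_starts)):
        rng = np.random.default_rng(child)
        means = _kmeanspp_centroids(Y, K, rng)
        covs = np.broadcast_to(base_cov, (K, d, d)).copy()
        weights = np.full(K, 1.0 / K)
        try:
            out = _em(Y, weights, means, covs, max_iter, tol, covariance_type)
        except (_EmptyClass, np.linalg.LinAlgError):
            logger.debug("start %d collapsed; skipped", start_idx)
            continue
        w, mu, cv, resp, trace, conv = out
        lls.append(trace[-1])
        if trace[-1] > best_ll:
            best_ll = trace[-1]
            best = (w, mu, cv, resp, trace, conv, start_idx)
    if best is None:
        raise RuntimeError("every EM start collapsed; try fewer classes")
    w, mu, cv, resp, trace, conv, start_idx = best
    n_rep = int(sum(abs(l - best_ll) < 1e-4 for l in lls))
    if n_starts >= 10 and n_rep < max(1, n_starts // 10):
        logger.warning("best log-likelihood replicated in only %d/%d starts",
                       n_rep, n_starts)
    fit = MixtureFit(K, w, mu, cv, resp, float(trace[-1]), trace,
                     _n_params(K, d, covariance_type), n,
                     best_start_seed=start_idx, n_replications=n_rep,
                     converged=conv, indicator_names=names)
    return fit.order_by(0) if "sit" == (names[0] if names else "") else fit


def _kmeanspp_centroids(Y: np.ndarray, K: int,
                        rng: np.random.Generator) -> np.ndarray:
    """kmeans++ seeding: spread starting centroids with probability
    proportional to squared distance from the chosen set.  Far more robust
    than uniform draws for overlapping classes."""
    n = Y.shape[0]
    centroids = [Y[rng.integers(n)]]
    for _ in range(K - 1):
        d2 = np.min([np.sum((Y - c) ** 2, axis=1) for c in centroids], axis=0)
        total = d2.sum()
        if total <= 0:
            centroids.append(Y[rng.integers(n)])
            continue
        centroids.append(Y[rng.choice(n, p=d2 / total)])
    return np.array(centroids)


def _check_not_closed(Y: np.ndarray, names: tuple[str, ...]) -> None:
    if Y.shape[1] < 2:
        return
    totals = Y.sum(axis=1)
    if np.ptp(totals) < 1e-8 * max(1.0, abs(totals[0])):
        raise ValueError(
            "indicators sum to a constant (a full closed composition): the "
            "covariance matrix is rank-deficient; drop one part or supply "
            "ilr coordinates"
        )


# ---------------------------------------------------------------------------
# Model selection statistics
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionStats:
    K: int
    log_likelihood: float
    n_params: int
    aic: float
    bic: float
    caic: float
    abic: float
    icl_bic: float
    entropy: float | None
    min_class_share: float

    def as_row(self) -> dict:
        return {"K": self.K, "loglik": self.log_likelihood,
                "n_params": self.n_params, "AIC": self.aic, "BIC": self.bic,
                "CAIC": self.caic, "aBIC": self.abic, "ICL_BIC": self.icl_bic,
                "entropy": self.entropy,
                "min_class_share": self.min_class_share}


def selection_stats(fit: MixtureFit) -> ModelSelectionStats:
    """Information criteria and the entropy statistic for a converged fit.

    AIC = -2l + 2p; BIC = -2l + p ln n; CAIC = -2l + p(ln n + 1);
    aBIC replaces n by (n + 2)/24; ICL-BIC = BIC + 2 * total posterior
    entropy; E = 1 - entropy / (n ln K) in [0, 1] (undefined at K = 1).
    """
    n, p, ll = fit.n, fit.n_params, fit.log_likelihood
    from scipy.special import xlogy
    ent_sum = float(-xlogy(fit.posteriors, fit.posteriors).sum())
    E = None if fit.K == 1 else 1.0 - ent_sum / (n * math.log(fit.K))
    return ModelSelectionStats(
        K=fit.K, log_likelihood=ll, n_params=p,
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * math.log(n),
        caic=-2 * ll + p * (math.log(n) + 1.0),
        abic=-2 * ll + p * math.log((n + 2) / 24.0),
        icl_bic=-2 * ll + p * math.log(n) + 2.0 * ent_sum,
        entropy=E,
        min_class_share=float(fit.weights.min()),
    )


def selection_table(fits: dict[int, MixtureFit]) -> pd.DataFrame:
    return pd.DataFrame([selection_stats(f).as_row()
                         for _, f in sorted(fits.items())])


# ---------------------------------------------------------------------------
# Bootstrap likelihood-ratio test
# ---------------------------------------------------------------------------

def bootstrap_lrt(indicators: pd.DataFrame | np.ndarray,
                  K: int,
                  reps: int = 99,
                  seed: int = 0,
                  n_starts: int = 8,
                  max_iter: int = 250,
                  tol: float = 1e-8,
                  max_redraws: int = 20,
                  covariance_type: str = "full") -> dict:
    """Parametric bootstrap test of K classes against K-1.

    Bootstrap samples are drawn from the fitted (K-1)-class model; the
    p-value is (1 + #{bootstrap LR >= observed LR}) / (reps + 1).
    Non-convergent bootstrap fits are redrawn (capped and logged).
    """
    if reps < 99:
        raise ValueError("use at least 99 bootstrap replicates")
    Y = indicators.to_numpy(dtype=float) if isinstance(indicators, pd.DataFrame) \
        else np.asarray(indicators, dtype=float)
    n = Y.shape[0]
    fit_null = fit_lpa(Y, K - 1, n_starts=n_starts, max_iter=max_iter,
                       tol=tol, seed=seed, covariance_type=covariance_type)
    fit_alt = fit_lpa(Y, K, n_starts=n_starts, max_iter=max_iter,
                      tol=tol, seed=seed, covariance_type=covariance_type)
    lr_obs = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)

    master = np.random.SeedSequence([seed, 0x5b5])
    rng = np.random.default_rng(master)
    count = 0
    redraws = 0
    lr_boot = []
    for b in range(reps):
        for attempt in range(max_redraws):
            Yb = _sample_mixture(fit_null, n, rng)
            try:
                f0 = fit_lpa(Yb, K - 1, n_starts=n_starts, max_iter=max_iter,
                             tol=tol, seed=seed + 7 * b + attempt,
                             covariance_type=covariance_type)
                f1 = fit_lpa(Yb, K, n_starts=n_starts, max_iter=max_iter,
                             tol=tol, seed=seed + 7 * b + attempt,
                             covariance_type=covariance_type)
                break
            except RuntimeError:
                redraws += 1
        else:
            raise RuntimeError("bootstrap fits failed to converge repeatedly")
        lr_b = 2.0 * (f1.log_likelihood - f0.log_likelihood)
        lr_boot.append(lr_b)
        if lr_b >= lr_obs:
            count += 1
    if redraws:
        logger.info("bootstrap_lrt: %d non-convergent bootstrap fits redrawn",
                    redraws)
    return {"K": K, "lr_observed": lr_obs,
            "p_value": (1 + count) / (reps + 1),
            "reps": reps, "lr_bootstrap": np.array(lr_boot)}


def _sample_mixture(fit: MixtureFit, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(fit.K, size=n, p=fit.weights)
    d = fit.means.shape[1]
    Y = np.empty((n, d))
    for k in range(fit.K):
        mask = comp == k
        if mask.any():
            Y[mask] = rng.multivariate_normal(fit.means[k], fit.covariances[k],
                                              size=int(mask.sum()),
                                              method="cholesky")
    return Y


# ---------------------------------------------------------------------------
# Modal assignment and classification error
# ---------------------------------------------------------------------------

def modal_assign(fit: MixtureFit) -> np.ndarray:
    """Assign each person to the class of highest posterior probability.

    Ties break to the lowest class index (logged)."""
    P = fit.posteriors
    labels = P.argmax(axis=1)
    row_max = P.max(axis=1)
    ties = (np.isclose(P, row_max[:, None]).sum(axis=1) > 1)
    if ties.any():
        logger.info("modal_assign: %d exact posterior ties broken to the "
                    "lowest class index", int(ties.sum()))
    return labels


def classification_matrix(fit: MixtureFit,
                          assignment: np.ndarray | None = None) -> np.ndarray:
    """Estimated misclassification matrix D[k, s] = P(assigned s | true k),
    D[k, s] = sum_i p_ik 1{a_i = s} / sum_i p_ik.  Rows sum to one; for
    degenerate 0/1 posteriors D is the identity."""
    if assignment is None:
        assignment = modal_assign(fit)
    P = fit.posteriors
    n, K = P.shape
    if assignment.shape[0] != n:
        raise ValueError("assignment does not match the fit")
    denom = P.sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("a class has zero total posterior mass")
    D = np.zeros((K, K))
    for s in range(K):
        D[:, s] = P[assignment == s].sum(axis=0) / denom
    return D


# ---------------------------------------------------------------------------
# Distal-outcome association
# ---------------------------------------------------------------------------

@dataclass
class DistalFit:
    """Class-specific outcome effects (reference-coded) with robust SEs."""

    method: str                      # naive | bch | ml
    reference: int
    effects: pd.Series               # class effects, reference fixed at 0
    robust_se: pd.Series
    p_values: pd.Series
    wald_global: float
    wald_global_p: float
    params: pd.Series = None         # full coefficient vector
    cov: pd.DataFrame = None
    n: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.effects,
                             "robust_se": self.robust_se,
                             "p_value": self.p_values})


def _class_design(assignment: np.ndarray, K: int, reference: int) -> pd.DataFrame:
    cols = {}
    for k in range(K):
        if k == reference:
            continue
        cols[f"class_{k}"] = (assignment == k).astype(float)
    return pd.DataFrame(cols)


def _effects_from(params: pd.Series, cov: pd.DataFrame, K: int,
                  reference: int, method: str, n: int) -> DistalFit:
    names = [f"class_{k}" for k in range(K) if k != reference]
    eff = pd.Series(0.0, index=[f"class_{k}" for k in range(K)])
    se = pd.Series(np.nan, index=eff.index)
    pv = pd.Series(np.nan, index=eff.index)
    for nm in names:
        eff[nm] = params[nm]
        se[nm] = math.sqrt(cov.loc[nm, nm])
        pv[nm] = 2.0 * stats.norm.sf(abs(eff[nm] / se[nm]))
    b = params[names].to_numpy()
    V = cov.loc[names, names].to_numpy()
    wald = float(b @ np.linalg.solve(V, b))
    wald_p = float(stats.chi2.sf(wald, df=len(names)))
    return DistalFit(method, reference, eff, se, pv, wald, wald_p,
                     params=params, cov=cov, n=n)


def distal_naive(assignment: np.ndarray,
                 outcome: np.ndarray,
                 covariate_table: pd.DataFrame | None = None,
                 covariates: list[str] | None = None,
                 K: int | None = None,
                 reference: int = 0) -> DistalFit:
    """OLS of the outcome on modal class dummies (+ covariates) with HC1
    sandwich SEs, treating the assignment as error-free.  Under imperfect
    separation this attenuates class effects and understates uncertainty."""
    assignment = np.asarray(assignment)
    K = K or int(assignment.max()) + 1
    if not np.any(assignment == reference):
        raise ValueError(f"reference class {reference} is empty")
    y = np.asarray(outcome, dtype=float)
    X = _class_design(assignment, K, reference)
    X.insert(0, "intercept", 1.0)
    if covariates:
        X = pd.concat([X.reset_index(drop=True),
                       covariate_design(covariate_table.reset_index(drop=True),
                                        covariates)], axis=1)
    mask = ~X.isna().any(axis=1).to_numpy() & np.isfinite(y)
    Xm = X.loc[mask].to_numpy(dtype=float)
    ym = y[mask]
    beta, cov = _ols_sandwich(Xm, ym)
    params = pd.Series(beta, index=X.columns)
    covdf = pd.DataFrame(cov, index=X.columns, columns=X.columns)
    return _effects_from(params, covdf, K, reference, "naive", int(mask.sum()))


def _ols_sandwich(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = X.T @ X
    beta = np.linalg.solve(A, X.T @ y)
    e = y - X @ beta
    n, p = X.shape
    meat = (X * e[:, None]).T @ (X * e[:, None])
    Ainv = np.linalg.inv(A)
    cov = Ainv @ meat @ Ainv * n / (n - p)   # HC1
    return beta, cov


def distal_bch(fit: MixtureFit,
               assignment: np.ndarray,
               D: np.ndarray,
               outcome: np.ndarray,
               covariate_table: pd.DataFrame | None = None,
               covariates: list[str] | None = None,
               reference: int = 0) -> DistalFit:
    """BCH weighted three-step regression of the outcome on class membership.

    Each person contributes K expanded records, record (i, k) carrying the
    class-k dummy and weight w_ik = (D^-1)[assigned_i, k] (weights can be
    negative; their per-person sum is one because the rows of D sum to one).
    The weighted normal equations give the effects; SEs are a cluster-robust
    (by person) sandwich.
    """
    K = fit.K
    cond = np.linalg.cond(D)
    if cond > 1e6:
        raise ValueError(
            f"classification-error matrix is ill-conditioned (cond={cond:.3g});"
            " the classes are too poorly separated for BCH weighting"
        )
    Dinv = np.linalg.inv(D)
    assignment = np.asarray(assignment)
    y = np.asarray(outcome, dtype=float)
    n = y.size

    cov_block = None
    if covariates:
        cov_block = covariate_design(
            covariate_table.reset_index(drop=True), covariates)
        keep = ~cov_block.isna().any(axis=1).to_numpy() & np.isfinite(y)
    else:
        keep = np.isfinite(y)
    idx = np.flatnonzero(keep)
    n_kept = idx.size

    # expanded design: rows (i, k)
    class_cols = [f"class_{k}" for k in range(K) if k != reference]
    p_cov = cov_block.shape[1] if cov_block is not None else 0
    p = 1 + len(class_cols) + p_cov
    Xe = np.zeros((n_kept * K, p))
    ye = np.repeat(y[idx], K)
    we = np.empty(n_kept * K)
    person = np.repeat(np.arange(n_kept), K)
    for j, i in enumerate(idx):
        rows = slice(j * K, (j + 1) * K)
        we[rows] = Dinv[assignment[i]]
        Xe[rows, 0] = 1.0
        col = 1
        for k in range(K):
            if k == reference:
                continue
            Xe[j * K + k, col + ([kk for kk in range(K) if kk != reference]
                                 .index(k))] = 1.0
        if cov_block is not None:
            Xe[rows, 1 + len(class_cols):] = cov_block.to_numpy(dtype=float)[i]

    A = Xe.T @ (we[:, None] * Xe)
    try:
        beta = np.linalg.solve(A, Xe.T @ (we * ye))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular BCH weighted system") from err
    e = ye - Xe @ beta
    g = we[:, None] * Xe * e[:, None]
    # cluster (person) scores
    G = np.zeros((n_kept, p))
    np.add.at(G, person, g)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ (G.T @ G) @ Ainv * n_kept / (n_kept - 1)
    names = ["intercept"] + class_cols + \
        (list(cov_block.columns) if cov_block is not None else [])
    params = pd.Series(beta, index=names)
    covdf = pd.DataFrame(cov, index=names, columns=names)
    return _effects_from(params, covdf, K, reference, "bch", n_kept)


# ---------------------------------------------------------------------------
# Step-3 maximum-likelihood estimator
# ---------------------------------------------------------------------------

def distal_ml(fit: MixtureFit,
              assignment: np.ndarray,
              D: np.ndarray,
              external: np.ndarray,
              role: str = "outcome",
              covariate_table: pd.DataFrame | None = None,
              covariates: list[str] | None = None,
              reference: int = 0,
              maxiter: int = 500) -> DistalFit:
    """Three-step ML: the modal assignment is an indicator of the latent
    class with known misclassification probabilities D.

    role="outcome": per-person likelihood
        sum_k pi_k D[k, a_i] Normal(y_i; b0 + alpha_k + g'x_i, sigma^2),
    maximized over class proportions, effects, and the residual scale.

    role="predictor": multinomial model of class membership on the external
    variable, P(C=k|v_i) = softmax(a_k + b_k v_i), with likelihood
        sum_k P(C=k|v_i) D[k, a_i].

    Robust SEs come from the empirical sandwich (outer product of per-person
    scores around the numerical Hessian).
    """
    if role not in {"outcome", "predictor"}:
        raise ValueError("role must be 'outcome' or 'predictor'")
    if not fit.converged:
        logger.warning("step-1 mixture fit stopped at its iteration cap "
                       "before meeting the tolerance; proceeding with its "
                       "final parameters")
    K = fit.K
    assignment = np.asarray(assignment)
    v = np.asarray(external, dtype=float)

    if role == "outcome":
        return _ml_outcome(fit, assignment, D, v, covariate_table, covariates,
                           reference, maxiter, K)
    return _ml_predictor(fit, assignment, D, v, reference, maxiter, K)


def _pack_softmax(pi: np.ndarray) -> np.ndarray:
    return np.log(pi[1:] / pi[0])


def _unpack_softmax(theta: np.ndarray, K: int) -> np.ndarray:
    z = np.concatenate([[0.0], theta])
    e = np.exp(z - z.max())
    return e / e.sum()


def _ml_outcome(fit, assignment, D, y, covariate_table, covariates,
                reference, maxiter, K):
    if covariates:
        cov_block = covariate_design(
            covariate_table.reset_index(drop=True), covariates)
        keep = ~cov_block.isna().any(axis=1).to_numpy() & np.isfinite(y)
        Xc = cov_block.to_numpy(dtype=float)[keep]
        cov_names = list(cov_block.columns)
    else:
        keep = np.isfinite(y)
        Xc = np.zeros((int(keep.sum()), 0))
        cov_names = []
    yk = y[keep]
    ak = assignment[keep]
    n = yk.size
    logD_a = np.log(np.maximum(D[:, ak], 1e-300))        # (K, n)

    alpha_idx = [k for k in range(K) if k != reference]
    p_cov = Xc.shape[1]
    # theta = [pi_logits (K-1), b0, alpha (K-1), gamma (p_cov), log sigma]
    def unpack(theta):
        pi = _unpack_softmax(theta[:K - 1], K)
        b0 = theta[K - 1]
        alpha = np.zeros(K)
        alpha[alpha_idx] = theta[K:K + K - 1]
        gamma = theta[K + K - 1:K + K - 1 + p_cov]
        sigma = math.exp(theta[-1])
        return pi, b0, alpha, gamma, sigma

    def per_person_ll(theta):
        pi, b0, alpha, gamma, sigma = unpack(theta)
        base = np.full(n, b0) + (Xc @ gamma if p_cov else 0.0)
        # (K, n) log components
        comp = (np.log(pi)[:, None] + logD_a
                + stats.norm.logpdf(yk[None, :],
                                    loc=base[None, :] + alpha[:, None],
                                    scale=sigma))
        m = comp.max(axis=0)
        return m + np.log(np.exp(comp - m).sum(axis=0))

    def negll(theta):
        return -float(per_person_ll(theta).sum())

    # start from naive class means
    theta0 = np.zeros(K - 1 + 1 + K - 1 + p_cov + 1)
    theta0[:K - 1] = _pack_softmax(np.maximum(fit.weights, 1e-6))
    ybar = np.array([yk[ak == k].mean() if np.any(ak == k) else yk.mean()
                     for k in range(K)])
    theta0[K - 1] = ybar[reference]
    theta0[K:K + K - 1] = ybar[alpha_idx] - ybar[reference]
    theta0[-1] = math.log(max(yk.std(), 1e-3))

    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-6})
    if not (res.success or res.status == 2):   # status 2: precision loss at optimum
        raise RuntimeError(f"step-3 ML did not converge: {res.message}\n{res}")
    theta = res.x
    cov_theta = _sandwich_cov(per_person_ll, theta)

    names = ([f"pi_logit_{k}" for k in alpha_idx] + ["intercept"]
             + [f"class_{k}" for k in alpha_idx] + cov_names + ["log_sigma"])
    params = pd.Series(theta, index=names)
    covdf = pd.DataFrame(cov_theta, index=names, columns=names)
    return _effects_from(params, covdf, K, reference, "ml", n)


def _ml_predictor(fit, assignment, D, v, reference, maxiter, K):
    keep = np.isfinite(v)
    vk = v[keep]
    ak = assignment[keep]
    n = vk.size
    logD_a = np.log(np.maximum(D[:, ak], 1e-300))
    free = [k for k in range(K) if k != reference]

    def per_person_ll(theta):
        a = np.zeros(K)
        b = np.zeros(K)
        a[free] = theta[:K - 1]
        b[free] = theta[K - 1:]
        lin = a[:, None] + b[:, None] * vk[None, :]
        lin -= lin.max(axis=0)
        logpk = lin - np.log(np.exp(lin).sum(axis=0))
        comp = logpk + logD_a
        m = comp.max(axis=0)
        return m + np.log(np.exp(comp - m).sum(axis=0))

    def negll(theta):
        return -float(per_person_ll(theta).sum())

    theta0 = np.zeros(2 * (K - 1))   # uniform class probabilities, null slopes
    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-6})
    if not (res.success or res.status == 2):
        raise RuntimeError(f"step-3 ML (predictor) did not converge: "
                           f"{res.message}")
    theta = res.x
    cov_theta = _sandwich_cov(per_person_ll, theta)
    names = ([f"intercept_class_{k}" for k in free]
             + [f"class_{k}" for k in free])
    params = pd.Series(theta, index=names)
    covdf = pd.DataFrame(cov_theta, index=names, columns=names)
    return _effects_from(params, covdf, K, reference, "ml", n)


def _sandwich_cov(per_person_ll, theta: np.ndarray,
                  eps: float = 1e-5) -> np.ndarray:
    """Empirical sandwich: A^-1 B A^-1 with B the outer product of per-person
    scores and A the (negative) Hessian of the total log-likelihood, both by
    central finite differences."""
    p = theta.size
    n = per_person_ll(theta).size
    scores = np.empty((n, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        h = eps * max(1.0, abs(theta[j]))
        tp[j] += h
        tm[j] -= h
        scores[:, j] = (per_person_ll(tp) - per_person_ll(tm)) / (2 * h)

    def grad(th):
        g = np.empty(p)
        for j in range(p):
            tp, tm = th.copy(), th.copy()
            h = eps * max(1.0, abs(th[j]))
            tp[j] += h
            tm[j] -= h
            g[j] = (per_person_ll(tp).sum() - per_person_ll(tm).sum()) / (2 * h)
        return g

    H = np.empty((p, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        h = eps * max(1.0, abs(theta[j]))
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad(tp) - grad(tm)) / (2 * h)
    H = (H + H.T) / 2.0
    A = -H
    B = scores.T @ scores
    Ainv = np.linalg.pinv(A)
    return Ainv @ B @ Ainv


# ---------------------------------------------------------------------------
# Label alignment and profile plotting
# ---------------------------------------------------------------------------

def match_labels(fit: MixtureFit, reference_means: np.ndarray) -> np.ndarray:
    """Permutation aligning the fit's classes to reference mean vectors by
    minimal total Euclidean distance (resolves label switching)."""
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(fit.means[:, None, :] - reference_means[None, :, :],
                          axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(fit.K, dtype=int)
    perm[cols] = rows
    return perm


def profile_boxplot(indicators: pd.DataFrame, assignment: np.ndarray,
                    path: str | None = None):
    """Per-class boxplots of each indicator (modal assignment)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = list(indicators.columns)
    K = int(np.max(assignment)) + 1
    fig, axes = plt.subplots(1, len(cols), figsize=(3.2 * len(cols), 3.5))
    for ax, col in zip(np.atleast_1d(axes).ravel(), cols):
        data = [indicators.loc[assignment == k, col].dropna() for k in range(K)]
        ax.boxplot(data, tick_labels=[f"{k + 1}" for k in range(K)])
        ax.set_title(col)
        ax.set_xlabel("profile")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
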