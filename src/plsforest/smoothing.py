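"""Two-stage zero-inflated spatial smoothing with quasi-Bayesian draws.

Grid-cell data for a taxon p are modeled in two independent stages:

* occupancy:  n_p(s) ~ Binomial(N(s), theta_p(s)),  logit(theta) smooth in s;
* potential:  log Ybar_p(s) ~ Normal(m_p(s), sigma_p^2 / n_p(s)) over the
  occupied cells, i.e. a weighted Gaussian regression with weights n_p(s)
  (the usual variance of an average of n_p point values).

The smooths are low-rank tensor-product B-spline surfaces over cell-center
coordinates with a second-order difference (P-spline) penalty, the roughness
penalty's nullspace containing constants (and bilinear trends).  The
smoothing parameter is chosen by generalized cross-validation.  The cell
prediction combines the stages as

    b_p(s) = theta_p(s) * exp(m_p(s)),

which weights the mean value over occupied points by the probability that a
point is occupied — the zero-inflation decomposition.  Cells with no survey
data are excluded from the likelihoods but predicted (spatial imputation).

Uncertainty is quasi-Bayesian: coefficient draws from the multivariate
normal centered at the penalized estimate with the Bayesian posterior
covariance of the penalized fit, ``sigma^2 (B'WB + lambda S)^{-1}`` for the
Gaussian stage and ``(B'WB + lambda S)^{-1}`` (unit scale) for the binomial
stage.  Draws from the two stages are combined independently, after two
ad-hoc adjustments that guard against numerically-degenerate occupancy
draws: taxon-level draws exceeding five times the point estimate are reset
to the point estimate, and (for the all-taxa total fit) draws in cells whose
occupancy point estimate exceeds 0.999 are set to one.

Smoothing on the log scale discounts outlying cells, so back-transformed
estimates carry a known downward bias relative to raw arithmetic means; see
the methods note.  The delta-method variance that would replace
``sigma^2/n_p`` by a form with an extra ``m_p(s)`` factor is provided only
as a diagnostic (:func:`delta_method_log_variance`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

#: Default smoothing-parameter grid for GCV (dimensionless, on the raw
#: penalty scale of the basis below).
LAMBDA_GRID = np.logspace(-4.0, 6.0, 11)

_ETA_CLIP = 15.0  # logit-scale clip guarding expit over/underflow


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Tensor-product B-spline basis evaluated at cell centers.

    ``B`` is the n_cells x K design matrix, ``S`` the K x K symmetric PSD
    roughness penalty (sum of marginal second-order difference penalties).
    Constants lie in the penalty nullspace: the marginal bases are a
    partition of unity, so a constant coefficient vector represents a
    constant surface and is annihilated by the difference penalty.
    """

    B: np.ndarray
    S: np.ndarray
    coords: np.ndarray
    k_requested: int
    kx: int
    ky: int
    degree: int

    @property
    def n_cells(self) -> int:
        return self.B.shape[0]

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]


def _marginal_design(x: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Uniform B-spline design matrix with ``n_basis`` functions over x's range."""
    xmin, xmax = float(np.min(x)), float(np.max(x))
    span = xmax - xmin
    if span <= 0:  # degenerate (all cells share a coordinate)
        return np.ones((x.size, 1))
    h = span / (n_basis - degree)
    t = xmin + h * (np.arange(n_basis + degree + 1) - degree)
    xc = np.clip(x, xmin, xmax - 1e-12 * span)
    return BSpline.design_matrix(xc, t, degree).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    if k <= order:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def build_basis(coords: np.ndarray, k: int) -> SplineBasis:
    """Build a 2-D tensor-product P-spline basis with at most ``k`` functions.

    ``coords`` is (n_cells, 2).  The marginal dimension is ``floor(sqrt(k))``
    in each direction (so the tensor basis has at most k functions); cubic
    marginals when the dimension allows, lower degree for very small bases.
    A ``k`` exceeding the number of cells is capped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells to build a spatial basis")
    if k < 4:
        raise ValueError("k must be at least 4")
    if k > n:
        warnings.warn(f"k={k} exceeds the number of cells ({n}); capping", stacklevel=2)
        k = n
    kx = max(2, int(np.floor(np.sqrt(k))))
    ky = kx
    degree = 3 if kx >= 4 else kx - 1
    Bx = _marginal_design(coords[:, 0], kx, degree)
    By = _marginal_design(coords[:, 1], ky, degree)
    kx_eff, ky_eff = Bx.shape[1], By.shape[1]
    B = np.einsum("ni,nj->nij", Bx, By).reshape(n, kx_eff * ky_eff)
    S = (np.kron(_difference_penalty(kx_eff), np.eye(ky_eff))
         + np.kron(np.eye(kx_eff), _difference_penalty(ky_eff)))
    return SplineBasis(B=B, S=S, coords=coords, k_requested=k,
                       kx=kx_eff, ky=ky_eff, degree=degree)


# ---------------------------------------------------------------------------
# penalized fits
# ---------------------------------------------------------------------------

@dataclass
class SmoothFit:
    """A penalized-spline fit: coefficients, posterior covariance, metadata.

    ``V_beta`` is the Bayesian posterior covariance of the penalized fit;
    ``sigma2`` is the residual variance of the potential (log-Gaussian)
    stage and ``None`` for the binomial stage.  ``include`` records which
    cells entered the likelihood; predictions cover all cells.
    """

    basis: SplineBasis
    beta: np.ndarray
    V_beta: np.ndarray
    lam: float
    edf: float
    family: str                      # "binomial" | "log-gaussian"
    sigma2: float | None = None
    include: np.ndarray | None = None
    gcv_path: pd.DataFrame | None = field(default=None, repr=False)
    degenerate: bool = False

    def linear_predictor(self) -> np.ndarray:
        """Fitted smooth (link scale) at every cell of the grid."""
        return self.basis.B @ self.beta

    def predict(self) -> np.ndarray:
        """Fitted values on the response scale at every cell."""
        eta = self.linear_predictor()
        if self.family == "binomial":
            return expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return eta


def _solve_penalized(BtWB, BtWz, S, lam):
    A = BtWB + lam * S
    try:
        c = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(A)) + 1e-12
        c = cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
    beta = cho_solve(c, BtWz)
    edf = float(np.trace(cho_solve(c, BtWB)))
    return beta, edf, c


def _inv_from_chol(c, k):
    return cho_solve(c, np.eye(k))


def fit_potential(
    ybar: np.ndarray,
    weights: np.ndarray,
    basis: SplineBasis,
    lam: float | None = None,
    include: np.ndarray | None = None,
    lambda_grid: np.ndarray = LAMBDA_GRID,
    scale_weights_by: float | None = None,
    log_scale: bool = True,
) -> SmoothFit:
    """Weighted penalized regression of log Ybar_p on the spatial smooth.

    Only cells with a positive ``ybar`` and positive weight (``n_p >= 1``)
    enter the likelihood; ``include`` can restrict further (e.g. CV train
    folds).  With ``lam=None`` the smoothing parameter minimizes GCV,
    ``n * RSS_w / (n - edf)^2``.  The residual variance ``sigma2`` is the
    weighted residual sum of squares over the residual degrees of freedom —
    with weights n_p this estimates the per-point log-scale variance
    sigma_p^2.  ``scale_weights_by`` optionally divides all weights by a
    constant (e.g. 70, one fully-surveyed cell = one unit of information);
    default off because point estimates are invariant to it.
    ``log_scale=False`` fits Ybar itself (the original-scale variant kept
    for the model-comparison harness).
    """
    ybar = np.asarray(ybar, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = np.isfinite(ybar) & (weights > 0)
    if log_scale:
        ok = ok & (ybar > 0)
    if include is not None:
        ok = ok & np.asarray(include, dtype=bool)
    nullspace_dim = max(1, basis.n_basis - np.linalg.matrix_rank(basis.S))
    if int(ok.sum()) < nullspace_dim:
        raise ValueError(
            f"only {int(ok.sum())} occupied cells but the penalty nullspace "
            f"has dimension {nullspace_dim}; the fit is unidentifiable"
        )
    B = basis.B[ok]
    w = weights[ok].copy()
    if scale_weights_by:
        w /= float(scale_weights_by)
    z = np.log(ybar[ok]) if log_scale else ybar[ok]
    n = z.size
    BtWB = (B * w[:, None]).T @ B
    BtWz = B.T @ (w * z)

    def fit_at(l):
        beta, edf, c = _solve_penalized(BtWB, BtWz, basis.S, l)
        resid = z - B @ beta
        rss_w = float(np.sum(w * resid**2))
        return beta, edf, c, rss_w

    path = None
    if lam is None:
        rows = []
        best = None
        for l in lambda_grid:
            beta, edf, c, rss_w = fit_at(l)
            gcv = n * rss_w / max(n - edf, 1e-8) ** 2
            rows.append({"lambda": l, "edf": edf, "gcv": gcv})
            if best is None or gcv < best[0]:
                best = (gcv, l, beta, edf, c, rss_w)
        _, lam, beta, edf, c, rss_w = best
        path = pd.DataFrame(rows)
    else:
        beta, edf, c, rss_w = fit_at(lam)
    sigma2 = rss_w / max(n - edf, 1e-8)
    V = sigma2 * _inv_from_chol(c, basis.n_basis)
    return SmoothFit(basis=basis, beta=beta, V_beta=V, lam=float(lam), edf=edf,
                     family="log-gaussian" if log_scale else "gaussian",
                     sigma2=float(sigma2), include=ok, gcv_path=path)


def _binomial_deviance(n_p, N, mu):
    p = n_p / N
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n_p > 0, n_p * np.log(p / mu), 0.0)
        t2 = np.where(n_p < N, (N - n_p) * np.log((1 - p) / (1 - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def fit_occupancy(
    n_p: np.ndarray,
    N: np.ndarray,
    basis: SplineBasis,
    lam: float | None = None,
    include: np.ndarray | None = None,
    lambda_grid: np.ndarray = LAMBDA_GRID,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> SmoothFit:
    """Penalized binomial (logit) regression of per-cell occupancy counts.

    Cells with ``N = 0`` are excluded from the likelihood but predicted.
    Fitting is penalized IRLS with prior weights ``N(s)``; the smoothing
    parameter minimizes a deviance-based GCV, ``n * dev / (n - edf)^2``.
    An all-zero response is flagged as degenerate (theta ~ 0 everywhere).
    """
    n_p = np.asarray(n_p, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(n_p < 0) or np.any(n_p > N):
        raise ValueError("need 0 <= n_p <= N in every cell")
    ok = N > 0
    if include is not None:
        ok = ok & np.asarray(include, dtype=bool)
    B = basis.B[ok]
    npk = n_p[ok]
    Nk = N[ok]
    n = int(ok.sum())
    degenerate = bool(np.all(npk == 0))
    if degenerate:
        warnings.warn("all occupancy counts are zero; fit is degenerate "
                      "(theta ~ 0 everywhere)", stacklevel=2)

    def irls(l):
        eta = np.clip(logit((npk + 0.5) / (Nk + 1.0)), -_ETA_CLIP, _ETA_CLIP)
        dev_old = np.inf
        beta = None
        for _ in range(max_iter):
            mu = expit(eta)
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            wt = Nk * mu * (1 - mu)
            z = eta + (npk / Nk - mu) / (mu * (1 - mu))
            BtWB = (B * wt[:, None]).T @ B
            BtWz = B.T @ (wt * z)
            beta, edf, c = _solve_penalized(BtWB, BtWz, basis.S, l)
            eta = np.clip(B @ beta, -_ETA_CLIP, _ETA_CLIP)
            dev = _binomial_deviance(npk, Nk, np.clip(expit(eta), 1e-10, 1 - 1e-10))
            if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
                dev_old = dev
                break
            dev_old = dev
        return beta, edf, c, dev_old

    path = None
    if lam is None:
        rows = []
        best = None
        for l in lambda_grid:
            beta, edf, c, dev = irls(l)
            gcv = n * dev / max(n - edf, 1e-8) ** 2
            rows.append({"lambda": l, "edf": edf, "gcv": gcv})
            if best is None or gcv < best[0]:
                best = (gcv, l, beta, edf, c)
        _, lam, beta, edf, c = best
        path = pd.DataFrame(rows)
    else:
        beta, edf, c, _ = irls(lam)
    V = _inv_from_chol(c, basis.n_basis)
    return SmoothFit(basis=basis, beta=beta, V_beta=V, lam=float(lam), edf=edf,
                     family="binomial", sigma2=None, include=ok,
                     gcv_path=path, degenerate=degenerate)


# ---------------------------------------------------------------------------
# field prediction and quasi-Bayesian draws
# ---------------------------------------------------------------------------

@dataclass
class Fields:
    """Point predictions per cell: occupancy theta, log-potential m, and the
    combined field b = theta * exp(m)."""

    theta: np.ndarray
    m: np.ndarray
    b: np.ndarray
    coords: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "theta": self.theta, "m": self.m, "b": self.b,
        })


def predict_fields(occupancy_fit: SmoothFit, potential_fit: SmoothFit) -> Fields:
    """Combine the two stages: b(s) = theta(s) * exp(m(s)) at every cell."""
    if occupancy_fit.basis.n_cells != potential_fit.basis.n_cells:
        raise ValueError("occupancy and potential fits are on different grids")
    theta = occupancy_fit.predict()
    m = potential_fit.linear_predictor()
    return Fields(theta=theta, m=m, b=theta * np.exp(m),
                  coords=occupancy_fit.basis.coords)


def draw_coefficients(
    fit: SmoothFit, n_draws: int, seed: int | np.random.Generator
) -> np.ndarray:
    """``n_draws`` multivariate-normal coefficient draws ~ N(beta, V_beta).

    Reproducible given the seed.  A covariance that is not numerically
    positive definite is repaired to the nearest PSD matrix (eigenvalue
    clipping) with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = 0.5 * (fit.V_beta + fit.V_beta.T)
    k = V.shape[0]
    if not np.any(V):
        return np.tile(fit.beta, (n_draws, 1))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        warnings.warn("posterior covariance not positive definite; using "
                      "nearest-PSD repair", stacklevel=2)
        evals, evecs = np.linalg.eigh(V)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    Z = rng.standard_normal((n_draws, k))
    return fit.beta[None, :] + Z @ L.T


def occupancy_draws(fit: SmoothFit, coef_draws: np.ndarray) -> np.ndarray:
    """Field-level occupancy draws, (n_draws, n_cells), in (0, 1)."""
    return expit(np.clip(coef_draws @ fit.basis.B.T, -_ETA_CLIP, _ETA_CLIP))


def potential_draws(fit: SmoothFit, coef_draws: np.ndarray) -> np.ndarray:
    """Field-level log-potential draws, (n_draws, n_cells)."""
    return coef_draws @ fit.basis.B.T


@dataclass
class DrawsCube:
    """Adjusted quasi-posterior draws: (n_draws, n_cells) arrays for theta,
    m, and b = theta * exp(m), with the generating seed and variable tag."""

    theta: np.ndarray
    m: np.ndarray
    b: np.ndarray
    seed: int | None = None
    variable: str = ""

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def summary(self) -> pd.DataFrame:
        """Per-cell posterior mean and standard deviation of b."""
        return pd.DataFrame({"b_mean": self.b.mean(axis=0), "b_sd": self.b.std(axis=0)})

    def to_dataset(self):
        """The cube as an xarray Dataset (dims: draw, cell); write with
        ``ds.to_netcdf(path, engine="scipy")``."""
        import xarray as xr

        dims = ("draw", "cell")
        return xr.Dataset(
            {"theta": (dims, self.theta), "m": (dims, self.m), "b": (dims, self.b)},
            coords={"draw": np.arange(self.n_draws), "cell": np.arange(self.theta.shape[1])},
            attrs={"variable": self.variable, "seed": -1 if self.seed is None else self.seed},
        )


def combine_and_adjust(
    theta_draws: np.ndarray,
    m_draws: np.ndarray,
    theta_hat: np.ndarray,
    total: bool = False,
    seed: int | None = None,
    variable: str = "",
) -> DrawsCube:
    """Combine independent stage draws into b-draws after the two guards.

    Rule (i), taxon fits: an occupancy draw exceeding five times the point
    estimate is reset to the point estimate.  Rule (ii), the all-taxa total
    fit (``total=True``): in cells where the occupancy *point estimate*
    exceeds 0.999, every draw is set to exactly 1.  Then
    ``b_d(s) = theta_d(s) * exp(m_d(s))`` elementwise.
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    m_draws = np.asarray(m_draws, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_draws.shape != m_draws.shape or theta_draws.shape[1] != theta_hat.size:
        raise ValueError("draw arrays and point estimates are on mismatched grids")
    adj = theta_draws.copy()
    if total:
        adj[:, theta_hat > 0.999] = 1.0
    else:
        cap = 5.0 * theta_hat[None, :]
        adj = np.where(adj > cap, theta_hat[None, :], adj)
    return DrawsCube(theta=adj, m=m_draws, b=adj * np.exp(m_draws),
                     seed=seed, variable=variable)


def delta_method_log_variance(fit: SmoothFit, n_p: np.ndarray) -> np.ndarray:
    """Diagnostic only: per-cell delta-method variance of log Ybar.

    The fitted likelihood uses Var(log Ybar) = sigma^2 / n_p.  Treating the
    *original-scale* mean as having variance sigma_orig^2 / n_p, the delta
    method gives Var(log Ybar) ~ Var(Ybar) / E[Ybar]^2; expressed through the
    fitted log-scale quantities this divides the fitted variance by an extra
    factor of the potential surface.  There is no principled way to fit under
    this form with the penalized-regression machinery, so it is surfaced only
    for comparison against the working assumption.
    """
    if fit.family != "log-gaussian":
        raise ValueError("delta-method diagnostic applies to the potential fit")
    m = fit.linear_predictor()
    n_p = np.asarray(n_p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n_p > 0, fit.sigma2 / (n_p * np.abs(m)), np.nan)
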