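"""MIMIC structural equation model for the global-asymmetry index.

The model integrates eleven per-slice asymmetry indicators into one
latent Global Asymmetry (GA) factor and regresses it on observed causes
(SES, age, sex):

measurement part
    y_j = lambda_j * eta + eps_j,          Theta = Cov(eps) (diagonal
    plus a few adjacent-slice residual covariances)

structural part
    eta = gamma' x + zeta,                 psi = Var(zeta)

The implied covariance of v = (y, x) is

    Sigma_yy = (gamma' Phi gamma + psi) lambda lambda' + Theta
    Sigma_yx = lambda (Phi gamma)'
    Sigma_xx = Phi

Estimation minimizes the ML discrepancy

    F(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

with chi-square T = (n - 1) F at the optimum.  The exogenous block Phi
is saturated, so by the conditional-likelihood factorization its ML
estimate is exactly the sample block S_xx; it is held there and the
remaining parameters are optimized.  This convention reproduces the
published degrees of freedom (70 for the full 11-indicator model) and
yields fixed-x standard errors for the measurement/structural
parameters.

Identification: either the first indicator's loading is fixed to 1
(default; the latent scale is the first indicator's) or the latent
(disturbance) variance is fixed to 1 with all loadings free.  Both give
the same fitted covariance and the same standardized solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "MimicSpec",
    "SampleMoments",
    "SemFit",
    "FitIndices",
    "ModificationIndexEntry",
    "TwoStepResult",
    "default_mimic_spec",
    "spec_for_indicators",
    "model_implied_covariance",
    "degrees_of_freedom",
    "fit_ml",
    "fit_baseline",
    "fit_indices",
    "rmsea",
    "modification_indices",
    "standardized_solution",
    "two_step_fit",
    "FIT_THRESHOLDS",
]

#: Conventional acceptable-fit cutoffs used by the two-step report.
FIT_THRESHOLDS = {"cfi": 0.95, "tli": 0.95, "rmsea": 0.08, "srmr": 0.10}


class IdentificationError(ValueError):
    """Model not identified (e.g. more parameters than moments)."""


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class MimicSpec:
    """Declarative MIMIC/CFA model specification.

    ``structural=False`` drops the predictors (step 1 of the two-step
    procedure, a plain CFA of the indicators).
    """

    indicators: tuple[str, ...]
    predictors: tuple[str, ...] = ()
    latent: str = "GA"
    residual_cov_pairs: tuple[tuple[str, str], ...] = ()
    identification: str = "first_loading"  # or "latent_variance"
    structural: bool = True

    def __post_init__(self) -> None:
        if len(self.indicators) < 2:
            raise ValueError("at least two indicators required")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("duplicate indicator names")
        if self.identification not in ("first_loading", "latent_variance"):
            raise ValueError(f"unknown identification {self.identification!r}")
        seen = set()
        for a, b in self.residual_cov_pairs:
            if a not in self.indicators or b not in self.indicators or a == b:
                raise ValueError(f"invalid residual covariance pair ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate residual covariance pair ({a}, {b})")
            seen.add(key)
        if self.structural and not self.predictors:
            object.__setattr__(self, "structural", False)

    # -- bookkeeping ---------------------------------------------------

    @property
    def observed(self) -> tuple[str, ...]:
        return self.indicators + (self.predictors if self.structural else ())

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors) if self.structural else 0

    def cfa(self) -> "MimicSpec":
        """The measurement-only (CFA) version of this spec."""
        return replace(self, structural=False)

    def free_loading_names(self) -> list[str]:
        if self.identification == "first_loading":
            return [f"lambda[{name}]" for name in self.indicators[1:]]
        return [f"lambda[{name}]" for name in self.indicators]

    def param_names(self) -> list[str]:
        """Ordered names of the free parameters (excluding Phi)."""
        names = self.free_loading_names()
        if self.identification == "first_loading":
            names.append("psi")
        if self.structural:
            names += [f"gamma[{name}]" for name in self.predictors]
        names += [f"theta[{name},{name}]" for name in self.indicators]
        names += [f"theta[{a},{b}]" for a, b in self.residual_cov_pairs]
        return names

    def n_free(self) -> int:
        return len(self.param_names())


def default_mimic_spec(structural: bool = True) -> MimicSpec:
    """The 11-indicator global-asymmetry model with its four adjacent
    residual covariances and SES/age/sex predictors."""
    from .synthetic import DEFAULT_INDICATORS, DEFAULT_RESIDUAL_PAIRS

    return MimicSpec(
        indicators=DEFAULT_INDICATORS,
        predictors=("ses", "age", "sex"),
        residual_cov_pairs=DEFAULT_RESIDUAL_PAIRS,
        structural=structural,
    )


def spec_for_indicators(
    indicators: tuple[str, ...], predictors: tuple[str, ...] = ("ses", "age", "sex")
) -> MimicSpec:
    """Build the standard model structure for an arbitrary slice set.

    Expects the profile ordering (diagonal, 5 axial, 5 coronal) and
    frees the same positional residual covariances as the default model:
    the three upper adjacent coronal pairs and the first axial pair.
    """
    if len(indicators) != 11:
        raise ValueError("expected 11 indicators (1 diagonal + 5 axial + 5 coronal)")
    ax, co = indicators[1:6], indicators[6:11]
    pairs = ((co[1], co[2]), (co[2], co[3]), (co[3], co[4]), (ax[0], ax[1]))
    return MimicSpec(indicators=tuple(indicators), predictors=tuple(predictors),
                     residual_cov_pairs=pairs)


# ---------------------------------------------------------------------------
# sample moments


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance matrix (divisor n-1) with variable names."""

    cov: np.ndarray
    names: list[str]
    n: int

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1] or cov.shape[0] != len(self.names):
            raise ValueError("cov must be square and match the names")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        object.__setattr__(self, "cov", (cov + cov.T) / 2.0)
        if self.n <= len(self.names):
            raise ValueError(f"n = {self.n} too small for p = {len(self.names)} variables")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns: list[str] | None = None) -> "SampleMoments":
        """Moments from a subject table; rows with missing values are
        dropped listwise."""
        cols = list(columns) if columns is not None else [
            c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        ]
        data = df[cols].dropna()
        return cls(cov=data.cov().to_numpy(), names=cols, n=len(data))

    def subset(self, names: list[str]) -> "SampleMoments":
        idx = [self.names.index(v) for v in names]
        return SampleMoments(cov=self.cov[np.ix_(idx, idx)], names=list(names), n=self.n)


# ---------------------------------------------------------------------------
# implied covariance and derivatives


def _unpack(spec: MimicSpec, theta: np.ndarray):
    k, m = spec.n_indicators, spec.n_predictors
    pos = 0
    lam = np.ones(k)
    if spec.identification == "first_loading":
        lam[1:] = theta[pos : pos + k - 1]
        pos += k - 1
        psi = theta[pos]
        pos += 1
    else:
        lam = theta[pos : pos + k].copy()
        pos += k
        psi = 1.0
    gamma = theta[pos : pos + m].copy()
    pos += m
    th_d = theta[pos : pos + k]
    pos += k
    th_o = theta[pos:]
    return lam, psi, gamma, th_d, th_o


def _theta_matrix(spec: MimicSpec, th_d: np.ndarray, th_o: np.ndarray) -> np.ndarray:
    k = spec.n_indicators
    idx = {name: i for i, name in enumerate(spec.indicators)}
    theta_mat = np.diag(th_d)
    for (a, b), val in zip(spec.residual_cov_pairs, th_o):
        i, j = idx[a], idx[b]
        theta_mat[i, j] = theta_mat[j, i] = val
    return theta_mat


def model_implied_covariance(
    spec: MimicSpec, theta: np.ndarray, phi: np.ndarray | None = None
) -> np.ndarray:
    """Sigma(theta) over the modeled observed variables.

    ``phi`` is the (fixed) predictor covariance block; required when the
    structural part is on.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free(),):
        raise ValueError(
            f"theta has {theta.shape} entries, spec requires {spec.n_free()}"
        )
    lam, psi, gamma, th_d, th_o = _unpack(spec, theta)
    theta_mat = _theta_matrix(spec, th_d, th_o)
    k, m = spec.n_indicators, spec.n_predictors
    if not spec.structural:
        return psi * np.outer(lam, lam) + theta_mat
    if phi is None or np.shape(phi) != (m, m):
        raise ValueError("structural model requires the predictor covariance block phi")
    phi = np.asarray(phi, dtype=float)
    u = phi @ gamma
    var_eta = float(gamma @ u + psi)
    sigma = np.empty((k + m, k + m))
    sigma[:k, :k] = var_eta * np.outer(lam, lam) + theta_mat
    sigma[:k, k:] = np.outer(lam, u)
    sigma[k:, :k] = sigma[:k, k:].T
    sigma[k:, k:] = phi
    return sigma


def _sigma_and_derivs(spec: MimicSpec, theta: np.ndarray, phi: np.ndarray | None):
    """Sigma(theta) and the stack dSigma/dtheta_q, analytic."""
    lam, psi, gamma, th_d, th_o = _unpack(spec, theta)
    k, m = spec.n_indicators, spec.n_predictors
    p = k + m
    idx = {name: i for i, name in enumerate(spec.indicators)}
    theta_mat = _theta_matrix(spec, th_d, th_o)

    if spec.structural:
        phi = np.asarray(phi, dtype=float)
        u = phi @ gamma
        var_eta = float(gamma @ u + psi)
    else:
        u = np.zeros(0)
        var_eta = psi

    sigma = np.zeros((p, p))
    sigma[:k, :k] = var_eta * np.outer(lam, lam) + theta_mat
    if spec.structural:
        sigma[:k, k:] = np.outer(lam, u)
        sigma[k:, :k] = sigma[:k, k:].T
        sigma[k:, k:] = phi

    q = spec.n_free()
    dsig = np.zeros((q, p, p))
    pos = 0
    free_load_idx = range(1, k) if spec.identification == "first_loading" else range(k)
    for j in free_load_idx:
        d = dsig[pos]
        d[:k, j] += var_eta * lam
        d[j, :k] += var_eta * lam
        if spec.structural:
            d[j, k:] += u
            d[k:, j] += u
        pos += 1
    if spec.identification == "first_loading":
        dsig[pos][:k, :k] = np.outer(lam, lam)  # psi
        pos += 1
    if spec.structural:
        for mm in range(m):
            d = dsig[pos]
            d[:k, :k] = 2.0 * u[mm] * np.outer(lam, lam)
            d[:k, k:] += np.outer(lam, phi[mm, :])
            d[k:, :k] += np.outer(phi[mm, :], lam)
            pos += 1
    for j in range(k):
        dsig[pos][j, j] = 1.0
        pos += 1
    for a, b in spec.residual_cov_pairs:
        i, j = idx[a], idx[b]
        dsig[pos][i, j] = dsig[pos][j, i] = 1.0
        pos += 1
    return sigma, dsig


def degrees_of_freedom(spec: MimicSpec, p: int | None = None) -> int:
    """Model degrees of freedom under the saturated-exogenous convention.

    Counted parameters: free loadings, latent (disturbance) variance if
    free, structural paths, indicator residual variances and
    covariances, plus the m(m+1)/2 exogenous moments that are fitted
    exactly at their sample values.
    """
    p = p if p is not None else len(spec.observed)
    m = spec.n_predictors
    n_params = spec.n_free() + m * (m + 1) // 2
    df = p * (p + 1) // 2 - n_params
    if df < 0:
        raise IdentificationError(
            f"over-parameterized model: {n_params} parameters for "
            f"{p * (p + 1) // 2} sample moments"
        )
    return df


# ---------------------------------------------------------------------------
# estimation


@dataclass(frozen=True)
class SemFit:
    """A fitted covariance-structure model."""

    spec: MimicSpec
    moments: SampleMoments = field(repr=False)
    param_names: list[str] = field(repr=False)
    theta: np.ndarray = field(repr=False)
    se: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    phi: np.ndarray | None = field(repr=False)
    fmin: float
    chisq: float
    df: int
    pvalue: float
    converged: bool
    n_iter: int
    heywood: bool

    @property
    def n(self) -> int:
        return self.moments.n

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.theta.tolist()))

    @property
    def standard_errors(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.se.tolist()))

    def wald_z(self) -> dict[str, float]:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.theta / self.se
        return dict(zip(self.param_names, z.tolist()))

    def parameter_table(self) -> pd.DataFrame:
        z = np.array(list(self.wald_z().values()))
        pvals = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"parameter": self.param_names, "estimate": self.theta,
             "se": self.se, "z": z, "pvalue": pvals}
        )


def _start_values(spec: MimicSpec, s_yy: np.ndarray) -> np.ndarray:
    """First-principal-axis loadings, residuals at half the variances."""
    k = spec.n_indicators
    evals, evecs = np.linalg.eigh(s_yy)
    a = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-8))
    if a.sum() < 0:  # orient the principal axis positively
        a = -a
    theta0 = []
    if spec.identification == "first_loading":
        a0 = a[0] if abs(a[0]) > 1e-6 * np.abs(a).mean() else np.sqrt(s_yy[0, 0] / 2)
        theta0 += list(a[1:] / a0)
        theta0.append(max(a0**2, 1e-3 * s_yy[0, 0]))  # psi (total latent var at start)
    else:
        theta0 += list(a)
    theta0 += [0.0] * spec.n_predictors
    theta0 += list(np.maximum(0.5 * np.diag(s_yy), 1e-6))
    theta0 += [0.0] * len(spec.residual_cov_pairs)
    return np.asarray(theta0)


def _discrepancy_factory(spec: MimicSpec, s: np.ndarray, phi: np.ndarray | None):
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    def fobj(theta: np.ndarray):
        sigma, dsig = _sigma_and_derivs(spec, theta, phi)
        try:
            cf = linalg.cho_factor(sigma, check_finite=False)
        except linalg.LinAlgError:
            return 1e12, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sigma_inv = linalg.cho_solve(cf, np.eye(p), check_finite=False)
        f = logdet - logdet_s + float(np.sum(sigma_inv * s)) - p
        grad_mat = sigma_inv - sigma_inv @ s @ sigma_inv
        grad = np.einsum("ij,qij->q", grad_mat, dsig)
        return f, grad

    return fobj


def _information(spec: MimicSpec, theta: np.ndarray, phi: np.ndarray | None) -> np.ndarray:
    """Expected information of F: H_ab = tr(Si dS_a Si dS_b)."""
    sigma, dsig = _sigma_and_derivs(spec, theta, phi)
    sigma_inv = np.linalg.inv(sigma)
    w = np.einsum("ij,qjk->qik", sigma_inv, dsig)
    return np.einsum("qij,rji->qr", w, w)


def _param_scales(spec: MimicSpec, d: np.ndarray) -> np.ndarray:
    """Per-parameter factors mapping standardized-scale estimates back
    to the original variable scales (each free parameter rescales by a
    constant under diagonal rescaling of the observed variables)."""
    k = spec.n_indicators
    d_y, d_x = d[:k], d[k:]
    scales: list[float] = []
    if spec.identification == "first_loading":
        scales += list(d_y[1:] / d_y[0])          # loadings relative to marker
        scales.append(d_y[0] ** 2)                # psi carries the marker scale
        eta_scale = d_y[0]
    else:
        scales += list(d_y)                       # latent variance fixed: free loadings
        eta_scale = 1.0
    if spec.structural:
        scales += list(eta_scale / d_x)
    scales += list(d_y**2)                        # residual variances
    idx = {name: i for i, name in enumerate(spec.indicators)}
    scales += [d_y[idx[a]] * d_y[idx[b]] for a, b in spec.residual_cov_pairs]
    return np.asarray(scales)


def fit_ml(
    spec: MimicSpec,
    moments: SampleMoments,
    start: np.ndarray | None = None,
    max_iter: int = 500,
) -> SemFit:
    """Maximum-likelihood fit of a MIMIC/CFA spec to sample moments.

    The exogenous predictor block is fixed at its sample values; the
    remaining parameters are optimized by L-BFGS with analytic
    gradients, then polished by Fisher scoring.  For numerical
    conditioning the optimization runs on sd-standardized moments (the
    discrepancy is invariant to that rescaling and every parameter maps
    back by a fixed factor).  Standard errors come from the inverse
    expected information, ``acov = 2 H^-1 / (n - 1)``.  Non-convergence
    and Heywood cases (negative variance estimates) are flagged on the
    returned fit, never silently ignored.
    """
    obs = list(spec.observed)
    mom = moments.subset(obs) if moments.names != obs else moments
    k, m = spec.n_indicators, spec.n_predictors
    degrees_of_freedom(spec)  # raises if over-parameterized

    d = np.sqrt(np.diag(mom.cov))
    if (d <= 0).any():
        bad = [obs[i] for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"zero sample variance for {bad}")
    scales = _param_scales(spec, d)
    s = mom.cov / np.outer(d, d)
    phi = s[k:, k:].copy() if spec.structural else None

    fobj = _discrepancy_factory(spec, s, phi)
    theta = (
        np.asarray(start, dtype=float) / scales
        if start is not None
        else _start_values(spec, s[:k, :k])
    )
    res = optimize.minimize(
        fobj, theta, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    theta = res.x
    n_iter = int(res.nit)

    # Fisher-scoring polish: quadratic convergence near the optimum
    f, grad = fobj(theta)
    for _ in range(50):
        if np.max(np.abs(grad)) < 1e-11:
            break
        h = _information(spec, theta, phi)
        try:
            step = np.linalg.solve(h + 1e-12 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = theta - damp * step
            f_new, g_new = fobj(cand)
            if f_new <= f + 1e-14:
                theta, f, grad = cand, f_new, g_new
                improved = True
                break
        n_iter += 1
        if not improved:
            break
    converged = bool(np.max(np.abs(grad)) < 1e-6)

    h = _information(spec, theta, phi)
    try:
        acov = 2.0 * np.linalg.inv(h) / (mom.n - 1)
        se = np.sqrt(np.clip(np.diag(acov), 0.0, None))
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; standard errors unavailable")
        se = np.full_like(theta, np.nan)

    lam, psi, gamma, th_d, th_o = _unpack(spec, theta)
    heywood = bool((th_d < 0).any() or psi < 0)
    if heywood:
        warnings.warn("Heywood case: negative variance estimate in the solution")
    if not converged:
        warnings.warn(
            f"ML fit did not converge (max |gradient| = {np.max(np.abs(grad)):.2e})"
        )

    df = degrees_of_freedom(spec)
    chisq = max((mom.n - 1) * f, 0.0)
    pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
    # map the standardized-scale solution back to the original scales
    theta_orig = theta * scales
    se_orig = se * scales
    phi_orig = mom.cov[k:, k:].copy() if spec.structural else None
    sigma = model_implied_covariance(spec, theta_orig, phi_orig)
    return SemFit(
        spec=spec, moments=mom, param_names=spec.param_names(), theta=theta_orig,
        se=se_orig, sigma=sigma, phi=phi_orig, fmin=float(max(f, 0.0)),
        chisq=float(chisq), df=df, pvalue=pvalue, converged=converged,
        n_iter=n_iter, heywood=heywood,
    )


def fit_baseline(spec: MimicSpec, moments: SampleMoments) -> tuple[float, int]:
    """Independence baseline: (chi-square, df), closed form.

    Indicators mutually independent and independent of the predictors;
    the exogenous block stays exactly fitted (consistent with the main
    model's convention).
    """
    obs = list(spec.observed)
    mom = moments.subset(obs) if moments.names != obs else moments
    s = mom.cov
    k, m = spec.n_indicators, spec.n_predictors
    p = k + m
    _, logdet_s = np.linalg.slogdet(s)
    logdet_b = float(np.sum(np.log(np.diag(s)[:k])))
    if m:
        _, logdet_xx = np.linalg.slogdet(s[k:, k:])
        logdet_b += logdet_xx
    f_b = logdet_b - logdet_s  # trace term equals p exactly
    df_b = p * (p + 1) // 2 - (k + m * (m + 1) // 2)
    return max((mom.n - 1) * f_b, 0.0), df_b


@dataclass(frozen=True)
class FitIndices:
    chisq: float
    df: int
    pvalue: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    p_rmsea_le_05: float
    srmr: float

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("chisq", "df", "pvalue", "cfi", "tli", "rmsea", "p_rmsea_le_05", "srmr")}
        d["rmsea_ci90_lo"], d["rmsea_ci90_hi"] = self.rmsea_ci90
        return d


def rmsea(chisq: float, df: int, n: int) -> float:
    """Root mean square error of approximation,
    ``sqrt(max(T - df, 0) / (df (n - 1)))``."""
    if df <= 0:
        return float("nan")
    return float(np.sqrt(max(chisq - df, 0.0) / (df * (n - 1))))


def _rmsea_ci(t: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Invert the noncentral chi-square in its noncentrality parameter."""
    if df <= 0:
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0

    def ncp_for(prob: float) -> float:
        # find ncp with P(Chi2_df(ncp) <= t) = prob; cdf decreases in ncp
        if stats.chi2.cdf(t, df) < prob:  # even ncp=0 gives too little mass
            return 0.0
        lo, hi = 0.0, max(4.0 * t, 10.0)
        while stats.ncx2.cdf(t, df, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(
            lambda nc: stats.ncx2.cdf(t, df, nc) - prob, lo, hi, xtol=1e-8))

    ncp_lo = ncp_for(1.0 - alpha)
    ncp_hi = ncp_for(alpha)
    denom = df * (n - 1)
    return (float(np.sqrt(ncp_lo / denom)), float(np.sqrt(ncp_hi / denom)))


def _srmr(s: np.ndarray, sigma: np.ndarray) -> float:
    sd = np.sqrt(np.diag(s))
    resid = (s - sigma) / np.outer(sd, sd)
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def fit_indices(fit: SemFit, baseline: tuple[float, int] | None = None) -> FitIndices:
    """Chi-square-based fit indices for a fitted model.

    ``baseline`` is (T_b, df_b) of the independence model; computed in
    closed form from the same moments when omitted.
    """
    t, df, n = fit.chisq, fit.df, fit.n
    t_b, df_b = baseline if baseline is not None else fit_baseline(fit.spec, fit.moments)

    excess = max(t - df, 0.0)
    denom_cfi = max(t_b - df_b, t - df, 0.0)
    cfi = 1.0 - (excess / denom_cfi if denom_cfi > 0 else 0.0)
    if df > 0 and df_b > 0 and t_b / df_b != 1.0:
        tli = ((t_b / df_b) - (t / df)) / ((t_b / df_b) - 1.0)
    else:
        tli = float("nan")
    if df > 0:
        rmsea_val = rmsea(t, df, n)
        ci = _rmsea_ci(t, df, n)
        ncp_close = 0.05**2 * df * (n - 1)
        p_close = float(stats.ncx2.sf(t, df, ncp_close))
    else:
        rmsea_val, ci, p_close = float("nan"), (float("nan"), float("nan")), float("nan")
    srmr = _srmr(fit.moments.cov, fit.sigma)
    pvalue = float(stats.chi2.sf(t, df)) if df > 0 else 1.0
    return FitIndices(chisq=t, df=df, pvalue=pvalue, cfi=float(cfi), tli=float(tli),
                      rmsea=rmsea_val, rmsea_ci90=ci, p_rmsea_le_05=p_close, srmr=srmr)


# ---------------------------------------------------------------------------
# modification indices


@dataclass(frozen=True)
class ModificationIndexEntry:
    parameter: str
    lhs: str
    rhs: str
    mi: float
    epc: float


def modification_indices(fit: SemFit) -> list[ModificationIndexEntry]:
    """Univariate score-test (Lagrange multiplier) modification indices.

    One entry per indicator residual covariance fixed at zero; the MI
    approximates the chi-square drop from freeing that parameter alone,
    and ``epc`` is the expected value it would take.  Entries whose
    information is numerically singular are flagged with NaN rather than
    fabricated.
    """
    spec = fit.spec
    k = spec.n_indicators
    p = fit.sigma.shape[0]
    freed = {frozenset(pair) for pair in spec.residual_cov_pairs}
    # standardized scale for conditioning; MI values are scale-invariant
    d = np.sqrt(np.diag(fit.moments.cov))
    theta_std = fit.theta / _param_scales(spec, d)
    s = fit.moments.cov / np.outer(d, d)
    phi_std = s[k:, k:] if spec.structural else None
    sigma, dsig = _sigma_and_derivs(spec, theta_std, phi_std)
    sigma_inv = np.linalg.inv(sigma)
    grad_mat = sigma_inv - sigma_inv @ s @ sigma_inv
    h_ff = _information(spec, theta_std, phi_std)
    try:
        h_ff_inv = np.linalg.inv(h_ff)
    except np.linalg.LinAlgError:
        h_ff_inv = None

    entries = []
    n1 = fit.n - 1
    for i in range(k):
        for j in range(i + 1, k):
            if frozenset((spec.indicators[i], spec.indicators[j])) in freed:
                continue
            cand = np.zeros((p, p))
            cand[i, j] = cand[j, i] = 1.0
            g_k = float(np.sum(grad_mat * cand))
            w = sigma_inv @ cand
            h_kk = float(np.sum(w * w.T))  # tr(Si cand Si cand)
            h_kf = np.einsum("ij,qji->q", w @ sigma_inv, dsig)
            if h_ff_inv is None:
                mi = epc = float("nan")
            else:
                schur = h_kk - h_kf @ h_ff_inv @ h_kf
                if schur <= 1e-12:
                    mi = epc = float("nan")
                else:
                    mi = 0.5 * n1 * g_k**2 / schur
                    epc = -g_k / schur * d[i] * d[j]  # back to original scale
            entries.append(ModificationIndexEntry(
                parameter=f"theta[{spec.indicators[i]},{spec.indicators[j]}]",
                lhs=spec.indicators[i], rhs=spec.indicators[j],
                mi=float(mi), epc=float(epc)))
    entries.sort(key=lambda e: (-(e.mi if np.isfinite(e.mi) else -np.inf), e.parameter))
    return entries


# ---------------------------------------------------------------------------
# standardized solution


def standardized_solution(fit: SemFit) -> dict[str, dict[str, float]]:
    """Estimates rescaled to the correlation metric.

    Loadings become indicator-factor correlations, structural paths are
    multiplied by sd(x)/sd(eta), residual covariances become residual
    correlations.  The result is invariant to the identification
    constraint.  Heywood cases make the rescaling unreliable; affected
    rows get NaN.
    """
    spec = fit.spec
    lam, psi, gamma, th_d, th_o = _unpack(spec, fit.theta)
    k = spec.n_indicators
    if spec.structural:
        u = fit.phi @ gamma
        var_eta = float(gamma @ u + psi)
    else:
        var_eta = psi
    sd_eta = np.sqrt(var_eta) if var_eta > 0 else np.nan
    sd_y = np.sqrt(np.clip(np.diag(fit.sigma)[:k], 0.0, None))
    out: dict[str, dict[str, float]] = {
        "loadings": {
            name: float(l * sd_eta / sy) if sy > 0 else float("nan")
            for name, l, sy in zip(spec.indicators, lam, sd_y)
        }
    }
    if spec.structural:
        sd_x = np.sqrt(np.diag(fit.phi))
        out["paths"] = {
            name: float(g * sx / sd_eta)
            for name, g, sx in zip(spec.predictors, gamma, sd_x)
        }
    idx = {name: i for i, name in enumerate(spec.indicators)}
    out["residual_correlations"] = {}
    for (a, b), val in zip(spec.residual_cov_pairs, th_o):
        i, j = idx[a], idx[b]
        denom = np.sqrt(th_d[i] * th_d[j]) if th_d[i] > 0 and th_d[j] > 0 else np.nan
        out["residual_correlations"][f"{a}~~{b}"] = float(val / denom)
    return out


# ---------------------------------------------------------------------------
# two-step procedure


@dataclass(frozen=True)
class TwoStepResult:
    cfa_fit: SemFit
    cfa_indices: FitIndices
    cfa_pass: dict[str, bool]
    structural_fit: SemFit
    structural_indices: FitIndices
    structural_pass: dict[str, bool]

    @property
    def measurement_model_acceptable(self) -> bool:
        return all(self.cfa_pass.values())


def _threshold_report(ix: FitIndices) -> dict[str, bool]:
    return {
        "cfi": ix.cfi >= FIT_THRESHOLDS["cfi"],
        "tli": ix.tli >= FIT_THRESHOLDS["tli"],
        "rmsea": ix.rmsea <= FIT_THRESHOLDS["rmsea"],
        "srmr": ix.srmr <= FIT_THRESHOLDS["srmr"],
    }


def two_step_fit(spec: MimicSpec, moments: SampleMoments) -> TwoStepResult:
    """Measurement-first model evaluation.

    Step 1 fits the CFA (measurement model only) and checks it against
    the conventional cutoffs (CFI/TLI >= 0.95, RMSEA <= 0.08,
    SRMR <= 0.1); step 2 fits the full MIMIC model.  Step 2 runs even if
    step 1 fails its thresholds — with a warning — so a failing pipeline
    stays inspectable.
    """
    cfa_spec = spec.cfa()
    cfa_fit_ = fit_ml(cfa_spec, moments.subset(list(cfa_spec.indicators)))
    cfa_ix = fit_indices(cfa_fit_)
    cfa_pass = _threshold_report(cfa_ix)
    if not all(cfa_pass.values()):
        failed = [name for name, ok in cfa_pass.items() if not ok]
        warnings.warn(
            "measurement model fails acceptability thresholds "
            f"({', '.join(failed)}); proceeding to the structural model anyway"
        )
    full_fit = fit_ml(spec, moments)
    full_ix = fit_indices(full_fit)
    return TwoStepResult(
        cfa_fit=cfa_fit_, cfa_indices=cfa_ix, cfa_pass=cfa_pass,
        structural_fit=full_fit, structural_indices=full_ix,
        structural_pass=_threshold_report(full_ix),
    )
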