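"""Synthetic data: brain-like 2D/3D phantoms and latent-model cohorts.

Two generators make the whole pipeline testable without any imaging
download:

* ``make_phantom`` / ``make_phantom_volume`` build mirror-symmetric
  elliptical "brain" slices with optional one-sided blobs (controlled
  asymmetry amplitude), known axis tilt and centroid offset, and MRI-like
  noise (Gaussian, salt-and-pepper, speckle).
* ``simulate_cohort`` draws subject tables from the global-asymmetry
  MIMIC model: a latent factor regressed on SES, age and sex, measured
  by eleven slice indicators.  Defaults are the standardized loadings
  (0.64-0.87) and paths (SES -0.22, age 0.57, sex 0.40) of the study
  this package reimplements, with the study's sample composition
  (SES categories 25.8/34.8/22/17.4%, 28% male, age ~ N(69, 12) truncated
  to [33, 94]).

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .symmetry import integer_shift, mirror, rotate

__all__ = [
    "PhantomParams",
    "make_phantom",
    "make_phantom_volume",
    "CohortParams",
    "simulate_cohort",
    "population_moments",
    "DEFAULT_INDICATORS",
    "DEFAULT_LOADINGS",
    "DEFAULT_PATHS",
    "DEFAULT_RESIDUAL_PAIRS",
]

# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomParams:
    """Construction recipe for a 2D brain-like phantom.

    With ``asymmetry_amplitude = 0``, ``true_angle_deg = 0``,
    ``true_offset_px = (0, 0)`` and no noise, the emitted image is
    exactly mirror-symmetric about its central vertical axis.

    ``noise`` is ``None`` or ``(kind, level)`` with kind in
    ``{"gaussian", "salt_pepper", "speckle"}``; for Gaussian noise the
    level is the standard deviation as a fraction of the dynamic range,
    for salt-and-pepper the corrupted-pixel fraction, for speckle the
    multiplicative noise standard deviation.
    """

    height: int = 176
    width: int = 208
    base_intensity: float = 180.0
    #: (row, col) semi-axes; None scales the default 176x208 geometry
    ellipse_semi_axes: tuple[float, float] | None = None
    asymmetry_amplitude: float = 0.0
    #: (drow, dcol) of the one-sided blob from the canvas center;
    #: None places it in the upper-right quadrant, scaled to the canvas
    asymmetry_pos: tuple[float, float] | None = None
    asymmetry_sigma: float | None = None

    def resolved_geometry(self) -> tuple[tuple[float, float], tuple[float, float], float]:
        axes = self.ellipse_semi_axes or (0.41 * self.height, 0.30 * self.width)
        pos = self.asymmetry_pos or (-0.16 * self.height, 0.16 * self.width)
        sigma = self.asymmetry_sigma or 0.051 * self.height
        return axes, pos, sigma
    true_angle_deg: float = 0.0
    true_offset_px: tuple[int, int] = (0, 0)
    noise: tuple[str, float] | None = None
    seed: int = 0


def _symmetric_base(p: PhantomParams) -> np.ndarray:
    """Mirror-exact base: components depend on |col - center| only."""
    rows = np.arange(p.height, dtype=float)[:, None]
    cols = np.arange(p.width, dtype=float)[None, :]
    rc, cc = (p.height - 1) / 2.0, (p.width - 1) / 2.0
    dr = rows - rc
    dc_abs = np.abs(cols - cc)

    (a, b), _, _ = p.resolved_geometry()
    r2 = (dr / a) ** 2 + (dc_abs / b) ** 2
    img = np.where(r2 <= 1.0, p.base_intensity, 0.0)
    # inner ellipse: brighter "tissue" core
    img += np.where((dr / (0.72 * a)) ** 2 + (dc_abs / (0.72 * b)) ** 2 <= 1.0, 30.0, 0.0)
    # mirrored ventricle-like dark blobs, one per hemisphere
    for sr, scol, amp, sig in [(-0.14 * a, 0.26 * b, -70.0, 0.16 * b),
                               (0.31 * a, 0.39 * b, -40.0, 0.13 * b)]:
        img += amp * np.exp(-(((dr - sr) ** 2) + (dc_abs - scol) ** 2) / (2 * sig**2))
    return np.clip(img, 0.0, None)


def make_phantom(params: PhantomParams) -> tuple[np.ndarray, dict]:
    """Build a phantom image plus its ground-truth record.

    Construction order: symmetric base -> one-sided Gaussian blob at the
    stated amplitude -> rotation by ``true_angle_deg`` about the canvas
    center -> integer translation by ``true_offset_px`` -> noise.
    Identical parameters and seed give bit-identical images.
    """
    p = params
    _, pos, sigma = p.resolved_geometry()
    rc, cc = (p.height - 1) / 2.0, (p.width - 1) / 2.0
    br, bc = rc + pos[0], cc + pos[1]
    if not (0 <= br < p.height and 0 <= bc < p.width):
        raise ValueError(f"asymmetric blob center ({br}, {bc}) outside canvas")
    img = _symmetric_base(p)
    if p.asymmetry_amplitude:
        rows = np.arange(p.height, dtype=float)[:, None]
        cols = np.arange(p.width, dtype=float)[None, :]
        img += p.asymmetry_amplitude * np.exp(
            -(((rows - br) ** 2) + (cols - bc) ** 2) / (2 * sigma**2)
        )
    if p.true_angle_deg:
        img = rotate(img, p.true_angle_deg)
    if p.true_offset_px != (0, 0):
        img = integer_shift(img, *p.true_offset_px)
    if p.noise is not None:
        img = _apply_noise(img, p.noise, np.random.default_rng(p.seed))
    truth = {
        "angle_deg": p.true_angle_deg,
        "offset_px": tuple(p.true_offset_px),
        "amplitude": p.asymmetry_amplitude,
        "axis_point": (cc + p.true_offset_px[0], rc + p.true_offset_px[1]),
    }
    return img, truth


def _apply_noise(img: np.ndarray, noise: tuple[str, float], rng: np.random.Generator) -> np.ndarray:
    kind, level = noise
    drange = float(img.max() - img.min())
    if kind == "gaussian":
        out = img + rng.normal(0.0, level * drange, img.shape)
    elif kind == "salt_pepper":
        out = img.copy()
        corrupt = rng.random(img.shape) < level
        salt = rng.random(img.shape) < 0.5
        out[corrupt & salt] = img.max()
        out[corrupt & ~salt] = 0.0
    elif kind == "speckle":
        out = img * (1.0 + rng.normal(0.0, level, img.shape))
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    return np.clip(out, 0.0, None)


def make_phantom_volume(
    slice_params: dict[int, PhantomParams],
    shape: tuple[int, int, int] = (176, 208, 176),
    default: PhantomParams | None = None,
) -> tuple[np.ndarray, dict[int, dict]]:
    """Stack 2D phantoms into a 3D volume along the third (axial) axis.

    ``slice_params`` maps axial indices to phantom recipes; remaining
    slices use ``default`` (a plain symmetric phantom when omitted).
    The volume follows the anatomical storage convention (left-right
    axis first), so a phantom for a ``(d0, d1, d2)`` volume must have
    ``height = d1`` and ``width = d0`` and is stored transposed:
    ``vol[:, :, k] = phantom.T``.  The profiling stage transposes each
    extracted slice back, recovering the phantom with its symmetry axis
    along image columns.
    """
    d0, d1, d2 = shape
    default = default or PhantomParams(height=d1, width=d0)
    for k, p in slice_params.items():
        if not 0 <= k < d2:
            raise ValueError(f"axial index {k} outside volume depth {d2}")
        if (p.height, p.width) != (d1, d0):
            raise ValueError(
                f"slice {k} phantom shape {(p.height, p.width)} != expected {(d1, d0)}"
            )
    if (default.height, default.width) != (d1, d0):
        raise ValueError("default phantom shape does not match volume slice shape")
    # unspecified slices share one default phantom image
    default_img, _ = make_phantom(default)
    truths: dict[int, dict] = {}
    vol = np.empty(shape, dtype=float)
    for k in range(d2):
        if k in slice_params:
            img, truths[k] = make_phantom(slice_params[k])
        else:
            img = default_img
        vol[:, :, k] = img.T
    return vol, truths


# ---------------------------------------------------------------------------
# cohorts

DEFAULT_INDICATORS: tuple[str, ...] = (
    "dg", "a68", "a78", "a88", "a98", "a108",
    "c84", "c94", "c104", "c114", "c124",
)
#: Standardized factor loadings of the eleven slice indicators.
DEFAULT_LOADINGS: tuple[float, ...] = (
    0.79, 0.82, 0.85, 0.87, 0.68, 0.72, 0.84, 0.81, 0.69, 0.78, 0.64,
)
#: Standardized structural paths (SES, age, sex) onto the latent factor.
DEFAULT_PATHS: tuple[float, float, float] = (-0.22, 0.57, 0.40)
#: Residual covariances between spatially adjacent slices.
DEFAULT_RESIDUAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("c94", "c104"), ("c104", "c114"), ("c114", "c124"), ("a68", "a78"),
)

_SES_LEVELS = (1, 2, 3, 4)
_SES_PROBS = (0.258, 0.348, 0.22, 0.174)
_SEX_P_MALE = 0.28
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 69.0, 12.0, 33.0, 94.0


@dataclass(frozen=True)
class CohortParams:
    """Generating values for a MIMIC-model cohort, standardized metric.

    ``loadings`` and ``paths`` are the standardized generating values;
    indicators and the latent factor have unit population variance, and
    the raw predictor draws (SES category, age in years, sex 0/1) enter
    the structural part after standardization by their population
    moments.  ``residual_corr`` is the residual correlation assigned to
    each ``residual_pairs`` entry (the study reports that adjacent-slice
    residuals covary but not by how much; 0.3 is a moderate default).
    """

    n_subjects: int = 132
    loadings: tuple[float, ...] = DEFAULT_LOADINGS
    paths: tuple[float, float, float] = DEFAULT_PATHS
    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    predictors: tuple[str, ...] = ("ses", "age", "sex")
    residual_pairs: tuple[tuple[str, str], ...] = DEFAULT_RESIDUAL_PAIRS
    residual_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.loadings) != len(self.indicators):
            raise ValueError("one loading per indicator required")
        if any(not 0 < abs(l) < 1 for l in self.loadings):
            raise ValueError("standardized loadings must lie in (0, 1) in magnitude")
        psi = self.disturbance_variance()
        if psi <= 0:
            raise ValueError(
                f"path coefficients imply non-positive latent disturbance variance {psi:.3f}"
            )
        # PD check of the full implied covariance (raises if violated)
        np.linalg.cholesky(self.implied_covariance())

    def disturbance_variance(self) -> float:
        """Var of the latent residual: 1 - b'b (independent predictors)."""
        b = np.asarray(self.paths)
        return float(1.0 - b @ b)

    def residual_covariance(self) -> np.ndarray:
        """Theta: residual (co)variance matrix of the indicators."""
        lam = np.asarray(self.loadings)
        theta = np.diag(1.0 - lam**2)
        idx = {name: i for i, name in enumerate(self.indicators)}
        for a, b in self.residual_pairs:
            i, j = idx[a], idx[b]
            cov = self.residual_corr * np.sqrt(theta[i, i] * theta[j, j])
            theta[i, j] = theta[j, i] = cov
        return theta

    def predictor_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Population means and standard deviations of (ses, age, sex)."""
        ses_mean = float(np.dot(_SES_LEVELS, _SES_PROBS))
        ses_var = float(np.dot((np.asarray(_SES_LEVELS) - ses_mean) ** 2, _SES_PROBS))
        a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
        age_mean, age_var = stats.truncnorm.stats(a, b, loc=_AGE_MEAN, scale=_AGE_SD, moments="mv")
        sex_var = _SEX_P_MALE * (1 - _SEX_P_MALE)
        means = np.array([ses_mean, float(age_mean), _SEX_P_MALE])
        sds = np.sqrt([ses_var, float(age_var), sex_var])
        return means, sds

    def implied_covariance(self) -> np.ndarray:
        """Population covariance of (indicators, predictors), raw scales.

        In the standardized metric the latent factor and indicators have
        unit variance; predictors are rescaled to their raw population
        variances.  Independent predictors give a diagonal predictor
        block.
        """
        lam = np.asarray(self.loadings)[:, None]
        beta = np.asarray(self.paths)[:, None]
        _, sds = self.predictor_moments()
        k = len(self.indicators)
        m = len(self.predictors)
        sigma = np.empty((k + m, k + m))
        sigma[:k, :k] = lam @ lam.T + self.residual_covariance()
        np.fill_diagonal(sigma[:k, :k], 1.0)
        cov_yx = (lam @ beta.T) * sds[None, :]  # cov(y, x_raw), R_x = I
        sigma[:k, k:] = cov_yx
        sigma[k:, :k] = cov_yx.T
        sigma[k:, k:] = np.diag(sds**2)
        return sigma

    def raw_parameters(self) -> dict[str, float]:
        """Generating values on the fitted (marker-indicator) raw scale.

        The estimator fixes the first indicator's loading to 1, so the
        latent scale is ``lambda_1`` times the standardized factor; this
        maps the standardized generating values onto the parameters the
        fit actually estimates (for recovery/coverage studies).
        """
        lam = np.asarray(self.loadings)
        beta = np.asarray(self.paths)
        _, sds = self.predictor_moments()
        theta = self.residual_covariance()
        out: dict[str, float] = {}
        for name, l in zip(self.indicators[1:], lam[1:]):
            out[f"lambda[{name}]"] = float(l / lam[0])
        out["psi"] = float(lam[0] ** 2 * self.disturbance_variance())
        for name, b, s in zip(self.predictors, beta, sds):
            out[f"gamma[{name}]"] = float(lam[0] * b / s)
        for i, name in enumerate(self.indicators):
            out[f"theta[{name},{name}]"] = float(theta[i, i])
        idx = {name: i for i, name in enumerate(self.indicators)}
        for a, b_ in self.residual_pairs:
            out[f"theta[{a},{b_}]"] = float(theta[idx[a], idx[b_]])
        return out


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw a cohort table from the MIMIC generating model.

    Returns ``(table, generating_raw_parameters)``.  The table has one
    row per subject: ``subject_id``, the indicator columns, then the raw
    predictors (SES category 1-4, age in years, sex 0=female/1=male).
    """
    p = params
    if p.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(p.seed)
    n = p.n_subjects

    ses = rng.choice(_SES_LEVELS, size=n, p=_SES_PROBS).astype(float)
    a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
    age = stats.truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD, size=n, random_state=rng)
    sex = (rng.random(n) < _SEX_P_MALE).astype(float)

    means, sds = p.predictor_moments()
    x_raw = np.column_stack([ses, age, sex])
    z = (x_raw - means) / sds

    beta = np.asarray(p.paths)
    zeta = rng.normal(0.0, np.sqrt(p.disturbance_variance()), n)
    ga = z @ beta + zeta  # standardized latent factor

    theta = p.residual_covariance()
    eps = rng.multivariate_normal(np.zeros(len(p.indicators)), theta, size=n,
                                  method="cholesky")
    y = ga[:, None] * np.asarray(p.loadings)[None, :] + eps

    table = pd.DataFrame(y, columns=list(p.indicators))
    table.insert(0, "subject_id", [f"sub-{i:05d}" for i in range(n)])
    table["ses"], table["age"], table["sex"] = ses, age, sex
    return table, p.raw_parameters()


def population_moments(params: CohortParams, n: int = 10**6):
    """Exact implied covariance packaged as sample moments.

    For zero-discrepancy tests: fitting these moments must return the
    generating parameters with a discrepancy of zero.  ``n`` only sets
    the nominal sample size attached to the moments.
    """
    from .mimic import SampleMoments  # local import to avoid a cycle

    names = list(params.indicators) + list(params.predictors)
    return SampleMoments(cov=params.implied_covariance(), names=names, n=n)
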