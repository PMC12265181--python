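"""Independent straight-line re-implementations used as test oracles.

Everything here is deliberately naive and written from the defining
formulas, independent of the package's production code paths: explicit
padded convolution loops for GMSD, a RAM-formulation model-implied
covariance plus a generic finite-difference optimizer for the SEM, and
textbook fit-index arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# naive GMSD

_PREWITT_X = [[1 / 3, 0, -1 / 3], [1 / 3, 0, -1 / 3], [1 / 3, 0, -1 / 3]]


def naive_gmsd(img_a, img_b, c: float) -> tuple[float, float]:
    """GMSD/GMSM via explicit symmetric padding and per-pixel loops."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    g_a = _naive_gradmag(a)
    g_b = _naive_gradmag(b)
    h, w = a.shape
    gms = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            num = 2.0 * g_a[i, j] * g_b[i, j] + c
            den = g_a[i, j] ** 2 + g_b[i, j] ** 2 + c
            gms[i, j] = num / den
    gmsm = gms.sum() / gms.size
    gmsd_val = np.sqrt(((gms - gmsm) ** 2).sum() / gms.size)
    return float(gmsd_val), float(gmsm)


def _naive_gradmag(img: np.ndarray) -> np.ndarray:
    kx = np.asarray(_PREWITT_X)
    ky = kx.T
    padded = np.pad(img, 1, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 3, j : j + 3]
            # scipy's convolve flips the kernel; do the same here
            gx = float((win * kx[::-1, ::-1]).sum())
            gy = float((win * ky[::-1, ::-1]).sum())
            out[i, j] = np.hypot(gx, gy)
    return out


# ---------------------------------------------------------------------------
# RAM-formulation SEM oracle

class RamSem:
    """Single-factor MIMIC/CFA in RAM form, fit by a generic optimizer.

    Variable order: latent eta, then indicators, then predictors.
    Parameters are a name -> value mapping using the same names as the
    production estimator so results can be compared directly; the
    implied covariance, discrepancy and optimization are all
    independent (finite-difference BFGS, no analytic structure).
    """

    def __init__(self, indicators, predictors=(), residual_pairs=(),
                 identification="first_loading"):
        self.indicators = list(indicators)
        self.predictors = list(predictors)
        self.residual_pairs = [tuple(p) for p in residual_pairs]
        self.identification = identification
        self.names = self._param_names()

    def _param_names(self):
        free_loads = self.indicators[1:] if self.identification == "first_loading" \
            else self.indicators
        names = [f"lambda[{v}]" for v in free_loads]
        if self.identification == "first_loading":
            names.append("psi")
        names += [f"gamma[{v}]" for v in self.predictors]
        names += [f"theta[{v},{v}]" for v in self.indicators]
        names += [f"theta[{a},{b}]" for a, b in self.residual_pairs]
        return names

    def implied(self, values: dict, phi: np.ndarray | None) -> np.ndarray:
        k, m = len(self.indicators), len(self.predictors)
        nv = 1 + k + m  # eta, y, x
        A = np.zeros((nv, nv))
        S = np.zeros((nv, nv))
        lam = {v: values.get(f"lambda[{v}]", 1.0) for v in self.indicators}
        if self.identification == "latent_variance":
            lam = {v: values[f"lambda[{v}]"] for v in self.indicators}
        for i, v in enumerate(self.indicators):
            A[1 + i, 0] = lam[v]
        for j, v in enumerate(self.predictors):
            A[0, 1 + k + j] = values[f"gamma[{v}]"]
        S[0, 0] = values.get("psi", 1.0)
        for i, v in enumerate(self.indicators):
            S[1 + i, 1 + i] = values[f"theta[{v},{v}]"]
        for a, b in self.residual_pairs:
            i, j = self.indicators.index(a), self.indicators.index(b)
            S[1 + i, 1 + j] = S[1 + j, 1 + i] = values[f"theta[{a},{b}]"]
        if m:
            S[1 + k :, 1 + k :] = phi
        inv = np.linalg.inv(np.eye(nv) - A)
        sigma_all = inv @ S @ inv.T
        keep = list(range(1, nv))  # drop the latent row/column
        return sigma_all[np.ix_(keep, keep)]

    def discrepancy(self, vec: np.ndarray, s: np.ndarray, phi) -> float:
        values = dict(zip(self.names, vec))
        sigma = self.implied(values, phi)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        _, logdet_s = np.linalg.slogdet(s)
        return float(logdet - logdet_s + np.trace(s @ np.linalg.inv(sigma)) - s.shape[0])

    def fit(self, s: np.ndarray, start: np.ndarray):
        """Generic numerical optimization (finite-difference BFGS)."""
        k = len(self.indicators)
        phi = s[k:, k:] if self.predictors else None
        res = optimize.minimize(
            self.discrepancy, np.asarray(start, dtype=float), args=(s, phi),
            method="BFGS", options={"gtol": 1e-10, "maxiter": 2000},
        )
        # polish with Nelder-Mead in case BFGS stops on numerical noise
        res2 = optimize.minimize(
            self.discrepancy, res.x, args=(s, phi), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000, "maxfev": 40000},
        )
        best = res2 if res2.fun < res.fun else res
        return dict(zip(self.names, best.x)), float(best.fun)


def oracle_fit_indices(fmin: float, df: int, s: np.ndarray, sigma: np.ndarray,
                       n: int, n_indicators: int, n_predictors: int) -> dict:
    """Textbook fit-index arithmetic, written independently."""
    p = s.shape[0]
    t = (n - 1) * fmin
    # independence baseline, exogenous block saturated (closed form)
    d = np.diag(np.diag(s)[:n_indicators])
    if n_predictors:
        sigma_b = np.zeros_like(s)
        sigma_b[:n_indicators, :n_indicators] = d
        sigma_b[n_indicators:, n_indicators:] = s[n_indicators:, n_indicators:]
    else:
        sigma_b = d
    _, ld_b = np.linalg.slogdet(sigma_b)
    _, ld_s = np.linalg.slogdet(s)
    f_b = ld_b - ld_s + np.trace(s @ np.linalg.inv(sigma_b)) - p
    t_b = (n - 1) * f_b
    df_b = p * (p + 1) // 2 - (n_indicators + n_predictors * (n_predictors + 1) // 2)

    cfi = 1.0 - max(t - df, 0.0) / max(t_b - df_b, t - df, 0.0)
    tli = ((t_b / df_b) - (t / df)) / ((t_b / df_b) - 1.0)
    rmsea = np.sqrt(max(t - df, 0.0) / (df * (n - 1)))

    def ncp(prob):
        if stats.chi2.cdf(t, df) < prob:
            return 0.0
        lo, hi = 0.0, 1.0
        while stats.ncx2.cdf(t, df, hi) > prob:
            hi *= 2.0
        for _ in range(200):  # plain bisection
            mid = 0.5 * (lo + hi)
            if stats.ncx2.cdf(t, df, mid) > prob:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    ci = (np.sqrt(ncp(0.95) / (df * (n - 1))), np.sqrt(ncp(0.05) / (df * (n - 1))))
    sd = np.sqrt(np.diag(s))
    resid = (s - sigma) / np.outer(sd, sd)
    tri = resid[np.triu_indices(p)]
    srmr = np.sqrt(np.mean(tri**2))
    return {
        "chisq": t, "df": df, "cfi": float(cfi), "tli": float(tli),
        "rmsea": float(rmsea), "rmsea_ci90": (float(ci[0]), float(ci[1])),
        "p_rmsea_le_05": float(stats.ncx2.sf(t, df, 0.05**2 * df * (n - 1))),
        "srmr": float(srmr),
    }
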