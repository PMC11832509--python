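"""Independent reference implementations used only as test oracles.

Nothing here may call into sembeddings' fitting code: the single-factor ML
solution comes from statsmodels' factor-analysis fitter, the independence
baseline from its closed form (for a unit-diagonal correlation matrix the
independence model's ML discrepancy is -ln|S|), and the fit-index formulas
are restated from first principles. Tests compare the package's engine
against this separate route.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from statsmodels.multivariate.factor import Factor


def oracle_fit_1f(S: np.ndarray, n_pseudo: int) -> dict:
    """ML single-factor fit of a correlation matrix via statsmodels.

    Returns chisq, df, loadings (sign-aligned to positive sum), and the four
    fit indices computed from independently coded formulas.
    """
    p = S.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = Factor(corr=S, n_factor=1, method="ml", nobs=n_pseudo)
        res = fa.fit()
    load = np.asarray(res.loadings).ravel()
    if load.sum() < 0:
        load = -load
    psi = np.asarray(res.uniqueness).ravel()
    sigma = np.outer(load, load) + np.diag(psi)

    sign_S, logdet_S = np.linalg.slogdet(S)
    sign_M, logdet_M = np.linalg.slogdet(sigma)
    F = logdet_M - logdet_S + float(np.trace(np.linalg.solve(sigma, S))) - p
    T = (n_pseudo - 1) * max(F, 0.0)
    df = p * (p + 1) // 2 - 2 * p

    # independence baseline: variances free, optimum at diag(S) (= I here)
    F_b = -logdet_S
    T_b = (n_pseudo - 1) * F_b
    df_b = p * (p - 1) // 2

    cfi = 1.0 - max(T - df, 0.0) / max(T_b - df_b, T - df, 0.0)
    if df > 0:
        tli = ((T_b / df_b) - (T / df)) / ((T_b / df_b) - 1.0)
        rmsea = math.sqrt(max(T - df, 0.0) / (df * (n_pseudo - 1)))
    else:
        tli = float("nan")
        rmsea = float("nan")
    resid = S - sigma  # unit-diagonal input: already standardized
    iu = np.triu_indices(p)
    srmr = math.sqrt(float(np.mean(resid[iu] ** 2)))
    return {
        "loadings": load,
        "chisq": T,
        "df": df,
        "cfi": cfi,
        "tli": tli,
        "srmr": srmr,
        "rmsea": rmsea,
    }


def triad_loadings(r12: float, r13: float, r23: float) -> tuple[float, float, float]:
    """Closed-form loadings of the just-identified 3-item one-factor model."""
    l1 = math.sqrt(r12 * r13 / r23)
    l2 = math.sqrt(r12 * r23 / r13)
    l3 = math.sqrt(r13 * r23 / r12)
    return l1, l2, l3


def random_onefactorish_matrix(rng: np.random.Generator, p: int, noise: float = 0.04) -> np.ndarray:
    """A PD correlation matrix near (but not at) a one-factor structure."""
    lam = rng.uniform(0.45, 0.85, size=p)
    R = np.outer(lam, lam)
    E = rng.standard_normal((p, p)) * noise
    E = (E + E.T) / 2.0
    R = R + E
    np.fill_diagonal(R, 1.0)
    w = np.linalg.eigvalsh(R)
    if w[0] < 0.05:  # keep the optimum interior
        R = R + (0.05 - w[0]) * np.eye(p)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R
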