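"""Maximum-likelihood CFA on correlation-scale matrices.

The model is the standard linear factor structure

    Sigma(theta) = Lambda Phi Lambda' + Theta

with factor variances fixed to 1 for identification (all loadings free),
free factor correlations, free residual variances and optionally freed
residual covariances. The input matrix is treated as a correlation matrix
observed on a nominal ("pseudo") sample of size N, so the usual ML
discrepancy

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

yields T = (N-1) F_ML as an approximate chi-square with
df = p(p+1)/2 - q degrees of freedom, from which CFI, TLI, RMSEA and SRMR
are computed against an independence baseline fitted by the same engine.

Optimization is Fisher scoring (Newton steps on the expected information)
with analytic gradients and step halving, falling back to L-BFGS-B when
scoring stalls. Residual variances are box-bounded below at
``HEYWOOD_BOUND``; estimates pinned there are reported as Heywood items
rather than aborting, because badly misspecified models must still yield
fit indices.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.optimize
import yaml

from .corpus_io import ItemSet, SquareMatrix

# -- numerical policy ---------------------------------------------------------
HEYWOOD_BOUND = 1e-4      # lower box bound on residual variances
GRAD_TOL = 1e-7           # projected-gradient infinity norm at convergence
MAX_ITER = 500            # scoring + fallback iteration cap
RIDGE_EIG_MIN = 1e-8      # input matrices repaired below this eigenvalue
PHI_BOUND = 0.995         # |factor correlation| box bound

DEFAULT_N_PSEUDO = 10_000
DEFAULT_CUTOFFS = (0.90, 0.08)   # (incremental-index floor, residual-index ceiling)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A CFA measurement model over a fixed item order.

    ``loadings`` maps each factor id to the items with a free loading on it.
    Factor variances are fixed to 1; off-diagonal factor covariances are
    free; residual variances are always free; ``residual_free_pairs`` lists
    item pairs whose residual covariance is additionally freed.
    """

    item_ids: tuple[str, ...]
    factors: tuple[str, ...]
    loadings: dict[str, tuple[str, ...]]
    residual_free_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(
            self, "loadings", {f: tuple(v) for f, v in self.loadings.items()}
        )
        pairs = frozenset(tuple(sorted(p)) for p in self.residual_free_pairs)
        object.__setattr__(self, "residual_free_pairs", pairs)
        known = set(self.item_ids)
        loaded: set[str] = set()
        for f in self.factors:
            for i in self.loadings.get(f, ()):
                if i not in known:
                    raise ValueError(f"loading on unknown item {i!r}")
                loaded.add(i)
        orphans = known - loaded
        if orphans:
            raise ValueError(f"item(s) load on no factor: {sorted(orphans)}")
        for a, b in pairs:
            if a not in known or b not in known:
                raise ValueError(f"residual pair ({a!r}, {b!r}) names unknown item")
            if a == b:
                raise ValueError("residual pair must join two distinct items")
        p = len(self.item_ids)
        if self.n_free > p * (p + 1) // 2:
            raise ValueError(
                f"model has {self.n_free} free parameters but only "
                f"{p * (p + 1) // 2} observed moments"
            )

    @property
    def p(self) -> int:
        return len(self.item_ids)

    @property
    def n_free(self) -> int:
        n_lambda = sum(len(v) for v in self.loadings.values())
        k = len(self.factors)
        return n_lambda + k * (k - 1) // 2 + self.p + len(self.residual_free_pairs)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    # -- constructors -------------------------------------------------------

    @staticmethod
    def single_factor(item_ids: Sequence[str], factor: str = "F1") -> "ModelSpec":
        ids = tuple(item_ids)
        return ModelSpec(ids, (factor,), {factor: ids})

    @staticmethod
    def from_item_set(item_set: ItemSet) -> "ModelSpec":
        """One factor per scale (the instrument's theoretical model)."""
        loadings = {
            s: tuple(it.item_id for it in item_set.scale_items(s)) for s in item_set.scales
        }
        return ModelSpec(item_set.item_ids, item_set.scales, loadings)

    def with_freed(self, kind: str, lhs: str, rhs: str) -> "ModelSpec":
        """Return a copy with one additional free parameter."""
        if kind == "residual_cov":
            pairs = set(self.residual_free_pairs) | {tuple(sorted((lhs, rhs)))}
            return dataclasses.replace(self, residual_free_pairs=frozenset(pairs))
        if kind == "cross_loading":
            loadings = {f: v for f, v in self.loadings.items()}
            loadings[lhs] = tuple(loadings.get(lhs, ())) + (rhs,)
            return dataclasses.replace(self, loadings=loadings)
        raise ValueError(f"unknown parameter kind {kind!r}")


def read_model_spec(path: str | Path) -> ModelSpec:
    """Read a model spec from YAML: {factors: {name: [items]}, residual_free: [[a,b]]}."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    factors = doc["factors"]
    order: list[str] = []
    for items in factors.values():
        for i in items:
            if i not in order:
                order.append(i)
    pairs = frozenset(tuple(p) for p in doc.get("residual_free", []))
    return ModelSpec(
        tuple(order),
        tuple(factors.keys()),
        {f: tuple(v) for f, v in factors.items()},
        pairs,
    )


# ---------------------------------------------------------------------------
# parameter indexing
# ---------------------------------------------------------------------------

class _ParamMap:
    """Flat parameter vector layout for a ModelSpec."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        idx = {i: n for n, i in enumerate(spec.item_ids)}
        fidx = {f: n for n, f in enumerate(spec.factors)}
        self.lam_entries = [
            (idx[i], fidx[f]) for f in spec.factors for i in spec.loadings.get(f, ())
        ]
        k = len(spec.factors)
        self.phi_entries = [(a, b) for a in range(k) for b in range(a + 1, k)]
        self.theta_pairs = [
            tuple(sorted((idx[a], idx[b]))) for a, b in sorted(spec.residual_free_pairs)
        ]
        self.p, self.k = spec.p, k
        self.n_lam = len(self.lam_entries)
        self.n_phi = len(self.phi_entries)
        self.n_diag = spec.p
        self.q = self.n_lam + self.n_phi + self.n_diag + len(self.theta_pairs)
        # flat scatter indices for fast unpacking
        self._lam_flat = np.array(
            [i * k + f for i, f in self.lam_entries], dtype=np.intp
        )
        self._phi_flat_u = np.array([a * k + b for a, b in self.phi_entries], dtype=np.intp)
        self._phi_flat_l = np.array([b * k + a for a, b in self.phi_entries], dtype=np.intp)
        p = spec.p
        self._diag_flat = np.arange(p, dtype=np.intp) * (p + 1)
        self._pair_flat_u = np.array([i * p + j for i, j in self.theta_pairs], dtype=np.intp)
        self._pair_flat_l = np.array([j * p + i for i, j in self.theta_pairs], dtype=np.intp)

    def unpack(self, theta: np.ndarray):
        lam = np.zeros(self.p * self.k)
        lam[self._lam_flat] = theta[: self.n_lam]
        lam = lam.reshape(self.p, self.k)
        phi = np.eye(self.k)
        off = self.n_lam
        if self.n_phi:
            pf = phi.reshape(-1)
            pf[self._phi_flat_u] = theta[off : off + self.n_phi]
            pf[self._phi_flat_l] = theta[off : off + self.n_phi]
        off += self.n_phi
        th = np.zeros(self.p * self.p)
        th[self._diag_flat] = theta[off : off + self.n_diag]
        off += self.n_diag
        if len(self.theta_pairs):
            th[self._pair_flat_u] = theta[off:]
            th[self._pair_flat_l] = theta[off:]
        return lam, phi, th.reshape(self.p, self.p)

    def names(self) -> list[str]:
        spec = self.spec
        out = [
            f"lambda:{spec.item_ids[i]}:{spec.factors[f]}" for i, f in self.lam_entries
        ]
        out += [f"phi:{spec.factors[a]}:{spec.factors[b]}" for a, b in self.phi_entries]
        out += [f"theta:{i}:{i}" for i in spec.item_ids]
        out += [
            f"theta:{spec.item_ids[i]}:{spec.item_ids[j]}" for i, j in self.theta_pairs
        ]
        return out

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.full(self.q, -np.inf)
        hi = np.full(self.q, np.inf)
        off = self.n_lam
        lo[off : off + self.n_phi] = -PHI_BOUND
        hi[off : off + self.n_phi] = PHI_BOUND
        off += self.n_phi
        lo[off : off + self.n_diag] = HEYWOOD_BOUND
        return lo, hi

    def start(self, S: np.ndarray) -> np.ndarray:
        """Start values: lambda from mean within-factor correlation, phi = 0."""
        spec = self.spec
        idx = {i: n for n, i in enumerate(spec.item_ids)}
        lam_start: dict[int, float] = {}
        for fi, f in enumerate(spec.factors):
            ii = np.array([idx[i] for i in spec.loadings.get(f, ())])
            if ii.size >= 2:
                sub = S[np.ix_(ii, ii)]
                r = (sub.sum() - np.trace(sub)) / (ii.size * (ii.size - 1))
            else:
                r = 0.25
            lam_start[fi] = math.sqrt(min(max(r, 0.0025), 0.9025))
        theta = np.zeros(self.q)
        for t, (i, f) in enumerate(self.lam_entries):
            theta[t] = lam_start[f]
        off = self.n_lam + self.n_phi
        for i in range(self.p):
            tot = sum(lam_start[f] ** 2 for (ii, f) in self.lam_entries if ii == i)
            theta[off + i] = max(1.0 - tot, 0.1)
        return theta


# ---------------------------------------------------------------------------
# model-implied matrix
# ---------------------------------------------------------------------------

def implied_matrix(spec: ModelSpec, params: dict[str, float] | np.ndarray) -> SquareMatrix:
    """Sigma(theta) = Lambda Phi Lambda' + Theta for the given parameter values."""
    pm = _ParamMap(spec)
    if isinstance(params, dict):
        names = pm.names()
        theta = np.array([params[n] for n in names])
    else:
        theta = np.asarray(params, dtype=float)
    lam, phi, th = pm.unpack(theta)
    sigma = lam @ phi @ lam.T + th
    return SquareMatrix((sigma + sigma.T) / 2.0, spec.item_ids)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CFAFit:
    """A fitted CFA with discrepancy, chi-square and fit indices.

    ``tli`` and ``rmsea`` are NaN for just-identified models (df = 0), where
    they are undefined; ``heywood`` lists items whose residual variance sits
    on the lower bound.
    """

    estimates: dict[str, float]
    F_ml: float
    chisq: float
    df: int
    n_pseudo: int
    cfi: float
    tli: float
    srmr: float
    rmsea: float
    baseline_chisq: float
    baseline_df: int
    converged: bool
    n_iter: int
    heywood: tuple[str, ...]
    grad_norm: float
    ridge_delta: float = 0.0

    def indices(self) -> dict[str, float]:
        return {"cfi": self.cfi, "tli": self.tli, "srmr": self.srmr, "rmsea": self.rmsea}


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def _logdet_pd(M: np.ndarray) -> float:
    """log|M| via Cholesky; +inf signals non-PD to the line search."""
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return np.inf
    return 2.0 * float(np.sum(np.log(np.diag(L))))


class _Objective:
    def __init__(self, S: np.ndarray, pm: _ParamMap):
        self.S = S
        self.pm = pm
        self.logdet_S = _logdet_pd(S)
        self.p = S.shape[0]

    #: finite stand-in for the objective on non-PD Sigma (keeps L-BFGS-B sane)
    BIG = 1e12

    def value(self, theta: np.ndarray) -> float:
        lam, phi, th = self.pm.unpack(theta)
        sigma = lam @ phi @ lam.T + th
        ld = _logdet_pd(sigma)
        if not np.isfinite(ld):
            return self.BIG
        sigma_inv = np.linalg.inv(sigma)
        return ld - self.logdet_S + float(np.sum(sigma_inv * self.S)) - self.p

    def value_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        pm = self.pm
        lam, phi, th = pm.unpack(theta)
        sigma = lam @ phi @ lam.T + th
        ld = _logdet_pd(sigma)
        if not np.isfinite(ld):
            return self.BIG, np.zeros(pm.q)
        sigma_inv = np.linalg.inv(sigma)
        F = ld - self.logdet_S + float(np.sum(sigma_inv * self.S)) - self.p
        A = sigma_inv - sigma_inv @ self.S @ sigma_inv  # dF/dSigma up to symmetry
        g = np.empty(pm.q)
        ALP = A @ lam @ phi
        for t, (i, f) in enumerate(pm.lam_entries):
            g[t] = 2.0 * ALP[i, f]
        off = pm.n_lam
        LAL = lam.T @ A @ lam
        for t, (a, b) in enumerate(pm.phi_entries):
            g[off + t] = 2.0 * LAL[a, b]
        off += pm.n_phi
        g[off : off + pm.n_diag] = np.diag(A)
        off += pm.n_diag
        for t, (i, j) in enumerate(pm.theta_pairs):
            g[off + t] = 2.0 * A[i, j]
        return F, g

    def _deriv_mats(self, theta: np.ndarray) -> np.ndarray:
        """dSigma/dtheta_t stacked as a (q, p, p) array of symmetric matrices."""
        pm = self.pm
        lam, phi, _ = pm.unpack(theta)
        lam_phi = lam @ phi
        p = pm.p
        mats = np.zeros((pm.q, p, p))
        for t, (i, f) in enumerate(pm.lam_entries):
            mats[t, i, :] += lam_phi[:, f]
            mats[t, :, i] += lam_phi[:, f]
        off = pm.n_lam
        for t, (a, b) in enumerate(pm.phi_entries):
            D = np.outer(lam[:, a], lam[:, b])
            mats[off + t] = D + D.T
        off += pm.n_phi
        for i in range(p):
            mats[off + i, i, i] = 1.0
        off += pm.n_diag
        for t, (i, j) in enumerate(pm.theta_pairs):
            mats[off + t, i, j] = mats[off + t, j, i] = 1.0
        return mats

    def expected_information(self, theta: np.ndarray) -> np.ndarray:
        """H_ts = tr(Sigma^-1 D_t Sigma^-1 D_s), the expected Hessian of F."""
        lam, phi, th = self.pm.unpack(theta)
        sigma = lam @ phi @ lam.T + th
        sigma_inv = np.linalg.inv(sigma)
        W = sigma_inv @ self._deriv_mats(theta)  # (q, p, p) batch
        q, p = W.shape[0], W.shape[1]
        Wf = W.reshape(q, p * p)
        WTf = W.transpose(0, 2, 1).reshape(q, p * p)
        return Wf @ WTf.T

    def value_grad_info(self, theta: np.ndarray):
        """F, gradient and expected information sharing one factorization."""
        pm = self.pm
        if pm.k == 1 and pm.n_phi == 0 and not pm.theta_pairs and pm.n_lam == pm.p:
            return self._value_grad_info_1f(theta)
        lam, phi, th = pm.unpack(theta)
        sigma = lam @ phi @ lam.T + th
        ld = _logdet_pd(sigma)
        if not np.isfinite(ld):
            return self.BIG, np.zeros(pm.q), np.eye(pm.q)
        sigma_inv = np.linalg.inv(sigma)
        F = ld - self.logdet_S + float(np.sum(sigma_inv * self.S)) - self.p
        A = sigma_inv - sigma_inv @ self.S @ sigma_inv  # symmetric
        mats = self._deriv_mats(theta)
        q, p = pm.q, pm.p
        Mf = mats.reshape(q, p * p)
        g = Mf @ A.reshape(-1)
        W = sigma_inv @ mats
        Wf = W.reshape(q, p * p)
        WTf = W.transpose(0, 2, 1).reshape(q, p * p)
        H = Wf @ WTf.T
        return F, g, H

    def _value_grad_info_1f(self, theta: np.ndarray):
        """Single-factor closed forms for gradient and expected information.

        With Sigma = lam lam' + diag(d), K = Sigma^-1 and u = K lam:
        dF/dlam_i = 2(A lam)_i, dF/dd_i = A_ii, and the information blocks are
        H_ll = 2(uu' + (lam'u) K), H_ld = 2 K*u (columnwise), H_dd = K∘K.
        """
        pm = self.pm
        p = pm.p
        scatter = pm._lam_flat  # lam_entries item index per theta slot (k = 1)
        lam = np.zeros(p)
        lam[scatter] = theta[: pm.n_lam]
        d = theta[pm.n_lam : pm.n_lam + p]
        sigma = lam[:, None] * lam[None, :]
        sigma.flat[pm._diag_flat] += d
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return self.BIG, np.zeros(pm.q), np.eye(pm.q)
        ld = 2.0 * float(np.sum(np.log(L.diagonal())))
        K = np.linalg.inv(sigma)
        F = ld - self.logdet_S + float(np.sum(K * self.S)) - self.p
        B = K @ self.S @ K
        A = K - B
        u = K @ lam
        v = B @ lam
        c = float(lam @ u)
        b = float(lam @ v)
        g = np.empty(pm.q)
        g[: pm.n_lam] = 2.0 * (u - v)[scatter]  # A lam = (K - B) lam
        g[pm.n_lam :] = A.flat[pm._diag_flat]
        # observed Hessian (quadratic convergence) when PD, else expected info
        sl = (scatter[:, None], scatter[None, :])
        us, vs = u[scatter], v[scatter]
        Ks, Bs, As = K[sl], B[sl], A[sl]
        uu = us[:, None] * us[None, :]
        H = np.empty((pm.q, pm.q))
        H_ll = (
            -2.0 * (uu + c * Ks)
            + 2.0 * (us[:, None] * vs[None, :] + vs[:, None] * us[None, :] + b * Ks + c * Bs)
            + 2.0 * As
        )
        Krow, Brow = K[scatter, :], B[scatter, :]
        H_ld = -2.0 * Krow * u[None, :] + 2.0 * (Brow * u[None, :] + Krow * v[None, :])
        H_dd = 2.0 * K * B - K * K
        H[: pm.n_lam, : pm.n_lam] = H_ll
        H[: pm.n_lam, pm.n_lam :] = H_ld
        H[pm.n_lam :, : pm.n_lam] = H_ld.T
        H[pm.n_lam :, pm.n_lam :] = H_dd
        try:
            np.linalg.cholesky(H + 1e-10 * np.eye(pm.q))
            return F, g, H
        except np.linalg.LinAlgError:
            pass
        H[: pm.n_lam, : pm.n_lam] = 2.0 * (uu + c * Ks)
        cross = 2.0 * Krow * u[None, :]
        H[: pm.n_lam, pm.n_lam :] = cross
        H[pm.n_lam :, : pm.n_lam] = cross.T
        H[pm.n_lam :, pm.n_lam :] = K * K
        return F, g, H


def _projected_grad_norm(theta, g, lo, hi) -> float:
    pg = g.copy()
    at_lo = (theta <= lo + 1e-12) & (g > 0)
    at_hi = (theta >= hi - 1e-12) & (g < 0)
    pg[at_lo | at_hi] = 0.0
    return float(np.max(np.abs(pg), initial=0.0))


def _minimize(obj: _Objective, theta0: np.ndarray, lo, hi, max_iter=MAX_ITER):
    """Fisher scoring with step halving and box projection; L-BFGS-B fallback."""
    theta = np.clip(theta0, lo, hi)
    F, g, H = obj.value_grad_info(theta)
    if F >= _Objective.BIG:  # degenerate start: inflate residual variances
        theta = theta.copy()
        off = obj.pm.n_lam + obj.pm.n_phi
        theta[off : off + obj.pm.n_diag] = 1.0
        F, g, H = obj.value_grad_info(theta)
    n_iter = 0
    eye = np.eye(len(theta))
    # scoring converges in a handful of steps on well-behaved problems; cap it
    # early and let the quasi-Newton fallback finish boundary-hugging fits
    scoring_cap = min(max_iter, 40)
    for n_iter in range(1, scoring_cap + 1):
        if _projected_grad_norm(theta, g, lo, hi) < GRAD_TOL:
            return theta, F, g, n_iter, True
        try:
            step = np.linalg.solve(H + 1e-10 * eye, g)
        except np.linalg.LinAlgError:
            break
        # full Newton step first (usual case), then halve on the cheap value()
        cand = np.clip(theta - step, lo, hi)
        Fc, gc, Hc = obj.value_grad_info(cand)
        if Fc < F - 1e-14:
            theta, F, g, H = cand, Fc, gc, Hc
            continue
        alpha, improved = 0.5, False
        for _ in range(29):
            cand = np.clip(theta - alpha * step, lo, hi)
            if obj.value(cand) < F - 1e-14:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        theta = cand
        F, g, H = obj.value_grad_info(theta)
    # fallback: quasi-Newton with bounds
    res = scipy.optimize.minimize(
        obj.value_grad,
        theta,
        jac=True,
        method="L-BFGS-B",
        bounds=list(zip(np.where(np.isinf(lo), None, lo), np.where(np.isinf(hi), None, hi))),
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
    )
    theta2 = np.clip(res.x, lo, hi)
    F2, g2 = obj.value_grad(theta2)
    if F2 <= F:
        theta, F, g = theta2, F2, g2
    total = n_iter + int(res.nit)
    converged = _projected_grad_norm(theta, g, lo, hi) < GRAD_TOL
    return theta, F, g, total, converged


# ---------------------------------------------------------------------------
# input repair
# ---------------------------------------------------------------------------

def ridge_repair(S: np.ndarray, eig_min: float = RIDGE_EIG_MIN) -> tuple[np.ndarray, float]:
    """Add a diagonal ridge and renormalize to unit diagonal if near-singular.

    Returns the (possibly untouched) matrix and the ridge delta applied.
    """
    w = np.linalg.eigvalsh(S)
    if w[0] >= eig_min:
        return S, 0.0
    delta = float(eig_min - w[0]) + 1e-10
    R = S + delta * np.eye(S.shape[0])
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R)[0] <= 0:
        raise np.linalg.LinAlgError("matrix remains singular after ridge repair")
    return R, delta


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_baseline(S: np.ndarray, n_pseudo: int) -> tuple[float, int]:
    """Independence model (Sigma = diag of free variances), same ML engine.

    Started at its stationary point diag(S); the engine just verifies the
    gradient, so this costs one evaluation on well-posed input.
    """
    p = S.shape[0]
    pm = _ParamMap(ModelSpec.single_factor([f"__b{i}" for i in range(p)]))
    # baseline = zero loadings; emulate by bounding lambdas at 0
    lo, hi = pm.bounds()
    lo[: pm.n_lam] = 0.0
    hi[: pm.n_lam] = 0.0
    obj = _Objective(S, pm)
    theta0 = np.zeros(pm.q)
    off = pm.n_lam + pm.n_phi
    theta0[off : off + p] = np.diag(S)
    theta, F, g, n_iter, conv = _minimize(obj, theta0, lo, hi)
    T_b = (n_pseudo - 1) * F
    df_b = p * (p + 1) // 2 - p
    return float(T_b), df_b


def fit_indices(
    chisq: float,
    df: int,
    baseline_chisq: float,
    baseline_df: int,
    n_pseudo: int,
    S: np.ndarray,
    sigma_hat: np.ndarray,
) -> tuple[float, float, float, float]:
    """CFI, TLI, SRMR, RMSEA from chi-squares and the residual matrix.

    TLI is left uncapped (it may exceed 1 or go negative); TLI and RMSEA are
    NaN when df = 0. SRMR averages squared standardized residuals over the
    p(p+1)/2 unique entries including the diagonal.
    """
    T, T_b = chisq, baseline_chisq
    denom = max(T_b - baseline_df, T - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T - df, 0.0) / denom
    if df > 0 and baseline_df > 0:
        ratio_b = T_b / baseline_df
        tli = (ratio_b - T / df) / (ratio_b - 1.0) if ratio_b != 1.0 else float("nan")
        rmsea = math.sqrt(max(T - df, 0.0) / (df * (n_pseudo - 1)))
    else:
        tli = float("nan")
        rmsea = float("nan")
    d = np.sqrt(np.diag(S))
    resid = (S - sigma_hat) / np.outer(d, d)
    p = S.shape[0]
    iu = np.triu_indices(p)
    srmr = math.sqrt(float(np.mean(resid[iu] ** 2)))
    return float(cfi), float(tli), float(srmr), float(rmsea)


def fit_cfa(
    S: SquareMatrix,
    spec: ModelSpec,
    n_pseudo: int = DEFAULT_N_PSEUDO,
) -> CFAFit:
    """Fit a CFA to a (pseudo-)correlation matrix by maximum likelihood.

    ``n_pseudo`` is the nominal sample size attached to the matrix so that
    chi-square-based indices are computable; 10,000 by default so index
    behaviour is dominated by the discrepancy, not sampling noise.
    """
    if n_pseudo < 2:
        raise ValueError("n_pseudo must be >= 2")
    if set(spec.item_ids) - set(S.axis_ids):
        raise ValueError("model references items not on the matrix axis")
    sub = S.submatrix(spec.item_ids) if S.axis_ids != spec.item_ids else S
    Sv, delta = ridge_repair(sub.values)

    pm = _ParamMap(spec)
    obj = _Objective(Sv, pm)
    lo, hi = pm.bounds()
    theta0 = pm.start(Sv)
    theta, F, g, n_iter, converged = _minimize(obj, theta0, lo, hi)
    F = max(F, 0.0)
    chisq = (n_pseudo - 1) * F
    T_b, df_b = _fit_baseline(Sv, n_pseudo)
    sigma_hat = implied_matrix(spec, theta).values
    cfi, tli, srmr, rmsea = fit_indices(chisq, spec.df, T_b, df_b, n_pseudo, Sv, sigma_hat)

    off = pm.n_lam + pm.n_phi
    heywood = tuple(
        spec.item_ids[i]
        for i in range(pm.n_diag)
        if theta[off + i] <= HEYWOOD_BOUND + 1e-12
    )
    estimates = dict(zip(pm.names(), (float(v) for v in theta)))
    return CFAFit(
        estimates=estimates,
        F_ml=float(F),
        chisq=float(chisq),
        df=spec.df,
        n_pseudo=n_pseudo,
        cfi=cfi,
        tli=tli,
        srmr=srmr,
        rmsea=rmsea,
        baseline_chisq=float(T_b),
        baseline_df=df_b,
        converged=bool(converged),
        n_iter=int(n_iter),
        heywood=heywood,
        grad_norm=_projected_grad_norm(theta, g, lo, hi),
        ridge_delta=delta,
    )


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MIRow:
    param_kind: Literal["residual_cov", "cross_loading"]
    lhs: str  # item (residual_cov) or factor (cross_loading)
    rhs: str  # item
    mi: float
    rank: int
    note: str = ""


@dataclass(frozen=True)
class MITable:
    """Modification indices for currently fixed parameters, largest first."""

    rows: tuple[MIRow, ...]
    method: str

    def head(self, n: int) -> "MITable":
        return MITable(self.rows[:n], self.method)

    def top(self) -> MIRow:
        if not self.rows:
            raise ValueError("empty MI table")
        return self.rows[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": [r.param_kind for r in self.rows],
                "lhs": [r.lhs for r in self.rows],
                "rhs": [r.rhs for r in self.rows],
                "mi": [r.mi for r in self.rows],
                "rank": [r.rank for r in self.rows],
            }
        )


def _candidates(spec: ModelSpec) -> list[tuple[str, str, str]]:
    cands: list[tuple[str, str, str]] = []
    ids = spec.item_ids
    free = spec.residual_free_pairs
    for a in range(spec.p):
        for b in range(a + 1, spec.p):
            pair = tuple(sorted((ids[a], ids[b])))
            if pair not in free:
                cands.append(("residual_cov", pair[0], pair[1]))
    if len(spec.factors) > 1:
        for f in spec.factors:
            loaded = set(spec.loadings.get(f, ()))
            for i in ids:
                if i not in loaded:
                    cands.append(("cross_loading", f, i))
    return cands


def modification_indices(
    S: SquareMatrix,
    spec: ModelSpec,
    fit: CFAFit,
    method: Literal["score", "refit"] = "score",
) -> MITable:
    """Modification indices for all fixed residual covariances / cross-loadings.

    ``refit`` frees each candidate and refits, reporting the exact chi-square
    drop; ``score`` is the one-step expected-information score (Lagrange
    multiplier) statistic, far cheaper and asymptotically equal for small
    freed values.
    """
    if not fit.converged:
        raise ValueError("modification indices require a converged fit")
    sub = S.submatrix(spec.item_ids) if S.axis_ids != spec.item_ids else S
    Sv, _ = ridge_repair(sub.values)
    pm = _ParamMap(spec)
    theta_hat = np.array([fit.estimates[n] for n in pm.names()])
    cands = _candidates(spec)
    rows: list[MIRow] = []

    if method == "score":
        mis = _score_mis(Sv, spec, pm, theta_hat, cands, fit.n_pseudo)
        for (kind, lhs, rhs), mi in zip(cands, mis):
            rows.append(MIRow(kind, lhs, rhs, float(max(mi, 0.0)), rank=0))
    elif method == "refit":
        for kind, lhs, rhs in cands:
            spec_f = spec.with_freed(kind, lhs, rhs)
            fit_f = fit_cfa(sub, spec_f, n_pseudo=fit.n_pseudo)
            mi = max(fit.chisq - fit_f.chisq, 0.0)
            note = "" if fit_f.converged else "refit did not converge"
            rows.append(MIRow(kind, lhs, rhs, float(mi), rank=0, note=note))
    else:
        raise ValueError(f"unknown MI method {method!r}")

    rows.sort(key=lambda r: -r.mi)
    ranked = tuple(
        dataclasses.replace(r, rank=i + 1) for i, r in enumerate(rows)
    )
    return MITable(ranked, method=method)


def _score_mis(Sv, spec, pm, theta_hat, cands, n_pseudo) -> np.ndarray:
    """Univariate expected-information score statistics for each candidate.

    MI_c = (N-1) * g_c^2 / (2 * h_c) where g_c is the discrepancy gradient in
    the candidate direction at the restricted optimum and h_c the expected
    Hessian of F in that direction after concentrating out the free
    parameters (Schur complement).
    """
    obj = _Objective(Sv, pm)
    lam, phi, th = pm.unpack(theta_hat)
    sigma = lam @ phi @ lam.T + th
    sigma_inv = np.linalg.inv(sigma)
    A = sigma_inv - sigma_inv @ Sv @ sigma_inv
    lam_phi = lam @ phi
    idx = {i: n for n, i in enumerate(spec.item_ids)}
    fidx = {f: n for n, f in enumerate(spec.factors)}

    def cand_deriv(kind: str, lhs: str, rhs: str) -> np.ndarray:
        p = pm.p
        D = np.zeros((p, p))
        if kind == "residual_cov":
            i, j = idx[lhs], idx[rhs]
            D[i, j] = D[j, i] = 1.0
        else:  # cross_loading of item rhs on factor lhs, at lambda = 0
            i, f = idx[rhs], fidx[lhs]
            D[i, :] += lam_phi[:, f]
            D[:, i] += lam_phi[:, f]
        return D

    H = obj.expected_information(theta_hat)
    H_inv = np.linalg.pinv(H)
    W_free = sigma_inv @ obj._deriv_mats(theta_hat)  # (q, p, p)
    mis = np.empty(len(cands))
    for c, (kind, lhs, rhs) in enumerate(cands):
        Dc = cand_deriv(kind, lhs, rhs)
        Wc = sigma_inv @ Dc
        g_c = float(np.sum(A * Dc))
        h_cc = float(np.sum(Wc.T * Wc))
        h_ct = np.einsum("ij,tji->t", Wc, W_free)
        h_eff = h_cc - float(h_ct @ H_inv @ h_ct)
        if h_eff <= 1e-12:
            mis[c] = 0.0
        else:
            mis[c] = (n_pseudo - 1) * g_c**2 / (2.0 * h_eff)
    return mis


# ---------------------------------------------------------------------------
# misfit classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitVerdict:
    """Per-index poor flags and the two-or-more-poor misfit rule."""

    poor_flags: dict[str, bool]
    n_poor: int
    verdict: Literal["adequate", "misfit"]
    not_applicable: tuple[str, ...] = ()

    def __str__(self) -> str:
        flags = ", ".join(f"{k}={'poor' if v else 'ok'}" for k, v in self.poor_flags.items())
        return f"{self.verdict} ({flags})"


def classify_fit(
    fit: CFAFit, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> FitVerdict:
    """Apply the descriptive misfit rule: two or more poor indices => misfit.

    CFI/TLI below ``cutoffs[0]`` and SRMR/RMSEA above ``cutoffs[1]`` count
    as poor. An undefined index (df = 0) counts as not-poor and is listed in
    ``not_applicable``.
    """
    c1, c2 = cutoffs
    if not (0 < c1 < 1):
        raise ValueError("incremental-index cutoff must be in (0, 1)")
    if c2 <= 0:
        raise ValueError("residual-index cutoff must be positive")
    vals = fit.indices()
    na = tuple(k for k, v in vals.items() if isinstance(v, float) and math.isnan(v))
    flags = {
        "cfi": (not math.isnan(vals["cfi"])) and vals["cfi"] < c1,
        "tli": (not math.isnan(vals["tli"])) and vals["tli"] < c1,
        "srmr": (not math.isnan(vals["srmr"])) and vals["srmr"] > c2,
        "rmsea": (not math.isnan(vals["rmsea"])) and vals["rmsea"] > c2,
    }
    n_poor = sum(flags.values())
    return FitVerdict(
        poor_flags=flags,
        n_poor=n_poor,
        verdict="misfit" if n_poor >= 2 else "adequate",
        not_applicable=na,
    )
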