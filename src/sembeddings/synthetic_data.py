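"""Synthetic instruments, response samples and controllable-fidelity proxies.

Everything downstream of an embedding model can be exercised without one:
``make_instrument`` builds a multi-scale instrument with a known factor
structure (one factor per scale, optional injected residual correlations),
``sample_responses`` draws Likert responses from the implied population,
and ``pseudo_similarity`` degrades the population correlation matrix into a
noisy proxy whose lower-triangle agreement with the truth is controlled —
emulating an embedding-similarity matrix of known fidelity.

``verdict_agreement_experiment`` then measures, over replications, how often
screening verdicts on the proxy agree with verdicts on the population truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .comparison import lower_triangle_correlation
from .corpus_io import Item, ItemSet, SquareMatrix
from .screening import ScreenResult, unidimensional_screen

# default equal-probability quintile cuts of the standard normal
LIKERT5_THRESHOLDS = tuple(norm.ppf([0.2, 0.4, 0.6, 0.8]))

_TEXT_TEMPLATES = (
    "I often {verb} when dealing with {theme}.",
    "People who know me say I {verb} about {theme}.",
    "I make a point of trying to {verb} whenever {theme} comes up.",
    "Even under pressure, I usually {verb} in matters of {theme}.",
    "It is typical of me to {verb} where {theme} is concerned.",
)
_VERBS = (
    "stay focused", "take initiative", "look for new angles", "keep my word",
    "help others", "plan ahead", "stay calm", "speak up", "listen carefully",
    "persist", "stay curious", "act fairly",
)
_THEMES = (
    "daily routines", "difficult decisions", "group projects", "new ideas",
    "personal goals", "other people's feelings", "unexpected problems",
    "long-term plans", "learning something new", "conflicts", "small setbacks",
    "shared responsibilities",
)


@dataclass(frozen=True)
class InstrumentSim:
    """A synthetic instrument with known population structure."""

    item_set: ItemSet
    true_loadings: dict[str, float]  # item_id -> lambda
    factor_corr: np.ndarray  # scale x scale Phi
    injected_residual_pairs: tuple[tuple[str, str, float], ...]
    population_R: SquareMatrix
    seed: int


@dataclass(frozen=True)
class PseudoSimilarity:
    """A noisy stand-in for an embedding-similarity matrix."""

    matrix: SquareMatrix
    target_agreement: float
    achieved_agreement: float
    seed: int


def _synthetic_text(rng: np.random.Generator, scale_idx: int, item_idx: int) -> str:
    tpl = _TEXT_TEMPLATES[item_idx % len(_TEXT_TEMPLATES)]
    verb = _VERBS[(scale_idx + item_idx) % len(_VERBS)]
    theme = _THEMES[scale_idx % len(_THEMES)]
    return tpl.format(verb=verb, theme=theme)


def make_instrument(
    n_scales: int,
    items_per_scale: int = 4,
    loading_range: tuple[float, float] = (0.5, 0.85),
    factor_corr_range: tuple[float, float] = (0.1, 0.5),
    injected_pairs: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
) -> InstrumentSim:
    """Build a one-factor-per-scale instrument with a known population matrix.

    Loadings are uniform on ``loading_range``. Factor correlations come from
    a single higher-order dimension — Phi_ab = sqrt(u_a u_b) with u uniform
    on ``factor_corr_range`` — which keeps every pairwise correlation inside
    the requested range while guaranteeing Phi is positive semidefinite for
    any number of scales. Injected residual pairs are written into Theta and
    must leave it positive semidefinite.
    """
    lo, hi = loading_range
    if not (0 < lo <= hi < 1):
        raise ValueError("loading_range must lie strictly inside (0, 1)")
    clo, chi = factor_corr_range
    if not (0 <= clo <= chi < 1):
        raise ValueError("factor_corr_range must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    items: list[Item] = []
    pos = 0
    for s in range(n_scales):
        sid = f"s{s + 1:02d}"
        for k in range(items_per_scale):
            pos += 1
            items.append(
                Item(
                    item_id=f"{sid}_i{k + 1}",
                    scale_id=sid,
                    text=_synthetic_text(rng, s, k),
                    position=pos,
                )
            )
    item_set = ItemSet(tuple(items))
    p = len(item_set)

    lam_vals = rng.uniform(lo, hi, size=p)
    true_loadings = dict(zip(item_set.item_ids, (float(v) for v in lam_vals)))

    if chi == 0:
        phi = np.eye(n_scales)
    else:
        u = rng.uniform(clo, chi, size=n_scales)
        g = np.sqrt(u)
        phi = np.outer(g, g)
        np.fill_diagonal(phi, 1.0)

    # Lambda maps items to their scale's factor
    lam = np.zeros((p, n_scales))
    for i, it in enumerate(item_set.items):
        lam[i, item_set.scales.index(it.scale_id)] = lam_vals[i]

    theta = np.diag(1.0 - lam_vals**2)
    idx = {i: n for n, i in enumerate(item_set.item_ids)}
    injected = []
    for a, b, v in injected_pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"injected pair names unknown item(s): ({a!r}, {b!r})")
        theta[idx[a], idx[b]] = theta[idx[b], idx[a]] = v
        injected.append((a, b, float(v)))
    if np.linalg.eigvalsh(theta)[0] < 0:
        raise ValueError(
            "injected residual covariances make the residual matrix non-PSD; "
            "lower the injected values or the loadings"
        )

    R = lam @ phi @ lam.T + theta
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R)[0] < -1e-10:
        raise ValueError("population correlation matrix is not PSD")
    return InstrumentSim(
        item_set=item_set,
        true_loadings=true_loadings,
        factor_corr=phi,
        injected_residual_pairs=tuple(injected),
        population_R=SquareMatrix(R, item_set.item_ids),
        seed=seed,
    )


def sample_responses(
    sim: InstrumentSim,
    n: int,
    likert: int | None = 5,
    thresholds: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SquareMatrix]:
    """Draw n response vectors from the population and return their correlations.

    Latent scores are multivariate normal with correlation ``population_R``;
    with ``likert=5`` they are discretized at ``thresholds`` (defaults to
    equal-probability quintile cuts) into 1..5.
    """
    if n < 10:
        raise ValueError("need at least 10 respondents")
    if likert not in (5, None):
        raise ValueError("likert must be 5 or None")
    rng = np.random.default_rng(seed)
    R = sim.population_R.values
    L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
    Z = rng.standard_normal((n, R.shape[0])) @ L.T
    if likert == 5:
        cuts = np.asarray(LIKERT5_THRESHOLDS if thresholds is None else thresholds)
        if cuts.ndim != 1 or len(cuts) != 4 or np.any(np.diff(cuts) <= 0):
            raise ValueError("thresholds must be 4 strictly increasing cut points")
        X = np.digitize(Z, cuts) + 1  # 1..5
    else:
        X = Z
    df = pd.DataFrame(X, columns=list(sim.item_set.item_ids))
    C = np.corrcoef(X, rowvar=False)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return df, SquareMatrix(C, sim.item_set.item_ids)


def _psd_project(M: np.ndarray, rounds: int = 5) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    R = M.copy()
    for _ in range(rounds):
        w, V = np.linalg.eigh(R)
        if w[0] >= 0:
            break
        R = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(R), 1e-12, None))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
    return R


def pseudo_similarity(
    R: SquareMatrix,
    target_agreement: float,
    seed: int = 0,
    tol: float = 0.03,
) -> PseudoSimilarity:
    """Degrade a correlation matrix into a proxy of chosen fidelity.

    Additive seeded Gaussian noise on the off-diagonal is scaled by a short
    secant search on the noise standard deviation until the lower-triangle
    correlation of the *final* matrix — after projection back to
    unit-diagonal PSD form — is within ``tol`` of ``target_agreement``.
    Tuning on the post-projection matrix matters because eigenvalue clipping
    removes part of the injected noise and would otherwise bias the achieved
    agreement upward.
    """
    if not (0 < target_agreement <= 1):
        raise ValueError("target_agreement must be in (0, 1]")
    vals = R.values
    if target_agreement == 1.0:
        return PseudoSimilarity(
            matrix=SquareMatrix(vals.copy(), R.axis_ids),
            target_agreement=1.0,
            achieved_agreement=1.0,
            seed=seed,
        )
    p = R.p
    rng = np.random.default_rng(seed)
    il = np.tril_indices(p, k=-1)
    r = vals[il]
    noise = rng.standard_normal(len(r))
    noise = (noise - noise.mean()) / noise.std()
    sd_r = float(np.std(r))
    t = target_agreement
    sigma = sd_r * np.sqrt(1.0 / t**2 - 1.0)  # exact under independent noise

    def build(s: float) -> tuple[np.ndarray, float]:
        tri = r + s * noise
        M = np.eye(p)
        M[il] = tri
        M[(il[1], il[0])] = tri
        M = _psd_project(np.clip(M, -1.0, 1.0))
        return M, float(np.corrcoef(r, M[il])[0, 1])

    M, a = build(sigma)
    for _ in range(40):
        if abs(a - t) <= tol / 2:
            break
        # invert the attenuation relation on the observed agreement
        ratio = np.sqrt(max(1.0 / t**2 - 1.0, 1e-12) / max(1.0 / a**2 - 1.0, 1e-12))
        sigma *= ratio
        M, a = build(sigma)

    out = SquareMatrix(M, R.axis_ids)
    ach = lower_triangle_correlation(R, out).r_lower_triangle
    return PseudoSimilarity(
        matrix=out,
        target_agreement=target_agreement,
        achieved_agreement=float(ach),
        seed=seed,
    )


def verdict_agreement_experiment(
    sim: InstrumentSim,
    target_agreement: float,
    n_reps: int,
    seed: int = 0,
    n_pseudo: int = 10_000,
) -> dict:
    """Cross-classify proxy-arm and population-arm screening verdicts.

    For each replication a fresh pseudo-similarity matrix is generated and
    the unidimensional screen is run on it; verdicts are compared with the
    screen on the population matrix (computed once — it is deterministic).
    Returns confusion counts over scale x replication and summary rates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    pop_results = unidimensional_screen(sim.population_R, sim.item_set, n_pseudo=n_pseudo)
    pop_verdicts = {r.scale_id: r.verdict.verdict for r in pop_results}
    counts = {
        "both_adequate": 0,
        "both_misfit": 0,
        "proxy_misfit_only": 0,  # false alarm relative to population truth
        "proxy_adequate_only": 0,  # miss
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    for rep in range(n_reps):
        ps = pseudo_similarity(sim.population_R, target_agreement, seed=int(child_seeds[rep]))
        proxy_results = unidimensional_screen(ps.matrix, sim.item_set, n_pseudo=n_pseudo)
        for r in proxy_results:
            pop_v = pop_verdicts[r.scale_id]
            prox_v = r.verdict.verdict
            if prox_v == pop_v:
                counts["both_adequate" if pop_v == "adequate" else "both_misfit"] += 1
            elif prox_v == "misfit":
                counts["proxy_misfit_only"] += 1
            else:
                counts["proxy_adequate_only"] += 1
    total = sum(counts.values())
    n_disagree = counts["proxy_misfit_only"] + counts["proxy_adequate_only"]
    pop_misfit = [s for s, v in pop_verdicts.items() if v == "misfit"]
    return {
        "counts": counts,
        "n_comparisons": total,
        "disagreement_rate": n_disagree / total if total else float("nan"),
        "population_misfit_scales": pop_misfit,
        "target_agreement": target_agreement,
        "n_reps": n_reps,
        "seed": seed,
    }
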