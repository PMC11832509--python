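"""Pre-data-collection screening batteries.

Two validation workflows over a similarity (pseudo-correlation) matrix:

* ``unidimensional_screen`` — one single-factor CFA per scale, the
  theoretically correct model, to flag scales whose items do not cohere.
* ``wrong_model_battery`` — for every unordered pair of scales, one
  deliberately misspecified single-factor CFA over both scales' items;
  a usable screening procedure must call these models misfits.

Misfit verdicts use the two-or-more-poor-indices rule; modification
indices, annotated with verbatim item texts, point at the offending item
pairs so a researcher can judge whether the suggestion is meaningful.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cfa_core import (
    DEFAULT_CUTOFFS,
    DEFAULT_N_PSEUDO,
    CFAFit,
    FitVerdict,
    MITable,
    ModelSpec,
    classify_fit,
    fit_cfa,
    modification_indices,
)
from .corpus_io import ItemSet, SquareMatrix


@dataclass(frozen=True)
class ScreenResult:
    """Verdict for one screened model (a scale, or a forced pair of scales)."""

    scale_id: str  # scale id, or "a+b" for a pair model
    fit: CFAFit
    verdict: FitVerdict
    top_mi: MITable | None = None


def unidimensional_screen(
    S: SquareMatrix,
    item_set: ItemSet,
    n_pseudo: int = DEFAULT_N_PSEUDO,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    mi_method: Literal["score", "refit"] = "score",
    mi_top: int = 10,
) -> list[ScreenResult]:
    """Fit one single-factor CFA per scale and classify its fit.

    Scales with fewer than three items are skipped (not even just-identified).
    MI tables are attached to misfitting scales only; an adequate scale needs
    no diagnosis.
    """
    import warnings

    results: list[ScreenResult] = []
    for scale in item_set.scales:
        ids = tuple(it.item_id for it in item_set.scale_items(scale))
        if len(ids) < 3:
            warnings.warn(
                f"scale {scale!r} has {len(ids)} item(s); needs >= 3 for a CFA — skipped",
                stacklevel=2,
            )
            continue
        spec = ModelSpec.single_factor(ids, factor=scale)
        fit = fit_cfa(S, spec, n_pseudo=n_pseudo)
        verdict = classify_fit(fit, cutoffs)
        top_mi = None
        if verdict.verdict == "misfit" and fit.converged and fit.df > 0:
            top_mi = modification_indices(S, spec, fit, method=mi_method).head(mi_top)
        results.append(ScreenResult(scale, fit, verdict, top_mi))
    return results


def wrong_model_battery(
    S: SquareMatrix,
    item_set: ItemSet,
    n_pseudo: int = DEFAULT_N_PSEUDO,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
) -> list[ScreenResult]:
    """Fit a single factor over every unordered pair of scales (k(k-1)/2 models).

    Each model collapses two scales into one latent variable — wrong by
    construction whenever the scales measure distinct things — so the
    verdicts measure the screen's ability to detect misspecification.
    """
    if len(item_set.scales) < 2:
        raise ValueError("battery needs at least two scales")
    results: list[ScreenResult] = []
    for a, b in itertools.combinations(item_set.scales, 2):
        ids = tuple(it.item_id for it in item_set.scale_items(a)) + tuple(
            it.item_id for it in item_set.scale_items(b)
        )
        spec = ModelSpec.single_factor(ids, factor=f"{a}+{b}")
        fit = fit_cfa(S, spec, n_pseudo=n_pseudo)
        results.append(ScreenResult(f"{a}+{b}", fit, classify_fit(fit, cutoffs)))
    return results


def battery_summary(
    results: list[ScreenResult], srmr_cutoff: float = DEFAULT_CUTOFFS[1]
) -> dict:
    """Min/max per index, SRMR-below-cutoff fraction and misfit fraction.

    Non-convergent fits count toward the misfit fraction (conservative) and
    are also reported separately.
    """
    if not results:
        raise ValueError("no screening results to summarize")
    out: dict = {"n_models": len(results)}
    for index in ("cfi", "tli", "srmr", "rmsea"):
        vals = np.array([r.fit.indices()[index] for r in results])
        vals = vals[~np.isnan(vals)]
        out[index] = {"min": float(vals.min()), "max": float(vals.max())}
    out["frac_srmr_below_cutoff"] = float(
        np.mean([r.fit.srmr < srmr_cutoff for r in results])
    )
    out["frac_misfit"] = float(
        np.mean(
            [r.verdict.verdict == "misfit" or not r.fit.converged for r in results]
        )
    )
    out["n_nonconverged"] = int(sum(not r.fit.converged for r in results))
    return out


def screen_report(results: list[ScreenResult], item_set: ItemSet) -> str:
    """Human-readable screening report with item texts beside each top MI.

    Deterministic: identical inputs render byte-identical reports.
    """
    lines: list[str] = []
    for r in results:
        f = r.fit
        lines.append(f"== {r.scale_id}: {r.verdict.verdict.upper()} ==")
        lines.append(
            "   CFI={:.3f} TLI={} SRMR={:.3f} RMSEA={} chisq={:.2f} df={}".format(
                f.cfi,
                "n/a" if np.isnan(f.tli) else f"{f.tli:.3f}",
                f.srmr,
                "n/a" if np.isnan(f.rmsea) else f"{f.rmsea:.3f}",
                f.chisq,
                f.df,
            )
        )
        if not f.converged:
            lines.append("   WARNING: fit did not converge")
        if f.heywood:
            lines.append(f"   Heywood items: {', '.join(f.heywood)}")
        if r.top_mi is not None and r.top_mi.rows:
            lines.append("   top modification indices:")
            for row in r.top_mi.rows:
                if row.param_kind == "residual_cov":
                    t1 = item_set.text_of(row.lhs)
                    t2 = item_set.text_of(row.rhs)
                    lines.append(
                        f"     #{row.rank} MI={row.mi:.2f} residual {row.lhs} ~~ {row.rhs}"
                    )
                    lines.append(f'        {row.lhs}: "{t1}"')
                    lines.append(f'        {row.rhs}: "{t2}"')
                else:
                    t2 = item_set.text_of(row.rhs)
                    lines.append(
                        f"     #{row.rank} MI={row.mi:.2f} cross-loading {row.rhs} on {row.lhs}"
                    )
                    lines.append(f'        {row.rhs}: "{t2}"')
        lines.append("")
    return "\n".join(lines)
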