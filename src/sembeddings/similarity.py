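"""Cosine similarities between item embeddings, used as pseudo-correlations.

The cosine-similarity matrix of unit-normalized embedding vectors is a Gram
matrix: symmetric, unit diagonal, positive semidefinite. Treated as a
correlation matrix it supports the same covariance-structure analyses one
would run on empirical item correlations, before any data are collected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .corpus_io import EmbeddingMatrix, ItemSet, SquareMatrix


class EmbeddingProvider(Protocol):
    """Anything that maps a batch of texts to fixed-length vectors."""

    def __call__(self, texts: Sequence[str]) -> np.ndarray: ...


def embed_items(item_set: ItemSet, provider: EmbeddingProvider) -> EmbeddingMatrix:
    """Embed every item text, keeping canonical item order.

    Provider failures are re-raised with the offending item batch's ids so a
    long run is diagnosable. Inconsistent output dimensions are an error.
    """
    texts = [it.text for it in item_set.items]
    try:
        vectors = np.asarray(provider(texts), dtype=float)
    except Exception as exc:  # noqa: BLE001 - context added, then re-raised
        raise RuntimeError(
            f"embedding provider failed for items {list(item_set.item_ids)}: {exc}"
        ) from exc
    if vectors.ndim != 2 or vectors.shape[0] != len(texts):
        raise ValueError(
            "provider must return one fixed-length vector per item "
            f"(got shape {vectors.shape} for {len(texts)} items)"
        )
    return EmbeddingMatrix(vectors, item_set.item_ids)


def cosine_similarity_matrix(E: EmbeddingMatrix) -> SquareMatrix:
    """Pairwise cosine similarities, returned as a unit-diagonal SquareMatrix."""
    V = E.values
    norms = np.linalg.norm(V, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm embedding for item(s): {[E.item_ids[i] for i in zero]}")
    U = V / norms[:, None]
    S = U @ U.T
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    return SquareMatrix(S, E.item_ids)


@dataclass(frozen=True)
class CrossLoadFlag:
    """Descriptive cross-loading screen for one item.

    An item is flagged when its mean similarity to some other scale's items
    meets or exceeds its mean similarity to its own scale mates — the
    similarity-matrix analogue of a cross-loading or jingle-jangle warning.
    """

    item_id: str
    own_scale_mean: float
    best_other_scale: str
    best_other_mean: float
    flagged: bool


def cross_loading_screen(S: SquareMatrix, item_set: ItemSet) -> list[CrossLoadFlag]:
    """Flag items more similar to a foreign scale than to their own.

    Means exclude the item itself; ties between foreign scales are broken by
    scale order in the instrument. Output order follows item order.
    """
    if len(item_set.scales) < 2:
        raise ValueError("cross-loading screen needs at least two scales")
    vals = S.reindex(item_set.item_ids).values if S.axis_ids != item_set.item_ids else S.values
    idx_by_scale = {s: item_set.scale_indices(s) for s in item_set.scales}
    for s, idx in idx_by_scale.items():
        if idx.size < 2:
            raise ValueError(
                f"scale {s!r} has a single item; own-scale mean similarity is undefined"
            )
    out: list[CrossLoadFlag] = []
    for i, item in enumerate(item_set.items):
        own_idx = idx_by_scale[item.scale_id]
        own = float(np.mean(vals[i, own_idx[own_idx != i]]))
        best_scale, best_mean = None, -np.inf
        for s in item_set.scales:
            if s == item.scale_id:
                continue
            m = float(np.mean(vals[i, idx_by_scale[s]]))
            if m > best_mean:  # strict: ties keep the earlier scale
                best_scale, best_mean = s, m
        assert best_scale is not None
        out.append(
            CrossLoadFlag(
                item_id=item.item_id,
                own_scale_mean=own,
                best_other_scale=best_scale,
                best_other_mean=best_mean,
                flagged=best_mean >= own,
            )
        )
    return out


def hash_embedding_provider(dim: int = 16, seed: int = 0) -> Callable[[Sequence[str]], np.ndarray]:
    """Deterministic text-hash embedding provider (testing / offline demos).

    Each text is mapped to a reproducible pseudo-random unit vector seeded by
    (seed, text). Identical texts give identical vectors, so duplicated
    wording shows up as similarity 1 — handy for exercising the pipeline
    without any embedding model.
    """

    def provider(texts: Sequence[str]) -> np.ndarray:
        rows = []
        for t in texts:
            h = abs(hash_text(t, seed)) % (2**31)
            rng = np.random.default_rng(h)
            v = rng.standard_normal(dim)
            rows.append(v / np.linalg.norm(v))
        return np.asarray(rows)

    return provider


def hash_text(text: str, seed: int = 0) -> int:
    """Stable (non-salted) text hash, identical across processes."""
    h = 2166136261 ^ (seed & 0xFFFFFFFF)
    for b in text.encode("utf-8"):
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h
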