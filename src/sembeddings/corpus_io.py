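"""Reading and writing instrument artifacts.

All on-disk artifacts are comma-delimited UTF-8 text with a header row;
item text is quoted so free text round-trips. Item order in the items file
is the canonical axis order for every matrix derived from it.
"""

from __future__ import annotations

import dataclasses
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

#: maximum tolerated asymmetry |M - M.T| when reading a square matrix
ASYMMETRY_TOL = 1e-8
#: symmetry tolerance required of SquareMatrix values
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class Item:
    """A single questionnaire item."""

    item_id: str
    scale_id: str
    text: str
    position: int  # 1-based position within the instrument

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"item {self.item_id!r}: position must be >= 1")


@dataclass(frozen=True)
class ItemSet:
    """An ordered collection of items grouped into scales.

    The item order here is the canonical axis order for all matrices
    (embeddings, similarities, correlations) derived from the instrument.
    ``scales`` lists the distinct scale ids in first-appearance order.
    """

    items: tuple[Item, ...]
    scales: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate item_id(s): {sorted(dupes)}")
        seen: list[str] = []
        for it in self.items:
            if it.scale_id not in seen:
                seen.append(it.scale_id)
        expect = tuple(seen)
        if not self.scales:
            object.__setattr__(self, "scales", expect)
        elif tuple(self.scales) != expect:
            raise ValueError("scales must equal distinct scale_ids in first-appearance order")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def scale_items(self, scale_id: str) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.scale_id == scale_id)

    def scale_indices(self, scale_id: str) -> np.ndarray:
        """Row/column indices of a scale's items in canonical order."""
        return np.array([i for i, it in enumerate(self.items) if it.scale_id == scale_id])

    def subset(self, item_ids: Sequence[str]) -> "ItemSet":
        keep = set(item_ids)
        return ItemSet(tuple(it for it in self.items if it.item_id in keep))

    def text_of(self, item_id: str) -> str:
        for it in self.items:
            if it.item_id == item_id:
                return it.text
        raise KeyError(item_id)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """One embedding vector per item, aligned to an ItemSet's order."""

    values: np.ndarray  # (p, n)
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (items x dimensions)")
        if v.shape[0] != len(self.item_ids):
            raise ValueError("one embedding row per item required")
        norms = np.linalg.norm(v, axis=1)
        zero = np.where(norms == 0)[0]
        if zero.size:
            bad = [self.item_ids[i] for i in zero]
            raise ValueError(f"zero embedding vector(s) for item(s): {bad}")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SquareMatrix:
    """A symmetric p x p matrix with item-id axis labels."""

    values: np.ndarray
    axis_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("matrix must be square")
        if v.shape[0] != len(self.axis_ids):
            raise ValueError("axis_ids length must match matrix dimension")
        if np.max(np.abs(v - v.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError("matrix not symmetric within tolerance")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "axis_ids", tuple(self.axis_ids))

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def submatrix(self, item_ids: Sequence[str]) -> "SquareMatrix":
        pos = {a: i for i, a in enumerate(self.axis_ids)}
        missing = [i for i in item_ids if i not in pos]
        if missing:
            raise KeyError(f"item_ids not on matrix axis: {missing}")
        idx = np.array([pos[i] for i in item_ids])
        return SquareMatrix(self.values[np.ix_(idx, idx)], tuple(item_ids))

    def reindex(self, item_ids: Sequence[str]) -> "SquareMatrix":
        if set(item_ids) != set(self.axis_ids) or len(item_ids) != len(self.axis_ids):
            raise ValueError("reindex ids must be a permutation of axis_ids")
        return self.submatrix(item_ids)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_items(path: str | Path) -> ItemSet:
    """Read an item table (columns item_id, scale_id, text) into an ItemSet.

    Item text is kept verbatim apart from Unicode NFC normalization.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["item_id", "scale_id", "text"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"items file {path}: missing required column {col!r}")
    counts = df["item_id"].value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise ValueError(f"items file {path}: duplicate item_id(s): {sorted(dupes.index)}")
    items = tuple(
        Item(
            item_id=row.item_id,
            scale_id=row.scale_id,
            text=unicodedata.normalize("NFC", row.text),
            position=i + 1,
        )
        for i, row in enumerate(df.itertuples(index=False))
    )
    return ItemSet(items)


def write_items(item_set: ItemSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "item_id": [it.item_id for it in item_set.items],
            "scale_id": [it.scale_id for it in item_set.items],
            "text": [it.text for it in item_set.items],
        }
    )
    df.to_csv(path, index=False)


def read_matrix(path: str | Path, item_set: ItemSet | None = None) -> SquareMatrix:
    """Read a labelled square matrix; reindex to the ItemSet's canonical order.

    Small asymmetries (below 1e-8, e.g. decimal truncation) are repaired by
    averaging with the transpose; anything larger is an error.
    """
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if ids != row_ids:
        raise ValueError(f"matrix file {path}: row and column labels differ")
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"matrix file {path}: non-numeric cell ({exc})") from exc
    if np.isnan(vals).any():
        raise ValueError(f"matrix file {path}: non-numeric or missing cell")
    asym = float(np.max(np.abs(vals - vals.T), initial=0.0))
    if asym > ASYMMETRY_TOL:
        raise ValueError(f"matrix file {path}: asymmetry {asym:.3g} exceeds {ASYMMETRY_TOL:g}")
    vals = (vals + vals.T) / 2.0
    m = SquareMatrix(vals, tuple(ids))
    if item_set is not None:
        if len(ids) != len(item_set):
            raise ValueError(
                f"matrix file {path}: dimension {len(ids)} does not match "
                f"item set of {len(item_set)} items"
            )
        if set(ids) != set(item_set.item_ids):
            raise ValueError(f"matrix file {path}: axis ids do not match item set ids")
        m = m.reindex(item_set.item_ids)
    return m


def write_matrix(m: SquareMatrix, path: str | Path) -> None:
    """Write a full p x p labelled matrix at full float precision."""
    df = pd.DataFrame(m.values, index=list(m.axis_ids), columns=list(m.axis_ids))
    df.to_csv(path, float_format="%.17g")


def read_embeddings(path: str | Path, item_set: ItemSet) -> EmbeddingMatrix:
    """Read an embeddings file: first column item_id, remaining columns numeric."""
    df = pd.read_csv(path)
    if "item_id" not in df.columns:
        raise ValueError(f"embeddings file {path}: missing required column 'item_id'")
    df = df.set_index("item_id")
    missing = [i for i in item_set.item_ids if i not in df.index]
    if missing:
        raise ValueError(f"embeddings file {path}: missing rows for item(s) {missing}")
    df = df.loc[list(item_set.item_ids)]
    return EmbeddingMatrix(df.to_numpy(dtype=float), item_set.item_ids)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(emb.values, index=list(emb.item_ids))
    df.index.name = "item_id"
    df.columns = [f"d{i}" for i in range(emb.dim)]
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(obj: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a report object (CFAFit, MITable, plain dict, ...).

    ``json`` round-trips float fields losslessly; ``csv`` is provided for
    tabular objects (anything exposing ``to_frame()``); ``text`` writes
    ``str(obj)``.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(obj), indent=2), encoding="utf-8")
    elif format == "csv":
        if hasattr(obj, "to_frame"):
            obj.to_frame().to_csv(path, index=False, float_format="%.17g")
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False, float_format="%.17g")
        else:
            raise TypeError(f"object of type {type(obj).__name__} has no tabular form")
    elif format == "text":
        path.write_text(str(obj), encoding="utf-8")
    else:
        raise ValueError(f"unsupported report format {format!r} (use json, csv or text)")


def read_report(path: str | Path) -> Any:
    """Read a JSON report back into plain dict/list structure."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
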