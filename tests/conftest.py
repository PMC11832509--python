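import numpy as np
import pytest
from hypothesis import settings

import sembeddings as se

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def two_scale_items(tmp_path):
    """An 8-item, 2-scale items file on disk."""
    path = tmp_path / "items.csv"
    rows = ["item_id,scale_id,text"]
    for s in ("warmth", "order"):
        for k in range(1, 5):
            rows.append(f'{s}_{k},{s},"I show {s} in way {k}."')
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def clean_instrument():
    """4 scales x 4 items, moderate loadings, no injected misfit."""
    return se.make_instrument(4, 4, seed=11)


@pytest.fixture
def corrupted_instrument():
    """6 scales x 4 items; first scale has two redundant-wording item pairs.

    Two injected residual correlations split the scale into two sub-factors,
    the classic cause of unidimensional misfit.
    """
    return se.make_instrument(
        6,
        4,
        loading_range=(0.5, 0.7),
        injected_pairs=[("s01_i1", "s01_i2", 0.25), ("s01_i3", "s01_i4", 0.25)],
        seed=7,
    )


def random_spec_and_population(rng: np.random.Generator):
    """A random identified CFA (1-2 factors, 4-8 items) and its population matrix."""
    k = rng.integers(1, 3)
    p = int(rng.integers(4, 9))
    if k == 2 and p < 6:
        k = 1
    ids = tuple(f"i{j}" for j in range(p))
    if k == 1:
        spec = se.ModelSpec.single_factor(ids)
        lam_items = {0: list(range(p))}
        phi = np.eye(1)
    else:
        half = p // 2
        loadings = {"F1": ids[:half], "F2": ids[half:]}
        spec = se.ModelSpec(ids, ("F1", "F2"), loadings)
        lam_items = {0: list(range(half)), 1: list(range(half, p))}
        phi = np.array([[1.0, 0.35], [0.35, 1.0]])
    lam_vals = rng.uniform(0.4, 0.85, size=p)
    lam = np.zeros((p, k))
    for f, items in lam_items.items():
        for i in items:
            lam[i, f] = lam_vals[i]
    R = lam @ phi @ lam.T + np.diag(1 - lam_vals**2)
    np.fill_diagonal(R, 1.0)
    truth = {
        f"lambda:{ids[i]}:{spec.factors[f]}": lam[i, f]
        for f in range(k)
        for i in lam_items[f]
    }
    if k == 2:
        truth["phi:F1:F2"] = 0.35
    return spec, se.SquareMatrix(R, ids), truth


def block_two_factor(phi: float, lam: float = 0.7, n_per: int = 4) -> se.SquareMatrix:
    """Population matrix of two n_per-item scales with factor correlation phi."""
    p = 2 * n_per
    lam_vec = np.full(p, lam)
    load = np.zeros((p, 2))
    load[:n_per, 0] = lam
    load[n_per:, 1] = lam
    Phi = np.array([[1.0, phi], [phi, 1.0]])
    R = load @ Phi @ load.T + np.diag(1 - lam_vec**2)
    np.fill_diagonal(R, 1.0)
    ids = tuple(f"a{i}" for i in range(n_per)) + tuple(f"b{i}" for i in range(n_per))
    return se.SquareMatrix(R, ids)
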