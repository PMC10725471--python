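"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library's own code paths: rigid
superposition via Horn's quaternion eigenvalue method, triangle area
via the cross product, and pharmacophore matching via exhaustive
enumeration over all injective kind-compatible feature mappings.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import settings

from baxdm import pharmacophore as ph
from baxdm import synthetic_data as syn

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Quaternion (Horn) superposition oracle


def horn_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation of Q onto P via the quaternion method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    S = Qc.T @ Pc  # S[i, j] = sum_k Qc[k, i] * Pc[k, j]
    N = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, -1]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# Exhaustive pharmacophore-matching oracle


def brute_force_mappings(
    model: ph.PharmacophoreModel,
    conformer: ph.LigandConformer,
    tolerance: float,
    min_size: int,
) -> set[tuple[tuple[int, int], ...]]:
    """All injective kind-compatible distance-consistent mappings."""
    mpos = model.positions
    lpos = conformer.positions
    nm, nl = len(model.features), len(conformer.features)
    dm = np.linalg.norm(mpos[:, None] - mpos[None, :], axis=-1)
    dl = np.linalg.norm(lpos[:, None] - lpos[None, :], axis=-1)
    out = set()
    for k in range(min_size, min(nm, nl) + 1):
        for msub in combinations(range(nm), k):
            for lperm in permutations(range(nl), k):
                if any(
                    model.features[i].kind != conformer.features[j].kind
                    for i, j in zip(msub, lperm)
                ):
                    continue
                if any(
                    abs(dm[msub[a], msub[b]] - dl[lperm[a], lperm[b]]) > 2 * tolerance
                    for a in range(k)
                    for b in range(a + 1, k)
                ):
                    continue
                out.add(tuple(zip(msub, lperm)))
    return out


def brute_force_match(
    model: ph.PharmacophoreModel,
    conformer: ph.LigandConformer,
    tolerance: float,
    rule: ph.CompositionRule,
) -> tuple[bool, int, float]:
    """(passed, n_matched, rmsd) by exhaustive search + quaternion fits."""
    mpos = model.positions
    lpos = conformer.positions
    best = None
    for mapping in brute_force_mappings(model, conformer, tolerance, rule.min_matched):
        kinds = [model.features[i].kind for i, _ in mapping]
        if not rule.satisfied(kinds):
            continue
        mi = [p[0] for p in mapping]
        li = [p[1] for p in mapping]
        R, t, rmsd = horn_superpose(mpos[mi], lpos[li])
        aligned = lpos[li] @ R.T + t
        if np.any(np.linalg.norm(aligned - mpos[mi], axis=1) > tolerance + 1e-12):
            continue
        key = (-len(mapping), rmsd)
        if best is None or key < best:
            best = key
    if best is None:
        return False, 0, float("inf")
    return True, -best[0], best[1]


def random_instance(
    rng: np.random.Generator, n_model: int, n_ligand: int, box: float = 8.0
) -> tuple[ph.PharmacophoreModel, ph.LigandConformer]:
    """Random small model/conformer pair with mixed feature kinds."""
    kinds = list(ph.FeatureKind)
    mfeat = [
        ph.FeaturePoint(kinds[int(rng.integers(len(kinds)))], rng.uniform(0, box, 3))
        for _ in range(n_model)
    ]
    lfeat = [
        ph.FeaturePoint(kinds[int(rng.integers(len(kinds)))], rng.uniform(0, box, 3))
        for _ in range(n_ligand)
    ]
    model = ph.PharmacophoreModel(mfeat, tolerance=2.0)
    return model, ph.LigandConformer("rand", lfeat)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def toy_structure():
    return syn.toy_fold()


@pytest.fixture(scope="session")
def toy_model(toy_structure):
    return ph.build_model(toy_structure)
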