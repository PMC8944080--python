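"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force — enumerating
all global alignments, or all basic feasible solutions of a small LP — so the
implementation under test is never checked against itself.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from indolekit.bioprospecting import Scoring


# ---------------------------------------------------------------------------
# brute-force global alignment oracle (all alignments, exponential)
# ---------------------------------------------------------------------------

def brute_force_align_score(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Optimal global alignment score by exhaustive recursion (len <= ~8)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, scoring.gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, scoring.gap + rec(i, j + 1))
        return best

    return rec(0, 0)


# ---------------------------------------------------------------------------
# brute-force LP vertex enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_vertex_optimum(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                             c: np.ndarray) -> float:
    """max c.v over the polytope {S v = 0, lb <= v <= ub} by vertex enumeration.

    At any vertex at least n - rank(S) coordinates sit on a bound; fix every
    such subset at every bound combination, solve the remaining square-ish
    system, and keep feasible solutions.  Exponential — small toys only.
    """
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    best = -np.inf
    idx = range(n)
    for fixed in itertools.combinations(idx, k):
        free = [j for j in idx if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue  # fixed set does not determine a unique point
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            best = max(best, float(c @ v))
    return best


def model_vertex_optimum(model, objective: str) -> float:
    """Vertex-enumeration FBA optimum of a small model."""
    S, _, rids = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(rids))
    c[rids.index(objective)] = 1.0
    return enumerate_vertex_optimum(S, lb, ub, c)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_families():
    """Small planted-structure family set with truth labels (deterministic)."""
    from indolekit.synthetic_data import FamilySpec, generate_sequence_families
    spec = FamilySpec(n_families=3, members_per_family=5, seed_length_mean=40,
                      seed_length_sd=3, within_family_identity=0.9,
                      between_family_identity_max=0.4, rng_seed=1)
    records, labels = generate_sequence_families(spec)
    return spec, records, labels


@pytest.fixture(scope="session")
def planted_identity_matrix(planted_families):
    from indolekit.bioprospecting import identity_matrix
    _, records, _ = planted_families
    return identity_matrix(records)
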