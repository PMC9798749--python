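"""Shared fixtures: small planted factor structures and cohorts."""

from itertools import permutations

import numpy as np
import pytest

from expofactor.synthetic import (OutcomeSpec, default_generative_spec,
                                  simulate_cohort)


def make_oblique_population(loadings: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Population correlation matrix from a pattern matrix and Phi."""
    R = loadings @ phi @ loadings.T
    np.fill_diagonal(R, 1.0)
    return R


def align_columns(truth: np.ndarray, estimate: np.ndarray):
    """Best column permutation/sign of `estimate` against `truth`.

    Returns (aligned estimate, perm, signs).  Brute force over k! x 2^k;
    only for small k.
    """
    k = truth.shape[1]
    best = None
    for perm in permutations(range(k)):
        for bits in np.ndindex(*(2,) * k):
            s = np.array([1.0 if b == 0 else -1.0 for b in bits])
            cand = estimate[:, perm] * s
            err = np.abs(truth - cand).max()
            if best is None or err < best[0]:
                best = (err, perm, s)
    _, perm, s = best
    return estimate[:, perm] * s, perm, s


def tucker_congruence(truth: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """Per-column Tucker congruence after best alignment."""
    aligned, _, _ = align_columns(truth, estimate)
    num = np.sum(truth * aligned, axis=0)
    den = np.sqrt(np.sum(truth**2, axis=0) * np.sum(aligned**2, axis=0))
    return num / den


@pytest.fixture(scope="session")
def three_factor_population():
    """Planted oblique 3-factor structure (simple structure)."""
    p, k = 15, 3
    L = np.zeros((p, k))
    mains = [0.7, 0.6, 0.65, 0.55, 0.5]
    for j in range(k):
        L[j * 5:(j + 1) * 5, j] = mains
    phi = np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.25], [0.2, 0.25, 1.0]])
    return L, phi, make_oblique_population(L, phi)


@pytest.fixture(scope="session")
def complex_structure_population():
    """Planted 3-factor structure with two true cross-loadings of 0.35."""
    p, k = 18, 3
    L = np.zeros((p, k))
    mains = [0.7, 0.6, 0.65, 0.55, 0.5, 0.6]
    for j in range(k):
        L[j * 6:(j + 1) * 6, j] = mains
    L[1, 1] = 0.35
    L[7, 2] = 0.35
    phi = np.full((k, k), 0.3)
    np.fill_diagonal(phi, 1.0)
    return L, phi, make_oblique_population(L, phi)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cohort, 4 specific factors, n=3000 — reused across tests."""
    spec = default_generative_spec(n_subjects=3000, n_specific=4,
                                   items_per_factor=6, seed=42,
                                   missing_rate=0.0)
    ospec = OutcomeSpec(beta_specific=OutcomeSpec().beta_specific[:4], seed=42)
    return simulate_cohort(spec, ospec)
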