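"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities with naive, loop-based
code (nested sums over contingency cells, explicit set algebra, exact
combinatorial tail sums) so they stay independent of the vectorized
implementation paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirmod import ExpressionMatrix, SimulationConfig, simulate_dataset


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def equal_frequency_labels(x, B):
    """Reference equal-frequency binning: split the argsort into B runs."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=int)
    for b, chunk in enumerate(np.array_split(order, B)):
        for i in chunk:
            labels[i] = b
    return labels


def brute_force_mi(d, r, B):
    """Plug-in MI by explicit nested loops over the B×B table (nats)."""
    ld = equal_frequency_labels(d, B)
    lr = equal_frequency_labels(r, B)
    n = len(ld)
    mi = 0.0
    for i in range(B):
        for j in range(B):
            nij = int(np.sum((ld == i) & (lr == j)))
            if nij == 0:
                continue
            pij = nij / n
            pi = float(np.sum(ld == i)) / n
            pj = float(np.sum(lr == j)) / n
            mi += pij * math.log(pij / (pi * pj))
    return mi


def brute_force_cmi(d, r, m, B, S):
    """Stratified conditional MI via the loop-based MI oracle."""
    lm = equal_frequency_labels(m, S)
    n = len(lm)
    total = 0.0
    for s in range(S):
        idx = np.flatnonzero(lm == s)
        total += (len(idx) / n) * brute_force_mi(
            np.asarray(d)[idx], np.asarray(r)[idx], B
        )
    return total


def hypergeom_tail_brute(k, M, n1, n2):
    """P(X >= k) for shared targets, by explicit combinatorial sum."""
    total = 0.0
    for x in range(k, min(n1, n2) + 1):
        total += (
            math.comb(n1, x) * math.comb(M - n1, n2 - x) / math.comb(M, n2)
        )
    return total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression(rng):
    """A modest random expression matrix (20 features × 30 samples)."""
    return ExpressionMatrix(
        [f"miR-{i:02d}" for i in range(20)],
        [f"S{j:02d}" for j in range(30)],
        rng.standard_normal((20, 30)),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small planted cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_mirnas=30,
        n_mrnas=40,
        n_true_triplets=4,
        n_null_triplets=6,
        hub_triplets=3,
        n_decoy_edges=5,
        seed=7,
    )
    return simulate_dataset(cfg)
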