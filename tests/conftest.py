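"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: the Fisher
tail is enumerated with exact integer binomials, Benjamini-Hochberg is
re-derived from the step-up definition, and the paired t statistic comes
straight from the textbook formula.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from trapscreen import GeneModel, ScreenSimConfig, simulate_screen


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def hypergeom_tail_oracle(k_sel: int, n_sel: int, k_ctl: int, n_ctl: int) -> float:
    """One-sided Fisher p by exhaustive upper-tail enumeration with exact
    integer arithmetic: P(X >= k_sel) for X hypergeometric with population
    n_sel + n_ctl, K = k_sel + k_ctl successes, n_sel draws."""
    K = k_sel + k_ctl
    n = n_sel + n_ctl
    num = 0
    for j in range(k_sel, min(n_sel, K) + 1):
        if K - j > n_ctl:
            continue
        num += math.comb(n_sel, j) * math.comb(n_ctl, K - j)
    return num / math.comb(n, K)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) n / j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        q[order[i]] = running
    return q


def paired_t_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t from the direct formula: t = mean(d) / (sd(d)/sqrt(n))."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least squares (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    slope = (xc * (y - y.mean())).sum() / (xc * xc).sum()
    return slope, y.mean() - slope * x.mean()


def median_effect_points(m: float, Dm: float, doses) -> list[tuple[float, float]]:
    """Noiseless (dose, fa) pairs from fa/(1-fa) = (D/Dm)^m."""
    return [(d, 1.0 / (1.0 + (Dm / d) ** m)) for d in doses]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("geneA", "chr1", 100, 500, "+"),
        GeneModel("geneB", "chr1", 700, 900, "-"),
    ]


@pytest.fixture(scope="session")
def small_screen():
    """A small but complete simulated screen with one spiked resistance
    gene, shared across mapping and round-trip tests."""
    cfg = ScreenSimConfig(
        genome_length=5_000,
        n_genes=8,
        n_cells=300,
        resistance_genes=("G000",),
        p_survive_resistant=0.95,
        p_survive_background=0.02,
        readcount_log_mean=1.0,
        readcount_log_sd=0.8,
        read_length=40,
        seed=42,
    )
    return simulate_screen(cfg)
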