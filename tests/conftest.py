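"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pytest

from oligotrace.coloc import ColocImageSet
from oligotrace.steps import StepCountTable


def enumeration_pmf(n: int, p: float, k: int) -> float:
    """Detection-conditional step-count probability by brute-force
    enumeration of all 2^n subunit on/off configurations."""
    visible = 0.0
    at_k = 0.0
    for cfg in product((0, 1), repeat=n):
        pr = 1.0
        for bit in cfg:
            pr *= p if bit else 1.0 - p
        lit = sum(cfg)
        if lit >= 1:
            visible += pr
            if lit == k:
                at_k += pr
    return at_k / visible


def grid_search_p(table: StepCountTable, n: int, step: float = 1e-4) -> float:
    """Dense grid-search ML estimate of p; independent of the package fitter."""
    ks = np.arange(1, n + 1)
    obs = np.array([table.counts.get(int(k), 0) for k in ks], dtype=float)
    grid = np.arange(step, 1.0 + step / 2, step)
    best_p, best_ll = grid[0], -np.inf
    for p in grid:
        pmf = np.array([enumeration_pmf(n, p, int(k)) for k in ks])
        with np.errstate(divide="ignore"):
            lp = np.log(pmf)
        if np.any(np.isneginf(lp) & (obs > 0)):
            continue
        ll = float(np.sum(obs * np.where(obs > 0, lp, 0.0)))
        if ll > best_ll:
            best_ll, best_p = ll, float(p)
    return best_p


def four_pixel_coloc(a, b) -> ColocImageSet:
    """A 1x4 two-channel image set whose coefficients are hand-computable."""
    return ColocImageSet(
        channels={"A": np.array([a], dtype=float), "B": np.array([b], dtype=float)},
        cell_mask=np.ones((1, 4), dtype=bool),
    )


@pytest.fixture
def dimer_table() -> StepCountTable:
    return StepCountTable.from_counts({1: 248, 2: 252})
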