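"""Shared fixtures and independent oracles for the stopflux test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from stopflux import synthetic_data as sd


def power_iteration_stationary(rates: np.ndarray, tol: float = 1e-14,
                               max_iter: int = 2_000_000) -> np.ndarray:
    """Stationary distribution by long-run iteration of the per-generation
    transition matrix P = I + Q*dt. Independent of the linear-solve path."""
    R = np.array(rates, dtype=float)
    np.fill_diagonal(R, 0.0)
    Q = R - np.diag(R.sum(axis=1))
    dt = 0.5 / np.abs(np.diag(Q)).max()
    P = np.eye(R.shape[0]) + Q * dt
    pi = np.full(R.shape[0], 1.0 / R.shape[0])
    for _ in range(max_iter):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < tol:
            return nxt / nxt.sum()
        pi = nxt
    raise RuntimeError("power iteration did not converge")


def asr_enumeration_oracle(codes: np.ndarray, pi: np.ndarray, kappa: float,
                           ts) -> np.ndarray:
    """Brute-force marginal posteriors: per column, sum over the 4 internal
    states with explicitly exponentiated HKY transition matrices."""
    piA, piC, piG, piT = pi
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    Ps = [expm(Q * (t / mu)) for t in ts]
    L = codes.shape[1]
    post = np.empty((L, 4))
    for col in range(L):
        for x in range(4):
            p = pi[x]
            for tip in range(3):
                b = codes[tip, col]
                if b != 4:
                    p *= Ps[tip][x, b]
            post[col, x] = p
        post[col] /= post[col].sum()
    return post


def two_state_stationary(r_ab: float, r_ba: float, tol: float = 1e-15) -> float:
    """Long-run fraction of state B in the two-state chain A<->B."""
    P = np.array([[1 - r_ab, r_ab], [r_ba, 1 - r_ba]])
    pi = np.array([0.5, 0.5])
    for _ in range(10_000_000):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < tol:
            break
        pi = nxt
    return float(pi[1] / pi.sum())


@pytest.fixture(scope="session")
def small_bundle():
    """A deterministic 60-gene synthetic study used across modules."""
    cfg = sd.SyntheticConfig(seed=7, n_genes=60, n_mutations=6000)
    return sd.generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    sd.write_bundle(small_bundle, d)
    return d
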