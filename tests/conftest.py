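"""Shared fixtures: small synthetic cohorts and helper generators."""

from dataclasses import replace

import numpy as np
import pytest

from erpkit import synth


@pytest.fixture(scope="session")
def paradigm_small():
    """Short sessions for fast unit tests (timing structure preserved)."""
    return synth.ParadigmSpec(n_sessions=2, trials_per_session=10)


@pytest.fixture(scope="session")
def quiet_effects():
    """No noise, no jitter, no blinks: deterministic programmed waveforms."""
    return replace(synth.GroupEffectSpec(), noise_sd_uv=0.0,
                   latency_jitter_sd_ms=0.0, amplitude_jitter_sd_uv=0.0,
                   eog_rate_per_min=0.0)


def make_mixture(seed: int, dists, n: int = 20000):
    """Random square mixture of named iid sources; returns (X, M, S)."""
    rng = np.random.default_rng(seed)
    k = len(dists)
    S = []
    for d in dists:
        if d == "laplace":
            S.append(rng.laplace(size=n))
        elif d == "uniform":
            S.append(rng.uniform(-1, 1, n))
        elif d == "bimodal":
            S.append(rng.normal(size=n) * 0.3 + rng.choice([-1.0, 1.0], n))
        else:
            raise ValueError(d)
    S = np.array(S)
    M = rng.uniform(-1, 1, (k, k))
    while abs(np.linalg.det(M)) < 0.1:
        M = rng.uniform(-1, 1, (k, k))
    return M @ S, M, S


def amari_oracle(P):
    """Loop-based Amari index, independent of the package implementation."""
    P = np.abs(np.asarray(P, dtype=float))
    k = P.shape[0]
    total = 0.0
    for i in range(k):
        total += sum(P[i, j] for j in range(k)) / max(P[i]) - 1.0
    for j in range(k):
        total += sum(P[i, j] for i in range(k)) / max(P[:, j]) - 1.0
    return total / (2 * k * (k - 1))
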