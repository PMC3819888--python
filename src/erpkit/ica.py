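"""Extended Infomax ICA with EOG-based artifact rejection.

The unmixing matrix is learned by the natural-gradient extended Infomax
rule

    dW  = [I - K tanh(u) u^T - u u^T] W,      W <- W + mu * dW

on PCA-whitened data, where K = diag(k_i) switches each source between a
super-Gaussian (k_i = +1) and sub-Gaussian (k_i = -1) nonlinearity. The
switching signs are re-estimated every sweep from the empirical kurtosis
sign of the recovered sources,

    k_i = sign( E[u_i^4] / E[u_i^2]^2 - 3 ).

Updates run over mini-batches in randomized order; convergence is
declared when the Frobenius norm of the per-sweep weight change falls
below ``tol``. The full stored transform is W_full = W @ whitening, and
``A = pinv(W_full)`` maps sources back to (centered) channel space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_DIVERGENCE_GUARD = 1e8


@dataclass
class UnmixingResult:
    W: np.ndarray              # unmixing in whitened space (k x k)
    whitening: np.ndarray      # whitening transform (k x L)
    mean: np.ndarray           # per-channel mean removed before whitening
    W_full: np.ndarray         # W @ whitening (k x L)
    A: np.ndarray              # pinv(W_full): channels x sources
    sources: np.ndarray        # k x n_samples
    K_diag: np.ndarray         # per-source switching signs, +/-1
    iterations: int
    converged: bool
    mu: float                  # final step size after any halving

    @property
    def n_sources(self) -> int:
        return self.W_full.shape[0]


@dataclass
class ArtifactReport:
    removed: list              # flagged source indices
    correlations: np.ndarray   # n_sources x n_eog, Pearson r
    threshold: float


def kurtosis_sign(u: np.ndarray) -> int:
    """Switching sign from the empirical excess kurtosis of one source.

    Returns +1 for super-Gaussian, -1 for sub-Gaussian; exactly zero
    excess kurtosis maps to +1 (documented tie-break).
    """
    u = np.asarray(u, dtype=float)
    m2 = np.mean(u ** 2)
    if m2 == 0 or np.ptp(u) == 0:
        raise ValueError("kurtosis sign undefined for a constant source")
    excess = np.mean(u ** 4) / m2 ** 2 - 3.0
    return -1 if excess < 0 else 1


def _kurtosis_signs(U: np.ndarray) -> np.ndarray:
    U2 = U * U
    m2 = np.mean(U2, axis=1)
    excess = np.mean(U2 * U2, axis=1) / (m2 * m2) - 3.0
    return np.where(excess < 0, -1.0, 1.0)


def _stability_signs(U: np.ndarray) -> np.ndarray:
    """Switching signs from the nonlinearity-stability criterion,
    sign(E[sech^2 u] E[u^2] - E[u tanh u]).

    This is the rigorous form of the super/sub-Gaussian switch (the
    kurtosis sign is its moment simplification); used during learning
    because raw kurtosis signs admit self-consistent mislabelings of
    still-mixed source pairs that freeze the separation.
    """
    th = np.tanh(U)
    crit = (np.mean(1.0 - th * th, axis=1) * np.mean(U * U, axis=1) -
            np.mean(th * U, axis=1))
    return np.where(crit < 0, -1.0, 1.0)


def _whiten(X: np.ndarray, n_components: int):
    cov = (X @ X.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[n_components - 1] <= 1e-12 * max(evals[0], 1e-300):
        # rank deficient: name the most redundant channel pair
        sd = np.sqrt(np.diag(cov))
        sd[sd == 0] = 1.0
        corr = cov / np.outer(sd, sd)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"input is rank deficient: channel {j} is (nearly) linearly "
            f"dependent on channel {i} (|r| = {abs(corr[i, j]):.6f})")
    wh = (evecs[:, :n_components] / np.sqrt(evals[:n_components])).T
    return wh


def fit_unmixing(X: np.ndarray, n_components: Optional[int] = None,
                 mu: float = 0.01, max_iter: int = 512, tol: float = 1e-6,
                 seed: Optional[int] = None,
                 block_size: int = 512) -> UnmixingResult:
    """Learn the extended-Infomax unmixing of a channels x samples matrix.

    Raises ``ValueError`` on rank-deficient input (naming the offending
    channel pair) and ``FloatingPointError`` if the weights diverge even
    after repeated step-size halving.
    """
    X = np.asarray(X, dtype=float)
    L, n = X.shape
    if n_components is None:
        n_components = L
    if n_components > L:
        raise ValueError("n_components cannot exceed the channel count")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    wh = _whiten(Xc, n_components)
    Xw = wh @ Xc
    k = n_components

    rng = np.random.default_rng(seed)
    # switching signs are re-estimated each sweep; a fixed subsample is
    # statistically ample for a sign and keeps the sweep cost flat
    sub = rng.choice(n, size=min(n, 8192), replace=False) if n > 8192 \
        else slice(None)
    W = np.eye(k)
    I = np.eye(k)
    ksigns = np.ones(k)
    converged = False
    sweeps = 0
    mu_cur = mu
    restarts = 0
    delta_prev = None
    while sweeps < max_iter:
        W_prev = W.copy()
        Xp = Xw[:, rng.permutation(n)]
        bad = False
        for start in range(0, n - block_size + 1, block_size):
            xb = Xp[:, start:start + block_size]
            u = W @ xb
            y = ksigns[:, None] * np.tanh(u)
            dW = (I - (y @ u.T + u @ u.T) / xb.shape[1]) @ W
            W = W + mu_cur * dW
            if not np.all(np.isfinite(W)) or \
                    np.linalg.norm(W) > _DIVERGENCE_GUARD:
                bad = True
                break
        if bad:
            restarts += 1
            if restarts > 20:
                raise FloatingPointError(
                    "extended Infomax diverged repeatedly; "
                    f"try a step size smaller than {mu_cur:g}")
            mu_cur /= 2.0
            W = np.eye(k)
            ksigns = np.ones(k)
            continue
        sweeps += 1
        ksigns = _stability_signs(W @ Xw[:, sub])
        delta = W - W_prev
        if np.linalg.norm(delta) < tol:
            converged = True
            break
        # anneal the step when successive sweep updates change direction
        # sharply (oscillation around the optimum)
        if delta_prev is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(delta_prev)
            if denom > 0 and np.sum(delta * delta_prev) / denom < 0.5:
                mu_cur *= 0.95
        delta_prev = delta

    W_full = W @ wh
    sources = W_full @ Xc
    return UnmixingResult(
        W=W, whitening=wh, mean=mean, W_full=W_full,
        A=np.linalg.pinv(W_full), sources=sources,
        K_diag=_kurtosis_signs(sources).astype(int),
        iterations=sweeps, converged=converged, mu=mu_cur)


def identify_artifact_components(result: UnmixingResult, eog: np.ndarray,
                                 threshold: float = 0.6) -> ArtifactReport:
    """Flag sources whose |Pearson r| with any EOG channel >= threshold."""
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eog.shape[1] != result.sources.shape[1]:
        raise ValueError("EOG signals must be time-aligned with the sources")
    sd = eog.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance EOG channel")
    S = result.sources
    Sc = S - S.mean(axis=1, keepdims=True)
    Ec = eog - eog.mean(axis=1, keepdims=True)
    num = Sc @ Ec.T
    denom = np.outer(np.linalg.norm(Sc, axis=1), np.linalg.norm(Ec, axis=1))
    denom[denom == 0] = np.inf
    corr = num / denom
    removed = [int(i) for i in
               np.nonzero(np.max(np.abs(corr), axis=1) >= threshold)[0]]
    return ArtifactReport(removed=removed, correlations=corr,
                          threshold=threshold)


def backproject(result: UnmixingResult,
                keep: Sequence[int]) -> np.ndarray:
    """Reconstruct (centered) channel data from a subset of sources."""
    keep = sorted(set(int(i) for i in keep))
    if not keep:
        raise ValueError("keep set must not be empty")
    if keep[-1] >= result.n_sources or keep[0] < 0:
        raise ValueError("keep contains an out-of-range source index")
    return result.A[:, keep] @ result.sources[keep]


def amari_index(P: np.ndarray) -> float:
    """Normalized Amari separation index of a permutation-like matrix.

    ``P = W_full @ M`` for an estimated unmixing ``W_full`` and true
    mixing ``M``; 0 means perfect separation up to permutation and
    scaling, 1 is the worst case.
    """
    P = np.abs(np.asarray(P, dtype=float))
    k = P.shape[0]
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * k * (k - 1)))
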