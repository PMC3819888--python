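"""Orthogonal empirical mode decomposition (OEMD).

Classical EMD sifting extracts intrinsic mode functions (IMFs) g_o1,
g_o2, ... by iteratively removing the mean of cubic-spline envelopes
through the local extrema. The raw IMFs are not mutually orthogonal,
which leaks energy between modes; here each newly sifted IMF is
orthogonalized against every previously accepted IMF,

    g_j = g_oj - sum_{k<j} beta_jk g_k,
    beta_jk = <g_k, g_oj> / <g_k, g_k>,

the Gram-Schmidt generalization of the two-mode orthogonalization with
beta_21. Because g_j differs from g_oj, reconstruction coefficients
c_k = 1 + sum_{j>k} beta_jk are carried along so that

    f(t) = sum_k c_k g_k(t) + r(t)

holds to machine precision for every decomposition.

Sifting details: envelopes are cubic splines through the extrema with a
mirror-symmetric boundary extension of two extrema per side; the sift
stops on a Cauchy-type SD criterion (threshold 0.2) or after 10
iterations per IMF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

SD_THRESHOLD = 0.2
MAX_SIFT_ITER = 10


@dataclass
class IMFSet:
    """Orthogonalized IMFs plus residue and reconstruction bookkeeping."""

    imfs: List[np.ndarray]        # orthogonal IMFs g_j
    residue: np.ndarray
    recon_coeffs: np.ndarray      # c_j: f = sum c_j g_j + residue
    betas: np.ndarray             # lower-triangular orthogonalization coeffs
    signal: np.ndarray            # the decomposed input (for invariants)

    @property
    def M(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c, g in zip(self.recon_coeffs, self.imfs):
            out += c * g
        return out


@dataclass
class ImfSelection:
    index: int
    used_fallback: bool
    theta_fractions: np.ndarray
    has_peak: np.ndarray


def _local_extrema(x: np.ndarray):
    """Indices of local maxima and minima, with plateau handling."""
    d = np.sign(np.diff(x))
    nz = np.nonzero(d)[0]
    if len(nz) < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = d[nz]
    turn = np.nonzero(s[:-1] != s[1:])[0]
    # extremum sits at the end of the run that precedes the sign change
    idx = nz[turn] + 1
    maxima = idx[s[turn] > 0]
    minima = idx[s[turn] < 0]
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through (idx, x[idx]) with mirrored ends."""
    t = idx.astype(float)
    v = x[idx]
    n_ext = min(2, len(idx))
    t_pre = -t[:n_ext][::-1]
    v_pre = v[:n_ext][::-1]
    t_post = 2 * (n - 1.0) - t[-n_ext:][::-1]
    v_post = v[-n_ext:][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], vv[keep])(np.arange(n))


@dataclass
class SiftResult:
    imf: Optional[np.ndarray]
    residue: np.ndarray
    is_residue: bool = False


def sift_one_imf(signal: np.ndarray,
                 sd_threshold: float = SD_THRESHOLD,
                 max_sift_iter: int = MAX_SIFT_ITER) -> SiftResult:
    """Extract the fastest oscillatory mode of ``signal`` by sifting.

    A signal with fewer than two maxima and two minima carries no
    oscillation: it is returned unchanged as a residue (``is_residue``
    set), which is the caller's signal to stop decomposing.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise ValueError("signal too short to sift (need >= 8 samples)")
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return SiftResult(imf=None, residue=x.copy(), is_residue=True)
    n = x.size
    h = x.copy()
    for _ in range(max_sift_iter):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
        h_new = h - mean_env
        denom = float(np.sum(h ** 2))
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_threshold:
            break
    return SiftResult(imf=h, residue=x - h, is_residue=False)


def orthogonal_coefficient(g_prev: np.ndarray, g_new: np.ndarray) -> float:
    """Projection coefficient beta = <g_prev, g_new> / <g_prev, g_prev>."""
    g_prev = np.asarray(g_prev, dtype=float)
    g_new = np.asarray(g_new, dtype=float)
    denom = float(np.dot(g_prev, g_prev))
    if denom == 0:
        raise ValueError("cannot orthogonalize against a zero-norm series")
    return float(np.dot(g_prev, g_new) / denom)


def decompose(signal: np.ndarray, max_imfs: int = 10,
              sd_threshold: float = SD_THRESHOLD,
              max_sift_iter: int = MAX_SIFT_ITER) -> IMFSet:
    """Full OEMD of a series: sift, orthogonalize, track reconstruction.

    Stops at ``max_imfs`` or when the running residue carries no further
    oscillation. Orthogonalization uses two passes of modified
    Gram-Schmidt so pairwise normalized inner products stay at machine
    precision even for ill-conditioned mode sets.
    """
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("cannot decompose a constant signal")
    imfs: List[np.ndarray] = []
    beta_rows: List[np.ndarray] = []
    dropped: List[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        res = sift_one_imf(residue, sd_threshold, max_sift_iter)
        if res.is_residue:
            break
        g_o = res.imf
        residue = residue - g_o
        g = g_o.copy()
        beta = np.zeros(len(imfs))
        for _ in range(2):  # MGS with re-orthogonalization
            for k, gk in enumerate(imfs):
                b = np.dot(gk, g) / np.dot(gk, gk)
                g = g - b * gk
                beta[k] += b
        if np.linalg.norm(g) < 1e-12 * np.linalg.norm(x):
            # degenerate mode: fold it whole into the residue so the
            # reconstruction identity is preserved
            dropped.append(g_o)
            continue
        imfs.append(g)
        beta_rows.append(beta)

    M = len(imfs)
    betas = np.zeros((M, M))
    for j, row in enumerate(beta_rows):
        betas[j, : len(row)] = row
    coeffs = np.ones(M)
    for j in range(M):
        for k in range(j):
            coeffs[k] += betas[j, k]
    for d in dropped:
        residue = residue + d
    return IMFSet(imfs=imfs, residue=residue, recon_coeffs=coeffs,
                  betas=betas, signal=x)


def _theta_fraction(series: np.ndarray, fs: float, band) -> float:
    f, p = periodogram(series, fs=fs)
    total = p.sum()
    if total == 0:
        return 0.0
    in_band = (f >= band[0]) & (f < band[1])
    return float(p[in_band].sum() / total)


def select_imf_of_interest(imfset: IMFSet, fs: float,
                           epoch_zero: Union[int, Sequence[int]],
                           window_ms=(200.0, 450.0),
                           theta_band=(4.0, 8.0),
                           post_ms: float = 800.0) -> ImfSelection:
    """Pick the task-relevant IMF: theta-dominant with a peak in-window.

    Candidates are IMFs whose event-locked average (over the onset
    sample(s) in ``epoch_zero``) has a local maximum between
    ``window_ms`` after onset; among candidates the one with the largest
    fraction of spectral energy inside ``theta_band`` wins. If no IMF
    has such a peak the pure theta-fraction maximizer is returned with
    ``used_fallback`` set.
    """
    if imfset.M == 0:
        raise ValueError("empty IMF set")
    onsets = np.atleast_1d(np.asarray(epoch_zero, dtype=int))
    n = imfset.signal.size
    n_post = int(round(post_ms / 1000.0 * fs))
    w0 = int(round(window_ms[0] / 1000.0 * fs))
    w1 = int(round(window_ms[1] / 1000.0 * fs))
    if w1 >= n_post or w0 < 0:
        raise ValueError("peak window must lie inside the epoch")

    fractions = np.empty(imfset.M)
    has_peak = np.zeros(imfset.M, dtype=bool)
    for j in range(imfset.M):
        contrib = imfset.recon_coeffs[j] * imfset.imfs[j]
        fractions[j] = _theta_fraction(contrib, fs, theta_band)
        segs = [contrib[o:o + n_post] for o in onsets
                if 0 <= o and o + n_post <= n]
        if not segs:
            continue
        avg = np.mean(segs, axis=0)
        inner = avg[max(w0, 1):min(w1 + 1, len(avg) - 1)]
        if inner.size == 0:
            continue
        left = avg[max(w0, 1) - 1:min(w1 + 1, len(avg) - 1) - 1]
        right = avg[max(w0, 1) + 1:min(w1 + 1, len(avg) - 1) + 1]
        has_peak[j] = bool(np.any((inner >= left) & (inner > right)))

    if np.any(has_peak):
        scores = np.where(has_peak, fractions, -np.inf)
        return ImfSelection(index=int(np.argmax(scores)),
                            used_fallback=False,
                            theta_fractions=fractions, has_peak=has_peak)
    return ImfSelection(index=int(np.argmax(fractions)), used_fallback=True,
                        theta_fractions=fractions, has_peak=has_peak)
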