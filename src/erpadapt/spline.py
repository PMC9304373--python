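"""Spherical spline interpolation of scalp potentials.

Bad channels are reconstructed from good ones with spline basis functions on
the unit sphere (Perrin-style).  The spline kernel is

    g(x) = (1 / 4*pi) * sum_{l=1}^{L} (2l + 1) / (l (l+1))**m  P_l(x)

with ``x`` the cosine of the angle between electrode positions, ``P_l`` the
Legendre polynomials, stiffness order ``m`` (default 4) and the series
truncated once terms fall below a tolerance (default 1e-10, cap 50 terms).
A small diagonal regularization stabilizes the linear solve.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spline_kernel", "interpolation_matrix", "interpolate_channels"]


def _legendre_weights(m: int, tol: float, max_terms: int) -> np.ndarray:
    """Series weights (2l+1)/(l(l+1))^m for l = 1..L, truncated at ``tol``."""
    ls = np.arange(1, max_terms + 1, dtype=float)
    w = (2.0 * ls + 1.0) / (ls * (ls + 1.0)) ** m
    keep = np.nonzero(w >= tol)[0]
    last = keep[-1] + 1 if keep.size else 1
    return w[:last]


def spline_kernel(
    cosang: np.ndarray, m: int = 4, tol: float = 1e-10, max_terms: int = 50
) -> np.ndarray:
    """Evaluate g at an array of inter-electrode cosines."""
    w = _legendre_weights(m, tol, max_terms)
    x = np.clip(np.asarray(cosang, dtype=float), -1.0, 1.0)
    # upward Legendre recursion, accumulated in place
    out = np.zeros_like(x)
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    for i, wl in enumerate(w):
        l = i + 1
        out += wl * p_cur
        p_next = ((2 * l + 1) * x * p_cur - l * p_prev) / (l + 1)
        p_prev, p_cur = p_cur, p_next
    return out / (4.0 * np.pi)


def interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    m: int = 4,
    regularization: float = 1e-5,
    tol: float = 1e-10,
    max_terms: int = 50,
) -> np.ndarray:
    """Matrix A with v_bad = A @ v_good for spherical-spline interpolation.

    Solves the standard constrained system: spline coefficients ``c`` and a
    constant ``c0`` satisfy ``(G + lam*I) c + c0 = v_good`` with ``sum(c) = 0``,
    then the bad-channel estimate is ``c0 + G_bad_good @ c``.
    """
    pos_good = np.asarray(pos_good, dtype=float)
    pos_bad = np.asarray(pos_bad, dtype=float)
    n_good = pos_good.shape[0]
    if n_good < 4:
        raise np.linalg.LinAlgError("too few good channels for a spline fit")
    G = spline_kernel(pos_good @ pos_good.T, m=m, tol=tol, max_terms=max_terms)
    G = G + regularization * np.eye(n_good)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    # columns of inv(A) restricted to the data rows give the fit weights
    B = np.linalg.solve(A, np.vstack([np.eye(n_good), np.zeros(n_good)]))
    Gb = spline_kernel(pos_bad @ pos_good.T, m=m, tol=tol, max_terms=max_terms)
    # v_bad = Gb @ c + c0, with [c; c0] = B @ v_good
    return Gb @ B[:n_good, :] + B[n_good, :]


def interpolate_channels(
    data: np.ndarray,
    positions: np.ndarray,
    bad: np.ndarray,
    m: int = 4,
    regularization: float = 1e-5,
    tol: float = 1e-10,
    max_terms: int = 50,
) -> np.ndarray:
    """Replace rows ``bad`` of a (channels x samples) array by spline estimates."""
    bad = np.asarray(bad)
    if bad.dtype == bool:
        bad = np.flatnonzero(bad)
    if bad.size == 0:
        return data
    good = np.setdiff1d(np.arange(data.shape[0]), bad)
    A = interpolation_matrix(
        positions[good], positions[bad], m=m, regularization=regularization,
        tol=tol, max_terms=max_terms,
    )
    out = data.copy()
    out[bad] = A @ data[good]
    return out
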