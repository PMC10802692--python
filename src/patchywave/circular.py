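"""Circular statistics used throughout the wave/motif pipeline.

Phases and tuning preferences are angles; every comparison in this package
therefore runs through the small set of estimators collected here: the
circular mean and resultant, the Fisher--Lee circular-circular correlation
(the Phase Similarity Index), and a signed circular-linear correlation of
phase against distance (the traveling-wave statistic).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circ_mean",
    "circ_resultant",
    "circ_dist",
    "fisher_lee_corr",
    "circ_linear_corr",
]


def wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2.0 * np.pi) - np.pi)


def circ_dist(a, b):
    """Signed circular difference a - b, wrapped to (-pi, pi]."""
    return wrap_angle(np.asarray(a) - np.asarray(b))


def circ_mean(phi: np.ndarray, axis=None):
    """Circular mean (angle of the resultant vector)."""
    phi = np.asarray(phi, dtype=float)
    return np.angle(np.exp(1j * phi).mean(axis=axis))


def circ_resultant(phi: np.ndarray, weights: np.ndarray | None = None):
    """Weighted resultant vector of unit vectors at angles ``phi``.

    Returns ``(angle, length)`` with ``length`` in [0, 1]; weights are
    normalized by their sum (responses acting as vector magnitudes).
    """
    phi = np.asarray(phi, dtype=float)
    if weights is None:
        z = np.exp(1j * phi).mean()
    else:
        w = np.asarray(weights, dtype=float)
        tot = w.sum()
        if tot == 0:
            return 0.0, 0.0
        z = (w * np.exp(1j * phi)).sum() / tot
    return float(np.angle(z)), float(np.abs(z))


def fisher_lee_corr(phi: np.ndarray, psi: np.ndarray) -> float:
    """Fisher--Lee circular-circular correlation of two angle samples.

    rho = sum_{i<j} sin(phi_i-phi_j) sin(psi_i-psi_j)
          / sqrt( sum sin^2(phi_i-phi_j) * sum sin^2(psi_i-psi_j) )

    Equals 1 when ``psi = phi + const`` and -1 when ``psi = -phi + const``.
    Returns NaN when either sample is (effectively) constant.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    psi = np.asarray(psi, dtype=float).ravel()
    if phi.shape != psi.shape:
        raise ValueError("phase maps must have the same shape")
    dphi = np.sin(phi[:, None] - phi[None, :])
    dpsi = np.sin(psi[:, None] - psi[None, :])
    iu = np.triu_indices(phi.size, k=1)
    num = float((dphi[iu] * dpsi[iu]).sum())
    den = float(np.sqrt((dphi[iu] ** 2).sum() * (dpsi[iu] ** 2).sum()))
    if den == 0.0:
        return float("nan")
    return num / den


def circ_linear_corr(phi: np.ndarray, x: np.ndarray) -> float:
    """Signed circular-linear correlation of angles ``phi`` against ``x``.

    The magnitude is the Mardia circular-linear correlation coefficient

        rho^2 = (r_xc^2 + r_xs^2 - 2 r_xc r_xs r_cs) / (1 - r_cs^2),

    where r_xc, r_xs, r_cs are Pearson correlations of x with cos(phi),
    sin(phi), and between cos and sin.  The sign is taken from the slope of
    the best-fitting helical model phi ~ a*x + b (the sign of a maximizing
    the resultant of phi - a*x), so that phase increasing with distance
    yields a positive value.  Returns NaN on degenerate input.
    """
    phi = np.asarray(phi, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if phi.size != x.size:
        raise ValueError("inputs must have equal length")
    if phi.size < 3 or np.ptp(x) == 0:
        return float("nan")
    s, c = np.sin(phi), np.cos(phi)
    if np.std(s) == 0 and np.std(c) == 0:
        return float("nan")

    def _pearson(a, b):
        sa, sb = np.std(a), np.std(b)
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rxc = _pearson(x, c)
    rxs = _pearson(x, s)
    rcs = _pearson(c, s)
    den = 1.0 - rcs**2
    if den <= 0:
        return float("nan")
    rho2 = (rxc**2 + rxs**2 - 2.0 * rxc * rxs * rcs) / den
    rho = float(np.sqrt(max(rho2, 0.0)))

    # slope search for the sign: coarse grid over plausible spatial
    # frequencies, refined once; resultant length R(a) = |mean exp(i(phi-ax))|
    span = np.ptp(x)
    amax = 4.0 * np.pi / max(span, 1e-12)
    grid = np.linspace(-amax, amax, 201)
    R = np.abs(np.exp(1j * (phi[None, :] - grid[:, None] * x[None, :])).mean(axis=1))
    a0 = grid[int(np.argmax(R))]
    fine = np.linspace(a0 - amax / 100, a0 + amax / 100, 41)
    Rf = np.abs(np.exp(1j * (phi[None, :] - fine[:, None] * x[None, :])).mean(axis=1))
    a_hat = fine[int(np.argmax(Rf))]
    sign = 1.0 if a_hat >= 0 else -1.0
    return sign * rho
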