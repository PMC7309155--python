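"""Exact synthesis of fractional Gaussian noise and fractional Brownian motion.

Uses the Davies–Harte circulant-embedding construction: the target fGn
autocovariance is embedded in a circulant matrix whose eigenvalues are
obtained by FFT, giving O(n log n) exact (in distribution) sampling.
The graph of fBm with Hurst exponent H has box-counting dimension 2 - H,
which is what makes these paths useful as a fractal-dimension oracle and
as the rough component of synthetic gait signals.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fgn_autocovariance", "fgn", "fbm"]


def fgn_autocovariance(lags: np.ndarray, hurst: float, sigma: float = 1.0) -> np.ndarray:
    """Theoretical autocovariance of fractional Gaussian noise.

    gamma(k) = sigma^2/2 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def fgn(n: int, hurst: float, rng: np.random.Generator, sigma: float = 1.0) -> np.ndarray:
    """Draw one exact fGn path of length ``n`` with Hurst exponent ``hurst``.

    Parameters
    ----------
    n : int
        Number of increments.
    hurst : float
        Hurst exponent in (0, 1). 0.5 gives white noise; larger values give
        persistent, smoother noise, smaller values anti-persistent noise.
    rng : numpy.random.Generator
        Source of randomness; the draw is fully determined by its state.
    sigma : float
        Standard deviation of each increment.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n) * sigma
    gamma = fgn_autocovariance(np.arange(n + 1), hurst, sigma)
    # First row of the 2n-circulant embedding; eigenvalues via FFT.
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    # Tiny negative eigenvalues can appear from round-off; clip them.
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    return w.real[:n] * np.sqrt(2)


def fbm(n: int, hurst: float, rng: np.random.Generator, sigma: float = 1.0) -> np.ndarray:
    """Draw one fBm path of length ``n`` (cumulative sum of exact fGn).

    The path starts at its first increment; its graph against sample index
    (or any affine time axis) has box-counting dimension 2 - hurst.
    """
    return np.cumsum(fgn(n, hurst, rng, sigma))
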