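"""Fractional Gaussian noise (fGn): exact generation and closed-form statistics.

fGn is the stationary increment process of fractional Brownian motion.  A
scalar fGn sequence ``xi_0, xi_1, ...`` is zero-mean Gaussian with
autocovariance

    gamma(n) = sigma^2 / 2 * (|n+1|^{2H} - 2|n|^{2H} + |n-1|^{2H}),

where ``H`` is the Hurst index and ``sigma`` the per-step standard deviation.
``H = 1/2`` gives uncorrelated increments (ordinary Brownian motion);
``H > 1/2`` gives persistent, ``H < 1/2`` anti-persistent steps.  A 2D walk
uses two independent scalar series, one per spatial component.

Two generators are provided.  The default, circulant embedding
(Davies-Harte), realises the target covariance exactly.  The spectral
("fourier") alternative filters white noise through the square root of the
power spectrum obtained from the periodised autocovariance; its covariance
differs from the target only by a wrap-around term that is negligible for
the series lengths used here.  Covariance agreement, not bit-level identity
between the two methods, is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseParams",
    "FGNSeries",
    "autocovariance",
    "target_autocovariance",
    "neighbor_correlation",
    "generate_fgn",
    "MAX_N_STEPS",
]

#: Largest series length for which the spectral embedding is attempted.
#: Beyond this the FFT work arrays (several float64 arrays of length 2n)
#: would exceed a few GiB.
MAX_N_STEPS = 2**26


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of one scalar fGn component.

    Parameters
    ----------
    hurst
        Hurst index, dimensionless, in the open interval (0, 1).
    sigma
        Per-step standard deviation, in length units.
    n_steps
        Number of increments to generate (>= 1).
    seed
        RNG seed used when no explicit generator is passed.
    """

    hurst: float
    sigma: float
    n_steps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise ValueError(f"n_steps must be a positive integer, got {self.n_steps}")


@dataclass(frozen=True)
class FGNSeries:
    """One realised fGn component together with its generation parameters."""

    values: np.ndarray
    params: NoiseParams

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != self.params.n_steps:
            raise ValueError(
                f"values must be 1D of length n_steps={self.params.n_steps}, "
                f"got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("fGn values must all be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Write the increments as a single-column CSV (debugging aid)."""
        np.savetxt(
            path,
            self.values,
            delimiter=",",
            header="increment",
            comments="",
        )


def autocovariance(hurst: float, sigma: float, lags) -> np.ndarray | float:
    """Closed-form fGn autocovariance ``gamma(lag)`` (vectorised in ``lags``)."""
    lags_arr = np.asarray(lags, dtype=float)
    if np.any(lags_arr < 0):
        raise ValueError("lags must be non-negative")
    two_h = 2.0 * hurst
    gamma = 0.5 * sigma**2 * (
        np.abs(lags_arr + 1) ** two_h
        - 2.0 * np.abs(lags_arr) ** two_h
        + np.abs(lags_arr - 1) ** two_h
    )
    if np.isscalar(lags) or np.ndim(lags) == 0:
        return float(gamma)
    return gamma


def target_autocovariance(params: NoiseParams, lag: int) -> float:
    """Autocovariance of the target noise at a non-negative integer lag."""
    if lag < 0:
        raise ValueError(f"lag must be non-negative, got {lag}")
    return float(autocovariance(params.hurst, params.sigma, lag))


def neighbor_correlation(hurst: float) -> float:
    """Correlation ``2^{2H-1} - 1`` between two successive increments.

    Zero at H = 1/2 (independent steps), approaching 1 in the ballistic
    limit H = 1, and negative for anti-persistent H < 1/2.
    """
    if not (0.0 < hurst <= 1.0):
        raise ValueError(f"hurst must lie in (0, 1], got {hurst}")
    return float(2.0 ** (2.0 * hurst - 1.0) - 1.0)


def _check_size(n: int) -> None:
    if n > MAX_N_STEPS:
        raise ValueError(
            f"n_steps={n} exceeds the supported maximum {MAX_N_STEPS}: the "
            "spectral embedding would need FFTs of length 2*n_steps. Generate "
            "shorter series, or split the walk into independent runs."
        )


def _circulant_embedding(params: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    """Davies-Harte sampling: exact covariance via a 2n circulant embedding."""
    n = params.n_steps
    if n == 1:
        return params.sigma * rng.standard_normal(1)
    gamma = autocovariance(params.hurst, params.sigma, np.arange(n + 1))
    # First row of the circulant embedding: gamma_0..gamma_n, gamma_{n-1}..gamma_1
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = len(row)  # == 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        # Known not to occur for fGn with 0 < H < 1, but guard anyway.
        raise ValueError(
            f"circulant embedding not non-negative definite (min eigenvalue "
            f"{lam.min():.3e}); cannot generate exactly at these parameters"
        )
    np.clip(lam, 0.0, None, out=lam)
    # Hermitian-symmetric complex spectrum with the prescribed eigenvalues.
    z_edge = rng.standard_normal(2)
    z_re = rng.standard_normal(n - 1)
    z_im = rng.standard_normal(n - 1)
    spec = np.empty(m, dtype=complex)
    spec[0] = np.sqrt(lam[0] / m) * z_edge[0]
    spec[n] = np.sqrt(lam[n] / m) * z_edge[1]
    spec[1:n] = np.sqrt(lam[1:n] / (2.0 * m)) * (z_re + 1j * z_im)
    spec[n + 1 :] = np.conj(spec[n - 1 : 0 : -1])
    return np.fft.fft(spec)[:n].real


def _fourier_filtering(params: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    """Spectral synthesis: filter white noise by sqrt of the power spectrum.

    The spectrum is the DFT of the autocovariance periodised on a ring of
    length 2 * n_steps; only the first n_steps samples are returned, so the
    wrap-around covariance bias at lag ``l`` is ``gamma(2n - l)``, which is
    O(n^{2H-2}) and negligible at the lags any test inspects.
    """
    n = params.n_steps
    if n == 1:
        return params.sigma * rng.standard_normal(1)
    m = 2 * n
    gamma = autocovariance(params.hurst, params.sigma, np.arange(n + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    power = np.fft.fft(row).real
    np.clip(power, 0.0, None, out=power)
    white = rng.standard_normal(m)
    # Cov(filtered_j, filtered_{j+k}) = ifft(power)_k = row_k exactly:
    # E|fft(white)_q|^2 = m cancels the 1/m^2 of the two transforms.
    filtered = np.fft.ifft(np.fft.fft(white) * np.sqrt(power)).real
    return filtered[:n]


_METHODS = {
    "circulant": _circulant_embedding,
    "davies-harte": _circulant_embedding,
    "fourier": _fourier_filtering,
    "spectral": _fourier_filtering,
}


def generate_fgn(
    params: NoiseParams,
    method: str = "circulant",
    rng: np.random.Generator | None = None,
) -> FGNSeries:
    """Generate one scalar fGn series.

    Parameters
    ----------
    params
        Noise parameters; ``params.seed`` seeds the generator unless an
        explicit ``rng`` is supplied (ensemble code passes per-fiber
        sub-streams spawned from a master seed).
    method
        ``"circulant"`` (exact Davies-Harte, default) or ``"fourier"``
        (spectral filtering).

    Identical parameters and seed give bitwise-identical output.
    """
    try:
        gen = _METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(set(_METHODS))}"
        ) from None
    _check_size(params.n_steps)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    try:
        values = gen(params, rng)
    except MemoryError as exc:
        raise MemoryError(
            f"cannot allocate FFT work arrays for n_steps={params.n_steps}; "
            "reduce n_steps or split the run into independent series"
        ) from exc
    return FGNSeries(values=values, params=params)
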