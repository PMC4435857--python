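"""Higuchi fractal dimension of CoP position time series.

The Higuchi estimator builds, for each lag k (in samples), the normalized
mean curve length

    L(k) = (1/k) * mean over offsets m = 1..k of
           [ sum_{i=1..n_m} |x(m + i k) - x(m + (i-1) k)| ]
           * (N - 1) / (n_m * k),      n_m = floor((N - m) / k),

and estimates the fractal dimension as minus the slope of ln L(k) vs ln k.
For CoP data the log-log curve shows two regimes, so the regression is done
separately over a short (lags up to 0.3 s) and a long (0.8-12 s) window of
lag durations k / fs, excluding the transition region between them.

FD is ~1 for a smooth line, ~2 for uncorrelated noise, and 2 - H for
fractional-Brownian-type traces with Hurst exponent H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copio import CoPTrial

__all__ = [
    "CurveLengths",
    "FractalFit",
    "FractalError",
    "ConstantSeriesError",
    "InsufficientWindowError",
    "SHORT_WINDOW_S",
    "LONG_WINDOW_S",
    "default_k_grid",
    "higuchi_lengths",
    "fit_fd",
    "fd_all",
]

#: regime windows in seconds of lag duration k / fs
SHORT_WINDOW_S: tuple[float, float] = (0.0, 0.3)
LONG_WINDOW_S: tuple[float, float] = (0.8, 12.0)

#: number of (approximately) log-spaced lags in the long-regime grid
N_LONG_K = 25


class FractalError(ValueError):
    """Base class for fractal-dimension failures."""


class ConstantSeriesError(FractalError):
    """All curve lengths are zero: the series is constant."""


class InsufficientWindowError(FractalError):
    """Fewer than two usable lags fall in the regression window."""


@dataclass
class CurveLengths:
    """Higuchi curve-length table L(k) for a set of integer lags."""

    k_values: np.ndarray
    lengths: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.k_values.size != self.lengths.size:
            raise FractalError("k_values and lengths must have equal length")

    @property
    def lag_seconds(self) -> np.ndarray:
        return self.k_values / self.sampling_rate_hz


@dataclass
class FractalFit:
    """One regressed fractal dimension: axis x regime."""

    axis: str  # "ML" or "AP"
    regime: str  # "short" or "long"
    window_s: tuple[float, float]
    slope: float
    fd: float  # = -slope
    r_squared: float
    n_points: int


def default_k_grid(
    sampling_rate_hz: float,
    n_samples: int,
    short_window_s: tuple[float, float] = SHORT_WINDOW_S,
    long_window_s: tuple[float, float] = LONG_WINDOW_S,
    n_long: int = N_LONG_K,
) -> np.ndarray:
    """Default lag grid: every integer lag in the short window, ~n_long
    log-spaced integer lags across the long window.

    Lags are capped at floor((N - 1) / 4) so each offset contributes at
    least four increments.
    """
    fs = float(sampling_rate_hz)
    k_cap = (n_samples - 1) // 4
    if k_cap < 1:
        raise FractalError(f"series too short for Higuchi analysis (N={n_samples})")
    short_max = min(int(np.floor(short_window_s[1] * fs + 1e-9)), k_cap)
    ks = np.arange(1, max(short_max, 1) + 1)
    lo = max(int(np.ceil(long_window_s[0] * fs - 1e-9)), 1)
    hi = min(int(np.floor(long_window_s[1] * fs + 1e-9)), k_cap)
    if hi >= lo:
        k_long = np.unique(
            np.round(np.geomspace(lo, hi, num=n_long)).astype(int)
        )
        ks = np.union1d(ks, k_long)
    return ks.astype(int)


def higuchi_lengths(
    series: np.ndarray,
    sampling_rate_hz: float,
    k_values: np.ndarray | None = None,
) -> CurveLengths:
    """Normalized Higuchi curve lengths L(k) of a 1-D series.

    Offsets m run over the full 1..k (full Higuchi averaging); each offset
    must contribute at least one increment, so every k must satisfy
    k <= (N - 1) / 2 ... the default grid caps harder at (N - 1) / 4.
    A constant series yields all-zero lengths (the downstream fit refuses).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise FractalError("series must be 1-D with at least 2 samples")
    if not np.isfinite(x).all():
        raise FractalError("series contains non-finite values")
    n = x.size
    if k_values is None:
        k_values = default_k_grid(sampling_rate_hz, n)
    k_values = np.asarray(k_values, dtype=int)
    if (k_values < 1).any():
        raise FractalError("lags must be positive integers")
    if 2 * int(k_values.max()) > n:
        raise FractalError(
            f"max lag {k_values.max()} too large for series of length {n}"
        )

    lengths = np.empty(k_values.size, dtype=float)
    for j, k in enumerate(k_values):
        lm = np.empty(k, dtype=float)
        for m in range(1, k + 1):
            sub = x[m - 1 :: k]  # x(m), x(m+k), x(m+2k), ... (1-based)
            n_inc = sub.size - 1
            lm[m - 1] = (
                np.abs(np.diff(sub)).sum() * (n - 1) / (n_inc * k)
            )
        lengths[j] = lm.mean() / k
    return CurveLengths(k_values=k_values, lengths=lengths, sampling_rate_hz=sampling_rate_hz)


def fit_fd(
    lengths: CurveLengths,
    window_s: tuple[float, float],
    axis: str = "",
    regime: str = "",
) -> FractalFit:
    """Fractal dimension from the log-log slope of L(k) within a lag window.

    Lags with window_s[0] <= k/fs <= window_s[1] (boundaries inclusive, with
    a small float guard) enter an unweighted least-squares line of ln L(k)
    on ln k; fd = -slope.
    """
    t = lengths.lag_seconds
    eps = 1e-12
    mask = (t >= window_s[0] - eps) & (t <= window_s[1] + eps)
    k_sel = lengths.k_values[mask]
    l_sel = lengths.lengths[mask]
    if k_sel.size < 2:
        raise InsufficientWindowError(
            f"only {k_sel.size} lag(s) fall in window {window_s} s; need >= 2"
        )
    if (l_sel <= 0.0).any():
        if (lengths.lengths == 0.0).all():
            raise ConstantSeriesError(
                "all curve lengths are zero (constant series); FD undefined"
            )
        raise FractalError(
            f"non-positive curve length inside window {window_s} s"
        )
    lx = np.log(k_sel.astype(float))
    ly = np.log(l_sel)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalFit(
        axis=axis,
        regime=regime,
        window_s=tuple(window_s),
        slope=float(slope),
        fd=float(-slope),
        r_squared=r2,
        n_points=int(k_sel.size),
    )


def fd_all(
    trial: CoPTrial,
    short_window_s: tuple[float, float] = SHORT_WINDOW_S,
    long_window_s: tuple[float, float] = LONG_WINDOW_S,
    k_values: np.ndarray | None = None,
) -> dict[tuple[str, str], FractalFit]:
    """All four fractal dimensions of a trial: {ML, AP} x {short, long}.

    Curve lengths are computed once per axis over the combined lag grid and
    regressed separately per regime window.
    """
    if k_values is None:
        k_values = default_k_grid(
            trial.sampling_rate_hz, trial.n, short_window_s, long_window_s
        )
    fits: dict[tuple[str, str], FractalFit] = {}
    for axis, series in (("ML", trial.ml_cm), ("AP", trial.ap_cm)):
        cl = higuchi_lengths(series, trial.sampling_rate_hz, k_values)
        for regime, window in (("short", short_window_s), ("long", long_window_s)):
            fits[(axis, regime)] = fit_fd(cl, window, axis=axis, regime=regime)
    return fits
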