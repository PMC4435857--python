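"""Sway-area estimators: Fourier-analysis outline (FAO) and PCA ellipse.

Two standard posturographic area measures of the 2-D CoP point cloud:

* FAO — the extreme CoP radius is taken in each of ``n_intervals`` equal
  angular bins about the cloud centroid and a truncated Fourier series
  r(phi) = A0 + sum_m (Am cos m phi + Bm sin m phi), m = 1..m_max, is fitted
  by ordinary least squares; the enclosed area follows in closed form from
  Parseval: area = pi A0^2 + (pi/2) sum_m (Am^2 + Bm^2).
* PCA ellipse — the 95 % confidence ellipse of the cloud: semi-axes
  1.96 sqrt(lambda_i) along the eigenvectors of the 2x2 sample covariance,
  area = pi 1.96^2 sqrt(lambda_1 lambda_2).

Defaults follow common stabilometric practice: 100 angular intervals and
m_max = 20 Fourier harmonics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .copio import CoPTrial

__all__ = [
    "OutlineModel",
    "EllipseModel",
    "OutlineError",
    "DegenerateOutlineError",
    "InvalidOutlineError",
    "fit_pca_ellipse",
    "extreme_points",
    "fit_outline",
    "outline_area",
    "fao_area",
]

#: 95 % two-sided normal quantile used for the confidence-ellipse semi-axes.
CONFIDENCE_MULTIPLIER = 1.96

DEFAULT_N_INTERVALS = 100
DEFAULT_M_MAX = 20


class OutlineError(ValueError):
    """Base class for outline-fitting failures."""


class DegenerateOutlineError(OutlineError):
    """Too few non-empty angular bins to describe an outline."""


class InvalidOutlineError(OutlineError):
    """The fitted radius goes negative somewhere on the circle."""


@dataclass
class OutlineModel:
    """Fitted Fourier outline of the sway area.

    ``coeff_a`` holds A0..A_mmax (A0 is the mean radius term), ``coeff_b``
    holds B1..B_mmax; all in cm about (center_ml_cm, center_ap_cm).
    """

    center_ml_cm: float
    center_ap_cm: float
    m_max: int
    n_intervals: int
    coeff_a: np.ndarray  # A0..A_mmax
    coeff_b: np.ndarray  # B1..B_mmax
    area_cm2: float = field(init=False)
    residual_rms_cm: float = 0.0

    def __post_init__(self) -> None:
        self.coeff_a = np.asarray(self.coeff_a, dtype=float)
        self.coeff_b = np.asarray(self.coeff_b, dtype=float)
        if self.coeff_a.size != self.m_max + 1 or self.coeff_b.size != self.m_max:
            raise OutlineError(
                f"coefficient lengths ({self.coeff_a.size}, {self.coeff_b.size}) "
                f"inconsistent with m_max={self.m_max}"
            )
        self.area_cm2 = float(
            np.pi * self.coeff_a[0] ** 2
            + (np.pi / 2.0) * (np.sum(self.coeff_a[1:] ** 2) + np.sum(self.coeff_b**2))
        )

    def radius(self, phi: np.ndarray | float) -> np.ndarray:
        """Evaluate the fitted radius r(phi) in cm."""
        phi = np.atleast_1d(np.asarray(phi, dtype=float))
        m = np.arange(1, self.m_max + 1)
        r = (
            self.coeff_a[0]
            + np.cos(np.outer(phi, m)) @ self.coeff_a[1:]
            + np.sin(np.outer(phi, m)) @ self.coeff_b
        )
        return r


@dataclass
class EllipseModel:
    """95 % confidence ellipse of the CoP cloud from PCA.

    ``s0_major_cm``/``s0_minor_cm`` are the principal-axis standard
    deviations (square roots of the covariance eigenvalues); the semi-axes
    of the drawn ellipse are 1.96 times these.
    """

    center_ml_cm: float
    center_ap_cm: float
    s0_major_cm: float
    s0_minor_cm: float
    orientation_rad: float
    area_cm2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.s0_major_cm < self.s0_minor_cm:
            raise ValueError("s0_major_cm must be >= s0_minor_cm")
        self.area_cm2 = float(
            np.pi * CONFIDENCE_MULTIPLIER**2 * self.s0_major_cm * self.s0_minor_cm
        )


def fit_pca_ellipse(trial: CoPTrial) -> EllipseModel:
    """Fit the 95 % PCA confidence ellipse to a trial's CoP cloud.

    Eigen-decomposes the 2x2 sample covariance of (ML, AP); a fully
    degenerate cloud (all points identical) yields a zero-area ellipse with
    a warning rather than an exception.
    """
    if trial.n < 3:
        raise ValueError(f"PCA ellipse needs at least 3 samples, got {trial.n}")
    xy = np.column_stack([trial.ml_cm, trial.ap_cm])
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)  # guard roundoff
    if evals[1] == 0.0:
        warnings.warn(
            "all CoP samples identical: zero-area ellipse", stacklevel=2
        )
    major = float(np.sqrt(evals[1]))
    minor = float(np.sqrt(evals[0]))
    vmajor = evecs[:, 1]
    return EllipseModel(
        center_ml_cm=float(center[0]),
        center_ap_cm=float(center[1]),
        s0_major_cm=major,
        s0_minor_cm=minor,
        orientation_rad=float(np.arctan2(vmajor[1], vmajor[0])),
    )


def extreme_points(
    trial: CoPTrial,
    n_intervals: int = DEFAULT_N_INTERVALS,
    center: tuple[float, float] | None = None,
    angle: str = "point",
) -> np.ndarray:
    """Extreme CoP radius per angular bin about a centre.

    Partitions [0, 2pi) into ``n_intervals`` equal bins by the polar angle of
    each sample about ``center`` (default: the cloud centroid) and keeps, per
    non-empty bin, the sample of maximum radius.  Returns an array of
    (phi, r) rows sorted by phi.

    ``angle`` selects what phi is reported: ``"point"`` (default) the polar
    angle of the extreme sample itself, ``"bin_center"`` the bin midpoint.
    Ties for the maximum radius are broken by first occurrence.
    """
    if n_intervals < 8:
        raise ValueError(f"n_intervals must be >= 8, got {n_intervals}")
    if angle not in ("point", "bin_center"):
        raise ValueError(f"angle must be 'point' or 'bin_center', got {angle!r}")
    xy = np.column_stack([trial.ml_cm, trial.ap_cm])
    if center is None:
        center = tuple(xy.mean(axis=0))
    dx = xy[:, 0] - center[0]
    dy = xy[:, 1] - center[1]
    r = np.hypot(dx, dy)
    phi = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    width = 2.0 * np.pi / n_intervals
    bins = np.minimum((phi // width).astype(int), n_intervals - 1)

    out: list[tuple[float, float]] = []
    for b in np.unique(bins):
        mask = bins == b
        idx = np.flatnonzero(mask)
        best = idx[np.argmax(r[idx])]  # argmax keeps the first of any ties
        if r[best] == 0.0:
            continue  # the centre itself carries no angular information
        phi_out = phi[best] if angle == "point" else (b + 0.5) * width
        out.append((float(phi_out), float(r[best])))
    if len(out) < 3:
        raise DegenerateOutlineError(
            f"only {len(out)} non-empty angular bins; outline undefined"
        )
    arr = np.asarray(out, dtype=float)
    return arr[np.argsort(arr[:, 0])]


def fit_outline(
    polar_samples: np.ndarray,
    m_max: int = DEFAULT_M_MAX,
    center: tuple[float, float] = (0.0, 0.0),
    n_intervals: int = DEFAULT_N_INTERVALS,
) -> OutlineModel:
    """Least-squares Fourier fit of r(phi) to (phi, r) samples.

    The design matrix is {1, cos m phi, sin m phi} for m = 1..m_max; the
    system must be overdetermined (>= 2 m_max + 1 samples), otherwise the
    caller is told to lower ``m_max``.
    """
    samples = np.asarray(polar_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise OutlineError("polar_samples must be an array of (phi, r) rows")
    n = samples.shape[0]
    n_params = 2 * m_max + 1
    if n < n_params:
        raise OutlineError(
            f"{n} polar samples cannot determine {n_params} Fourier "
            f"coefficients; lower m_max (need >= {n_params} samples)"
        )
    phi, r = samples[:, 0], samples[:, 1]
    m = np.arange(1, m_max + 1)
    design = np.hstack(
        [
            np.ones((n, 1)),
            np.cos(np.outer(phi, m)),
            np.sin(np.outer(phi, m)),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    resid = r - design @ coef
    return OutlineModel(
        center_ml_cm=float(center[0]),
        center_ap_cm=float(center[1]),
        m_max=m_max,
        n_intervals=n_intervals,
        coeff_a=coef[: m_max + 1],
        coeff_b=coef[m_max + 1 :],
        residual_rms_cm=float(np.sqrt(np.mean(resid**2))),
    )


def outline_area(outline: OutlineModel, n_check: int = 1000) -> float:
    """Area enclosed by a fitted outline, in cm^2.

    Closed-form polar area (1/2) integral r(phi)^2 dphi; validates that the
    fitted radius is non-negative on an ``n_check``-point angle grid first.
    """
    grid = np.linspace(0.0, 2.0 * np.pi, n_check, endpoint=False)
    rad = outline.radius(grid)
    bad = np.flatnonzero(rad < 0.0)
    if bad.size:
        raise InvalidOutlineError(
            f"fitted radius is negative at phi={grid[bad[0]]:.4f} rad "
            f"(r={rad[bad[0]]:.4g} cm); outline invalid"
        )
    return outline.area_cm2


def fao_area(
    trial: CoPTrial,
    n_intervals: int = DEFAULT_N_INTERVALS,
    m_max: int = DEFAULT_M_MAX,
    angle: str = "point",
) -> tuple[float, OutlineModel]:
    """Convenience: extreme points -> Fourier fit -> area for one trial."""
    xy_center = (float(np.mean(trial.ml_cm)), float(np.mean(trial.ap_cm)))
    polar = extreme_points(trial, n_intervals=n_intervals, center=xy_center, angle=angle)
    outline = fit_outline(
        polar, m_max=m_max, center=xy_center, n_intervals=n_intervals
    )
    return outline_area(outline), outline
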