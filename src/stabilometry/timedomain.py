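"""Time-domain sway variables of a CoP trial.

Positional variability (SD of each axis), path lengths (per axis and total)
and mean velocity.  Together with the two sway areas and the four fractal
dimensions these make up the twelve variables the reliability analysis
reports.  No filtering or detrending is applied before computing metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .copio import CoPTrial

__all__ = [
    "SwayMetrics",
    "InsufficientDataError",
    "positional_variability",
    "path_lengths",
    "mean_velocity",
]


class InsufficientDataError(ValueError):
    """Too few samples for the requested metric."""


@dataclass
class SwayMetrics:
    """The twelve per-trial sway variables.

    Units: cm for SDs and path lengths, cm/s for velocity, cm^2 for areas;
    fractal dimensions are dimensionless (~1 for a smooth line, ~2 for
    noise-like series).
    """

    sd_ml_cm: float
    sd_ap_cm: float
    path_ml_cm: float
    path_ap_cm: float
    path_total_cm: float
    mean_velocity_cm_s: float
    area_fao_cm2: float
    area_pca_cm2: float
    fd_ml_short: float
    fd_ml_long: float
    fd_ap_short: float
    fd_ap_long: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _require(trial: CoPTrial, n_min: int = 2) -> None:
    if trial.n < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} samples, trial has {trial.n}"
        )
    if not trial.is_finite():
        raise InsufficientDataError("trial contains non-finite samples")


def positional_variability(trial: CoPTrial) -> tuple[float, float]:
    """Sample SD (n-1 denominator) of the ML and AP position series, in cm."""
    _require(trial)
    return (
        float(np.std(trial.ml_cm, ddof=1)),
        float(np.std(trial.ap_cm, ddof=1)),
    )


def path_lengths(trial: CoPTrial) -> tuple[float, float, float]:
    """Per-axis and total CoP path length in cm.

    path_ml = sum |dml|, path_ap = sum |dap|, and the total path is the sum
    of Euclidean step lengths sqrt(dml^2 + dap^2); by the triangle inequality
    max(path_ml, path_ap) <= path_total <= path_ml + path_ap.
    """
    _require(trial)
    dml = np.diff(trial.ml_cm)
    dap = np.diff(trial.ap_cm)
    return (
        float(np.sum(np.abs(dml))),
        float(np.sum(np.abs(dap))),
        float(np.sum(np.hypot(dml, dap))),
    )


def mean_velocity(trial: CoPTrial) -> float:
    """Mean CoP speed in cm/s: total path length divided by trial duration.

    For uniform sampling this equals the mean of the per-step speeds
    |dr| / dt.
    """
    _require(trial)
    duration = trial.duration_s
    if duration <= 0:
        raise InsufficientDataError("trial duration must be positive")
    return path_lengths(trial)[2] / duration
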