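"""Test-retest reliability statistics.

ICC(2,1) — two-way random-effects, absolute-agreement, single-measures
intraclass correlation in the Shrout & Fleiss taxonomy — quantifies the
agreement between session-1 and session-2 scores.  From the two-way ANOVA
mean squares (rows = subjects, columns = sessions, k sessions, n subjects):

    ICC(2,1) = (MS_R - MS_E) /
               (MS_R + (k-1) MS_E + (k/n) (MS_C - MS_E))

with the approximate F-based confidence interval of Shrout & Fleiss.

Two distinct "SEM"s appear in the reliability literature and both are
provided, clearly labelled: the standard error of *measurement*
SD * sqrt(1 - ICC), and the standard error of the *mean* SD / sqrt(n).

The Romberg quotient (eyes-closed / eyes-open ratio of a sway variable)
summarises visual dependence; it is computed per subject and averaged
(mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreMatrix",
    "ReliabilityRow",
    "RombergResult",
    "ReliabilityError",
    "anova_mean_squares",
    "icc_2_1",
    "sem_measurement",
    "se_of_mean",
    "romberg_quotient",
    "reliability_table",
    "romberg_table",
]

logger = logging.getLogger(__name__)


class ReliabilityError(ValueError):
    """Invalid input to a reliability statistic."""


@dataclass
class ScoreMatrix:
    """Paired session scores of one variable for one (condition, group) cell."""

    subject_ids: list[str]
    session1: np.ndarray
    session2: np.ndarray
    variable: str = ""
    condition: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.session1 = np.asarray(self.session1, dtype=float)
        self.session2 = np.asarray(self.session2, dtype=float)
        n = len(self.subject_ids)
        if self.session1.size != n or self.session2.size != n:
            raise ReliabilityError("session arrays must match subject_ids length")
        if n < 3:
            raise ReliabilityError(f"need at least 3 subjects, got {n}")
        if not (np.isfinite(self.session1).all() and np.isfinite(self.session2).all()):
            raise ReliabilityError("scores must be pairwise complete and finite")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def to_array(self) -> np.ndarray:
        return np.column_stack([self.session1, self.session2])


@dataclass
class ReliabilityRow:
    """One rendered table row: session summaries plus agreement statistics."""

    variable: str
    condition: str
    group: str
    n: int
    mean1: float
    sd1: float
    se1: float
    mean2: float
    sd2: float
    se2: float
    icc: float
    ci_low: float
    ci_high: float
    sem_measurement: float


@dataclass
class RombergResult:
    """Mean and SD across subjects of the per-subject EC/EO ratio."""

    variable: str
    group: str
    mean_rq: float
    sd_rq: float
    n: int


def anova_mean_squares(scores: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares of an n x k score matrix.

    Returns (MS_rows, MS_cols, MS_error) for rows = subjects and
    cols = sessions, the decomposition underlying ICC(2,1).
    """
    y = np.asarray(scores, dtype=float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid**2)
    return (
        float(ss_rows / (n - 1)),
        float(ss_cols / (k - 1)),
        float(ss_err / ((n - 1) * (k - 1))),
    )


def icc_2_1(
    scores: ScoreMatrix | np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1) with its 100(1-alpha)% confidence interval.

    Accepts a :class:`ScoreMatrix` or a plain n x k array (n >= 3 subjects,
    k >= 2 sessions).  Returns (icc, ci_low, ci_high); bounds are clipped to
    [-1, 1].  The interval uses the Shrout-Fleiss approximate F procedure
    with Satterthwaite degrees of freedom.
    """
    y = scores.to_array() if isinstance(scores, ScoreMatrix) else np.asarray(scores, float)
    if y.ndim != 2:
        raise ReliabilityError("scores must be a 2-D subjects x sessions array")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ReliabilityError(f"need >= 3 subjects and >= 2 sessions, got {n} x {k}")
    if np.ptp(y) == 0.0:
        raise ReliabilityError("zero total variance: ICC undefined")
    msr, msc, mse = anova_mean_squares(y)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ReliabilityError("degenerate variance decomposition: ICC undefined")
    icc = (msr - mse) / denom

    # Shrout & Fleiss CI for ICC(2,1)
    if mse == 0.0:
        # perfect within-subject agreement: interval collapses at 1
        return float(icc), float(icc), 1.0
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
    # strongly negative ICC collapses the Satterthwaite df to ~0 and the
    # F quantiles blow up; the interval is then vacuous on that side
    ci_low = float(np.clip(ci_low, -1.0, 1.0)) if np.isfinite(ci_low) else -1.0
    ci_high = float(np.clip(ci_high, -1.0, 1.0)) if np.isfinite(ci_high) else 1.0
    return float(icc), min(ci_low, float(icc)), max(ci_high, float(icc))


def sem_measurement(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement: SD_pooled * sqrt(1 - ICC).

    Negative ICC is allowed (the argument 1 - ICC simply exceeds 1).
    """
    if sd_pooled < 0:
        raise ReliabilityError("sd_pooled must be non-negative")
    if icc > 1:
        raise ReliabilityError("icc cannot exceed 1")
    return float(sd_pooled * np.sqrt(1.0 - icc))


def se_of_mean(sd: float, n: int) -> float:
    """Standard error of the mean: SD / sqrt(n)."""
    if n < 1:
        raise ReliabilityError("n must be >= 1")
    if sd < 0:
        raise ReliabilityError("sd must be non-negative")
    return float(sd / np.sqrt(n))


def romberg_quotient(
    eo_values: np.ndarray,
    ec_values: np.ndarray,
    subject_ids: list[str] | None = None,
    variable: str = "",
    group: str = "",
) -> RombergResult:
    """Romberg quotient: per-subject eyes-closed / eyes-open ratio.

    ``eo_values`` and ``ec_values`` are paired per-subject scores; the result
    is the mean and sample SD of the ratios across subjects (mean of ratios,
    not ratio of means).
    """
    eo = np.asarray(eo_values, dtype=float)
    ec = np.asarray(ec_values, dtype=float)
    if eo.size != ec.size or eo.size == 0:
        raise ReliabilityError("eo and ec values must be paired and non-empty")
    ids = subject_ids if subject_ids is not None else [str(i) for i in range(eo.size)]
    bad = np.flatnonzero(eo <= 0.0)
    if bad.size:
        raise ReliabilityError(
            f"non-positive eyes-open value for subject {ids[bad[0]]!r}; "
            "Romberg quotient undefined"
        )
    rq = ec / eo
    sd = float(np.std(rq, ddof=1)) if rq.size > 1 else 0.0
    return RombergResult(
        variable=variable,
        group=group,
        mean_rq=float(rq.mean()),
        sd_rq=sd,
        n=int(rq.size),
    )


def _pooled_sd(sd1: float, sd2: float) -> float:
    return float(np.sqrt((sd1**2 + sd2**2) / 2.0))


def reliability_table(
    metrics: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable test-retest table over every (condition, group) cell.

    ``metrics`` is a wide per-trial table with columns ``subject_id``,
    ``group``, ``condition``, ``session`` plus one column per sway variable
    (default: every other numeric column).  Subjects missing either session
    in a condition are excluded from that condition's rows with a logged
    warning; the exclusions are also available in ``result.attrs["excluded"]``.

    Returns one row per variable x condition x group with session means,
    SDs, SEs (SD/sqrt(n)), ICC(2,1), its CI and the standard error of
    measurement (pooled SD * sqrt(1 - ICC)).
    """
    meta_cols = {"subject_id", "group", "condition", "session"}
    missing = meta_cols - set(metrics.columns)
    if missing:
        raise ReliabilityError(f"metrics table missing columns {sorted(missing)}")
    if variables is None:
        variables = [
            c
            for c in metrics.columns
            if c not in meta_cols and pd.api.types.is_numeric_dtype(metrics[c])
        ]

    rows: list[ReliabilityRow] = []
    excluded: list[tuple[str, str]] = []
    for (condition, group), cell in metrics.groupby(["condition", "group"], sort=False):
        sessions = cell.pivot_table(
            index="subject_id", columns="session", values=variables, aggfunc="first"
        )
        complete_mask = sessions.notna().all(axis=1)
        for sid in sessions.index[~complete_mask]:
            excluded.append((str(sid), str(condition)))
            logger.warning(
                "subject %s excluded from condition %s: missing a session",
                sid,
                condition,
            )
        sessions = sessions[complete_mask]
        n = len(sessions)
        if n < 3:
            logger.warning(
                "condition %s group %s: only %d complete subject(s); cell skipped",
                condition,
                group,
                n,
            )
            continue
        for var in variables:
            s1 = sessions[(var, 1)].to_numpy(dtype=float)
            s2 = sessions[(var, 2)].to_numpy(dtype=float)
            icc, lo, hi = icc_2_1(np.column_stack([s1, s2]), alpha=alpha)
            sd1 = float(np.std(s1, ddof=1))
            sd2 = float(np.std(s2, ddof=1))
            rows.append(
                ReliabilityRow(
                    variable=var,
                    condition=str(condition),
                    group=str(group),
                    n=n,
                    mean1=float(s1.mean()),
                    sd1=sd1,
                    se1=se_of_mean(sd1, n),
                    mean2=float(s2.mean()),
                    sd2=sd2,
                    se2=se_of_mean(sd2, n),
                    icc=icc,
                    ci_low=lo,
                    ci_high=hi,
                    sem_measurement=sem_measurement(_pooled_sd(sd1, sd2), icc),
                )
            )
    if not rows and len(metrics):
        raise ReliabilityError(
            "no (condition, group) cell has >= 3 subjects with both sessions"
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["excluded"] = excluded
    return out


def romberg_table(
    metrics: pd.DataFrame,
    variables: tuple[str, ...] = ("path_total_cm", "area_pca_cm2"),
    pair: tuple[str, str] = ("FO", "FC"),
    session: int = 1,
) -> pd.DataFrame:
    """Romberg quotients per group for selected variables.

    ``pair`` names the (eyes-open, eyes-closed) conditions to ratio; the
    default pairs the firm-surface conditions.  One session is used so the
    quotient reflects a single test occasion.
    """
    eo_cond, ec_cond = pair
    out: list[RombergResult] = []
    sub = metrics[metrics["session"] == session]
    for group, cell in sub.groupby("group", sort=False):
        piv = cell.pivot_table(
            index="subject_id", columns="condition", values=list(variables), aggfunc="first"
        )
        for var in variables:
            if (var, eo_cond) not in piv.columns or (var, ec_cond) not in piv.columns:
                continue
            pairdf = piv[[(var, eo_cond), (var, ec_cond)]].dropna()
            if pairdf.empty:
                continue
            out.append(
                romberg_quotient(
                    pairdf[(var, eo_cond)].to_numpy(),
                    pairdf[(var, ec_cond)].to_numpy(),
                    subject_ids=[str(s) for s in pairdf.index],
                    variable=var,
                    group=str(group),
                )
            )
    return pd.DataFrame([r.__dict__ for r in out])
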