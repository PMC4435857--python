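"""Synthetic CoP cohorts with known ground truth.

Replaces human data with simulated 2-session x 4-condition cohorts whose
statistical structure is controlled:

* each trial's positional sway scale (the SD of each axis, in cm) is
  log-normal with a between-subject component u_j ~ N(0, sigma_subject^2)
  and a within-subject between-session component v_js ~ N(0,
  sigma_session^2), so the *designed* test-retest ICC of the log sway scale
  is sigma_subject^2 / (sigma_subject^2 + sigma_session^2), exactly;
* the trace shape per axis is a stationary Ornstein-Uhlenbeck process, a
  leaky-integrated fractional Gaussian noise trace (fBm-like roughness with
  Hurst exponent H at short lags, nominal Higuchi FD ~ 2 - H, but bounded
  like real quiet-stance sway so the long-lag FD rises towards 2), or an
  equal mixture;
* traces are standardized to zero mean and unit sample SD before scaling,
  so the realized positional SD of each trial equals its drawn scale.

Default cohort sizes (26 young, 15 elderly), base sway scales
(~0.4-0.6 cm) and condition multipliers ordered FO < FC < CO < CC mirror
typical quiet-stance cohorts on firm/compliant surfaces with eyes
open/closed.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .copio import CoPTrial, Group, Condition, TrialSet

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_fgn",
    "generate_fbm_trace",
    "generate_ou_trace",
    "generate_trial",
    "generate_cohort",
]


@dataclass
class GroupSpec:
    """Cohort group: size and base per-axis sway scales (cm)."""

    n_subjects: int
    base_scale_ml_cm: float
    base_scale_ap_cm: float


def _default_groups() -> dict[str, GroupSpec]:
    # sizes and firm-surface eyes-open sway magnitudes typical of young and
    # elderly female cohorts
    return {
        "young": GroupSpec(26, 0.44, 0.51),
        "elderly": GroupSpec(15, 0.57, 0.62),
    }


def _default_multipliers() -> dict[str, float]:
    # sensory-condition difficulty ordering: firm/eyes-open easiest,
    # compliant/eyes-closed hardest
    return {"FO": 1.0, "FC": 1.2, "CO": 1.5, "CC": 2.7}


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort.

    ``sigma_subject`` and ``sigma_session`` are SDs on the log sway scale;
    their ratio fixes the designed ICC.  ``hurst`` sets the nominal fractal
    dimension (2 - H) of fBm-type traces; ``ou_theta`` (1/s) the mean
    reversion rate of OU traces (larger theta -> faster, longer-path sway at
    the same positional SD).
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    condition_multipliers: dict[str, float] = field(default_factory=_default_multipliers)
    sigma_subject: float = 0.2
    sigma_session: float = 0.1
    trace_model: str = "fgn"  # {"ou", "fgn", "mixture"}
    hurst: float = 0.85
    ou_theta: float = 1.0
    fgn_leak_per_s: float = 1.0
    axis_correlation: float = 0.0
    sampling_rate_hz: float = 50.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trace_model not in ("ou", "fgn", "mixture"):
            raise ValueError(f"unknown trace_model {self.trace_model!r}")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if not -1.0 <= self.axis_correlation <= 1.0:
            raise ValueError("axis_correlation must be in [-1, 1]")

    @property
    def designed_icc(self) -> float:
        """True test-retest ICC of the log sway scale implied by the config."""
        su2 = self.sigma_subject**2
        sv2 = self.sigma_session**2
        if su2 + sv2 == 0.0:
            return 1.0
        return su2 / (su2 + sv2)

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.duration_s))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["designed_icc"] = self.designed_icc
        return d


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery checks."""

    designed_icc: float
    nominal_fd: float | None  # 2 - hurst for fBm-type traces, else None
    #: (subject_id, condition, session) -> (scale_ml_cm, scale_ap_cm)
    scales: dict[tuple[str, str, int], tuple[float, float]]
    #: subject_id -> u_j (between-subject log-scale effect)
    subject_effects: dict[str, float]
    #: (subject_id, session) -> v_js (session log-scale effect)
    session_effects: dict[tuple[str, int], float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "designed_icc": self.designed_icc,
            "nominal_fd": self.nominal_fd,
            "scales": {
                f"{s}|{c}|{sess}": list(v) for (s, c, sess), v in self.scales.items()
            },
            "subject_effects": self.subject_effects,
            "session_effects": {
                f"{s}|{sess}": v for (s, sess), v in self.session_effects.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def generate_fgn(
    n: int, hurst: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact stationary fractional Gaussian noise, unit variance.

    Davies-Harte circulant embedding: the length-2N circulant built from the
    fGn autocovariance is diagonalized by FFT; complex Gaussian weights with
    those eigenvalue variances transform back to an exact sample.  H = 0.5
    reduces to white noise.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 1:
        return rng.standard_normal(1)

    h2 = 2.0 * hurst
    k = np.arange(n, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)
    # circulant first row: gamma(0..N-1), gamma(N-2..1) — length 2N-2
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:
        raise ValueError(
            f"circulant embedding not nonnegative definite (min eigenvalue "
            f"{lam.min():.3g}); cannot generate exactly"
        )
    lam = np.clip(lam, 0.0, None)
    m = row.size  # 2n - 2
    half = m // 2  # = n - 1
    v = np.zeros(m, dtype=complex)
    v[0] = rng.standard_normal() * np.sqrt(lam[0])
    v[half] = rng.standard_normal() * np.sqrt(lam[half])
    u = rng.standard_normal(half - 1)
    w = rng.standard_normal(half - 1)
    v[1:half] = np.sqrt(lam[1:half] / 2.0) * (u + 1j * w)
    v[half + 1 :] = np.conj(v[half - 1 : 0 : -1])
    x = np.fft.fft(v) / np.sqrt(m)
    return x.real[:n]


def generate_fbm_trace(
    n: int,
    hurst: float,
    rng: np.random.Generator,
    leak_per_s: float = 0.0,
    sampling_rate_hz: float = 50.0,
) -> np.ndarray:
    """Fractional-Brownian-type trace: (leaky) cumulative sum of fGn.

    With ``leak_per_s = 0`` this is exact fBm-increment integration (Higuchi
    FD ~ 2 - H at every lag).  A positive leak rate theta turns the
    integrator into x_i = exp(-theta dt) x_{i-1} + g_i, which keeps the
    short-lag roughness (FD ~ 2 - H for lags << 1/theta) but bounds the
    excursion the way postural feedback bounds real CoP sway; beyond the
    correlation time 1/theta the curve-length slope drifts towards FD ~ 2,
    reproducing the empirical two-regime log-log shape.
    """
    g = generate_fgn(n, hurst, rng)
    if leak_per_s <= 0.0:
        return np.cumsum(g)
    a = np.exp(-leak_per_s / sampling_rate_hz)
    return lfilter([1.0], [1.0, -a], g)


def generate_ou_trace(
    n: int, theta: float, sampling_rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck trace with unit stationary variance.

    Exact AR(1) discretization: x_{t+1} = a x_t + sqrt(1 - a^2) eps,
    a = exp(-theta dt), x_0 ~ N(0, 1).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    dt = 1.0 / sampling_rate_hz
    a = np.exp(-theta * dt)
    eps = rng.standard_normal(n)
    c = np.sqrt(1.0 - a * a)
    return lfilter([1.0], [1.0, -a], np.concatenate([[eps[0]], c * eps[1:]]))


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(x)
    return x / sd


def _base_trace(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    if config.trace_model == "ou":
        return generate_ou_trace(n, config.ou_theta, config.sampling_rate_hz, rng)
    if config.trace_model == "fgn":
        return generate_fbm_trace(
            n, config.hurst, rng, config.fgn_leak_per_s, config.sampling_rate_hz
        )
    # mixture: equal parts standardized OU and leaky-fBm
    ou = _standardize(generate_ou_trace(n, config.ou_theta, config.sampling_rate_hz, rng))
    fbm = _standardize(
        generate_fbm_trace(
            n, config.hurst, rng, config.fgn_leak_per_s, config.sampling_rate_hz
        )
    )
    return ou + fbm


def generate_trial(
    scale_ml: float,
    scale_ap: float,
    config: SyntheticConfig,
    seed: int | np.random.Generator,
    *,
    subject_id: str = "synthetic",
    group: Group | str = Group.YOUNG,
    condition: Condition | str = Condition.FO,
    session: int = 1,
) -> CoPTrial:
    """One synthetic trial with realized per-axis positional SD = scale.

    Each axis is an independently generated trace (optionally correlated via
    ``config.axis_correlation``), standardized to unit sample SD and
    multiplied by its scale; scale 0 yields a constant (zero) axis.
    """
    if scale_ml < 0 or scale_ap < 0:
        raise ValueError("scales must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_ml = _standardize(_base_trace(config, rng))
    z_ap_raw = _standardize(_base_trace(config, rng))
    rho = config.axis_correlation
    if rho != 0.0:
        z_ap_raw = _standardize(rho * z_ml + np.sqrt(1.0 - rho**2) * z_ap_raw)
    ml = scale_ml * z_ml
    ap = scale_ap * z_ap_raw
    return CoPTrial(
        subject_id=subject_id,
        group=group,
        condition=condition,
        session=session,
        sampling_rate_hz=config.sampling_rate_hz,
        ml_cm=ml,
        ap_cm=ap,
    )


def generate_cohort(config: SyntheticConfig) -> tuple[TrialSet, GroundTruth]:
    """Full 2-session x 4-condition cohort with ground truth.

    For subject j: u_j ~ N(0, sigma_subject^2); per session s:
    v_js ~ N(0, sigma_session^2), shared across conditions within the
    session.  The trial scale on each axis is
    base_group x mult_condition x exp(u_j + v_js).  Output is bitwise
    reproducible for a fixed config (seeds are spawned deterministically).
    """
    ss = np.random.SeedSequence(config.seed)
    effect_rng = np.random.default_rng(ss.spawn(1)[0])
    trial_seed_root = ss.spawn(1)[0]

    trials = TrialSet(provenance=f"synthetic cohort, seed={config.seed}")
    scales: dict[tuple[str, str, int], tuple[float, float]] = {}
    subject_effects: dict[str, float] = {}
    session_effects: dict[tuple[str, int], float] = {}

    conditions = list(config.condition_multipliers)
    trial_children = iter(
        trial_seed_root.spawn(
            sum(g.n_subjects for g in config.groups.values()) * 2 * len(conditions)
        )
    )
    for group_name, spec in config.groups.items():
        for j in range(spec.n_subjects):
            sid = f"{group_name[0].upper()}{j + 1:03d}"
            u_j = effect_rng.normal(0.0, config.sigma_subject)
            subject_effects[sid] = float(u_j)
            for session in (1, 2):
                v_js = effect_rng.normal(0.0, config.sigma_session)
                session_effects[(sid, session)] = float(v_js)
                factor = float(np.exp(u_j + v_js))
                for cond in conditions:
                    mult = config.condition_multipliers[cond]
                    scale_ml = spec.base_scale_ml_cm * mult * factor
                    scale_ap = spec.base_scale_ap_cm * mult * factor
                    scales[(sid, cond, session)] = (scale_ml, scale_ap)
                    trial = generate_trial(
                        scale_ml,
                        scale_ap,
                        config,
                        np.random.default_rng(next(trial_children)),
                        subject_id=sid,
                        group=group_name,
                        condition=cond,
                        session=session,
                    )
                    trials.add(trial)

    truth = GroundTruth(
        designed_icc=config.designed_icc,
        nominal_fd=(2.0 - config.hurst) if config.trace_model in ("fgn", "mixture") else None,
        scales=scales,
        subject_effects=subject_effects,
        session_effects=session_effects,
    )
    return trials, truth
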