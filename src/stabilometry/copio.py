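"""Reading, writing and validating centre-of-pressure (CoP) trials.

A trial is one stabilogram: the medio-lateral (ML) and antero-posterior (AP)
CoP position in cm, sampled at a nominal 50 Hz for 60 s, plus the metadata
the reliability analysis needs (subject, age group, sensory condition,
session).  Files are plain delimited text (comma or tab), two or three
numeric columns: an optional time column in seconds, then ML and AP in cm.

The half-open sampling convention is used throughout: a 60-s trial at 50 Hz
holds N = rate x duration = 3000 samples at t = 0, 0.02, ..., 59.98 s, and
its duration is N / rate.  This makes mean velocity = total path / 60 s exact
for standard trials.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_SAMPLING_RATE_HZ",
    "DEFAULT_DURATION_S",
    "Group",
    "Condition",
    "CoPTrial",
    "TrialSet",
    "CoPError",
    "EmptyTrialError",
    "TrialParseError",
    "SamplingError",
    "DuplicateTrialError",
    "read_trial",
    "write_trial",
    "validate_trial",
    "read_manifest",
    "write_trialset",
]

DEFAULT_SAMPLING_RATE_HZ = 50.0
DEFAULT_DURATION_S = 60.0

#: numeric print format used for trial files; 12 significant digits so a
#: write -> read round trip preserves doubles to ~1e-12 relative.
_FLOAT_FMT = "%.12g"


class Group(str, Enum):
    """Age group of a participant."""

    YOUNG = "young"
    ELDERLY = "elderly"


class Condition(str, Enum):
    """The four modified Sensory Interaction Test conditions.

    Firm or compliant support surface crossed with eyes open or closed.
    """

    FO = "FO"  # firm surface, eyes open
    FC = "FC"  # firm surface, eyes closed
    CO = "CO"  # compliant surface, eyes open
    CC = "CC"  # compliant surface, eyes closed


class CoPError(ValueError):
    """Base class for trial I/O and validation errors."""


class EmptyTrialError(CoPError):
    """Trial has fewer than two samples."""


class TrialParseError(CoPError):
    """A trial file contains a malformed row."""


class SamplingError(CoPError):
    """The time column is not uniformly sampled within tolerance."""


class DuplicateTrialError(CoPError):
    """Two trials share (subject, condition, session) in one TrialSet."""


@dataclass
class CoPTrial:
    """One stabilogram with its metadata.

    ``ml_cm`` and ``ap_cm`` are equal-length arrays (N >= 2) of CoP position
    in cm; axis 1 is medio-lateral, axis 2 antero-posterior.  Non-finite
    samples are representable (so that validation can report them) but every
    analysis routine requires finite data.
    """

    subject_id: str
    group: Group
    condition: Condition
    session: int
    sampling_rate_hz: float
    ml_cm: np.ndarray
    ap_cm: np.ndarray

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.condition = Condition(self.condition)
        self.session = int(self.session)
        if self.session not in (1, 2):
            raise CoPError(f"session must be 1 or 2, got {self.session}")
        if not self.sampling_rate_hz > 0:
            raise CoPError(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )
        self.ml_cm = np.asarray(self.ml_cm, dtype=float)
        self.ap_cm = np.asarray(self.ap_cm, dtype=float)
        if self.ml_cm.ndim != 1 or self.ap_cm.ndim != 1:
            raise CoPError("ml_cm and ap_cm must be 1-D sequences")
        if self.ml_cm.size != self.ap_cm.size:
            raise CoPError(
                f"axis length mismatch: ML has {self.ml_cm.size} samples, "
                f"AP has {self.ap_cm.size}"
            )
        if self.ml_cm.size < 2:
            raise EmptyTrialError(
                f"trial needs at least 2 samples, got {self.ml_cm.size}"
            )

    @property
    def n(self) -> int:
        return int(self.ml_cm.size)

    @property
    def duration_s(self) -> float:
        """Trial duration under the half-open convention (N / rate)."""
        return self.n / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n) / self.sampling_rate_hz

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.condition.value, self.session)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.ml_cm).all() and np.isfinite(self.ap_cm).all())


@dataclass
class TrialSet:
    """A collection of trials with unique (subject, condition, session)."""

    trials: list[CoPTrial] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for t in self.trials:
            if t.key in seen:
                raise DuplicateTrialError(
                    f"duplicate trial for subject={t.key[0]!r} "
                    f"condition={t.key[1]} session={t.key[2]}"
                )
            seen.add(t.key)

    def add(self, trial: CoPTrial) -> None:
        if any(t.key == trial.key for t in self.trials):
            raise DuplicateTrialError(
                f"duplicate trial for subject={trial.key[0]!r} "
                f"condition={trial.key[1]} session={trial.key[2]}"
            )
        self.trials.append(trial)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _parse_rows(path: Path) -> list[tuple[int, list[float]]]:
    """Parse a delimited trial file into (line_number, floats) rows.

    A single leading non-numeric line is treated as a header.  Any other
    non-numeric row raises :class:`TrialParseError` naming the line.
    """
    text = path.read_text()
    rows: list[tuple[int, list[float]]] = []
    header_allowed = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(_sniff_delimiter(line))]
        try:
            values = [float(f) for f in fields]
        except ValueError:
            if header_allowed:
                header_allowed = False
                continue
            raise TrialParseError(
                f"{path}: non-numeric row at line {lineno}: {raw!r}"
            ) from None
        header_allowed = False
        rows.append((lineno, values))
    return rows


def read_trial(
    path: str | Path,
    *,
    subject_id: str,
    group: Group | str,
    condition: Condition | str,
    session: int,
    sampling_rate_hz: float | None = None,
    trim_leading_s: float = 0.0,
    dt_tolerance: float = 1e-3,
) -> CoPTrial:
    """Read one CoP trial from a delimited text file.

    Parameters
    ----------
    path
        Comma- or tab-delimited text with 2 columns (ML, AP) or 3 columns
        (time, ML, AP); one optional header line.
    sampling_rate_hz
        Required for 2-column files; for 3-column files the rate is inferred
        from the time column (median step) and the steps must be uniform to
        a relative ``dt_tolerance``.
    trim_leading_s
        Seconds to drop from the start (pre-acquisition settling); default 0
        assumes settling was excluded before export.
    """
    path = Path(path)
    rows = _parse_rows(path)
    if len(rows) < 2:
        raise EmptyTrialError(f"{path}: trial has {len(rows)} data rows (need >= 2)")
    ncols = len(rows[0][1])
    if ncols < 2:
        raise TrialParseError(f"{path}: need at least 2 numeric columns, got {ncols}")
    for lineno, values in rows:
        if len(values) != ncols:
            raise TrialParseError(
                f"{path}: inconsistent column count at line {lineno}"
            )
    data = np.asarray([v for _, v in rows], dtype=float)

    if ncols >= 3:
        t, ml, ap = data[:, 0], data[:, 1], data[:, 2]
        dt = np.diff(t)
        dt_med = float(np.median(dt))
        if dt_med <= 0:
            raise SamplingError(f"{path}: time column is not increasing")
        if np.max(np.abs(dt - dt_med)) > dt_tolerance * dt_med:
            worst = int(np.argmax(np.abs(dt - dt_med)))
            raise SamplingError(
                f"{path}: non-uniform sampling near row {worst + 1} "
                f"(dt={dt[worst]:.6g} s vs median {dt_med:.6g} s)"
            )
        rate = 1.0 / dt_med
        t0 = t - t[0]
    else:
        if sampling_rate_hz is None:
            sampling_rate_hz = DEFAULT_SAMPLING_RATE_HZ
        rate = float(sampling_rate_hz)
        ml, ap = data[:, 0], data[:, 1]
        t0 = np.arange(len(ml)) / rate

    if trim_leading_s > 0:
        keep = t0 >= trim_leading_s - 1e-12
        ml, ap = ml[keep], ap[keep]
        if ml.size < 2:
            raise EmptyTrialError(
                f"{path}: fewer than 2 samples remain after trimming "
                f"{trim_leading_s} s"
            )

    return CoPTrial(
        subject_id=subject_id,
        group=group,
        condition=condition,
        session=session,
        sampling_rate_hz=rate,
        ml_cm=ml,
        ap_cm=ap,
    )


def write_trial(trial: CoPTrial, path: str | Path) -> None:
    """Write a trial as CSV with time_s, ml_cm, ap_cm columns."""
    if trial.n < 2:
        raise EmptyTrialError("refusing to write a trial with fewer than 2 samples")
    path = Path(path)
    t = trial.time_s
    with path.open("w", newline="") as fh:
        fh.write("time_s,ml_cm,ap_cm\n")
        for ti, mli, api in zip(t, trial.ml_cm, trial.ap_cm):
            fh.write(
                f"{_FLOAT_FMT % ti},{_FLOAT_FMT % mli},{_FLOAT_FMT % api}\n"
            )


def validate_trial(
    trial: CoPTrial,
    expected_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    expected_duration_s: float = DEFAULT_DURATION_S,
    tolerance: float = 0.01,
) -> list[str]:
    """Check a trial against the acquisition conventions; return findings.

    An empty list means the trial matches the expected sampling rate and
    duration within relative ``tolerance`` and all samples are finite.
    Findings are human-readable strings; nothing is raised.
    """
    findings: list[str] = []
    if abs(trial.sampling_rate_hz - expected_rate_hz) > tolerance * expected_rate_hz:
        findings.append(
            f"sampling rate {trial.sampling_rate_hz:g} Hz differs from expected "
            f"{expected_rate_hz:g} Hz"
        )
    if abs(trial.duration_s - expected_duration_s) > tolerance * expected_duration_s:
        findings.append(
            f"duration {trial.duration_s:g} s differs from expected "
            f"{expected_duration_s:g} s"
        )
    for name, series in (("ML", trial.ml_cm), ("AP", trial.ap_cm)):
        bad = np.flatnonzero(~np.isfinite(series))
        if bad.size:
            findings.append(
                f"{name} series has {bad.size} non-finite sample(s), "
                f"first at index {bad[0]}"
            )
    return findings


_MANIFEST_FIELDS = ["path", "subject_id", "group", "condition", "session"]


def read_manifest(
    manifest_path: str | Path,
    *,
    sampling_rate_hz: float | None = None,
) -> TrialSet:
    """Load a batch of trials listed in a manifest CSV.

    The manifest has one row per trial with columns
    path, subject_id, group, condition, session; relative paths are resolved
    against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    trials = TrialSet(provenance=f"manifest: {manifest_path}")
    with manifest_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_FIELDS) - set(reader.fieldnames or [])
        if missing:
            raise TrialParseError(
                f"{manifest_path}: manifest missing columns {sorted(missing)}"
            )
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            trials.add(
                read_trial(
                    p,
                    subject_id=row["subject_id"],
                    group=row["group"],
                    condition=row["condition"],
                    session=int(row["session"]),
                    sampling_rate_hz=sampling_rate_hz,
                )
            )
    return trials


def write_trialset(trialset: TrialSet, out_dir: str | Path) -> Path:
    """Write every trial plus a manifest.csv under ``out_dir``.

    Returns the manifest path.  File names encode the trial key so a round
    trip through :func:`read_manifest` reproduces the set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_FIELDS)
        for trial in trialset:
            fname = (
                f"{trial.subject_id}_{trial.condition.value}_s{trial.session}.csv"
            )
            write_trial(trial, out_dir / fname)
            writer.writerow(
                [
                    fname,
                    trial.subject_id,
                    trial.group.value,
                    trial.condition.value,
                    trial.session,
                ]
            )
    return manifest
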