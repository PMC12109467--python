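"""Synthetic data with known ground truth.

Two generators back the test strategy:

* :func:`generate_recording` synthesizes a rotary-pump-like acceleration
  signal — a fundamental near 42-47 Hz plus 11 higher harmonics with
  prescribed relative powers over a white Gaussian noise floor — so the
  whole spectral chain (PSD → windowed harmonic power → 0 dB
  normalization) can be verified against a known signature.
* :func:`generate_cohort` and :func:`studylike_cohort` produce labeled
  harmonic-power feature tables with controlled two-class geometry, so the
  cross-validation engine can be exercised on cohorts whose correct
  behavior is known by construction.

Defaults are sized for fast tests (6 kHz, 10 s): the 12th harmonic of a
47 Hz fundamental sits at 564 Hz, far below the 3 kHz Nyquist, and 10 s
gives a 0.1 Hz periodogram grid — ample for 1 Hz integration windows. The
clinical recording geometry (60 kHz, 60 s) is available by passing those
values explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import HarmonicProfile, Recording
from .spectral import normalize_profile

__all__ = [
    "SyntheticSignalSpec",
    "SyntheticCohortSpec",
    "generate_recording",
    "generate_cohort",
    "studylike_cohort",
]


@dataclass(frozen=True)
class SyntheticSignalSpec:
    """Generative parameters for one synthetic pump recording.

    ``harmonic_db`` are target normalized powers (they are re-normalized
    to a 0 dB sum on construction); ``total_power`` is the linear variance
    of the harmonic component; ``noise_db`` the broadband noise power
    relative to the total harmonic power (-inf for noiseless).
    """

    ff: float  # Hz
    harmonic_db: tuple[float, ...]
    total_power: float = 1.0
    noise_db: float = -30.0
    sampling_rate: float = 6000.0
    duration: float = 10.0
    phase_seed: int = 0
    noise_seed: int = 1
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.harmonic_db) != 12:
            raise ValueError("harmonic_db must have 12 entries")
        if self.duration < 2.0:
            raise ValueError("duration must be at least 2 s")
        if 12.0 * self.ff >= self.sampling_rate / 2.0:
            raise ValueError(
                f"12 x {self.ff} Hz = {12 * self.ff:.0f} Hz reaches Nyquist "
                f"{self.sampling_rate / 2:.0f} Hz (aliasing)")
        object.__setattr__(
            self, "harmonic_db",
            tuple(float(v) for v in normalize_profile(self.harmonic_db)))


def generate_recording(spec: SyntheticSignalSpec) -> Recording:
    """Synthesize samples = sum_n sqrt(2 p_n) sin(2 pi n ff t + phi_n) + noise.

    Linear harmonic powers ``p_n`` scale to ``total_power``; phases are
    seeded uniform draws (PSD features are phase-invariant, which a test
    asserts). Reproducible given (phase_seed, noise_seed).
    """
    n = int(round(spec.sampling_rate * spec.duration))
    t = np.arange(n) / spec.sampling_rate
    linear = 10.0 ** (np.asarray(spec.harmonic_db) / 10.0)
    powers = spec.total_power * linear / linear.sum()
    phases = np.random.default_rng(spec.phase_seed).uniform(0, 2 * np.pi, 12)
    samples = np.zeros(n)
    for h, (p, phi) in enumerate(zip(powers, phases), start=1):
        samples += np.sqrt(2.0 * p) * np.sin(2 * np.pi * h * spec.ff * t + phi)
    if np.isfinite(spec.noise_db):
        noise_power = spec.total_power * 10.0 ** (spec.noise_db / 10.0)
        samples = samples + np.random.default_rng(spec.noise_seed).normal(
            0.0, np.sqrt(noise_power), n)
    return Recording(patient_id=spec.patient_id, samples=samples,
                     sampling_rate=spec.sampling_rate)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-class Gaussian feature-table generator parameters.

    Rows are multivariate-normal draws around per-class mean vectors (dB)
    with a shared covariance; used to hand the CV engine cohorts of known
    separability.
    """

    n_no: int = 8
    n_yes: int = 3
    mean_no: tuple[float, ...] = (-0.5, -26.0, -36.0)
    mean_yes: tuple[float, ...] = (-1.0, -13.0, -24.0)
    covariance: float | tuple = 1.0  # scalar -> cov * I
    variables: tuple[str, ...] = ("P_FF", "P_2H", "P_3H")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_no < 1 or self.n_yes < 1:
            raise ValueError("need at least one row per class")
        if len(self.mean_no) != len(self.variables) or \
                len(self.mean_yes) != len(self.variables):
            raise ValueError("class means must match the variable count")

    def cov_matrix(self) -> np.ndarray:
        d = len(self.variables)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(d)
        if cov.shape != (d, d) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be scalar or symmetric (d, d)")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")
        return cov


def _fill_profile(values: np.ndarray, variables: tuple[str, ...]) -> tuple[float, ...]:
    """Embed generated variable values into a full 12-vector.

    Unspecified harmonics get a deep decaying tail (-40 dB and below) so
    they carry negligible power. The drawn values are stored as-is — these
    tables exercise the CV engine with a prescribed class geometry, which
    a per-row 0 dB renormalization would distort — so, unlike extracted
    profiles, their linearized sum is close to but not exactly 1.
    """
    from .cohort import HARMONIC_COLUMNS
    full = np.array([-40.0 - 1.5 * i for i in range(12)])
    for name, v in zip(variables, values):
        full[HARMONIC_COLUMNS.index(name)] = v
    return tuple(float(x) for x in full)


def generate_cohort(spec: SyntheticCohortSpec) -> list[HarmonicProfile]:
    """Seeded two-class Gaussian cohort, NO rows first, labels attached."""
    rng = np.random.default_rng(spec.seed)
    cov = spec.cov_matrix()
    rows: list[HarmonicProfile] = []
    for label, n, mean in (("NO", spec.n_no, spec.mean_no),
                           ("YES", spec.n_yes, spec.mean_yes)):
        draws = rng.multivariate_normal(np.asarray(mean, dtype=float), cov, size=n)
        for i, values in enumerate(draws, start=1):
            rows.append(HarmonicProfile(
                patient_id=f"SYN-{label}-{i}",
                power_db=_fill_profile(values, spec.variables),
                outcome=label))
    return rows


def studylike_cohort(seed: int = 0) -> list[HarmonicProfile]:
    """An 11-row cohort shaped like the clinical one: 3 YES, 8 NO.

    The geometry in (P_FF, P_2H, P_3H) mirrors the study cohort's failure
    mechanism: a tight YES cluster, a well-separated main NO cluster of
    six, and two NO "confuser" rows placed nearer to the YES cluster than
    to the NO cluster. When both confusers are held out together, a
    1-nearest-neighbor model trained on the rest misreads them as
    thrombotic — the analogue of the [HW-B, HW-G] validation pair — while
    leave-one-out keeps one confuser in training and classifies correctly.
    """
    rng = np.random.default_rng(seed)
    centers = {
        "YES": np.array([-0.8, -13.0, -24.0]),
        "NO": np.array([-0.1, -27.0, -37.0]),
        "CONF": np.array([-3.5, -11.5, -22.5]),
    }
    rows = []
    jitter = 0.4  # dB; small vs the ~14 dB cluster separation
    for i in range(3):
        rows.append((f"SYN-YES-{i + 1}", "YES",
                     centers["YES"] + rng.normal(0, jitter, 3)))
    for i in range(6):
        rows.append((f"SYN-NO-{i + 1}", "NO",
                     centers["NO"] + rng.normal(0, jitter, 3)))
    for i in range(2):
        rows.append((f"SYN-CONF-{i + 1}", "NO",
                     centers["CONF"] + rng.normal(0, jitter, 3)))
    return [HarmonicProfile(pid, _fill_profile(vals, ("P_FF", "P_2H", "P_3H")),
                            outcome)
            for pid, outcome, vals in rows]
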