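"""Synthetic gait recordings with per-subject signatures.

The generator is a signal-level surrogate for a walking subject carrying a
phone in a fixed but arbitrary orientation: body-frame vertical acceleration
is gravity plus a small sum of harmonics of the subject's step frequency
(walking cadence, 1.4–2.6 Hz) plus Gaussian noise, with smaller independent
horizontal components; the gyroscope channel oscillates about zero with the
same cadence.  Both channels are rotated into the sensor frame by the
device's rotation matrix.  Noise is drawn in the body frame *before*
rotation, so the whole preprocessing chain is exactly
orientation-invariant on simulated data.

"easy" cohorts space step frequencies ≥ 0.15 Hz apart with low noise;
"hard" cohorts draw frequencies freely (overlap allowed) with higher noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import DomainError
from .sensor_io import TriaxialSeries, write_triaxial_csv

Separability = Literal["easy", "hard"]

STEP_FREQ_RANGE = (1.4, 2.6)  # Hz, walking cadence
EASY_MIN_GAP_HZ = 0.15
DEFAULT_GRAVITY = 9.81  # m/s²
N_HARMONICS = 3


@dataclass
class SyntheticUserProfile:
    """Everything that determines one subject's simulated recordings."""

    subject_id: str
    step_frequency_hz: float
    harmonic_amps: np.ndarray  # m/s², harmonics 1..H of the step frequency
    harmonic_phases: np.ndarray  # rad
    noise_sd: float  # m/s²
    gyro_amp: float  # rad/s
    device_rotation: np.ndarray  # 3×3, orthonormal, det +1
    gravity_mag: float = DEFAULT_GRAVITY
    noise_seed: int = 0

    def __post_init__(self) -> None:
        self.harmonic_amps = np.asarray(self.harmonic_amps, dtype=float)
        self.harmonic_phases = np.asarray(self.harmonic_phases, dtype=float)
        self.device_rotation = np.asarray(self.device_rotation, dtype=float)
        if len(self.harmonic_amps) != len(self.harmonic_phases):
            raise DomainError("harmonic_amps and harmonic_phases differ in length")
        R = self.device_rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DomainError("device_rotation must be a 3×3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise DomainError("device_rotation must be a proper rotation (det +1)")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _draw_profile(rng: np.random.Generator, subject_id: str, step_freq: float,
                  separability: Separability) -> SyntheticUserProfile:
    if separability == "easy":
        noise_sd = rng.uniform(0.05, 0.15)
    else:
        noise_sd = rng.uniform(0.3, 0.8)
    # fundamental 1–3 m/s², decaying higher harmonics; phases free
    base = rng.uniform(1.0, 3.0)
    decay = rng.uniform(0.3, 0.6)
    amps = base * decay ** np.arange(N_HARMONICS)
    phases = rng.uniform(0, 2 * np.pi, size=N_HARMONICS)
    return SyntheticUserProfile(
        subject_id=subject_id,
        step_frequency_hz=step_freq,
        harmonic_amps=amps,
        harmonic_phases=phases,
        noise_sd=noise_sd,
        gyro_amp=rng.uniform(0.5, 1.5),
        device_rotation=random_rotation(rng),
        noise_seed=int(rng.integers(2**31)),
    )


def sample_profile(seed: int, separability: Separability = "easy",
                   subject_id: str = "user00",
                   step_frequency_hz: float | None = None) -> SyntheticUserProfile:
    """Draw one subject profile, fully determined by ``seed``."""
    if separability not in ("easy", "hard"):
        raise DomainError(f"separability must be 'easy' or 'hard', got {separability!r}")
    rng = np.random.default_rng(seed)
    if step_frequency_hz is None:
        step_frequency_hz = float(rng.uniform(*STEP_FREQ_RANGE))
    return _draw_profile(rng, subject_id, step_frequency_hz, separability)


def _cohort_frequencies(n_users: int, rng: np.random.Generator,
                        separability: Separability) -> np.ndarray:
    lo, hi = STEP_FREQ_RANGE
    if separability == "hard":
        return rng.uniform(lo, hi, size=n_users)
    # evenly spaced with jitter small enough to keep pairwise gaps >= 0.15 Hz
    if n_users == 1:
        return np.array([rng.uniform(lo, hi)])
    spacing = (hi - lo) / (n_users - 1)
    # for cohorts too large to honour the 0.15 Hz gap inside the cadence
    # range, fall back to maximal even spacing (still distinct frequencies)
    jitter_max = max(0.0, (spacing - EASY_MIN_GAP_HZ) / 2)
    base = np.linspace(lo, hi, n_users)
    freqs = base + rng.uniform(-jitter_max, jitter_max, size=n_users)
    # clipping keeps cadences inside the walking range; adjacent gaps stay
    # >= spacing - jitter_max >= (spacing + min_gap)/2 >= min_gap
    return rng.permutation(np.clip(freqs, lo, hi))


def sample_cohort_profiles(n_users: int, seed: int,
                           separability: Separability = "easy"
                           ) -> list[SyntheticUserProfile]:
    """Draw ``n_users`` distinct profiles, deterministic in ``seed``."""
    if n_users < 1:
        raise DomainError("n_users must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = _cohort_frequencies(n_users, rng, separability)
    return [
        _draw_profile(rng, f"user{i:02d}", float(freqs[i]), separability)
        for i in range(n_users)
    ]


def simulate_walk(profile: SyntheticUserProfile, duration_s: float, fs_hz: float
                  ) -> tuple[TriaxialSeries, TriaxialSeries]:
    """Simulate one walk: synchronized accelerometer and gyroscope streams.

    Body-frame model (z = vertical):

        a_z(t) = g + Σ_k A_k sin(2π k f t + φ_k) + ε,  ε ~ N(0, σ²)
        a_x, a_y: harmonics at ~30% of the vertical amplitudes, own phases
        ω_z(t): gyro_amp-scaled harmonics about zero; ω_x, ω_y smaller

    Both streams are then rotated by the device rotation.  The body-frame
    noise realisation depends only on ``profile.noise_seed``, never on the
    rotation.
    """
    n = int(round(duration_s * fs_hz))
    if n < 2:
        raise DomainError("duration_s * fs_hz must be >= 2 samples")
    t = np.arange(n) / fs_hz
    rng = np.random.default_rng(profile.noise_seed)
    f = profile.step_frequency_hz
    k = np.arange(1, len(profile.harmonic_amps) + 1)
    # (n, H) bank of harmonics
    phases = 2 * np.pi * np.outer(t, k) * f

    a_z = profile.gravity_mag + (np.sin(phases + profile.harmonic_phases)
                                 @ profile.harmonic_amps)
    horiz_phases = rng.uniform(0, 2 * np.pi, size=(2, len(k)))
    a_x = np.sin(phases + horiz_phases[0]) @ (0.3 * profile.harmonic_amps)
    a_y = np.sin(phases + horiz_phases[1]) @ (0.3 * profile.harmonic_amps)
    acc_body = np.column_stack([a_x, a_y, a_z])
    acc_body += rng.normal(0.0, profile.noise_sd, size=acc_body.shape)

    g_amps = profile.gyro_amp * (0.6 ** np.arange(len(k)))
    gyro_phases = rng.uniform(0, 2 * np.pi, size=(3, len(k)))
    w_z = np.sin(phases + gyro_phases[0]) @ g_amps
    w_x = np.sin(phases + gyro_phases[1]) @ (0.3 * g_amps)
    w_y = np.sin(phases + gyro_phases[2]) @ (0.3 * g_amps)
    gyro_body = np.column_stack([w_x, w_y, w_z])
    gyro_body += rng.normal(0.0, 0.1 * profile.gyro_amp + 0.01, size=gyro_body.shape)

    R = profile.device_rotation
    acc = TriaxialSeries(profile.subject_id, "accelerometer", fs_hz, t,
                         acc_body @ R.T)
    gyro = TriaxialSeries(profile.subject_id, "gyroscope", fs_hz, t,
                          gyro_body @ R.T)
    return acc, gyro


@dataclass
class SyntheticCohort:
    """A simulated cohort: per-subject profiles and recordings."""

    profiles: list[SyntheticUserProfile]
    recordings: list[tuple[TriaxialSeries, TriaxialSeries]]  # (acc, gyro) per subject
    seed: int
    manifest: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]


def simulate_cohort(
    n_users: int,
    duration_s: float = 600.0,
    fs_hz: float = 50.0,
    seed: int = 0,
    separability: Separability = "easy",
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Simulate a labelled cohort; optionally write it as a CSV corpus.

    Defaults emulate the study conditions: ~10 min of walking at ~50 Hz
    (30,000 samples) per subject.  With ``out_dir`` set, per-subject
    accelerometer/gyroscope CSVs plus a JSON manifest are written in the
    default t,x,y,z dialect; the corpus is byte-identical for a given seed.
    """
    if n_users < 2:
        raise DomainError("a cohort needs at least 2 users")
    profiles = sample_cohort_profiles(n_users, seed, separability)
    recordings = [simulate_walk(p, duration_s, fs_hz) for p in profiles]
    manifest = {
        "seed": seed,
        "n_users": n_users,
        "duration_s": duration_s,
        "fs_hz": fs_hz,
        "separability": separability,
        "subjects": {},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for profile, (acc, gyro) in zip(profiles, recordings):
        entry = {
            "step_frequency_hz": profile.step_frequency_hz,
            "n_samples": len(acc),
        }
        if out_dir is not None:
            acc_path = out_dir / f"{profile.subject_id}_accelerometer.csv"
            gyro_path = out_dir / f"{profile.subject_id}_gyroscope.csv"
            write_triaxial_csv(acc, acc_path)
            write_triaxial_csv(gyro, gyro_path)
            entry["accelerometer"] = acc_path.name
            entry["gyroscope"] = gyro_path.name
        manifest["subjects"][profile.subject_id] = entry
    if out_dir is not None:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return SyntheticCohort(profiles, recordings, seed, manifest)
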