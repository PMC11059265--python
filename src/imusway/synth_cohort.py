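"""Synthetic sway cohort: subject table plus IMU recordings.

Each horizontal sway axis (ML, AP) is simulated as an independent
white-noise-driven damped second-order process integrated by
Euler-Maruyama; the measured acceleration is the smooth restoring term
plus a slow drift and sensor noise.  The vertical channel carries gravity
plus a small bobbing component, and gyroscope channels are scaled
angular-velocity analogues of the sway states.  Group differences are
planted by :func:`plant_group_effect`, which shifts the impaired group
toward faster, broader-band, lower-amplitude sway (higher path length,
velocity and spectral spread; lower excursion amplitude).

Sub-seeding is counter-based per (subject, session, trial), so cohorts
are reproducible and adding subjects does not perturb existing ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ModelError
from .signal_prep import IMURecording, SESSIONS, recording_filename, write_recording

__all__ = [
    "CohortSpec",
    "SwayModelParams",
    "DEFAULT_DEMOGRAPHICS",
    "default_params",
    "simulate_sway_trial",
    "plant_group_effect",
    "generate_cohort",
    "write_cohort",
]

#: (mean, sd) per variable and male proportion, per group.  Values follow
#: the demographic profile of a 30/30 CN-vs-MCI balance cohort.
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float] | float]] = {
    "CN": {
        "mmse": (27.53, 2.029),
        "age": (74.77, 4.797),
        "height_cm": (160.35, 7.06),
        "weight_kg": (61.64, 7.21),
        "education_yr": (9.97, 4.498),
        "male_prop": 16 / 30,
    },
    "MCI": {
        "mmse": (25.87, 3.36),
        "age": (76.53, 3.45),
        "height_cm": (162.76, 8.72),
        "weight_kg": (63.26, 8.24),
        "education_yr": (10.70, 4.55),
        "male_prop": 20 / 30,
    },
}

_DEMO_BOUNDS = {
    "mmse": (0.0, 30.0),
    "age": (50.0, 100.0),
    "height_cm": (120.0, 210.0),
    "weight_kg": (30.0, 150.0),
    "education_yr": (0.0, 25.0),
}

#: Session difficulty: harder stances drive more sway.
SESSION_NOISE_SCALE = {"EO": 1.0, "EC": 1.3, "RL": 1.6, "LL": 1.6}


@dataclass(frozen=True)
class SwayModelParams:
    """Parameters of the per-axis damped second-order sway process."""

    noise_intensity: float = 0.02   # (m/s^2) * Hz^(1/2) white drive
    stiffness: float = 39.5         # s^-2 (natural frequency ~1 Hz)
    damping: float = 3.0            # s^-1
    drift_amp: float = 0.01         # m/s^2, low-frequency drift amplitude
    gyro_noise_sd: float = 0.1      # deg/s
    accel_noise_sd: float = 0.005   # m/s^2
    gravity: float = 9.81           # m/s^2, on the V axis
    gyro_gain: float = 50.0         # deg/s per unit sway-velocity state
    gyro_drift_amp: float = 0.15    # deg/s, slow rotational drift amplitude
    gyro_stiffness: float | None = None  # s^-2 rotational process; None = stiffness
    gyro_ml_stiffness: float | None = None  # ML rotational override; None = gyro_stiffness
    gyro_ml_damping: float | None = None    # ML rotational override; None = damping

    def validate(self) -> None:
        vals = [
            self.noise_intensity, self.stiffness, self.damping, self.drift_amp,
            self.gyro_noise_sd, self.accel_noise_sd, self.gravity, self.gyro_gain,
            self.gyro_drift_amp,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ModelError("sway model parameters must be finite")
        if self.stiffness <= 0 or self.damping <= 0:
            raise ModelError("stiffness and damping must be positive")
        for name in ("gyro_stiffness", "gyro_ml_stiffness", "gyro_ml_damping"):
            val = getattr(self, name)
            if val is not None and not (np.isfinite(val) and val > 0):
                raise ModelError(f"{name} must be positive and finite")
        if min(self.noise_intensity, self.drift_amp,
               self.gyro_noise_sd, self.accel_noise_sd) < 0:
            raise ModelError("noise amplitudes must be non-negative")

    @property
    def natural_freq_hz(self) -> float:
        return float(np.sqrt(self.stiffness) / (2 * np.pi))


@dataclass
class CohortSpec:
    """Configuration of one synthetic cohort."""

    n_cn: int = 30
    n_mci: int = 30
    trials_per_subject: int = 2
    sessions: tuple[str, ...] = SESSIONS
    trial_duration_s: float = 30.0
    fs: float = 64.0
    effect_scale: float = 1.0
    seed: int = 0
    subject_jitter: float = 0.12
    demographics_profile: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()}
    )

    def validate(self, base: SwayModelParams) -> None:
        if self.n_cn < 2:
            raise ConfigurationError(f"n_cn must be >= 2, got {self.n_cn}")
        if self.n_mci < 2:
            raise ConfigurationError(f"n_mci must be >= 2, got {self.n_mci}")
        if self.trials_per_subject < 1:
            raise ConfigurationError(
                f"trials_per_subject must be >= 1, got {self.trials_per_subject}"
            )
        if self.trial_duration_s < 10:
            raise ConfigurationError(
                f"trial_duration_s must be >= 10, got {self.trial_duration_s}"
            )
        if self.effect_scale < 0:
            raise ConfigurationError(
                f"effect_scale must be >= 0, got {self.effect_scale}"
            )
        unknown = set(self.sessions) - set(SESSIONS)
        if unknown:
            raise ConfigurationError(f"sessions contains unknown labels {unknown}")
        mci_params = plant_group_effect(base, self.effect_scale)
        f_max = max(base.natural_freq_hz, mci_params.natural_freq_hz)
        if self.fs <= 2 * f_max:
            raise ConfigurationError(
                f"fs={self.fs} must exceed twice the sway model's highest "
                f"characteristic frequency ({f_max:.2f} Hz)"
            )


def default_params() -> SwayModelParams:
    return SwayModelParams()


def plant_group_effect(
    params: SwayModelParams, effect_scale: float
) -> SwayModelParams:
    """Impaired-group parameters at the given effect size.

    Monotonically (in ``effect_scale``) raises the process's natural
    frequency and bandwidth while lowering the drive and drift amplitude,
    so extracted features shift toward higher MVELO/TOTEX/MFREQ and
    spectral entropy with lower RMS/MDIST/AREA-CC.  ``effect_scale = 0``
    returns the parameters unchanged.
    """
    if effect_scale < 0:
        raise ConfigurationError(
            f"effect_scale must be >= 0, got {effect_scale}"
        )
    e = float(effect_scale)
    if e == 0:
        return params
    return replace(
        params,
        stiffness=params.stiffness * (1 + 1.5 * e),
        damping=params.damping * (1 + 1.0 * e),
        noise_intensity=params.noise_intensity * max(1 - 0.25 * e, 0.05),
        drift_amp=params.drift_amp * max(1 - 0.5 * e, 0.0),
        # slower rotational control; the raised damping broadens the AP/V
        # gyro spectra (entropy up) while the ML rotation becomes slow and
        # narrow, pulling its spectral edge down
        gyro_stiffness=(params.gyro_stiffness or params.stiffness) / (1 + 0.5 * e),
        gyro_ml_stiffness=(
            params.gyro_ml_stiffness
            or params.gyro_stiffness
            or params.stiffness
        ) / (1 + 3.0 * e),
        gyro_ml_damping=(params.gyro_ml_damping or params.damping) / (1 + 0.5 * e),
    )


def _sway_process(
    rng: np.random.Generator, params: SwayModelParams, n: int, fs: float,
    drive_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of x'' = -k x - c x' + sigma xi(t).

    Returns (acceleration, velocity) state series of length n.  The state
    is initialized from the stationary distribution so trials need no
    burn-in.
    """
    k, c = params.stiffness, params.damping
    sigma = params.noise_intensity * drive_scale
    dt = 1.0 / fs
    if sigma == 0:
        return np.zeros(n), np.zeros(n)
    x = rng.normal(0.0, sigma / np.sqrt(2 * c * k))
    v = rng.normal(0.0, sigma / np.sqrt(2 * c))
    kicks = rng.normal(0.0, sigma * np.sqrt(dt), size=n)
    acc = np.empty(n)
    vel = np.empty(n)
    for i in range(n):
        a = -k * x - c * v
        acc[i] = a
        vel[i] = v
        x = x + v * dt
        v = v + a * dt + kicks[i]
    return acc, vel


def _drift(rng: np.random.Generator, amp: float, n: int, fs: float) -> np.ndarray:
    """Slow quasi-sinusoidal drift (random frequency in 0.05-0.2 Hz)."""
    if amp == 0:
        return np.zeros(n)
    f = rng.uniform(0.05, 0.2)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * f * t + phase)


def simulate_sway_trial(
    params: SwayModelParams,
    duration_s: float,
    fs: float,
    seed,
    subject_id: str = "S000",
    session: str = "EO",
    trial: int = 1,
) -> IMURecording:
    """Simulate one trial's IMU recording from the sway model."""
    params.validate()
    if duration_s < 10:
        raise ConfigurationError(f"duration_s must be >= 10, got {duration_s}")
    if fs < 32:
        raise ConfigurationError(f"fs must be >= 32, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))

    a_ml, v_ml = _sway_process(rng, params, n, fs)
    a_ap, v_ap = _sway_process(rng, params, n, fs)
    # vertical bobbing: a weaker independent copy of the sway process
    a_v, v_v = _sway_process(rng, params, n, fs, drive_scale=0.3)
    # rotational states behind the gyroscope channels
    rot_params = replace(
        params, stiffness=params.gyro_stiffness or params.stiffness
    )
    rot_ml_params = replace(
        params,
        stiffness=params.gyro_ml_stiffness
        or params.gyro_stiffness
        or params.stiffness,
        damping=params.gyro_ml_damping or params.damping,
    )
    _, w_ml = _sway_process(rng, rot_ml_params, n, fs)
    _, w_ap = _sway_process(rng, rot_params, n, fs)
    _, w_v = _sway_process(rng, rot_params, n, fs, drive_scale=0.3)

    acc = np.empty((3, n))
    acc[0] = a_ml + _drift(rng, params.drift_amp, n, fs)
    acc[1] = params.gravity + a_v + _drift(rng, 0.3 * params.drift_amp, n, fs)
    acc[2] = a_ap + _drift(rng, params.drift_amp, n, fs)
    if params.accel_noise_sd > 0:
        acc += rng.normal(0.0, params.accel_noise_sd, size=(3, n))

    gyr = np.empty((3, n))
    # drift amplitude is tied to the drive so the all-zero example stays zero
    g_drift = params.gyro_drift_amp if params.noise_intensity > 0 else 0.0
    gyr[0] = params.gyro_gain * w_ml + _drift(rng, g_drift, n, fs)
    gyr[1] = params.gyro_gain * w_v + _drift(rng, 0.3 * g_drift, n, fs)
    gyr[2] = params.gyro_gain * w_ap + _drift(rng, g_drift, n, fs)
    if params.gyro_noise_sd > 0:
        gyr += rng.normal(0.0, params.gyro_noise_sd, size=(3, n))

    return IMURecording(
        subject_id=subject_id, session=session, trial=trial,
        fs=float(fs), acc=acc, gyr=gyr,
    )


def _jitter_params(
    params: SwayModelParams, rng: np.random.Generator, sd: float
) -> SwayModelParams:
    """Per-subject lognormal variation of the core process parameters."""
    if sd <= 0:
        return params
    m = rng.lognormal(mean=0.0, sigma=sd, size=3)
    return replace(
        params,
        noise_intensity=params.noise_intensity * m[0],
        stiffness=params.stiffness * m[1],
        damping=params.damping * m[2],
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _sample_demographics(
    rng: np.random.Generator, profile: dict
) -> dict[str, float | str]:
    row: dict[str, float | str] = {}
    for var in ("mmse", "age", "height_cm", "weight_kg", "education_yr"):
        mean, sd = profile[var]
        lo, hi = _DEMO_BOUNDS[var]
        row[var] = round(_truncated_normal(rng, mean, sd, lo, hi), 1)
    row["mmse"] = float(int(round(row["mmse"])))
    row["sex"] = "M" if rng.random() < profile["male_prop"] else "F"
    return row


def generate_cohort(
    spec: CohortSpec, base_params: SwayModelParams | None = None
) -> tuple[pd.DataFrame, list[IMURecording]]:
    """Generate the subject table and every trial recording of a cohort.

    Returns ``(subjects, recordings)`` with exactly
    ``(n_cn + n_mci) * trials_per_subject * len(sessions)`` recordings.
    The MCI MMSE distribution sits below the CN one by profile; signals
    depend on the group only through :func:`plant_group_effect`, so at
    ``effect_scale = 0`` the label is independent of all signals.
    """
    base = base_params if base_params is not None else default_params()
    spec.validate(base)

    n_total = spec.n_cn + spec.n_mci
    rows = []
    recordings: list[IMURecording] = []
    for i in range(n_total):
        group = "CN" if i < spec.n_cn else "MCI"
        sid = f"S{i + 1:03d}"
        demo_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, i, 10**6])
        )
        row = {"subject_id": sid, "group": group}
        row.update(_sample_demographics(demo_rng, spec.demographics_profile[group]))
        rows.append(row)

        jitter_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, i, 10**6 + 1])
        )
        subj_params = _jitter_params(base, jitter_rng, spec.subject_jitter)
        if group == "MCI":
            subj_params = plant_group_effect(subj_params, spec.effect_scale)

        for s_idx, session in enumerate(spec.sessions):
            sess_params = replace(
                subj_params,
                noise_intensity=subj_params.noise_intensity
                * SESSION_NOISE_SCALE[session],
            )
            for trial in range(1, spec.trials_per_subject + 1):
                trial_seed = np.random.SeedSequence([spec.seed, i, s_idx, trial])
                recordings.append(
                    simulate_sway_trial(
                        sess_params,
                        spec.trial_duration_s,
                        spec.fs,
                        trial_seed,
                        subject_id=sid,
                        session=session,
                        trial=trial,
                    )
                )

    subjects = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "mmse", "age", "sex",
            "height_cm", "weight_kg", "education_yr",
        ],
    )
    return subjects, recordings


def write_cohort(
    subjects: pd.DataFrame, recordings: list[IMURecording], out_dir: str
) -> None:
    """Write ``subjects.csv`` plus one CSV per trial into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    subjects.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    for rec in recordings:
        write_recording(rec, os.path.join(out_dir, recording_filename(rec)))
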