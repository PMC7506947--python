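"""Synthetic throwing-study generator.

Emulates a laboratory session protocol in which each participant performs
five throws of each of five throw types (low-, medium- and maximum-intensity
standing throws without run-up, a maximum-intensity standing throw with
run-up, and a jump throw) while two instruments record simultaneously:

* a 3-D motion-capture system samples a ball marker and a hand marker at
  240 Hz, from which the ground-truth release speed is later measured, and
* a wrist-worn triaxial accelerometer samples continuously at 500 Hz for the
  whole session, from which one peak-total-acceleration feature per throw is
  later extracted.

The statistical backbone is a log-linear relation between peak total
acceleration ``a`` (in g) and release speed ``v`` (in m/s),

    v = b0 + b_log * ln(a) + b_sex * 1[male] + b_type + eps,

with ``eps ~ Normal(0, residual_speed_sd)`` independent of the predictors.
The generator draws a *systematic* speed per throw,

    v_sys = type_mean + sex_speed_offset * 1[male] + skill + eta,

(``skill`` a per-participant level-of-play offset, ``eta`` a per-throw
variation), inverts the log-linear relation on the noise-free part,

    ln(a) = (v_sys - b0 - b_sex * 1[male] - b_type) / b_log,

and records the observed (motion-capture) speed as ``v_obs = v_sys + eps``.
The regression relation above then holds exactly with ``eps`` independent of
``ln(a)``, sex and type, which is what makes the downstream coefficient
recovery, calibration and precision checks reproducible by construction.

A truth table (one row per throw) records every planted quantity so that
each downstream stage can be tested against the values it should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError

__all__ = [
    "THROW_TYPES",
    "TYPE_MEAN_SPEEDS",
    "TYPE_SPEED_RANGES",
    "AccelModelCoefficients",
    "GeneratorConfig",
    "ParticipantProfile",
    "ThrowTruth",
    "Session",
    "Study",
    "generate_study",
    "synthesize_throw_kinematics",
    "synthesize_accel_stream",
    "features_from_truth",
    "write_truth_table",
    "read_truth_table",
]

#: The five protocol throw types, in protocol order.
THROW_TYPES = ("low_norun", "med_norun", "max_norun", "max_run", "jump")

#: Cohort mean release speed per throw type (m/s).
TYPE_MEAN_SPEEDS = {
    "low_norun": 13.7,
    "med_norun": 15.8,
    "max_norun": 21.0,
    "max_run": 22.6,
    "jump": 20.9,
}

#: Cohort release-speed range per throw type (m/s).
TYPE_SPEED_RANGES = {
    "low_norun": (9.4, 17.5),
    "med_norun": (11.8, 20.8),
    "max_norun": (15.1, 25.9),
    "max_run": (16.8, 28.1),
    "jump": (15.4, 26.8),
}


@dataclass(frozen=True)
class AccelModelCoefficients:
    """Coefficients of the log-linear acceleration-to-speed map.

    Defaults are the published Full-model point estimates (speed in m/s,
    acceleration in g, natural logarithm, reference levels female and
    jump throw).
    """

    intercept: float = 9.0
    log_slope: float = 2.7
    sex_male: float = 2.4
    type_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "low_norun": -5.0,
            "med_norun": -3.7,
            "max_norun": -0.3,
            "max_run": 0.9,
            "jump": 0.0,
        }
    )

    def linear_predictor(self, log_peak: float, sex: str, throw_type: str) -> float:
        return (
            self.intercept
            + self.log_slope * log_peak
            + (self.sex_male if sex == "male" else 0.0)
            + self.type_offsets[throw_type]
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic study.

    Parameters
    ----------
    n_participants, n_female
        Cohort size and number of female participants (default 19 with 8
        female, 11 male).
    n_throws_per_type
        Throws per type per participant (default 5, i.e. 25 per session).
    type_mean_speeds, type_speed_ranges
        Per-type cohort mean and range of release speed in m/s.
    within_type_speed_sd
        Total within-type standard deviation of the observed release speed
        in m/s (default 2.7). This marginal SD is decomposed internally into
        the sex offset, the participant skill spread, a per-throw speed
        variation and the regression residual; with the defaults the overall
        speed SD across types is ~4.36 m/s.
    sex_speed_offset
        Mean male-female speed difference in m/s (default 2.4).
    skill_offset_sd
        SD of the per-participant level-of-play offset in m/s (default 1.2).
    residual_speed_sd
        SD of the speed residual around the log-linear acceleration relation
        in m/s (default 1.63; a correctly specified model then has expected
        absolute error 1.63 * sqrt(2/pi) = 1.30 m/s).
    accel_model_coefficients
        The inverse log-linear map used to plant accelerometer peaks.
    clip_speeds
        "low" (default) clips the systematic speed at the per-type range
        minimum, which bounds the smallest plantable peak away from the
        segmentation threshold; "full" clips both the systematic and the
        observed speed to the per-type range; "none" disables clipping.
    mocap_rate, accel_rate
        Sampling rates in Hz (defaults 240 and 500; the accelerometer grid
        is exactly uniform).
    inter_throw_gap, lead_in
        Seconds between consecutive releases and before the first release.
    pulse_width
        Width of the raised-cosine acceleration pulse in s (default 0.15).
    background_noise_sd
        Per-axis SD of the accelerometer background noise in g.
    sensor_range_g
        Nominal sensor range metadata (not enforced during synthesis).
    seed
        Root seed; all generator randomness derives from it.
    """

    n_participants: int = 19
    n_female: int = 8
    n_throws_per_type: int = 5
    type_mean_speeds: Mapping[str, float] = field(
        default_factory=lambda: dict(TYPE_MEAN_SPEEDS)
    )
    type_speed_ranges: Mapping[str, tuple] = field(
        default_factory=lambda: dict(TYPE_SPEED_RANGES)
    )
    within_type_speed_sd: float = 2.7
    sex_speed_offset: float = 2.4
    skill_offset_sd: float = 1.2
    residual_speed_sd: float = 1.63
    accel_model_coefficients: AccelModelCoefficients = field(
        default_factory=AccelModelCoefficients
    )
    clip_speeds: str = "low"
    mocap_rate: float = 240.0
    accel_rate: float = 500.0
    inter_throw_gap: float = 3.0
    lead_in: float = 2.0
    pulse_width: float = 0.15
    background_noise_sd: float = 0.03
    sensor_range_g: float = 200.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if not 0 <= self.n_female <= self.n_participants:
            raise ConfigError("n_female", "must be between 0 and n_participants")
        if self.n_throws_per_type < 1:
            raise ConfigError("n_throws_per_type", "must be >= 1")
        if self.mocap_rate <= 0:
            raise ConfigError("mocap_rate", "must be > 0")
        if self.accel_rate <= 0:
            raise ConfigError("accel_rate", "must be > 0")
        if self.residual_speed_sd < 0:
            raise ConfigError("residual_speed_sd", "must be >= 0")
        if self.skill_offset_sd < 0:
            raise ConfigError("skill_offset_sd", "must be >= 0")
        if self.within_type_speed_sd < 0:
            raise ConfigError("within_type_speed_sd", "must be >= 0")
        if self.inter_throw_gap <= self.pulse_width:
            raise ConfigError(
                "inter_throw_gap", "must exceed pulse_width (pulses must not overlap)"
            )
        if self.clip_speeds not in ("low", "full", "none"):
            raise ConfigError("clip_speeds", "must be one of 'low', 'full', 'none'")
        missing = [t for t in THROW_TYPES if t not in self.type_mean_speeds]
        if missing:
            raise ConfigError("type_mean_speeds", f"missing throw types {missing}")
        # Fail early if the marginal within-type SD cannot accommodate the
        # variance already committed to sex, skill and residual components.
        self.throw_speed_sd  # noqa: B018 - property performs the check

    @property
    def p_male(self) -> float:
        return (self.n_participants - self.n_female) / self.n_participants

    @property
    def throw_speed_sd(self) -> float:
        """SD of the per-throw speed variation implied by the configured
        within-type SD after removing the sex, skill and residual variance."""
        sex_var = self.sex_speed_offset**2 * self.p_male * (1.0 - self.p_male)
        var = (
            self.within_type_speed_sd**2
            - sex_var
            - self.skill_offset_sd**2
            - self.residual_speed_sd**2
        )
        if var < 0:
            raise ConfigError(
                "within_type_speed_sd",
                "too small for the configured sex offset, skill SD and residual SD",
            )
        return math.sqrt(var)


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    sex: str  # "female" | "male"
    skill_offset: float  # m/s level-of-play offset


@dataclass(frozen=True)
class ThrowTruth:
    """Planted ground truth for a single throw."""

    participant_id: str
    sex: str
    throw_type: str
    true_release_speed: float  # m/s, what the motion capture observes
    release_time: float  # s, within the session
    peak_total_accel: float  # g, planted accelerometer peak norm
    throw_id: str = ""
    seed: int = 0  # per-throw seed for reproducible signal synthesis

    def __post_init__(self):
        if self.throw_type not in THROW_TYPES:
            raise ConfigError("throw_type", f"unknown throw type {self.throw_type!r}")
        if self.true_release_speed <= 0:
            raise ConfigError("true_release_speed", "must be > 0")
        if self.peak_total_accel <= 0:
            raise ConfigError("peak_total_accel", "must be > 0")


@dataclass(frozen=True)
class Session:
    """One participant's recording session: 25 throws in randomised order."""

    participant: ParticipantProfile
    truths: tuple  # time-ordered ThrowTruth
    seed: int  # session seed for the accelerometer stream


@dataclass(frozen=True)
class Study:
    """A full synthetic study: cohort, sessions and the truth table."""

    config: GeneratorConfig
    participants: tuple
    sessions: tuple
    truth: pd.DataFrame

    def trajectory(self, truth: ThrowTruth):
        """Marker trajectory (ball + hand) for one throw."""
        return synthesize_throw_kinematics(truth, self.config.mocap_rate)

    def accel_stream(self, session: Session):
        """Continuous accelerometer stream for one session."""
        return synthesize_accel_stream(session.truths, self.config, seed=session.seed)

    def iter_throws(self):
        for session in self.sessions:
            for truth in session.truths:
                yield session, truth


def _sub_seed(root: int, *key: int) -> int:
    """Deterministic 32-bit child seed from a root seed and an index path."""
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0])


def generate_study(config: GeneratorConfig) -> Study:
    """Generate a complete synthetic study from ``config``.

    Returns a :class:`Study` holding ``n_participants`` profiles, one session
    per participant with ``n_throws_per_type * 5`` throws in randomised order,
    and a truth table with one row per throw. Bit-identical for equal seeds.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    coef = config.accel_model_coefficients

    participants = []
    sessions = []
    rows = []
    n_types = len(THROW_TYPES)
    for p_idx in range(config.n_participants):
        sex = "female" if p_idx < config.n_female else "male"
        pid = f"P{p_idx + 1:02d}"
        skill = rng.normal(0.0, config.skill_offset_sd)
        profile = ParticipantProfile(pid, sex, skill)
        participants.append(profile)

        order = rng.permutation(np.repeat(THROW_TYPES, config.n_throws_per_type))
        truths = []
        for t_idx, throw_type in enumerate(order):
            eta = rng.normal(0.0, config.throw_speed_sd)
            v_sys = (
                config.type_mean_speeds[throw_type]
                + (config.sex_speed_offset if sex == "male" else 0.0)
                + skill
                + eta
            )
            lo, hi = config.type_speed_ranges[throw_type]
            if config.clip_speeds == "low":
                v_sys = max(v_sys, lo)
            elif config.clip_speeds == "full":
                v_sys = min(max(v_sys, lo), hi)
            log_peak = (
                v_sys
                - coef.intercept
                - (coef.sex_male if sex == "male" else 0.0)
                - coef.type_offsets[throw_type]
            ) / coef.log_slope
            eps = rng.normal(0.0, config.residual_speed_sd)
            v_obs = v_sys + eps
            if config.clip_speeds == "full":
                v_obs = min(max(v_obs, lo), hi)
            truth = ThrowTruth(
                participant_id=pid,
                sex=sex,
                throw_type=str(throw_type),
                true_release_speed=float(v_obs),
                release_time=config.lead_in + t_idx * config.inter_throw_gap,
                peak_total_accel=float(math.exp(log_peak)),
                throw_id=f"{pid}-{t_idx + 1:02d}",
                seed=_sub_seed(config.seed, 1, p_idx, t_idx),
            )
            truths.append(truth)
            rows.append(truth)
        sessions.append(
            Session(profile, tuple(truths), seed=_sub_seed(config.seed, 2, p_idx))
        )
    assert len(rows) == config.n_participants * config.n_throws_per_type * n_types

    truth_df = pd.DataFrame(
        {
            "throw_id": [t.throw_id for t in rows],
            "participant_id": [t.participant_id for t in rows],
            "sex": [t.sex for t in rows],
            "throw_type": [t.throw_type for t in rows],
            "true_release_speed_mps": [t.true_release_speed for t in rows],
            "release_time_s": [t.release_time for t in rows],
            "peak_total_accel_g": [t.peak_total_accel for t in rows],
        }
    )
    return Study(config, tuple(participants), tuple(sessions), truth_df)


def synthesize_throw_kinematics(
    truth: ThrowTruth,
    rate: float = 240.0,
    *,
    pre_window: float = 0.4,
    post_window: float = 0.2,
    ramp_duration: float = 0.25,
    decel_duration: float | None = None,
    hand_offset: float = 0.005,
):
    """Synthesize ball and hand marker trajectories for one throw.

    The ball accelerates along a straight line with a raised-sine speed
    profile that peaks (with zero slope) exactly at the release frame, then
    travels ballistically at ``true_release_speed``. The hand tracks the ball
    (at a constant ``hand_offset`` lateral separation, below the 1 cm release
    criterion) until one frame before release and then decelerates to rest
    within ``decel_duration`` (default: one frame), so the frame-to-frame
    ball-hand distance increase first exceeds 1 cm at the planted release
    frame. The zero-slope speed peak keeps the 20 Hz zero-phase low-pass
    filter's effect on the release-frame speed below 2%.
    """
    if rate <= 0:
        raise GenerationError("rate must be > 0")
    dt = 1.0 / rate
    if decel_duration is None:
        decel_duration = dt
    n_pre = int(round(pre_window * rate))
    n_post = int(round(post_window * rate))
    release_frame = n_pre
    if truth.release_time - pre_window < -1e-12:
        raise GenerationError(
            f"release_time {truth.release_time:.3f}s lies outside the "
            f"trajectory span (needs {pre_window:.3f}s of pre-release data)"
        )
    v = truth.true_release_speed
    if v <= 0:
        raise GenerationError("true_release_speed must be > 0")

    tau = (np.arange(n_pre + n_post + 1) - release_frame) * dt  # time from release
    times = truth.release_time + tau

    # Ball arc length: integral of v*sin^2(pi*(tau+T)/(2T)) over the ramp,
    # then linear flight at speed v.
    T = min(ramp_duration, pre_window)
    x = np.clip(tau + T, 0.0, None)
    ramp = v * (x / 2.0 - (T / np.pi) * np.sin(np.pi * np.minimum(x, T) / T) / 2.0)
    arc_ball = np.where(tau <= 0.0, ramp, v * T / 2.0 + v * tau)

    # Hand arc length: identical to the ball until one frame before release,
    # then a cos^2 deceleration to rest over decel_duration.
    t_break = -dt
    s_break = v * math.sin(math.pi * (t_break + T) / (2.0 * T)) ** 2
    arc_at_break = v * (
        (t_break + T) / 2.0 - (T / np.pi) * math.sin(math.pi * (t_break + T) / T) / 2.0
    )
    y = np.clip(tau - t_break, 0.0, decel_duration)
    decel = s_break * (
        y / 2.0 + (decel_duration / np.pi) * np.sin(np.pi * y / decel_duration) / 2.0
    )
    arc_hand = np.where(tau <= t_break, arc_ball, arc_at_break + decel)

    rng = np.random.default_rng(truth.seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    perp = np.cross(direction, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    origin = rng.uniform(-0.5, 0.5, size=3)

    ball = origin + np.outer(arc_ball, direction)
    hand = origin + np.outer(arc_hand, direction) + hand_offset * perp

    from .kinematics import MarkerTrajectory  # local import avoids a cycle

    return MarkerTrajectory(times=times, ball=ball, hand=hand, frame_rate=rate)


def synthesize_accel_stream(
    truths: Sequence[ThrowTruth],
    config: GeneratorConfig,
    *,
    seed: int = 0,
    lead_out: float = 2.0,
):
    """Synthesize a continuous session accelerometer stream.

    One raised-cosine pulse per throw, centred at its release time, on a
    random unit axis direction, with peak Euclidean norm equal to the planted
    ``peak_total_accel``; low-level Gaussian background noise everywhere.
    """
    if len(truths) == 0:
        raise GenerationError("session contains no throws")
    ordered = sorted(truths, key=lambda t: t.release_time)
    release_times = np.array([t.release_time for t in ordered])
    gaps = np.diff(release_times)
    if np.any(gaps < config.pulse_width):
        raise GenerationError("overlapping pulses: throws closer than pulse_width")
    if np.any(gaps < config.inter_throw_gap - 1e-9):
        raise GenerationError(
            "throws closer than the configured inter_throw_gap"
        )

    rate = config.accel_rate
    duration = release_times[-1] + lead_out
    n = int(round(duration * rate)) + 1
    times = np.arange(n) / rate

    rng = np.random.default_rng(seed)
    accel = rng.normal(0.0, config.background_noise_sd, size=(n, 3))
    half = config.pulse_width / 2.0
    for truth in ordered:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lo = np.searchsorted(times, truth.release_time - half)
        hi = np.searchsorted(times, truth.release_time + half, side="right")
        local = times[lo:hi] - truth.release_time
        pulse = truth.peak_total_accel * 0.5 * (
            1.0 + np.cos(2.0 * np.pi * local / config.pulse_width)
        )
        accel[lo:hi] += np.outer(pulse, direction)

    from .accel import AccelStream  # local import avoids a cycle

    return AccelStream(
        times=times,
        accel=accel,
        nominal_rate=rate,
        sensor_range_g=config.sensor_range_g,
    )


def features_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Feature rows derived directly from the truth table (no signal path).

    Uses the planted peaks and speeds; the signal route (release detection,
    peak picking) should agree with these up to its documented measurement
    error.
    """
    return pd.DataFrame(
        {
            "throw_id": truth["throw_id"],
            "log_peak_accel": np.log(truth["peak_total_accel_g"].to_numpy(float)),
            "sex": truth["sex"],
            "throw_type": truth["throw_type"],
            "observed_speed_mps": truth["true_release_speed_mps"],
        }
    )


TRUTH_COLUMNS = [
    "participant_id",
    "sex",
    "throw_type",
    "true_release_speed_mps",
    "release_time_s",
    "peak_total_accel_g",
]


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError("truth_table", f"missing columns {sorted(missing)}")
    # Reconstruct throw ids from participant and within-session time order.
    df = df.sort_values(["participant_id", "release_time_s"], kind="stable")
    df["throw_id"] = [
        f"{pid}-{k + 1:02d}"
        for pid, k in zip(
            df["participant_id"], df.groupby("participant_id").cumcount()
        )
    ]
    return df.reset_index(drop=True)


def noiseless(config: GeneratorConfig) -> GeneratorConfig:
    """A copy of ``config`` with all stochastic nuisance terms switched off
    (zero residual and background noise); used by identifiability checks."""
    return replace(config, residual_speed_sd=0.0, background_noise_sd=0.0)
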