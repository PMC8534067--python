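"""Synthetic binocular eye-movement recordings.

Emulates a REMOBI-style oculomotor testing session recorded at 200 Hz per
eye: vergence trials (fixation at 40 cm, convergence step to 20 cm or
divergence step to 150 cm, overlap paradigm), horizontal saccade trials
(20 deg left/right), and out-loud reading traces composed of progressive
and regressive saccades separated by fixations.

Movements follow a raised-cosine position ramp, so velocity is a half-sine
with an analytically known peak ``pi * |A| / (2 D)`` for amplitude ``A``
and duration ``D``.  Every generated trial carries a ground-truth record
holding the descriptor values a velocity-criterion analysis should find,
evaluated in closed form on the noiseless profile: onsets and offsets are
referenced to the 5 deg/s crossing (vergence) or the 10 %-of-peak crossing
(saccades), matching how latency and amplitude are operationally defined
for real recordings.

Sign conventions: rightward positive for each eye; vergence = left - right,
so convergence is positive; all positions in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "FS_DEFAULT",
    "IPD_DEFAULT_M",
    "Trial",
    "StimulusProtocol",
    "KinematicParams",
    "ReadingParams",
    "GroundTruth",
    "ReadingGroundTruth",
    "BinocularTrace",
    "GroupEffects",
    "SubjectVariability",
    "SpeedModel",
    "CohortSpec",
    "Subject",
    "Cohort",
    "vergence_angle",
    "default_vergence_params",
    "default_saccade_params",
    "generate_vergence_trial",
    "generate_saccade_trial",
    "generate_test_trace",
    "generate_reading_trace",
    "generate_cohort",
    "generate_feature_cohort",
]

FS_DEFAULT = 200.0  # Hz per eye
IPD_DEFAULT_M = 0.060  # interocular distance reproducing the 9/17/2 deg angles

# Operational onset criteria the ground truth is referenced to.  They mirror
# the extraction defaults but belong to the generator: "latency" is defined
# as the time the movement's velocity first exceeds the criterion.
VERGENCE_ONSET_CRITERION = 5.0  # deg/s
SACCADE_ONSET_FRACTION = 0.10  # fraction of peak velocity

CONVERGENCE = "convergence"
DIVERGENCE = "divergence"
SACCADE_LEFT = "saccade-left"
SACCADE_RIGHT = "saccade-right"

VERGENCE_KINDS = (CONVERGENCE, DIVERGENCE)
SACCADE_KINDS = (SACCADE_LEFT, SACCADE_RIGHT)


# --------------------------------------------------------------------------
# stimulus geometry and protocols
# --------------------------------------------------------------------------

def vergence_angle(distance_m: float, interocular_m: float = IPD_DEFAULT_M) -> float:
    """Vergence angle (deg) required to binocularly fixate a target.

    ``2 * atan((ipd / 2) / d)`` — 8.58 deg at 40 cm, 17.1 deg at 20 cm and
    2.3 deg at 150 cm for a 6 cm interocular distance, i.e. the 9/17/2 deg
    targets of the vergence test under integer rounding.  ``distance_m`` may
    be ``inf`` (angle 0).
    """
    if not distance_m > 0 or not interocular_m > 0:
        raise ValueError("distance and interocular distance must be positive")
    return math.degrees(2.0 * math.atan((interocular_m / 2.0) / distance_m))


@dataclass(frozen=True)
class Trial:
    """One stimulus presentation: fixation period then target period."""

    kind: str
    fixation_ms: float
    target_ms: float = 2000.0
    overlap_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.kind not in VERGENCE_KINDS + SACCADE_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if not 0 < self.fixation_ms:
            raise ValueError("fixation duration must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial list plus the target geometry of a REMOBI-style test.

    Fixation durations are drawn uniformly from 1400-2000 ms; a vergence
    test interleaves 20 convergence and 20 divergence trials, a saccade
    test 20 left and 20 right, pseudo-randomly.
    """

    trials: tuple[Trial, ...]
    fixation_distance_m: float = 0.40
    convergence_distance_m: float = 0.20
    divergence_distance_m: float = 1.50
    saccade_eccentricity_deg: float = 20.0
    interocular_m: float = IPD_DEFAULT_M
    fixation_range_ms: tuple[float, float] = (1400.0, 2000.0)

    @classmethod
    def _interleaved(cls, kinds: tuple[str, str], n_each: int,
                     rng: np.random.Generator, **kwargs) -> "StimulusProtocol":
        lo, hi = kwargs.get("fixation_range_ms", (1400.0, 2000.0))
        order = rng.permutation([kinds[0]] * n_each + [kinds[1]] * n_each)
        trials = tuple(
            Trial(kind=k, fixation_ms=float(rng.uniform(lo, hi))) for k in order
        )
        return cls(trials=trials, **kwargs)

    @classmethod
    def vergence(cls, rng: np.random.Generator, n_each: int = 20,
                 **kwargs) -> "StimulusProtocol":
        return cls._interleaved(VERGENCE_KINDS, n_each, rng, **kwargs)

    @classmethod
    def saccade(cls, rng: np.random.Generator, n_each: int = 20,
                **kwargs) -> "StimulusProtocol":
        return cls._interleaved(SACCADE_KINDS, n_each, rng, **kwargs)

    def fixation_vergence_deg(self) -> float:
        return vergence_angle(self.fixation_distance_m, self.interocular_m)

    def target_vergence_deg(self, kind: str) -> float:
        if kind == CONVERGENCE:
            return vergence_angle(self.convergence_distance_m, self.interocular_m)
        if kind == DIVERGENCE:
            return vergence_angle(self.divergence_distance_m, self.interocular_m)
        raise ValueError(f"not a vergence trial kind: {kind!r}")


# --------------------------------------------------------------------------
# kinematic parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicParams:
    """Per-movement kinematics of one subject for one test.

    ``duration_ms`` is the full raised-cosine ramp duration; the analytic
    peak velocity is ``pi * |A| / (2 D)``.  If ``main_sequence_slope`` is
    set ((deg/s)/deg), the duration is derived from it instead:
    ``D = pi / (2 * slope)``, so peak velocity scales linearly with
    amplitude.  Post-movement drift is exponential per eye with time
    constant ``drift_tau_ms``; ``disconjugacy_deg`` is the left-minus-right
    amplitude difference of saccades.  A blink replaces ~100 ms of both
    traces with a large downward excursion.
    """

    latency_mean_ms: float = 200.0
    latency_sd_ms: float = 30.0
    latency_min_ms: float = 80.0
    duration_ms: float = 450.0
    duration_jitter: float = 0.08  # uniform +/- fraction
    main_sequence_slope: Optional[float] = None  # (deg/s)/deg
    drift_left_deg: float = 0.20
    drift_right_deg: float = 0.10
    drift_sd_deg: float = 0.05
    drift_tau_ms: float = 80.0
    disconjugacy_deg: float = 0.0
    disconjugacy_sd_deg: float = 0.0
    noise_sd_deg: float = 0.05
    blink_prob: float = 0.0
    amplitude_deg: Optional[float] = None  # override protocol geometry

    def __post_init__(self) -> None:
        for name in ("latency_sd_ms", "drift_sd_deg", "disconjugacy_sd_deg",
                     "noise_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_ms <= 0 or self.drift_tau_ms <= 0:
            raise ValueError("durations must be positive")
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValueError("blink_prob must lie in [0, 1]")

    def movement_duration_s(self, rng: Optional[np.random.Generator] = None) -> float:
        if self.main_sequence_slope is not None:
            base = math.pi / (2.0 * self.main_sequence_slope)
        else:
            base = self.duration_ms / 1000.0
        if rng is not None and self.duration_jitter > 0:
            base *= 1.0 + rng.uniform(-self.duration_jitter, self.duration_jitter)
        return base


def default_vergence_params(**overrides) -> KinematicParams:
    """Vergence kinematics: ~8 deg steps in ~450 ms (peak ~28 deg/s)."""
    base = dict(latency_mean_ms=200.0, latency_sd_ms=30.0, duration_ms=450.0,
                drift_left_deg=0.20, drift_right_deg=0.10, noise_sd_deg=0.05,
                blink_prob=0.02)
    base.update(overrides)
    return KinematicParams(**base)


def default_saccade_params(**overrides) -> KinematicParams:
    """Saccade kinematics: 20 deg in ~70 ms (peak ~450 deg/s)."""
    base = dict(latency_mean_ms=180.0, latency_sd_ms=30.0, duration_ms=70.0,
                drift_left_deg=0.15, drift_right_deg=0.05,
                disconjugacy_deg=0.20, disconjugacy_sd_deg=0.10,
                noise_sd_deg=0.05, blink_prob=0.02)
    base.update(overrides)
    return KinematicParams(**base)


# --------------------------------------------------------------------------
# ground truth and trace containers
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Criterion-referenced descriptor truth for one generated trial.

    All amplitude/latency/duration values are closed-form evaluations of
    the noiseless raised-cosine profile at its velocity-criterion crossing
    points, i.e. the values an ideal threshold analysis recovers.
    ``movement_amplitude_deg`` and ``drawn_latency_ms`` keep the raw step
    parameters.
    """

    kind: str
    target_onset_s: float
    latency_ms: float
    phasic_amplitude_deg: float
    amp80_deg: float
    amp160_deg: float
    total_amplitude_deg: float
    phasic_duration_ms: float
    total_duration_ms: float
    peak_velocity_deg_s: float
    avg_velocity_deg_s: float
    disconjugacy_deg: float
    drift1_deg: float
    drift2_deg: float
    movement_amplitude_deg: float
    drawn_latency_ms: float
    blink: bool


@dataclass
class ReadingGroundTruth:
    """Truth for a generated reading trace."""

    n_words: int
    n_progressive: int
    n_regressive: int
    fixation_durations_ms: np.ndarray
    saccade_amplitudes_deg: np.ndarray
    speed_wpm: float


@dataclass
class BinocularTrace:
    """Uniformly sampled left/right horizontal eye positions (deg).

    ``events`` lists ``(onset_s, kind)`` stimulus markers.
    """

    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    rate: float = FS_DEFAULT
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.left) == len(self.right)):
            raise ValueError("time/left/right must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.time) / self.rate


# --------------------------------------------------------------------------
# raised-cosine profile helpers (closed forms)
# --------------------------------------------------------------------------

def _ramp(t: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Raised-cosine position ramp from 0 to ``amplitude`` over ``duration``."""
    tt = np.clip(t, 0.0, duration)
    return amplitude * 0.5 * (1.0 - np.cos(np.pi * tt / duration))


def _profile_truth(amplitude: float, duration: float, criterion: float):
    """Closed-form descriptor truth of a raised-cosine movement.

    Returns ``(peak_velocity, t_cross, phasic_amplitude, phasic_duration,
    tail)`` where ``t_cross`` is the time after profile start at which
    |velocity| crosses ``criterion`` and ``tail`` the position change still
    to come after the symmetric down-crossing.
    """
    peak = math.pi * abs(amplitude) / (2.0 * duration)
    if criterion >= peak:
        raise ValueError("velocity criterion exceeds the profile peak")
    t_cross = duration / math.pi * math.asin(criterion / peak)
    cosf = math.cos(math.pi * t_cross / duration)
    phasic_amplitude = amplitude * cosf
    phasic_duration = duration - 2.0 * t_cross
    tail = amplitude * 0.5 * (1.0 - cosf)
    return peak, t_cross, phasic_amplitude, phasic_duration, tail


def _exp_drift(t: np.ndarray, start: float, amplitude: float, tau: float) -> np.ndarray:
    dt = np.maximum(t - start, 0.0)
    return amplitude * (1.0 - np.exp(-dt / tau))


def _drift_gain(elapsed_s: float, tau_s: float) -> float:
    return 1.0 - math.exp(-max(elapsed_s, 0.0) / tau_s) if elapsed_s > 0 else 0.0


BLINK_DURATION_S = 0.100
BLINK_EXCURSION_DEG = -45.0  # large downward spike, flagged as aberrant downstream


def _inject_blink(t: np.ndarray, left: np.ndarray, right: np.ndarray,
                  start_s: float) -> None:
    # the eyelid occludes the two pupils unequally, so the artifact hits
    # both the conjugate and the vergence channel
    win = (t >= start_s) & (t < start_s + BLINK_DURATION_S)
    shape = BLINK_EXCURSION_DEG * np.sin(
        np.pi * (t[win] - start_s) / BLINK_DURATION_S)
    left[win] += shape
    right[win] += 0.6 * shape


# --------------------------------------------------------------------------
# trial generators
# --------------------------------------------------------------------------

def _draw_latency_s(params: KinematicParams, rng: np.random.Generator) -> float:
    lat = rng.normal(params.latency_mean_ms, params.latency_sd_ms)
    return max(lat, params.latency_min_ms) / 1000.0


def _common_truth(kind, target_onset, lat_s, amp, dur, criterion,
                  drift_channel, drift_disconj, drift_tau_s, disconj, blink):
    """Assemble a GroundTruth from profile closed forms.

    ``drift_channel`` is the exponential-drift amplitude seen on the
    analyzed channel (vergence channel for vergence trials, conjugate for
    saccades), ``drift_disconj`` the left-minus-right drift amplitude and
    ``disconj`` the left-minus-right movement amplitude difference.
    """
    peak, t_cross, phasic, phasic_dur, tail = _profile_truth(amp, dur, criterion)
    # The 80/160 ms windows start at the velocity-criterion offset, i.e.
    # t_cross before the profile completes; the remaining ramp tail falls
    # inside the first window, then exponential drift accumulates.
    amp_w = {}
    disc_w = {}
    for w in (0.080, 0.160):
        g = _drift_gain(w - t_cross, drift_tau_s)
        amp_w[w] = tail + drift_channel * g
        # on the individual eye channels the ramp tails differ by the
        # disconjugacy share; add the disconjugate exponential drift
        disc_tail = disconj * 0.5 * (1.0 - math.cos(math.pi * t_cross / dur))
        disc_w[w] = disc_tail + drift_disconj * g
    total_amp = phasic + amp_w[0.160]
    total_dur_ms = phasic_dur * 1000.0 + 160.0
    return GroundTruth(
        kind=kind,
        target_onset_s=target_onset,
        latency_ms=lat_s * 1000.0,
        phasic_amplitude_deg=phasic,
        amp80_deg=amp_w[0.080],
        amp160_deg=amp_w[0.160],
        total_amplitude_deg=total_amp,
        phasic_duration_ms=phasic_dur * 1000.0,
        total_duration_ms=total_dur_ms,
        peak_velocity_deg_s=peak,
        avg_velocity_deg_s=abs(total_amp) / (total_dur_ms / 1000.0),
        disconjugacy_deg=disconj * math.cos(math.pi * t_cross / dur),
        drift1_deg=disc_w[0.080],
        drift2_deg=disc_w[0.160],
        movement_amplitude_deg=amp,
        drawn_latency_ms=lat_s * 1000.0,
        blink=blink,
    )


def generate_vergence_trial(trial: Trial, protocol: StimulusProtocol,
                            params: KinematicParams, rng: np.random.Generator,
                            fs: float = FS_DEFAULT):
    """One vergence trial segment: ``(t, left, right, GroundTruth)``.

    The vergence channel steps from the fixation angle to the target angle
    after the drawn latency; the profile is placed so its 5 deg/s crossing
    occurs exactly at fixation-onset + latency.
    """
    if trial.kind not in VERGENCE_KINDS:
        raise ValueError(f"not a vergence trial: {trial.kind!r}")
    v0 = protocol.fixation_vergence_deg()
    v1 = protocol.target_vergence_deg(trial.kind)
    amp = (params.amplitude_deg if params.amplitude_deg is not None
           else v1 - v0)

    n = int(round((trial.fixation_ms + trial.target_ms) / 1000.0 * fs))
    t = np.arange(n) / fs
    target_onset = trial.fixation_ms / 1000.0
    lat_s = _draw_latency_s(params, rng)
    dur = params.movement_duration_s(rng)
    _, t_cross, _, _, _ = _profile_truth(amp, dur, VERGENCE_ONSET_CRITERION)
    start = target_onset + lat_s - t_cross

    d_left = rng.normal(params.drift_left_deg, params.drift_sd_deg)
    d_right = rng.normal(params.drift_right_deg, params.drift_sd_deg)
    tau = params.drift_tau_ms / 1000.0
    blink = bool(rng.random() < params.blink_prob)

    verg = v0 + _ramp(t - start, amp, dur)
    left = verg / 2.0 + _exp_drift(t, start + dur, d_left, tau)
    right = -verg / 2.0 + _exp_drift(t, start + dur, d_right, tau)
    if params.noise_sd_deg > 0:
        left = left + rng.normal(0.0, params.noise_sd_deg, n)
        right = right + rng.normal(0.0, params.noise_sd_deg, n)
    if blink:
        _inject_blink(t, left, right, target_onset + lat_s)

    gt = _common_truth(trial.kind, target_onset, lat_s, amp, dur,
                       VERGENCE_ONSET_CRITERION,
                       drift_channel=d_left - d_right,
                       drift_disconj=d_left - d_right, drift_tau_s=tau,
                       disconj=0.0, blink=blink)
    # vergence trials have no saccadic disconjugacy; the disconjugate drift
    # IS the vergence drift, already in amp80/amp160
    gt.disconjugacy_deg = float("nan")
    gt.drift1_deg = gt.amp80_deg
    gt.drift2_deg = gt.amp160_deg
    return t, left, right, gt


def generate_saccade_trial(trial: Trial, protocol: StimulusProtocol,
                           params: KinematicParams, rng: np.random.Generator,
                           fs: float = FS_DEFAULT):
    """One saccade trial segment: ``(t, left, right, GroundTruth)``.

    The conjugate channel makes a signed 20 deg step; the two eyes differ
    by the drawn disconjugacy and by their individual post-saccadic drifts.
    """
    if trial.kind not in SACCADE_KINDS:
        raise ValueError(f"not a saccade trial: {trial.kind!r}")
    ecc = (params.amplitude_deg if params.amplitude_deg is not None
           else protocol.saccade_eccentricity_deg)
    amp = ecc if trial.kind == SACCADE_RIGHT else -ecc
    v0 = protocol.fixation_vergence_deg()

    n = int(round((trial.fixation_ms + trial.target_ms) / 1000.0 * fs))
    t = np.arange(n) / fs
    target_onset = trial.fixation_ms / 1000.0
    lat_s = _draw_latency_s(params, rng)
    dur = params.movement_duration_s(rng)
    peak = math.pi * abs(amp) / (2.0 * dur)
    criterion = SACCADE_ONSET_FRACTION * peak
    _, t_cross, _, _, _ = _profile_truth(amp, dur, criterion)
    start = target_onset + lat_s - t_cross

    disconj = rng.normal(params.disconjugacy_deg, params.disconjugacy_sd_deg)
    amp_left = amp + disconj / 2.0
    amp_right = amp - disconj / 2.0
    d_left = rng.normal(params.drift_left_deg, params.drift_sd_deg)
    d_right = rng.normal(params.drift_right_deg, params.drift_sd_deg)
    tau = params.drift_tau_ms / 1000.0
    blink = bool(rng.random() < params.blink_prob)

    left = v0 / 2.0 + _ramp(t - start, amp_left, dur) + \
        _exp_drift(t, start + dur, d_left, tau)
    right = -v0 / 2.0 + _ramp(t - start, amp_right, dur) + \
        _exp_drift(t, start + dur, d_right, tau)
    if params.noise_sd_deg > 0:
        left = left + rng.normal(0.0, params.noise_sd_deg, n)
        right = right + rng.normal(0.0, params.noise_sd_deg, n)
    if blink:
        _inject_blink(t, left, right, target_onset + lat_s)

    gt = _common_truth(trial.kind, target_onset, lat_s, amp, dur, criterion,
                       drift_channel=(d_left + d_right) / 2.0,
                       drift_disconj=d_left - d_right, drift_tau_s=tau,
                       disconj=disconj, blink=blink)
    return t, left, right, gt


def generate_test_trace(protocol: StimulusProtocol, params: KinematicParams,
                        rng: np.random.Generator,
                        fs: float = FS_DEFAULT):
    """Concatenate a protocol's trials into one annotated test recording.

    Returns ``(BinocularTrace, list[GroundTruth])``; event markers carry
    the absolute target-onset time of each trial.
    """
    chunks_l, chunks_r, truths, events = [], [], [], []
    offset = 0.0
    for trial in protocol.trials:
        gen = (generate_vergence_trial if trial.kind in VERGENCE_KINDS
               else generate_saccade_trial)
        t, left, right, gt = gen(trial, protocol, params, rng, fs=fs)
        events.append((offset + gt.target_onset_s, trial.kind))
        gt.target_onset_s += offset
        chunks_l.append(left)
        chunks_r.append(right)
        truths.append(gt)
        offset += len(t) / fs
    left = np.concatenate(chunks_l)
    right = np.concatenate(chunks_r)
    time = np.arange(len(left)) / fs
    return BinocularTrace(time=time, left=left, right=right, rate=fs,
                          events=events), truths


# --------------------------------------------------------------------------
# reading traces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadingParams:
    """Kinematics of a synthetic left-to-right reading trace.

    Fixations are gamma-distributed (shape ``fixation_shape``) around
    ``fixation_mean_ms``; each word is advanced by a ~2 deg progressive
    saccade, with a regressive (leftward) saccade inserted before a word
    with probability ``regression_prob``.  Each fixation carries an
    exponential disconjugate (left-minus-right) drift.
    """

    fixation_mean_ms: float = 250.0
    fixation_shape: float = 4.0
    fixation_min_ms: float = 80.0
    progressive_amp_deg: float = 2.0
    regressive_amp_deg: float = -1.5
    saccade_duration_ms: float = 30.0
    regression_prob: float = 0.15
    drift_disconj_deg: float = 0.10
    drift_sd_deg: float = 0.05
    drift_tau_ms: float = 80.0
    noise_sd_deg: float = 0.03
    start_pos_deg: float = -8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.regression_prob <= 1.0:
            raise ValueError("regression_prob must lie in [0, 1]")
        if self.fixation_mean_ms <= 0 or self.saccade_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd_deg < 0 or self.drift_sd_deg < 0:
            raise ValueError("noise SDs must be >= 0")


def generate_reading_trace(n_words: int, params: ReadingParams,
                           rng: np.random.Generator, fs: float = FS_DEFAULT):
    """Reading trace: ``(BinocularTrace, ReadingGroundTruth, speed_wpm)``.

    Reading speed is ``n_words / (trace duration in minutes)``.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    v0 = vergence_angle(0.40)
    scale = params.fixation_mean_ms / params.fixation_shape
    sacc_n = max(int(round(params.saccade_duration_ms / 1000.0 * fs)), 2)
    sacc_dur = sacc_n / fs

    conj_parts: list[np.ndarray] = []
    verg_parts: list[np.ndarray] = []
    fix_durations: list[float] = []
    amplitudes: list[float] = []
    pos = params.start_pos_deg
    n_prog = n_reg = 0

    def add_fixation() -> None:
        dur_ms = max(rng.gamma(params.fixation_shape, scale),
                     params.fixation_min_ms)
        n = max(int(round(dur_ms / 1000.0 * fs)), 1)
        fix_durations.append(n / fs * 1000.0)
        conj_parts.append(np.full(n, pos))
        d = rng.normal(params.drift_disconj_deg, params.drift_sd_deg)
        tt = np.arange(n) / fs
        verg_parts.append(v0 + d * (1.0 - np.exp(-tt / (params.drift_tau_ms / 1000.0))))

    def add_saccade(amp: float) -> None:
        nonlocal pos
        tt = np.arange(sacc_n) / fs
        conj_parts.append(pos + _ramp(tt, amp, sacc_dur))
        verg_parts.append(np.full(sacc_n, v0))
        amplitudes.append(amp)
        pos += amp

    add_fixation()
    for _ in range(n_words):
        if rng.random() < params.regression_prob:
            add_saccade(params.regressive_amp_deg)
            n_reg += 1
            add_fixation()
        add_saccade(params.progressive_amp_deg)
        n_prog += 1
        add_fixation()

    conj = np.concatenate(conj_parts)
    verg = np.concatenate(verg_parts)
    left = conj + verg / 2.0
    right = conj - verg / 2.0
    if params.noise_sd_deg > 0:
        left = left + rng.normal(0.0, params.noise_sd_deg, len(conj))
        right = right + rng.normal(0.0, params.noise_sd_deg, len(conj))
    time = np.arange(len(conj)) / fs
    duration_min = len(conj) / fs / 60.0
    speed = n_words / duration_min
    trace = BinocularTrace(time=time, left=left, right=right, rate=fs,
                           events=[(0.0, "reading-start")])
    gt = ReadingGroundTruth(
        n_words=n_words, n_progressive=n_prog, n_regressive=n_reg,
        fixation_durations_ms=np.asarray(fix_durations),
        saccade_amplitudes_deg=np.asarray(amplitudes), speed_wpm=speed)
    return trace, gt, speed


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffects:
    """Offsets applied to the dyslexic group's kinematic parameters.

    Latency shifts are additive (ms); duration, drift, disconjugacy and
    regression-rate effects are multiplicative.  Defaults emulate the
    direction and rough magnitude of the group differences reported for
    this population: longer latencies, slower movements, larger
    disconjugate drifts, more regressive saccades.
    """

    latency_shift_ms: float = 30.0
    duration_scale: float = 1.25
    drift_scale: float = 2.0
    disconjugacy_scale: float = 1.5
    regression_prob_scale: float = 1.8
    fixation_shift_ms: float = 30.0

    @classmethod
    def null(cls) -> "GroupEffects":
        """Zero effect in every field (exchangeable groups)."""
        return cls(latency_shift_ms=0.0, duration_scale=1.0, drift_scale=1.0,
                   disconjugacy_scale=1.0, regression_prob_scale=1.0,
                   fixation_shift_ms=0.0)


@dataclass(frozen=True)
class SubjectVariability:
    """Between-subject spread around the group-level parameters."""

    latency_sd_ms: float = 25.0
    duration_log_sd: float = 0.10
    drift_sd_deg: float = 0.10
    disconjugacy_sd_deg: float = 0.08
    regression_prob_sd: float = 0.04
    fixation_mean_sd_ms: float = 25.0


@dataclass(frozen=True)
class SpeedModel:
    """Linear model tying a subject's reading speed (words/min) to the
    subject-level true descriptor values, plus Gaussian noise."""

    intercept: float = 365.0
    coefs: dict = field(default_factory=lambda: {
        "saccade.latency_ms": -0.5,
        "vergence.latency_ms": -0.3,
        "saccade.duration_ms": -0.3,
        "reading.regression_prob": -150.0,
        "saccade.drift_deg": -30.0,
    })
    noise_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the clinical study's setup: 41 controls vs 46 dyslexic
    adolescents, 20 + 20 trials per test, 200 Hz, ~150-word reading text.
    Deterministic given ``seed``: each subject draws from the substream
    ``default_rng([seed, subject_index])`` so cohorts are extensible
    without perturbing existing subjects.
    """

    n_control: int = 41
    n_dyslexic: int = 46
    vergence_params: KinematicParams = field(default_factory=default_vergence_params)
    saccade_params: KinematicParams = field(default_factory=default_saccade_params)
    reading_params: ReadingParams = field(default_factory=ReadingParams)
    effects: GroupEffects = field(default_factory=GroupEffects)
    between: SubjectVariability = field(default_factory=SubjectVariability)
    speed_model: SpeedModel = field(default_factory=SpeedModel)
    trials_per_condition: int = 20
    n_words: int = 150
    fs: float = FS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_dyslexic < 1:
            raise ValueError("need at least one subject per group")


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" | "dyslexic"
    traces: dict  # test name -> BinocularTrace
    ground_truth: dict  # test name -> list[GroundTruth] | ReadingGroundTruth
    reading_speed: float
    true_values: dict  # descriptor name -> subject-level truth


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]


def _subject_params(spec: CohortSpec, group: str, rng: np.random.Generator):
    """Draw subject-level kinematics: group baseline (+ dyslexic effects)
    plus between-subject jitter."""
    eff = spec.effects if group == "dyslexic" else GroupEffects.null()
    btw = spec.between

    def jitter_kin(p: KinematicParams, with_disconj: bool) -> KinematicParams:
        lat = rng.normal(p.latency_mean_ms + eff.latency_shift_ms,
                         btw.latency_sd_ms)
        dur = p.duration_ms * eff.duration_scale * \
            math.exp(rng.normal(0.0, btw.duration_log_sd))
        dl = rng.normal(p.drift_left_deg * eff.drift_scale, btw.drift_sd_deg)
        dr = rng.normal(p.drift_right_deg * eff.drift_scale, btw.drift_sd_deg)
        kw = dict(latency_mean_ms=max(lat, p.latency_min_ms),
                  duration_ms=max(dur, 20.0),
                  drift_left_deg=dl, drift_right_deg=dr)
        if with_disconj:
            dc = rng.normal(p.disconjugacy_deg * eff.disconjugacy_scale,
                            btw.disconjugacy_sd_deg)
            kw["disconjugacy_deg"] = dc
        return replace(p, **kw)

    verg = jitter_kin(spec.vergence_params, with_disconj=False)
    sacc = jitter_kin(spec.saccade_params, with_disconj=True)
    rp = spec.reading_params
    preg = float(np.clip(rng.normal(rp.regression_prob * eff.regression_prob_scale,
                                    btw.regression_prob_sd), 0.0, 0.9))
    fix = max(rng.normal(rp.fixation_mean_ms + eff.fixation_shift_ms,
                         btw.fixation_mean_sd_ms), rp.fixation_min_ms + 20.0)
    read = replace(rp, regression_prob=preg, fixation_mean_ms=fix)
    return verg, sacc, read


def _true_descriptor_values(verg: KinematicParams, sacc: KinematicParams,
                            read: ReadingParams) -> dict:
    return {
        "vergence.latency_ms": verg.latency_mean_ms,
        "vergence.duration_ms": verg.duration_ms,
        "vergence.drift_deg": verg.drift_left_deg - verg.drift_right_deg,
        "saccade.latency_ms": sacc.latency_mean_ms,
        "saccade.duration_ms": sacc.duration_ms,
        "saccade.drift_deg": sacc.drift_left_deg - sacc.drift_right_deg,
        "saccade.disconjugacy_deg": sacc.disconjugacy_deg,
        "reading.regression_prob": read.regression_prob,
        "reading.fixation_ms": read.fixation_mean_ms,
    }


def generate_subject(spec: CohortSpec, index: int, group: str) -> Subject:
    rng = np.random.default_rng([spec.seed, index])
    verg_p, sacc_p, read_p = _subject_params(spec, group, rng)
    protocol_v = StimulusProtocol.vergence(rng, n_each=spec.trials_per_condition)
    protocol_s = StimulusProtocol.saccade(rng, n_each=spec.trials_per_condition)
    trace_v, gts_v = generate_test_trace(protocol_v, verg_p, rng, fs=spec.fs)
    trace_s, gts_s = generate_test_trace(protocol_s, sacc_p, rng, fs=spec.fs)
    trace_r, gt_r, _ = generate_reading_trace(spec.n_words, read_p, rng,
                                              fs=spec.fs)
    true_vals = _true_descriptor_values(verg_p, sacc_p, read_p)
    speed = spec.speed_model.intercept + sum(
        coef * true_vals[name] for name, coef in spec.speed_model.coefs.items())
    if spec.speed_model.noise_sd > 0:
        speed += rng.normal(0.0, spec.speed_model.noise_sd)
    speed = max(speed, 30.0)
    return Subject(
        subject_id=f"S{index:03d}", group=group,
        traces={"vergence": trace_v, "saccade": trace_s, "reading": trace_r},
        ground_truth={"vergence": gts_v, "saccade": gts_s, "reading": gt_r},
        reading_speed=float(speed), true_values=true_vals)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministic synthetic cohort: controls first, then dyslexics."""
    subjects = []
    idx = 0
    for group, n in (("control", spec.n_control), ("dyslexic", spec.n_dyslexic)):
        for _ in range(n):
            subjects.append(generate_subject(spec, idx, group))
            idx += 1
    return Cohort(spec=spec, subjects=subjects)


# --------------------------------------------------------------------------
# descriptor-level cohorts (calibration-scale Monte Carlo)
# --------------------------------------------------------------------------

def generate_feature_cohort(n_per_group: int, n_features: int = 30,
                            group_shift: float = 0.0, n_shifted: int = 0,
                            planted_coefs: Optional[dict] = None,
                            speed_intercept: float = 160.0,
                            speed_noise_sd: float = 10.0,
                            seed: int = 0):
    """Draw a per-subject feature table directly, skipping trace synthesis.

    Features are iid standard normal; the dyslexic group's first
    ``n_shifted`` features are shifted by ``group_shift`` SDs.  Reading
    speed follows ``intercept + X[:, planted] @ beta + noise`` where
    ``planted_coefs`` maps feature index to beta.  With ``group_shift = 0``
    and empty ``planted_coefs`` the groups/speeds are exchangeable by
    construction.  Used for Monte-Carlo calibration at scales where full
    trace synthesis adds nothing.

    Returns a :class:`oculoml.features.FeatureMatrix`.
    """
    from .features import FeatureMatrix
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    values = rng.normal(size=(n, n_features))
    labels = np.array(["control"] * n_per_group + ["dyslexic"] * n_per_group)
    if group_shift != 0.0 and n_shifted > 0:
        values[n_per_group:, :n_shifted] += group_shift
    speed = np.full(n, speed_intercept)
    for j, beta in (planted_coefs or {}).items():
        speed = speed + beta * values[:, j]
    if speed_noise_sd > 0:
        speed = speed + rng.normal(0.0, speed_noise_sd, n)
    ids = [f"S{i:03d}" for i in range(n)]
    cols = [f"f{j:02d}" for j in range(n_features)]
    vdf = pd.DataFrame(values, index=ids, columns=cols)
    mask = pd.DataFrame(False, index=ids, columns=cols)
    return FeatureMatrix(values=vdf, mask=mask,
                         labels=pd.Series(labels, index=ids),
                         speed=pd.Series(speed, index=ids))
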