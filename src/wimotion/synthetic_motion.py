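"""Synthetic accelerometer data: poses, exercises, walking, impulse rig.

Generates every input the rest of the pipeline consumes, with known
ground truth:

- scripted exercises (e.g. the reduced Sun-Salutation cycle) as per-pose
  target polar angles θ per sensor, cosine-eased transitions, additive
  Gaussian noise and arbitrary per-sensor mounting rotations;
- quasi-periodic walking signals;
- the rigid-bar impulse fixture: five rigidly coupled modules sampling
  the same mechanical impulse with free-running sampling clocks, used to
  measure worst-case cross-module desynchronisation.

Streams are emitted as integer raw counts (quantised at the configured
counts-per-g) so the packet codec and protocol simulator see realistic
16-bit payloads. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .motion_features import COUNTS_PER_G, g_to_counts

N_SENSORS = 5

#: per-pose target polar angle (degrees from vertical) for the five
#: sensors (right forearm, left forearm, back waist, right calf, left
#: calf) over the reduced six-pose cycle. Pose 0 is the standing
#: calibration posture (θ = 180° everywhere: gravity to the floor).
#: Values are template data describing plausible limb inclinations for
#: each stage of the reduced sequence.
SUN_SALUTATION_THETAS: Dict[int, Tuple[float, ...]] = {
    0: (180.0, 180.0, 180.0, 180.0, 180.0),  # standing, arms down
    1: (20.0, 20.0, 170.0, 180.0, 180.0),    # arms raised overhead
    2: (160.0, 160.0, 90.0, 175.0, 175.0),   # standing forward fold
    3: (170.0, 170.0, 95.0, 90.0, 90.0),     # lunge / plank stage
    4: (120.0, 120.0, 130.0, 105.0, 105.0),  # prone backbend stage
    5: (40.0, 40.0, 60.0, 120.0, 120.0),     # inverted-V stage
}

TRANSITION_LABEL = -1


@dataclass(frozen=True)
class Segment:
    """One scripted stage: ease into the pose, then hold it."""

    pose: int
    theta_targets: Tuple[float, ...]  # degrees, one per sensor
    hold_s: float
    transition_s: float = 0.0  # time to reach this pose from the previous

    def __post_init__(self) -> None:
        if self.hold_s <= 0 or self.transition_s < 0:
            raise ValueError("segment durations must be positive")
        for t in self.theta_targets:
            if not 0.0 <= t <= 180.0:
                raise ValueError(f"θ target {t} outside [0°, 180°]")


@dataclass
class MotionScript:
    """Ordered pose segments plus acquisition and noise parameters."""

    segments: List[Segment]
    noise_sigma_g: float = 0.0
    sampling_rate_hz: float = 160.0
    mounting: Optional[Dict[int, np.ndarray]] = None  # sensor → 3×3 rotation
    counts_per_g: float = COUNTS_PER_G
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("script needs at least one segment")
        if self.noise_sigma_g < 0:
            raise ValueError("noise sigma must be non-negative")


def sun_salutation_script(
    hold_s: float = 5.0,
    transition_s: float = 1.5,
    noise_sigma_g: float = 0.0,
    repetitions: int = 1,
    sampling_rate_hz: float = 160.0,
    mounting: Optional[Dict[int, np.ndarray]] = None,
    seed: int = 0,
    hold_overrides: Optional[Dict[int, float]] = None,
) -> MotionScript:
    """Reduced-cycle exercise script: q0 → q1 → … → q5, repeated.

    Every pose is held ``hold_s`` seconds (the instructed pace) unless
    overridden per pose; transitions take ``transition_s``. Each
    repetition closes with a return to the standing pose q0, so a
    multi-repetition session alternates cycle and calibration posture.
    """
    segs: List[Segment] = []
    overrides = hold_overrides or {}
    for rep in range(repetitions):
        for pose in range(6):
            segs.append(Segment(
                pose=pose,
                theta_targets=SUN_SALUTATION_THETAS[pose],
                hold_s=overrides.get(pose, hold_s),
                transition_s=0.0 if (rep == 0 and pose == 0) else transition_s,
            ))
    # final return to standing closes the last repetition
    segs.append(Segment(
        pose=0,
        theta_targets=SUN_SALUTATION_THETAS[0],
        hold_s=max(2.0, hold_s / 2),
        transition_s=transition_s,
    ))
    return MotionScript(segs, noise_sigma_g, sampling_rate_hz, mounting,
                        COUNTS_PER_G, seed)


def true_pose_durations(script: MotionScript) -> Dict[int, List[float]]:
    """Ground-truth active duration per pose and repetition.

    Transition time is split evenly between the two poses it connects,
    so the truth for pose *k* is its hold plus half of each adjacent
    transition; the durations of the cycle poses then partition each
    repetition's span, mirroring how recognised (dominant-state)
    durations partition the session.
    """
    out: Dict[int, List[float]] = {}
    segs = script.segments
    for i, seg in enumerate(segs):
        if seg.pose == 0:
            continue
        t_out = segs[i + 1].transition_s if i + 1 < len(segs) else 0.0
        d = seg.hold_s + seg.transition_s / 2 + t_out / 2
        out.setdefault(seg.pose, []).append(d)
    return out


@dataclass
class ExerciseData:
    """Generated exercise: per-sensor count streams plus ground truth."""

    streams: Dict[int, np.ndarray]  # sensor → (n, 3) int16 counts
    labels: np.ndarray  # per sample: pose index, or -1 in transitions
    times: np.ndarray
    script: MotionScript

    def streams_g(self) -> Dict[int, np.ndarray]:
        return {
            s: v.astype(float) / self.script.counts_per_g
            for s, v in self.streams.items()
        }


def _theta_profile(script: MotionScript) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample θ targets (n, sensors) and label track for a script."""
    rate = script.sampling_rate_hz
    thetas: List[np.ndarray] = []
    labels: List[np.ndarray] = []
    prev = np.asarray(script.segments[0].theta_targets, dtype=float)
    for seg in script.segments:
        target = np.asarray(seg.theta_targets, dtype=float)
        n_tr = int(round(seg.transition_s * rate))
        if n_tr > 0:
            # cosine easing: smooth start and stop of the movement
            s = (1 - np.cos(np.linspace(0.0, np.pi, n_tr, endpoint=False))) / 2
            thetas.append(prev + s[:, None] * (target - prev))
            labels.append(np.full(n_tr, TRANSITION_LABEL))
        n_hold = int(round(seg.hold_s * rate))
        thetas.append(np.tile(target, (n_hold, 1)))
        labels.append(np.full(n_hold, seg.pose))
        prev = target
    return np.vstack(thetas), np.concatenate(labels)


def gen_exercise(script: MotionScript) -> ExerciseData:
    """Generate five gravity-consistent sensor streams for a script.

    During holds each sensor reads a unit gravity vector at its target
    polar angle (body frame: (sin θ, 0, cos θ), so θ = 180° gives
    (0, 0, −1 g)); transitions sweep θ with cosine easing. The optional
    per-sensor mounting rotation is applied before noise and
    quantisation, emulating arbitrarily oriented sensors that the
    calibration stage must undo.
    """
    rng = np.random.default_rng(script.seed)
    theta, labels = _theta_profile(script)
    n = theta.shape[0]
    times = np.arange(n) / script.sampling_rate_hz

    streams: Dict[int, np.ndarray] = {}
    t_rad = np.radians(theta)
    for s in range(1, N_SENSORS + 1):
        body = np.column_stack([
            np.sin(t_rad[:, s - 1]),
            np.zeros(n),
            np.cos(t_rad[:, s - 1]),
        ])
        if script.mounting and s in script.mounting:
            body = body @ np.asarray(script.mounting[s], dtype=float).T
        if script.noise_sigma_g > 0:
            body = body + rng.normal(0.0, script.noise_sigma_g, body.shape)
        streams[s] = g_to_counts(body, script.counts_per_g)
    return ExerciseData(streams, labels, times, script)


# ---------------------------------------------------------------------------
# Rigid-bar impulse fixture
# ---------------------------------------------------------------------------

@dataclass
class ImpulseFixture:
    """Shared mechanical impulse sampled by five free-running modules.

    All modules sense the identical waveform (rigid mechanical
    coupling); they differ only in sampling phase. Two independent
    quantisations separate a module's recorded row from true time:

    * ``acquisition_phase_s`` — the accelerometer's own sampling clock
      phase in [0, 1/rate); it free-runs and cannot be synchronised to
      the board clock;
    * ``latch_phase_s`` — the phase of the module's beacon-synchronised
      buffer-copy timer in [0, 1/rate); the timer copies the most
      recently acquired sample into the outgoing packet.

    Each mechanism contributes up to one sample period of staleness or
    advance, so the worst-case onset spread across modules is two
    sample periods (12.5 ms at 160 Hz).
    """

    impulse_time_s: float = 0.5
    duration_s: float = 1.0
    amplitude_g: float = 2.0
    decay_tau_s: float = 0.05
    freq_hz: float = 30.0
    sampling_rate_hz: float = 160.0
    acquisition_phase_s: Tuple[float, ...] = (0.0,) * N_SENSORS
    latch_phase_s: Tuple[float, ...] = (0.0,) * N_SENSORS
    counts_per_g: float = COUNTS_PER_G
    seed: int = 0

    def __post_init__(self) -> None:
        period = 1.0 / self.sampling_rate_hz
        for name in ("acquisition_phase_s", "latch_phase_s"):
            for p in getattr(self, name):
                if not 0.0 <= p < period:
                    raise ValueError(
                        f"{name} entries must lie in [0, {period:.6f} s)"
                    )


def adversarial_fixture(**kwargs) -> ImpulseFixture:
    """Worst-case phase assignment for the impulse fixture.

    Module 1 records maximally stale content (latch tick lands just
    before a fresh acquisition), module 2 maximally fresh (latch tick
    just after acquisition, acquisition phase just under one period):
    their onset rows then straddle the full two-sample window.
    """
    period = 1.0 / kwargs.get("sampling_rate_hz", 160.0)
    eps = period * 1e-3
    acq = [eps, period - eps] + [0.0] * (N_SENSORS - 2)
    latch = [0.0, period - eps] + [0.0] * (N_SENSORS - 2)
    return ImpulseFixture(
        acquisition_phase_s=tuple(acq),
        latch_phase_s=tuple(latch),
        **kwargs,
    )


def random_fixture(rng: np.random.Generator, **kwargs) -> ImpulseFixture:
    """Impulse fixture with phases drawn uniformly in [0, 1/rate)."""
    period = 1.0 / kwargs.get("sampling_rate_hz", 160.0)
    return ImpulseFixture(
        acquisition_phase_s=tuple(rng.uniform(0.0, period, N_SENSORS)),
        latch_phase_s=tuple(rng.uniform(0.0, period, N_SENSORS)),
        **kwargs,
    )


def impulse_waveform(t_since_onset: np.ndarray, amplitude_g: float,
                     decay_tau_s: float, freq_hz: float) -> np.ndarray:
    """Exponentially decaying sinusoid, zero before the onset."""
    t = np.asarray(t_since_onset, dtype=float)
    w = amplitude_g * np.exp(-t / decay_tau_s) * np.sin(2 * np.pi * freq_hz * t)
    return np.where(t >= 0.0, w, 0.0)


def gen_wooden_bar(fixture: ImpulseFixture) -> Dict[int, np.ndarray]:
    """Generate the five aligned module streams for the impulse fixture.

    Row *k* of module *m* holds the sample most recently acquired at or
    before the module's latch tick ``k/rate + latch_phase``; acquisition
    happens on the module's own grid ``acquisition_phase + n/rate``.
    Gravity sits on −Z with the impulse superimposed on Z.
    """
    period = 1.0 / fixture.sampling_rate_hz
    n_rows = int(round(fixture.duration_s * fixture.sampling_rate_hz))
    rows = np.arange(n_rows)
    streams: Dict[int, np.ndarray] = {}
    for m in range(1, N_SENSORS + 1):
        acq = fixture.acquisition_phase_s[m - 1]
        latch = fixture.latch_phase_s[m - 1]
        tick = rows * period + latch
        # most recent acquisition at or before each latch tick
        n_acq = np.floor((tick - acq) / period).astype(int)
        sample_time = acq + n_acq * period
        z = -1.0 + impulse_waveform(
            sample_time - fixture.impulse_time_s,
            fixture.amplitude_g, fixture.decay_tau_s, fixture.freq_hz,
        )
        xyz = np.column_stack([np.zeros(n_rows), np.zeros(n_rows), z])
        streams[m] = g_to_counts(xyz, fixture.counts_per_g)
    return streams


def detect_onset(stream_counts: np.ndarray,
                 threshold_g: float = 0.25,
                 counts_per_g: float = COUNTS_PER_G) -> int:
    """First row index where the Z deviation from rest exceeds threshold."""
    z = stream_counts[:, 2].astype(float) / counts_per_g
    baseline = np.median(z[: max(4, len(z) // 10)])
    hits = np.nonzero(np.abs(z - baseline) > threshold_g)[0]
    if hits.size == 0:
        raise ValueError("no impulse onset found in stream")
    return int(hits[0])


def onset_spread_ms(streams: Dict[int, np.ndarray],
                    sampling_rate_hz: float = 160.0,
                    threshold_g: float = 0.25,
                    counts_per_g: float = COUNTS_PER_G) -> float:
    """Max onset desynchronisation across modules, in milliseconds."""
    onsets = [detect_onset(v, threshold_g, counts_per_g)
              for v in streams.values()]
    return (max(onsets) - min(onsets)) * 1000.0 / sampling_rate_hz


# ---------------------------------------------------------------------------
# Walking
# ---------------------------------------------------------------------------

def gen_walking(
    duration_s: float,
    cadence_hz: float = 2.0,
    amplitude_g: float = 0.5,
    seed: int = 0,
    sampling_rate_hz: float = 160.0,
    noise_sigma_g: float = 0.02,
    counts_per_g: float = COUNTS_PER_G,
) -> Dict[int, np.ndarray]:
    """Quasi-periodic walking signals for the five sensors.

    Lower-limb sensors (4, 5) carry the full stride amplitude at the
    cadence fundamental (anti-phase between legs, plus a weaker second
    harmonic for the stance/swing asymmetry); the waist sensor carries
    an attenuated bounce at twice the cadence; forearm sensors swing
    gently at the cadence. Zero amplitude degenerates to the static
    gravity-only signal.
    """
    if cadence_hz <= 0:
        raise ValueError("cadence must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    w = 2 * np.pi * cadence_hz * t

    gains = {1: 0.3, 2: 0.3, 3: 0.4, 4: 1.0, 5: 1.0}
    phases = {1: 0.0, 2: np.pi, 3: 0.0, 4: 0.0, 5: np.pi}
    streams: Dict[int, np.ndarray] = {}
    for s in range(1, N_SENSORS + 1):
        a = amplitude_g * gains[s]
        if s == 3:
            x = 0.3 * a * np.sin(2 * w)
            z = -1.0 + a * np.sin(2 * w + 0.5)
        else:
            x = a * np.sin(w + phases[s])
            z = -1.0 + 0.4 * a * np.sin(2 * (w + phases[s]))
        y = 0.15 * a * np.sin(w + phases[s] + 1.0)
        xyz = np.column_stack([x, y, z])
        if amplitude_g > 0 and noise_sigma_g > 0:
            xyz = xyz + rng.normal(0.0, noise_sigma_g, xyz.shape)
        streams[s] = g_to_counts(xyz, counts_per_g)
    return streams
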