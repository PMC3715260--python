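"""Fuzzy finite-state machine (FFSM) pose recognition and duration reports.

The exercise is modelled as an ordered cycle of fuzzy states
q₀ → q₁ → … → q₅ (q₀ is the standing calibration pose), each carrying a
graded activation degree in [0, 1]. The input at every time step is the
ten-dimensional feature vector (θ₁…θ₅, dθ₁/dt…dθ₅/dt) from the five
body sensors. Each state holds a trapezoidal membership template over
the five polar angles; a transition qₖ → qₖ₊₁ fires to the degree that
the features lie in the *next* pose's region AND motion is occurring
(|dθ/dt| high on at least one sensor). Activations evolve by max–min
composition over self-loops and cycle transitions, renormalised to sum
to one; when no rule fires (feature gaps, or features outside every
template) the previous activations are held.

The dominant state over time segments the session into poses, from
which per-pose and whole-exercise duration statistics are reported —
the feedback a therapist uses to judge the pace and uniformity of the
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .motion_features import SphericalSeries
from .synthetic_motion import SUN_SALUTATION_THETAS

N_SENSORS = 5


def trapezoid(x: np.ndarray, center: float, core: float,
              support: float) -> np.ndarray:
    """Symmetric trapezoidal membership: 1 within ±core, 0 beyond ±support."""
    d = np.abs(np.asarray(x, dtype=float) - center)
    return np.clip((support - d) / (support - core), 0.0, 1.0)


def rising_edge(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Piecewise-linear membership rising from 0 at ``low`` to 1 at ``high``."""
    return np.clip((np.asarray(x, dtype=float) - low) / (high - low), 0.0, 1.0)


@dataclass(frozen=True)
class StateDef:
    """One fuzzy state: a pose template over the five sensor angles.

    ``support_deg``/``core_deg`` set the trapezoid half-widths of this
    state's θ memberships. Scaling the support to the template distance
    from the *previous* pose in the cycle makes every transition commit
    at the same relative point of its movement, whatever the angular
    travel, which keeps recognised pose durations comparable across
    transitions of very different amplitude.
    """

    name: str
    pose: int
    theta_deg: Tuple[float, ...]  # template centre per sensor
    support_deg: float = 25.0
    core_deg: float = 10.0


#: support = this fraction of the largest per-sensor travel from the
#: previous pose in the cycle
SUPPORT_FRACTION = 0.35
CORE_FRACTION = 0.4  # of the support


@dataclass
class FFSMModel:
    """Fuzzy state machine over the ordered pose cycle.

    ``motion_low_dps``/``motion_high_dps`` bound the |dθ/dt| band in
    which the "motion occurring" degree rises from 0 to 1. With
    ``closing_edge`` the cycle closes q₅ → q₀ so multi-repetition
    sessions can be segmented.
    """

    states: List[StateDef]
    motion_low_dps: float = 3.0
    motion_high_dps: float = 12.0
    closing_edge: bool = True

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_membership(self, theta: np.ndarray) -> np.ndarray:
        """Membership of each state given θ features.

        ``theta`` is (..., 5); returns (..., n_states): the min over
        sensors of the per-sensor trapezoids (a pose matches only when
        every sensor is near its template angle).
        """
        th = np.atleast_2d(np.asarray(theta, dtype=float))
        mus = np.empty(th.shape[:-1] + (self.n_states,))
        for j, st in enumerate(self.states):
            per_sensor = np.stack([
                trapezoid(th[..., i], st.theta_deg[i],
                          st.core_deg, st.support_deg)
                for i in range(N_SENSORS)
            ], axis=-1)
            mus[..., j] = per_sensor.min(axis=-1)
        return mus

    def motion_degree(self, dtheta: np.ndarray) -> np.ndarray:
        """Degree to which motion is occurring: max over sensors."""
        dt = np.atleast_2d(np.asarray(dtheta, dtype=float))
        per = rising_edge(np.abs(dt), self.motion_low_dps,
                          self.motion_high_dps)
        return per.max(axis=-1)


def build_model(
    pose_thetas: Dict[int, Sequence[float]],
    motion_low_dps: float = 3.0,
    motion_high_dps: float = 12.0,
    closing_edge: bool = True,
) -> FFSMModel:
    """Build a cycle model from a pose → θ-template table.

    Each state's membership support is ``SUPPORT_FRACTION`` of the
    largest per-sensor angular travel from its predecessor in the
    cycle (clipped to [12°, 56°]), its core ``CORE_FRACTION`` of the
    support.
    """
    poses = sorted(pose_thetas)
    states = []
    for idx, p in enumerate(poses):
        prev = np.asarray(pose_thetas[poses[idx - 1]], dtype=float)
        here = np.asarray(pose_thetas[p], dtype=float)
        travel = float(np.max(np.abs(here - prev)))
        support = float(np.clip(SUPPORT_FRACTION * travel, 12.0, 56.0))
        states.append(StateDef(
            name=f"q{p}", pose=p, theta_deg=tuple(here),
            support_deg=support, core_deg=CORE_FRACTION * support,
        ))
    return FFSMModel(states=states, motion_low_dps=motion_low_dps,
                     motion_high_dps=motion_high_dps,
                     closing_edge=closing_edge)


def default_sun_salutation_model(**overrides) -> FFSMModel:
    """The reduced-cycle model built from the bundled pose templates."""
    return build_model(SUN_SALUTATION_THETAS, **overrides)


def load_model(path) -> FFSMModel:
    """Load a pose-template model from its YAML schema.

    Schema::

        states:
          - {name: q0, pose: 0, theta_deg: [180, 180, 180, 180, 180],
             support_deg: 49.0, core_deg: 19.6}
          ...
        motion_low_dps: 3.0
        motion_high_dps: 12.0
        closing_edge: true
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    states = [
        StateDef(
            name=s["name"], pose=int(s["pose"]),
            theta_deg=tuple(float(v) for v in s["theta_deg"]),
            support_deg=float(s.get("support_deg", 25.0)),
            core_deg=float(s.get("core_deg", 10.0)),
        )
        for s in raw["states"]
    ]
    kwargs = {k: raw[k] for k in (
        "motion_low_dps", "motion_high_dps", "closing_edge") if k in raw}
    return FFSMModel(states=states, **kwargs)


def save_model(model: FFSMModel, path) -> None:
    doc = {
        "states": [
            {"name": s.name, "pose": s.pose,
             "theta_deg": [float(v) for v in s.theta_deg],
             "support_deg": float(s.support_deg),
             "core_deg": float(s.core_deg)}
            for s in model.states
        ],
        "motion_low_dps": model.motion_low_dps,
        "motion_high_dps": model.motion_high_dps,
        "closing_edge": model.closing_edge,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# State update
# ---------------------------------------------------------------------------

def step(
    activations: np.ndarray,
    theta: np.ndarray,
    dtheta: np.ndarray,
    model: FFSMModel,
) -> np.ndarray:
    """One fuzzy update of the activation vector.

    new(qⱼ) = max( min(A(qⱼ), μⱼ(θ)),
                   min(A(qⱼ₋₁), min(μⱼ(θ), motion)) ),
    renormalised to sum 1. Feature vectors containing gaps (NaN) leave
    the activations unchanged, as does a step where no rule fires.
    """
    a = np.asarray(activations, dtype=float)
    if not np.isclose(a.sum(), 1.0, atol=1e-6):
        raise ValueError("activations must sum to 1")
    th = np.asarray(theta, dtype=float)
    dth = np.asarray(dtheta, dtype=float)
    if th.shape != (N_SENSORS,) or dth.shape != (N_SENSORS,):
        raise ValueError(
            f"feature vectors must have {N_SENSORS} components"
        )
    if np.isnan(th).any() or np.isnan(dth).any():
        return a.copy()

    mu = model.state_membership(th)[0]
    motion = float(model.motion_degree(dth)[0])
    return _step_from_memberships(a, mu, motion, model)


def _step_from_memberships(a: np.ndarray, mu: np.ndarray, motion: float,
                           model: FFSMModel) -> np.ndarray:
    n = model.n_states
    new = np.empty(n)
    for j in range(n):
        hold = min(a[j], mu[j])
        prev = j - 1
        if prev < 0:
            incoming = min(a[n - 1], mu[j], motion) if model.closing_edge \
                else 0.0
        else:
            incoming = min(a[prev], mu[j], motion)
        new[j] = max(hold, incoming)
    total = new.sum()
    if total < 1e-9:
        return a.copy()
    return new / total


@dataclass
class PoseTimeline:
    """Activation trajectories and dominant-state track over a session."""

    times: np.ndarray
    activations: np.ndarray  # (n, n_states), rows sum to 1
    dominant: np.ndarray  # state index per step
    sampling_rate_hz: float
    model: FFSMModel

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for j, st in enumerate(self.model.states):
            cols[f"act_{st.name}"] = self.activations[:, j]
        cols["dominant"] = self.dominant
        return pd.DataFrame(cols)


def recognize(
    features: Dict[int, SphericalSeries] | Tuple[np.ndarray, np.ndarray],
    model: Optional[FFSMModel] = None,
    sampling_rate_hz: Optional[float] = None,
    dominance_threshold: float = 0.5,
) -> PoseTimeline:
    """Run the FFSM over a feature series, starting concentrated on q₀.

    ``features`` is either the per-sensor :class:`SphericalSeries` dict
    from feature extraction (must cover all five sensors and include
    dθ/dt) or a raw pair ``(theta, dtheta)`` of (n, 5) arrays in
    degrees and degrees/s. The dominant state follows the argmax with a
    hysteresis band: it switches only when the winning activation
    exceeds ``dominance_threshold``, avoiding chatter mid-transition.
    """
    model = model or default_sun_salutation_model()
    if isinstance(features, dict):
        ids = sorted(features)
        if len(ids) != N_SENSORS:
            raise ValueError(
                f"need features for all {N_SENSORS} sensors, got {ids}"
            )
        theta = np.column_stack([features[i].theta_deg for i in ids])
        dtheta = np.column_stack([features[i].dtheta_dt for i in ids])
        rate = sampling_rate_hz or features[ids[0]].sampling_rate_hz
    else:
        theta, dtheta = features
        theta = np.asarray(theta, dtype=float)
        dtheta = np.asarray(dtheta, dtype=float)
        rate = sampling_rate_hz or 160.0
    if theta.ndim != 2 or theta.shape[1] != N_SENSORS:
        raise ValueError("theta features must be (n, 5)")
    if theta.shape != dtheta.shape:
        raise ValueError("theta and dtheta shapes differ")

    n = theta.shape[0]
    # vectorised memberships; the recurrence itself is sequential
    mu_all = model.state_membership(theta)
    motion_all = model.motion_degree(dtheta)
    gap = np.isnan(theta).any(axis=1) | np.isnan(dtheta).any(axis=1)

    a = np.zeros(model.n_states)
    a[0] = 1.0
    acts = np.empty((n, model.n_states))
    dominant = np.empty(n, dtype=int)
    dom = 0
    for k in range(n):
        if not gap[k]:
            a = _step_from_memberships(a, mu_all[k], float(motion_all[k]),
                                       model)
        acts[k] = a
        j = int(np.argmax(a))
        if a[j] > dominance_threshold:
            dom = j
        dominant[k] = dom
    times = np.arange(n) / rate
    return PoseTimeline(times, acts, dominant, rate, model)


# ---------------------------------------------------------------------------
# Duration statistics
# ---------------------------------------------------------------------------

@dataclass
class DurationReport:
    """Per-pose and whole-exercise duration statistics across repetitions.

    ``per_pose`` maps pose index (1…5; the calibration pose q₀ is
    excluded) to the list of active durations, one per repetition.
    Standard deviations use the unbiased estimator (0 for a single
    repetition).
    """

    per_pose: Dict[int, List[float]]
    n_repetitions: int

    def pose_mean_std(self, pose: int) -> Tuple[float, float]:
        d = np.asarray(self.per_pose[pose])
        return float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0

    def pose_summary(self) -> Tuple[float, float]:
        """Mean/std over all (pose, repetition) durations."""
        pooled = np.concatenate([np.asarray(v) for v in self.per_pose.values()])
        std = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        return float(pooled.mean()), std

    def exercise_summary(self) -> Tuple[float, float]:
        """Mean/std of the total exercise duration per repetition."""
        totals = np.sum(
            [np.asarray(self.per_pose[p]) for p in sorted(self.per_pose)],
            axis=0,
        )
        std = float(totals.std(ddof=1)) if totals.size > 1 else 0.0
        return float(totals.mean()), std

    def to_dataframe(self) -> pd.DataFrame:
        """One-row table in the duration-report schema."""
        row = {}
        for p in sorted(self.per_pose):
            m, s = self.pose_mean_std(p)
            row[f"q{p}_mean_s"] = m
            row[f"q{p}_std_s"] = s
        row["pose_mean_s"], row["pose_std_s"] = self.pose_summary()
        row["exercise_mean_s"], row["exercise_std_s"] = self.exercise_summary()
        row["n_repetitions"] = self.n_repetitions
        return pd.DataFrame([row])


def durations(timeline: PoseTimeline) -> DurationReport:
    """Active duration of each pose per repetition, q₀ excluded.

    A repetition starts when the dominant state first leaves q₀ and
    ends when it returns to q₀ (or at the end of the timeline). The
    duration of pose *j* within a repetition is the total time the FFSM
    recognised qⱼ as the active (dominant) state.
    """
    dom = timeline.dominant
    dt = 1.0 / timeline.sampling_rate_hz
    n_states = timeline.model.n_states
    poses = list(range(1, n_states))

    reps: List[Dict[int, float]] = []
    inside = False
    current: Dict[int, float] = {}
    for d in dom:
        if not inside:
            if d != 0:
                inside = True
                current = {p: 0.0 for p in poses}
                current[d] = dt
        else:
            if d == 0:
                reps.append(current)
                inside = False
            else:
                current[d] = current.get(d, 0.0) + dt
    if inside:
        reps.append(current)

    if not reps:
        raise ValueError("no complete repetition found in the timeline")
    per_pose = {p: [rep.get(p, 0.0) for rep in reps] for p in poses}
    return DurationReport(per_pose=per_pose, n_repetitions=len(reps))
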