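"""Synthetic smartphone recordings with known ground truth.

The generator emulates the structure the pipeline assumes — a phone resting
in a pocket while the wearer is static, walking, running, or on stairs — so
every stage can be exercised without human-subject recordings:

* **Accelerometer**: gravity (9.81 m/s^2 along the canonical device Y axis)
  plus a gait component plus white noise, all rotated into the carried
  orientation.  The gait component is a planar rotating vector

      LA(t) = r(t) * (cos th * d1 + sin th * d2),   th = 2 pi step_hz t,

  whose per-axis signals are nearly DC-free, so the 0.25 Hz gravity split
  passes it through essentially intact and the magnitude channel la3a tracks
  r(t) directly (no rectification doubling the frequency).  The magnitude

      r(t) = amp * (1 + 0.35 cos th + 2.2 asym * burst(th)) * env(t)

  oscillates at the step frequency itself, with ``burst`` a brief once-per-
  cycle pulse (mean-removed ``((1+cos th)/2)^4``): positive asymmetry adds
  heel-strike-like spikes (positive skew, upstairs), negative asymmetry adds
  dips (negative skew, downstairs).  ``|asym| <= 0.25`` keeps r(t) > 0.
  ``env`` is a per-stride jitter envelope.
* **Gyroscope**: periodic angular velocity at the same step frequency plus
  noise, rotated identically.
* **Magnetometer**: a constant ambient field (~50 uT total) rotated into the
  device frame plus noise — orientation-dependent on purpose.
* **Context**: 1 Hz light/proximity/call samples consistent with the
  scenario, so the pocket detector's ground truth is known by construction.

The activity profiles are tunable defaults chosen to make the five classes
separable while walking/upstairs/downstairs overlap partially; they carry no
claim of physiological fidelity.  Coat pockets scale amplitudes down
(trunk moves less than the legs), so coat recordings show smaller mean la3a
than trouser recordings for the same activity — a generator contract the
tests assert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sensor_io import (
    ACTIVITY_LABELS,
    ActivityAnnotation,
    ContextTrace,
    Recording,
    SensorTrace,
    ValidationError,
)
from . import preprocess
from .features import DEFAULT_OVERLAP, DEFAULT_WINDOW_S, extract_feature_table, slide_windows

__all__ = [
    "ActivityProfile",
    "PlacementProfile",
    "DEFAULT_PROFILES",
    "POCKET_POSITIONS",
    "CARRY_ORIENTATIONS",
    "activity_script",
    "gen_recording",
    "gen_context",
    "gen_dataset",
]

GRAVITY_MS2 = 9.81
#: Ambient geomagnetic field in the world frame, uT (|B| ~ 49 uT).
AMBIENT_FIELD_UT = np.array([22.0, 5.0, -43.0])


@dataclass(frozen=True)
class ActivityProfile:
    """Signal parameters for one activity class.

    ``step_hz`` is the fundamental gait frequency (0 for static), ``la_amp``
    the linear-acceleration magnitude scale in m/s^2, ``gyro_amp`` the
    angular-velocity scale in rad/s, ``asymmetry`` the up/down half-cycle
    skew in (-0.25, 0.25) (positive for upstairs, negative for downstairs),
    and ``noise_sd`` the additive accelerometer noise in m/s^2.
    """

    label: str
    step_hz: float
    la_amp: float
    gyro_amp: float
    asymmetry: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.step_hz < 0 or self.la_amp < 0 or self.gyro_amp < 0:
            raise ValidationError("profile rates/amplitudes must be >= 0")
        if abs(self.asymmetry) > 0.25:
            raise ValidationError("asymmetry must lie in [-0.25, 0.25]")


# step_hz / la_amp follow the standard walking-cadence figures; gyro_amp
# orders the classes by leg angular velocity (stair gait swings slower than
# level walking, running swings fastest) with wide gaps so the classes stay
# separable under any pocket's amplitude scaling.
DEFAULT_PROFILES: dict[str, ActivityProfile] = {
    "static": ActivityProfile("static", 0.0, 0.05, 0.01, 0.0, noise_sd=0.02),
    "walking": ActivityProfile("walking", 1.8, 2.0, 2.0, 0.0),
    "running": ActivityProfile("running", 2.8, 6.0, 3.5, 0.0),
    "upstairs": ActivityProfile("upstairs", 1.5, 2.5, 0.5, +0.25),
    "downstairs": ActivityProfile("downstairs", 1.6, 3.0, 1.0, -0.25),
}

POCKET_POSITIONS = (
    "trouser_front_left",
    "trouser_front_right",
    "trouser_back_left",
    "trouser_back_right",
    "coat_front_left",
    "coat_front_right",
)

_COAT_AMP_SCALE = 0.8


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


#: The four vertical carry orientations (phone head up/down x face in/out),
#: as rotations of the canonical device frame.
CARRY_ORIENTATIONS: dict[str, np.ndarray] = {
    "head_up_face_in": np.eye(3),
    "head_up_face_out": _rot_y(math.pi),
    "head_down_face_in": _rot_x(math.pi),
    "head_down_face_out": _rot_x(math.pi) @ _rot_y(math.pi),
}


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@dataclass(frozen=True)
class PlacementProfile:
    """Where and how the phone is carried."""

    position: str = "trouser_front_right"
    amp_scale: float | None = None  # default: 0.6 for coat, 1.0 for trousers
    orientation: np.ndarray | str = "head_up_face_in"

    def __post_init__(self) -> None:
        if self.position not in POCKET_POSITIONS:
            raise ValidationError(f"unknown pocket position {self.position!r}")
        if self.amp_scale is not None and not self.amp_scale > 0:
            raise ValidationError("amp_scale must be > 0")

    @property
    def effective_amp_scale(self) -> float:
        if self.amp_scale is not None:
            return self.amp_scale
        return _COAT_AMP_SCALE if self.position.startswith("coat") else 1.0

    def rotation(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.orientation, str):
            if self.orientation == "random":
                return random_rotation(rng)
            if self.orientation not in CARRY_ORIENTATIONS:
                raise ValidationError(
                    f"unknown orientation {self.orientation!r}"
                )
            return CARRY_ORIENTATIONS[self.orientation]
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValidationError("orientation must be an orthonormal 3x3 matrix")
        return R


def activity_script(
    labels: list[str], duration_s: float = 60.0, gap_s: float = 5.0
) -> list[ActivityAnnotation]:
    """Back-to-back annotations with stationary gaps between activities."""
    out, t = [], 0.0
    for lab in labels:
        out.append(ActivityAnnotation(t, t + duration_s, lab))
        t += duration_s + gap_s
    return out


# ---------------------------------------------------------------------------
# recording generator
# ---------------------------------------------------------------------------

# fixed body-frame plane of the gait acceleration (orthonormal pair)
_LA_D1 = np.array([1.0, 0.0, 0.0])
_LA_D2 = np.array([0.0, 0.8, 0.6])
_LA_D2 = _LA_D2 / np.linalg.norm(_LA_D2)

# mean of ((1+cos)/2)^4 over a cycle
_BURST_MEAN = 4.375 / 16.0


def _stride_envelope(
    t_rel: np.ndarray, step_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-stride multiplicative amplitude jitter, ~N(1, 0.08) clipped."""
    step_idx = np.floor(step_hz * t_rel).astype(int)
    n_steps = int(step_idx.max()) + 1 if len(step_idx) else 1
    env = 1.0 + 0.08 * rng.standard_normal(n_steps).clip(-1.2, 1.2)
    return env[step_idx]


def _gait_la(
    t_rel: np.ndarray, prof: ActivityProfile, rng: np.random.Generator
) -> np.ndarray:
    """Planar rotating linear-acceleration vector, shape (n, 3)."""
    theta = 2 * math.pi * prof.step_hz * t_rel + rng.uniform(0, 2 * math.pi)
    burst = ((1 + np.cos(theta)) / 2) ** 4 - _BURST_MEAN
    r = 1.0 + 0.35 * np.cos(theta) + 2.2 * prof.asymmetry * burst
    r = r * prof.la_amp * _stride_envelope(t_rel, prof.step_hz, rng)
    return r[:, None] * (
        np.outer(np.cos(theta), _LA_D1) + np.outer(np.sin(theta), _LA_D2)
    )


def gen_recording(
    annotations: list[ActivityAnnotation],
    placement: PlacementProfile | None = None,
    rate_hz: float = 25.0,
    seed: int = 0,
    profiles: dict[str, ActivityProfile] | None = None,
    tail_s: float = 0.0,
) -> Recording:
    """Generate one labelled in-pocket recording.

    The recording spans ``[0, last annotation end + tail_s]``; outside the
    annotated intervals the wearer is treated as stationary.  All three
    motion sensors, a 1 Hz in-pocket context trace, and the annotations are
    embedded in the returned :class:`Recording`.
    """
    placement = placement or PlacementProfile()
    profiles = profiles or DEFAULT_PROFILES
    annotations = sorted(annotations, key=lambda a: a.start_s)
    for a in annotations:
        if a.label not in profiles:
            raise ValidationError(f"no profile for activity {a.label!r}")
    if not annotations:
        raise ValidationError("need at least one annotation")

    rng = np.random.default_rng(seed)
    R = placement.rotation(rng)
    scale = placement.effective_amp_scale
    T = annotations[-1].end_s + tail_s
    n = int(round(T * rate_hz)) + 1
    t = np.arange(n) / rate_hz

    la = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    for a in annotations:
        prof = profiles[a.label]
        sel = (t >= a.start_s) & (t < a.end_s)
        if prof.step_hz > 0:
            t_rel = t[sel] - a.start_s
            la[sel] = _gait_la(t_rel, prof, rng) * scale
            theta = 2 * math.pi * prof.step_hz * t_rel + rng.uniform(0, 2 * math.pi)
            w = prof.gyro_amp * scale
            gyro[sel, 0] = w * np.sin(theta)
            gyro[sel, 1] = 0.6 * w * np.sin(theta + 1.3)
            gyro[sel, 2] = 0.4 * w * np.sin(2 * theta)

    # per-sample noise follows the locally active profile
    noise_sd = np.full(n, profiles.get("static", DEFAULT_PROFILES["static"]).noise_sd)
    for a in annotations:
        sel = (t >= a.start_s) & (t < a.end_s)
        noise_sd[sel] = profiles[a.label].noise_sd

    gravity = np.array([0.0, GRAVITY_MS2, 0.0])
    acc_world = gravity + la + noise_sd[:, None] * rng.standard_normal((n, 3))
    gyro_world = gyro + 0.02 * rng.standard_normal((n, 3))
    mag_world = AMBIENT_FIELD_UT + 0.3 * rng.standard_normal((n, 3))

    traces = {
        "accelerometer": SensorTrace("accelerometer", rate_hz, t, acc_world @ R.T),
        "gyroscope": SensorTrace("gyroscope", rate_hz, t, gyro_world @ R.T),
        "magnetometer": SensorTrace("magnetometer", rate_hz, t, mag_world @ R.T),
    }
    context = gen_context("in_pocket_day", duration_s=T, seed=seed + 1)
    return Recording(traces=traces, context=context, annotations=list(annotations))


def gen_context(
    scenario: str, duration_s: float, seed: int = 0, rate_hz: float = 1.0
) -> ContextTrace:
    """Context trace for a scenario with known ground-truth pocket state.

    ``in_pocket_day``: covered light sensor (dim readings well below 100
    lux), near proximity, idle.  ``in_pocket_night_call``: full-moon-level
    darkness (0.25 lux) with a call occupying the middle third of the trace —
    out-of-pocket only during the call.  ``out_of_pocket``: overcast-daylight
    readings (10000 lux), far proximity, idle.
    """
    if duration_s <= 0:
        raise ValidationError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    if scenario == "in_pocket_day":
        lux = rng.uniform(5.0, 60.0, size=n)
        prox = np.full(n, "near", dtype=object)
        call = np.full(n, "idle", dtype=object)
    elif scenario == "in_pocket_night_call":
        lux = np.full(n, 0.25)
        prox = np.full(n, "near", dtype=object)
        call = np.full(n, "idle", dtype=object)
        in_call = (t >= duration_s / 3) & (t < 2 * duration_s / 3)
        call[in_call] = "in_call"
    elif scenario == "out_of_pocket":
        lux = np.full(n, 10000.0)
        prox = np.full(n, "far", dtype=object)
        call = np.full(n, "idle", dtype=object)
    else:
        raise ValidationError(f"unknown context scenario {scenario!r}")
    return ContextTrace(t=t, lux=lux, proximity=prox, call_state=call)


# ---------------------------------------------------------------------------
# end-to-end dataset generator
# ---------------------------------------------------------------------------


def _default_placements() -> list[PlacementProfile]:
    return [
        PlacementProfile("trouser_front_right", orientation="head_up_face_in"),
        PlacementProfile("coat_front_left", orientation="random"),
    ]


def gen_dataset(
    n_per_class: int = 50,
    placements: list[PlacementProfile] | None = None,
    seed: int = 0,
    profiles: dict[str, ActivityProfile] | None = None,
    rate_hz: float = 25.0,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    trim_s: float = preprocess.DEFAULT_TRIM_SECONDS,
) -> pd.DataFrame:
    """Balanced labelled feature table via the real preprocessing pipeline.

    For each activity class and each placement, a recording long enough to
    yield its share of windows is generated, edge-trimmed, reduced to the
    five channels, windowed, and featurized; the first ``n_per_class`` rows
    per class are kept.  Deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    placements = placements or _default_placements()
    profiles = profiles or DEFAULT_PROFILES
    stride_s = window_s * (1 - overlap)
    tables = []
    for ci, label in enumerate(ACTIVITY_LABELS):
        per_place = -(-n_per_class // len(placements))  # ceil division
        rows = []
        for pi, placement in enumerate(placements):
            need_s = (per_place - 1) * stride_s + window_s
            dur = need_s + 2 * trim_s + 2.0  # margin for trim + edge effects
            rec = gen_recording(
                [ActivityAnnotation(0.0, dur, label)],
                placement=placement,
                rate_hz=rate_hz,
                seed=seed * 1000 + ci * 10 + pi,
                profiles=profiles,
            )
            rec = preprocess.trim_edges(rec, trim_s)
            signals = preprocess.derive_signals(rec, rate_hz=rate_hz)
            windows = slide_windows(signals, window_s, overlap, rec.annotations)
            rows.append(extract_feature_table(windows).head(per_place))
        tables.append(pd.concat(rows, ignore_index=True).head(n_per_class))
    table = pd.concat(tables, ignore_index=True)
    expected = n_per_class * len(ACTIVITY_LABELS)
    if len(table) != expected:
        raise ValidationError(
            f"generator produced {len(table)} rows, expected {expected}"
        )
    return table


def with_contrast(
    profiles: dict[str, ActivityProfile], contrast: float
) -> dict[str, ActivityProfile]:
    """Scale inter-class amplitude gaps around the walking baseline.

    ``contrast`` > 1 widens the gaps (amplitudes move away from walking's),
    < 1 narrows them; amplitudes are floored at a small positive value.
    """
    base = profiles["walking"]
    out = {}
    for k, p in profiles.items():
        la = max(base.la_amp + contrast * (p.la_amp - base.la_amp), 0.01)
        gy = max(base.gyro_amp + contrast * (p.gyro_amp - base.gyro_amp), 0.005)
        out[k] = replace(p, la_amp=la, gyro_amp=gy)
    return out
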