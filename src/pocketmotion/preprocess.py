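"""Signal conditioning: resampling, gravity separation, edge trimming, and
derivation of the five classification channels.

The accelerometer reads gravity plus body acceleration.  A zero-phase
low-pass at 0.25 Hz isolates the gravity component GA; the remainder
LA = raw - GA is the linear (body) acceleration.  The two channels actually
used for classification are Euclidean magnitudes,

    la3a  = sqrt(LA_x^2 + LA_y^2 + LA_z^2)       (m/s^2)
    gyr3a = sqrt(w_x^2 + w_y^2 + w_z^2)          (rad/s)

which are invariant under any rigid rotation of the device, so a phone
dropped into a pocket in an arbitrary orientation yields the same series.
The three magnetometer axes are carried through raw; they are
orientation-dependent by construction and are kept only because the field's
reference pipeline uses them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .sensor_io import (
    ActivityAnnotation,
    ContextTrace,
    Recording,
    SENSOR_KINDS,
    SensorTrace,
    ValidationError,
)

__all__ = [
    "DEFAULT_RATE_HZ",
    "DEFAULT_GRAVITY_CUTOFF_HZ",
    "DEFAULT_TRIM_SECONDS",
    "GravitySplit",
    "SignalSet",
    "resample",
    "split_gravity",
    "trim_edges",
    "derive_signals",
]

logger = logging.getLogger(__name__)

DEFAULT_RATE_HZ = 25.0
DEFAULT_GRAVITY_CUTOFF_HZ = 0.25
DEFAULT_TRIM_SECONDS = 5.0


@dataclass
class GravitySplit:
    """Gravity (GA) and linear (LA) acceleration on the same clock.

    ``ga + la`` reconstructs the raw acceleration exactly (LA is defined as
    the residual of the low-pass, so additivity holds to round-off).
    """

    t: np.ndarray
    ga: np.ndarray  # (n, 3) m/s^2
    la: np.ndarray  # (n, 3) m/s^2
    rate_hz: float


@dataclass
class SignalSet:
    """The five derived channels on a common uniform clock."""

    t: np.ndarray
    rate_hz: float
    la3a: np.ndarray
    gyr3a: np.ndarray
    mag_x: np.ndarray
    mag_y: np.ndarray
    mag_z: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("la3a", "gyr3a", "mag_x", "mag_y", "mag_z"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name} length mismatch")
        if (self.la3a < 0).any() or (self.gyr3a < 0).any():
            raise ValidationError("magnitude channels must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


def resample(trace: SensorTrace, rate_hz: float) -> SensorTrace:
    """Linear interpolation of a trace onto a uniform grid at ``rate_hz``.

    The grid starts at the first sample and never extends past the last
    (no extrapolation).  Requires at least two samples.
    """
    if len(trace) < 2:
        raise ValidationError("resample needs at least 2 samples")
    if not rate_hz > 0:
        raise ValidationError("rate_hz must be > 0")
    t0, t1 = trace.t[0], trace.t[-1]
    n = int(np.floor((t1 - t0) * rate_hz + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate_hz
    xyz = np.column_stack(
        [np.interp(grid, trace.t, trace.xyz[:, k]) for k in range(3)]
    )
    return SensorTrace(kind=trace.kind, rate_hz=rate_hz, t=grid, xyz=xyz)


def _lowpass_sos(cutoff_hz: float, rate_hz: float):
    return sp_signal.butter(2, cutoff_hz, btype="low", fs=rate_hz, output="sos")


def split_gravity(
    acc: SensorTrace, cutoff_hz: float = DEFAULT_GRAVITY_CUTOFF_HZ
) -> GravitySplit:
    """Split acceleration into gravity + linear parts.

    GA is a 2nd-order Butterworth low-pass (zero-phase, forward-backward)
    applied per axis; LA is the raw signal minus GA, so GA + LA == raw
    elementwise.  The zero-phase realization keeps windows aligned with their
    labels; its edge transient decays within ~1/cutoff seconds, which the
    recording-edge trim absorbs.
    """
    if not cutoff_hz < acc.rate_hz / 2:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({acc.rate_hz / 2} Hz)"
        )
    sos = _lowpass_sos(cutoff_hz, acc.rate_hz)
    ga = np.column_stack(
        [sp_signal.sosfiltfilt(sos, acc.xyz[:, k]) for k in range(3)]
    )
    la = acc.xyz - ga
    return GravitySplit(t=acc.t.copy(), ga=ga, la=la, rate_hz=acc.rate_hz)


def _clip_trace(trace: SensorTrace, lo: float, hi: float) -> SensorTrace:
    keep = (trace.t >= lo) & (trace.t < hi)
    return SensorTrace(
        kind=trace.kind, rate_hz=trace.rate_hz, t=trace.t[keep], xyz=trace.xyz[keep]
    )


def trim_edges(recording: Recording, seconds: float = DEFAULT_TRIM_SECONDS) -> Recording:
    """Drop the first and last ``seconds`` of a recording.

    The subject needs time to pocket the phone and to take it back out, so
    the signal edges are unstable; everything — traces, context, annotations —
    is clipped to ``[t0 + seconds, tend - seconds)``.
    """
    if seconds < 0:
        raise ValidationError("trim seconds must be >= 0")
    if seconds == 0:
        return recording
    t0, tend = recording.span()
    lo, hi = t0 + seconds, tend - seconds
    if not lo < hi:
        raise ValidationError(
            f"recording of {tend - t0:.3f} s too short to trim {seconds} s per edge"
        )
    traces = {k: _clip_trace(tr, lo, hi) for k, tr in recording.traces.items()}
    context = None
    if recording.context is not None:
        keep = (recording.context.t >= lo) & (recording.context.t < hi)
        context = ContextTrace(
            t=recording.context.t[keep],
            lux=recording.context.lux[keep],
            proximity=recording.context.proximity[keep],
            call_state=recording.context.call_state[keep],
        )
    annotations = []
    for a in recording.annotations:
        s, e = max(a.start_s, lo), min(a.end_s, hi)
        if s < e:
            annotations.append(ActivityAnnotation(s, e, a.label))
    return Recording(traces=traces, context=context, annotations=annotations)


def derive_signals(
    recording: Recording,
    rate_hz: float = DEFAULT_RATE_HZ,
    gravity_cutoff_hz: float = DEFAULT_GRAVITY_CUTOFF_HZ,
) -> SignalSet:
    """Resample all sensors onto a common clock and derive the five channels.

    All three sensor kinds must be present.  The common grid starts at the
    latest trace start and ends at the earliest trace end (intersection of
    spans), at ``rate_hz``.
    """
    for kind in SENSOR_KINDS:
        if kind not in recording.traces:
            raise ValidationError(f"recording is missing a {kind} trace")
        if len(recording.traces[kind]) < 2:
            raise ValidationError(f"{kind} trace too short to resample")

    start = max(recording.traces[k].t[0] for k in SENSOR_KINDS)
    end = min(recording.traces[k].t[-1] for k in SENSOR_KINDS)
    if not start < end:
        raise ValidationError("sensor traces have no overlapping time span")
    n = int(np.floor((end - start) * rate_hz + 1e-9)) + 1
    grid = start + np.arange(n) / rate_hz

    on_grid = {}
    for kind in SENSOR_KINDS:
        tr = recording.traces[kind]
        on_grid[kind] = np.column_stack(
            [np.interp(grid, tr.t, tr.xyz[:, k]) for k in range(3)]
        )

    acc = SensorTrace(
        kind="accelerometer", rate_hz=rate_hz, t=grid, xyz=on_grid["accelerometer"]
    )
    split = split_gravity(acc, gravity_cutoff_hz)
    la3a = np.linalg.norm(split.la, axis=1)
    gyr3a = np.linalg.norm(on_grid["gyroscope"], axis=1)
    mag = on_grid["magnetometer"]
    logger.debug(
        "derived signals: %d samples at %.3g Hz over [%.3f, %.3f)",
        n, rate_hz, start, end,
    )
    return SignalSet(
        t=grid,
        rate_hz=rate_hz,
        la3a=la3a,
        gyr3a=gyr3a,
        mag_x=mag[:, 0],
        mag_y=mag[:, 1],
        mag_z=mag[:, 2],
    )
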