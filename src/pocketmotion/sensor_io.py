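"""Readers and writers for the on-disk dialects of the pipeline.

Four plain-text formats are defined here and consumed everywhere else:

* **motion log** — CSV with header ``t_s,sensor,x,y,z``; one row per tri-axial
  sample; ``sensor`` is one of ``accelerometer``/``gyroscope``/``magnetometer``
  (short aliases ``acc``/``gyro``/``mag`` accepted on read).
* **context log** — CSV with header ``t_s,lux,proximity,call_state``;
  ``proximity`` is stored as ``near``/``far`` (raw device distances are mapped
  at parse time: 0.0 -> near, anything greater -> far); ``call_state`` is
  ``idle``/``in_call``.
* **annotations** — CSV ``start_s,end_s,label`` with half-open activity
  intervals drawn from the five-activity vocabulary.
* **feature table** — CSV (header + one row per window) or ARFF with one
  numeric attribute per feature and a nominal class attribute.

Timestamps are seconds since recording start, as reals.  Readers never drop
rows silently: every input row is either parsed or counted in the attached
:class:`ParseReport`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SENSOR_KINDS",
    "ACTIVITY_LABELS",
    "ParseError",
    "ValidationError",
    "SensorTrace",
    "ContextTrace",
    "ActivityAnnotation",
    "ParseReport",
    "Recording",
    "read_raw_log",
    "write_raw_log",
    "read_context_log",
    "write_context_log",
    "read_annotations",
    "write_annotations",
    "write_feature_table",
    "read_feature_table",
]

SENSOR_KINDS = ("accelerometer", "gyroscope", "magnetometer")
_SENSOR_ALIASES = {
    "accelerometer": "accelerometer",
    "acc": "accelerometer",
    "gyroscope": "gyroscope",
    "gyro": "gyroscope",
    "magnetometer": "magnetometer",
    "mag": "magnetometer",
}

#: The five activity classes, in the fixed order used by confusion matrices
#: and nominal ARFF attributes.
ACTIVITY_LABELS = ("static", "walking", "running", "upstairs", "downstairs")

PROXIMITY_STATES = ("near", "far")
CALL_STATES = ("idle", "in_call")

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class ParseError(ValueError):
    """A row that cannot be interpreted under the declared dialect."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class SensorTrace:
    """Time series for one sensor kind.

    Parameters
    ----------
    kind
        One of :data:`SENSOR_KINDS`.
    rate_hz
        Nominal sampling rate (the device logs at 25 Hz; resampled traces
        carry their grid rate).
    t
        Sample times in seconds, strictly increasing, shape ``(n,)``.
    xyz
        Tri-axial readings, shape ``(n, 3)``; m/s^2 for the accelerometer,
        rad/s for the gyroscope, uT for the magnetometer.
    """

    kind: str
    rate_hz: float
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(len(self.t), 3)
        if self.kind not in SENSOR_KINDS:
            raise ValidationError(f"unknown sensor kind {self.kind!r}")
        if not self.rate_hz > 0:
            raise ValidationError("rate_hz must be > 0")
        if len(self.t) and (not np.isfinite(self.t).all() or self.t[0] < 0):
            raise ValidationError("timestamps must be finite and >= 0")
        if not np.isfinite(self.xyz).all():
            raise ValidationError("sensor readings must be finite")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValidationError(
                f"{self.kind} trace timestamps are not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ContextTrace:
    """Light / proximity / call-state samples used for pocket detection."""

    t: np.ndarray
    lux: np.ndarray
    proximity: np.ndarray  # array of "near"/"far"
    call_state: np.ndarray  # array of "idle"/"in_call"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.lux = np.asarray(self.lux, dtype=float)
        self.proximity = np.asarray(self.proximity, dtype=object)
        self.call_state = np.asarray(self.call_state, dtype=object)
        n = len(self.t)
        if not (len(self.lux) == len(self.proximity) == len(self.call_state) == n):
            raise ValidationError("context channels must have equal length")
        if n > 1 and not (np.diff(self.t) > 0).all():
            raise ValidationError("context timestamps are not strictly increasing")
        if n and (not np.isfinite(self.lux).all() or (self.lux < 0).any()):
            raise ValidationError("lux must be finite and >= 0")
        for p in self.proximity:
            if p not in PROXIMITY_STATES:
                raise ValidationError(f"invalid proximity state {p!r}")
        for c in self.call_state:
            if c not in CALL_STATES:
                raise ValidationError(f"invalid call state {c!r}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ActivityAnnotation:
    """Half-open labelled interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"annotation start {self.start_s} must precede end {self.end_s}"
            )
        if self.label not in ACTIVITY_LABELS:
            raise ValidationError(
                f"unknown activity label {self.label!r}; expected one of "
                f"{ACTIVITY_LABELS}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class ParseReport:
    """Row accounting for a reader: file rows = parsed + malformed."""

    n_rows: int = 0
    n_parsed: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_malformed(self) -> int:
        return len(self.malformed)


@dataclass
class Recording:
    """One session: motion traces, optional context, activity annotations."""

    traces: dict[str, SensorTrace] = field(default_factory=dict)
    context: ContextTrace | None = None
    annotations: list[ActivityAnnotation] = field(default_factory=list)
    parse_report: ParseReport | None = None

    def __post_init__(self) -> None:
        self.annotations = validate_annotations(self.annotations)

    def span(self) -> tuple[float, float]:
        """Earliest and latest motion-sample time; falls back to context."""
        starts, ends = [], []
        for tr in self.traces.values():
            if len(tr):
                starts.append(tr.t[0])
                ends.append(tr.t[-1])
        if not starts and self.context is not None and len(self.context):
            starts.append(self.context.t[0])
            ends.append(self.context.t[-1])
        if not starts:
            raise ValidationError("recording is empty")
        return float(min(starts)), float(max(ends))


def validate_annotations(
    annotations: list[ActivityAnnotation],
) -> list[ActivityAnnotation]:
    """Sort annotations and reject overlapping intervals (half-open)."""
    anns = sorted(annotations, key=lambda a: (a.start_s, a.end_s))
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start_s < prev.end_s - 1e-12:
            raise ValidationError(
                f"annotations overlap: [{prev.start_s}, {prev.end_s}) and "
                f"[{nxt.start_s}, {nxt.end_s})"
            )
    return anns


# ---------------------------------------------------------------------------
# motion log
# ---------------------------------------------------------------------------

_MOTION_HEADER = ["t_s", "sensor", "x", "y", "z"]


def read_raw_log(path, rate_hz: float | None = None) -> Recording:
    """Parse a motion log into a :class:`Recording`.

    Rows with the wrong arity or unparseable numbers are counted in
    ``recording.parse_report`` rather than dropped silently.  An unknown
    sensor tag raises :class:`ParseError` naming the line; non-monotone
    timestamps raise :class:`ValidationError`.

    ``rate_hz`` overrides the nominal rate attached to each trace; by default
    it is inferred from the median timestamp spacing (25 Hz if fewer than two
    samples).
    """
    report = ParseReport()
    rows: dict[str, list[tuple[float, float, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:  # empty file -> empty Recording
            return Recording(parse_report=report)
        if [h.strip() for h in header] != _MOTION_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(_MOTION_HEADER)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            report.n_rows += 1
            if len(row) != 5:
                report.malformed.append((lineno, "wrong field count"))
                continue
            tag = row[1].strip()
            kind = _SENSOR_ALIASES.get(tag)
            if kind is None:
                raise ParseError(f"{path}:{lineno}: unknown sensor tag {tag!r}")
            try:
                t = float(row[0])
                x, y, z = float(row[2]), float(row[3]), float(row[4])
            except ValueError:
                report.malformed.append((lineno, "unparseable number"))
                continue
            rows.setdefault(kind, []).append((t, x, y, z))
            report.n_parsed += 1

    traces = {}
    for kind, samples in rows.items():
        arr = np.array(samples, dtype=float)
        t = arr[:, 0]
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValidationError(
                f"{path}: non-monotone timestamps in {kind} trace"
            )
        rate = rate_hz if rate_hz is not None else _infer_rate(t)
        traces[kind] = SensorTrace(kind=kind, rate_hz=rate, t=t, xyz=arr[:, 1:])
    return Recording(traces=traces, parse_report=report)


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        return 25.0
    dt = float(np.median(np.diff(t)))
    return 1.0 / dt if dt > 0 else 25.0


def write_raw_log(recording: Recording, path) -> None:
    """Write all motion traces of a recording as one time-sorted CSV."""
    merged: list[tuple[float, int, str, float, float, float]] = []
    for kind, tr in recording.traces.items():
        order = SENSOR_KINDS.index(kind)
        for i in range(len(tr)):
            merged.append((tr.t[i], order, kind, *tr.xyz[i]))
    merged.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MOTION_HEADER)
        for t, _, kind, x, y, z in merged:
            w.writerow(
                [_FLOAT_FMT % t, kind, _FLOAT_FMT % x, _FLOAT_FMT % y, _FLOAT_FMT % z]
            )


# ---------------------------------------------------------------------------
# context log
# ---------------------------------------------------------------------------

_CONTEXT_HEADER = ["t_s", "lux", "proximity", "call_state"]


def read_context_log(path) -> ContextTrace:
    """Parse a context log.

    ``proximity`` may be the strings near/far or a raw device distance in cm
    (0.0 -> near, anything greater -> far, matching handsets that report only
    two distances).
    """
    t, lux, prox, call = [], [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return ContextTrace(t=[], lux=[], proximity=[], call_state=[])
        if [h.strip() for h in header] != _CONTEXT_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(_CONTEXT_HEADER)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"{path}:{lineno}: wrong field count")
            t.append(float(row[0]))
            lux.append(float(row[1]))
            prox.append(_parse_proximity(row[2].strip(), path, lineno))
            c = row[3].strip()
            if c not in CALL_STATES:
                raise ParseError(f"{path}:{lineno}: invalid call state {c!r}")
            call.append(c)
    return ContextTrace(t=t, lux=lux, proximity=prox, call_state=call)


def _parse_proximity(token: str, path, lineno: int) -> str:
    if token in PROXIMITY_STATES:
        return token
    try:
        cm = float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: invalid proximity value {token!r}"
        ) from None
    return "near" if cm == 0.0 else "far"


def write_context_log(context: ContextTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CONTEXT_HEADER)
        for i in range(len(context)):
            w.writerow(
                [
                    _FLOAT_FMT % context.t[i],
                    _FLOAT_FMT % context.lux[i],
                    context.proximity[i],
                    context.call_state[i],
                ]
            )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path) -> list[ActivityAnnotation]:
    """Read ``start_s,end_s,label`` rows; sorted, validated, non-overlapping."""
    anns = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and row[0].strip() == "start_s":
                continue  # optional header
            if len(row) != 3:
                raise ParseError(f"{path}:{lineno}: expected start,end,label")
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: unparseable interval") from None
            anns.append(ActivityAnnotation(start, end, row[2].strip()))
    return validate_annotations(anns)


def write_annotations(annotations: list[ActivityAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "label"])
        for a in annotations:
            w.writerow([_FLOAT_FMT % a.start_s, _FLOAT_FMT % a.end_s, a.label])


# ---------------------------------------------------------------------------
# feature tables (CSV / ARFF)
# ---------------------------------------------------------------------------

LABEL_COLUMN = "label"


def write_feature_table(table: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a feature table (feature columns + ``label``) as CSV or ARFF.

    ARFF declares one numeric attribute per feature and a nominal class
    attribute over the five activities, so a 30-feature table yields 31
    ``@attribute`` lines.
    """
    _validate_table(table)
    if format == "csv":
        table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "arff":
        with open(path, "w") as fh:
            fh.write(_to_arff(table))
    else:
        raise ValueError(f"unknown feature-table format {format!r}")


def _validate_table(table: pd.DataFrame) -> None:
    if LABEL_COLUMN not in table.columns:
        raise ValidationError(f"feature table must contain a {LABEL_COLUMN!r} column")
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    if not feats:
        raise ValidationError("feature table has no feature columns")
    values = table[feats].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("feature table contains non-finite values")


def _to_arff(table: pd.DataFrame) -> str:
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    buf = io.StringIO()
    buf.write("@relation activity_features\n\n")
    for name in feats:
        buf.write(f"@attribute {name} numeric\n")
    buf.write(f"@attribute {LABEL_COLUMN} {{{','.join(ACTIVITY_LABELS)}}}\n")
    buf.write("\n@data\n")
    for _, row in table.iterrows():
        vals = [_FLOAT_FMT % row[c] for c in feats]
        vals.append(str(row[LABEL_COLUMN]))
        buf.write(",".join(vals) + "\n")
    return buf.getvalue()


def read_feature_table(path, format: str | None = None) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`.

    ``format`` defaults to the file extension (.arff -> ARFF, else CSV).
    ARFF parsing is delegated to :mod:`scipy.io.arff`.
    """
    fmt = format or ("arff" if str(path).lower().endswith(".arff") else "csv")
    if fmt == "csv":
        table = pd.read_csv(path)
    elif fmt == "arff":
        from scipy.io import arff as sp_arff

        data, _meta = sp_arff.loadarff(path)
        table = pd.DataFrame(data)
        table[LABEL_COLUMN] = table[LABEL_COLUMN].str.decode("utf-8")
    else:
        raise ValueError(f"unknown feature-table format {fmt!r}")
    _validate_table(table)
    return table
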