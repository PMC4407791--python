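"""Sliding windows and the 30-dimensional statistical feature vector.

The five channels are cut into 1.6 s windows advanced with 50 % overlap
(0.8 s stride), and six statistics — mean, standard deviation, median,
skewness, kurtosis, inter-quartile range — are computed per channel per
window, giving 5 x 6 = 30 features.  Feature names are signal-major,
statistic-minor (``la3a_mean``, ``la3a_std``, ..., ``mag_z_iqr``); the
gyroscope magnitude is exported under its conventional label ``gyr3z``.

Statistic conventions
---------------------
* std uses the n-1 denominator.
* skewness: ``n/((n-1)(n-2)) * sum(((x - mean)/std)^3)`` — the bias-corrected
  sample estimator.
* kurtosis: ``[n(n+1) S4 - 3 S2^2 (n-1)] / [(n-1)(n-2)(n-3) std^4]`` with
  ``Sk = sum((x - mean)^k)`` — algebraically the spreadsheet KURT excess
  kurtosis.
* Degenerate windows (std == 0, e.g. a perfectly static stretch) define
  skewness and kurtosis as 0 so static activity stays classifiable.
* Q1/Q3 use linear interpolation between order statistics (numpy's default,
  the "type 7" rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sensor_io import ActivityAnnotation, LABEL_COLUMN, ValidationError
from .preprocess import SignalSet

__all__ = [
    "SIGNAL_NAMES",
    "STAT_NAMES",
    "FEATURE_NAMES",
    "DEFAULT_WINDOW_S",
    "DEFAULT_OVERLAP",
    "Window",
    "slide_windows",
    "skewness",
    "kurtosis",
    "iqr",
    "extract_features",
    "extract_feature_table",
]

#: Channel names in export order (gyroscope magnitude under its field label).
SIGNAL_NAMES = ("la3a", "gyr3z", "mag_x", "mag_y", "mag_z")
STAT_NAMES = ("mean", "std", "median", "skew", "kurt", "iqr")
#: The fixed 30-name feature order: signal-major, statistic-minor.
FEATURE_NAMES = tuple(f"{s}_{st}" for s in SIGNAL_NAMES for st in STAT_NAMES)

DEFAULT_WINDOW_S = 1.6
DEFAULT_OVERLAP = 0.5

_EPS = 1e-9


@dataclass
class Window:
    """One window: aligned slices of the five channels plus an optional label."""

    start_s: float
    n: int
    channels: dict[str, np.ndarray]
    label: str | None = None

    def __post_init__(self) -> None:
        for name, x in self.channels.items():
            if len(x) != self.n:
                raise ValidationError(f"channel {name} has length {len(x)} != {self.n}")


def _signal_channels(signals: SignalSet) -> dict[str, np.ndarray]:
    return {
        "la3a": signals.la3a,
        "gyr3z": signals.gyr3a,
        "mag_x": signals.mag_x,
        "mag_y": signals.mag_y,
        "mag_z": signals.mag_z,
    }


def slide_windows(
    signals: SignalSet,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    annotations: list[ActivityAnnotation] | None = None,
) -> list[Window]:
    """Cut the signal set into overlapping windows.

    The stride is ``window_s * (1 - overlap)``; with the defaults, 0.8 s.
    Before label filtering the window count is ``floor((N - n)/stride) + 1``.
    When ``annotations`` is given, each window is labelled by the annotation
    containing it entirely (half-open intervals); windows spanning an
    annotation boundary or falling in a gap are dropped.  Without
    annotations, all windows are returned unlabeled.
    """
    rate = signals.rate_hz
    n_f = window_s * rate
    n = round(n_f)
    if abs(n_f - n) > 1e-6 or n < 4:
        raise ValidationError(
            f"window of {window_s} s at {rate} Hz must be an integer >= 4 samples"
        )
    if not 0 <= overlap < 1:
        raise ValidationError("overlap must be in [0, 1)")
    stride = round(n * (1 - overlap))
    if stride < 1:
        raise ValidationError("overlap too large: stride below one sample")

    chans = _signal_channels(signals)
    N = len(signals)
    if N < n:
        return []
    windows: list[Window] = []
    for i0 in range(0, N - n + 1, stride):
        start_s = float(signals.t[i0])
        end_s = start_s + window_s
        label = None
        if annotations is not None:
            label = _covering_label(annotations, start_s, end_s)
            if label is None:
                continue
        windows.append(
            Window(
                start_s=start_s,
                n=n,
                channels={k: v[i0 : i0 + n] for k, v in chans.items()},
                label=label,
            )
        )
    return windows


def _covering_label(
    annotations: list[ActivityAnnotation], start_s: float, end_s: float
) -> str | None:
    for a in annotations:
        if a.start_s <= start_s + _EPS and end_s <= a.end_s + _EPS:
            return a.label
    return None


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------


def _std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def skewness(x) -> float:
    """Bias-corrected sample skewness; 0 for a degenerate (constant) window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("skewness needs n >= 3")
    s = _std(x)
    if s == 0.0:
        return 0.0
    d = x - x.mean()
    return n / ((n - 1) * (n - 2)) * float(np.sum((d / s) ** 3))


def kurtosis(x) -> float:
    """Bias-corrected sample excess kurtosis; 0 for a degenerate window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("kurtosis needs n >= 4")
    s = _std(x)
    if s == 0.0:
        return 0.0
    d = x - x.mean()
    s2 = float(np.sum(d**2))
    s4 = float(np.sum(d**4))
    return (n * (n + 1) * s4 - 3 * s2**2 * (n - 1)) / (
        (n - 1) * (n - 2) * (n - 3) * s**4
    )


def iqr(x) -> float:
    """Inter-quartile range Q3 - Q1 with linearly interpolated percentiles."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValidationError("iqr needs n >= 4")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


_STAT_FUNCS = {
    "mean": lambda x: float(np.mean(x)),
    "std": _std,
    "median": lambda x: float(np.median(x)),
    "skew": skewness,
    "kurt": kurtosis,
    "iqr": iqr,
}


def extract_features(window: Window) -> dict[str, float | str | None]:
    """The 30 statistics of one window, in the fixed name order, plus label.

    Raises if any statistic comes out non-finite, naming the offending
    feature.
    """
    out: dict[str, float | str | None] = {}
    for sig in SIGNAL_NAMES:
        x = window.channels[sig]
        for stat in STAT_NAMES:
            v = _STAT_FUNCS[stat](x)
            if not math.isfinite(v):
                raise ValidationError(f"feature {sig}_{stat} is non-finite")
            out[f"{sig}_{stat}"] = v
    out[LABEL_COLUMN] = window.label
    return out


def extract_feature_table(windows: list[Window]) -> pd.DataFrame:
    """Feature rows for a batch of windows, columns in the fixed order."""
    rows = [extract_features(w) for w in windows]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + [LABEL_COLUMN])
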