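"""In-pocket detection from the phone's context sensors.

A phone is treated as pocket-carried when the ambient light level is below a
threshold (default 100 lux, roughly the luminance under a cloudy sky — darker
readings mean the sensor is covered), the proximity sensor reports an object
at near range (the pocket fabric), and no call is in progress.  The call-state
override exists because a phone held to the ear at night also shows low light
and near proximity; an active call therefore forces out-of-pocket.

The lux comparison is strict: a reading exactly at the threshold is
out-of-pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sensor_io import ContextTrace

__all__ = [
    "IN_POCKET",
    "OUT_OF_POCKET",
    "PocketRuleConfig",
    "classify_pocket_state",
    "segment_in_pocket",
]

IN_POCKET = "in_pocket"
OUT_OF_POCKET = "out_of_pocket"


@dataclass(frozen=True)
class PocketRuleConfig:
    """Thresholds and switches of the in-pocket rule.

    Attributes
    ----------
    lux_threshold
        Light level (lux) below which the sensor is considered covered.
    require_near
        Require the proximity sensor to report ``near``.
    call_overrides
        An in-progress call forces ``out_of_pocket`` regardless of light and
        proximity.
    """

    lux_threshold: float = 100.0
    require_near: bool = True
    call_overrides: bool = True

    def __post_init__(self) -> None:
        if not self.lux_threshold > 0:
            raise ValueError("lux_threshold must be > 0")


def classify_pocket_state(
    lux: float,
    proximity: str,
    call_state: str,
    cfg: PocketRuleConfig | None = None,
) -> str:
    """Classify one context sample as ``in_pocket`` or ``out_of_pocket``.

    Total and deterministic: in-pocket iff ``lux < lux_threshold`` (strict),
    proximity is ``near`` (when required), and the phone is idle (when the
    call override is enabled).
    """
    cfg = cfg or PocketRuleConfig()
    if lux >= cfg.lux_threshold:
        return OUT_OF_POCKET
    if cfg.require_near and proximity != "near":
        return OUT_OF_POCKET
    if cfg.call_overrides and call_state != "idle":
        return OUT_OF_POCKET
    return IN_POCKET


def classify_context(
    context: ContextTrace, cfg: PocketRuleConfig | None = None
) -> list[str]:
    """Per-sample pocket states for a whole context trace."""
    return [
        classify_pocket_state(
            context.lux[i], context.proximity[i], context.call_state[i], cfg
        )
        for i in range(len(context))
    ]


def segment_in_pocket(
    context: ContextTrace, cfg: PocketRuleConfig | None = None
) -> list[tuple[float, float]]:
    """Maximal half-open in-pocket intervals of a context trace.

    The state is held piecewise-constant from each sample until the next, so
    a run of in-pocket samples from t_i through t_j maps to the interval
    [t_i, t_of_first_out_sample) — or [t_i, t_last) for a trailing run.
    Zero-length intervals (a lone in-pocket sample at the final timestamp)
    are dropped.
    """
    n = len(context)
    if n == 0:
        return []
    states = classify_context(context, cfg)
    t = context.t
    intervals: list[tuple[float, float]] = []
    start: float | None = None
    for i in range(n):
        if states[i] == IN_POCKET and start is None:
            start = float(t[i])
        elif states[i] == OUT_OF_POCKET and start is not None:
            intervals.append((start, float(t[i])))
            start = None
    if start is not None and start < t[-1]:
        intervals.append((start, float(t[-1])))
    return intervals
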