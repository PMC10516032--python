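"""Hill-response mathematics for behavior rules.

A single rule maps a signal ``s`` to a behavior parameter through a
saturating response ``R(s)`` in [0, 1]::

    b(s) = b0 + (bM - b0) * R(s)

Multiple rules acting on the same behavior are combined by pooling the
up-regulating signals into a total up-response ``U`` and the
down-regulating signals into a total down-response ``D`` (each a
multivariate Hill function), and interpolating bilinearly::

    b(u, d) = (1 - D) * ((1 - U) * b0 + U * bM) + D * bm

so that with no signal the behavior sits at its base value ``b0``, fully
up-regulated it reaches ``bM``, and the down-response overrides the
up-response toward ``bm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .grammar import BehaviorRuleGroup

__all__ = [
    "SignalVector",
    "ResponseValue",
    "hill",
    "linear_response",
    "multivariate_hill",
    "combined_behavior",
    "evaluate_behavior",
]

# Largest value a single Hill term may take; beyond this the pooled
# response is 1 to double precision, and capping avoids inf/inf.
_TERM_CAP = 1e15


class SignalVector(dict):
    """Named map from signal token to its current (non-negative) value.

    A missing signal reads as 0, i.e. "no signal".
    """

    def __missing__(self, key: str) -> float:
        return 0.0

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "SignalVector":
        return cls(mapping)


@dataclass(frozen=True)
class ResponseValue:
    """Evaluated response: pooled up/down responses and the behavior value."""

    U: float
    D: float
    b: float


def _hill_term(s, half_max: float, power: float):
    """(s/s*)^p computed without overflow for large powers.

    For s/s* > 1 the power is taken in log space and capped, so printed
    powers up to ~10 (and far beyond) stay finite.
    """
    x = np.asarray(s, dtype=float) / half_max
    with np.errstate(over="ignore", divide="ignore"):
        out = np.where(
            x > 1.0,
            np.exp(np.minimum(power * np.log(np.maximum(x, 1e-300)), np.log(_TERM_CAP))),
            x**power,
        )
    return np.minimum(out, _TERM_CAP)


def hill(s, half_max: float, power: float):
    """Sigmoidal response (s/s*)^p / (1 + (s/s*)^p), in [0, 1].

    Parameters
    ----------
    s : float or ndarray
        Signal value(s), >= 0.
    half_max : float
        Signal value at which the response is 0.5. Must be > 0.
    power : float
        Hill coefficient, > 0. Larger powers sharpen the switch.
    """
    if half_max <= 0:
        raise ValueError(f"half_max must be > 0, got {half_max}")
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("signal value must be >= 0")
    t = _hill_term(s_arr, half_max, power)
    out = t / (1.0 + t)
    return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out

def linear_response(s, half_max: float):
    """Capped linear response clamp(s / (2*half_max), 0, 1).

    Anchored so the response is 0.5 at the half-max, 0 at no signal, and
    saturates at 1 for s >= 2*half_max.
    """
    if half_max <= 0:
        raise ValueError(f"half_max must be > 0, got {half_max}")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("signal value must be >= 0")
    out = np.clip(s_arr / (2.0 * half_max), 0.0, 1.0)
    return float(out) if np.isscalar(s) or s_arr.ndim == 0 else out


def _response_term(s, half_max: float, power: float, shape: str):
    """One signal's additive term in the pooled response sum."""
    if shape == "hill":
        return _hill_term(s, half_max, power)
    if shape == "linear":
        # Choose the term so that a single linear signal pools to the
        # capped linear response: t/(1+t) == r  =>  t = r/(1-r).
        r = linear_response(s, half_max)
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore"):
            t = np.where(r < 1.0, r / np.maximum(1.0 - r, 1e-300), _TERM_CAP)
        return np.minimum(t, _TERM_CAP)
    raise ValueError(f"unknown response shape {shape!r}")


def multivariate_hill(values, half_maxes, powers, shapes=None):
    """Pooled response of several signals: sum of terms / (1 + sum).

    Reduces to :func:`hill` for a single signal and to 0 for no signals.
    ``shapes`` optionally gives a per-signal response shape ("hill" or
    "linear"); default all-Hill.
    """
    if not (len(values) == len(half_maxes) == len(powers)):
        raise ValueError(
            f"length mismatch: {len(values)} values, {len(half_maxes)} "
            f"half-maxes, {len(powers)} powers"
        )
    if shapes is None:
        shapes = ["hill"] * len(values)
    elif len(shapes) != len(values):
        raise ValueError("shapes length must match values")
    if len(values) == 0:
        return 0.0
    total = 0.0
    for s, h, p, shape in zip(values, half_maxes, powers, shapes):
        total = total + _response_term(s, h, p, shape)
    out = total / (1.0 + total)
    return float(out) if np.ndim(out) == 0 else out


def combined_behavior(U, D, b0: float, bM: float, bm: float):
    """Bilinear combination of the pooled up/down responses.

    (1-D) * ((1-U)*b0 + U*bM) + D*bm — at U=D=0 the base value, at U=1
    (D=0) the maximum, and at D=1 the minimum regardless of U.
    """
    return (1.0 - D) * ((1.0 - U) * b0 + U * bM) + D * bm


def evaluate_behavior(group: "BehaviorRuleGroup", signals: Mapping[str, float],
                      dead: bool = False) -> ResponseValue:
    """Evaluate one behavior's rule group against a signal vector.

    Signals missing from the vector read as 0. When ``dead`` is true only
    rules flagged ``applies_to_dead`` contribute; all other terms are 0.
    """
    if not isinstance(signals, SignalVector):
        signals = SignalVector(signals)

    def pooled(entries):
        total = 0.0
        for e in entries:
            if dead and not e.applies_to_dead:
                continue
            total += float(_response_term(signals[e.signal], e.half_max,
                                          e.hill_power, e.response_shape))
        return total / (1.0 + total)

    U = pooled(group.up_signals)
    D = pooled(group.down_signals)
    b = combined_behavior(U, D, group.base_value, group.max_value, group.min_value)
    return ResponseValue(U=U, D=D, b=float(b))
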