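"""Additive-baseline test for joint effector stimulation.

Whether two effectors (here Smaug and Cup) stimulate deadenylation more
than additively is judged against the additive prediction built from the
single-effector product-accumulation curves:

    P_add(t) = clip(P_smaug(t) + P_cup(t) - P_none(t), 0, 1)

The cooperativity score is the mean excess of the measured combined curve
over this prediction; a positive score indicates more-than-additive
(cooperative) stimulation.
"""

from __future__ import annotations

import numpy as np

from .types import Curve, InvalidInputError

__all__ = ["additive_prediction", "cooperativity_score"]


def _check_curve(c: Curve) -> Curve:
    t = np.asarray(c.times, dtype=float)
    v = np.asarray(c.values, dtype=float)
    if t.size != v.size or t.size == 0:
        raise InvalidInputError("curve must be non-empty with matching grids")
    if np.any(v < -1e-9) or np.any(v > 1.0 + 1e-9):
        raise InvalidInputError("curve values must lie in [0, 1]")
    return Curve(t, v)


def _common_grid(*curves: Curve) -> np.ndarray:
    grid = curves[0].times
    for c in curves[1:]:
        if c.times.shape != grid.shape or not np.array_equal(c.times, grid):
            raise InvalidInputError("curves must share a common time grid")
    return grid


def additive_prediction(p_smaug: Curve, p_cup: Curve, p_none: Curve) -> Curve:
    """Product accumulation predicted by purely additive effector behaviour."""
    p_smaug, p_cup, p_none = (_check_curve(c) for c in (p_smaug, p_cup, p_none))
    grid = _common_grid(p_smaug, p_cup, p_none)
    vals = np.clip(p_smaug.values + p_cup.values - p_none.values, 0.0, 1.0)
    return Curve(grid.copy(), vals)


def cooperativity_score(p_both: Curve, p_add: Curve) -> float:
    """Mean excess of the combined curve over the additive prediction.

    Positive: more than additive (cooperativity); zero when the combined
    curve is itself the additive construction; bounded below by -1.
    """
    p_both, p_add = _check_curve(p_both), _check_curve(p_add)
    _common_grid(p_both, p_add)
    return float(np.mean(p_both.values - p_add.values))
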