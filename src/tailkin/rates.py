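"""Rate quantification from deadenylation time courses.

Two estimators mirror standard gel-based quantification: the deadenylation
rate in nt/min is the (negated) least-squares slope of the modal tail
length over time, restricted to the decreasing segment before the tail is
gone; the end-product accumulation rate in nM/min is the slope of
(fraction deadenylated x total concentration) over the post-lag linear
segment.  Burst-phase experiments are fitted with a single exponential plus
a linear steady-state term, P(t) = A*(1 - exp(-k*t)) + v*t.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = [
    "deadenylation_rate",
    "modal_slope_fit",
    "endproduct_rate",
    "burst_fit",
    "relative_specific_activity",
]


def modal_slope_fit(times_min, modal_lengths, stop_below: float = 5.0):
    """Least-squares fit of modal tail length vs time.

    The fit window runs from t = 0 up to (excluding) the first time point at
    which the modal length drops below ``stop_below`` nt: once the modal
    band merges with the accumulating end product the mode jumps to zero
    and no longer reports the shortening of the substrate band.

    Returns ``(rate_nt_per_min, r_squared, n_used)`` with the rate as the
    negated slope.
    """
    t = np.asarray(times_min, dtype=float)
    m = np.asarray(modal_lengths, dtype=float)
    if t.size != m.size:
        raise InvalidInputError("times and modal lengths must be equal length")
    below = np.nonzero(m < stop_below)[0]
    end = int(below[0]) if below.size else m.size
    t, m = t[:end], m[:end]
    if t.size < 3:
        raise InsufficientDataError(
            f"need >= 3 usable points for a slope, got {t.size}")
    if np.all(m == m[0]):
        return 0.0, 1.0, int(t.size)
    slope, intercept = np.polyfit(t, m, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((m - pred) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return -float(slope), r2, int(t.size)


def deadenylation_rate(times_min, modal_lengths) -> float:
    """Deadenylation rate in nt/min from a modal-tail-length time series."""
    rate, _, _ = modal_slope_fit(times_min, modal_lengths)
    return rate


def endproduct_rate(times_min, fractions, conc_total: float,
                    alpha: float = 0.02, plateau: float = 0.98) -> float:
    """End-product accumulation rate in nM/min.

    The fit segment starts at the last point still below the detection
    threshold ``alpha`` (so the lag phase is excluded) and ends at the first
    point reaching the ``plateau`` fraction (so the exhausted-substrate
    plateau does not flatten the slope).  If the threshold is never crossed
    the slope over the whole series is returned (zero for flat data).
    """
    t = np.asarray(times_min, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size != f.size:
        raise InvalidInputError("times and fractions must be equal length")
    if t.size < 3:
        raise InsufficientDataError("need >= 3 points")
    above = np.nonzero(f >= alpha)[0]
    if above.size == 0:
        i0, i1 = 0, t.size - 1
    else:
        first = int(above[0])
        i0 = first - 1 if first > 0 else 0
        high = np.nonzero(f >= plateau)[0]
        i1 = int(high[0]) if high.size else t.size - 1
        # widen degenerate windows so a slope is defined
        while i1 - i0 + 1 < 3 and (i0 > 0 or i1 < t.size - 1):
            if i0 > 0:
                i0 -= 1
            elif i1 < t.size - 1:
                i1 += 1
    seg_t, seg_p = t[i0:i1 + 1], f[i0:i1 + 1] * conc_total
    slope = np.polyfit(seg_t, seg_p, 1)[0]
    return float(slope)


def _burst_model(t, A, k, v):
    return A * (1.0 - np.exp(-k * t)) + v * t


def burst_fit(times, product_nM):
    """Fit biphasic product accumulation P(t) = A*(1-exp(-k t)) + v*t.

    A is the burst amplitude (nM), k the burst rate constant and v the slow
    steady-state rate; A >= 0, k > 0, v >= 0 are enforced as bounds.
    Returns (A, k, v); raises FitFailureError with diagnostics when the
    optimizer does not converge.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(product_nM, dtype=float)
    if t.size != p.size:
        raise InvalidInputError("times and product must be equal length")
    if t.size < 5:
        raise InsufficientDataError("need >= 5 points spanning both phases")
    # crude initial guesses: late slope for v, early excess for A
    half = max(t.size // 2, 2)
    v0 = max(float(np.polyfit(t[half:], p[half:], 1)[0]), 0.0)
    a0 = max(float(np.max(p - v0 * t)), 1e-6)
    t_pos = t[t > 0]
    k0 = 2.0 / float(t_pos[0]) if t_pos.size else 1.0
    try:
        popt, _ = curve_fit(
            _burst_model, t, p, p0=(a0, k0, v0),
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            f"burst fit failed: {exc}; p0=({a0:.4g}, {k0:.4g}, {v0:.4g}), "
            f"n={t.size}, range=({p.min():.4g}, {p.max():.4g})") from exc
    A, k, v = (float(x) for x in popt)
    return A, k, v


def relative_specific_activity(conc_reference: float, conc_test: float) -> float:
    """Specific activity of a test enzyme relative to a reference.

    Computed from the concentrations at which the two preparations show
    equal activity: if 250 nM of a heterodimer matches 5 nM of the full
    complex, the heterodimer's specific activity is 5/250 = 2%.
    Returns a fraction.
    """
    if conc_reference <= 0 or conc_test <= 0:
        raise InvalidInputError("concentrations must be > 0")
    return conc_reference / conc_test
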