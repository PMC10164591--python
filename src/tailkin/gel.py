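"""Denaturing-gel lane emulation and per-lane quantification.

A population snapshot is rendered as a densitometry trace: every molecule of
total length L (body + remaining tail) contributes a Gaussian band centred
at the migration position ``pos(L) = a - b*log10(L)``, with a band width
that grows with length (``sigma(L) = c0 + c1*L`` nucleotides, converted to
position units through the local slope of the length map).  Total intensity
is conserved before noise: each band integrates to one molecule times a
fixed gain.

The quantification operations mirror the analysis applied to real lanes:
the modal tail length (most intense band, ties resolved to the longest
length), the fraction of fully deadenylated product, and the first time at
which that product becomes detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    Curve,
    InvalidInputError,
    PopulationState,
    UndefinedModeError,
)

__all__ = [
    "NoiseSpec",
    "LaneProfile",
    "lane_profile",
    "modal_tail_length",
    "fraction_fully_deadenylated",
    "first_appearance_time",
    "DEFAULT_SIGMA_MODEL",
]

#: band-width model sigma(L) = c0 + c1*L in nucleotides
DEFAULT_SIGMA_MODEL = (1.5, 0.03)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive constant background plus Gaussian multiplicative noise."""

    background: float = 0.0
    multiplicative_sd: float = 0.0

    def __post_init__(self):
        if self.background < 0 or self.multiplicative_sd < 0:
            raise InvalidInputError("noise levels must be >= 0")


@dataclass
class LaneProfile:
    """Densitometry trace of one gel lane.

    ``length_map`` holds the coefficients (a, b) of the migration model
    ``pos(L) = a - b*log10(L)``; larger molecules migrate less (smaller
    position values sit at the top of the lane).
    """

    positions: np.ndarray
    intensities: np.ndarray
    length_map: tuple
    meta: dict = field(default_factory=dict)

    def position_of(self, length: float) -> float:
        a, b = self.length_map
        return a - b * math.log10(length)

    def length_of(self, position: float) -> float:
        a, b = self.length_map
        return 10.0 ** ((a - position) / b)


def lane_profile(state: PopulationState, sigma_model=DEFAULT_SIGMA_MODEL,
                 noise: NoiseSpec | None = None, *, body_length: int,
                 length_map: tuple = (100.0, 40.0), gain: float = 1.0,
                 grid_step: float = 0.05, rng=None) -> LaneProfile:
    """Render a population snapshot as a gel-lane intensity trace."""
    tails = np.asarray(state.tail_lengths)
    if tails.size < 1:
        raise InvalidInputError("population must contain at least one molecule")
    a, b = length_map
    if b <= 0:
        raise ConfigError("length_map must be strictly monotone (b > 0)")
    c0, c1 = sigma_model

    lengths = body_length + tails
    lmin, lmax = int(lengths.min()), int(lengths.max())

    def sig_pos(L: float) -> float:
        return (c0 + c1 * L) * b / (L * _LN10)

    p_hi = a - b * math.log10(lmin) + 5.0 * sig_pos(lmin)
    p_lo = a - b * math.log10(lmax) - 5.0 * sig_pos(lmax)
    positions = np.arange(p_lo, p_hi + grid_step, grid_step)

    intensities = np.zeros_like(positions)
    counts = np.bincount(lengths)
    for L in np.nonzero(counts)[0]:
        n = counts[L]
        center = a - b * math.log10(L)
        s = sig_pos(float(L))
        band = np.exp(-0.5 * ((positions - center) / s) ** 2)
        intensities += band * (n * gain / band.sum())

    if noise is not None and (noise.background > 0 or noise.multiplicative_sd > 0):
        if rng is None:
            raise InvalidInputError("noise requires an rng")
        if noise.multiplicative_sd > 0:
            factor = 1.0 + noise.multiplicative_sd * rng.standard_normal(intensities.size)
            intensities = intensities * np.clip(factor, 0.0, None)
        intensities = intensities + noise.background

    return LaneProfile(
        positions=positions,
        intensities=intensities,
        length_map=(a, b),
        meta={"time_s": state.time, "body_length": int(body_length), "gain": gain,
              "n_molecules": int(tails.size)},
    )


def _histogram_mode(lengths: np.ndarray, counts: np.ndarray) -> int:
    best = counts.max()
    if best <= 0:
        raise UndefinedModeError("all-zero histogram has no mode")
    tied = lengths[counts == best]
    return int(tied.max())        # tie-break: longest length


def modal_tail_length(profile_or_histogram, body_length: int | None = None) -> int:
    """Modal poly(A) tail length of a lane or tail-length histogram, in nt.

    For a :class:`LaneProfile`, the most intense position is mapped back to a
    molecule length and the body is subtracted (clipped at zero).  Ties are
    resolved to the longest length.  Histogram inputs may be a pandas Series
    (index = tail length), a ``(lengths, counts)`` pair, a
    :class:`~tailkin.types.PopulationState`, or a 1-D array of per-molecule
    tail lengths.
    """
    p = profile_or_histogram
    if isinstance(p, LaneProfile):
        inten = np.asarray(p.intensities)
        if inten.size == 0 or np.all(inten <= 0):
            raise UndefinedModeError("profile has no intensity")
        # positions ascend => lengths descend; argmax returns the first
        # (smallest-position = longest-length) maximum, the tie-break rule
        idx = int(np.argmax(inten))
        L = p.length_of(float(p.positions[idx]))
        body = p.meta.get("body_length") if body_length is None else body_length
        if body is None:
            raise InvalidInputError("body_length required to convert to tail length")
        return max(int(round(L)) - int(body), 0)
    if isinstance(p, PopulationState):
        tails = np.asarray(p.tail_lengths)
        counts = np.bincount(tails)
        return _histogram_mode(np.arange(counts.size), counts)
    if isinstance(p, pd.Series):
        if p.empty:
            raise UndefinedModeError("empty histogram")
        return _histogram_mode(p.index.to_numpy(), p.to_numpy())
    if isinstance(p, tuple) and len(p) == 2:
        lengths, counts = (np.asarray(x) for x in p)
        return _histogram_mode(lengths, counts)
    tails = np.asarray(p)
    if tails.size == 0:
        raise UndefinedModeError("empty sample")
    counts = np.bincount(tails.astype(np.int64))
    return _histogram_mode(np.arange(counts.size), counts)


def fraction_fully_deadenylated(state_or_profile, window_nt: float = 2.0) -> float:
    """Fraction of the population that has lost its entire tail.

    On raw population states this is the exact fraction of molecules with
    tail length zero; on lane profiles it is the fraction of total intensity
    migrating within ``window_nt`` of the body-only position.
    """
    if window_nt < 0:
        raise InvalidInputError("window_nt must be >= 0")
    p = state_or_profile
    if isinstance(p, PopulationState):
        tails = np.asarray(p.tail_lengths)
        if tails.size == 0:
            return 0.0
        return float(np.mean(tails == 0))
    if isinstance(p, LaneProfile):
        body = p.meta.get("body_length")
        if body is None:
            raise InvalidInputError("profile lacks body_length metadata")
        total = float(np.sum(p.intensities))
        if total <= 0:
            return 0.0
        cutoff = p.position_of(body + window_nt)
        mask = p.positions >= cutoff       # short molecules migrate far
        return float(np.sum(p.intensities[mask]) / total)
    tails = np.asarray(p)
    if tails.size == 0:
        return 0.0
    return float(np.mean(tails == 0))


def first_appearance_time(timecourse, alpha: float = 0.02) -> float | None:
    """Time at which the fully deadenylated product first becomes detectable.

    Linear interpolation of the first upward crossing of
    ``fraction_fully_deadenylated >= alpha``; None if the threshold is never
    reached.  ``timecourse`` is a (times, fractions) pair or Curve.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    times, fracs = (np.asarray(x, dtype=float) for x in timecourse)
    if times.size != fracs.size or times.size == 0:
        raise InvalidInputError("times and fractions must be equal-length, non-empty")
    above = np.nonzero(fracs >= alpha)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    f0, f1 = fracs[i - 1], fracs[i]
    return float(t0 + (alpha - f0) * (t1 - t0) / (f1 - f0))


def timecourse_table(ensemble) -> pd.DataFrame:
    """Standard summary table: time_s, modal_tail_nt, frac_deadenylated."""
    rows = []
    for s in ensemble.states:
        rows.append({
            "time_s": s.time,
            "modal_tail_nt": modal_tail_length(s),
            "frac_deadenylated": fraction_fully_deadenylated(s),
        })
    return pd.DataFrame(rows)


def fraction_curve_from_table(table: pd.DataFrame) -> Curve:
    return Curve(table["time_s"].to_numpy(dtype=float),
                 table["frac_deadenylated"].to_numpy(dtype=float))
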