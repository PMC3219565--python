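"""Melt-curve transformations: normalization, shifting, derivatives, differences.

These are the standard HRM software operations.  Raw dye fluorescence is
rescaled to 0-100 % using linear baselines fitted in a pre-melt and a
post-melt temperature window; curves can then be translated along the
temperature axis so they coincide at a low-fluorescence level (isolating
shape from Tm); the melting temperature is read off the peak of the
smoothed negative derivative -dF/dT; and difference plots subtract a
reference curve pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Window",
    "NormalizedCurve",
    "DerivativeCurve",
    "DifferenceCurve",
    "DegenerateBaselineError",
    "FlatCurveError",
    "LevelNotCrossedError",
    "NoMeltError",
    "WindowError",
    "normalize",
    "auto_windows",
    "temperature_shift",
    "derivative_curve",
    "estimate_tm",
    "estimate_tm_batch",
    "difference_curve",
    "difference_amplitude",
    "transition_width",
]

Window = tuple[float, float]


class DegenerateBaselineError(ValueError):
    """Fitted upper baseline does not exceed the lower baseline everywhere."""


class FlatCurveError(ValueError):
    """Curve has no detectable melt transition."""


class LevelNotCrossedError(ValueError):
    """Curve never crosses the requested fluorescence level."""


class NoMeltError(ValueError):
    """Negative derivative has no positive maximum (nothing melted)."""


class WindowError(ValueError):
    """A baseline window is outside the grid or holds too few acquisitions."""


@dataclass
class NormalizedCurve:
    """Melt curve rescaled to percent fluorescence (100 pre-melt, 0 post-melt)."""

    sample_id: str
    replicate: int
    temperatures_c: np.ndarray
    values: np.ndarray
    pre_window: Window
    post_window: Window
    shift_c: float = 0.0


@dataclass
class DerivativeCurve:
    temperatures_c: np.ndarray
    minus_df_dt: np.ndarray
    smoothing_halfwidth_points: int


@dataclass
class DifferenceCurve:
    temperatures_c: np.ndarray
    delta_values: np.ndarray
    reference_id: str


def _signal(curve) -> np.ndarray:
    return curve.values if hasattr(curve, "values") else curve.fluorescence


def _window_mask(t: np.ndarray, window: Window, min_points: int = 5) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise WindowError(f"window {window} is empty")
    mask = (t >= lo) & (t <= hi)
    n = int(mask.sum())
    if n < min_points:
        raise WindowError(
            f"window {window} holds {n} acquisitions; at least {min_points} required"
        )
    return mask


def normalize(curve, pre_window: Window, post_window: Window) -> NormalizedCurve:
    """Rescale fluorescence to 0-100 % between two fitted linear baselines.

    A straight line is fitted to the signal inside each window
    (``pre_window`` on the high-fluorescence side, ``post_window`` on the
    post-melt side); the normalized value is
    ``100 * (F - lower_fit) / (upper_fit - lower_fit)``.  By least-squares
    construction the mean normalized value is pinned to ~100 inside the
    pre-window and ~0 inside the post-window.
    """
    t = curve.temperatures_c
    f = _signal(curve)
    pre_mask = _window_mask(t, pre_window)
    post_mask = _window_mask(t, post_window)
    upper_fit = np.polyval(np.polyfit(t[pre_mask], f[pre_mask], 1), t)
    lower_fit = np.polyval(np.polyfit(t[post_mask], f[post_mask], 1), t)
    span = upper_fit - lower_fit
    if np.min(span) <= 0:
        raise DegenerateBaselineError(
            "upper baseline fit does not exceed lower baseline fit over the grid "
            "(no melt transition between the windows?)"
        )
    values = 100.0 * (f - lower_fit) / span
    return NormalizedCurve(
        sample_id=curve.sample_id,
        replicate=curve.replicate,
        temperatures_c=t.copy(),
        values=values,
        pre_window=pre_window,
        post_window=post_window,
        shift_c=getattr(curve, "shift_c", 0.0),
    )


def auto_windows(
    curve, margin_low_c: float = 5.0, margin_high_c: float = 3.0
) -> tuple[Window, Window]:
    """Place baseline windows around a coarse Tm from the unsmoothed derivative.

    The pre-melt window is ``[Tm - margin_low - 2, Tm - margin_low]`` and the
    post-melt window ``[Tm + margin_high, Tm + margin_high + 2]``, clipped to
    the grid.  The coarse Tm comes from the argmax of a lightly smoothed
    derivative (quarter of the default analysis half-width): window
    placement only needs ~1 degC accuracy, but an unsmoothed argmax can
    land on an acquisition-noise spike.  Raises :class:`FlatCurveError`
    when no transition stands out of the background slope.
    """
    t = curve.temperatures_c
    f = _signal(curve)
    if f.size >= 16:
        h = max(3, min(12, (f.size - 2) // 2))
        dt = _uniform_spacing(t)
        g = -savgol_filter(f, window_length=2 * h + 1, polyorder=2, deriv=1, delta=dt, mode="interp")
    else:
        g = -np.gradient(f, t)
    gmax = float(g.max())
    if np.ptp(f) == 0 or gmax <= 0:
        raise FlatCurveError("curve has no detectable melt transition")
    background = float(np.median(np.abs(g)))
    if gmax < 3.0 * background:
        raise FlatCurveError("no melt transition stands out of the background slope")
    tm_coarse = float(t[int(np.argmax(g))])
    lo, hi = float(t[0]), float(t[-1])
    pre = (max(lo, tm_coarse - margin_low_c - 2.0), min(hi, tm_coarse - margin_low_c))
    post = (max(lo, tm_coarse + margin_high_c), min(hi, tm_coarse + margin_high_c + 2.0))
    for window in (pre, post):
        _window_mask(t, window)  # raises WindowError if clipped too hard
    return pre, post


def _last_downward_crossing(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """Temperature of the last downward crossing of ``level`` (linear interp)."""
    above = v >= level
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        raise LevelNotCrossedError(f"curve never crosses {level} % downward")
    i = int(idx[-1])
    frac = (v[i] - level) / (v[i] - v[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _first_downward_crossing(t: np.ndarray, v: np.ndarray, level: float) -> float:
    above = v >= level
    idx = np.nonzero(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        raise LevelNotCrossedError(f"curve never crosses {level} % downward")
    i = int(idx[0])
    frac = (v[i] - level) / (v[i] - v[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def temperature_shift(
    curves: Sequence[NormalizedCurve],
    reference: NormalizedCurve,
    level_percent: float = 5.0,
) -> list[NormalizedCurve]:
    """Translate curves so they cross ``level_percent`` where the reference does.

    Only the temperature coordinate moves; values are untouched.  Under
    noise a curve may cross the level several times -- the last downward
    crossing is used, which is robust to pre-melt fluctuation.
    """
    ref_t = _last_downward_crossing(
        reference.temperatures_c, reference.values, level_percent
    )
    shifted = []
    for curve in curves:
        own_t = _last_downward_crossing(curve.temperatures_c, curve.values, level_percent)
        shift = ref_t - own_t
        shifted.append(
            NormalizedCurve(
                sample_id=curve.sample_id,
                replicate=curve.replicate,
                temperatures_c=curve.temperatures_c + shift,
                values=curve.values.copy(),
                pre_window=(curve.pre_window[0] + shift, curve.pre_window[1] + shift),
                post_window=(curve.post_window[0] + shift, curve.post_window[1] + shift),
                shift_c=curve.shift_c + shift,
            )
        )
    return shifted


def _uniform_spacing(t: np.ndarray) -> float:
    dt = np.diff(t)
    mean = float(dt.mean())
    if np.max(np.abs(dt - mean)) > 1e-6 * max(abs(mean), 1e-12):
        raise ValueError("derivative computation requires a uniform temperature grid")
    return mean


def derivative_curve(curve, smoothing_halfwidth_points: int = 25) -> DerivativeCurve:
    """Smoothed negative derivative -dF/dT (Savitzky-Golay, quadratic).

    The filter fits a local quadratic in a window of
    ``2 * halfwidth + 1`` points and reads off its slope; boundary points
    use one-sided polynomial fits.  The default half-width of 25 points is
    0.5 degC on the default grid.
    """
    t = curve.temperatures_c
    f = _signal(curve)
    h = int(smoothing_halfwidth_points)
    if h < 1:
        raise ValueError("smoothing_halfwidth_points must be >= 1")
    if f.size < 2 * h + 2:
        raise ValueError(
            f"need at least {2 * h + 2} points for half-width {h}, got {f.size}"
        )
    dt = _uniform_spacing(t)
    d = savgol_filter(f, window_length=2 * h + 1, polyorder=2, deriv=1, delta=dt, mode="interp")
    return DerivativeCurve(t.copy(), -d, h)


def _parabolic_refine(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine a peak position through the vertex of a parabola at i-1, i, i+1."""
    if i <= 0 or i >= y.size - 1:
        return float(t[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not locally concave; keep grid point
        return float(t[i])
    offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
    offset = float(np.clip(offset, -1.0, 1.0))
    return float(t[i] + offset * (t[i + 1] - t[i]))


def estimate_tm(d: DerivativeCurve) -> float:
    """Tm = temperature of the global maximum of -dF/dT.

    Refined by parabolic interpolation through the peak and its two
    neighbours; exact ties resolve toward the lower temperature (first
    maximum on the ascending grid).
    """
    y = d.minus_df_dt
    i = int(np.argmax(y))
    if y[i] <= 0:
        raise NoMeltError("negative derivative has no positive maximum")
    return _parabolic_refine(d.temperatures_c, y, i)


def estimate_tm_batch(
    temperatures_c: np.ndarray,
    fluorescence: np.ndarray,
    smoothing_halfwidth_points: int = 25,
) -> np.ndarray:
    """Vectorized :func:`estimate_tm` for many curves sharing one grid.

    ``fluorescence`` is ``(n_curves, n_points)``.  Used by simulation
    studies that estimate thousands of Tms.
    """
    t = np.asarray(temperatures_c, dtype=float)
    f = np.atleast_2d(np.asarray(fluorescence, dtype=float))
    h = int(smoothing_halfwidth_points)
    dt = _uniform_spacing(t)
    y = -savgol_filter(f, window_length=2 * h + 1, polyorder=2, deriv=1, delta=dt, mode="interp", axis=1)
    i = np.argmax(y, axis=1)
    rows = np.arange(y.shape[0])
    if np.any(y[rows, i] <= 0):
        raise NoMeltError("at least one curve has no positive derivative maximum")
    inner = np.clip(i, 1, y.shape[1] - 2)
    y0, y1, y2 = y[rows, inner - 1], y[rows, inner], y[rows, inner + 1]
    denom = y0 - 2.0 * y1 + y2
    offset = np.where(denom < 0, 0.5 * (y0 - y2) / np.where(denom < 0, denom, 1.0), 0.0)
    offset = np.clip(offset, -1.0, 1.0)
    offset = np.where(i == inner, offset, 0.0)  # no refinement at boundaries
    return t[i] + offset * dt


def difference_curve(curve: NormalizedCurve, reference: NormalizedCurve) -> DifferenceCurve:
    """Pointwise ``curve - reference`` on the reference grid (linear resampling).

    Overhanging ends are dropped; grids that do not overlap raise.
    """
    lo = max(curve.temperatures_c[0], reference.temperatures_c[0])
    hi = min(curve.temperatures_c[-1], reference.temperatures_c[-1])
    if hi <= lo:
        raise ValueError("curve and reference temperature grids do not overlap")
    mask = (reference.temperatures_c >= lo) & (reference.temperatures_c <= hi)
    if int(mask.sum()) < 2:
        raise ValueError("fewer than two overlapping grid points")
    t = reference.temperatures_c[mask]
    resampled = np.interp(t, curve.temperatures_c, curve.values)
    delta = resampled - reference.values[mask]
    return DifferenceCurve(t.copy(), delta, reference.sample_id)


def difference_amplitude(diff: DifferenceCurve) -> float:
    """Signed value of the difference curve at its largest absolute excursion."""
    i = int(np.argmax(np.abs(diff.delta_values)))
    return float(diff.delta_values[i])


def transition_width(curve: NormalizedCurve, hi: float = 90.0, lo: float = 10.0) -> float:
    """Temperature span of the melt transition between two fluorescence levels.

    Last downward crossing of ``lo`` minus first downward crossing of
    ``hi``; positive for a melting curve.  For a single logistic species of
    width ``s`` the 90-10 span is ``s * ln(81)``.
    """
    t_hi = _first_downward_crossing(curve.temperatures_c, curve.values, hi)
    t_lo = _last_downward_crossing(curve.temperatures_c, curve.values, lo)
    return t_lo - t_hi
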