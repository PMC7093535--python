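"""Dirac-point extraction from transfer curves and shift series.

The Dirac point of an ambipolar sweep is located by a moving-average
smooth, a grid argmin, and a local parabola refinement — robust on the
coarse −0.5…1 V sweeps the devices are measured with.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import DiracEstimate, ShiftSeries, TransferCurve


class EdgeMinimumError(ValueError):
    """The current minimum sits at the sweep edge; widen the window."""


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    window = min(window if window % 2 == 1 else window + 1, len(y) | 1)
    pad = window // 2
    padded = np.concatenate([y[pad:0:-1], y, y[-2:-pad - 2:-1]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def extract_dirac_point(curve: TransferCurve, smooth_window: int = 5,
                        fit_halfwidth: float = 0.1) -> DiracEstimate:
    """Locate the Dirac point of an ambipolar transfer curve.

    Moving-average smooth (default 5-point window), grid argmin, then a
    parabola fit over ±``fit_halfwidth`` volts around the argmin.  Ties
    between equal minima resolve to the smallest voltage and are flagged.
    Raises :class:`EdgeMinimumError` when the minimum sits on the sweep
    edge.
    """
    v, i = curve.v_gs, curve.i_ds
    if v.size < 7:
        raise ValueError("need at least 7 sweep points")
    smooth = _moving_average(i, smooth_window)
    i_min = smooth.min()
    minima = np.nonzero(smooth == i_min)[0]
    idx = int(minima[0])
    tie = minima.size > 1
    if idx == 0 or idx == v.size - 1:
        raise EdgeMinimumError(
            f"current minimum at sweep edge V = {v[idx]:.3f} V; "
            "the sweep window does not bracket the Dirac point")

    # index-based window (translation-covariant on a uniform grid)
    step = float(np.median(np.diff(v)))
    n_side = max(int(round(fit_halfwidth / step)), 1)
    window = np.zeros(v.size, dtype=bool)
    window[max(idx - n_side, 0):idx + n_side + 1] = True
    v_d = float(v[idx])
    if window.sum() >= 3:
        a, b, c = np.polyfit(v[window], smooth[window], 2)
        if a > 0:
            vertex = -b / (2.0 * a)
            lo, hi = v[window].min(), v[window].max()
            if lo <= vertex <= hi:
                v_d = float(vertex)
    return DiracEstimate(v_dirac=v_d, i_min=float(i_min),
                         window_used=(float(v[window].min()), float(v[window].max())),
                         tie_flag=tie)


def shift_series(curves: Sequence[TransferCurve], baseline_label: str,
                 smooth_window: int = 5, fit_halfwidth: float = 0.1) -> ShiftSeries:
    """Per-condition Dirac shifts (mV) against a baseline condition.

    Curves sharing a label are replicates and aggregate as mean ± SD; the
    baseline's shift is zero by construction.
    """
    groups: Dict[str, list] = defaultdict(list)
    for curve in curves:
        est = extract_dirac_point(curve, smooth_window, fit_halfwidth)
        groups[curve.label].append(est.v_dirac)
    if baseline_label not in groups:
        raise KeyError(f"baseline condition {baseline_label!r} not present")
    v0 = float(np.mean(groups[baseline_label]))

    conditions, shifts, sds = [], [], []
    for label, vds in groups.items():
        vds = np.asarray(vds)
        conditions.append(label)
        if label == baseline_label:
            shifts.append(0.0)
        else:
            shifts.append(float(np.mean(vds) - v0) * 1e3)
        sds.append(float(np.std(vds, ddof=1)) * 1e3 if vds.size > 1 else 0.0)
    return ShiftSeries(condition=conditions, shift_mV=np.asarray(shifts),
                       uncertainty=np.asarray(sds), baseline=baseline_label)


def ph_sensitivity(series: ShiftSeries) -> tuple:
    """Least-squares Dirac-shift slope vs pH, in mV per pH unit.

    Conditions must parse as numeric pH levels (≥ 3 distinct); returns
    (slope, standard_error).
    """
    try:
        ph = np.asarray([float(c) for c in series.condition])
    except (TypeError, ValueError) as exc:
        raise ValueError("pH sensitivity needs numeric pH conditions") from exc
    if np.unique(ph).size < 3:
        raise ValueError("need at least 3 distinct pH levels")
    fit = stats.linregress(ph, series.shift_mV)
    return float(fit.slope), float(fit.stderr)
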