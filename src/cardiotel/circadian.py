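"""Single-harmonic cosinor rhythm analysis over sliding 27-hour windows.

The model is ``y(t) = M + A cos(2 pi (t - phi) / P)`` with the period P
fixed at 24 h; M is the mesor (rhythm-adjusted mean), A >= 0 the amplitude
(half peak-to-trough) and phi the acrophase, the clock hour of the peak,
wrapped to [0, 24).  The fit is linear least squares in the
``beta_c cos + beta_s sin`` parameterisation, so a noiseless 24 h cosine
is reproduced exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = ["CosinorFit", "cosinor_fit", "sliding_cosinor"]

_TWO_PI = 2.0 * math.pi


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float          # clock hours in [0, 24); NaN when undefined
    period_h: float
    window: tuple               # (start_h, end_h) of the fitted window
    rss: float
    n_points: int
    phase_defined: bool = True


def cosinor_fit(times_h: np.ndarray, values: np.ndarray,
                period_h: float = 24.0, window_h: float = 27.0) -> CosinorFit:
    """Least-squares cosinor fit of one window of epoch-level data.

    ``times_h`` are clock hours (monotonic, may exceed 24 across days).
    Requires at least 8 points spanning at least one full period, and a
    window no shorter than the period.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if window_h < period_h:
        raise AnalysisError("window shorter than the rhythm period")
    if len(t) < 8:
        raise AnalysisError("need at least 8 points for a cosinor fit")
    span = t.max() - t.min()
    if span < period_h * (1.0 - 1e-9):
        raise AnalysisError("points must span at least one full period")
    if span > window_h * (1.0 + 1e-9):
        raise AnalysisError("points exceed the declared window length")
    w = _TWO_PI / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise AnalysisError("rank-deficient cosinor design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, bc, bs = beta
    amp = math.hypot(bc, bs)
    resid = y - X @ beta
    rss = float(resid @ resid)
    scale = max(1.0, float(np.abs(y).max()))
    if amp <= 1e-12 * scale:
        return CosinorFit(mesor=float(m), amplitude=0.0,
                          acrophase_h=math.nan, period_h=period_h,
                          window=(float(t.min()), float(t.max())), rss=rss,
                          n_points=len(t), phase_defined=False)
    phi = math.atan2(bs, bc) * period_h / _TWO_PI % period_h
    return CosinorFit(mesor=float(m), amplitude=float(amp),
                      acrophase_h=float(phi % 24.0), period_h=period_h,
                      window=(float(t.min()), float(t.max())), rss=rss,
                      n_points=len(t))


def sliding_cosinor(times_h: np.ndarray, values: np.ndarray,
                    window_h: float = 27.0, step_h: float = 3.0,
                    period_h: float = 24.0) -> pd.DataFrame:
    """Fit cosinors over sliding windows; returns one row per window."""
    t = np.asarray(times_h, dtype=float)
    rows = []
    start = t.min()
    while start + window_h <= t.max() + 1e-9:
        m = (t >= start) & (t < start + window_h)
        try:
            fit = cosinor_fit(t[m], np.asarray(values)[m], period_h, window_h)
        except AnalysisError:
            start += step_h
            continue
        rows.append({"window_start_h": start, "mesor": fit.mesor,
                     "amplitude": fit.amplitude,
                     "acrophase_h": fit.acrophase_h, "rss": fit.rss,
                     "n_points": fit.n_points})
        start += step_h
    return pd.DataFrame(rows)
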