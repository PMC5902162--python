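"""Orientation tuning, OSI, receptive-field center and the AUC-vs-Δspikes fit.

Orientation statistics live in doubled-angle space (period 180°): with
normalized rates :math:`r_k` at orientations :math:`\\theta_k`,

.. math:: x = \\sum_k r_k \\cos 2\\theta_k,\\qquad y = \\sum_k r_k \\sin 2\\theta_k

the preferred orientation is half the two-argument angle of ``(x, y)`` mapped
to [0, 180), and the orientation selectivity index is the vector strength
:math:`\\sqrt{x^2+y^2} / \\sum_k r_k` (0 = untuned, 1 = responds to a single
orientation).  Both are invariant to uniform scaling of the rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

__all__ = [
    "TuningCurve",
    "tuning_curve",
    "preferred_orientation",
    "osi",
    "rf_center",
    "LinearFit",
    "auc_vs_dspikes_fit",
]


@dataclass
class TuningCurve:
    thetas: np.ndarray  # degrees, e.g. 12 values at 15° steps
    rates: np.ndarray  # max-normalized mean rates
    degenerate: bool = False  # all-zero responses

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.thetas.shape != self.rates.shape:
            raise ValidationError("thetas and rates must have equal length")

    @property
    def xy(self) -> tuple[float, float]:
        ang = np.deg2rad(2.0 * self.thetas)
        return float(np.sum(self.rates * np.cos(ang))), float(np.sum(self.rates * np.sin(ang)))


def tuning_curve(responses: pd.DataFrame, window_ms: float = 330.0) -> TuningCurve:
    """Build one unit's tuning curve from passive-viewing responses.

    ``responses`` has one row per repetition with columns ``orientation_deg``
    and ``count`` (spikes over the analysis window after cortical onset).
    Counts are converted to rates over ``window_ms``, averaged across
    repetitions, then normalized by the maximum across orientations.
    """
    needed = {"orientation_deg", "count"}
    if not needed.issubset(responses.columns):
        raise ValidationError(f"passive responses need columns {sorted(needed)}")
    per_ori = responses.groupby("orientation_deg")["count"].mean().sort_index()
    if per_ori.isna().any() or len(per_ori) == 0:
        raise ValidationError("every orientation needs at least one repetition")
    rates = per_ori.to_numpy(float) / (window_ms / 1000.0)
    peak = rates.max()
    if peak <= 0:
        return TuningCurve(per_ori.index.to_numpy(float), np.zeros_like(rates), degenerate=True)
    return TuningCurve(per_ori.index.to_numpy(float), rates / peak)


def preferred_orientation(curve: TuningCurve) -> float:
    """Vector-average preferred orientation in degrees, in [0, 180)."""
    x, y = curve.xy
    if np.hypot(x, y) < 1e-12:
        raise ValidationError("degenerate tuning: orientation vector is zero")
    angle = 0.5 * np.degrees(np.arctan2(y, x))
    return float(angle % 180.0)


def osi(curve: TuningCurve) -> float:
    """Orientation selectivity index: doubled-angle vector strength in [0, 1]."""
    total = float(curve.rates.sum())
    if total <= 0:
        raise ValidationError("OSI undefined for all-zero rates")
    x, y = curve.xy
    return float(np.hypot(x, y) / total)


def rf_center(
    responses: np.ndarray,
    x_deg: np.ndarray,
    y_deg: np.ndarray,
) -> tuple[float, float]:
    """Center of mass of a receptive-field map, in stimulus-grid degrees.

    ``responses`` is shaped ``(..., ny, nx)``; leading axes (channels and/or
    black/white polarity) are each peak-normalized and then averaged, after
    flooring baseline-subtracted values at zero.
    """
    resp = np.asarray(responses, dtype=float)
    if resp.ndim < 2:
        raise ValidationError("responses must be at least 2-D (ny, nx)")
    resp = np.clip(resp, 0.0, None)
    flat = resp.reshape(-1, resp.shape[-2], resp.shape[-1])
    maps = []
    for m in flat:
        peak = m.max()
        maps.append(m / peak if peak > 0 else m)
    mean_map = np.mean(maps, axis=0)
    total = mean_map.sum()
    if total <= 0:
        raise ValidationError("all-zero receptive-field map")
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    cx = float((mean_map.sum(axis=0) * x_deg).sum() / total)
    cy = float((mean_map.sum(axis=1) * y_deg).sum() / total)
    return cx, cy


@dataclass
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    p_slope_positive: float  # one-sided test that the slope exceeds zero
    n: int


def auc_vs_dspikes_fit(dspikes, auc) -> LinearFit:
    """OLS fit of 80 ms task AUC against the passive Δspike count (90° − 45°).

    Standard errors come from the inverse information matrix (the usual OLS
    parameter covariance under Gaussian errors); R² is the fraction of
    variance explained.  A one-sided p-value for slope > 0 is reported.
    """
    x = np.asarray(dspikes, dtype=float)
    y = np.asarray(auc, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in the predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    t_slope = model.tvalues[1]
    from scipy import stats as _st

    p_one_sided = float(_st.t.sf(t_slope, df=model.df_resid))
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        se_slope=float(model.bse[1]),
        se_intercept=float(model.bse[0]),
        r2=float(model.rsquared),
        p_slope_positive=p_one_sided,
        n=int(x.size),
    )
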