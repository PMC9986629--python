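"""Enzyme characterization fits and comparative bookkeeping.

Michaelis–Menten kinetics (v = Vmax*S/(Km+S)) fitted by nonlinear least
squares on substrate/velocity tables; first-order thermal inactivation
(A(t) = A0*exp(-k t)) fitted on time/activity tables with the half-life
t1/2 = ln2/k; plus delta/fold-change records for wild-type vs mutant
comparisons (e.g. melting-temperature shifts and half-life fold increases).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MmFit",
    "DecayFit",
    "ComparisonRecord",
    "fit_michaelis_menten",
    "fit_decay",
    "compare",
    "catalytic_efficiency",
    "load_xy_table",
]

LN2 = math.log(2.0)


@dataclass
class MmFit:
    """Michaelis–Menten parameters with standard errors and fit diagnostics."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    rss: float
    converged: bool
    identifiable: bool = True

    def predict(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


@dataclass
class DecayFit:
    """First-order inactivation parameters; t_half = ln2 / k."""

    a0: float
    k: float              # min^-1
    t_half: float         # min
    a0_se: float
    k_se: float
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a0 * np.exp(-self.k * t)


@dataclass
class ComparisonRecord:
    """Wild-type vs mutant delta and fold increase for one quantity."""

    quantity: str
    wild: float
    mutant: float
    delta: float
    fold_increase: float   # (mutant - wild) / wild; NaN when wild == 0

    def display(self, precision: int = 1) -> str:
        fold = "" if math.isnan(self.fold_increase) else (
            f", {round(self.fold_increase, precision)}-fold increase"
        )
        return (
            f"{self.quantity}: {round(self.wild, precision)} -> "
            f"{round(self.mutant, precision)} "
            f"(delta {round(self.delta, precision)}{fold})"
        )


def _mm_model(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(substrate, velocity) -> MmFit:
    """Least-squares Michaelis–Menten fit.

    Initialized at Vmax0 = max(v) and Km0 = the substrate level at half-max
    velocity (linearly interpolated); parameters are bounded positive.  A fit
    whose Km collapses to zero (all velocities equal) is flagged
    non-identifiable.
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("substrate and velocity must be matching 1-D sequences")
    if len(s) < 4:
        raise ValueError("need at least 4 data points")
    if len(np.unique(s)) < 2:
        raise ValueError("need at least 2 distinct substrate levels")
    if np.any(v < 0) or np.any(s <= 0):
        raise ValueError("substrate must be positive and velocities non-negative")

    vmax0 = float(v.max())
    half = vmax0 / 2.0
    order = np.argsort(s)
    s_o, v_o = s[order], v[order]
    km0 = float(np.interp(half, v_o, s_o)) if v_o.max() > v_o.min() else float(s_o.mean())
    km0 = max(km0, 1e-6)

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _mm_model, s, v, p0=[vmax0, km0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=1e-8, max_nfev=1500,
            )
    except RuntimeError:
        converged = False
        popt = np.array([vmax0, km0])
        pcov = np.full((2, 2), np.nan)
    vmax, km = (float(x) for x in popt)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    rss = float(np.sum((v - _mm_model(s, vmax, km)) ** 2))
    identifiable = km > 1e-6 and math.isfinite(se[1])
    if not identifiable:
        converged = False
    return MmFit(vmax, km, float(se[0]), float(se[1]), rss, converged, identifiable)


def _decay_model(t, a0, k):
    return a0 * np.exp(-k * t)


def fit_decay(time, activity) -> DecayFit:
    """First-order inactivation fit with a log-linear starting point.

    Non-positive activities are excluded with a warning; flat data (no
    detectable decay) raises an error rather than reporting an infinite
    half-life.
    """
    t = np.asarray(time, dtype=float)
    a = np.asarray(activity, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("time and activity must be matching 1-D sequences")
    if len(np.unique(t)) != len(t) or np.any(t < 0):
        raise ValueError("times must be distinct and non-negative")
    usable = a > 0
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} non-positive activity point(s)",
            stacklevel=2,
        )
    t_u, a_u = t[usable], a[usable]
    if len(t_u) < 3:
        raise ValueError("need at least 3 usable (positive-activity) points")

    slope, intercept = np.polyfit(t_u, np.log(a_u), 1)
    k0 = max(-float(slope), 1e-9)
    a00 = float(np.exp(intercept))
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _decay_model, t_u, a_u, p0=[a00, k0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                xtol=1e-8, max_nfev=1500,
            )
    except RuntimeError:
        converged = False
        popt = np.array([a00, k0])
        pcov = np.full((2, 2), np.nan)
    a0, k = (float(x) for x in popt)
    if k <= 1e-9:
        raise ValueError("no decay detected (rate constant is zero)")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.nan, np.nan])
    rss = float(np.sum((a_u - _decay_model(t_u, a0, k)) ** 2))
    return DecayFit(a0, k, LN2 / k, float(se[0]), float(se[1]), rss, converged)


def compare(wild: float, mutant: float, quantity: str = "") -> ComparisonRecord:
    """Delta (mutant - wild) and fold increase ((mutant - wild) / wild)."""
    delta = mutant - wild
    fold = delta / wild if wild != 0 else float("nan")
    return ComparisonRecord(quantity, wild, mutant, delta, fold)


def catalytic_efficiency(kcat: float, km: float) -> float:
    """kcat / Km (mL mg^-1 s^-1 when kcat is s^-1 and Km mg/mL)."""
    if km <= 0:
        raise ValueError("Km must be positive")
    return kcat / km


def load_xy_table(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Two-column delimited assay table -> (x, y) arrays (header optional)."""
    df = pd.read_csv(io.StringIO(text), sep=r"\s+|\t|,", engine="python",
                     comment="#", header=None)
    # drop a header row if the first row is non-numeric
    df = df.apply(pd.to_numeric, errors="coerce").dropna()
    if df.shape[1] < 2 or len(df) == 0:
        raise ValueError("expected two numeric columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
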