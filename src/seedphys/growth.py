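"""Logistic growth-curve fitting and rapid-accumulation traits for seed weight.

Embryo (or seed) dry weight versus days after anthesis (DAA) follows a
sigmoid.  Fitting the three-parameter logistic

    W(t) = W_a / (1 + exp(-k (t - t_m)))

gives the asymptotic weight W_a (g per 100 embryos/seeds), the rate constant
k (d^-1) and the inflection time t_m (days).  The rapid-accumulation phase is
delimited by the two roots of the third derivative of W,

    DAA1 = t_m - ln(2 + sqrt(3)) / k,    DAA2 = t_m + ln(2 + sqrt(3)) / k,

the interval over which the growth rate stays above ~75% of its peak and in
which the logistic accumulates ~57.7% of W_a.  The peak accumulation rate is
the rate at the inflection, k * W_a / 4, so duration and peak rate satisfy the
identity duration * peak_rate = (ln(2 + sqrt(3)) / 2) * W_a ~= 0.65848 * W_a.

Seed volume is estimated from average seed width W and length L as a cone of
height L on diameter W plus a sphere of diameter W:
V = (1/3) pi (W/2)^2 L + (4/3) pi (W/2)^3.  (Note: a literal half-sphere cap
would carry (2/3) pi; the full-sphere form is the convention adopted here.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import FitFailureError, InvalidInputError

#: ln(2 + sqrt(3)), the half-width of the rapid-accumulation phase in k*t units.
LN_2_PLUS_SQRT3 = math.log(2.0 + math.sqrt(3.0))

#: duration * peak_rate = TRAIT_IDENTITY_COEF * w_asym for every logistic fit.
TRAIT_IDENTITY_COEF = LN_2_PLUS_SQRT3 / 2.0

__all__ = [
    "LN_2_PLUS_SQRT3",
    "TRAIT_IDENTITY_COEF",
    "LogisticFit",
    "RapidAccumulationTraits",
    "logistic",
    "fit_logistic",
    "derive_traits",
    "fit_growth_table",
    "seed_volume",
]


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters and goodness of fit."""

    w_asym: float  # asymptotic weight, g
    k: float  # rate constant, 1/d
    t_m: float  # inflection time, days after anthesis
    r2: float  # 1 - SSE/SST on the raw observations

    def predict(self, t):
        return logistic(np.asarray(t, dtype=float), self.w_asym, self.k, self.t_m)


@dataclass(frozen=True)
class RapidAccumulationTraits:
    """Start/end/duration of the rapid-accumulation phase and its peak rate."""

    daa1: float  # days
    daa2: float  # days
    duration: float  # days
    peak_rate: float  # g / day
    w_asym: float  # g


def logistic(t, w_asym, k, t_m):
    """Three-parameter logistic growth curve."""
    return w_asym / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t_m)))


def _initial_guess(daa: np.ndarray, weight: np.ndarray) -> tuple[float, float, float]:
    """Start values: asymptote above the max, t_m at the steepest observed rise,
    k from a log-linearised slope of w / (w0 - w)."""
    w0 = 1.05 * float(weight.max())
    order = np.argsort(daa, kind="stable")
    d_sorted, w_sorted = daa[order], weight[order]
    # steepest increase between consecutive *distinct* time points
    dd = np.diff(d_sorted)
    keep = dd > 0
    slopes = np.where(keep, np.diff(w_sorted) / np.where(keep, dd, 1.0), -np.inf)
    i = int(np.argmax(slopes)) if len(slopes) else 0
    t_m0 = float((d_sorted[i] + d_sorted[i + 1]) / 2.0) if len(slopes) else float(d_sorted[0])
    # logit-linearisation on interior points
    frac = np.clip(w_sorted / w0, 1e-6, 1 - 1e-6)
    z = np.log(frac / (1.0 - frac))
    slope = np.polyfit(d_sorted, z, 1)[0]
    k0 = float(slope) if slope > 0 else 0.1
    return w0, k0, t_m0


def fit_logistic(daa: Sequence[float], weight: Sequence[float]) -> LogisticFit:
    """Least-squares logistic fit of weight vs days after anthesis.

    Requires >= 4 distinct DAA values and a non-constant weight series.  Uses a
    data-driven start plus up to 5 deterministically jittered restarts before
    declaring failure.

    Raises
    ------
    InvalidInputError
        On degenerate data (too few distinct times, constant weights,
        negative values).
    FitFailureError
        If no restart converges; carries the start values tried.
    """
    daa = np.asarray(daa, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if daa.shape != weight.shape or daa.ndim != 1:
        raise InvalidInputError("daa and weight must be 1-d sequences of equal length")
    if not (np.isfinite(daa).all() and np.isfinite(weight).all()):
        raise InvalidInputError("observations must be finite")
    if (daa < 0).any() or (weight < 0).any():
        raise InvalidInputError("daa and weight must be non-negative")
    if len(np.unique(daa)) < 4:
        raise InvalidInputError("need >= 4 distinct daa values to fit a logistic")
    if np.ptp(weight) == 0:
        raise InvalidInputError("weights are constant; logistic fit is undefined")

    w0, k0, t_m0 = _initial_guess(daa, weight)
    span = float(np.ptp(daa))
    # deterministic multi-start: the data-driven guess then fixed jitters
    jitters = [
        (1.0, 1.0, 0.0),
        (1.3, 0.5, 0.15 * span),
        (1.3, 2.0, -0.15 * span),
        (2.0, 0.25, 0.0),
        (1.1, 4.0, 0.3 * span),
        (3.0, 1.0, -0.3 * span),
    ]
    tried = []
    best = None
    for fw, fk, dt in jitters:
        p0 = (w0 * fw, k0 * fk, t_m0 + dt)
        tried.append(p0)
        try:
            popt, _ = curve_fit(
                logistic,
                daa,
                weight,
                p0=p0,
                bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((weight - logistic(daa, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitFailureError(
            "logistic fit did not converge after bounded restarts",
            diagnostics={"starts_tried": tried, "n_obs": int(len(daa))},
        )
    (w_a, k, t_m), sse = best
    sst = float(np.sum((weight - weight.mean()) ** 2))
    r2 = 1.0 - sse / sst
    return LogisticFit(w_asym=float(w_a), k=float(k), t_m=float(t_m), r2=float(r2))


def derive_traits(fit: LogisticFit) -> RapidAccumulationTraits:
    """Rapid-accumulation traits of a fitted logistic (see module docstring)."""
    if not (fit.k > 0) or not (fit.w_asym > 0):
        raise InvalidInputError("derive_traits requires k > 0 and w_asym > 0")
    half = LN_2_PLUS_SQRT3 / fit.k
    daa1 = fit.t_m - half
    daa2 = fit.t_m + half
    return RapidAccumulationTraits(
        daa1=daa1,
        daa2=daa2,
        duration=daa2 - daa1,
        peak_rate=fit.k * fit.w_asym / 4.0,
        w_asym=fit.w_asym,
    )


def fit_growth_table(
    obs: pd.DataFrame,
    group_cols: Iterable[str] = ("group",),
    daa_col: str = "daa",
    weight_col: str = "weight_g_per_100",
) -> pd.DataFrame:
    """Fit one logistic per group and tabulate its rapid-accumulation traits.

    Returns one row per group with columns daa1, daa2, duration, peak_rate,
    w_asym and r2.  Groups are never pooled.
    """
    group_cols = list(group_cols)
    rows = []
    for key, sub in obs.groupby(group_cols, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        fit = fit_logistic(sub[daa_col].to_numpy(), sub[weight_col].to_numpy())
        tr = derive_traits(fit)
        rows.append(
            dict(zip(group_cols, key))
            | {
                "daa1": tr.daa1,
                "daa2": tr.daa2,
                "duration": tr.duration,
                "peak_rate": tr.peak_rate,
                "w_asym": tr.w_asym,
                "r2": fit.r2,
            }
        )
    return pd.DataFrame(rows)


def seed_volume(width: float, length: float) -> float:
    """Seed volume (mm^3) from average width and length (mm).

    V = (1/3) pi (W/2)^2 L + (4/3) pi (W/2)^3 — a cone of height L plus a
    sphere on the seed width.
    """
    if not (width > 0) or not (length >= 0) or not math.isfinite(width + length):
        raise InvalidInputError("width must be positive and length non-negative")
    r = width / 2.0
    return (math.pi / 3.0) * r * r * length + (4.0 * math.pi / 3.0) * r**3
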