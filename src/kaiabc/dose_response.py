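"""KaiB-free ultrasensitive dose–response and effective Hill coefficients.

With the conformational switch and reset removed (ω = ω1 = 0) the inactive
P2 rung is disconnected and the active P1/P3 subnetwork always settles into
a stationary state — no oscillations.  Steady-state KaiC phosphorylation
versus total KaiA then shows a switch-like (ultrasensitive) response whose
steepness grows with the KaiA-free dephosphorylation rate k1: KaiA-assisted
phosphorylation in P3 and autodephosphorylation in P1 are two antagonistic
near-saturated processes, the classic zero-order ultrasensitivity setup.

Two effective-Hill-number estimators are provided:

* ``ec`` (default): n_eff = ln 81 / ln(EC90/EC10), with EC10/EC90 the KaiA
  doses at 10%/90% of the curve's own dynamic range (monotone
  interpolation on a log-dose axis);
* ``slope``: the maximum local slope of the logit of the normalized
  response against log dose, d ln[z/(1−z)]/d ln A_T — equal to n for an
  exact Hill curve at every dose.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .model import (build_state_space, build_W_at_Af,
                    phosphorylation_fraction)
from .params import ModelParams
from .steady_state import FixedPointError
from scipy.optimize import brentq


@dataclasses.dataclass
class ResponseCurve:
    a_total: np.ndarray            # strictly increasing KaiA doses
    phosphorylation: np.ndarray    # stationary mean phosphorylation
    K_d0: float
    alpha: float
    k1: float
    monotone_increasing: bool = True

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"A_T": self.a_total,
                             "phosphorylation": self.phosphorylation})


def _active_stationary(space, A_f: float) -> np.ndarray:
    """Stationary distribution of the P1/P3 subnetwork at frozen A_f."""
    W = build_W_at_Af(space, A_f)
    idx = np.r_[np.arange(space.p1_slice.start, space.p1_slice.stop),
                np.arange(space.p3_slice.start, space.p3_slice.stop)]
    Wa = W[np.ix_(idx, idx)]
    n = len(idx)
    A = np.vstack([Wa, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    sub = np.clip(sub, 0.0, None)
    sub /= sub.sum()
    p = np.zeros(space.n)
    p[idx] = sub
    return p


def kaiB_free_response(params: ModelParams, a_grid) -> ResponseCurve:
    """Stationary phosphorylation of the P1/P3 subnetwork for each total
    KaiA concentration in ``a_grid`` (ω = ω1 = 0 enforced)."""
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid.ndim != 1 or len(a_grid) < 2 or np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be a strictly increasing sequence")
    if np.any(a_grid < 0):
        raise ValueError("KaiA concentrations must be nonnegative")
    params = params.replace(omega=0.0, omega1=0.0)
    space = build_state_space(params)
    weights = phosphorylation_fraction(space.phi)
    levels = []
    for A_T in a_grid:

        def mismatch(A_f):
            p = _active_stationary(space, A_f)
            return A_f - (A_T - p[space.p3_slice].sum())

        if A_T == 0.0:
            A_f = 0.0
        else:
            lo, hi = 0.0, float(A_T)
            if mismatch(lo) * mismatch(hi) > 0:
                raise FixedPointError(
                    f"no self-consistent free KaiA at A_T = {A_T}")
            A_f = brentq(mismatch, lo, hi, xtol=1e-14, rtol=8.9e-16)
        p = _active_stationary(space, A_f)
        levels.append(float(weights @ p))
    levels = np.array(levels)
    return ResponseCurve(
        a_total=a_grid, phosphorylation=levels,
        K_d0=params.K_d0, alpha=params.alpha, k1=params.k1,
        monotone_increasing=bool(np.all(np.diff(levels) > -1e-9)))


class NoPlateauError(RuntimeError):
    pass


def _normalized(curve: ResponseCurve):
    y = curve.phosphorylation
    x = curve.a_total
    base, top = float(y.min()), float(y.max())
    if top - base <= 0:
        raise NoPlateauError("flat response curve: no dynamic range")
    # saturated means the tail is flat: the end slope, extrapolated over a
    # full decade of dose, must stay within 2% of the dynamic range
    if x[-1] > x[-2] > 0:
        end_slope = (y[-1] - y[-2]) / math.log10(x[-1] / x[-2])
        if abs(end_slope) > 0.02 * (top - base):
            raise NoPlateauError(
                "no plateau: the response has not saturated on the dose "
                f"grid (end slope {end_slope:.3g} per decade)")
    return (y - base) / (top - base)


def hill_coefficient(curve: ResponseCurve, method: str = "ec") -> float:
    """Effective Hill coefficient of a monotone response curve."""
    z = _normalized(curve)
    x = curve.a_total
    if method == "ec":
        def dose_at(level):
            i = int(np.searchsorted(z, level))
            i = min(max(i, 1), len(z) - 1)
            x0, x1 = x[i - 1], x[i]
            z0, z1 = z[i - 1], z[i]
            if z1 == z0:
                return x1
            w = (level - z0) / (z1 - z0)
            return x0 * (x1 / x0) ** w       # interpolate on log-dose
        ec10, ec90 = dose_at(0.10), dose_at(0.90)
        if ec90 <= ec10:
            raise NoPlateauError("degenerate EC10/EC90 on this grid")
        return math.log(81.0) / math.log(ec90 / ec10)
    if method == "slope":
        mask = (z > 0.05) & (z < 0.95) & (x > 0)
        if mask.sum() < 3:
            raise NoPlateauError("too few transition points for the "
                                 "logit-slope estimator")
        logit = np.log(z[mask] / (1.0 - z[mask]))
        lx = np.log(x[mask])
        return float(np.max(np.diff(logit) / np.diff(lx)))
    raise ValueError(f"unknown estimator {method!r}; use 'ec' or 'slope'")


def hill_summary(curve: ResponseCurve) -> dict:
    """Both Hill estimators (the relative-amplification style EC estimate
    and the maximum logit slope) keyed by name."""
    return {"ec": hill_coefficient(curve, "ec"),
            "slope": hill_coefficient(curve, "slope"),
            "K_d0": curve.K_d0, "alpha": curve.alpha, "k1": curve.k1}
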