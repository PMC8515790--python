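"""Linear stability of stationary states: oscillation onset and period.

Perturbations δp around a fixed point p* of dP/dt = W(P)P evolve as
dδp/dt = M δp with M = W(p*) + (∂W/∂A_f)·p* ⊗ ∇A_f — the frozen rate
matrix plus the rank-one free-KaiA feedback term.  M annihilates total
mass (column sums vanish), so one eigenvalue is always 0 (the conservation
mode); the physical spectrum is M restricted to the zero-sum subspace.
Oscillation onset is the crossing of the leading restricted eigenvalue
into the positive real half-plane with nonzero imaginary part, and the
predicted period is 2π/|Im λ_lead| (a Hopf-type instability).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import scipy.linalg

from .model import (build_state_space, build_rate_matrix,
                    kaiA_structure_matrix, free_kaiA_gradient, max_rate)
from .params import ModelParams
from .steady_state import (FixedPoint, FixedPointError, analytic_k1_zero,
                           approx_k1, numeric_fixed_point)

ONSET_TOL = 1e-9   # Re(λ) above this counts as unstable


@dataclasses.dataclass
class StabilityReport:
    fixed_point: FixedPoint
    eigenvalues: np.ndarray        # restricted (non-conservation) spectrum
    leading: complex               # max real part over that spectrum
    oscillating: bool              # Re(leading) > tol and Im ≠ 0
    predicted_period: float        # 2π/|Im(leading)|; nan if Im = 0
    non_oscillatory_instability: bool


@dataclasses.dataclass
class GershgorinDiagnostics:
    centers: np.ndarray
    radii: np.ndarray
    max_positive_protrusion: float
    eigenvalues_in_union: bool


def _linearize(params: ModelParams, p, space=None) -> np.ndarray:
    """Jacobian of the nonlinear right-hand side at an arbitrary state."""
    if space is None:
        space = build_state_space(params)
    p = np.asarray(p, dtype=float)
    W = build_rate_matrix(params, p, space)
    D = kaiA_structure_matrix(space)
    g = free_kaiA_gradient(params, space, p)
    return W + np.outer(D @ p, g)


def linearized_operator(params: ModelParams, fp: FixedPoint) -> np.ndarray:
    """Instability matrix M at a fixed point (residual-checked)."""
    space = build_state_space(params)
    scale = max_rate(space)
    if fp.residual > 1e-8 * scale:
        raise FixedPointError(
            f"fixed-point residual {fp.residual:.3g} exceeds "
            f"1e-8·max-rate = {1e-8 * scale:.3g}")
    return _linearize(params, fp.p, space)


def restricted_spectrum(M: np.ndarray) -> np.ndarray:
    """Eigenvalues of M on the mass-zero subspace (conservation mode
    removed exactly by restriction, not by sorting heuristics)."""
    n = M.shape[0]
    Q = scipy.linalg.null_space(np.ones((1, n)))   # n × (n−1), orthonormal
    return np.linalg.eigvals(Q.T @ M @ Q)


def stability_report(params: ModelParams,
                     fp: Optional[FixedPoint] = None) -> StabilityReport:
    """Assemble the stability report around the (possibly unstable)
    stationary state.

    The expansion point is obtained by Newton iteration seeded with the
    analytic (k1 = 0) or approximate (k1 > 0) ladder construction —
    integration cannot be used because it diverges to the limit cycle
    exactly where the report is most interesting.
    """
    if fp is None:
        guess = None
        try:
            if params.k1 == 0 and params.k1_fwd == 0:
                guess = analytic_k1_zero(params, strict=False).p
            else:
                guess = approx_k1(params).p
        except FixedPointError:
            guess = None
        fp = numeric_fixed_point(params, guess=guess)
    M = linearized_operator(params, fp)
    eig = restricted_spectrum(M)
    lead = eig[np.argmax(eig.real)]
    unstable = lead.real > ONSET_TOL
    has_freq = abs(lead.imag) > 1e-12
    oscillating = bool(unstable and has_freq)
    period = 2 * math.pi / abs(lead.imag) if has_freq else math.nan
    return StabilityReport(
        fixed_point=fp, eigenvalues=eig, leading=lead,
        oscillating=oscillating, predicted_period=period,
        non_oscillatory_instability=bool(unstable and not has_freq))


def critical_parameter(params: ModelParams, which: str,
                       lo: float, hi: float, tol: float = 1e-3) -> float:
    """Bisect for the onset value of one parameter.

    ``tol`` is relative to the bracket scale.  Raises if the oscillating
    flag does not differ between the endpoints.
    """

    def flag(value: float) -> bool:
        return stability_report(params.replace(**{which: value})).oscillating

    f_lo, f_hi = flag(lo), flag(hi)
    if f_lo == f_hi:
        raise ValueError(
            f"no sign change: oscillating({which}={lo}) == "
            f"oscillating({which}={hi}) == {f_lo}")
    scale = max(abs(lo), abs(hi))
    while hi - lo > tol * scale:
        mid = 0.5 * (lo + hi)
        if flag(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gershgorin(matrix: np.ndarray) -> GershgorinDiagnostics:
    """Column Gershgorin discs of a (rate-type) matrix.

    For a generator, each disc is centered at the negative total exit rate
    with radius equal to the off-diagonal column sum, so discs touch the
    origin; feedback terms can push them into the positive half-plane."""
    A = np.asarray(matrix, dtype=float)
    centers = A.diagonal().copy()
    radii = np.abs(A).sum(axis=0) - np.abs(centers)
    eig = np.linalg.eigvals(A)
    in_union = all(
        np.any(np.abs(lam - centers) <= radii * (1 + 1e-12) + 1e-12)
        for lam in eig)
    return GershgorinDiagnostics(
        centers=centers, radii=radii,
        max_positive_protrusion=float((centers + radii).max()),
        eigenvalues_in_union=bool(in_union))
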