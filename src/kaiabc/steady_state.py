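"""Time-independent solutions of the nonlinear master equation.

Three routes to a fixed point W(p*)p* = 0, Σp* = 1:

``analytic_k1_zero``
    Exact closed-form construction in the k1 = 0 limit.  With no P1-ladder
    edges every interior P1(j) is a vertical dead end, so KaiA exchange is
    locally balanced, k_Af·A_f·P1(φ) = k_Ab0·α^(φ−π)·P3(φ), exactly.  The
    stationary network then carries a single circulating current J
    (up the P3 ladder, across the conformational switch, down the P2 ladder,
    through the reset): each ladder profile is the constant-current solution
    (a constant plus a geometric mode), and the reset-closure, normalization
    and free-KaiA self-consistency conditions determine the three remaining
    scalars (P3(0) ≡ b, J, A_f).  Eliminating A_f reduces the closure to a
    scalar root problem (quadratic in b), solved here by bracketing.

``approx_k1``
    The k1 ≠ 0 generalization obtained by *assuming* the same vertical
    balance along the P1–P3 links for φ ≤ φ0 and P1 ≈ P3 ≈ 0 beyond φ0.
    The two parallel rails then collapse into one effective ladder with
    φ-dependent hop rates F_j = k3_fwd + (γ·k1 + k1_fwd)·ρ_j and
    B_j = γ1·k3_fwd + k1·ρ_j, where ρ_j = k_Ab0·α^(φ_j−π)/(k_Af·A_f).
    At k1 = k1_fwd = 0 this reduces exactly to ``analytic_k1_zero``.

``numeric_fixed_point``
    Damped Newton iteration on the full nonlinear system (the reference
    route; independent of the constructions above).

Profiles are propagated from the high-φ anchor downward so that only the
decaying geometric mode is ever multiplied — the (1/γ)^j growing mode of
the forward recurrence would destroy double precision for N ≳ 10.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .model import (StateSpace, build_state_space, build_rate_matrix,
                    build_W_at_Af, free_kaiA, kaiA_structure_matrix,
                    free_kaiA_gradient, max_rate, uniform_state)
from .params import ModelParams


class FixedPointError(RuntimeError):
    """Raised when no stationary solution can be produced."""


@dataclasses.dataclass
class FixedPoint:
    """A stationary occupancy vector with provenance.

    Attributes
    ----------
    p : ndarray
        Normalized occupancies over the StateSpace nodes.
    residual : float
        ‖W(p)·p‖∞ of the returned state.
    method : str
        "analytic" | "analytic-truncated" | "approximate" | "numeric".
    b : float or None
        P3(0) when produced by a ladder construction.
    A_f : float
        Self-consistent free-KaiA level at the fixed point.
    """
    p: np.ndarray
    residual: float
    method: str
    b: Optional[float]
    A_f: float
    params: ModelParams

    @property
    def space(self) -> StateSpace:
        return build_state_space(self.params)

    def to_frame(self):
        """Occupancies as a tidy DataFrame (rung, index, phase, occupancy)."""
        import pandas as pd
        space = self.space
        return pd.DataFrame({
            "rung": [nd[0] for nd in space.nodes],
            "index": [nd[1] for nd in space.nodes],
            "phase": space.phi,
            "occupancy": self.p,
        })


def _residual(params: ModelParams, p, space: StateSpace) -> float:
    return float(np.abs(build_rate_matrix(params, p, space) @ p).max())


# ---------------------------------------------------------------------------
# Ladder construction (shared by the analytic and approximate routes)
# ---------------------------------------------------------------------------

def _construct_at_Af(params: ModelParams, space: StateSpace, A_f: float):
    """Stationary profile of the single-current-loop construction for a
    frozen free-KaiA level.  Returns (p, b, J)."""
    N = params.N
    j0 = params.j0
    a = params.k_Af * A_f
    if a <= 0:
        raise FixedPointError("construction requires k_Af·A_f > 0")
    if params.omega <= 0 or params.omega1 <= 0:
        raise FixedPointError("construction requires omega, omega1 > 0 "
                              "(the oscillation loop must be closed)")
    phi = np.arange(N + 1) * math.pi / N
    rho = params.k_Ab0 * params.alpha ** (phi - math.pi) / a
    f3, b3 = params.k3_fwd, params.gamma1 * params.k3_fwd
    fP1 = params.gamma * params.k1 + params.k1_fwd
    bP1 = params.k1
    f2, b2 = params.k2_fwd, params.gamma2 * params.k2_fwd

    # effective combined-rail hop rates between columns
    F = f3 + fP1 * rho      # out of column j, upward
    B = b3 + bP1 * rho      # out of column j, downward

    # P3(j) = u_j·t + v_j·J with t = P3(j0); backward-stable propagation
    u = np.zeros(j0 + 1)
    v = np.zeros(j0 + 1)
    u[j0] = 1.0
    for j in range(j0 - 1, -1, -1):
        u[j] = B[j + 1] * u[j + 1] / F[j]
        v[j] = (B[j + 1] * v[j + 1] + 1.0) / F[j]

    # P2(k) = c_k·J for k = 2N−j0..2N, anchored at P2(2N) = J/ω1
    n_chain = j0 + 1
    c = np.zeros(n_chain)           # c[m] is P2(2N−j0+m)
    c[-1] = 1.0 / params.omega1
    for m in range(n_chain - 2, -1, -1):
        c[m] = (b2 * c[m + 1] + 1.0) / f2

    # linear coefficients of the two closure equations in (t, J):
    # (A) switch: ρ_{j0}·t − J/a − J/ω − c_0·J = 0
    A_t = rho[j0]
    A_J = -(1.0 / a + 1.0 / params.omega + c[0])
    # (B) normalization: Σ P3 + Σ P1 + Σ P2 = 1
    #   P1(j) = ρ_j P3(j) for 0 < j < j0; P1(0) = ρ_0 P3(0) + J/a;
    #   P1(j0) = ρ_{j0} P3(j0) − J/a
    w = 1.0 + rho[:j0 + 1]          # per-column weight (P3 + P1)
    B_t = float(w @ u)
    B_J = float(w @ v) + (1.0 / a - 1.0 / a) + c.sum()
    # the ± J/a end corrections at columns 0 and j0 cancel in the total mass
    M = np.array([[A_t, A_J], [B_t, B_J]])
    rhs = np.array([0.0, 1.0])
    t, J = np.linalg.solve(M, rhs)

    p3_cols = u * t + v * J
    p1_cols = rho[:j0 + 1] * p3_cols
    p1_cols[0] += J / a
    p1_cols[j0] -= J / a
    p2_chain = c * J

    p = np.zeros(space.n)
    p[space.p3_slice][:j0 + 1] = p3_cols
    p[space.p1_slice][:j0 + 1] = p1_cols
    # P2(2N−j0+m) ↔ chain index m
    p2 = np.zeros(N + 1)
    p2[N - j0:] = p2_chain
    p[space.p2_slice] = p2
    return p, float(p3_cols[0]), float(J)


def _self_consistent_construction(params: ModelParams, space: StateSpace,
                                  method: str) -> FixedPoint:
    """Close the ladder construction with A_f = A_T − ΣP3 − ε_seq·ΣP2."""

    def mismatch(A_f: float) -> float:
        p, _, _ = _construct_at_Af(params, space, A_f)
        bound = p[space.p3_slice].sum()
        seq = params.eps_seq * p[space.p2_slice].sum()
        return A_f - (params.A_T - bound - seq)

    lo = 1e-12 * max(params.A_T, 1.0)
    hi = params.A_T
    flo, fhi = mismatch(lo), mismatch(hi)
    if flo * fhi > 0:
        raise FixedPointError(
            "free-KaiA self-consistency has no root in (0, A_T]: "
            f"g({lo:.3g})={flo:.3g}, g({hi:.3g})={fhi:.3g}")
    A_f = brentq(mismatch, lo, hi, xtol=1e-15, rtol=1e-15)
    p, b, _ = _construct_at_Af(params, space, A_f)
    if p.min() < -1e-10:
        raise FixedPointError(
            f"construction produced negative occupancy {p.min():.3g}")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return FixedPoint(p=p, residual=_residual(params, p, space),
                      method=method, b=b, A_f=A_f, params=params)


def scan_self_consistency(params: ModelParams, n_grid: int = 200):
    """Grid scan of the A_f self-consistency mismatch (diagnostic oracle
    for the bracketed root solve)."""
    space = build_state_space(params)
    grid = np.linspace(1e-6 * params.A_T, params.A_T, n_grid)
    vals = []
    for A_f in grid:
        p, _, _ = _construct_at_Af(params, space, A_f)
        vals.append(A_f - (params.A_T - p[space.p3_slice].sum()
                           - params.eps_seq * p[space.p2_slice].sum()))
    return grid, np.array(vals)


# ---------------------------------------------------------------------------
# Public solvers
# ---------------------------------------------------------------------------

def analytic_k1_zero(params: ModelParams, strict: bool = True) -> FixedPoint:
    """Closed-form stationary solution in the k1 = 0 limit.

    In strict mode requires k1 = 0, k1_fwd = 0, eps_seq = 0 and phi0 = π,
    under which the returned profile is an *exact* fixed point (the vertical
    KaiA-exchange balance holds node by node).  With ``strict=False``,
    phi0 < π is allowed via the truncation P1(j) ≈ P2(2N−j) ≈ P3(j) ≈ 0 for
    j beyond j0 = ceil(N·φ0/π) (method tag "analytic-truncated"), and
    eps_seq > 0 is allowed (it only modifies the scalar free-KaiA closure,
    so exactness at phi0 = π is retained).
    """
    if params.k1 != 0 or params.k1_fwd != 0:
        raise FixedPointError("preconditions violated: analytic solution "
                              f"requires k1 = k1_fwd = 0 (k1={params.k1})")
    truncated = params.phi0 < math.pi - 1e-12
    if strict:
        if params.eps_seq != 0:
            raise FixedPointError("preconditions violated: strict mode "
                                  f"requires eps_seq = 0 (got {params.eps_seq})")
        if truncated:
            raise FixedPointError("preconditions violated: strict mode "
                                  f"requires phi0 = pi (got {params.phi0})")
    space = build_state_space(params)
    method = "analytic-truncated" if truncated else "analytic"
    fp = _self_consistent_construction(params, space, method)
    if not 0.0 < fp.b < 1.0:
        raise FixedPointError(f"no admissible root: P3(0) = {fp.b}")
    return fp


def approx_k1(params: ModelParams) -> FixedPoint:
    """Approximate stationary solution for k1 ≥ 0 under the vertical-balance
    ansatz k_Af·A_f·P1(φ) = k_Ab0·α^(φ−π)·P3(φ) for φ ≤ φ0 (and vanishing
    occupancies beyond φ0).  Exact when k1 = k1_fwd = 0 and phi0 = π."""
    space = build_state_space(params)
    return _self_consistent_construction(params, space, "approximate")


def numeric_fixed_point(params: ModelParams, guess=None,
                        max_iter: int = 200,
                        tol_factor: float = 1e-10) -> FixedPoint:
    """General fixed point by damped Newton iteration on W(p)p = 0, Σp = 1.

    The Newton matrix is the full linearization of the nonlinear right-hand
    side (rate matrix plus the free-KaiA feedback rank-one term) with one
    row replaced by the normalization constraint.  Backtracking halves the
    step until the residual decreases.  If Newton stalls, falls back to
    long-time integration (a fixed point is only reported when the
    trajectory actually converges — oscillatory dynamics raise instead).
    """
    space = build_state_space(params)
    scale = max_rate(space)
    tol = tol_factor * scale
    if guess is None:
        try:
            guess = approx_k1(params).p
        except FixedPointError:
            guess = uniform_state(space)
    p = np.asarray(guess, dtype=float).copy()
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    D = kaiA_structure_matrix(space)

    def rhs(p):
        return build_rate_matrix(params, p, space) @ p

    def newton(p, n_iter):
        res = float(np.abs(rhs(p)).max())
        for _ in range(n_iter):
            if res < tol:
                break
            W = build_rate_matrix(params, p, space)
            g = free_kaiA_gradient(params, space, p)
            M = W + np.outer(D @ p, g)
            F = (W @ p).copy()
            M[0, :] = 1.0
            F[0] = p.sum() - 1.0
            try:
                delta = np.linalg.solve(M, -F)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            improved = False
            for _ in range(40):
                trial = np.clip(p + step * delta, 0.0, None)
                s = trial.sum()
                if s > 0:
                    trial /= s
                    new_res = float(np.abs(rhs(trial)).max())
                    if new_res < res * (1.0 - 1e-4 * step) or new_res < tol:
                        p, res = trial, new_res
                        improved = True
                        break
                step *= 0.5
            if not improved:
                break
        return p, res

    p, res = newton(p, max_iter)
    if res >= tol:
        # fallback: relax toward the attractor by integration, then polish
        from .dynamics import integrate
        traj = integrate(params, p, t_end=3000.0, n_out=600)
        tail = traj.states[-1]
        drift = float(np.abs(traj.states[-1] - traj.states[-30]).max())
        p, res = newton(tail, max_iter)
        if res >= tol:
            raise FixedPointError(
                "no stationary convergence: Newton stalled "
                f"(residual {res:.3g}) and the dynamics do not settle "
                f"(late-time drift {drift:.3g}) — likely oscillatory")
    b = float(p[space.idx_p3(0)])
    return FixedPoint(p=p, residual=res, method="numeric", b=b,
                      A_f=free_kaiA(params, p, space), params=params)


def stationary_at_Af(space: StateSpace, A_f: float) -> np.ndarray:
    """Stationary distribution of the *linear* master equation at a frozen
    free-KaiA level (unique by Perron–Frobenius on the connected network).
    Solved as an augmented least-squares problem [W; 1ᵀ] p = [0; 1]."""
    W = build_W_at_Af(space, A_f)
    n = space.n
    A = np.vstack([W, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()
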