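"""Entropy production of stationary and oscillatory states.

The rate is the standard edge-flux (Schnakenberg) form

    σ̇ = Σ_edges (J₊ − J₋) · ln(J₊ / J₋),   J₊ = k_fwd·p_src, J₋ = k_bwd·p_dst,

in units of k_B per model time.  Every term is nonnegative and vanishes
exactly at detailed balance.  Nominally irreversible edges carry the
``reverse_floor`` rate so that no flux is identically zero; because the
coarse-grained ring lumps many microscopic transitions into each edge,
the total underestimates the entropy production of the full biochemical
network — it is a lower bound, reported as such.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .dynamics import Trajectory, detect_period, NotConvergedError
from .model import StateSpace, build_state_space, free_kaiA, max_rate
from .params import ModelParams
from .steady_state import FixedPoint, FixedPointError

TINY_FLUX = 1e-300


@dataclasses.dataclass
class EntropyReport:
    """Per-edge fluxes and contributions plus the total rate σ̇."""
    forward_flux: np.ndarray
    backward_flux: np.ndarray
    contributions: np.ndarray
    total: float                       # k_B per unit time
    n_zero_flux_edges: int             # both fluxes < 1e−300, contributed 0
    averaging_window: Optional[tuple] = None   # (t_start, t_end) on a cycle


def edge_entropy_terms(J_plus, J_minus) -> np.ndarray:
    """Per-edge entropy production (J₊ − J₋)·ln(J₊/J₋).

    Each term is nonnegative and vanishes iff the edge is in detailed
    balance; pairs with both fluxes below 1e−300 contribute 0 (the
    x·ln x → 0 limit).  A pair with exactly one vanishing flux is an
    infinite-affinity edge and raises.
    """
    J_plus = np.asarray(J_plus, dtype=float)
    J_minus = np.asarray(J_minus, dtype=float)
    both_tiny = (J_plus < TINY_FLUX) & (J_minus < TINY_FLUX)
    one_zero = (J_plus == 0.0) != (J_minus == 0.0)
    if one_zero.any():
        raise ValueError(
            "an edge has exactly one zero flux: entropy production "
            "diverges; set a positive reverse_floor")
    out = np.zeros_like(J_plus)
    live = ~both_tiny
    out[live] = (J_plus[live] - J_minus[live]) * np.log(
        J_plus[live] / J_minus[live])
    return out


def _edge_fluxes(params: ModelParams, space: StateSpace, p):
    # transiently empty states (clipped to exactly 0 by the integrator)
    # would make an edge affinity formally infinite although its flux
    # contribution vanishes; floor them at a negligible occupancy
    p = np.maximum(np.asarray(p, dtype=float), 1e-30)
    A_f = free_kaiA(params, p, space)
    J_plus = np.empty(len(space.edges))
    J_minus = np.empty(len(space.edges))
    for i, e in enumerate(space.edges):
        J_plus[i] = e.forward_rate(A_f) * p[e.src]
        J_minus[i] = e.bwd * p[e.dst]
    return J_plus, J_minus


def entropy_rate_at_state(params: ModelParams, p,
                          space: Optional[StateSpace] = None) -> EntropyReport:
    """Instantaneous σ̇ of an arbitrary occupancy vector."""
    if space is None:
        space = build_state_space(params)
    J_plus, J_minus = _edge_fluxes(params, space, p)
    contrib = edge_entropy_terms(J_plus, J_minus)
    both_tiny = (J_plus < TINY_FLUX) & (J_minus < TINY_FLUX)
    return EntropyReport(
        forward_flux=J_plus, backward_flux=J_minus, contributions=contrib,
        total=float(contrib.sum()), n_zero_flux_edges=int(both_tiny.sum()))


def entropy_production_stationary(params: ModelParams,
                                  fp: FixedPoint) -> EntropyReport:
    """σ̇ of a stationary state (fixed-point residual is checked)."""
    space = build_state_space(params)
    if fp.residual > 1e-8 * max_rate(space):
        raise FixedPointError(
            f"fixed-point residual {fp.residual:.3g} too large for a "
            "stationary entropy rate")
    return entropy_rate_at_state(params, fp.p, space)


def entropy_production_cycle(params: ModelParams,
                             traj: Trajectory,
                             transient_fraction: float = 0.3) -> EntropyReport:
    """Time-averaged σ̇ over an integer number of detected cycles.

    For a trajectory that has settled to a stationary state the average
    reduces to the stationary rate (constant integrand over the tail)."""
    space = build_state_space(params)
    t = traj.times
    summary = detect_period(traj, transient_fraction)
    if summary.oscillating:
        dt = t[1] - t[0]
        n_cycles = min(3, summary.n_cycles)
        n_window = int(round(n_cycles * summary.period / dt))
        sl = slice(len(t) - n_window - 1, len(t))
    else:
        sl = slice(int(0.9 * len(t)), len(t))
    window = (float(t[sl][0]), float(t[sl][-1]))
    rates = np.array([
        entropy_rate_at_state(params, traj.states[i], space).total
        for i in range(len(t))[sl]])
    total = float(np.trapezoid(rates, t[sl]) / (t[sl][-1] - t[sl][0]))
    rep = entropy_rate_at_state(params, traj.states[-1], space)
    return EntropyReport(
        forward_flux=rep.forward_flux, backward_flux=rep.backward_flux,
        contributions=rep.contributions, total=total,
        n_zero_flux_edges=rep.n_zero_flux_edges, averaging_window=window)
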