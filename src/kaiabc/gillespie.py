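"""Finite-copy-number stochastic simulation (direct-method Gillespie).

M KaiC hexamer copies hop on the same node set as the mean-field model,
coupled through a shared discrete KaiA pool: one copy represents a
concentration 1/scale (scale defaults to the copy number, so the total
KaiC concentration is 1 as in the mean-field equations), the pool starts
at round(scale·A_T) units, binding a copy into P3 debits one unit and
switching into P2 debits ε_seq units (tracked as a real-valued debit and
clamped at zero for propensity evaluation, since ε_seq is a mean-field
stoichiometry with no microscopic prescription).  As M → ∞ the empirical
occupancy fractions converge to the solution of the nonlinear master
equation — this module is the independent oracle for that limit.

The event loop is JIT-compiled with numba when available (the KaiA
exchange rates span orders of magnitude, so trajectories involve many
fast binding/unbinding events); a pure-Python loop with identical event
sequence is used otherwise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .dynamics import Trajectory
from .model import StateSpace, build_state_space
from .params import ModelParams

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclasses.dataclass
class EnsembleState:
    """Counts per node, the KaiA pool and the generator seed."""
    counts: np.ndarray         # integer copies per node
    kaiA_pool: float           # free KaiA units (real-valued after debits)
    seed: int

    @property
    def n_copies(self) -> int:
        return int(self.counts.sum())


def _edge_arrays(space: StateSpace):
    E = len(space.edges)
    src = np.empty(E, dtype=np.int64)
    dst = np.empty(E, dtype=np.int64)
    kf = np.empty(E)
    kb = np.empty(E)
    per_af = np.empty(E)
    floor = np.empty(E)
    for i, e in enumerate(space.edges):
        src[i], dst[i] = e.src, e.dst
        kf[i], kb[i], per_af[i] = e.fwd, e.bwd, e.fwd_per_Af
        floor[i] = e.floor
    return src, dst, kf, kb, per_af, floor


@njit(cache=False)
def _run_core(counts, src, dst, kf, kb, per_af, floor, is_p3, is_p2,
              kaiA_units, eps_seq, scale, t_grid, out, seed):  # pragma: no cover
    np.random.seed(seed)
    E = len(src)
    n_out = len(t_grid)
    n_copies = counts.sum()
    bound3 = 0.0
    seq2 = 0.0
    for i in range(len(counts)):
        if is_p3[i]:
            bound3 += counts[i]
        if is_p2[i]:
            seq2 += counts[i]
    prop = np.empty(2 * E)
    t = 0.0
    next_out = 0
    while next_out < n_out:
        pool = kaiA_units - bound3 - eps_seq * seq2
        if pool < 0.0:
            pool = 0.0
        A_f = pool / scale
        total = 0.0
        for i in range(E):
            if per_af[i] > 0.0:
                f = per_af[i] * A_f
                if f < floor[i]:
                    f = floor[i]
            else:
                f = kf[i]
            prop[i] = f * counts[src[i]]
            prop[E + i] = kb[i] * counts[dst[i]]
            total += prop[i] + prop[E + i]
        if total <= 0.0:
            t_next = 1e300
        else:
            t_next = t - math.log(np.random.random()) / total
        while next_out < n_out and t_grid[next_out] <= t_next:
            for i in range(len(counts)):
                out[next_out, i] = counts[i] / n_copies
            next_out += 1
        if next_out >= n_out:
            break
        t = t_next
        r = np.random.random() * total
        acc = 0.0
        k = 2 * E - 1
        for i in range(2 * E):
            acc += prop[i]
            if r < acc:
                k = i
                break
        if k < E:
            s, d = src[k], dst[k]
        else:
            s, d = dst[k - E], src[k - E]
        counts[s] -= 1
        counts[d] += 1
        if counts[s] < 0:
            raise RuntimeError("negative copy count - rate-law bug")
        if is_p3[s]:
            bound3 -= 1.0
        if is_p3[d]:
            bound3 += 1.0
        if is_p2[s]:
            seq2 -= 1.0
        if is_p2[d]:
            seq2 += 1.0
    return counts


def gillespie_run(params: ModelParams, n_copies: int, t_end: float,
                  seed: int, scale: float | None = None,
                  n_out: int = 400, p0=None) -> Trajectory:
    """Exact stochastic simulation; returns empirical occupancy fractions
    sampled at ``n_out`` evenly spaced times (piecewise-constant between
    events), packaged as a Trajectory on the mean-field node set.

    ``p0`` (default: all copies at P1(0)) sets the initial placement
    deterministically by largest remainders.  The same seed always yields
    the same event sequence.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    space = build_state_space(params)
    if scale is None:
        scale = float(n_copies)
    src, dst, kf, kb, per_af, floor = _edge_arrays(space)
    if np.any(kf < 0) or np.any(kb < 0):
        raise ValueError("negative propensity coefficient - rate-law bug")

    counts = np.zeros(space.n, dtype=np.int64)
    if p0 is None:
        counts[space.idx_p1(0)] = n_copies
    else:
        p0 = np.asarray(p0, dtype=float)
        ideal = p0 * n_copies
        base = np.floor(ideal).astype(np.int64)
        short = n_copies - base.sum()
        order = np.argsort(-(ideal - base))
        base[order[:short]] += 1
        counts = base

    kaiA_units = float(round(scale * params.A_T))
    is_p3 = space.rung_mask("P3")
    is_p2 = space.rung_mask("P2")
    t_grid = np.linspace(0.0, t_end, n_out)
    out = np.empty((n_out, space.n))
    _run_core(counts, src, dst, kf, kb, per_af, floor, is_p3, is_p2,
              kaiA_units, params.eps_seq, float(scale), t_grid, out,
              seed & 0x7FFFFFFF)
    return Trajectory(times=t_grid, states=out, params=params)


def final_ensemble(params: ModelParams, traj: Trajectory, n_copies: int,
                   seed: int) -> EnsembleState:
    """Package the last sampled occupancy of a Gillespie trajectory as an
    EnsembleState (counts reconstructed from fractions)."""
    counts = np.rint(traj.states[-1] * n_copies).astype(np.int64)
    space = build_state_space(params)
    bound = counts[space.p3_slice].sum()
    seq = params.eps_seq * counts[space.p2_slice].sum()
    pool = max(0.0, round(n_copies * params.A_T) - bound - seq)
    return EnsembleState(counts=counts, kaiA_pool=pool, seed=seed)
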