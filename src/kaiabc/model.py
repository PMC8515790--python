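"""State space and state-dependent rate matrix of the phase-ring model.

The network (three rungs on a phosphorylation ring):

* ``P1(j)``, j = 0..N — active, KaiA-free hexamers at phase φ_j = jπ/N.
  Horizontal motion is dephosphorylation at rate ``k1`` (toward lower φ)
  against a hydrolysis-suppressed reverse rate ``gamma*k1 + k1_fwd``.
  With ``k1 = k1_fwd = 0`` the P1 rung has no horizontal edges at all —
  the limit in which the stationary state is exactly solvable.
* ``P3(j)``, j = 0..N — active, KaiA-bound hexamers; phosphorylation ladder
  with forward rate ``k3_fwd`` and backward ``gamma1*k3_fwd``.
* ``P2(k)``, k = N..2N — inactive (KaiB-bound) hexamers at phase kπ/N
  ∈ [π, 2π]; dephosphorylation ladder ``k2_fwd`` / ``gamma2*k2_fwd``.

Vertical edges: KaiA binding P1(j)→P3(j) at ``k_Af*A_f`` and unbinding
P3(j)→P1(j) at ``k_Ab0*alpha**(φ_j−π)`` (differential affinity);
conformational switching P1(j)↔P2(2N−j) at rate ``omega`` for φ_j ≥ phi0;
and the complex-dissociation reset P2(2π)→P1(0) at ``omega1``.

The only state dependence of the rate matrix is through the free-KaiA
concentration ``A_f(p) = max(0, A_T − ΣP3 − eps_seq·ΣP2)``, which makes the
master equation dP/dt = W(P)P nonlinear.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .params import ModelParams, ParameterError

P1, P2, P3 = "P1", "P2", "P3"


@dataclasses.dataclass
class Edge:
    """A reversible edge. If ``fwd_per_Af`` > 0 the forward rate is
    ``fwd_per_Af * A_f`` (KaiA-binding edge), floored at ``floor`` so the
    edge never becomes one-way when the free-KaiA pool is exhausted;
    otherwise it is the constant ``fwd``."""
    src: int
    dst: int
    fwd: float = 0.0
    bwd: float = 0.0
    fwd_per_Af: float = 0.0
    floor: float = 0.0
    label: str = ""

    def forward_rate(self, A_f: float) -> float:
        if self.fwd_per_Af > 0:
            return max(self.fwd_per_Af * A_f, self.floor)
        return self.fwd


@dataclasses.dataclass
class StateSpace:
    """Enumerated nodes and reversible edges of the ring network.

    Node order: P1(0..N), P3(0..N), P2(N..2N); ``n = 3N + 3`` nodes.
    """
    params: ModelParams
    nodes: list          # (rung, grid index, phase)
    phi: np.ndarray      # node phases in [0, 2π]
    edges: list          # list[Edge]

    @property
    def n(self) -> int:
        return len(self.nodes)

    # index helpers -------------------------------------------------------
    def idx_p1(self, j: int) -> int:
        return j

    def idx_p3(self, j: int) -> int:
        return self.params.N + 1 + j

    def idx_p2(self, k: int) -> int:
        # k runs N..2N
        return 2 * (self.params.N + 1) + (k - self.params.N)

    @property
    def p1_slice(self) -> slice:
        return slice(0, self.params.N + 1)

    @property
    def p3_slice(self) -> slice:
        return slice(self.params.N + 1, 2 * self.params.N + 2)

    @property
    def p2_slice(self) -> slice:
        return slice(2 * self.params.N + 2, 3 * self.params.N + 3)

    def rung_mask(self, rung: str) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[{P1: self.p1_slice, P3: self.p3_slice, P2: self.p2_slice}[rung]] = True
        return m

    # exports -------------------------------------------------------------
    def edge_table(self, A_f: Optional[float] = None):
        """Edge list as a pandas DataFrame (source, target, rates).

        KaiA-dependent forward rates are evaluated at ``A_f`` when given,
        otherwise reported per unit A_f with a flag.
        """
        import pandas as pd
        rows = []
        for e in self.edges:
            fwd = e.forward_rate(A_f) if A_f is not None else (
                e.fwd_per_Af if e.fwd_per_Af > 0 else e.fwd)
            rows.append({
                "source": _node_name(self.nodes[e.src]),
                "target": _node_name(self.nodes[e.dst]),
                "forward_rate": fwd,
                "backward_rate": e.bwd,
                "kaiA_dependent": e.fwd_per_Af > 0,
                "label": e.label,
            })
        return pd.DataFrame(rows)

    def to_edge_tsv(self, path, A_f: Optional[float] = None) -> None:
        self.edge_table(A_f).to_csv(path, sep="\t", index=False)


def _node_name(node) -> str:
    rung, idx, _ = node
    return f"{rung}({idx})"


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_state_space(params: ModelParams) -> StateSpace:
    """Enumerate nodes and reversible edges for a parameter set.

    Raises
    ------
    ParameterError
        if N < 2 or phi0 > π (checked by ModelParams as well).
    """
    if params.N < 2:
        raise ParameterError(f"N must be >= 2, got {params.N}")
    if params.phi0 > math.pi + 1e-12:
        raise ParameterError(f"phi0 must be <= pi, got {params.phi0}")
    N = params.N
    nodes = []
    for j in range(N + 1):
        nodes.append((P1, j, j * math.pi / N))
    for j in range(N + 1):
        nodes.append((P3, j, j * math.pi / N))
    for k in range(N, 2 * N + 1):
        nodes.append((P2, k, k * math.pi / N))
    space = StateSpace(params=params, nodes=nodes,
                       phi=np.array([nd[2] for nd in nodes]), edges=[])

    edges = []
    # P3 phosphorylation ladder
    for j in range(N):
        edges.append(Edge(space.idx_p3(j), space.idx_p3(j + 1),
                          fwd=params.k3_fwd, bwd=params.gamma1 * params.k3_fwd,
                          label="P3-ladder"))
    # P1 dephosphorylation ladder (absent when k1 = k1_fwd = 0)
    p1_up = params.gamma * params.k1 + params.k1_fwd   # φ-increasing
    p1_down = params.k1                                # φ-decreasing
    if p1_up > 0 or p1_down > 0:
        for j in range(N):
            edges.append(Edge(space.idx_p1(j + 1), space.idx_p1(j),
                              fwd=p1_down, bwd=p1_up, label="P1-ladder"))
    # vertical KaiA exchange P1(j) <-> P3(j)
    if params.k_Af > 0 or params.k_Ab0 > 0:
        for j in range(N + 1):
            phi_j = j * math.pi / N
            edges.append(Edge(space.idx_p1(j), space.idx_p3(j),
                              fwd_per_Af=params.k_Af,
                              bwd=params.unbinding_rate(phi_j),
                              label="KaiA-exchange"))
    # conformational switch P1(j) <-> P2(2N-j) for φ_j >= phi0
    if params.omega > 0:
        for j in range(params.j0, N + 1):
            edges.append(Edge(space.idx_p1(j), space.idx_p2(2 * N - j),
                              fwd=params.omega, bwd=params.omega,
                              label="switch"))
    # P2 dephosphorylation ladder
    for k in range(N, 2 * N):
        edges.append(Edge(space.idx_p2(k), space.idx_p2(k + 1),
                          fwd=params.k2_fwd, bwd=params.gamma2 * params.k2_fwd,
                          label="P2-ladder"))
    # reset P2(2N) -> P1(0)
    if params.omega1 > 0:
        edges.append(Edge(space.idx_p2(2 * N), space.idx_p1(0),
                          fwd=params.omega1, bwd=0.0, label="reset"))

    # reversibility floor on nominally irreversible edges; KaiA-binding
    # edges are floored dynamically (their rate vanishes with A_f)
    if params.reverse_floor > 0:
        for e in edges:
            has_fwd = e.fwd > 0 or e.fwd_per_Af > 0
            if has_fwd and e.bwd == 0.0:
                e.bwd = params.reverse_floor
            if e.bwd > 0 and not has_fwd:
                e.fwd = params.reverse_floor
            if e.fwd_per_Af > 0:
                e.floor = params.reverse_floor
    space.edges = edges
    return space


# ---------------------------------------------------------------------------
# Probability states
# ---------------------------------------------------------------------------

def as_probability_state(p, n: Optional[int] = None) -> np.ndarray:
    """Validate and clean an occupancy vector: Σp = 1 (tol 1e−9),
    entries ≥ −1e−12 (clipped to 0)."""
    p = np.asarray(p, dtype=float)
    if n is not None and p.shape != (n,):
        raise ValueError(f"state must have shape ({n},), got {p.shape}")
    if p.min() < -1e-12:
        raise ValueError(f"negative occupancy {p.min()} below tolerance")
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"occupancies sum to {s}, not 1")
    return p


def uniform_state(space: StateSpace) -> np.ndarray:
    return np.full(space.n, 1.0 / space.n)


# ---------------------------------------------------------------------------
# Free KaiA and rate matrices
# ---------------------------------------------------------------------------

def free_kaiA(params: ModelParams, p, space: Optional[StateSpace] = None) -> float:
    """Free KaiA concentration A_f = max(0, A_T − ΣP3 − eps_seq·ΣP2)."""
    if space is None:
        space = build_state_space(params)
    p = np.asarray(p, dtype=float)
    bound = p[space.p3_slice].sum()
    seq = p[space.p2_slice].sum()
    return max(0.0, params.A_T - bound - params.eps_seq * seq)


def build_W_at_Af(space: StateSpace, A_f: float) -> np.ndarray:
    """Rate matrix for a frozen free-KaiA level.  W[i, j] is the rate from
    node j to node i; diagonal entries make every column sum to zero."""
    if A_f < 0:
        raise ValueError(f"free KaiA must be nonnegative, got {A_f}")
    n = space.n
    W = np.zeros((n, n))
    for e in space.edges:
        kf = e.forward_rate(A_f)
        kb = e.bwd
        if kf < 0 or kb < 0:
            raise ValueError(f"negative rate on edge {e.label}")
        W[e.dst, e.src] += kf
        W[e.src, e.dst] += kb
    np.fill_diagonal(W, W.diagonal() - W.sum(axis=0))
    return W


def build_rate_matrix(params: ModelParams, p,
                      space: Optional[StateSpace] = None) -> np.ndarray:
    """State-dependent rate matrix W(P⃗), evaluated at the free-KaiA level
    implied by the occupancy vector ``p``."""
    if space is None:
        space = build_state_space(params)
    return build_W_at_Af(space, free_kaiA(params, p, space))


def kaiA_structure_matrix(space: StateSpace) -> np.ndarray:
    """∂W/∂A_f — the structural generator of the KaiA-binding edges
    (constant; the binding rates are linear in A_f)."""
    n = space.n
    D = np.zeros((n, n))
    for e in space.edges:
        if e.fwd_per_Af > 0:
            D[e.dst, e.src] += e.fwd_per_Af
            D[e.src, e.src] -= e.fwd_per_Af
    return D


def free_kaiA_gradient(params: ModelParams, space: StateSpace,
                       p=None) -> np.ndarray:
    """Row vector ∂A_f/∂p (zero when the A_f ≥ 0 clamp is active)."""
    g = np.zeros(space.n)
    g[space.p3_slice] = -1.0
    g[space.p2_slice] = -params.eps_seq
    if p is not None:
        unclamped = (params.A_T - np.asarray(p)[space.p3_slice].sum()
                     - params.eps_seq * np.asarray(p)[space.p2_slice].sum()) > 0
        if not unclamped:
            g[:] = 0.0
    return g


def max_rate(space: StateSpace, A_f: Optional[float] = None) -> float:
    """Largest single-edge rate in the network (scale for tolerances)."""
    if A_f is None:
        A_f = space.params.A_T
    rates = [e.bwd for e in space.edges]
    rates += [e.forward_rate(A_f) for e in space.edges]
    return max(rates) if rates else 0.0


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def phosphorylation_fraction(phi) -> np.ndarray:
    """Per-node phosphorylation weight: φ/π for φ ≤ π, 2 − φ/π beyond —
    0 at the fully dephosphorylated states, 1 at full phosphorylation."""
    phi = np.asarray(phi, dtype=float)
    return np.where(phi <= math.pi, phi / math.pi, 2.0 - phi / math.pi)


def phosphorylation_level(p, space: StateSpace) -> float:
    """Mean phosphorylation Σ f(φ_i)·p_i of an occupancy vector."""
    p = np.asarray(p, dtype=float)
    return float(phosphorylation_fraction(space.phi) @ p)


def is_strongly_connected(space: StateSpace) -> bool:
    """Whether the directed edge graph (with its realized positive rates)
    is strongly connected — the oscillation cycle can complete."""
    n = space.n
    adj = [[] for _ in range(n)]
    radj = [[] for _ in range(n)]
    for e in space.edges:
        if e.fwd > 0 or e.fwd_per_Af > 0:
            adj[e.src].append(e.dst)
            radj[e.dst].append(e.src)
        if e.bwd > 0:
            adj[e.dst].append(e.src)
            radj[e.src].append(e.dst)

    def reach(start, graph):
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in graph[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    return len(reach(0, adj)) == n and len(reach(0, radj)) == n
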