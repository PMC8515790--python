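import math

import numpy as np
import pytest

from kaiabc import (ModelParams, build_state_space, build_rate_matrix,
                    free_kaiA, phosphorylation_level, uniform_state,
                    is_strongly_connected, get_preset)
from kaiabc.model import max_rate, phosphorylation_fraction

from conftest import random_params, random_state


def _all_ones_params():
    """N = 2, every rate equal to 1 (alpha = 1, K_d0 = 1), switch from
    phi0 = pi/2; A_T chosen so A_f = 1 at the uniform state."""
    return ModelParams(N=2, alpha=1.0, k_Af=1.0, k_Ab0=1.0, K_d0=1.0,
                       k1=1.0, k3_fwd=1.0, k1_fwd=0.0, k2_fwd=1.0,
                       gamma=1.0, gamma1=1.0, gamma2=1.0,
                       omega=1.0, omega1=1.0, eps_seq=0.0,
                       A_T=1.0 + 1.0 / 3.0, phi0=math.pi / 2)


def test_state_space_matches_hand_enumeration_at_n2():
    """The N = 2 network, written out by hand: 9 nodes and 12 reversible
    edges (2 per ladder rung pair, 3 vertical exchanges, 2 switches from
    phi0 = pi/2, 1 reset)."""
    p = _all_ones_params()
    space = build_state_space(p)
    assert space.n == 9
    name = lambda i: f"{space.nodes[i][0]}({space.nodes[i][1]})"
    got = {(name(e.src), name(e.dst)): (e.fwd if e.fwd_per_Af == 0 else "Af",
                                        round(e.bwd, 12))
           for e in space.edges}
    expected = {
        ("P3(0)", "P3(1)"): (1.0, 1.0), ("P3(1)", "P3(2)"): (1.0, 1.0),
        ("P1(1)", "P1(0)"): (1.0, 1.0), ("P1(2)", "P1(1)"): (1.0, 1.0),
        ("P1(0)", "P3(0)"): ("Af", 1.0), ("P1(1)", "P3(1)"): ("Af", 1.0),
        ("P1(2)", "P3(2)"): ("Af", 1.0),
        ("P1(1)", "P2(3)"): (1.0, 1.0), ("P1(2)", "P2(2)"): (1.0, 1.0),
        ("P2(2)", "P2(3)"): (1.0, 1.0), ("P2(3)", "P2(4)"): (1.0, 1.0),
        ("P2(4)", "P1(0)"): (1.0, p.reverse_floor),
    }
    assert got == expected
    # rate-matrix entries equal the hand-enumerated rates (A_f = 1 here)
    W = build_rate_matrix(p, uniform_state(space), space)
    for e in space.edges:
        fwd = 1.0 if e.fwd_per_Af else e.fwd
        assert W[e.dst, e.src] == pytest.approx(fwd)
        assert W[e.src, e.dst] == pytest.approx(e.bwd)


def test_symmetric_network_has_uniform_kernel():
    """With every forward rate equal to its backward rate the uniform
    distribution is stationary (the one-way reset edge is switched off —
    it is the only structurally irreversible element)."""
    p = _all_ones_params().replace(omega1=0.0, reverse_floor=0.0)
    space = build_state_space(p)
    u = uniform_state(space)
    W = build_rate_matrix(p, u, space)
    assert np.abs(W @ u).max() <= 1e-8 * max_rate(space)


def test_kaiB_free_limit_disconnects_p2():
    p = _all_ones_params().replace(omega=0.0, omega1=0.0)
    space = build_state_space(p)
    labels = {e.label for e in space.edges}
    assert "switch" not in labels and "reset" not in labels
    assert not is_strongly_connected(space)


def test_no_differential_affinity_means_flat_unbinding():
    p = get_preset("table_s1").replace(alpha=1.0)
    space = build_state_space(p)
    rates = [e.bwd for e in space.edges if e.label == "KaiA-exchange"]
    assert rates == pytest.approx([p.k_Ab0] * (p.N + 1))


def test_strong_connectivity_with_positive_switch_rates():
    rng = np.random.default_rng(3)
    for base in (get_preset("table_s1"), get_preset("table_s2")):
        for _ in range(10):
            space = build_state_space(random_params(rng, base))
            assert is_strongly_connected(space)


def test_free_kaiA_matches_brute_force_sum():
    rng = np.random.default_rng(11)
    p = get_preset("table_s2").replace(A_T=1.0, eps_seq=0.5)
    space = build_state_space(p)
    for _ in range(5):
        x = random_state(rng, space.n)
        direct = p.A_T
        for i, (rung, _, _) in enumerate(space.nodes):
            if rung == "P3":
                direct -= x[i]
            elif rung == "P2":
                direct -= p.eps_seq * x[i]
        assert free_kaiA(p, x, space) == pytest.approx(max(0.0, direct),
                                                       abs=1e-14)


def test_free_kaiA_edge_cases_and_monotonicity():
    p = get_preset("table_s2")
    space = build_state_space(p)
    all_p1 = np.zeros(space.n)
    all_p1[space.p1_slice] = 1.0 / (p.N + 1)
    assert free_kaiA(p, all_p1, space) == pytest.approx(p.A_T)
    # full binding exhausts the pool
    q = p.replace(eps_seq=0.0, A_T=1.0)
    all_p3 = np.zeros(space.n)
    all_p3[space.p3_slice] = 1.0 / (p.N + 1)
    assert free_kaiA(q, all_p3, space) == 0.0
    # moving mass into P3 or P2 never increases A_f
    rng = np.random.default_rng(4)
    x = random_state(rng, space.n)
    base = free_kaiA(p, x, space)
    y = x.copy()
    y[space.idx_p1(3)] -= 0.01
    y[space.idx_p3(3)] += 0.01
    assert free_kaiA(p, y, space) <= base + 1e-15


def test_rate_matrix_columns_sum_to_zero():
    rng = np.random.default_rng(5)
    for base in (get_preset("table_s1"), get_preset("table_s2")):
        for _ in range(10):
            p = random_params(rng, base)
            space = build_state_space(p)
            W = build_rate_matrix(p, random_state(rng, space.n), space)
            assert np.abs(W.sum(axis=0)).max() <= 1e-10 * max_rate(space)


def test_phosphorylation_level_definition():
    p = get_preset("table_s1")
    space = build_state_space(p)
    at_zero = np.zeros(space.n)
    at_zero[space.idx_p1(0)] = 1.0
    assert phosphorylation_level(at_zero, space) == 0.0
    at_pi = np.zeros(space.n)
    at_pi[space.idx_p1(p.N)] = 1.0
    assert phosphorylation_level(at_pi, space) == pytest.approx(1.0)
    # reflection symmetry: phi and 2*pi - phi carry the same weight
    j = 5
    split = np.zeros(space.n)
    split[space.idx_p1(j)] = 0.5
    split[space.idx_p2(2 * p.N - j)] = 0.5
    alone = np.zeros(space.n)
    alone[space.idx_p1(j)] = 1.0
    assert phosphorylation_level(split, space) == pytest.approx(
        phosphorylation_level(alone, space))
    # random state equals the explicit elementwise sum
    rng = np.random.default_rng(6)
    x = random_state(rng, space.n)
    direct = sum(float(phosphorylation_fraction(space.phi[i])) * x[i]
                 for i in range(space.n))
    assert phosphorylation_level(x, space) == pytest.approx(direct)


def test_constructor_rejects_tiny_grids():
    from kaiabc.params import ParameterError
    with pytest.raises(ParameterError):
        build_state_space(ModelParams(N=1))
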