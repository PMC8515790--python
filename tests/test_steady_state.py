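import math

import numpy as np
import pytest

from kaiabc import (analytic_k1_zero, approx_k1, numeric_fixed_point,
                    build_state_space, build_rate_matrix, uniform_state,
                    free_kaiA, FixedPointError, get_preset)
from kaiabc.model import max_rate
from kaiabc.steady_state import scan_self_consistency


def test_analytic_solution_is_an_exact_fixed_point(s1):
    """In the k1 = 0, eps_seq = 0, phi0 = pi limit the ladder construction
    satisfies the stationarity equations to within the reverse-floor
    correction (well below 1e-8 times the largest rate)."""
    space = build_state_space(s1)
    for alpha in (2.0, 4.0, 6.0, 8.0):
        fp = analytic_k1_zero(s1.replace(alpha=alpha))
        assert fp.method == "analytic"
        assert fp.residual <= 1e-8 * max_rate(space)
        assert fp.p.min() >= 0 and fp.p.sum() == pytest.approx(1.0)
        assert 0 < fp.b < 1


def test_analytic_matches_newton_from_uniform(s1):
    """Dual-route check: the closed-form construction and a damped Newton
    solve started from the uniform state agree to 1e-7 in max-norm."""
    space = build_state_space(s1)
    for alpha in (2.0, 4.0, 6.0, 8.0):
        p = s1.replace(alpha=alpha)
        fp_a = analytic_k1_zero(p)
        fp_n = numeric_fixed_point(p, guess=uniform_state(space),
                                   tol_factor=1e-13)
        assert np.abs(fp_a.p - fp_n.p).max() <= 1e-7


def test_self_consistency_root_agrees_with_grid_scan(s1):
    """The bracketed root of the free-KaiA closure matches a brute-force
    scan of the mismatch function."""
    p = s1.replace(alpha=6.0)
    fp = analytic_k1_zero(p)
    grid, vals = scan_self_consistency(p, n_grid=400)
    sign_change = np.nonzero(np.diff(np.sign(vals)))[0]
    assert len(sign_change) >= 1
    i = sign_change[0]
    # linear interpolation of the scan crossing
    x0, x1, y0, y1 = grid[i], grid[i + 1], vals[i], vals[i + 1]
    crossing = x0 - y0 * (x1 - x0) / (y1 - y0)
    assert fp.A_f == pytest.approx(crossing, abs=2 * (x1 - x0))


def test_analytic_preconditions_are_enforced(s1):
    with pytest.raises(FixedPointError, match="k1"):
        analytic_k1_zero(s1.replace(k1=0.01))
    with pytest.raises(FixedPointError, match="eps_seq"):
        analytic_k1_zero(s1.replace(eps_seq=0.5))
    with pytest.raises(FixedPointError, match="phi0"):
        analytic_k1_zero(s1.replace(phi0=0.8 * math.pi))
    # non-strict mode accepts the truncated geometry and flags it
    fp = analytic_k1_zero(s1.replace(phi0=0.8 * math.pi), strict=False)
    assert fp.method == "analytic-truncated"


def test_approx_reduces_to_analytic_at_k1_zero(s1):
    fp_a = analytic_k1_zero(s1)
    fp_x = approx_k1(s1)
    assert np.abs(fp_a.p - fp_x.p).max() <= 1e-8


def test_approx_error_decreases_as_k1_vanishes(s2):
    """The vertical-balance ansatz becomes exact as k1 -> 0: its max-norm
    error against the Newton fixed point shrinks monotonically."""
    errs = []
    for k1 in (1e-2, 1e-3, 1e-4):
        p = s2.replace(k1=k1)
        fp_x = approx_k1(p)
        fp_n = numeric_fixed_point(p, guess=uniform_state(build_state_space(p)))
        errs.append(np.abs(fp_x.p - fp_n.p).max())
    assert errs[0] > errs[1] > errs[2]
    # with phi0 = pi the truncation error is absent and the ansatz error
    # itself vanishes with k1
    p = s2.replace(phi0=math.pi, k1=1e-4)
    fp_x = approx_k1(p)
    fp_n = numeric_fixed_point(p, guess=uniform_state(build_state_space(p)))
    assert np.abs(fp_x.p - fp_n.p).max() < 1e-4


def test_approx_satisfies_vertical_balance_by_construction(s2):
    """Along the P1-P3 links below phi0 the construction enforces
    k_Af*A_f*P1 = k_Ab0*alpha^(phi-pi)*P3 (interior columns)."""
    p = s2.replace(k1=5e-3)
    fp = approx_k1(p)
    space = build_state_space(p)
    a = p.k_Af * fp.A_f
    for j in range(1, p.j0):
        lhs = a * fp.p[space.idx_p1(j)]
        rhs = p.unbinding_rate(space.phi[space.idx_p3(j)]) * \
            fp.p[space.idx_p3(j)]
        assert lhs == pytest.approx(rhs, rel=1e-9)


def test_newton_finds_uniform_state_on_equilibrium_network(eq):
    space = build_state_space(eq)
    fp = numeric_fixed_point(eq, guess=None)
    assert np.abs(fp.p - uniform_state(space)).max() <= 1e-9


def test_unstable_fixed_point_is_reachable_by_newton(osc):
    """Above onset the stationary state is unstable; Newton seeded with
    the ladder construction still lands on it with a tiny residual."""
    fp = numeric_fixed_point(osc, guess=analytic_k1_zero(osc).p)
    assert fp.residual <= 1e-10 * max_rate(build_state_space(osc))
    assert fp.p.min() >= 0


def test_fixed_points_are_normalized_probability_states(s1, s2):
    for p in (s1, s2.replace(k1=0.02), s2):
        fp = approx_k1(p)
        assert fp.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert fp.p.min() >= 0
        A_f = free_kaiA(p, fp.p)
        assert fp.A_f == pytest.approx(A_f, abs=1e-9)
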