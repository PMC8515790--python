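import numpy as np
import pytest

from kaiabc import get_preset, equilibrium_params, build_state_space


@pytest.fixture(scope="session")
def s1():
    """Differential-affinity operating point (k1 = 0 studies)."""
    return get_preset("table_s1")


@pytest.fixture(scope="session")
def s2():
    """Ultrasensitivity operating point (k1 studies at alpha = 10)."""
    return get_preset("table_s2")


@pytest.fixture(scope="session")
def eq():
    """Detailed-balance parameterization with a uniform stationary state."""
    return equilibrium_params(N=8)


@pytest.fixture(scope="session")
def osc():
    """A robustly oscillating parameter point (above the alpha onset)."""
    return get_preset("default")


def random_params(rng, base):
    """A random valid parameterization near a preset (rates perturbed by
    factors in [0.7, 1.4]); used by property tests."""
    f = lambda: float(rng.uniform(0.7, 1.4))
    k_Af = base.k_Af * f()
    return base.replace(
        alpha=max(1.0, base.alpha * f()),
        k_Af=k_Af, K_d0=base.K_d0 * f(),
        k1=base.k1 * f() if base.k1 else float(rng.uniform(0, 0.05)),
        k3_fwd=base.k3_fwd * f(), k2_fwd=base.k2_fwd * f(),
        gamma=min(1.0, base.gamma * f()),
        gamma1=min(1.0, base.gamma1 * f()),
        gamma2=min(1.0, base.gamma2 * f()),
        omega=base.omega * f(), omega1=base.omega1 * f(),
        eps_seq=base.eps_seq * f(), A_T=base.A_T * f(),
    )


def random_state(rng, n):
    p = rng.gamma(0.5, size=n)
    return p / p.sum()
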