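"""Model parameters for the coarse-grained KaiABC phase-ring model.

The model lives on a discretized ring of phosphorylation phase φ ∈ [0, 2π].
Active, KaiA-free hexamers (P1) and active, KaiA-bound hexamers (P3) occupy
the top half φ ∈ [0, π] (phosphorylation increasing with φ); inactive,
KaiB-bound hexamers (P2) occupy the bottom half φ ∈ [π, 2π]
(dephosphorylation).  All units are dimensionless model units: time in units
of the inverse base phosphotransfer rate, concentrations in units of total
KaiC.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import yaml


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclasses.dataclass
class ModelParams:
    """All rate constants and structural parameters of the ring model.

    Parameters
    ----------
    N : int
        Number of grid intervals on the half-ring [0, π]; phases are
        φ_j = jπ/N for j = 0..N on the top rungs, and the P2 rung node
        P2(2N−j) sits at phase 2π − φ_j.
    alpha : float
        Differential-affinity base (≥ 1).  The KaiA unbinding rate from
        P3(j) is ``k_Ab0 * alpha**(φ_j − π)``: strong KaiA binding at low
        phosphorylation, weak at high phosphorylation.
    k_Af : float
        P1→P3 KaiA-binding rate coefficient (per concentration per time).
    k_Ab0 : float
        P3→P1 unbinding base rate (the rate at φ = π).
    K_d0 : float
        ``k_Ab0 / k_Af``; stored redundantly and kept consistent.  The
        model's proxy for %ATP (larger K_d0 ↔ lower %ATP).
    k1 : float
        Dephosphorylation rate along the P1 rung (P1(j+1)→P1(j)); the
        ultrasensitivity knob.  k1 = 0 removes the P1 ladder entirely.
    k3_fwd : float
        Forward (KaiA-assisted) phosphorylation rate along the P3 rung.
    k1_fwd : float
        Residual KaiA-free phosphorylation rate along the P1 rung
        (default 0; added to the hydrolysis-ratio reverse rate gamma*k1).
    k2_fwd : float
        Forward dephosphorylation rate along the P2 rung.
    gamma, gamma1, gamma2 : float
        Backward/forward rate ratios in (0, 1] of the hydrolysis-driven
        P1, P3 and P2 rungs respectively.
    omega : float
        P1(j) ↔ P2(2N−j) conformational-switch rate, active for φ_j ≥ phi0.
    omega1 : float
        P2(2π) → P1(0) reset (complex-dissociation) rate.
    eps_seq : float
        KaiA sequestration stoichiometry of the P2 states: free KaiA is
        reduced by ``eps_seq * ΣP2``.
    A_T : float
        Total KaiA concentration (in units of total KaiC).
    phi0 : float
        Phase (radians, in (0, π]) at which P1→P2 switching begins.
    reverse_floor : float
        Minimal reverse rate added to any nominally irreversible edge so
        that every edge carries strictly positive rates in both directions
        (required by the entropy-production accounting).
    """

    N: int = 20
    alpha: float = 10.0
    k_Af: float = 10.0
    k_Ab0: float = 50.0
    K_d0: float = 5.0
    k1: float = 0.0
    k3_fwd: float = 1.0
    k1_fwd: float = 0.0
    k2_fwd: float = 1.0
    gamma: float = 0.05
    gamma1: float = 0.05
    gamma2: float = 0.05
    omega: float = 2.0
    omega1: float = 2.0
    eps_seq: float = 1.0
    A_T: float = 1.0
    phi0: float = math.pi
    reverse_floor: float = 1e-8

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ParameterError(f"N must be an integer >= 2, got {self.N}")
        self.N = int(self.N)
        if self.alpha < 1.0:
            raise ParameterError(f"alpha must be >= 1, got {self.alpha}")
        for name in ("k_Af", "k_Ab0", "K_d0", "k1", "k3_fwd", "k1_fwd",
                     "k2_fwd", "omega", "omega1", "eps_seq", "A_T",
                     "reverse_floor"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a nonnegative finite "
                                     f"number, got {v}")
        for name in ("gamma", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.phi0 <= math.pi + 1e-12:
            raise ParameterError(f"phi0 must lie in (0, pi], got {self.phi0}")
        self.phi0 = min(self.phi0, math.pi)
        if self.k_Af > 0:
            implied = self.k_Ab0 / self.k_Af
            if abs(implied - self.K_d0) > 1e-12 * max(1.0, abs(self.K_d0)):
                raise ParameterError(
                    f"K_d0 ({self.K_d0}) inconsistent with k_Ab0/k_Af "
                    f"({implied}); they must agree to 1e-12 relative")

    # -- derived quantities ----------------------------------------------

    @property
    def phases_top(self):
        """φ_j = jπ/N for j = 0..N (P1/P3 rungs)."""
        import numpy as np
        return np.linspace(0.0, math.pi, self.N + 1)

    @property
    def j0(self) -> int:
        """First grid index with an ω switch edge: ceil(N·φ0/π)."""
        return min(self.N, math.ceil(self.N * self.phi0 / math.pi - 1e-12))

    def unbinding_rate(self, phi: float) -> float:
        """KaiA unbinding rate from P3 at phase φ: k_Ab0 · α^(φ−π)."""
        return self.k_Ab0 * self.alpha ** (phi - math.pi)

    # -- copies ----------------------------------------------------------

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with fields replaced (K_d0/k_Ab0 kept consistent).

        If exactly one of ``K_d0``/``k_Ab0`` is given, the other is recomputed
        from ``k_Af`` so the redundant pair stays consistent.
        """
        if "K_d0" in kwargs and "k_Ab0" not in kwargs:
            k_Af = kwargs.get("k_Af", self.k_Af)
            kwargs["k_Ab0"] = kwargs["K_d0"] * k_Af
        elif "k_Ab0" in kwargs and "K_d0" not in kwargs:
            k_Af = kwargs.get("k_Af", self.k_Af)
            if k_Af > 0:
                kwargs["K_d0"] = kwargs["k_Ab0"] / k_Af
        elif "k_Af" in kwargs and "K_d0" not in kwargs and "k_Ab0" not in kwargs:
            kwargs["k_Ab0"] = self.K_d0 * kwargs["k_Af"]
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _preset_table_s1() -> ModelParams:
    """Operating point for the k1 = 0 (differential-affinity) studies.

    Synthetic stand-in parameter set: the published supplementary table is
    not redistributable here, so these values are the package's own
    calibration, chosen once so that at k1 = 0 the oscillatory onset is
    reached by raising alpha (critical alpha ≈ 24 at K_d0 = 5, rising
    steeply with K_d0), with period ≈ 100 model-time units.  The feedback
    is pure free-KaiA depletion by binding (eps_seq = 0) and phi0 = π, the
    regime in which the k1 = 0 stationary state is exactly solvable.
    """
    return ModelParams(
        N=20, alpha=10.0, k_Af=100.0, k_Ab0=500.0, K_d0=5.0,
        k1=0.0, k3_fwd=1.0, k1_fwd=0.0, k2_fwd=0.6,
        gamma=0.005, gamma1=0.005, gamma2=0.005,
        omega=1.0, omega1=3.0, eps_seq=0.0, A_T=0.3,
        phi0=math.pi, reverse_floor=1e-8,
    )


def _preset_table_s2() -> ModelParams:
    """Operating point for the k1 (ultrasensitivity) studies at alpha = 10.

    Synthetic stand-in parameter set (see _preset_table_s1): calibrated so
    that at alpha = 10 and k1 = 0 the stationary state is stable for all
    K_d0 ≥ 1 and raising k1 carries the system through the oscillatory
    onset (critical k1 ≈ 0.026 at K_d0 = 8, non-decreasing in K_d0, with
    no oscillations beyond K_d0 ≈ 12).  KaiA sequestration by the P2
    states (eps_seq > 0) with a slow conformational switch closes the
    delayed negative-feedback loop; period ≈ 58 model-time units.

    The KaiB-free dose–response study uses this preset with the switch
    removed and a residual KaiA-free phosphorylation rate:
    ``replace(omega=0, omega1=0, K_d0=10, k1_fwd=0.05)``.
    """
    return ModelParams(
        N=20, alpha=10.0, k_Af=200.0, k_Ab0=1600.0, K_d0=8.0,
        k1=0.0, k3_fwd=1.0, k1_fwd=0.0, k2_fwd=0.4,
        gamma=0.01, gamma1=0.01, gamma2=0.01,
        omega=0.1, omega1=2.0, eps_seq=4.0, A_T=0.6,
        phi0=0.75 * math.pi, reverse_floor=1e-8,
    )


def _preset_default() -> ModelParams:
    """A robustly oscillating operating point (table_s1 above onset)."""
    return _preset_table_s1().replace(alpha=30.0)


def equilibrium_params(N: int = 8) -> ModelParams:
    """A detailed-balance parameterization whose stationary state is uniform.

    Every edge has equal forward and backward rates: all hydrolysis ratios
    are 1, alpha = 1, the switch is symmetric, the reset edge is switched
    off (omega1 = 0) and A_T is chosen so the self-consistent free KaiA at
    the uniform state equals K_d0, making the vertical exchange symmetric
    too.  Used as the zero-entropy-production / stable-equilibrium oracle.
    """
    K_d0 = 1.0
    # at uniform p, ΣP3 = (N+1)/(3N+3) = 1/3, so A_f = A_T - 1/3 = K_d0
    return ModelParams(
        N=N, alpha=1.0, k_Af=1.0, k_Ab0=K_d0, K_d0=K_d0,
        k1=1.0, k3_fwd=1.0, k1_fwd=0.0, k2_fwd=1.0,
        gamma=1.0, gamma1=1.0, gamma2=1.0,
        omega=1.0, omega1=0.0, eps_seq=0.0, A_T=K_d0 + 1.0 / 3.0,
        phi0=math.pi / 2, reverse_floor=0.0,
    )


PRESETS = {
    "default": _preset_default,
    "table_s1": _preset_table_s1,
    "table_s2": _preset_table_s2,
    "equilibrium": equilibrium_params,
}


def get_preset(name: str) -> ModelParams:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def load_config(path) -> ModelParams:
    """Load a ModelParams from a YAML or JSON file.

    Keys must match ModelParams field names exactly; a ``preset`` key may
    name a base preset whose fields the remaining keys override.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a mapping")
    base = data.pop("preset", None)
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - valid
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    if base is not None:
        return get_preset(base).replace(**data)
    return ModelParams(**data)


def save_config(params: ModelParams, path) -> None:
    """Write a ModelParams to YAML or JSON (by file suffix)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
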