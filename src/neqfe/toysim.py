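"""Synthetic work generators with analytically known free energies.

Two engines back the test suite and the benchmark machinery:

1. :func:`gaussian_cft_sample` draws forward/reverse work pairs from the
   Gaussian family that satisfies the Crooks fluctuation theorem exactly at
   a chosen ΔG and dissipation width.
2. A one-particle overdamped Langevin simulator driven through a
   λ-dependent potential, mirroring the two-step protocol of real
   non-equilibrium alchemistry (equilibrium end-state sampling →
   equidistant snapshots → fixed-length bidirectional switches) with an
   analytic ΔF for harmonic end states.

The toy engines work in reduced units (kT = 1). Exported
:class:`~neqfe.work_io.WorkSet` objects carry the reduced temperature
``1/k_B`` so that numeric work values equal their kT values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import quad

from .constants import KB_KJ_PER_MOL_K
from .work_io import WorkSet

__all__ = [
    "ToyAlchemyConfig",
    "HarmonicPotential",
    "DoubleWellPotential",
    "gaussian_cft_sample",
    "simulate_switch_work",
    "run_toy_campaign",
    "REDUCED_TEMPERATURE",
]

#: Temperature (K) at which k_B*T == 1 kJ/mol; used to export reduced-unit
#: work sets whose numeric values equal kT multiples.
REDUCED_TEMPERATURE = 1.0 / KB_KJ_PER_MOL_K


def gaussian_cft_sample(
    dg: float,
    sigma: float,
    n_forward: int,
    n_reverse: int,
    seed: int,
    temperature: float = REDUCED_TEMPERATURE,
) -> WorkSet:
    """Crooks-consistent Gaussian work samples at a known ΔG (kT units).

    Forward works ~ N(dg + σ²/2, σ²) and reverse works ~ N(−dg + σ²/2, σ²)
    in the work-as-performed convention; this pair of Gaussians satisfies
    p_F(W)/p_R(−W) = exp(W − dg) exactly. With σ=0 the reversible limit is
    recovered (all forward works dg, all reverse works −dg).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n_forward < 0 or n_reverse < 0 or n_forward + n_reverse == 0:
        raise ValueError("need at least one sample in some direction")
    rng = np.random.default_rng(seed)
    dissipation = sigma**2 / 2.0
    wf = rng.normal(dg + dissipation, sigma, size=n_forward)
    wr = rng.normal(-dg + dissipation, sigma, size=n_reverse)
    kt = KB_KJ_PER_MOL_K * temperature
    return WorkSet(w_forward=wf * kt, w_reverse=wr * kt, temperature=temperature)


@dataclass(frozen=True)
class HarmonicPotential:
    """H(x;λ) = ½k(λ)(x−x₀(λ))² with k and x₀ linear in λ."""

    k_a: float = 1.0
    k_b: float = 1.0
    a: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("force constants must be positive")

    def k(self, lam):
        return (1.0 - lam) * self.k_a + lam * self.k_b

    def x0(self, lam):
        return (1.0 - lam) * self.a + lam * self.b

    def energy(self, x, lam):
        return 0.5 * self.k(lam) * (x - self.x0(lam)) ** 2

    def force(self, x, lam):
        return -self.k(lam) * (x - self.x0(lam))

    def dhdl(self, x, lam):
        d = x - self.x0(lam)
        return 0.5 * (self.k_b - self.k_a) * d**2 - self.k(lam) * d * (self.b - self.a)

    @property
    def max_stiffness(self) -> float:
        return max(self.k_a, self.k_b)

    def free_energy_difference(self, kt: float) -> float:
        """ΔF = F(λ=1) − F(λ=0) = (kT/2) ln(k_b/k_a)."""
        return 0.5 * kt * math.log(self.k_b / self.k_a)


@dataclass(frozen=True)
class DoubleWellPotential:
    """λ-interpolation between a symmetric double well and a harmonic trap.

    H(x;λ) = (1−λ)·h((x/w)² − 1)² + λ·½k_b(x−b)². The λ=0 state has two
    basins at ±w separated by a barrier of height h.
    """

    h: float = 5.0
    w: float = 1.0
    k_b: float = 4.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.w <= 0 or self.k_b <= 0:
            raise ValueError("h, w and k_b must be positive")

    def energy_a(self, x):
        return self.h * ((x / self.w) ** 2 - 1.0) ** 2

    def energy_b(self, x):
        return 0.5 * self.k_b * (x - self.b) ** 2

    def energy(self, x, lam):
        return (1.0 - lam) * self.energy_a(x) + lam * self.energy_b(x)

    def force(self, x, lam):
        da = 4.0 * self.h * x / self.w**2 * ((x / self.w) ** 2 - 1.0)
        db = self.k_b * (x - self.b)
        return -((1.0 - lam) * da + lam * db)

    def dhdl(self, x, lam):
        return self.energy_b(x) - self.energy_a(x)

    @property
    def max_stiffness(self) -> float:
        # curvature at the bottom of a double-well basin is 8h/w²
        return max(8.0 * self.h / self.w**2, self.k_b)

    def free_energy_difference(self, kt: float) -> float:
        """ΔF by 1-D quadrature of the two partition functions."""
        span = 6.0 * max(self.w, abs(self.b) + math.sqrt(kt / self.k_b) * 6)
        za, _ = quad(lambda x: math.exp(-self.energy_a(x) / kt), -span, span, limit=200)
        zb, _ = quad(lambda x: math.exp(-self.energy_b(x) / kt), -span, span, limit=200)
        return -kt * math.log(zb / za)


@dataclass(frozen=True)
class ToyAlchemyConfig:
    """Configuration of one toy switching campaign (reduced units, kT=1)."""

    potential: HarmonicPotential | DoubleWellPotential = field(
        default_factory=HarmonicPotential
    )
    temperature: float = 1.0
    gamma: float = 1.0
    dt: float = 0.01
    n_steps_switch: int = 100
    n_equil_samples: int = 1000
    snapshot_count: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.temperature <= 0 or self.gamma <= 0 or self.dt <= 0:
            raise ValueError("temperature, gamma and dt must be positive")
        if self.n_steps_switch < 0:
            raise ValueError("n_steps_switch must be non-negative")
        if not 1 <= self.snapshot_count <= self.n_equil_samples:
            raise ValueError("need 1 <= snapshot_count <= n_equil_samples")
        if self.dt * self.potential.max_stiffness / self.gamma >= 0.1:
            raise ValueError(
                "unstable integration: require dt*max(k)/gamma < 0.1, got "
                f"{self.dt * self.potential.max_stiffness / self.gamma:.3g}"
            )


Basin = Literal["both", "left", "right"]


def _equilibrium_draws(
    cfg: ToyAlchemyConfig, lam: float, n: int, rng: np.random.Generator,
    basin: Basin = "both",
) -> np.ndarray:
    """Draw n coordinates from the Boltzmann distribution at fixed λ.

    Harmonic states are sampled exactly (Gaussian). Double-well states are
    sampled exactly via inverse-CDF on a fine grid; restricting ``basin``
    to "left"/"right" truncates the density to x<0 / x>0, modelling
    equilibrium sampling that never crossed the barrier.
    """
    pot = cfg.potential
    kt = cfg.temperature
    if isinstance(pot, HarmonicPotential):
        return rng.normal(pot.x0(lam), math.sqrt(kt / pot.k(lam)), size=n)
    # grid inverse-CDF for the general 1-D density
    span = 4.0 * max(pot.w, abs(pot.b)) + 6.0 * math.sqrt(kt / pot.k_b)
    lo, hi = -span, span
    if basin == "left":
        hi = 0.0
    elif basin == "right":
        lo = 0.0
    x = np.linspace(lo, hi, 20001)
    p = np.exp(-(pot.energy(x, lam) - pot.energy(x, lam).min()) / kt)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, x)


def _switch_batch(
    cfg: ToyAlchemyConfig, direction: str, x_start: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drive a batch of trajectories through the λ switch; return works.

    Overdamped Langevin (Euler–Maruyama): x ← x + (dt/γ)F + √(2kT·dt/γ)ξ.
    λ advances after each coordinate update; the work is the trapezoid of
    the ∂H/∂λ values at the (x, λ) pairs actually visited.
    ``n_steps_switch == 0`` is an instantaneous switch,
    W = H(x;λ_end) − H(x;λ_start).
    """
    pot = cfg.potential
    kt = cfg.temperature
    lam_start, lam_end = (0.0, 1.0) if direction == "forward" else (1.0, 0.0)
    x = np.array(x_start, dtype=float, copy=True)
    n_steps = cfg.n_steps_switch
    if n_steps == 0:
        return pot.energy(x, lam_end) - pot.energy(x, lam_start)
    lam_path = np.linspace(lam_start, lam_end, n_steps + 1)
    dhdl = np.empty((n_steps + 1, x.size))
    dhdl[0] = pot.dhdl(x, lam_start)
    mobility = cfg.dt / cfg.gamma
    noise_scale = math.sqrt(2.0 * kt * mobility)
    for step in range(1, n_steps + 1):
        lam_prev = lam_path[step - 1]
        x += mobility * pot.force(x, lam_prev) + noise_scale * rng.standard_normal(x.size)
        dhdl[step] = pot.dhdl(x, lam_path[step])
    return np.trapezoid(dhdl, lam_path, axis=0)


def simulate_switch_work(
    cfg: ToyAlchemyConfig,
    direction: str,
    rng: np.random.Generator | None = None,
    x_start: float | None = None,
) -> float:
    """Run a single non-equilibrium switch and return its work (kT units).

    The start coordinate is drawn exactly from the Boltzmann distribution
    of the starting end state unless ``x_start`` is given.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lam0 = 0.0 if direction == "forward" else 1.0
    if x_start is None:
        x0 = _equilibrium_draws(cfg, lam0, 1, rng)
    else:
        x0 = np.array([x_start], dtype=float)
    return float(_switch_batch(cfg, direction, x0, rng)[0])


def run_toy_campaign(
    cfg: ToyAlchemyConfig,
    basin_forward: Basin = "both",
    basin_reverse: Basin = "both",
) -> tuple[WorkSet, float]:
    """Full two-step toy protocol: end-state sampling + bidirectional switches.

    ``snapshot_count`` equilibrium starts are drawn per end state, one
    switch is launched from each in each direction, and the resulting
    reduced-unit :class:`WorkSet` is returned together with the analytic
    ΔF (closed form for harmonic potentials, 1-D quadrature for double
    wells). Snapshot origin indices (1..n, as pseudo-ns) are attached so
    the work set supports truncation.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.snapshot_count
    x_f = _equilibrium_draws(cfg, 0.0, n, rng, basin=basin_forward)
    x_r = _equilibrium_draws(cfg, 1.0, n, rng, basin=basin_reverse)
    wf = _switch_batch(cfg, "forward", x_f, rng)
    wr = _switch_batch(cfg, "reverse", x_r, rng)
    origins = np.arange(1, n + 1, dtype=float)
    ws = WorkSet(
        w_forward=wf, w_reverse=wr, temperature=REDUCED_TEMPERATURE,
        origin_forward=origins, origin_reverse=origins.copy(),
    )
    df = cfg.potential.free_energy_difference(cfg.temperature)
    return ws, df
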