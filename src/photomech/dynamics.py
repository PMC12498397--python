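"""Langevin sampling of collective variables on model potentials.

A production-scale engine would propagate a full QM/MM system; the
toy engine here evolves the collective variables (Ru–S, Ru–O_min) directly on an
analytic model potential with a BAOAB-split Langevin integrator.  Only
the sampling statistics matter for the downstream free-energy and
mechanism analysis, so the CV "mass" is fictitious (1 amu by default).

Also provides the Ornstein–Uhlenbeck generator for the chelate dihedral
θ and a smooth spin surrogate mapping (d_RuS, d_RuOmin) to a Ru Mulliken
spin value anchored at ≈0.7 (³MLCT), ≥1.2 (³MC), ≈0.8 (³P).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import BiasState, bias_force, deposit_hill
from .constants import AMU_TO_INTERNAL, KB
from .potentials import ModelPotential


@dataclass(frozen=True)
class SimulationParams:
    """Thermostat and integrator settings for the toy CV engine."""

    temperature: float = 300.0   # K
    friction: float = 10.0       # 1/ps
    timestep: float = 0.002      # ps
    mass: float = 1.0            # amu per CV (fictitious)
    n_steps: int = 20_000
    seed: int = 0

    kB: float = KB               # kJ/mol/K, here for discoverability

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")

    @property
    def mass_internal(self) -> float:
        """Mass in kJ/mol·ps²/Å²."""
        return self.mass * AMU_TO_INTERNAL


def baoab_diffusion_constant(params: SimulationParams) -> float:
    """Analytic free-particle diffusion constant of the BAOAB chain.

    For zero force the velocity is an AR(1) process with decay
    c = exp(−γ·dt) and variance k_B T/m, and positions advance by
    dt·(v_n + v_{n+1})/2.  Summing the displacement autocovariances gives
    D = (dt/2)·(k_B T/m)·(1+c)/(1−c), which tends to k_B T/(m γ) as
    dt → 0.  Units Å²/ps.
    """
    c = np.exp(-params.friction * params.timestep)
    return 0.5 * params.timestep * (KB * params.temperature /
                                    params.mass_internal) * (1 + c) / (1 - c)


def simulate_langevin(potential: ModelPotential, params: SimulationParams,
                      bias: BiasState | None = None,
                      x0=None, sample_every: int = 1,
                      return_bias_state: bool = False):
    """Sample CVs with BAOAB Langevin dynamics under an optional bias.

    When ``bias`` carries a metadynamics part, hills are deposited every
    ``bias.pace`` integrator steps at the current position of the
    metadynamics coordinate (well-tempered heights).

    Returns a DataFrame with columns ``time``, ``s1`` (and ``s2`` for 2D
    potentials); with ``return_bias_state=True`` also returns the final
    BiasState carrying all deposited hills.

    The trajectory is bitwise-reproducible for a fixed
    ``params.seed``.  Raises on non-finite energies or forces, reporting
    the step index.
    """
    ndim = potential.ndim
    if x0 is None:
        if potential.known_minima:
            x0 = np.asarray(potential.known_minima[0][0], dtype=float)
        else:
            x0 = np.zeros(ndim)
    x = np.array(x0, dtype=float).reshape(ndim)

    rng = np.random.default_rng(params.seed)
    m = params.mass_internal
    dt = params.timestep
    kT = KB * params.temperature
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT / m) if params.temperature > 0 else 0.0
    sigma_v = np.sqrt(kT / m) if params.temperature > 0 else 0.0
    v = rng.normal(0.0, sigma_v, size=ndim) if sigma_v else np.zeros(ndim)

    state = bias if bias is not None else None

    def total_force(pos, t):
        f = -np.asarray(potential.gradient(pos), dtype=float)
        if state is not None:
            f = f + bias_force(state, pos)
        return f

    f = total_force(x, 0.0)
    n_out = params.n_steps // sample_every + 1
    out = np.empty((n_out, ndim))
    times = np.empty(n_out)
    out[0] = x
    times[0] = 0.0
    k_out = 1

    for step in range(1, params.n_steps + 1):
        # B: half kick — A: half drift — O: thermostat — A — B
        v = v + 0.5 * dt * f / m
        x = x + 0.5 * dt * v
        if c2:
            v = c1 * v + c2 * rng.normal(size=ndim)
        else:
            v = c1 * v
        x = x + 0.5 * dt * v
        t = step * dt
        if (state is not None and state.metad_enabled
                and step % state.pace == 0):
            state = deposit_hill(state, x[state.meta_cv if ndim > 1 else 0], t)
        f = total_force(x, t)
        if not (np.isfinite(f[0]) and np.isfinite(f[-1])):
            raise FloatingPointError(
                f"non-finite force at step {step} (x={x})")
        v = v + 0.5 * dt * f / m
        if step % sample_every == 0:
            if not np.isfinite(potential.energy(x)):
                raise FloatingPointError(
                    f"non-finite energy at step {step} (x={x})")
            out[k_out] = x
            times[k_out] = t
            k_out += 1

    cols = ["s1"] if ndim == 1 else ["s1", "s2"]
    df = pd.DataFrame(out[:k_out], columns=cols)
    df.insert(0, "time", times[:k_out])
    if return_bias_state:
        return df, state
    return df


# ---------------------------------------------------------------------------
# chelate dihedral process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThetaProcess:
    """Ornstein–Uhlenbeck model of the signed chelate dihedral θ.

    ``mean_deg``/``sd_deg`` are the stationary mean and standard
    deviation of the *signed* process; after folding onto [0°, 90°] the
    folded mean matches ``mean_deg`` closely whenever mean_deg is a few
    sd away from 0° and 90°.
    """

    mean_deg: float
    sd_deg: float
    relaxation_time: float = 0.1  # ps

    def __post_init__(self):
        if not 0.0 <= self.mean_deg <= 90.0:
            raise ValueError("mean_deg must lie in [0, 90]")
        if self.sd_deg < 0:
            raise ValueError("sd_deg must be >= 0")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be > 0")


def generate_theta_series(proc: ThetaProcess, n: int, seed: int,
                          dt: float = 0.05, mean_series=None) -> np.ndarray:
    """Exact-discretization OU path of the signed dihedral, degrees.

    ``mean_series`` optionally modulates the process mean frame-by-frame
    (a hook for coupling θ to the reaction coordinates; off by default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rho = np.exp(-dt / proc.relaxation_time)
    noise_sd = proc.sd_deg * np.sqrt(1.0 - rho * rho)
    rng = np.random.default_rng(seed)
    mu = (np.full(n, proc.mean_deg) if mean_series is None
          else np.asarray(mean_series, dtype=float))
    if mu.shape != (n,):
        raise ValueError("mean_series must have length n")
    theta = np.empty(n)
    theta[0] = mu[0] if proc.sd_deg == 0 else rng.normal(mu[0], proc.sd_deg)
    if proc.sd_deg == 0:
        return mu.copy()
    eps = rng.normal(0.0, noise_sd, size=n - 1)
    for i in range(1, n):
        theta[i] = mu[i] + rho * (theta[i - 1] - mu[i - 1]) + eps[i - 1]
    return theta


# ---------------------------------------------------------------------------
# spin surrogate
# ---------------------------------------------------------------------------

def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def spin_surrogate(d_RuS, d_RuOmin):
    """Smooth surrogate for the Ru Mulliken spin population.

    Anchored to the electronic-state signatures: ≈0.7 with the thioether
    bound (³MLCT), rising past 1.2 toward ≈1.4 once Ru–S is broken with
    no aqua ligand (³MC), and relaxing toward ≈0.8 when a water oxygen
    coordinates (³P).  Total function of the two distances.
    """
    dS = np.asarray(d_RuS, dtype=float)
    dO = np.asarray(d_RuOmin, dtype=float)
    broken = _logistic((dS - 3.25) / 0.30)
    aqua = _logistic((2.75 - dO) / 0.25)
    return 0.7 + 0.7 * broken - 0.6 * broken * aqua
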