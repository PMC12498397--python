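"""Analytic model potentials over the (Ru–S, Ru–O_min) plane.

The real system evolves on a triplet-state QM/MM hypersurface; here that
engine is replaced by archetype 2D potentials that realize the canonical
ligand-exchange topologies — dissociative (pentacoordinate intermediate),
associative (heptacoordinate intermediate), the interchange family
(no intermediate), and a photoinactive single-basin surface.  Each
archetype is built as a "valley" potential: a reference reaction path in
the (d_RuS, d_RuOmin) plane, a free-energy profile along the path, and a
harmonic confinement transverse to it.  This gives exact control over
where minima and barriers sit, so the archetypes can serve as ground
truth for free-energy reconstruction and mechanism classification.

Coordinates are in Å, energies in kJ/mol.  s1 = d_RuS, s2 = d_RuOmin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

ARCHETYPES = (
    "dissociative",
    "interchange_dissociative",
    "interchange",
    "interchange_associative",
    "associative",
    "inactive",
)


@dataclass(frozen=True)
class ModelPotential:
    """An analytic potential standing in for the triplet hypersurface.

    Parameters
    ----------
    name : label for reports.
    energy : callable mapping an array of shape (d,) or (n, d) to kJ/mol.
    gradient : callable returning dV/dx with the same leading shape.
    known_minima : refined local minima as (location, depth-below-zero)
        pairs; ``depth`` here is simply V at the minimum.
    archetype : one of :data:`ARCHETYPES`, or "" for generic potentials.
    ndim : dimensionality of the coordinate space.
    """

    name: str
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    known_minima: tuple[tuple[tuple[float, ...], float], ...] = ()
    archetype: str = ""
    ndim: int = 2


# ---------------------------------------------------------------------------
# simple 1D potentials used for calibration and unit tests
# ---------------------------------------------------------------------------

def harmonic_potential(k: float, center: float = 0.0) -> ModelPotential:
    """1D harmonic well V = k/2 (x-c)^2, k in kJ/mol/Å²."""
    c = float(center)

    def energy(x):
        x = np.asarray(x, dtype=float)
        return 0.5 * k * (x[..., 0] - c) ** 2

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 0] = k * (x[..., 0] - c)
        return g

    return ModelPotential(
        name=f"harmonic(k={k})", energy=energy, gradient=gradient,
        known_minima=(((c,), 0.0),), ndim=1,
    )


def double_well_potential(barrier: float = 5.0, spacing: float = 1.0,
                          tilt: float = 0.0) -> ModelPotential:
    """1D quartic double well with minima near ±spacing/2.

    V(x) = barrier * ((2x/spacing)^2 - 1)^2 + tilt * x.  With tilt = 0 the
    wells are degenerate; a small tilt makes the analytic population ratio
    exp(-beta * ΔF) nontrivial.
    """
    a = 2.0 / spacing

    def energy(x):
        x = np.asarray(x, dtype=float)
        u = (a * x[..., 0]) ** 2 - 1.0
        return barrier * u * u + tilt * x[..., 0]

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        u = (a * x[..., 0]) ** 2 - 1.0
        g[..., 0] = barrier * 4.0 * a * a * x[..., 0] * u + tilt
        return g

    pot = ModelPotential(
        name=f"double_well(b={barrier})", energy=energy, gradient=gradient,
        ndim=1,
    )
    minima = []
    for x0 in (-spacing / 2, spacing / 2):
        res = minimize(lambda v: float(energy(v)), np.array([x0]),
                       jac=lambda v: np.asarray(gradient(v), dtype=float))
        minima.append(((float(res.x[0]),), float(res.fun)))
    object.__setattr__(pot, "known_minima", tuple(minima))
    return pot


def linear_potential(slope: float) -> ModelPotential:
    """1D linear ramp V = slope * x (kJ/mol/Å); no minima."""

    def energy(x):
        x = np.asarray(x, dtype=float)
        return slope * x[..., 0]

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        g[..., 0] = slope
        return g

    return ModelPotential(name=f"linear({slope})", energy=energy,
                          gradient=gradient, ndim=1)


# ---------------------------------------------------------------------------
# path-valley construction for the 2D archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Profile:
    """Free-energy profile along a path: Gaussians in arclength t∈[0,1]."""
    amplitudes: tuple[float, ...]
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    slope: float = 0.0

    def value(self, t):
        t = np.asarray(t, dtype=float)
        v = self.slope * t
        for a, c, w in zip(self.amplitudes, self.centers, self.widths):
            v = v + a * np.exp(-0.5 * ((t - c) / w) ** 2)
        return v

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        d = np.full_like(t, self.slope)
        for a, c, w in zip(self.amplitudes, self.centers, self.widths):
            d = d - a * ((t - c) / w**2) * np.exp(-0.5 * ((t - c) / w) ** 2)
        return d


class _PathValley:
    """V(x) = profile(t*) + k_perp/2 d² + soft walls, with (t*, d) the
    arclength parameter and distance of the nearest point on a polyline."""

    def __init__(self, waypoints: Sequence[Sequence[float]],
                 profile: _Profile, k_perp: float = 30.0,
                 bounds=((1.8, 6.5), (1.8, 6.5)), k_wall: float = 400.0):
        self.pts = np.asarray(waypoints, dtype=float)
        seg = np.diff(self.pts, axis=0)
        self.seg_vec = seg
        self.seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(self.seg_len)])
        self.total_len = cum[-1]
        self.t0 = cum[:-1] / self.total_len          # segment start arclength
        self.dt = self.seg_len / self.total_len
        self.profile = profile
        self.k_perp = k_perp
        self.bounds = np.asarray(bounds, dtype=float)
        self.k_wall = k_wall

    def _project(self, x):
        """Nearest-segment projection.  x: (n, 2) → t (n,), d² (n,), plus
        the per-point quantities needed for the analytic gradient."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p0 = self.pts[:-1]                              # (m, 2)
        d = self.seg_vec                                # (m, 2)
        ll = self.seg_len**2
        # fractional position on each segment, clamped
        diff = x[:, None, :] - p0[None, :, :]           # (n, m, 2)
        u = np.einsum("nmd,md->nm", diff, d) / ll       # (n, m)
        uc = np.clip(u, 0.0, 1.0)
        foot = p0[None] + uc[..., None] * d[None]       # (n, m, 2)
        dist2 = np.sum((x[:, None, :] - foot) ** 2, axis=-1)
        j = np.argmin(dist2, axis=1)                    # nearest segment
        nn = np.arange(x.shape[0])
        t = self.t0[j] + uc[nn, j] * self.dt[j]
        interior = (u[nn, j] > 0.0) & (u[nn, j] < 1.0)
        return t, dist2[nn, j], foot[nn, j], j, interior

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        t, d2, _, _, _ = self._project(x)
        v = self.profile.value(t) + 0.5 * self.k_perp * d2 + self._wall(np.atleast_2d(x))
        return v[0] if single else v

    def _wall(self, x):
        lo = self.bounds[:, 0][None, :]
        hi = self.bounds[:, 1][None, :]
        below = np.clip(lo - x, 0.0, None)
        above = np.clip(x - hi, 0.0, None)
        return 0.5 * self.k_wall * np.sum(below**2 + above**2, axis=1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xx = np.atleast_2d(x)
        t, _, foot, j, interior = self._project(xx)
        r = xx - foot                                   # ⊥ component (or to endpoint)
        g = self.k_perp * r
        # profile term: dV/dx = profile'(t) * dt/dx; dt/dx = seg_dir/total_len
        # only where the projection falls in a segment interior (elsewhere the
        # foot is a waypoint and t is locally constant).
        dirs = self.seg_vec[j] / self.seg_len[j][:, None]
        dprof = self.profile.derivative(t)
        g = g + np.where(interior[:, None],
                         dprof[:, None] * dirs / self.total_len, 0.0)
        lo = self.bounds[:, 0][None, :]
        hi = self.bounds[:, 1][None, :]
        g = g - self.k_wall * np.clip(lo - xx, 0.0, None)
        g = g + self.k_wall * np.clip(xx - hi, 0.0, None)
        return g[0] if single else g


def _refine_minimum(pot_energy, pot_gradient, x0: np.ndarray) -> tuple[np.ndarray, float]:
    res = minimize(lambda v: float(pot_energy(v)), np.asarray(x0, dtype=float),
                   jac=lambda v: np.asarray(pot_gradient(v), dtype=float),
                   method="L-BFGS-B")
    return res.x, float(res.fun)


#: MLCT anchor shared by all archetypes: bound Ru–S, unbound water.
MLCT_CENTER = (2.3, 4.5)
#: Product anchor: broken Ru–S, coordinated aqua ligand.
PRODUCT_CENTER = (5.0, 2.3)

# (waypoints, profile) per archetype.  Profile Gaussian centers are in
# normalized arclength; negative amplitude = well, positive = barrier.
# Arclength positions of the wells were laid out so that the intermediate
# minima fall where the mechanism taxonomy needs them: the pentacoordinate
# well at (≈4.37, ≈4.36) has both distances beyond the 4.0 Å interaction
# cutoff, the heptacoordinate well at (≈3.06, ≈3.72) has both inside it.
_ARCHETYPE_SPECS: dict[str, tuple[list, _Profile]] = {
    # MLCT → MC (≈3.1, 4.45) → pentacoordinate (≈4.37, 4.36) → product
    "dissociative": (
        [MLCT_CENTER, (4.5, 4.35), PRODUCT_CENTER],
        _Profile(amplitudes=(-8.0, 8.0, -10.0, 6.0, -9.0, 5.0, -14.0),
                 centers=(0.0, 0.10, 0.18, 0.33, 0.48, 0.70, 0.97),
                 widths=(0.04, 0.04, 0.045, 0.05, 0.045, 0.06, 0.06)),
    ),
    # MLCT → TS near (3.6, 4.5) → product; Ru–S crosses 4 Å first
    "interchange_dissociative": (
        [MLCT_CENTER, (4.4, 4.5), PRODUCT_CENTER],
        _Profile(amplitudes=(-8.0, 7.0, -14.0),
                 centers=(0.0, 0.30, 0.97),
                 widths=(0.07, 0.09, 0.06)),
    ),
    # nearly flat diagonal channel; barrier below k_B T
    "interchange": (
        [MLCT_CENTER, PRODUCT_CENTER],
        _Profile(amplitudes=(-1.0, 0.3, -6.0),
                 centers=(0.0, 0.4, 0.95),
                 widths=(0.10, 0.12, 0.10)),
    ),
    # water comes in first: Ru–O_min crosses 4 Å while Ru–S is short
    "interchange_associative": (
        [MLCT_CENTER, (3.2, 3.6), PRODUCT_CENTER],
        _Profile(amplitudes=(-8.0, 7.0, -14.0),
                 centers=(0.0, 0.28, 0.95),
                 widths=(0.07, 0.09, 0.09)),
    ),
    # MLCT → heptacoordinate (≈3.06, 3.72) → product
    "associative": (
        [MLCT_CENTER, (3.0, 3.75), (4.0, 3.2), PRODUCT_CENTER],
        _Profile(amplitudes=(-8.0, 8.0, -10.0, 6.0, -14.0),
                 centers=(0.0, 0.17, 0.31, 0.55, 0.95),
                 widths=(0.05, 0.05, 0.06, 0.08, 0.08)),
    ),
    # single MLCT basin, uphill everywhere else
    "inactive": (
        [MLCT_CENTER, PRODUCT_CENTER],
        _Profile(amplitudes=(-10.0,), centers=(0.0,), widths=(0.08,),
                 slope=30.0),
    ),
}

#: design locations of the minima on each archetype (pre-refinement);
#: used only as starting guesses when the exact minima are computed.
_ARCHETYPE_MINIMA_GUESS = {
    "dissociative": [MLCT_CENTER, (3.08, 4.45), (4.37, 4.36), (4.95, 2.45)],
    "interchange_dissociative": [MLCT_CENTER, (4.95, 2.45)],
    "interchange": [MLCT_CENTER, (4.87, 2.41)],
    "interchange_associative": [MLCT_CENTER, (4.85, 2.41)],
    "associative": [MLCT_CENTER, (3.06, 3.72), (4.87, 2.42)],
    "inactive": [MLCT_CENTER],
}


def archetype_potential(name: str, k_perp: float = 30.0) -> ModelPotential:
    """Build one of the six archetype triplet surfaces by name."""
    if name not in _ARCHETYPE_SPECS:
        raise ValueError(f"unknown archetype {name!r}; choose from {ARCHETYPES}")
    waypoints, profile = _ARCHETYPE_SPECS[name]
    valley = _PathValley(waypoints, profile, k_perp=k_perp)
    minima = tuple(
        (tuple(np.round(loc, 6)), round(val, 6))
        for loc, val in (_refine_minimum(valley.energy, valley.gradient,
                                         np.asarray(g, dtype=float))
                         for g in _ARCHETYPE_MINIMA_GUESS[name])
    )
    return ModelPotential(name=name, energy=valley.energy,
                          gradient=valley.gradient, known_minima=minima,
                          archetype=name, ndim=2)


def singlet_surrogate(archetype: str = "", k1: float = 100.0,
                      k2: float = 50.0) -> ModelPotential:
    """Harmonic stand-in for the *singlet* ground-state surface.

    Photon absorption is vertical: the 95% absorption region is measured
    from unbiased ground-state dynamics, where the complex is intact and
    both coordinates fluctuate around the bound geometry.  All archetypes
    share the MLCT anchor, so this basin is archetype-independent.
    """
    c1, c2 = MLCT_CENTER

    def energy(x):
        x = np.asarray(x, dtype=float)
        return 0.5 * k1 * (x[..., 0] - c1) ** 2 + 0.5 * k2 * (x[..., 1] - c2) ** 2

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        g[..., 0] = k1 * (x[..., 0] - c1)
        g[..., 1] = k2 * (x[..., 1] - c2)
        return g

    return ModelPotential(name=f"singlet_surrogate({archetype})",
                          energy=energy, gradient=gradient,
                          known_minima=(((c1, c2), 0.0),), ndim=2)
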