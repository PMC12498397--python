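"""Enhanced-sampling biases: harmonic umbrella restraints and
well-tempered metadynamics hills.

The protocol combines a ladder of harmonic umbrella windows along the
Ru–S distance (centers 2.50, 2.65, ..., 5.35 Å; k = 350 kJ/mol/Å²) with
a well-tempered metadynamics bias along the minimum Ru–O(water)
distance (initial Gaussian height 2.0 kJ/mol, width 0.1 Å, deposition
pace 50 steps, bias factor γ = 15).  Both biases are represented as
composable energy/force objects shared by the toy simulator and the
free-energy estimators.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import KB


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic umbrella slice along the restrained coordinate."""

    index: int
    center: float                 # Å
    force_constant: float         # kJ/mol/Å²
    equilibration_time: float = 5.0   # ps
    production_time: float = 40.0     # ps

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")


@dataclass(frozen=True)
class Hill:
    """One deposited metadynamics Gaussian."""

    center: float        # Å, along the metadynamics coordinate
    sigma: float         # Å
    height: float        # kJ/mol
    deposit_time: float  # ps

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")


@dataclass
class BiasState:
    """The complete applied bias at any time.

    ``umbrella_cv`` / ``meta_cv`` index the biased coordinates within the
    CV vector (defaults: umbrella on s1 = Ru–S, metadynamics on
    s2 = Ru–O_min; for 1D runs set both to 0 or disable one part).
    """

    window: UmbrellaWindow | None = None
    hills: list[Hill] = field(default_factory=list)
    bias_factor: float = 15.0       # γ, unitless
    initial_height: float = 2.0     # w0, kJ/mol
    sigma: float = 0.1              # Gaussian width, Å
    pace: int = 50                  # integrator steps between deposits
    temperature: float = 300.0      # K, enters the well-tempered rule
    umbrella_cv: int = 0
    meta_cv: int = 1
    metad_enabled: bool = True

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ValueError("bias_factor γ must be > 1")

    # -- well-tempered deposition ------------------------------------------

    @property
    def delta_T(self) -> float:
        """ΔT = (γ − 1)·T of the well-tempered rule."""
        return (self.bias_factor - 1.0) * self.temperature

    def _hill_arrays(self):
        """Cached (centers, sigmas, heights, times) arrays of the hills."""
        key = (len(self.hills), id(self.hills))
        cached = getattr(self, "_cache", None)
        if cached is None or cached[0] != key:
            arr = (np.array([h.center for h in self.hills]),
                   np.array([h.sigma for h in self.hills]),
                   np.array([h.height for h in self.hills]),
                   np.array([h.deposit_time for h in self.hills]))
            object.__setattr__(self, "_cache", (key, arr))
            return arr
        return cached[1]

    def hills_energy(self, s, t: float | None = None):
        """Metadynamics bias from hills with deposit_time ≤ t, at point(s)
        s along the metadynamics coordinate."""
        s = np.asarray(s, dtype=float)
        if not self.hills:
            return np.zeros_like(s)
        c, sg, h, times = self._hill_arrays()
        if t is not None:
            keep = times <= t
            c, sg, h = c[keep], sg[keep], h[keep]
        z = (s[..., None] - c) / sg
        return np.einsum("...k,k->...", np.exp(-0.5 * z * z), h)

    def hills_force(self, s, t: float | None = None):
        """-d/ds of the hills energy."""
        s = np.asarray(s, dtype=float)
        if not self.hills:
            return np.zeros_like(s)
        c, sg, h, times = self._hill_arrays()
        if t is not None:
            keep = times <= t
            c, sg, h = c[keep], sg[keep], h[keep]
        d = s[..., None] - c
        g = np.exp(-0.5 * (d / sg) ** 2) * h
        return np.sum(g * d / sg**2, axis=-1)


def make_window_schedule(start: float, step: float, n_windows: int,
                         force_constant: float,
                         equilibration_time: float = 5.0,
                         production_time: float = 40.0) -> list[UmbrellaWindow]:
    """Arithmetic ladder of umbrella windows: centers start, start+step, ...

    The default protocol, ``make_window_schedule(2.50, 0.15, 20, 350)``,
    spans 2.50–5.35 Å in 20 slices.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    return [
        UmbrellaWindow(index=i, center=start + i * step,
                       force_constant=force_constant,
                       equilibration_time=equilibration_time,
                       production_time=production_time)
        for i in range(n_windows)
    ]


def umbrella_energy(window: UmbrellaWindow, s):
    """½·k·(s − s0)² in kJ/mol."""
    s = np.asarray(s, dtype=float)
    return 0.5 * window.force_constant * (s - window.center) ** 2


def umbrella_force(window: UmbrellaWindow, s):
    """-d/ds of the umbrella energy."""
    s = np.asarray(s, dtype=float)
    return -window.force_constant * (s - window.center)


def deposit_hill(state: BiasState, s_now: float, t: float) -> BiasState:
    """Append one well-tempered hill at the current position.

    The new height follows the tempering rule
    w = w0 · exp(−V(s_now, t) / (k_B ΔT)) with ΔT = (γ−1)·T, so heights
    decay geometrically wherever the bias has already accumulated.
    Returns a new BiasState; the input is not mutated.
    """
    v_here = float(state.hills_energy(np.asarray([s_now]), t)[0])
    w = state.initial_height * np.exp(-v_here / (KB * state.delta_T))
    new = replace(state)
    new.hills = list(state.hills) + [
        Hill(center=float(s_now), sigma=state.sigma, height=float(w),
             deposit_time=float(t))
    ]
    return new


def bias_energy(state: BiasState, cv, t: float | None = None):
    """Total bias (umbrella + hills up to time t) at CV vector(s) ``cv``.

    ``cv`` has shape (d,) or (n, d); returns scalar or (n,).
    """
    cv = np.asarray(cv, dtype=float)
    single = cv.ndim == 1
    cc = np.atleast_2d(cv)
    d = cc.shape[1]
    meta_cv = state.meta_cv if d > 1 else 0
    umb_cv = state.umbrella_cv if d > 1 else 0
    v = np.zeros(cc.shape[0])
    if state.metad_enabled:
        v = v + state.hills_energy(cc[:, meta_cv], t)
    if state.window is not None:
        v = v + umbrella_energy(state.window, cc[:, umb_cv])
    return float(v[0]) if single else v


def bias_force(state: BiasState, cv, t: float | None = None):
    """-∇(total bias) with respect to the CV vector."""
    cv = np.asarray(cv, dtype=float)
    single = cv.ndim == 1
    cc = np.atleast_2d(cv)
    d = cc.shape[1]
    meta_cv = state.meta_cv if d > 1 else 0
    umb_cv = state.umbrella_cv if d > 1 else 0
    f = np.zeros_like(cc)
    if state.metad_enabled:
        f[:, meta_cv] += state.hills_force(cc[:, meta_cv], t)
    if state.window is not None:
        f[:, umb_cv] += umbrella_force(state.window, cc[:, umb_cv])
    return f[0] if single else f


# ---------------------------------------------------------------------------
# PLUMED-dialect HILLS files
# ---------------------------------------------------------------------------

_HILLS_FIELDS = ["time", "center", "sigma", "height", "biasf"]


def write_hills(path, state: BiasState) -> None:
    """Write deposited hills as a PLUMED-style HILLS text table."""
    lines = ["#! FIELDS " + " ".join(_HILLS_FIELDS)]
    for h in state.hills:
        lines.append(f"{h.deposit_time:.6f} {h.center:.9f} {h.sigma:.9f} "
                     f"{h.height:.9f} {state.bias_factor:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path) -> BiasState:
    """Read a HILLS table back into a BiasState (no umbrella attached)."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    required = set(_HILLS_FIELDS)
    if not required.issubset(fields):
        missing = required - set(fields)
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    idx = {name: fields.index(name) for name in fields}
    data = np.loadtxt(_io.StringIO("\n".join(lines[1:])), ndmin=2)
    biasf = float(data[0, idx["biasf"]]) if len(data) else 15.0
    hills = [
        Hill(center=row[idx["center"]], sigma=row[idx["sigma"]],
             height=row[idx["height"]], deposit_time=row[idx["time"]])
        for row in data
    ]
    state = BiasState(bias_factor=biasf)
    state.hills = hills
    if hills:
        state.sigma = hills[0].sigma
    return state
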