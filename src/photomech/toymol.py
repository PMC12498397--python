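"""Synthetic Cartesian frames of a toy Ru complex.

Builds minimal atomistic frames (Ru, S, the four chelate atoms, and a
solvent-oxygen bath) that realize a requested CV tuple exactly, so the
geometry code in :mod:`photomech.colvar` can be exercised round-trip:
build a frame from (d_RuS, d_RuOmin, α, θ), re-measure, and recover the
inputs to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colvar import RoleMap, chelate_dihedral

ELEMENTS_CORE = ("Ru", "S", "N", "C", "N", "C")


@dataclass
class Trajectory:
    """A stack of Cartesian frames plus the role map."""

    frames: np.ndarray          # (n_frames, n_atoms, 3), Å
    elements: tuple[str, ...]
    roles: RoleMap
    times: np.ndarray | None = None


@dataclass(frozen=True)
class ToyComplexTemplate:
    """Reference geometry and placement rules for the toy complex.

    The chelate reference is planar (θ = 0) with all four N/C atoms in
    the x–z plane; bending rotates the trans half-plane about the
    Ru→N_T axis.  The incoming oxygen is placed in the y–z plane at the
    requested attack angle from the Ru→S axis.  Decoy solvent oxygens
    are placed at least ``decoy_margin`` Å farther out than d_RuOmin so
    the nearest-oxygen search is exercised nontrivially.
    """

    ru_n: float = 2.05          # Å, Ru–N bond length
    n_decoys: int = 25
    decoy_margin: float = 0.5   # Å

    # reference chelate positions at θ = 0 (Ru at the origin)
    def _reference(self) -> dict[str, np.ndarray]:
        d = self.ru_n
        return {
            "N_C": np.array([d, 0.0, 0.0]),
            "C_C": np.array([d + 0.95, 0.0, 0.70]),
            "N_T": np.array([0.0, 0.0, -d]),
            "C_T": np.array([1.20, 0.0, -d - 0.65]),
        }


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_frame(template: ToyComplexTemplate, d_RuS: float, d_RuOmin: float,
                alpha: float, theta: float,
                rng: np.random.Generator) -> tuple[np.ndarray, RoleMap]:
    """One frame realizing the CV tuple exactly.  See :func:`build_frames`."""
    if d_RuS <= 0 or d_RuOmin <= 0:
        raise ValueError(f"distances must be > 0 (d_RuS={d_RuS}, "
                         f"d_RuOmin={d_RuOmin})")
    if not 0.0 <= alpha <= 180.0:
        raise ValueError(f"attack angle must lie in [0, 180], got {alpha}")
    ref = template._reference()
    ru = np.zeros(3)
    s_pos = np.array([0.0, 0.0, d_RuS])
    # bend the trans half-plane about the Ru→N_T axis (the z axis)
    c_t = _rot_z(theta) @ ref["C_T"]
    a = np.radians(alpha)
    o_min = d_RuOmin * np.array([0.0, np.sin(a), np.cos(a)])
    lo = d_RuOmin + template.decoy_margin
    radii = rng.uniform(lo, lo + 3.0, size=template.n_decoys)
    dirs = rng.normal(size=(template.n_decoys, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    decoys = radii[:, None] * dirs
    frame = np.vstack([ru, s_pos, ref["N_C"], ref["C_C"], ref["N_T"], c_t,
                       o_min, decoys])
    roles = RoleMap(Ru=0, S=1, N_C=2, C_C=3, N_T=4, C_T=5,
                    solvent_O=tuple(range(6, 7 + template.n_decoys)))
    # the rotation direction realizing a *positive* measured θ depends on
    # the sign convention of chelate_dihedral; fix it by measurement
    if abs(theta) > 1e-12:
        measured = chelate_dihedral(frame, roles)
        if measured * theta < 0:
            frame[5] = _rot_z(-theta) @ ref["C_T"]
    return frame, roles


def build_frames(template: ToyComplexTemplate, cv_path: pd.DataFrame,
                 theta=None, seed: int = 0) -> Trajectory:
    """Realize a CV path as Cartesian frames.

    ``cv_path`` needs columns ``d_RuS`` and ``d_RuOmin`` (or ``s1``/``s2``)
    and optionally ``alpha``; ``theta`` is a per-frame series of signed
    dihedrals (defaults to 0).  Unrealizable tuples raise with the
    offending row index.
    """
    df = cv_path.rename(columns={"s1": "d_RuS", "s2": "d_RuOmin"})
    n = len(df)
    alpha = (df["alpha"].to_numpy(dtype=float) if "alpha" in df
             else np.full(n, 60.0))
    th = np.zeros(n) if theta is None else np.asarray(theta, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    roles = None
    for i in range(n):
        try:
            frame, roles = build_frame(
                template, float(df["d_RuS"].iloc[i]),
                float(df["d_RuOmin"].iloc[i]), float(alpha[i]), float(th[i]),
                rng)
        except ValueError as exc:
            raise ValueError(f"unrealizable CV tuple at row {i}: {exc}") from exc
        frames.append(frame)
    elements = ELEMENTS_CORE + ("O",) * (1 + template.n_decoys)
    times = (df["time"].to_numpy(dtype=float) if "time" in df
             else np.arange(n, dtype=float))
    return Trajectory(frames=np.asarray(frames), elements=elements,
                      roles=roles, times=times)
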