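"""Collective variables from Cartesian trajectories.

The four reaction coordinates of the analysis are the Ru–S distance,
the minimum Ru–O(water) distance, the S–Ru–O_min attack angle α, and
the signed dihedral θ between the two chelate half-planes Ru–N_C–C_C
and Ru–N_T–C_T (N_C/C_C cis and N_T/C_T trans to the sulfur).

Atoms are identified by an explicit role map of indices, never by
element sniffing: XYZ files carry no residue information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical CV column names used across the package
CV_COLUMNS = ("time", "d_RuS", "d_RuOmin", "alpha", "theta")


@dataclass(frozen=True)
class RoleMap:
    """Atom indices of the chemically meaningful sites in a frame."""

    Ru: int
    S: int
    N_C: int
    C_C: int
    N_T: int
    C_T: int
    solvent_O: tuple[int, ...] = ()

    def __post_init__(self):
        core = (self.Ru, self.S, self.N_C, self.C_C, self.N_T, self.C_T)
        idx = core + tuple(self.solvent_O)
        if len(set(idx)) != len(idx):
            raise ValueError("role indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("role indices must be non-negative")

    def validate(self, n_atoms: int) -> None:
        for name in ("Ru", "S", "N_C", "C_C", "N_T", "C_T"):
            if getattr(self, name) >= n_atoms:
                raise IndexError(f"role {name} index out of bounds "
                                 f"({getattr(self, name)} >= {n_atoms})")
        for i in self.solvent_O:
            if i >= n_atoms:
                raise IndexError(f"solvent oxygen index {i} out of bounds")


@dataclass(frozen=True)
class CVFrame:
    """Per-frame collective variables."""

    time: float            # ps
    d_RuS: float           # Å
    d_RuOmin: float        # Å
    alpha: float           # degrees in [0, 180], S–Ru–O_min
    theta: float           # degrees signed in (−180, 180]
    spin_Ru: float | None = None
    monodentate_flag: bool = False  # either Ru–N beyond 4.0 Å


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def chelate_dihedral(frame: np.ndarray, roles: RoleMap) -> float:
    """Signed dihedral θ (degrees) between the two chelate half-planes.

    θ is the angle between the normals of planes (Ru, N_C, C_C) and
    (Ru, N_T, C_T); the sign is that of the triple product
    (n_C × n_T)·(Ru → midpoint of N_C, N_T), an arbitrary but fixed
    orientation convention — downstream folding onto [0°, 90°] erases it.
    """
    frame = np.asarray(frame, dtype=float)
    roles.validate(len(frame))
    ru = frame[roles.Ru]
    n_c = np.cross(frame[roles.N_C] - ru, frame[roles.C_C] - ru)
    n_t = np.cross(frame[roles.N_T] - ru, frame[roles.C_T] - ru)
    for name, n in (("cis", n_c), ("trans", n_t)):
        if np.linalg.norm(n) < 1e-10:
            raise ValueError(f"collinear atoms: {name} chelate plane undefined")
    cross = np.cross(n_c, n_t)
    mag = float(np.degrees(np.arctan2(np.linalg.norm(cross),
                                      float(np.dot(n_c, n_t)))))
    ref = 0.5 * (frame[roles.N_C] + frame[roles.N_T]) - ru
    sign = np.sign(np.dot(cross, ref))
    return mag if sign >= 0 else -mag


def measure_cv(frame: np.ndarray, roles: RoleMap, time: float = 0.0,
               spin: float | None = None,
               monodentate_cutoff: float = 4.0) -> CVFrame:
    """Measure all CVs on one Cartesian frame (Å).

    d_RuOmin is the minimum over the role map's solvent oxygens; α is
    the angle at Ru between Ru→S and Ru→O_min.  Frames where either
    Ru–N chelate bond exceeds ``monodentate_cutoff`` are flagged, not
    dropped.
    """
    frame = np.asarray(frame, dtype=float)
    roles.validate(len(frame))
    if not roles.solvent_O:
        raise ValueError("role map has no solvent oxygens: d_RuOmin undefined")
    ru = frame[roles.Ru]
    d_RuS = float(np.linalg.norm(frame[roles.S] - ru))
    o_pos = frame[list(roles.solvent_O)]
    dists = np.linalg.norm(o_pos - ru, axis=1)
    i_min = int(np.argmin(dists))
    d_RuOmin = float(dists[i_min])
    alpha = _angle_deg(frame[roles.S] - ru, o_pos[i_min] - ru)
    theta = chelate_dihedral(frame, roles)
    mono = (np.linalg.norm(frame[roles.N_C] - ru) > monodentate_cutoff or
            np.linalg.norm(frame[roles.N_T] - ru) > monodentate_cutoff)
    return CVFrame(time=time, d_RuS=d_RuS, d_RuOmin=d_RuOmin, alpha=alpha,
                   theta=theta, spin_Ru=spin, monodentate_flag=mono)


def measure_series(frames: np.ndarray, roles: RoleMap,
                   times=None) -> pd.DataFrame:
    """Measure CVs over a stack of frames (n_frames, n_atoms, 3)."""
    frames = np.asarray(frames, dtype=float)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    rows = [measure_cv(f, roles, time=t) for f, t in zip(frames, times)]
    return pd.DataFrame({
        "time": [r.time for r in rows],
        "d_RuS": [r.d_RuS for r in rows],
        "d_RuOmin": [r.d_RuOmin for r in rows],
        "alpha": [r.alpha for r in rows],
        "theta": [r.theta for r in rows],
        "monodentate_flag": [r.monodentate_flag for r in rows],
    })


def quasi_uniform_subsample(series: pd.DataFrame, n_out: int,
                            columns=("d_RuS", "d_RuOmin")) -> pd.DataFrame:
    """Greedy farthest-point subsample in CV space (delta-net style).

    Selects ``n_out`` rows so that the minimum pairwise distance among
    the selected points is greedily maximized: start from the point
    farthest from the centroid, then repeatedly add the point farthest
    from the current selection.
    """
    if len(series) == 0:
        raise ValueError("cannot subsample an empty series")
    if n_out > len(series):
        raise ValueError(f"n_out={n_out} exceeds series length {len(series)}")
    pts = series.loc[:, list(columns)].to_numpy(dtype=float)
    n = len(pts)
    if n_out == n:
        return series.copy()
    centroid = pts.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(pts - centroid, axis=1)))
    chosen = [first]
    min_dist = np.linalg.norm(pts - pts[first], axis=1)
    for _ in range(n_out - 1):
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist,
                              np.linalg.norm(pts - pts[nxt], axis=1))
    return series.iloc[sorted(chosen)].copy()
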