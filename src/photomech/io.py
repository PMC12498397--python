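"""File formats: PLUMED-dialect COLVAR tables, multi-frame XYZ, PDB
reading, and role-map JSON.

COLVAR/HILLS files are plain whitespace tables with a
``#! FIELDS time ...`` header; column order is not significant.
Trajectory reading goes through MDAnalysis; the XYZ writer is a minimal
conformant implementation (element + x y z in Å per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .colvar import RoleMap
from .toymol import Trajectory

#: columns a COLVAR file must provide (beyond these, extras are kept)
MANDATORY_COLVAR = ("time",)


def write_colvar(path, series: pd.DataFrame) -> None:
    """Write a CV series as PLUMED-style COLVAR text."""
    cols = list(series.columns)
    if "time" not in cols:
        raise ValueError("series must have a 'time' column")
    lines = ["#! FIELDS " + " ".join(cols)]
    for row in series.itertuples(index=False):
        lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{float(v):.12g}"


def read_colvar(path, mandatory=MANDATORY_COLVAR) -> pd.DataFrame:
    """Parse a COLVAR file; column order independent, extras preserved.

    Raises a named-column error when a mandatory column is missing and
    reports the line number of any malformed row.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    for col in mandatory:
        if col not in fields:
            raise ValueError(f"{path}: mandatory column {col!r} missing "
                             f"(found {fields})")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != len(fields):
            raise ValueError(f"{path}:{lineno}: expected {len(fields)} "
                             f"columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=fields)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_xyz(path, traj: Trajectory, comment: str = "") -> None:
    """Multi-frame XYZ: element symbol + Cartesian Å per atom."""
    n_atoms = traj.frames.shape[1]
    out = []
    for k, frame in enumerate(traj.frames):
        out.append(str(n_atoms))
        t = traj.times[k] if traj.times is not None else k
        out.append(f"{comment} frame={k} time={t}".strip())
        for el, (x, y, z) in zip(traj.elements, frame):
            out.append(f"{el} {x:.9f} {y:.9f} {z:.9f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_trajectory(path, roles: RoleMap | None = None) -> Trajectory:
    """Read a multi-frame XYZ or PDB file via MDAnalysis."""
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
        elements = tuple(
            str(nm) for nm in getattr(u.atoms, "names", [""] * len(u.atoms)))
    return Trajectory(frames=frames, elements=elements, roles=roles)


def write_role_map(path, roles: RoleMap) -> None:
    payload = {"Ru": roles.Ru, "S": roles.S, "N_C": roles.N_C,
               "C_C": roles.C_C, "N_T": roles.N_T, "C_T": roles.C_T,
               "solvent_O": list(roles.solvent_O)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_role_map(path) -> RoleMap:
    d = json.loads(Path(path).read_text())
    return RoleMap(Ru=d["Ru"], S=d["S"], N_C=d["N_C"], C_C=d["C_C"],
                   N_T=d["N_T"], C_T=d["C_T"],
                   solvent_O=tuple(d.get("solvent_O", ())))
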