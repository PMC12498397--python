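"""Electronic-state labels, the photon-absorption region, attack
statistics, and mechanism classification.

The taxonomy follows the classical ligand-exchange families: a
*dissociative* path visits a pentacoordinate intermediate (both Ru–S
and Ru–O_min beyond the 4.0 Å interaction cutoff), an *associative*
path a heptacoordinate one (both inside the cutoff, beyond the MLCT
region), and the *interchange* family has no intermediate — sub-typed
by whether the Ru–S or the Ru–O_min distance crosses the cutoff first
along the minimum-energy path, or left plain when the path is flat
(barrier below k_B T).  A surface whose only minima sit inside the
MLCT absorption region is *photoinactive*.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KB
from .fes import (FESGrid, PathNotFoundError, find_features,
                  minimum_energy_path, smooth_masked)

MECHANISMS = ("dissociative", "interchange_dissociative", "interchange",
              "interchange_associative", "associative", "photoinactive")


@dataclass(frozen=True)
class StateThresholds:
    """Spin and distance thresholds for state labels, Å / unitless."""

    mlct_spin: float = 0.7        # center of the MLCT spin band
    mlct_spin_band: float = 0.2   # half-width of that band
    mc_spin: float = 1.2          # ³MC onset
    interaction_cutoff: float = 4.0
    product_bond: float = 2.5
    cutoff_margin: float = 0.25   # Å, borderline-verdict margin

    def __post_init__(self):
        if self.mc_spin <= self.mlct_spin:
            raise ValueError("mc_spin must exceed mlct_spin")
        if self.interaction_cutoff <= self.product_bond:
            raise ValueError("interaction_cutoff must exceed product_bond")


@dataclass(frozen=True)
class AbsorptionRegion:
    """Axis-aligned 95% photon-absorption ellipse on the (s1, s2) plane.

    Center = per-CV means of the unbiased ground-state run, semi-axes =
    1.96·σ per CV (the per-axis convention: the protocol computes per-CV
    standard deviations, not a covariance ellipse).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    coverage: float = 0.95
    degenerate: bool = False

    def contains(self, s1, s2) -> np.ndarray:
        a = self.semi_axes[0] if self.semi_axes[0] > 0 else 1e-12
        b = self.semi_axes[1] if self.semi_axes[1] > 0 else 1e-12
        z = (((np.asarray(s1, dtype=float) - self.center[0]) / a) ** 2
             + ((np.asarray(s2, dtype=float) - self.center[1]) / b) ** 2)
        return z <= 1.0


@dataclass
class AttackStatistics:
    cis_pct: float | None
    trans_pct: float | None
    n_qualifying: int
    cutoff: float

    @property
    def empty(self) -> bool:
        return self.n_qualifying == 0


@dataclass
class MechanismReport:
    mechanism: str
    cis_pct: float | None
    trans_pct: float | None
    dominant_pathway: str | None
    intermediates: list[dict]
    path: list[tuple[int, int]]
    path_max_barrier: float | None
    borderline: bool = False
    notes: list[str] = field(default_factory=list)
    spin_gated: bool = False

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["path"] = [list(p) for p in self.path]
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [f"mechanism: {self.mechanism}"
                 + (" (borderline)" if self.borderline else "")]
        if self.cis_pct is not None:
            lines.append(f"attack split: cis {self.cis_pct:.1f}% / "
                         f"trans {self.trans_pct:.1f}% "
                         f"(dominant: {self.dominant_pathway})")
        for im in self.intermediates:
            loc = ", ".join(f"{x:.2f}" for x in im["location"])
            lines.append(f"  intermediate {im['label']} at ({loc}) Å, "
                         f"depth {im['depth']:.2f} kJ/mol")
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def attack_statistics(samples: pd.DataFrame,
                      cutoff: float = 4.0) -> AttackStatistics:
    """cis/trans percentages among samples with d_RuOmin < cutoff.

    cis means α ≤ 90° (ties to cis), trans α > 90°.  Percentages are
    reported to one decimal; with no qualifying sample an explicit
    empty-statistics result is returned rather than 0/0.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    col = "d_RuOmin" if "d_RuOmin" in samples.columns else "s2"
    d = samples[col].to_numpy(dtype=float)
    alpha = samples["alpha"].to_numpy(dtype=float)
    qual = d < cutoff
    n = int(qual.sum())
    if n == 0:
        return AttackStatistics(None, None, 0, cutoff)
    cis = float(np.round(100.0 * np.sum(alpha[qual] <= 90.0) / n, 1))
    trans = float(np.round(100.0 - cis, 1))
    return AttackStatistics(cis, trans, n, cutoff)


def label_state(cv, thr: StateThresholds = StateThresholds()) -> str:
    """Electronic-state label for one CV frame with a spin value.

    Rules, applied in order: MC (spin ≥ mc_spin with the Ru–S bond
    elongated), MLCT (spin in the 0.7 band with Ru–S still short), P
    (aqua coordinated after Ru–S rupture), pentacoordinate (both
    distances beyond the interaction cutoff), else unassigned.
    """
    spin = getattr(cv, "spin_Ru", None)
    if spin is None:
        raise ValueError("spin_Ru missing: cannot label electronic state")
    d_s = cv.d_RuS
    d_o = cv.d_RuOmin
    if spin >= thr.mc_spin and d_s > thr.product_bond:
        return "MC"
    if abs(spin - thr.mlct_spin) <= thr.mlct_spin_band and d_s <= 3.0:
        return "MLCT"
    if d_o <= thr.product_bond and d_s > thr.interaction_cutoff:
        return "P"
    if d_s > thr.interaction_cutoff and d_o > thr.interaction_cutoff:
        return "pentacoordinate"
    return "unassigned"


def absorption_region(unbiased: pd.DataFrame,
                      min_frames: int = 100) -> AbsorptionRegion:
    """95% photon-absorption region from unbiased ground-state dynamics.

    Axis-aligned ellipse centered at the per-CV means with semi-axes
    1.96·σ (population σ per CV).  A zero-variance series yields a
    degenerate point region, flagged.
    """
    if len(unbiased) < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {len(unbiased)}")
    cols = [c for c in ("s1", "s2", "d_RuS", "d_RuOmin")
            if c in unbiased.columns][:2]
    x = unbiased[cols[0]].to_numpy(dtype=float)
    y = unbiased[cols[1]].to_numpy(dtype=float)
    sx, sy = float(np.std(x)), float(np.std(y))
    sx = 0.0 if sx < 1e-12 else sx
    sy = 0.0 if sy < 1e-12 else sy
    return AbsorptionRegion(center=(float(np.mean(x)), float(np.mean(y))),
                            semi_axes=(1.96 * sx, 1.96 * sy),
                            degenerate=(sx == 0.0 and sy == 0.0))


def _classify_minimum(loc, region: AbsorptionRegion,
                      thr: StateThresholds) -> str:
    s1, s2 = loc
    if bool(region.contains(s1, s2)):
        return "MLCT"
    if s1 > thr.interaction_cutoff and s2 > thr.interaction_cutoff:
        return "pentacoordinate"
    # the product basin is classified with the borderline margin so that
    # binning jitter around d_RuOmin ≈ product_bond does not relabel it
    if s2 <= thr.product_bond + thr.cutoff_margin and s1 > thr.product_bond:
        return "P"
    if s1 <= thr.interaction_cutoff and s2 <= thr.interaction_cutoff:
        return "heptacoordinate"
    return "MC"


def _region_bin(grid: FESGrid, region: AbsorptionRegion):
    """Sampled bin nearest the absorption-region center."""
    c1, c2 = grid.centers()
    i = int(np.clip(np.argmin(np.abs(c1 - region.center[0])), 0, None))
    j = int(np.clip(np.argmin(np.abs(c2 - region.center[1])), 0, None))
    if grid.sampled_mask[i, j]:
        return (i, j)
    # nearest sampled bin by center distance
    ii, jj = np.nonzero(grid.sampled_mask)
    if len(ii) == 0:
        raise ValueError("grid has no sampled bins")
    d2 = (c1[ii] - region.center[0]) ** 2 + (c2[jj] - region.center[1]) ** 2
    k = int(np.argmin(d2))
    return (int(ii[k]), int(jj[k]))


def _product_bin(grid: FESGrid, thr: StateThresholds):
    """Lowest-F sampled bin in the product region (aqua bound, S gone)."""
    c1, c2 = grid.centers()
    C1, C2 = np.meshgrid(c1, c2, indexing="ij")
    cand = grid.sampled_mask & (C2 <= thr.product_bond + thr.cutoff_margin) \
        & (C1 > thr.interaction_cutoff)
    if not cand.any():
        return None
    F = np.where(cand, grid.F, np.inf)
    k = np.unravel_index(np.argmin(F), F.shape)
    return (int(k[0]), int(k[1]))


def classify_mechanism(cis_grid: FESGrid, trans_grid: FESGrid,
                       region: AbsorptionRegion,
                       thr: StateThresholds = StateThresholds(),
                       attack: AttackStatistics | None = None,
                       spin_field=None,
                       min_depth: float = 1.5,
                       max_level_kBT: float = 10.0,
                       barrier_smooth_A: float = 0.2) -> MechanismReport:
    """Assign the photosubstitution mechanism from the cis/trans surfaces.

    The dominant pathway (larger qualifying-sample percentage) is
    analyzed: minima beyond the MLCT absorption region are labeled by
    geometry (pentacoordinate / heptacoordinate / MC / P), optionally
    gated by a per-bin spin field for the MC label; the minimum-energy
    path from the absorption region to the product region determines
    interchange sub-typing by cutoff-crossing order.  A surface with no
    minima beyond the MLCT region on either grid is photoinactive.

    Only low-lying minima count as intermediates: bins more than
    ``max_level_kBT``·k_B T above the surface minimum are thermally
    irrelevant, and on reconstructed surfaces the sampling noise in such
    high-free-energy fringes would otherwise masquerade as features.

    All decisions (feature detection and the path barrier) are taken on
    a copy of the surface smoothed at ``barrier_smooth_A`` (default
    0.2 Å, twice the metadynamics kernel width): reconstruction noise is
    correlated at the kernel width, while genuine intermediates and
    transition regions are several times broader and survive the blur.
    """
    if cis_grid.ndim != 2 or trans_grid.ndim != 2:
        raise ValueError("classification requires 2D grids")
    ceiling = max_level_kBT * KB * cis_grid.temperature

    def decision_surface(grid):
        bin_w = (grid.axis1.hi - grid.axis1.lo) / grid.axis1.n_bins
        Fs = smooth_masked(grid.F, grid.sampled_mask,
                           sigma=barrier_smooth_A / bin_w)
        Fs = np.where(grid.sampled_mask, Fs, np.nan)
        return FESGrid(axis1=grid.axis1, axis2=grid.axis2, F=Fs,
                       counts=grid.counts, sampled_mask=grid.sampled_mask,
                       temperature=grid.temperature)

    cis_s = decision_surface(cis_grid)
    trans_s = decision_surface(trans_grid)

    def minima_beyond(grid):
        feats = [f for f in find_features(grid, min_depth=min_depth)
                 if f.kind == "minimum" and f.value <= ceiling]
        out = []
        for f in feats:
            label = _classify_minimum(f.location, region, thr)
            if label != "MLCT":
                out.append((f, label))
        return out

    cis_min = minima_beyond(cis_s)
    trans_min = minima_beyond(trans_s)

    if not cis_min and not trans_min:
        return MechanismReport(
            mechanism="photoinactive",
            cis_pct=attack.cis_pct if attack else None,
            trans_pct=attack.trans_pct if attack else None,
            dominant_pathway=None, intermediates=[], path=[],
            path_max_barrier=None,
            notes=["no minima beyond the MLCT absorption region on either "
                   "surface"])

    if attack is not None and not attack.empty:
        dominant = "cis" if attack.cis_pct >= attack.trans_pct else "trans"
    else:
        dominant = "cis" if cis_min else "trans"
    grid = cis_s if dominant == "cis" else trans_s
    minima = cis_min if dominant == "cis" else trans_min
    if not minima:   # dominant surface featureless; fall back to the other
        dominant = "trans" if dominant == "cis" else "cis"
        grid = cis_s if dominant == "cis" else trans_s
        minima = cis_min if dominant == "cis" else trans_min

    notes = []
    spin_gated = spin_field is not None
    if spin_gated:
        gated = []
        for f, label in minima:
            if label == "MC":
                s = float(spin_field[f.index])
                if s < thr.mc_spin:
                    notes.append(f"minimum at {f.location} geometrically "
                                 f"MC-like but spin {s:.2f} < {thr.mc_spin}")
                    label = "unassigned"
            gated.append((f, label))
        minima = gated

    intermediates = [
        {"label": label, "location": list(f.location), "depth": f.depth,
         "F": f.value}
        for f, label in minima
    ]

    start = _region_bin(grid, region)
    endb = _product_bin(grid, thr)
    path: list = []
    barrier = None
    crossing = None
    if endb is not None:
        try:
            path = minimum_energy_path(grid, start, endb)
            barrier = float(np.nanmax([grid.F[p] for p in path])
                            - grid.F[start])
            crossing = _crossing_order(grid, path, thr)
        except PathNotFoundError as exc:
            notes.append(str(exc))
    else:
        notes.append("product region (aqua bound, Ru–S broken) not sampled")

    labels = {label for _, label in minima}
    borderline = False
    if "pentacoordinate" in labels:
        mech = "dissociative"
    elif "heptacoordinate" in labels:
        mech = "associative"
        # soft criterion: an intermediate hugging the cutoff is borderline
        for f, label in minima:
            if label == "heptacoordinate":
                s1, s2 = f.location
                if (thr.interaction_cutoff - max(s1, s2)
                        < thr.cutoff_margin):
                    borderline = True
                    notes.append("heptacoordinate intermediate lies within "
                                 f"{thr.cutoff_margin} Å of the interaction "
                                 "cutoff")
    else:
        kBT = KB * grid.temperature
        if barrier is not None and barrier < kBT:
            mech = "interchange"
        elif crossing == "s1_first":
            mech = "interchange_dissociative"
        elif crossing == "s2_first":
            mech = "interchange_associative"
        else:
            mech = "interchange"
            if barrier is None:
                notes.append("no minimum-energy path available; plain "
                             "interchange by default")

    if not path and endb is None and mech not in ("photoinactive",):
        if not labels:
            mech = "indeterminate"
            notes.append("no product region and no photoinactive signature")

    return MechanismReport(
        mechanism=mech,
        cis_pct=attack.cis_pct if attack else None,
        trans_pct=attack.trans_pct if attack else None,
        dominant_pathway=dominant, intermediates=intermediates,
        path=path, path_max_barrier=barrier, borderline=borderline,
        notes=notes, spin_gated=spin_gated)


def _crossing_order(grid: FESGrid, path, thr: StateThresholds):
    """Which coordinate crosses the interaction cutoff first along the MEP.

    s1 (Ru–S) crosses upward through the cutoff; s2 (Ru–O_min) crosses
    downward.  Returns "s1_first", "s2_first", or None when a crossing
    is missing.
    """
    c1, c2 = grid.centers()
    s1 = np.array([c1[i] for i, _ in path])
    s2 = np.array([c2[j] for _, j in path])
    up = np.nonzero(s1 > thr.interaction_cutoff)[0]
    dn = np.nonzero(s2 < thr.interaction_cutoff)[0]
    i_up = int(up[0]) if len(up) else None
    i_dn = int(dn[0]) if len(dn) else None
    if i_up is None or i_dn is None:
        return None
    return "s1_first" if i_up < i_dn else "s2_first"
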