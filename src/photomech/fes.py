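"""Free-energy surfaces from biased sampling.

Umbrella-window samples are combined by self-consistent WHAM iteration;
the well-tempered metadynamics bias is removed by quasi-static
final-bias reweighting (per-sample weights ∝ exp(+β·V_meta(s2)) with the
bias frozen at its final state).  The reconstructed surface lives on an
:class:`FESGrid`, the central object every downstream classifier reads:
binned free energies with a sampled-mask, gauge-fixed so the lowest
sampled bin is zero.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import BiasState, Hill, UmbrellaWindow, bias_energy, umbrella_energy
from .constants import beta

_NEIGHBORS_8 = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]


class PathNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class Axis:
    name: str
    lo: float
    hi: float
    n_bins: int

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class FESGrid:
    """Binned free-energy surface over one or two collective variables.

    ``F`` is NaN on unsampled bins; over sampled bins its minimum is 0.
    """

    axis1: Axis
    axis2: Axis | None
    F: np.ndarray           # kJ/mol; shape (n1,) or (n1, n2)
    counts: np.ndarray      # raw sample counts per bin
    sampled_mask: np.ndarray
    temperature: float = 300.0
    metadata: dict = field(default_factory=dict)

    @property
    def ndim(self) -> int:
        return 1 if self.axis2 is None else 2

    def centers(self):
        if self.axis2 is None:
            return (self.axis1.centers,)
        return (self.axis1.centers, self.axis2.centers)

    def bin_center(self, idx) -> tuple[float, ...]:
        if self.axis2 is None:
            return (float(self.axis1.centers[idx[0]]),)
        return (float(self.axis1.centers[idx[0]]),
                float(self.axis2.centers[idx[1]]))

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """Long-format CSV (s1[, s2], F, count, sampled) + JSON sidecar."""
        rows = []
        if self.axis2 is None:
            for i, c in enumerate(self.axis1.centers):
                rows.append((c, self.F[i], self.counts[i],
                             int(self.sampled_mask[i])))
            df = pd.DataFrame(rows, columns=[self.axis1.name, "F", "count",
                                             "sampled"])
        else:
            c1, c2 = self.axis1.centers, self.axis2.centers
            for i in range(self.axis1.n_bins):
                for j in range(self.axis2.n_bins):
                    rows.append((c1[i], c2[j], self.F[i, j],
                                 self.counts[i, j],
                                 int(self.sampled_mask[i, j])))
            df = pd.DataFrame(rows, columns=[self.axis1.name, self.axis2.name,
                                             "F", "count", "sampled"])
        df.to_csv(path, index=False, float_format="%.10g")
        meta = {
            "axis1": vars(self.axis1),
            "axis2": vars(self.axis2) if self.axis2 else None,
            "temperature": self.temperature,
            **self.metadata,
        }
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")


def make_grid_spec(lo1=2.0, hi1=6.0, n1=60, lo2=2.0, hi2=6.0, n2=60,
                   name1="d_RuS", name2="d_RuOmin") -> tuple[Axis, Axis]:
    """Default 60×60 grid over [2, 6] Å × [2, 6] Å."""
    return Axis(name1, lo1, hi1, n1), Axis(name2, lo2, hi2, n2)


# ---------------------------------------------------------------------------
# reweighting + WHAM
# ---------------------------------------------------------------------------

def reweight_samples(samples: pd.DataFrame, state: BiasState,
                     temperature: float = 300.0,
                     include_umbrella: bool = True,
                     cv_columns=("s1", "s2")) -> np.ndarray:
    """Per-sample unbiasing weights ∝ exp(+β·V_bias(sample)).

    V_bias is the umbrella term plus the *final-time* metadynamics bias
    at the sample's metadynamics coordinate (quasi-static
    approximation).  The per-window maximum bias is subtracted before
    exponentiation to guard against overflow; weights are later
    renormalized inside WHAM, so only ratios matter.
    """
    cols = [c for c in cv_columns if c in samples.columns]
    cv = samples.loc[:, cols].to_numpy(dtype=float)
    if not include_umbrella and state.window is not None:
        state = replace_window(state, None)
    v = bias_energy(state, cv)
    v = np.atleast_1d(v)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite bias energy in reweighting")
    return np.exp(beta(temperature) * (v - v.max()))


def time_averaged_bias(state: BiasState, avg_fraction: float = 0.5) -> BiasState:
    """Quasi-static bias averaged over the late part of the deposition.

    The instantaneous hill sum carries ripple at the Gaussian width and a
    build-up transient; averaging V(s, t_k) over the deposit times t_k of
    the last ``avg_fraction`` of hills is equivalent to scaling each
    hill's height by the fraction of those late times at which it was
    already present.  With 0 < avg_fraction ≤ 1; 0 returns the final
    bias unchanged.
    """
    if not state.hills or avg_fraction <= 0:
        return state
    times = np.array([h.deposit_time for h in state.hills])
    k = max(1, int(round(len(times) * avg_fraction)))
    late = times[-k:]
    scale = np.array([(late >= t).mean() for t in times])
    new = replace_window(state, state.window)
    new.hills = [Hill(center=h.center, sigma=h.sigma, height=h.height * s,
                      deposit_time=h.deposit_time)
                 for h, s in zip(state.hills, scale) if h.height * s > 0]
    return new


def replace_window(state: BiasState, window) -> BiasState:
    new = BiasState(window=window, bias_factor=state.bias_factor,
                    initial_height=state.initial_height, sigma=state.sigma,
                    pace=state.pace, temperature=state.temperature,
                    umbrella_cv=state.umbrella_cv, meta_cv=state.meta_cv,
                    metad_enabled=state.metad_enabled)
    new.hills = state.hills
    return new


@dataclass
class WHAMState:
    f: np.ndarray               # per-window free energies, kJ/mol (f[0] = 0)
    residual: float             # final max |Δf|, kJ/mol
    iterations: int
    converged: bool
    residual_history: np.ndarray = field(default_factory=lambda: np.array([]))


def _digitize(values: np.ndarray, axis: Axis) -> np.ndarray:
    """Bin indices; −1 for out-of-range samples."""
    idx = np.floor((values - axis.lo) / (axis.hi - axis.lo) * axis.n_bins)
    idx = idx.astype(int)
    idx[(values < axis.lo) | (values >= axis.hi)] = -1
    return idx


def wham(windows: list[tuple[UmbrellaWindow | None, pd.DataFrame]],
         grid_spec: tuple[Axis, Axis | None],
         meta_states: list[BiasState] | None = None,
         temperature: float = 300.0, tolerance: float = 1e-6,
         max_iter: int = 10_000, min_count: int = 5,
         check_overlap: bool = True,
         bias_time_average: float = 0.5,
         f_init=None) -> tuple[FESGrid, WHAMState]:
    """Self-consistent WHAM over umbrella windows on a 1D or 2D grid.

    ``windows`` pairs each umbrella restraint (or None for an unbiased
    run) with its sampled CV series (columns ``s1``[, ``s2``]).
    ``meta_states`` optionally carries the per-window metadynamics bias;
    its final hills enter as per-sample weights (quasi-static
    reweighting) while the umbrella restraints are handled by the WHAM
    window free energies f_j.

    Returns the gauge-fixed grid (min F = 0 over sampled bins) and the
    converged :class:`WHAMState`.  Non-convergence at ``max_iter`` is
    flagged, not raised.
    """
    ax1, ax2 = grid_spec
    n_bins = ax1.n_bins * (ax2.n_bins if ax2 else 1)
    n_win = len(windows)
    bta = beta(temperature)

    n_ij = np.zeros((n_win, n_bins))         # weighted histograms
    counts = np.zeros(n_bins)
    s1_hists = []
    for j, (win, df) in enumerate(windows):
        s1 = df["s1"].to_numpy(dtype=float)
        i1 = _digitize(s1, ax1)
        if ax2 is not None:
            s2 = df["s2"].to_numpy(dtype=float)
            i2 = _digitize(s2, ax2)
            ok = (i1 >= 0) & (i2 >= 0)
            flat = i1[ok] * ax2.n_bins + i2[ok]
        else:
            ok = i1 >= 0
            flat = i1[ok]
        if meta_states is not None and meta_states[j] is not None:
            mstate = time_averaged_bias(meta_states[j], bias_time_average)
            w = reweight_samples(df, replace_window(mstate, None),
                                 temperature,
                                 cv_columns=("s1", "s2") if ax2 else ("s1",))
            w = w[ok]
        else:
            w = np.ones(ok.sum())
        np.add.at(n_ij[j], flat, w)
        np.add.at(counts, flat, 1.0)
        s1_hists.append(np.bincount(i1[ok], minlength=ax1.n_bins) > 0)

    if check_overlap and n_win > 1:
        order = np.argsort([w.center if w else -np.inf
                            for w, _ in windows])
        for a, b in zip(order[:-1], order[1:]):
            if not np.any(s1_hists[a] & s1_hists[b]):
                ca = windows[a][0].center if windows[a][0] else None
                cb = windows[b][0].center if windows[b][0] else None
                raise ValueError(
                    f"umbrella windows at {ca} and {cb} Å share no sampled "
                    f"bins along {ax1.name}: gap in ({ca}, {cb})")

    # umbrella bias of window j at bin i (depends on s1 only)
    if ax2 is not None:
        s1_centers = np.repeat(ax1.centers, ax2.n_bins)
    else:
        s1_centers = ax1.centers
    U = np.zeros((n_win, n_bins))
    for j, (win, _) in enumerate(windows):
        if win is not None:
            U[j] = umbrella_energy(win, s1_centers)

    N_j = n_ij.sum(axis=1)
    n_i = n_ij.sum(axis=0)
    expU = np.exp(-bta * U)                  # (n_win, n_bins)

    f = (np.zeros(n_win) if f_init is None
         else np.asarray(f_init, dtype=float).copy())
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = (N_j * np.exp(bta * f)) @ expU    # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, n_i / denom, 0.0)
        P_sum = P.sum()
        if P_sum <= 0:
            raise ValueError("WHAM produced an empty distribution")
        P /= P_sum
        with np.errstate(divide="ignore"):
            f_new = -np.log(expU @ P) / bta
        f_new -= f_new[0]                        # gauge: f_1 = 0
        resid = float(np.max(np.abs(f_new - f))) if n_win > 1 else 0.0
        history.append(resid)
        f = f_new
        if resid < tolerance:
            converged = True
            break

    denom = (N_j * np.exp(bta * f)) @ expU
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(denom > 0, n_i / denom, 0.0)
    P /= P.sum()

    sampled = counts >= min_count
    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -np.log(np.where(P > 0, P, 1.0)) / bta, np.nan)
    F[~sampled] = np.nan
    if sampled.any():
        F -= np.nanmin(F[sampled])

    shape = (ax1.n_bins,) if ax2 is None else (ax1.n_bins, ax2.n_bins)
    grid = FESGrid(axis1=ax1, axis2=ax2, F=F.reshape(shape),
                   counts=counts.reshape(shape),
                   sampled_mask=sampled.reshape(shape),
                   temperature=temperature,
                   metadata={"min_count": min_count,
                             "wham_tolerance": tolerance})
    state = WHAMState(f=f, residual=history[-1] if history else 0.0,
                      iterations=it, converged=converged,
                      residual_history=np.asarray(history))
    return grid, state


def boltzmann_invert(samples: pd.DataFrame, grid_spec, weights=None,
                     temperature: float = 300.0,
                     min_count: int = 5) -> FESGrid:
    """Single-run free energy: F = −k_B T ln(weighted histogram) + const."""
    ax1, ax2 = grid_spec
    win: list = [(None, samples)]
    grid, _ = wham(win, (ax1, ax2), meta_states=None,
                   temperature=temperature, min_count=min_count,
                   check_overlap=False, max_iter=1)
    if weights is not None:
        # re-histogram with explicit weights
        s1 = samples["s1"].to_numpy(dtype=float)
        i1 = _digitize(s1, ax1)
        if ax2 is not None:
            i2 = _digitize(samples["s2"].to_numpy(dtype=float), ax2)
            ok = (i1 >= 0) & (i2 >= 0)
            flat = i1[ok] * ax2.n_bins + i2[ok]
            n_bins = ax1.n_bins * ax2.n_bins
        else:
            ok = i1 >= 0
            flat = i1[ok]
            n_bins = ax1.n_bins
        h = np.zeros(n_bins)
        np.add.at(h, flat, np.asarray(weights, dtype=float)[ok])
        with np.errstate(divide="ignore"):
            F = np.where(h > 0, -np.log(np.where(h > 0, h, 1.0)) /
                         beta(temperature), np.nan)
        F = F.reshape(grid.F.shape)
        F[~grid.sampled_mask] = np.nan
        if grid.sampled_mask.any():
            F -= np.nanmin(F[grid.sampled_mask])
        grid.F = F
    return grid


# ---------------------------------------------------------------------------
# attack-geometry split
# ---------------------------------------------------------------------------

def split_by_attack(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition samples into cis (α ≤ 90°) and trans (α > 90°) subsets.

    α = 90° exactly is assigned to cis (documented tie rule); the two
    subsets partition the input.
    """
    alpha = samples["alpha"].to_numpy(dtype=float)
    cis = samples[alpha <= 90.0].copy()
    trans = samples[alpha > 90.0].copy()
    return cis, trans


# ---------------------------------------------------------------------------
# features and paths on the grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceFeature:
    kind: str                      # "minimum" | "saddle"
    index: tuple[int, ...]         # bin index
    location: tuple[float, ...]    # bin center, Å
    value: float                   # F at the bin, kJ/mol
    depth: float                   # escape depth (minimum) or barrier (saddle)


def _sampled_neighbors(mask: np.ndarray, i: int, j: int):
    n1, n2 = mask.shape
    for di, dj in _NEIGHBORS_8:
        a, b = i + di, j + dj
        if 0 <= a < n1 and 0 <= b < n2 and mask[a, b]:
            yield a, b


def _as_2d(grid: FESGrid) -> tuple[np.ndarray, np.ndarray]:
    if grid.ndim == 2:
        return grid.F, grid.sampled_mask
    return grid.F[:, None], grid.sampled_mask[:, None]


def _minimax_levels(F: np.ndarray, mask: np.ndarray,
                    start: tuple[int, int]) -> np.ndarray:
    """Per-bin minimax level (lowest possible max-F along any sampled
    8-connected path) from ``start``; +inf where unreachable."""
    levels = np.full(F.shape, np.inf)
    levels[start] = F[start]
    heap = [(F[start], start)]
    while heap:
        lvl, (i, j) = heapq.heappop(heap)
        if lvl > levels[i, j]:
            continue
        for a, b in _sampled_neighbors(mask, i, j):
            cand = max(lvl, F[a, b])
            if cand < levels[a, b]:
                levels[a, b] = cand
                heapq.heappush(heap, (cand, (a, b)))
    return levels


def find_features(grid: FESGrid, min_depth: float = 1.0) -> list[SurfaceFeature]:
    """Locate minima (and the saddles between them) on the surface.

    A minimum is a sampled bin strictly below all sampled 8-neighbors
    whose escape depth — the minimax barrier to any strictly lower
    sampled bin — is at least ``min_depth``.  Saddles are the highest
    bins on the minimax paths between retained minima.
    """
    F, mask = _as_2d(grid)
    if not mask.any():
        raise ValueError("grid has no sampled bins")
    cand = []
    n1, n2 = F.shape
    for i in range(n1):
        for j in range(n2):
            if not mask[i, j]:
                continue
            nb = list(_sampled_neighbors(mask, i, j))
            if nb and all(F[i, j] < F[a, b] for a, b in nb):
                cand.append((i, j))
            elif not nb:
                cand.append((i, j))   # isolated sampled bin
    if len(set(np.round(F[mask], 12))) == 1:
        return []                     # flat surface: no features

    minima = []
    for (i, j) in cand:
        levels = _minimax_levels(F, mask, (i, j))
        lower = (F < F[i, j]) & mask & np.isfinite(levels)
        if lower.any():
            depth = float(np.min(levels[lower])) - float(F[i, j])
        else:
            depth = np.inf
        if depth >= min_depth:
            minima.append(((i, j), depth))

    def _center(idx):
        if grid.ndim == 2:
            return grid.bin_center(idx)
        return grid.bin_center((idx[0],))

    features = [
        SurfaceFeature(kind="minimum",
                       index=idx if grid.ndim == 2 else (idx[0],),
                       location=_center(idx), value=float(F[idx]),
                       depth=float(depth))
        for idx, depth in minima
    ]
    # saddles on minimax paths between each pair of retained minima
    seen = set()
    for a in range(len(minima)):
        for b in range(a + 1, len(minima)):
            ia, _ = minima[a]
            ib, _ = minima[b]
            try:
                path = _minimax_path(F, mask, ia, ib)
            except PathNotFoundError:
                continue
            k = max(path, key=lambda idx: F[idx])
            if k in (ia, ib) or k in seen:
                continue
            seen.add(k)
            barrier = float(F[k]) - max(float(F[ia]), float(F[ib]))
            features.append(SurfaceFeature(
                kind="saddle", index=k if grid.ndim == 2 else (k[0],),
                location=_center(k), value=float(F[k]), depth=barrier))
    return features


def _minimax_path(F, mask, start, end) -> list[tuple[int, int]]:
    """Minimax 8-connected path, ties broken by lower integrated F."""
    levels = _minimax_levels(F, mask, start)
    if not np.isfinite(levels[end]):
        reach = np.isfinite(levels) & mask
        lvl = float(np.nanmax(np.where(reach, F, np.nan)))
        raise PathNotFoundError(
            f"no sampled path from {start} to {end}; blocked above "
            f"contour level {lvl:.3f} kJ/mol")
    L = levels[end]
    # min-sum Dijkstra restricted to bins with F <= L (+ tiny slack)
    ok = mask & (F <= L + 1e-9)
    dist = np.full(F.shape, np.inf)
    dist[start] = F[start]
    prev: dict = {start: None}
    heap = [(F[start], start)]
    while heap:
        d, (i, j) = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        if (i, j) == end:
            break
        for a, b in _sampled_neighbors(ok, i, j):
            nd = d + F[a, b]
            if nd < dist[a, b]:
                dist[a, b] = nd
                prev[(a, b)] = (i, j)
                heapq.heappush(heap, (nd, (a, b)))
    node = end
    path = []
    while node is not None:
        path.append(node)
        node = prev[node]
    return path[::-1]


def minimum_energy_path(grid: FESGrid, start, end) -> list[tuple[int, ...]]:
    """Minimax ("watershed") path between two bins through sampled bins.

    Minimizes the maximum F along the path; among such paths the one
    with the lowest integrated F is returned.  ``start``/``end`` are bin
    indices.  Raises :class:`PathNotFoundError` when the bins are not
    connected through sampled bins.
    """
    F, mask = _as_2d(grid)
    s = tuple(start) if grid.ndim == 2 else (start[0], 0)
    e = tuple(end) if grid.ndim == 2 else (end[0], 0)
    for name, idx in (("start", s), ("end", e)):
        if not mask[idx]:
            raise ValueError(f"{name} bin {idx} is not sampled")
    path = _minimax_path(F, mask, s, e)
    if grid.ndim == 1:
        return [(i,) for i, _ in path]
    return path


def smooth_masked(F: np.ndarray, mask: np.ndarray,
                  sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing that ignores unsampled (NaN) bins.

    Standard mask-normalized blur: both the zero-filled field and the
    mask are filtered and divided, so sampled values never bleed across
    large unsampled gaps.  Returns NaN where the local mask weight is
    negligible.
    """
    from scipy.ndimage import gaussian_filter

    A = np.where(mask, np.nan_to_num(F, nan=0.0), 0.0)
    W = mask.astype(float)
    num = gaussian_filter(A, sigma=sigma, mode="nearest")
    den = gaussian_filter(W, sigma=sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-6, num / den, np.nan)
    return out


def path_max_F(grid: FESGrid, path) -> float:
    F, _ = _as_2d(grid)
    idx = [(p[0], p[1] if grid.ndim == 2 else 0) for p in path]
    return float(max(F[i] for i in idx))


def plot_fes(grid: FESGrid, path=None, ax=None, **imshow_kw):
    """Optional heat-map rendering of a 2D surface (matplotlib)."""
    import matplotlib.pyplot as plt

    if grid.ndim != 2:
        raise ValueError("plot_fes requires a 2D grid")
    if ax is None:
        _, ax = plt.subplots()
    img = ax.imshow(grid.F.T, origin="lower",
                    extent=(grid.axis1.lo, grid.axis1.hi,
                            grid.axis2.lo, grid.axis2.hi),
                    aspect="auto", **imshow_kw)
    if path is not None:
        xs = [grid.axis1.centers[i] for i, _ in path]
        ys = [grid.axis2.centers[j] for _, j in path]
        ax.plot(xs, ys, color="cyan", lw=2)
    ax.set_xlabel(f"{grid.axis1.name} (Å)")
    ax.set_ylabel(f"{grid.axis2.name} (Å)")
    return img
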