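"""Chelate-planarity descriptors and correlation/regression statistics.

The signed dihedral θ between the two chelate half-planes is folded
onto [0°, 90°] (bending left or right is equivalent; 0° = planar,
90° = maximally bent).  Planarity μ(θ) is the mean of the folded
series, rigidity σ(θ) its standard deviation (population convention by
default).  Structure–activity analysis uses Spearman rank correlation
(exact permutation p-value at small n) and ordinary least squares with
a t-scaled 95% confidence band on the fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PlanarityResult:
    mu_theta: float     # degrees in [0, 90]
    sigma_theta: float  # degrees >= 0
    n_frames: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str         # "exact-permutation" | "t-approximation"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    residual_se: float
    dof: int
    t_crit: float
    confidence: float

    def band_half_width(self, x_star, x: np.ndarray) -> np.ndarray:
        """CI half-width of the fitted line at x*: t·s·sqrt(1/n + (x*−x̄)²/Sxx)."""
        x = np.asarray(x, dtype=float)
        xs = np.asarray(x_star, dtype=float)
        sxx = np.sum((x - x.mean()) ** 2)
        return self.t_crit * self.residual_se * np.sqrt(
            1.0 / len(x) + (xs - x.mean()) ** 2 / sxx)

    def predict(self, x_star):
        return self.slope * np.asarray(x_star, dtype=float) + self.intercept


def fold_theta(theta_signed):
    """Map a signed dihedral (degrees) onto the [0°, 90°] bending scale.

    folded = 90 − |90 − (|θ| mod 180)|; idempotent and even, with
    180° ≡ 0° (the two half-planes are unordered).
    """
    t = np.abs(np.asarray(theta_signed, dtype=float)) % 180.0
    return 90.0 - np.abs(90.0 - t)


def planarity_rigidity(theta_series, population_sd: bool = True) -> PlanarityResult:
    """μ(θ) and σ(θ) of a dihedral series (signed input is folded first)."""
    t = np.asarray(theta_series, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 frames")
    folded = fold_theta(t)
    ddof = 0 if population_sd else 1
    return PlanarityResult(mu_theta=float(np.mean(folded)),
                           sigma_theta=float(np.std(folded, ddof=ddof)),
                           n_frames=int(t.size))


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

_EXACT_PERMUTATION_MAX_N = 10


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of rank vectors (average-rank ties)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx * rx) * np.sum(ry * ry))
    if denom == 0:
        return np.nan
    return float(np.sum(rx * ry) / denom)


def _permutation_matrix(values: np.ndarray) -> np.ndarray:
    """All n! orderings of ``values`` as an (n!, n) array, built by the
    recursive block construction (avoids a slow Python-level loop)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    # build index permutations iteratively: insert element k into every
    # position of every (k-1)-permutation
    idx = np.zeros((1, 1), dtype=int)
    for k in range(1, n):
        m, w = idx.shape
        out = np.empty((m * (k + 1), w + 1), dtype=int)
        for pos in range(k + 1):
            block = out[pos * m:(pos + 1) * m]
            block[:, :pos] = idx[:, :pos]
            block[:, pos] = k
            block[:, pos + 1:] = idx[:, pos:]
        idx = out
    return values[idx]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties get average ranks.  For n ≤ 10 the p-value is computed by
    exact enumeration of all n! rank permutations; for larger n the
    usual t-distribution approximation is used.  Constant input vectors
    leave ρ undefined and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)

    if n <= _EXACT_PERMUTATION_MAX_N:
        # permutations of rx all share the same mean and sum of squares,
        # so rho reduces to a single matrix product against centered ry
        perms = _permutation_matrix(rx)
        ryc = ry - ry.mean()
        denom = np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum(ryc**2))
        rho_all = (perms @ ryc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        method = "exact-permutation"
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n, method=method)


def linear_fit_ci(x, y, confidence: float = 0.95) -> RegressionResult:
    """Ordinary least squares with a t-scaled confidence band.

    The band half-width at x* is t_crit · s · sqrt(1/n + (x*−x̄)²/Sxx)
    with s the residual standard error on n−2 degrees of freedom and
    t_crit the two-sided critical value at the requested confidence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]):
        raise ValueError("constant x: regression undefined")
    xb, yb = x.mean(), y.mean()
    sxx = np.sum((x - xb) ** 2)
    slope = float(np.sum((x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - yb) ** 2))
    dof = n - 2
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    s = float(np.sqrt(ss_res / dof))
    t_crit = float(sps.t.ppf(0.5 + confidence / 2.0, df=dof))
    return RegressionResult(slope=slope, intercept=intercept, R2=r2,
                            residual_se=s, dof=dof, t_crit=t_crit,
                            confidence=confidence)


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention used when comparing
    computed statistics with printed two-decimal values."""
    if not isfinite(value):
        return value
    factor = 10 ** decimals
    return float(np.sign(value) * np.floor(abs(value) * factor + 0.5) / factor)
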