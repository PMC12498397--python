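"""Packaged per-compound tables for the nine Ru polypyridyl complexes.

Three measured/computed tables ship with the package as CSV fixtures:
photophysical data (quantum yields Φ_515/Φ_625 among others), static-DFT
barriers ΔE_MLCT-MC / ΔE_MLCT-TS, and the cis/trans attack percentages
from the biased trajectories.  Entries printed only as upper bounds
(e.g. Φ_Δ < 0.001) are recorded at their bound; they play no role in
the correlation analyses.

The photoinactive compound Ru1 has empty quantum-yield cells; the
correlation analyses assign it Φ = 0 (the zero-assignment rule), the
unique reading under which the rank statistics reproduce the printed
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("photomech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_quantum_yields() -> pd.DataFrame:
    """Photophysical table, one row per complex (Ru1..Ru9)."""
    return _read("table1_photophysics.csv")


def load_dft_barriers() -> pd.DataFrame:
    """Static-DFT ³MLCT→³MC barriers (kJ/mol), two definitions."""
    return _read("table2_dft_barriers.csv")


def load_attack_fractions() -> pd.DataFrame:
    """cis/trans attack percentages (Ru–O_min < 4 Å) per complex."""
    return _read("table3_attack_fractions.csv")


def load_planarity_reference() -> pd.DataFrame:
    """Chelate planarity μ(θ) in degrees, where individually reported."""
    return _read("planarity_reference.csv")


@dataclass(frozen=True)
class CompoundRecord:
    """One complex: yields, barriers, descriptors."""

    id: str
    phi_515: float
    phi_625: float
    dE_MLCT_MC: float
    dE_MLCT_TS: float
    photoactive: bool
    planarity_mu: float | None = None
    cis_pct: float | None = None
    trans_pct: float | None = None

    def __post_init__(self):
        if self.phi_515 < 0 or self.phi_625 < 0:
            raise ValueError("quantum yields must be >= 0")


def compound_records(zero_assign_inactive: bool = True) -> list[CompoundRecord]:
    """Merge the packaged tables into one record per complex.

    With ``zero_assign_inactive`` (default) the photoinactive complex
    enters with Φ = 0 rather than missing values.
    """
    t1 = load_quantum_yields().set_index("complex")
    t2 = load_dft_barriers().set_index("complex")
    t3 = load_attack_fractions().set_index("complex")
    mu = load_planarity_reference().set_index("complex")
    records = []
    for cid in t1.index:
        phi515 = t1.loc[cid, "phi_515"]
        phi625 = t1.loc[cid, "phi_625"]
        active = not (np.isnan(phi515) and np.isnan(phi625))
        if not active and zero_assign_inactive:
            phi515 = phi625 = 0.0
        records.append(CompoundRecord(
            id=cid, phi_515=float(phi515), phi_625=float(phi625),
            dE_MLCT_MC=float(t2.loc[cid, "dE_MLCT_MC"]),
            dE_MLCT_TS=float(t2.loc[cid, "dE_MLCT_TS"]),
            photoactive=active,
            planarity_mu=(float(mu.loc[cid, "planarity_mu_deg"])
                          if cid in mu.index else None),
            cis_pct=float(t3.loc[cid, "cis_pct"]),
            trans_pct=float(t3.loc[cid, "trans_pct"]),
        ))
    return records


def yields_vs_barriers(wavelength: int = 515,
                       zero_assign_inactive: bool = True):
    """Vectors (Φ, ΔE_MLCT-MC, ΔE_MLCT-TS) over all nine complexes."""
    recs = compound_records(zero_assign_inactive)
    phi = np.array([r.phi_515 if wavelength == 515 else r.phi_625
                    for r in recs])
    return (phi,
            np.array([r.dE_MLCT_MC for r in recs]),
            np.array([r.dE_MLCT_TS for r in recs]))
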