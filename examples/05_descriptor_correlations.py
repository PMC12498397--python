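"""Structure–activity statistics on the packaged compound tables.

Reproduces the rank-correlation analysis between photosubstitution
quantum yields and the static-DFT triplet barriers, and demonstrates
the chelate-planarity descriptor on a synthetic dihedral trajectory.
"""

import numpy as np

from photomech import (ThetaProcess, generate_theta_series, linear_fit_ci,
                       planarity_rigidity, spearman, yields_vs_barriers)

phi, d_mc, d_ts = yields_vs_barriers(wavelength=515)

for name, barrier in (("ΔE_MLCT-MC", d_mc), ("ΔE_MLCT-TS", d_ts)):
    rho = spearman(phi, barrier)
    fit = linear_fit_ci(barrier, phi)
    print(f"Φ_515 vs {name}: Spearman ρ = {rho.rho:.2f} "
          f"(p = {rho.p_value:.2f}, {rho.method}), R² = {fit.R2:.2f}")

print("\nBoth barrier definitions correlate weakly and insignificantly "
      "with the measured quantum yields (p ≥ 0.05): the classic "
      "MLCT→MC energy gap does not predict photoreactivity here.")

theta = generate_theta_series(ThetaProcess(mean_deg=58.7, sd_deg=6.0),
                              n=20_000, seed=4)
res = planarity_rigidity(theta)
print(f"\nchelate dihedral series (n = {res.n_frames}): "
      f"planarity μ(θ) = {res.mu_theta:.1f}°, "
      f"rigidity σ(θ) = {res.sigma_theta:.1f}°")
print("μ(θ) near 0° means a flat chelate; large μ(θ) and σ(θ) mark the "
      "bent, flexible ligands that correlate with high quantum yields.")
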