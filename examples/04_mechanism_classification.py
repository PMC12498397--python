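"""End-to-end mechanism classification on one archetype surface.

Runs the full default protocol (20 umbrella windows + well-tempered
metadynamics, WHAM, cis/trans split, absorption region, classifier) on
the associative archetype and prints the verdict.  Takes ~1–2 minutes.
"""

from photomech import KB, PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(archetype="associative", seed=11))

print(res.report.summary())
print(f"\nfree-energy recovery vs the analytic surface: "
      f"{res.fes_rmse:.2f} kJ/mol RMSE "
      f"({res.fes_rmse / (KB * 300):.2f} k_B T) over "
      f"{int(res.grid_all.sampled_mask.sum())} sampled bins")
print(f"absorption region center {tuple(round(c, 2) for c in res.region.center)} Å, "
      f"semi-axes {tuple(round(a, 2) for a in res.region.semi_axes)} Å")
print("\nA heptacoordinate intermediate (both Ru–S and Ru–O_min inside "
      "the 4.0 Å interaction cutoff) is what makes this surface "
      "associative; a pentacoordinate one (both outside) would make it "
      "dissociative, and none at all an interchange.")
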