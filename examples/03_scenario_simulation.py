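"""Forward-simulate turnover regimes and recover the generating parameters.

Each preset fixes how a stimulus moves formation and degradation; analysing
the simulated data recovers the multipliers and shows which regimes the
conventional flux readout cannot tell apart.
"""

from autoflux import PRESETS, preset, recover, simulate

print(f"{'preset':>30} {'formation':>9} {'degradation':>11} {'net':>6}")
for name in sorted(PRESETS):
    rep = recover(simulate(preset(name, noise_cv=0.0, n_replicates=1)))
    m = rep.recovered_mean
    print(f"{name:>30} {m['formation_ratio']:9.2f} {m['degradation_ratio']:11.2f} "
          f"{m['net_ratio']:6.2f}")

print()
print("Ratios are stimulus/basal; net = degradation/formation (1 = equilibrium).")
print("formation_up and degradation_down share a conventional-flux signature but")
print("differ in pool size and net turnover — the point of splitting the two steps.")

# noisy, experiment-sized run: three replicates, 10% lane noise
rep = recover(simulate(preset("balanced_up", noise_cv=0.1, n_replicates=3, seed=42)))
print()
print(f"balanced_up, n=3, 10% noise: formation = {rep.recovered_mean['formation']:.1f}"
      f" ± {rep.recovered_sem['formation']:.1f} au (truth {rep.ground_truth['formation']:.0f})")
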