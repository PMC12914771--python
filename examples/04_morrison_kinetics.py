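"""Morrison tight-binding kinetics: Kiapp -> Ki, Ki fitting, selectivity folds.

Converts published-style apparent inhibition constants to intrinsic Ki at
the assay constants (S = 7.5 uM substrate, per-enzyme Km), then simulates
noisy inhibition curves at those Ki and fits them back, and finally builds
the selectivity profile (fold change of Ki relative to the intended target).
"""

from timpdesign import E_NM, KM_UM, S_UM, fit_ki, fold_changes, kiapp_to_ki
from timpdesign.synthetic import simulate_inhibition_data

# Apparent constants (nM) for a selectivity-switched inhibitor variant.
kiapp = {"MMP-9": 6.036, "MMP-3": 742.0, "MMP-1": 872.4}

print("enzyme   Kiapp(nM)   Ki(nM) = Kiapp/(1 + S/Km)")
ki = {}
for enzyme, value in kiapp.items():
    ki[enzyme] = kiapp_to_ki(value, S_UM, KM_UM[enzyme])
    print(f"{enzyme:7} {value:9.3f}   {ki[enzyme]:8.3f}")

i_grid = [0.0, 0.325, 0.65, 1.0, 2.0, 4.0, 8.0, 16.0, 60.0, 250.0]
print("\nfit of 3 simulated replicates at 2% noise:")
fitted = {}
for enzyme, true_ki in ki.items():
    curves = simulate_inhibition_data(
        true_ki, E_NM, S_UM, KM_UM[enzyme], i_grid, noise_sd=0.02, replicates=3, seed=5
    )
    fit = fit_ki(curves, S_UM, KM_UM[enzyme])
    fitted[enzyme] = fit.ki_nm
    print(f"{enzyme:7} planted {true_ki:8.3f} nM -> fitted {fit.ki_nm:8.3f} "
          f"+/- {fit.ki_sd_nm:.3f} nM")

profile = fold_changes(fitted, reference="MMP-9")
print("\nselectivity profile (fold change of Ki vs MMP-9):")
for enzyme, fold in profile.fold_change_display.items():
    print(f"  {enzyme}: {fold}x")
print("\nA ~100-fold higher Ki for the off-target enzymes means the variant "
      "inhibits MMP-9 two orders of magnitude more potently.")
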