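"""Ground-truth time-activity curves and 1TCM self-consistency.

Assembles the reference simulation case (TBR 8.05 at 6 min), prints the
end-time tissue ratios it is constrained to, then fits the one-tissue
compartment model back to its own noiseless myocardial curve: the recovered
wash-in/wash-out/blood-fraction should match the generating values
K1 = 0.33 ml/g/min, k2 = 0.21 /min, V_L = 40% to well under 1%.
"""

from gatedspect import kinetics
from gatedspect.kinetic_fit import fit_1tcm

tacs = kinetics.assemble_tacset(case=1)
end = -1
print(f"case 1: peak total activity {tacs.total_activity_max} mCi, "
      f"input-tail wash-out solved at {tacs.input_params.washout_rate:.3f}/min")
print(f"end-time ratios  myo:background {tacs.tbr_at_end:.2f}  "
      f"myo:blood {tacs.myocardium[end] / tacs.blood[end]:.2f}  "
      f"myo:liver {tacs.myocardium[end] / tacs.liver[end]:.2f}")

fit = fit_1tcm(tacs.myocardium, tacs.blood, tacs.times)
print(f"1TCM fit of the noiseless myocardial curve: "
      f"K1 = {fit.params.K1:.4f} ml/g/min, k2 = {fit.params.k2:.4f} /min, "
      f"V_L = {100 * fit.params.VL:.1f}%")
print("Matching the generating parameters confirms the fitting chain is")
print("unbiased before any imaging physics enters.")
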