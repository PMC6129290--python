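"""Flux balance analysis and model mutation on a minimal heterotroph.

Builds the packaged T1 model (glucose uptake capped at 10 mmol/gDW/h,
growth consuming 10 mmol glucose per gDW), solves the growth LP, then
applies the two standard consortium-engineering mutations: a
growth-coupled secretion and a fixed-carbon partition.
"""

from flexcop import (
    add_growth_coupled_secretion,
    partition_fixed_carbon,
    solve_fba,
    toy_phototroph,
    toy_t1_with_secretion,
)

model = toy_t1_with_secretion()
sol = solve_fba(model)
# mu = 1.0 /h: the uptake cap (10) divided by the glucose demand per gDW (10)
print(f"unmodified growth rate: {sol.objective_value:.4f} /h")

coupled = add_growth_coupled_secretion(model, "SECRETE", k=0.5)
sol = solve_fba(coupled)
# secretion taxes the same glucose budget: mu = 10/(10 + 0.5) ~ 0.952
print(f"with 0.5 mmol product per unit growth: {sol.objective_value:.4f} /h")
print(f"  secretion flux: {sol.fluxes['SECRETE']:.4f} mmol/gDW/h (= 0.5 mu)")

photo = partition_fixed_carbon(toy_phototroph(), "FIX", "SUC_EXPORT", p=0.4)
sol = solve_fba(photo)
# 40% of the 10 C-mmol/h fixation now leaves as sucrose carbon
print(f"phototroph at 40% carbon partition: mu = {sol.objective_value:.4f} /h, "
      f"sucrose carbon export = {12 * sol.fluxes['EX_suc']:.2f} C-mmol/gDW/h")
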