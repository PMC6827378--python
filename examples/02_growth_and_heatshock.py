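"""Doubling times and heat-shock reporter folds from plate-reader tables.

Simulates OD600 growth curves (15-min sampling, 24 h) for three strains,
fits the logistic model to each curve, and reports doubling times and their
fold change over the wild-type control, then the heat-shock reporter fold
inductions from a fluorescence table.
"""

import mistrans as mt
from mistrans.phenotype import fit_growth_table, heat_shock_fold, strain_doubling_times

cfg = mt.SimulationConfig(seed=2)
growth = mt.gen_growth_curves(cfg)
fits = fit_growth_table(growth)
tds = strain_doubling_times(fits)

print("strain      t_d (min)   fold vs reference")
for strain in sorted(tds):
    fold = mt.doubling_time_fold(tds[strain], tds["reference"])
    print(f"{strain:<12}{tds[strain]:>8.1f}   {fold.value:.2f} "
          f"(reported as {fold.rounded})")

fluor = mt.gen_fluorescence(cfg)
print("\nheat-shock reporter fold induction:")
ref = fluor.loc[fluor.strain_id == "reference", "fluorescence"].tolist()
for strain in sorted(cfg.heat_shock_folds):
    readings = fluor.loc[fluor.strain_id == strain, "fluorescence"].tolist()
    print(f"{strain:<12}{heat_shock_fold(readings, ref).value:.2f}")

print("\nA fold of 2.0 means the variant doubles the culture's doubling "
      "time; reporter folds above 1 indicate a proteotoxic-stress response.")
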