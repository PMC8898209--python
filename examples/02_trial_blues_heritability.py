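"""Per-trial adjusted means (BLUEs) and Cullis heritability.

Fits the stage-1 model for one year x treatment unit — genotype fixed,
replicate/block/season random, days-to-flowering as a covariate on yield —
and the per-trial heritability with genotype refit as random.
"""

import numpy as np
import pandas as pd

from gaintrend.simdata import SimConfig, simulate_dataset
from gaintrend.stage1 import fit_trial, trial_heritability

ds = simulate_dataset(SimConfig(seed=42))
unit = ds.phenotypes.query("year == 8 and treatment == 'non-stress'")

blues = fit_trial(unit)  # one adjusted mean + SE per genotype
print(blues.drop(columns="weight").head(5).round(2).to_string(index=False))
print(f"... {len(blues)} genotypes; mean SE {blues['se'].mean():.0f} kg/ha")
# the table also carries 'weight' = 1/se^2, which stage 2 uses to weight
# these means by their precision

truth = pd.Series(ds.true_bv)
r = np.corrcoef(blues.set_index("genotype")["blue"], truth[blues["genotype"]])[0, 1]
print(f"correlation of BLUEs with true breeding values: {r:.2f}")

for trial in unit["trial"].unique():
    est = trial_heritability(unit[unit["trial"] == trial])
    h = "undefined" if est.H2 is None else f"{est.H2:.2f}"
    print(f"{trial}: Cullis H2 = {h}  (plot-basis truth "
          f"{ds.truth['h2_plot_basis'][trial]:.2f})")
# H2 near its plot-basis value means the trial separates genotypes well;
# low-H2 trials will carry little weight downstream via their larger SEs.
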