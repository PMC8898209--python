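"""Elite core-panel selection and pedigree-PCA diversity check.

Selects the top genotypes by breeding value among those with reliability
above 0.4, then projects the pedigree relationship matrix onto its first
principal components to see whether the panel spans the collection's
diversity rather than clustering in one family.
"""

import numpy as np

from gaintrend.pedigree import build_a_matrix
from gaintrend.qc import run_qc
from gaintrend.simdata import SimConfig, simulate_dataset
from gaintrend.stage1 import stage1_all_units
from gaintrend.stage2 import fit_pedigree_blup
from gaintrend.trends import pedigree_pca, select_core_panel

ds = simulate_dataset(SimConfig(seed=42))
clean, _ = run_qc(ds.phenotypes)
blues = stage1_all_units(clean, contexts=("combined",))
tb = fit_pedigree_blup(blues[blues["context"] == "combined"], ds.pedigree).table
candidates = tb[tb["n_records"] > 0]

panel = select_core_panel(candidates, n_target=100, reliability_min=0.4)
sel = candidates[candidates["genotype"].isin(panel.selected)]
print(f"panel: {len(panel.selected)} of {len(candidates)} candidates; "
      f"EBV cutoff {panel.ebv_min:.0f} kg/ha; "
      f"mean EBV {sel['ebv'].mean():.0f} vs collection {candidates['ebv'].mean():.0f}")

A = build_a_matrix(ds.pedigree, ids=candidates["genotype"].tolist())
scores, varexp = pedigree_pca(A, selected=set(panel.selected))
print(f"pedigree PCA: PC1 {100 * varexp[0]:.0f}%, PC2 {100 * varexp[1]:.0f}% of variance")
spread = scores.groupby("selected")[["pc1", "pc2"]].std().round(2)
print(spread)
# Similar PC-score spread for selected and unselected genotypes means the
# panel samples the whole pedigree space, not a single top family.
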