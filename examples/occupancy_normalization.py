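"""Separate true phospho-regulation from parent-protein abundance changes.

A phosphopeptide can drop because the site lost its phosphate or because the
whole protein became less abundant.  Occupancy normalization subtracts the
parent protein's log2 fold change from the site's, and the reduced sets at
both levels are compared.
"""

import warnings

warnings.filterwarnings("ignore", message="only .* distinct label permutations")

from phosphoprimer.pipeline import run_study
from phosphoprimer.simulate import simulate_study

study = simulate_study(seed=2)
res = run_study(study, seed=2, n_permutations=9)

occ = res.occupancy
n_phos = (occ["call_phospho"] == "reduced").sum()
n_occ = (occ["call_occupancy"] == "reduced").sum()
ov = res.occupancy_overlap
print(f"records reduced at the phosphorylation level: {n_phos}")
print(f"records reduced at the occupancy level:       {n_occ}")
print(f"fraction of phospho-reduced records that stay reduced after "
      f"normalizing to the proteome: {ov.fraction_a_in_b:.3f}")
print("(records that drop out of the occupancy set changed mostly because "
      "their parent protein changed, not because the site was "
      "dephosphorylated)")
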