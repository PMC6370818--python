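"""AMD excess: observed strand disagreement beyond sampling noise.

Simulates 5,000 dyads at depth 30 twice - once without hemi-methylation and
once with a coherent 30% hemi fraction - and tests the mean AMD against the
exact binomial null with the within-dyad read-reshuffling permutation test.
"""

from hemimeth import amd_excess
from hemimeth.simulate import simulate_null_dyads

for label, hemi in (("no hemi-methylation", 0.0), ("hemi fraction 0.30", 0.3)):
    dyads, _ = simulate_null_dyads(5_000, depth=30, seed=42, hemi=hemi)
    res = amd_excess(dyads, n_permutations=999, seed=7)
    print(f"{label}:")
    print(f"  observed mean AMD  {res.observed_mean:7.3f} points")
    print(f"  sampling-null AMD  {res.null_aggregate:7.3f} points")
    print(f"  excess             {res.excess:7.3f} points  (permutation p = {res.p_value})")
print("-> the excess isolates genuine hemi-methylation from depth noise")
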