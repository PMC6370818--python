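"""Active versus passive demethylation across a simulated three-system study.

Generates the default synthetic study (MEF plus reprogramming with and
without vitamin C; control, sh-Dnmt1 and Tet1 arms), then reproduces the
dyad-level comparisons: per-condition mean AMD, overlap of demethylation
targets between the two routes, and the AMD-response curve.
"""

import pandas as pd
from scipy import stats

from hemimeth import (
    amd_response_curve,
    hemi_abundance_change,
    overlap_stats,
    pair_dyads,
    select_above_average,
)
from hemimeth.simulate import SimulationConfig, simulate_study

bundle = simulate_study(SimulationConfig(seed=1))
dyads = {
    pert: pair_dyads(bundle.calls[("MEF", pert)], min_depth=5).set_index("plus_pos")
    for pert in ("control", "sh-Dnmt1", "Tet1")
}

amd_tables = {pert: d["amd"] for pert, d in dyads.items()}
print("mean AMD per condition (hemi abundance):")
print(hemi_abundance_change(amd_tables, n_permutations=199).to_string(index=False))
print("  -> passive demethylation (sh-Dnmt1) leaves hemi dyads behind and raises")
print("     the AMD; active demethylation (Tet1) clears them and lowers it\n")

level = {p: 0.5 * (d["plus_level"] + d["minus_level"]) for p, d in dyads.items()}
deltas = {arm: (level["control"] - level[arm]).dropna() for arm in ("Tet1", "sh-Dnmt1")}
targets = {arm: set(select_above_average(d)) for arm, d in deltas.items()}
universe = set(level["control"].index)
res = overlap_stats(targets["Tet1"], targets["sh-Dnmt1"], universe)
base = len(targets["sh-Dnmt1"]) / len(universe)
print(f"dyads demethylated above average by Tet1 also hit by sh-Dnmt1: {res.frac_a_in_b:.2f}")
print(f"  (base rate of sh-Dnmt1 targets in the universe: {base:.2f}; "
      f"enrichment p = {res.p_enrichment:.2e})")
print("  -> the two routes demethylate largely the same hemi-rich sites\n")

curve = amd_response_curve(dyads["control"]["amd"], deltas["Tet1"], n_groups=14)
rho = stats.spearmanr(curve["group"], curve["mean_delta"]).statistic
print("AMD-response curve (Tet1 arm), 14 equal-count groups:")
print(curve.round(2).to_string(index=False))
print(f"  -> demethylation rises with strand asymmetry (Spearman {rho:.3f})")
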