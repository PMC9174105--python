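"""Diet/lifestyle associations with trait-related genera and the HMI.

Mutually adjusted linear regressions of each standardized panel genus (and
the HMI) on each dietary or lifestyle factor, a fibre-only scan, and the
food-group -> trait regressions with and without the HMI term.
"""

import pandas as pd

from gutglyc import (
    generate_cohort, diet_genus_scan, fibre_scan,
    trait_regression_with_without_hmi, compute_hmi,
)
from gutglyc.assoc import SignedPanel
from gutglyc.preprocess import standardize
from gutglyc.tables import GenusAbundanceTable

# plant a vegetable -> Genus008 link so the scan has a known discovery
table, cohort, truth = generate_cohort(
    n_participants=2772, n_provinces=15, seed=7,
    truth={"informative_diet_genera": {"vegetable": {"Genus008": 0.6}}},
)

data = table.data.reindex(cohort["participant_id"])
outcomes = pd.DataFrame(index=cohort.index)
for genus in ["Genus008", "Genus009", "Genus010"]:
    outcomes[genus], _, _ = standardize(data[genus].rename(genus))
outcomes["HMI"] = compute_hmi(
    GenusAbundanceTable(data), SignedPanel(entries=truth.panel)
)["hmi_z"].to_numpy()

scan = diet_genus_scan(cohort, outcomes)
sig = scan[scan["significant"]]
print(f"diet scan: {len(scan)} factor x outcome tests, "
      f"{len(sig)} significant at q < 0.05")
for _, r in sig.iterrows():
    print(f"  {r['factor']:>10} -> {r['outcome']:<8} beta {r['beta']:+.3f} "
          f"per SD (q = {r['q_bh']:.1e})")

fib = fibre_scan(cohort, outcomes)
print(f"fibre scan: smallest q = {fib['q_bh'].min():.3f} "
      f"(no planted fibre effect, so no discovery expected)")

trait_z, _, _ = standardize(cohort["fasting_glucose_0"].rename("glucose"))
paired = trait_regression_with_without_hmi(cohort, trait_z, outcomes["HMI"])
veg = paired.set_index("factor").loc["vegetable"]
print(f"vegetable -> glucose: beta {veg['beta_without_hmi']:+.4f} without HMI, "
      f"{veg['beta_with_hmi']:+.4f} with HMI adjustment")
print("Near-identical coefficients mean the diet-trait association is not "
      "carried by the microbiome score in this cohort.")
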