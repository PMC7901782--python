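"""Nitrogen-cycling summaries and microbe-phenotype association tests.

Simulates tank water chemistry (ammonia -> nitrite -> nitrate cascade with
a fish-death nitrate spike in one tank), reduces nitrate to per-tank AUCs,
fits the nitrate ~ inoculum + dead_fish variance partition, and runs the
NB-LRT association stage on root genus counts against inoculum and fish
mortality.
"""

import numpy as np
import pandas as pd

from aquamicrobe import association as assoc
from aquamicrobe import nitrogen as nit
from aquamicrobe import synthetic as syn

design = syn.StudyDesign()
db = syn.default_reference_db(seed=3)
profiles = syn.simulate_communities(design, db, seed=3)
chem = syn.simulate_water_chemistry(design, seed=3)

inoc = pd.Series({t: design.inoculum_of(t) for t in design.tanks})
deaths = pd.Series({t: design.deaths_of(t) for t in design.tanks})
aunc = nit.tank_aucs(chem, "nitrate")
print("area under the nitrate curve (mg*day/L) per tank:")
print(aunc.round(1).to_string())
print(f"(tank {design.nitrate_spike_tank} carries the fish-death nitrate spike)")

t, df, p = nit.welch_t_test(aunc[inoc == "CIT"], aunc[inoc == "EIT"])
print(f"\nWelch t-test CIT vs EIT nitrate AUC: p = {p:.2f} "
      "(no inoculum effect on nitrogen)")
partition = nit.fit_nitrate_model(aunc, inoc, deaths)
print("variance partition of 'nitrate ~ inoculum + dead_fish':")
print(partition.table.round(3).to_string())

# root-genus association tests on multinomial counts from the designed truth
rng = np.random.default_rng(3)
root = [p for p in profiles if p.compartment == "root" and p.tank > 0]
counts = pd.DataFrame(
    {
        p.sample_id: pd.Series(
            rng.multinomial(3000, np.array(list(p.abundances.values()))),
            index=list(p.abundances),
        )
        for p in root
    }
).T
meta = pd.DataFrame(
    {p.sample_id: {"inoculum": design.inoculum_of(p.tank),
                   "dead_fish": design.deaths_of(p.tank)} for p in root}
).T
responses = pd.DataFrame(
    {
        "inoculum": (meta["inoculum"] == "EIT").astype(float),
        "dead_fish": meta["dead_fish"].astype(float),
    },
    index=counts.index,
)
results = assoc.associate(counts, responses, report_cutoff=300.0)
sig = results[(results["p_adjusted"] < 0.05) & results["passed_report_filter"]]
print("\nsignificant root associations (BH-adjusted p < 0.05, reportable):")
print(sig[["response", "taxon", "coefficient", "p_adjusted"]]
      .round(4).to_string(index=False))
print("\nPositive coefficients mean higher counts in EIT tanks. The "
      "pathogen-like genus is\nenriched under the established inoculum, the "
      "diazotroph under the commercial one,\nand fish mortality associates "
      "with nothing — it is orthogonal to the microbiota.")
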