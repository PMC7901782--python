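"""Rarefied diversity and the beta-diversity variance decomposition.

Runs the quantification-free part of the study on designed community
profiles converted to counts: rarefaction to a common depth, Shannon alpha
diversity over time, Bray-Curtis distances, PCoA, and the sequential
PERMANOVA partition across compartment, inoculum and their interaction.
"""

import numpy as np
import pandas as pd

from aquamicrobe import diversity as div
from aquamicrobe import synthetic as syn

design = syn.StudyDesign()
db = syn.default_reference_db(seed=2)
profiles = syn.simulate_communities(design, db, seed=2)

rng = np.random.default_rng(2)
counts = pd.DataFrame(
    {
        p.sample_id: pd.Series(
            rng.multinomial(3000, np.array(list(p.abundances.values()))),
            index=list(p.abundances),
        )
        for p in profiles
    }
).T
meta = pd.DataFrame(
    {
        p.sample_id: {
            "compartment": p.compartment,
            "inoculum": design.inoculum_of(p.tank),
            "day": p.day,
        }
        for p in profiles
    }
).T

rare = div.rarefy_table(counts, depth=2000, seed=2)
alpha = rare.apply(div.shannon, axis=1)
print("mean Shannon (nats) by day:")
print(alpha.groupby(meta["day"]).mean().round(3).to_string())

dist = div.bray_curtis(rare)
coords, _, props = div.pcoa(dist)
print(f"\nPCoA: first two axes explain "
      f"{100 * props.iloc[0]:.0f}% and {100 * props.iloc[1]:.0f}% of variance")

result = div.permanova(
    dist, meta, ["compartment", "inoculum", "compartment:inoculum"],
    n_perm=999, seed=2,
)
print("\nPERMANOVA (sequential):")
print(result.table.round(3).to_string())
print("\nCompartment separates communities more strongly than inoculum, and "
      "the terms\npartition the total distance variance exactly (R^2 column "
      "sums to 1).")
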