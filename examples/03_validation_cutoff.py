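"""Cross-platform concordance and the spurious-mapping abundance cutoff.

Emulates comparing a long-read abundance table against a short-read ground
truth: shared taxa agree on a log-log regression, while off-target
("spurious") taxa appear only in the long-read estimate at low abundance.
A 300-read-count cutoff removes nearly all of them.
"""

from aquamicrobe import synthetic as syn
from aquamicrobe.validation import compare_platforms, detect_taxa, spurious_fraction_removed

estimate, truth = syn.simulate_validation_tables(
    n_shared=30, n_spurious=50, spurious_mean=20.0, seed=4
)
conc = compare_platforms(estimate, truth)
print(f"shared taxa: {conc.n_shared_taxa}, spurious taxa: {conc.n_spurious}")
print(f"log10-abundance regression: R^2 = {conc.r_squared:.2f}, "
      f"slope = {conc.slope:.2f}, Spearman rho = {conc.spearman_rho:.2f}")

for cutoff in (50, 150, 300):
    rep = spurious_fraction_removed(estimate, truth, cutoff=cutoff)
    print(f"cutoff {cutoff:>4d}: removes {100 * rep.fraction_removed:.0f}% "
          "of spurious taxa")
print("Spurious mappings are low-abundance; the 300-count cutoff removes "
      ">96% of them\nwhile leaving genuinely abundant taxa untouched.")

import pandas as pd

table = pd.DataFrame(
    {"Nitrospira": [12], "Nitrosomonas": [420], "Pseudomonas": [5100]},
    index=["biofilter_d61"],
)
print("\nnitrifier watch list on a biofilter sample:")
print(detect_taxa(table).to_string(index=False))
print("Low-abundance nitrifiers are detectable before the cutoff but do not "
      "survive it\n— detection and abundance filtering are separate questions.")
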