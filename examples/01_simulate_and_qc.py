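"""Simulate nanopore-like 16S reads for one sample and run read QC.

Builds the default 5-genus reference database, draws the day-61 root
community of an EIT tank, simulates 2000 error-prone long reads (12%
nominal error, predicted median Phred ~15), then applies the QC rules:
trim 10 bp from the 5' end, cap at 1.5 kbp, drop reads with more than 200
expected errors or more than 2 N bases.
"""

import numpy as np

from aquamicrobe import synthetic as syn
from aquamicrobe.qc import run_qc

db = syn.default_reference_db(seed=1)
design = syn.StudyDesign()
profiles = syn.simulate_communities(design, db, seed=1)
profile = next(p for p in profiles if (p.tank, p.compartment, p.day) == (5, "root", 61))

print("community (genus -> relative abundance):")
for genus, frac in sorted(profile.abundances.items(), key=lambda kv: -kv[1]):
    print(f"  {genus:<14s} {frac:.3f}")

reads, truth = syn.simulate_reads(profile, db, 2000, seed=7)
median_q = np.median(np.concatenate([r.qualities for r in reads]))
passed, report = run_qc(reads)

print(f"\nsimulated reads:        {report.n_input}")
print(f"median predicted Phred: {median_q:.0f}  (the basecaller's optimism; "
      "realized error is ~12%)")
print(f"failed expected-errors: {report.n_fail_ee}")
print(f"failed N-count:         {report.n_fail_n}")
print(f"passed QC:              {report.n_pass} ({100 * report.pass_fraction:.1f}%)")
print("\nA pass rate near 70% mirrors a realistic nanopore amplicon run; the"
      "\nfailures are the low-quality tail of the predicted-quality mixture.")
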