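"""Resolve multi-mapped reads into genus abundances with EM.

Simulates one sample, scores each QC-passing read against every reference
by shared k-mers (the desk-scale stand-in for a long-read aligner; real PAF
files can be loaded with aquamicrobe.read_paf instead), builds the per-read
compatibility matrix, and compares EM abundance estimates against the naive
highest-scoring-match counts and the known simulation truth.
"""

import numpy as np
from scipy import stats

from aquamicrobe import em, synthetic as syn
from aquamicrobe.qc import run_qc

db = syn.default_reference_db(seed=1)
design = syn.StudyDesign()
profiles = syn.simulate_communities(design, db, seed=1)
profile = next(p for p in profiles if (p.tank, p.compartment, p.day) == (5, "root", 61))

reads, truth = syn.simulate_reads(profile, db, 2000, seed=7)
passed, _ = run_qc(reads)
alignments = syn.score_alignments(passed, db)
print(f"{len(passed)} reads -> {len(alignments)} candidate alignments "
      f"({len(alignments) / len(passed):.1f} per read: within-genus ambiguity)")

matrix = em.build_compatibility(alignments)
estimate = em.em_quantify(matrix)
genus_em = em.collapse_taxonomy(estimate.expected_counts, db.taxonomy)
genus_naive = em.collapse_taxonomy(em.naive_count(matrix).astype(float), db.taxonomy)
realized = truth.loc[[r.read_id for r in passed], "genus"].value_counts()

print(f"\nEM converged: {estimate.converged} after {estimate.n_iterations} iterations")
print(f"{'genus':<14s} {'truth':>7s} {'EM':>7s} {'naive':>7s}")
for genus in sorted(db.genera):
    print(f"{genus:<14s} {realized.get(genus, 0):>7d} "
          f"{genus_em.get(genus, 0.0):>7.0f} {genus_naive.get(genus, 0.0):>7.0f}")

genera = sorted(db.genera)
rho = stats.spearmanr(
    [realized.get(g, 0) for g in genera], [genus_em.get(g, 0) for g in genera]
).statistic
em_refs = int((np.floor(estimate.expected_counts + 0.5) >= 1).sum())
naive_refs = int((em.naive_count(matrix) >= 1).sum())
print(f"\nSpearman(truth, EM) = {rho:.2f} over {len(genera)} genera")
print(f"unique references with >=1 count: EM {em_refs} vs naive {naive_refs} — "
      "EM concentrates mass instead of\nscattering single reads across "
      "spurious references.")
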