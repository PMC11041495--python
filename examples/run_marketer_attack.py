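"""One complete marketer attack on a sampled speaker split.

An adversary with 300 identified (known) speakers tries to reidentify a
shared set of 40 de-identified probes, 5 of which truly overlap the known
set.  The pipeline: sample the split, fit PLDA on the known recordings,
bootstrap the strict acceptance threshold, score all probe x known pairs,
and count outcomes.
"""

import numpy as np

from voicerisk import (
    STRICT_SPEC,
    bootstrap_threshold,
    count_outcomes,
    fit_plda,
    generate_cohort,
    make_split,
    run_attack,
)
from voicerisk.experiments import vox_like_generator

cohort = generate_cohort(vox_like_generator(n_speakers=400, dim=16, seed=8))
split = make_split(cohort, n_known=300, n_unknown=40, n_overlap=5, seed=11)

rec_index = cohort.index_by_recording()
rows = np.array([rec_index[r] for recs in split.known_enrollment.values() for r in recs])
known_cohort = cohort.subset(rows)
model = fit_plda(known_cohort.X, known_cohort.speaker_ids)
cal = bootstrap_threshold(known_cohort, model, STRICT_SPEC,
                          subset_size=100, runs=100, seed=2)

table = run_attack(model, split, cohort, cal.value)
summary = count_outcomes(table, split)

print(f"threshold {cal.value:.2f} over {summary.comparisons} comparisons")
print(f"true acceptances:  {summary.ta} of {summary.genuine_pairs} overlap speakers")
print(f"false acceptances: {summary.fa}  (FAR {summary.far:.2e})")
print(f"precision: {summary.precision if summary.precision is not None else 'undefined'}")
# TA counts how many shared speakers the adversary correctly linked; every FA
# is an innocent speaker wrongly flagged as a match, diluting the attack.
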