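"""Statistical screening of interval-spectrum markers across a cohort.

Simulates a 50-subject cohort in which epilepsy-like subjects carry a
reduced, more irregular alpha rhythm and drug load adds frontal theta,
then screens every well-populated histogram bin (raw count > 100 in all
subjects) plus the descriptive/entropy markers with Kruskal-Wallis tests
for diagnosis and drug-load effects, Bonferroni-corrected.
"""

import numpy as np

from eegintervals import BandPass, CohortDesign, simulate_cohort
from eegintervals.screening import screen_markers
from eegintervals.spectra import subject_spectra

design = CohortDesign(
    n_per_group={"TLE": 12, "FLE": 13, "PNES": 12, "headache": 13},
    naed_probs={g: (0.25, 0.25, 0.25, 0.25)
                for g in ("TLE", "FLE", "PNES", "headache")},
    segment_durations={"post-Hv": 120.0},
    seed=0,
)
recs = simulate_cohort(design)

band = BandPass(4, 13)
spectra = {r.subject_id: subject_spectra(r, [band])[band] for r in recs}
result = screen_markers(
    spectra,
    {r.subject_id: r.meta.diagnosis for r in recs},
    {r.subject_id: r.meta.n_aed for r in recs},
)

print(f"{result.n_tests} markers tested per factor "
      f"(Bonferroni threshold {result.threshold_per_variable:.2e})")
best_d = result.table.loc[result.table["p_diag"].idxmin()]
best_a = result.table.loc[result.table["p_naed"].idxmin()]
print(f"strongest diagnosis effect: {best_d['marker']} "
      f"(p = {best_d['p_diag']:.4f})")
print(f"strongest drug-load effect: {best_a['marker']} "
      f"(p = {best_a['p_naed']:.4f})")
print("-> the diagnosis effect concentrates in the alpha interval range "
      "(77-125 ms) and the drug effect in the theta range (125-250 ms)")
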