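"""How much recording does the classifier actually need?

For each repetition a random subsegment of fixed duration is drawn
independently per subject from the T5+T6 channels of the post-Hv segment,
the alpha-score marker is recomputed on that subsegment alone, and naive
AUC over the cohort is taken; the curve of mean relative AUC (normalised
by the full-segment AUC) shows the cost of shorter recordings.
"""

from eegintervals import (
    BandPass,
    ClassifierSpec,
    CohortDesign,
    MarkerDef,
    case_control_ids,
    simulate_cohort,
    subsegment_experiment,
)

design = CohortDesign(
    n_per_group={"TLE": 10, "FLE": 0, "PNES": 10, "headache": 0},
    naed_probs={g: (1, 0, 0, 0) for g in ("TLE", "FLE", "PNES", "headache")},
    segment_durations={"post-Hv": 120.0},
    seed=0,
)
recs = simulate_cohort(design)
cases, controls = case_control_ids([r.meta for r in recs])

spec = ClassifierSpec(
    marker=MarkerDef("bin_count", bin_left_ms=100.0, invert=True),
    band=BandPass(4, 13),
    channel_group="T5+T6",
    segment_label="post-Hv",
)
curve = subsegment_experiment(recs, cases, controls, spec,
                              lengths_s=[10, 30, 60, 90, 120],
                              reps=100, seed=0)
print(curve.to_string(index=False,
                      float_format=lambda v: f"{v:.3f}"))
print("-> relative AUC approaches 1 as the subsegment grows; short "
      "segments cost discrimination because the interval histogram gets "
      "noisy")
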