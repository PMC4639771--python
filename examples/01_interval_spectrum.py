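"""From a recording to its zero-crossing interval spectrum.

Simulates one control-like subject (19 channels, 250 Hz, 60 s), band-passes
the signal at 4-13 Hz with zero phase, detects isoelectric-line crossings
and prints the shape of the pooled whole-recording interval spectrum.
A healthy posterior alpha rhythm near 10 Hz should place the spectrum's
peak near 100 ms (one interval per cycle: interval = 1000/f).
"""

import numpy as np

from eegintervals import BandPass, CohortDesign, SubjectMeta, simulate_subject
from eegintervals.markers import descriptive_markers, entropy_markers
from eegintervals.spectra import subject_spectra

design = CohortDesign(segment_durations={"post-Hv": 60.0})
rec = simulate_subject(design, SubjectMeta("demo", "headache"), seed_seq=42)

band = BandPass(4, 13)
spectrum = subject_spectra(rec, [band])[band]

peak = int(np.argmax(spectrum.p))
desc = descriptive_markers(spectrum)
hs, hmin = entropy_markers(spectrum)

print(f"subject: {rec.subject_id}, {len(rec.channels)} channels, "
      f"{rec.duration:.0f} s at {rec.fs:.0f} Hz")
print(f"intervals pooled: {spectrum.total}  (band {band})")
print(f"spectrum peak: bin [{peak * 4}, {peak * 4 + 4}) ms with "
      f"p = {spectrum.p[peak]:.3f}")
print(f"mean {desc['mean']:.1f} ms, median {desc['median']:.1f} ms, "
      f"mode {desc['mode']:.0f} ms")
print(f"Shannon entropy {hs:.2f} bits, min-entropy {hmin:.2f} bits")
print("-> the peak near 100 ms is the ~10 Hz alpha rhythm; low entropies "
      "mean a regular rhythm dominates the recording")
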