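"""Shared fixtures: small synthetic cohorts and canned spectra.

Heavy objects are session-scoped so the expensive simulation and
filtering run once per test session.
"""

import numpy as np
import pytest

from eegintervals import (
    BandPass,
    CohortDesign,
    IntervalSpectrum,
    case_control_ids,
    simulate_cohort,
)
from eegintervals.spectra import cohort_spectra


def make_spectrum(counts, **kw):
    c = np.zeros(1000, dtype=np.int64)
    for left_ms, n in counts.items():
        c[int(left_ms // 4)] = n
    return IntervalSpectrum(c, **kw)


@pytest.fixture(scope="session")
def effect_design():
    """25 epilepsy / 25 control subjects, no drug effects, one 60-s
    segment — the calibrated alpha-deficit study condition."""
    return CohortDesign(
        n_per_group={"TLE": 12, "FLE": 13, "PNES": 12, "headache": 13},
        naed_probs={g: (1, 0, 0, 0)
                    for g in ("TLE", "FLE", "PNES", "headache")},
        segment_durations={"post-Hv": 60.0},
        seed=0,
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_design):
    return simulate_cohort(effect_design)


@pytest.fixture(scope="session")
def effect_labels(effect_cohort):
    return case_control_ids([r.meta for r in effect_cohort])


@pytest.fixture(scope="session")
def coarse_grid():
    return [BandPass(lo, hi) for lo in (0, 2, 4, 6, 8)
            for hi in (9, 11, 13, 15)]


@pytest.fixture(scope="session")
def effect_grid_spectra(effect_cohort, coarse_grid):
    return cohort_spectra(effect_cohort, coarse_grid)


@pytest.fixture(scope="session")
def effect_screen_spectra(effect_grid_spectra):
    band = BandPass(4, 13)
    return {sid: by_band[band]
            for sid, by_band in effect_grid_spectra.items()}
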