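"""Statistical screening of candidate markers.

Markers (per-bin relative counts, descriptive statistics, entropies) are
screened with a nonparametric one-way Kruskal-Wallis ANOVA, separately
for the effect of diagnosis (4 groups: TLE, FLE, PNES, headache) and of
antiepileptic drug load nAED (4 groups: 0-3 drugs).  Multiple testing is
handled by Bonferroni correction; the test count is derived from the
data (number of eligible bins plus non-bin markers, per independent
variable) rather than fixed.  Only histogram bins whose raw interval
count exceeds 100 for *every* subject enter the scan, which confines the
analysis to well-populated, robust parts of the spectrum.

Post-hoc pairwise comparisons follow the Tukey-Kramer procedure applied
to mean ranks — the standard follow-up to a significant Kruskal-Wallis
test, with the honest-significant-difference critical value from the
studentized range and an unequal-n correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSpectrum
from .markers import DESCRIPTIVE_KINDS, descriptive_markers, entropy_markers

#: Non-bin markers always included in a screen.
NON_BIN_MARKERS = (*DESCRIPTIVE_KINDS, "shannon_entropy", "min_entropy")

MIN_RAW_COUNT = 100  # strict ">" eligibility threshold per subject


def eligible_bins(spectra: Sequence[IntervalSpectrum],
                  min_count: int = MIN_RAW_COUNT) -> np.ndarray:
    """Mask of bins whose raw count exceeds ``min_count`` for all subjects."""
    counts = np.stack([s.raw_counts for s in spectra])
    return counts.min(axis=0) > min_count


def kw_scan(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis rank test of ``values`` across the factor ``groups``.

    Returns ``(H, p)`` with tie correction and a chi-square reference
    distribution on k−1 degrees of freedom.  Completely tied data (every
    value identical) are defined as no evidence: ``(0.0, 1.0)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [values[groups == g] for g in np.unique(groups)]
    levels = [lv for lv in levels if lv.size]
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*levels)
    return float(h), float(p)


def posthoc_groups(
    values: Sequence[float],
    groups: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons of mean ranks.

    For groups *i*, *j* the statistic is
    ``|R̄_i − R̄_j| / sqrt(S² (1/n_i + 1/n_j))`` with the tie-corrected
    rank variance ``S² = (N(N+1)/12)·T``; p-values come from the
    studentized range with infinite error degrees of freedom, matching
    the classical multiple-comparison follow-up to Kruskal-Wallis.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    ranks = stats.rankdata(values)
    n_tot = len(values)
    # tie correction factor
    _, tie_counts = np.unique(values, return_counts=True)
    tie = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n_tot ** 3 - n_tot)
    s2 = n_tot * (n_tot + 1) / 12.0 * tie
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            ra = ranks[groups == labels[a]]
            rb = ranks[groups == labels[b]]
            diff = ra.mean() - rb.mean()
            se = np.sqrt(s2 * (1 / len(ra) + 1 / len(rb)))
            if se == 0:
                q = 0.0
            else:
                q = abs(diff) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append({"group_a": labels[a], "group_b": labels[b],
                         "mean_rank_diff": float(diff), "q": float(q),
                         "p_adj": p, "significant": p < alpha})
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Outcome of a full marker screen over a cohort.

    ``table`` has one row per tested marker with Kruskal-Wallis H and p
    for diagnosis and for nAED, and Bonferroni significance flags under
    both threshold conventions (per independent variable, and joint over
    both).  ``n_tests`` is the per-variable count.
    """

    table: pd.DataFrame
    eligible_mask: np.ndarray
    n_tests: int
    alpha: float = 0.05

    @property
    def threshold_per_variable(self) -> float:
        return self.alpha / self.n_tests

    @property
    def threshold_joint(self) -> float:
        return self.alpha / (2 * self.n_tests)

    def significant(self, variable: str = "diagnosis",
                    joint: bool = False) -> pd.DataFrame:
        thr = self.threshold_joint if joint else self.threshold_per_variable
        col = "p_diag" if variable == "diagnosis" else "p_naed"
        return self.table[self.table[col] < thr]


def screen_markers(
    spectra: Mapping[str, IntervalSpectrum],
    diagnosis: Mapping[str, str],
    n_aed: Mapping[str, int],
    alpha: float = 0.05,
    min_count: int = MIN_RAW_COUNT,
    include_non_bin: bool = True,
) -> ScreenResult:
    """Screen every eligible bin plus the non-bin markers of a cohort.

    ``spectra`` maps subject id to a whole-recording interval spectrum;
    ``diagnosis`` and ``n_aed`` give the two 4-level factors.
    """
    sids = list(spectra)
    slist = [spectra[s] for s in sids]
    diag = np.array([diagnosis[s] for s in sids])
    aed = np.array([n_aed[s] for s in sids])

    def scan(values, factor):
        # a single-level factor carries no contrast: report NaN, not an error
        if len(np.unique(factor)) < 2:
            return np.nan, np.nan
        return kw_scan(values, factor)
    mask = eligible_bins(slist, min_count)
    p_mat = np.stack([s.p for s in slist])  # subjects × bins
    lefts = slist[0].bin_lefts

    rows = []
    for b in np.nonzero(mask)[0]:
        h_d, p_d = scan(p_mat[:, b], diag)
        h_a, p_a = scan(p_mat[:, b], aed)
        rows.append({"marker": f"bin_{lefts[b]:g}ms",
                     "kind": "bin_count", "bin_left_ms": float(lefts[b]),
                     "H_diag": h_d, "p_diag": p_d,
                     "H_naed": h_a, "p_naed": p_a})
    if include_non_bin:
        desc = {sid: descriptive_markers(spectra[sid]) for sid in sids}
        ent = {sid: entropy_markers(spectra[sid]) for sid in sids}
        for kind in NON_BIN_MARKERS:
            if kind in DESCRIPTIVE_KINDS:
                vals = np.array([desc[sid][kind] for sid in sids])
            else:
                j = 0 if kind == "shannon_entropy" else 1
                vals = np.array([ent[sid][j] for sid in sids])
            h_d, p_d = scan(vals, diag)
            h_a, p_a = scan(vals, aed)
            rows.append({"marker": kind, "kind": kind, "bin_left_ms": np.nan,
                         "H_diag": h_d, "p_diag": p_d,
                         "H_naed": h_a, "p_naed": p_a})
    table = pd.DataFrame(rows)
    n_tests = len(table)
    thr = alpha / n_tests if n_tests else np.nan
    table["sig_diag"] = table["p_diag"] < thr
    table["sig_naed"] = table["p_naed"] < thr
    table["sig_diag_joint"] = table["p_diag"] < thr / 2
    table["sig_naed_joint"] = table["p_naed"] < thr / 2
    return ScreenResult(table=table, eligible_mask=mask, n_tests=n_tests,
                        alpha=alpha)
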