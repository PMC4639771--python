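"""ROC/AUC analysis and leave-pair-out cross-validation.

The AUC of a scalar score is estimated by pair counting: the fraction of
case-control pairs in which the case scores higher, ties crediting 0.5
(the Mann-Whitney statistic scaled to [0, 1]).  Because a "naive" AUC
maximised over free parameters (passband edges, interval-length bin,
channel group, segment) is optimistically biased, classifiers are
evaluated by leave-pair-out cross-validation (LPO-CV): every case-control
pair is held out once, the classifier's parameters are fitted to maximise
AUC on the remainder, the held-out pair is scored with the fitted
parameters, and AUC* is the fraction of held-out pairs ranked correctly.

Four objectives are provided:

``alpha_score``
    minimise in-fold AUC of a single-bin marker over the alpha interval
    range (77-125 ms) × passband grid, then invert the classifier
    (epilepsy shows *reduced* alpha-interval counts);
``theta_score``
    maximise over the theta interval range (125-250 ms) × passband grid
    (drug load *increases* theta-interval counts);
``shannon_score`` / ``minentropy_score``
    maximise the AUC of the spectrum entropy over the passband grid.

With ``two_step`` the whole-recording fit is followed by a second
maximisation over singleton (channel group × segment) combinations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import BandPass
from .intervals import (
    ALPHA_RANGE_MS,
    THETA_RANGE_MS,
    IntervalSpectrum,
    bins_in_range,
    build_histogram,
    crossings_to_intervals,
    detect_crossings,
    pool_and_normalize,
)
from .markers import MarkerDef, entropy_markers

OBJECTIVES = ("alpha_score", "shannon_score", "minentropy_score",
              "theta_score")


@dataclass(frozen=True)
class ClassifierSpec:
    """A fitted classifier: marker + passband (+ channel group/segment).

    A whole-recording spec leaves ``channel_group`` and ``segment_label``
    unset.  ``marker.invert`` records classifier inversion (score =
    negated marker, AUC → 1 − AUC).
    """

    marker: MarkerDef
    band: BandPass
    channel_group: str | None = None
    segment_label: str | None = None


@dataclass
class FoldResult:
    case_id: str
    control_id: str
    spec: ClassifierSpec
    infold_auc: float          # maximised in-fold AUC of the final fit
    held_out_win: float        # 1 / 0.5 / 0
    first_step_auc: float = float("nan")   # whole-recording in-fold max
    second_step_aucs: dict[tuple[str, str], float] | None = None


@dataclass
class CVResult:
    """Leave-pair-out cross-validation outcome."""

    auc_star: float
    folds: list[FoldResult]
    param_mode: ClassifierSpec
    objective: str
    two_step: bool = False

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def param_counts(self) -> Counter:
        return Counter(f.spec for f in self.folds)


def auc(scores_cases: Sequence[float],
        scores_controls: Sequence[float]) -> float:
    """Pair-counting AUC with ties credited 0.5.

    Equals the probability that a randomly chosen case scores higher than
    a randomly chosen control, and the Wilcoxon rank-sum statistic scaled
    to [0, 1].
    """
    cases = np.asarray(scores_cases, dtype=float)
    controls = np.asarray(scores_controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return float((wins + 0.5 * ties) / (cases.size * controls.size))


def _win_table(feat_cases: np.ndarray,
               feat_controls: np.ndarray) -> np.ndarray:
    """Pairwise win scores, shape (n_cases, n_controls, n_candidates)."""
    a = feat_cases[:, None, :]
    b = feat_controls[None, :, :]
    return (a > b) + 0.5 * (a == b)


# ---------------------------------------------------------------------------
# Naive AUC curves
# ---------------------------------------------------------------------------

def auc_curve(
    spectra: Mapping[str, IntervalSpectrum],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    bins: np.ndarray | None = None,
    useful_threshold: float = 0.75,
) -> pd.DataFrame:
    """Naive AUC versus interval length over whole-recording spectra.

    One AUC per bin (all bins by default; pass an eligibility mask index
    array to restrict).  The usefulness region is flagged where
    AUC > 0.75 or, equivalently under inversion, < 0.25.
    """
    any_s = next(iter(spectra.values()))
    if bins is None:
        bins = np.arange(len(any_s.raw_counts))
    pc = np.stack([spectra[s].p for s in case_ids])
    pk = np.stack([spectra[s].p for s in control_ids])
    rows = []
    lefts = any_s.bin_lefts
    for b in bins:
        a = auc(pc[:, b], pk[:, b])
        rows.append({"bin_left_ms": float(lefts[b]), "auc": a,
                     "useful": a > useful_threshold
                     or a < 1 - useful_threshold})
    return pd.DataFrame(rows)


def fourier_auc_curve(
    psd: Mapping[str, tuple[np.ndarray, np.ndarray]],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    useful_threshold: float = 0.75,
) -> pd.DataFrame:
    """Naive AUC versus inverse frequency for Welch power densities.

    ``psd`` maps subject id to ``(freqs, pxx)`` on a common frequency
    grid; the curve is indexed by 1000/f ms to overlay the interval axis.
    """
    freqs = next(iter(psd.values()))[0]
    mat_c = np.stack([psd[s][1] for s in case_ids])
    mat_k = np.stack([psd[s][1] for s in control_ids])
    rows = []
    for j, f in enumerate(freqs):
        if f <= 0:
            continue
        a = auc(mat_c[:, j], mat_k[:, j])
        rows.append({"freq_hz": float(f), "inverse_ms": 1000.0 / f,
                     "auc": a, "useful": a > useful_threshold
                     or a < 1 - useful_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Leave-pair-out cross-validation
# ---------------------------------------------------------------------------

def _objective_candidates(
    objective: str,
    bands: Sequence[BandPass],
    bin_width_ms: float,
) -> tuple[list[tuple[BandPass, float | None]], bool]:
    """Candidate (band, bin_left_ms) list in lexicographic order, and
    whether the fit minimises (then inverts) rather than maximises."""
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    bands = sorted(bands, key=lambda b: (b.lo, b.hi))
    if objective in ("shannon_score", "minentropy_score"):
        return [(b, None) for b in bands], False
    rng = ALPHA_RANGE_MS if objective == "alpha_score" else THETA_RANGE_MS
    lefts = bins_in_range(*rng, bin_width_ms) * bin_width_ms
    cands = [(b, float(x)) for b in bands for x in lefts]
    return cands, objective == "alpha_score"


def _feature_value(spectrum: IntervalSpectrum, objective: str,
                   bin_left_ms: float | None) -> float:
    if bin_left_ms is not None:
        return float(spectrum.p[spectrum.bin_index(bin_left_ms)])
    hs, hmin = entropy_markers(spectrum)
    return hs if objective == "shannon_score" else hmin


def _marker_def(objective: str, bin_left_ms: float | None,
                invert: bool) -> MarkerDef:
    if bin_left_ms is not None:
        return MarkerDef("bin_count", bin_left_ms=bin_left_ms, invert=invert)
    kind = ("shannon_entropy" if objective == "shannon_score"
            else "min_entropy")
    return MarkerDef(kind, invert=invert)


def lpo_cv(
    spectra: Mapping[str, Mapping],
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    objective: str,
    two_step: bool = False,
    bands: Sequence[BandPass] | None = None,
) -> CVResult:
    """Leave-pair-out cross-validation of one classifier objective.

    ``spectra`` maps subject id → {band: IntervalSpectrum} (one-step) or
    subject id → {band: {(channel_group, segment): IntervalSpectrum}}
    including the key ``("whole", "whole")`` (required for two-step).
    Every case-control pair forms one fold.  Ties among equally good
    candidates break towards the lexicographically smallest
    (band.lo, band.hi, bin, channel-group, segment).
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    first = next(iter(spectra.values()))
    nested = isinstance(next(iter(first.values())), Mapping)
    if two_step and not nested:
        raise ValueError("two-step fitting needs per-(group, segment) "
                         "spectra; compute them with per_group_segment=True")
    if bands is None:
        bands = sorted(first.keys(), key=lambda b: (b.lo, b.hi))

    def whole(sid, band) -> IntervalSpectrum:
        s = spectra[sid][band]
        return s[("whole", "whole")] if nested else s

    any_s = whole(case_ids[0], bands[0])
    cands, minimise = _objective_candidates(objective, bands,
                                            any_s.bin_width_ms)
    sids = case_ids + control_ids
    feats = np.empty((len(sids), len(cands)))
    for i, sid in enumerate(sids):
        by_band: dict[BandPass, IntervalSpectrum] = {
            b: whole(sid, b) for b in bands}
        for c, (band, left) in enumerate(cands):
            feats[i, c] = _feature_value(by_band[band], objective, left)

    n1, n2 = len(case_ids), len(control_ids)
    fc, fk = feats[:n1], feats[n1:]
    W = _win_table(fc, fk)                      # (n1, n2, C)
    total = W.sum(axis=(0, 1))
    row = W.sum(axis=1)                         # (n1, C)
    col = W.sum(axis=0)                         # (n2, C)
    denom = (n1 - 1) * (n2 - 1)

    gs_keys: list[tuple[str, str]] = []
    gs_feats_cache: dict[int, np.ndarray] = {}
    if two_step:
        key_sets = [set(spectra[sid][bands[0]]) for sid in sids]
        common = set.intersection(*key_sets) - {("whole", "whole")}
        gs_keys = sorted(common)
        if not gs_keys:
            raise ValueError("no (channel group, segment) shared by all "
                             "subjects")

    def gs_features(cand_idx: int) -> np.ndarray:
        """Signed score per subject × (group, segment) for one candidate."""
        if cand_idx not in gs_feats_cache:
            band, left = cands[cand_idx]
            m = np.empty((len(sids), len(gs_keys)))
            for i, sid in enumerate(sids):
                for j, key in enumerate(gs_keys):
                    v = _feature_value(spectra[sid][band][key], objective,
                                       left)
                    m[i, j] = -v if minimise else v
            gs_feats_cache[cand_idx] = m
        return gs_feats_cache[cand_idx]

    folds: list[FoldResult] = []
    wins = 0.0
    for i, cid in enumerate(case_ids):
        for j, kid in enumerate(control_ids):
            infold = (total - row[i] - col[j] + W[i, j]) / denom
            best = int(np.argmin(infold) if minimise else np.argmax(infold))
            band, left = cands[best]
            score_auc = float(1 - infold[best] if minimise else infold[best])
            spec = ClassifierSpec(
                marker=_marker_def(objective, left, minimise), band=band)
            second: dict[tuple[str, str], float] | None = None
            if two_step:
                g = gs_features(best)
                gW = _win_table(g[:n1], g[n1:])
                g_in = ((gW.sum(axis=(0, 1)) - gW.sum(axis=1)[i]
                         - gW.sum(axis=0)[j] + gW[i, j]) / denom)
                gbest = int(np.argmax(g_in))
                second = {key: float(a) for key, a in zip(gs_keys, g_in)}
                grp, seg = gs_keys[gbest]
                spec = ClassifierSpec(marker=spec.marker, band=band,
                                      channel_group=grp, segment_label=seg)
                sc = gs_features(best)[:, gbest]
                case_score, control_score = sc[i], sc[n1 + j]
                infold_score = float(g_in[gbest])
            else:
                sign = -1.0 if minimise else 1.0
                case_score = sign * fc[i, best]
                control_score = sign * fk[j, best]
                infold_score = score_auc
            win = (1.0 if case_score > control_score
                   else 0.5 if case_score == control_score else 0.0)
            wins += win
            folds.append(FoldResult(
                case_id=cid, control_id=kid, spec=spec,
                infold_auc=infold_score, held_out_win=win,
                first_step_auc=score_auc, second_step_aucs=second))

    auc_star = wins / (n1 * n2)
    mode_spec = Counter(f.spec for f in folds).most_common(1)[0][0]
    return CVResult(auc_star=float(auc_star), folds=folds,
                    param_mode=mode_spec, objective=objective,
                    two_step=two_step)


def auc_ratio_map(cv: CVResult) -> pd.DataFrame:
    """Second-step AUC normalised by the fold's first-step maximum,
    averaged over folds: rows = channel groups, columns = segments.

    Ratios may exceed 1 because the second step scores restricted
    channel/segment data that the first (whole-recording) step pooled.
    """
    if not cv.two_step or any(f.second_step_aucs is None for f in cv.folds):
        raise ValueError("auc_ratio_map needs a two-step CVResult")
    keys = sorted(cv.folds[0].second_step_aucs)
    acc: dict[tuple[str, str], list[float]] = {k: [] for k in keys}
    for f in cv.folds:
        ref = max(f.first_step_auc, 1e-12)
        for k in keys:
            acc[k].append(f.second_step_aucs[k] / ref)
    groups = sorted({g for g, _ in keys})
    segs = sorted({s for _, s in keys})
    mat = pd.DataFrame(index=groups, columns=segs, dtype=float)
    for (g, s), vals in acc.items():
        mat.loc[g, s] = float(np.mean(vals))
    return mat


# ---------------------------------------------------------------------------
# Segment-length experiment
# ---------------------------------------------------------------------------

def subsegment_experiment(
    recordings: Sequence,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    spec: ClassifierSpec,
    lengths_s: Sequence[float],
    reps: int = 100,
    seed: int = 0,
    filter_order: int = 500,
) -> pd.DataFrame:
    """How naive AUC depends on the analysed segment length.

    For each repetition a random subsegment of fixed duration is chosen
    *independently for each subject* inside ``spec.segment_label`` (on
    ``spec.channel_group`` channels), the marker is recomputed and naive
    AUC taken over the cohort; mean ± sd over ``reps`` repetitions is
    normalised by the AUC of the full segment.  Deterministic given
    ``seed``.
    """
    from .filters import apply_zero_phase, get_filter
    from .io_core import extract_segment

    if spec.segment_label is None or spec.channel_group is None:
        raise ValueError("spec must name a channel group and segment")
    channels = spec.channel_group.split("+")
    rng = np.random.default_rng(seed)
    recs = {r.subject_id: r for r in recordings}
    sids = list(case_ids) + list(control_ids)

    crossings: dict[str, list[np.ndarray]] = {}
    seg_dur: dict[str, float] = {}
    for sid in sids:
        rec = recs[sid]
        block = extract_segment(rec, spec.segment_label, channels)
        filt = get_filter(spec.band, rec.fs, filter_order)
        y = apply_zero_phase(block, filt)
        crossings[sid] = [detect_crossings(row, rec.fs) for row in y]
        start, end = rec.segments[spec.segment_label]
        seg_dur[sid] = end - start

    def marker_at(sid: str, t0_ms: float, t1_ms: float) -> float:
        parts = []
        for t in crossings[sid]:
            sel = t[(t >= t0_ms) & (t < t1_ms)]
            parts.append(build_histogram(crossings_to_intervals(sel)))
        s = pool_and_normalize(parts, band=spec.band, subject_id=sid)
        return spec.marker.evaluate(s)

    def cohort_auc(starts: Mapping[str, float], length_s: float) -> float:
        vals = {sid: marker_at(sid, starts[sid] * 1000.0,
                               (starts[sid] + length_s) * 1000.0)
                for sid in sids}
        return auc([vals[s] for s in case_ids],
                   [vals[s] for s in control_ids])

    full_auc = cohort_auc({sid: 0.0 for sid in sids},
                          min(seg_dur.values()))
    rows = []
    for length in lengths_s:
        if length > min(seg_dur.values()) + 1e-9:
            raise ValueError(f"length {length} s exceeds the segment")
        rel = []
        for _ in range(reps):
            starts = {sid: rng.uniform(0.0, seg_dur[sid] - length)
                      for sid in sids}
            rel.append(cohort_auc(starts, length) / full_auc)
        rows.append({"length_s": float(length),
                     "mean_rel_auc": float(np.mean(rel)),
                     "sd_rel_auc": float(np.std(rel, ddof=0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Averaged ROC curves
# ---------------------------------------------------------------------------

def averaged_roc(
    fold_scores: Sequence[tuple[Sequence[float], Sequence[float]]],
    grid_points: int = 101,
) -> pd.DataFrame:
    """Vertically averaged ROC: mean sensitivity at each specificity.

    ``fold_scores`` holds per-fold ``(case_scores, control_scores)``
    pairs.  These curves are built from in-fold fitted scores, not from
    cross-validation, and may be optimistically biased — a warning is
    emitted to that effect.
    """
    warnings.warn("averaged ROC curves are built from in-fold fitted "
                  "scores and may be optimistically biased",
                  stacklevel=2)
    fpr_grid = np.linspace(0.0, 1.0, grid_points)
    sens = []
    for cases, controls in fold_scores:
        cases = np.asarray(cases, float)
        controls = np.asarray(controls, float)
        thr = np.unique(np.concatenate([cases, controls]))[::-1]
        tpr = [0.0]
        fpr = [0.0]
        for t in thr:
            tpr.append(np.mean(cases >= t))
            fpr.append(np.mean(controls >= t))
        sens.append(np.interp(fpr_grid, fpr, tpr))
    mean_sens = np.mean(sens, axis=0)
    return pd.DataFrame({"specificity": 1.0 - fpr_grid,
                         "fpr": fpr_grid,
                         "mean_sensitivity": mean_sens})
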