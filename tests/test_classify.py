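"""AUC estimation, LPO cross-validation, ratio maps, subsegment curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegintervals import (
    BandPass,
    ClassifierSpec,
    CohortDesign,
    MarkerDef,
    auc,
    auc_curve,
    auc_ratio_map,
    averaged_roc,
    case_control_ids,
    fourier_auc_curve,
    lpo_cv,
    simulate_cohort,
    subsegment_experiment,
)
from eegintervals.markers import entropy_markers
from eegintervals.spectra import cohort_spectra

from conftest import make_spectrum


def brute_force_auc(cases, controls):
    """Independent oracle: explicit double loop over all pairs."""
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else 0.5 if c == k else 0.0
    return wins / (len(cases) * len(controls))


class TestAuc:
    def test_enumerated_example(self):
        # pairs: (2,1)+ (2,2)~ (3,1)+ (3,2)+ -> 3.5/4
        assert auc([2, 3], [1, 2]) == pytest.approx(0.875)

    def test_perfect_separation(self):
        assert auc([5, 6], [1, 2]) == 1.0

    def test_pure_tie(self):
        assert auc([1.0], [1.0]) == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            auc([], [1.0])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        vals = st.floats(min_value=-5, max_value=5, allow_nan=False)
        # coarse grid induces ties
        coarse = st.integers(min_value=-3, max_value=3).map(float)
        strat = st.one_of(vals, coarse)
        cases = data.draw(st.lists(strat, min_size=1, max_size=20))
        controls = data.draw(st.lists(strat, min_size=1, max_size=20))
        assert auc(cases, controls) == pytest.approx(
            brute_force_auc(cases, controls))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        c, k = rng.normal(1, 1, 12), rng.normal(0, 1, 15)
        assert auc(np.exp(c), np.exp(k)) == pytest.approx(auc(c, k))


class TestAucCurve:
    @staticmethod
    def toy_spectra(seed=0, n=16, effect=-400):
        rng = np.random.default_rng(seed)
        out, cases, controls = {}, [], []
        for i in range(n):
            is_case = i < n // 2
            alpha = 1600 + (effect if is_case else 0) + rng.integers(0, 300)
            out[f"s{i}"] = make_spectrum(
                {96: alpha, 160: 900 + rng.integers(0, 200), 240: 500})
            (cases if is_case else controls).append(f"s{i}")
        return out, cases, controls

    def test_minimum_in_alpha_range(self):
        sp, cases, controls = self.toy_spectra()
        df = auc_curve(sp, cases, controls, bins=np.array([24, 40, 60]))
        assert df.loc[df["auc"].idxmin(), "bin_left_ms"] == 96.0

    def test_label_inversion_reflects(self):
        sp, cases, controls = self.toy_spectra()
        bins = np.array([24, 40, 60])
        a = auc_curve(sp, cases, controls, bins=bins)["auc"]
        b = auc_curve(sp, controls, cases, bins=bins)["auc"]
        np.testing.assert_allclose(a, 1.0 - b)

    def test_permuted_labels_stay_inside_useful_band(self):
        sp, cases, controls = self.toy_spectra(effect=0, n=32)
        rng = np.random.default_rng(7)
        sids = cases + controls
        inside = 0
        n_perm = 50
        for _ in range(n_perm):
            perm = rng.permutation(sids)
            df = auc_curve(sp, perm[:16], perm[16:],
                           bins=np.array([24, 40, 60]))
            inside += not df["useful"].any()
        assert inside / n_perm >= 0.90

    def test_fourier_curve_inverse_axis(self):
        rng = np.random.default_rng(2)
        freqs = np.arange(1.0, 20.0)
        psd = {f"s{i}": (freqs, rng.random(len(freqs)) + (2.0 * (freqs == 10)
                         if i < 5 else 0)) for i in range(10)}
        df = fourier_auc_curve(psd, [f"s{i}" for i in range(5)],
                               [f"s{i}" for i in range(5, 10)])
        row = df[df["freq_hz"] == 10.0].iloc[0]
        assert row["inverse_ms"] == pytest.approx(100.0)
        assert row["auc"] > 0.75


class TestLpoCv:
    @staticmethod
    def entropy_cohort(seed=0, shift=1.0, n=8):
        """Spectra whose entropy separates cases from controls."""
        rng = np.random.default_rng(seed)
        band = BandPass(4, 13)
        sp, cases, controls = {}, [], []
        for i in range(2 * n):
            is_case = i < n
            width = 12 if is_case and shift else 4
            counts = {4 * (20 + k): int(1000 * np.exp(-k / width)) + 1
                      for k in range(30)}
            counts[96] = counts[96] + int(rng.integers(0, 200))
            sid = f"s{i}"
            sp[sid] = {band: make_spectrum(counts, band=band)}
            (cases if is_case else controls).append(sid)
        return sp, cases, controls

    def test_single_candidate_reduces_to_plain_auc(self):
        """With one band and an entropy objective there is no fitting
        freedom, so LPO-CV equals pair counting of the fixed marker."""
        sp, cases, controls = self.entropy_cohort()
        cv = lpo_cv(sp, cases, controls, "shannon_score")
        band = next(iter(sp[cases[0]]))
        hs = {s: entropy_markers(sp[s][band])[0] for s in sp}
        expected = auc([hs[s] for s in cases], [hs[s] for s in controls])
        assert cv.auc_star == pytest.approx(expected)
        assert cv.n_folds == len(cases) * len(controls)

    def test_degenerate_groups_raise(self):
        sp, cases, controls = self.entropy_cohort()
        with pytest.raises(ValueError):
            lpo_cv(sp, cases[:1], controls, "shannon_score")

    def test_unknown_objective(self):
        sp, cases, controls = self.entropy_cohort()
        with pytest.raises(ValueError):
            lpo_cv(sp, cases, controls, "beta_score")

    def test_effect_cohort_alpha_score(self, effect_grid_spectra,
                                       effect_labels):
        """Calibrated alpha-deficit cohort: cross-validated AUC* is high
        and the fitted bin concentrates near the planted 100-ms period."""
        cases, controls = effect_labels
        cv = lpo_cv(effect_grid_spectra, cases, controls, "alpha_score")
        assert cv.auc_star >= 0.7
        assert cv.param_mode.marker.invert
        assert 88 <= cv.param_mode.marker.bin_left_ms <= 108

    def test_cv_removes_optimism(self, effect_grid_spectra, effect_labels):
        """AUC* never exceeds the mean maximised in-fold AUC."""
        cases, controls = effect_labels
        cv = lpo_cv(effect_grid_spectra, cases, controls, "alpha_score")
        mean_infold = np.mean([f.infold_auc for f in cv.folds])
        assert cv.auc_star <= mean_infold + 1e-9


class TestTwoStep:
    @pytest.fixture(scope="class")
    def localized_cohort(self):
        """Epilepsy deficit confined to T5/T6 in post-Hv only.

        Subject heterogeneity is reduced so the faint whole-recording
        trace of the localized effect can steer the first fitting step
        towards the planted bin.
        """
        design = CohortDesign(
            n_per_group={"TLE": 8, "FLE": 0, "PNES": 8, "headache": 0},
            naed_probs={g: (1, 0, 0, 0)
                        for g in ("TLE", "FLE", "PNES", "headache")},
            segment_durations={"Hv": 40.0, "post-Hv": 40.0},
            effect_channels=("T5", "T6"),
            effect_segments=("post-Hv",),
            epilepsy_alpha_deficit=0.8,
            alpha_freq_sd=0.1,
            alpha_amp_subject_sd=0.05,
            jitter_subject_sd=0.0,
            seed=3,
        )
        recs = simulate_cohort(design)
        bands = [BandPass(4, 13)]
        spectra = cohort_spectra(recs, bands, per_group_segment=True)
        cases, controls = case_control_ids([r.meta for r in recs])
        return spectra, cases, controls

    def test_ratio_map_peaks_at_injected_site(self, localized_cohort):
        spectra, cases, controls = localized_cohort
        cv = lpo_cv(spectra, cases, controls, "alpha_score", two_step=True)
        ratio = auc_ratio_map(cv)
        best = ratio.stack().idxmax()
        assert best == ("T5+T6", "post-Hv")

    def test_two_step_requires_nested_spectra(self, effect_grid_spectra,
                                              effect_labels):
        cases, controls = effect_labels
        with pytest.raises(ValueError, match="two-step"):
            lpo_cv(effect_grid_spectra, cases, controls, "alpha_score",
                   two_step=True)


class TestSubsegment:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        design = CohortDesign(
            n_per_group={"TLE": 5, "FLE": 0, "PNES": 5, "headache": 0},
            naed_probs={g: (1, 0, 0, 0)
                        for g in ("TLE", "FLE", "PNES", "headache")},
            segment_durations={"post-Hv": 40.0},
            seed=2,
        )
        recs = simulate_cohort(design)
        cases, controls = case_control_ids([r.meta for r in recs])
        spec = ClassifierSpec(
            marker=MarkerDef("bin_count", bin_left_ms=96, invert=True),
            band=BandPass(4, 13), channel_group="T5+T6",
            segment_label="post-Hv")
        return recs, cases, controls, spec

    def test_full_length_is_exactly_one(self, small_cohort):
        recs, cases, controls, spec = small_cohort
        df = subsegment_experiment(recs, cases, controls, spec,
                                   lengths_s=[40.0], reps=5, seed=0)
        assert df["mean_rel_auc"].iloc[0] == pytest.approx(1.0)
        assert df["sd_rel_auc"].iloc[0] == 0.0

    def test_seed_reproducibility(self, small_cohort):
        recs, cases, controls, spec = small_cohort
        a = subsegment_experiment(recs, cases, controls, spec,
                                  lengths_s=[10.0, 20.0], reps=10, seed=42)
        b = subsegment_experiment(recs, cases, controls, spec,
                                  lengths_s=[10.0, 20.0], reps=10, seed=42)
        assert a.equals(b)

    def test_too_long_raises(self, small_cohort):
        recs, cases, controls, spec = small_cohort
        with pytest.raises(ValueError):
            subsegment_experiment(recs, cases, controls, spec,
                                  lengths_s=[100.0], reps=2, seed=0)


class TestAveragedRoc:
    def test_identical_folds_equal_single_roc(self):
        cases, controls = [3.0, 2.0, 1.5], [1.0, 0.5]
        with pytest.warns(UserWarning, match="biased"):
            one = averaged_roc([(cases, controls)])
            two = averaged_roc([(cases, controls)] * 5)
        np.testing.assert_allclose(one["mean_sensitivity"],
                                   two["mean_sensitivity"])

    def test_perfect_classifier_steps_through_corner(self):
        with pytest.warns(UserWarning):
            df = averaged_roc([([2.0, 3.0], [0.0, 1.0])])
        # at specificity 1 (fpr 0) sensitivity is already 1
        assert df[df["fpr"] == 0.0]["mean_sensitivity"].iloc[0] == 1.0

    def test_random_scores_near_diagonal(self):
        rng = np.random.default_rng(0)
        folds = [(rng.normal(size=30), rng.normal(size=30))
                 for _ in range(40)]
        with pytest.warns(UserWarning):
            df = averaged_roc(folds)
        dev = np.abs(df["mean_sensitivity"] - df["fpr"])
        assert dev.max() < 0.1
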