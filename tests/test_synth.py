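"""Synthetic cohort generator: determinism, planted effects, honesty."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from eegintervals import (
    BandPass,
    CohortDesign,
    SubjectMeta,
    build_histogram,
    crossings_to_intervals,
    detect_crossings,
    simulate_cohort,
    simulate_subject,
)
from eegintervals.intervals import bins_in_range
from eegintervals.markers import entropy_markers
from eegintervals.spectra import subject_spectra
from eegintervals.synth import cohort_metas, null_design


def small_design(**kw):
    base = dict(
        n_per_group={"TLE": 10, "FLE": 0, "PNES": 10, "headache": 0},
        naed_probs={g: (1, 0, 0, 0)
                    for g in ("TLE", "FLE", "PNES", "headache")},
        segment_durations={"post-Hv": 40.0},
        seed=0,
    )
    base.update(kw)
    return CohortDesign(**base)


class TestDeterminism:
    def test_same_seed_identical_signals(self):
        a = simulate_cohort(small_design(n_per_group={"TLE": 2, "FLE": 0,
                                                      "PNES": 0,
                                                      "headache": 1}))
        b = simulate_cohort(small_design(n_per_group={"TLE": 2, "FLE": 0,
                                                      "PNES": 0,
                                                      "headache": 1}))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.signal, rb.signal)

    def test_edf_payload_bit_identical(self, tmp_path):
        design = small_design(n_per_group={"TLE": 1, "FLE": 0, "PNES": 0,
                                           "headache": 0})
        simulate_cohort(design, out_dir=tmp_path / "a")
        simulate_cohort(design, out_dir=tmp_path / "b")
        pa = (tmp_path / "a" / "TLE01.edf").read_bytes()
        pb = (tmp_path / "b" / "TLE01.edf").read_bytes()
        assert pa == pb

    def test_different_seed_differs(self):
        a = simulate_cohort(small_design(seed=0))[0]
        b = simulate_cohort(small_design(seed=1))[0]
        assert not np.array_equal(a.signal, b.signal)


class TestOscillatorLimit:
    def test_noiseless_regular_alpha_is_two_bin(self):
        """With jitter, noise and artifacts off, O1's rising-crossing
        intervals concentrate (>=99%) in the two bins at 1000/f."""
        design = small_design(
            alpha_jitter_sd=0.0, jitter_subject_sd=0.0, amp_mod_sd=0.0,
            noise_amp_uv=0.0, artifact_rate_per_min=0.0,
            alpha_freq_sd=0.0, theta_amp_base_uv=0.0)
        meta = SubjectMeta("c1", "headache")
        rec = simulate_subject(design, meta, 5)
        o1 = rec.signal[rec.channel_index("O1")]
        iv = crossings_to_intervals(detect_crossings(o1, rec.fs))
        counts, _ = build_histogram(iv)
        p = counts / counts.sum()
        period_bin = int(1000.0 / design.alpha_freq_mean // 4)
        assert p[period_bin - 1:period_bin + 2].sum() >= 0.99


class TestPlantedEffects:
    band = BandPass(4, 13)

    def cohort_markers(self, design):
        recs = simulate_cohort(design)
        alpha_bins = bins_in_range(77, 125)
        theta_bins = bins_in_range(125, 250)
        rows = {}
        for r in recs:
            s = subject_spectra(r, [self.band])[self.band]
            hs, _ = entropy_markers(s)
            rows[r.subject_id] = {
                "alpha": s.p[alpha_bins].sum(),
                "theta": s.p[theta_bins].sum(),
                "hs": hs,
                "meta": r.meta,
            }
        return rows

    def test_epilepsy_reduces_alpha_and_raises_entropy(self):
        rows = self.cohort_markers(small_design(
            n_per_group={"TLE": 25, "FLE": 0, "PNES": 25, "headache": 0},
            segment_durations={"post-Hv": 60.0}))
        ep = [v for v in rows.values() if v["meta"].is_epilepsy]
        ct = [v for v in rows.values() if not v["meta"].is_epilepsy]
        p_alpha = mannwhitneyu([e["alpha"] for e in ep],
                               [c["alpha"] for c in ct],
                               alternative="less").pvalue
        p_hs = mannwhitneyu([e["hs"] for e in ep], [c["hs"] for c in ct],
                            alternative="greater").pvalue
        assert p_alpha < 0.01
        assert p_hs < 0.01

    def test_drug_load_raises_theta_mass(self):
        design = small_design(
            n_per_group={"TLE": 0, "FLE": 0, "PNES": 0, "headache": 40},
            naed_probs={"headache": (0.5, 0.0, 0.0, 0.5),
                        "TLE": (1, 0, 0, 0), "FLE": (1, 0, 0, 0),
                        "PNES": (1, 0, 0, 0)})
        rows = self.cohort_markers(design)
        hi = [v["theta"] for v in rows.values() if v["meta"].n_aed == 3]
        lo = [v["theta"] for v in rows.values() if v["meta"].n_aed == 0]
        assert len(hi) >= 5 and len(lo) >= 5
        p = mannwhitneyu(hi, lo, alternative="greater").pvalue
        assert p < 0.01

    def test_effects_dominate_their_home_range(self):
        """Normalized spectra are compositional, so each planted effect
        spills into the other band; what must hold is dominance — the
        epilepsy effect separates alpha mass more strongly than theta
        mass, and the drug effect does the converse."""

        def sep(a, b, key):
            va = np.array([x[key] for x in a])
            vb = np.array([x[key] for x in b])
            sd = np.sqrt((va.var() + vb.var()) / 2)
            return abs(np.mean(va) - np.mean(vb)) / sd

        ep_rows = self.cohort_markers(small_design(
            n_per_group={"TLE": 25, "FLE": 0, "PNES": 25, "headache": 0},
            segment_durations={"post-Hv": 60.0}))
        ep = [v for v in ep_rows.values() if v["meta"].is_epilepsy]
        ct = [v for v in ep_rows.values() if not v["meta"].is_epilepsy]
        assert sep(ep, ct, "alpha") > sep(ep, ct, "theta")

        aed_rows = self.cohort_markers(small_design(
            n_per_group={"TLE": 0, "FLE": 0, "PNES": 0, "headache": 50},
            segment_durations={"post-Hv": 60.0},
            naed_probs={"headache": (0.5, 0.0, 0.0, 0.5),
                        "TLE": (1, 0, 0, 0), "FLE": (1, 0, 0, 0),
                        "PNES": (1, 0, 0, 0)}))
        hi = [v for v in aed_rows.values() if v["meta"].n_aed == 3]
        lo = [v for v in aed_rows.values() if v["meta"].n_aed == 0]
        assert sep(hi, lo, "theta") > sep(hi, lo, "alpha")


class TestCohortStructure:
    def test_reference_group_sizes(self):
        """The default design reproduces the reference cohort split
        19/32/13/14 = 51 epilepsy + 27 control = 78 subjects."""
        design = CohortDesign()
        metas = cohort_metas(design, np.random.default_rng(0))
        by = {g: sum(m.diagnosis == g for m in metas)
              for g in ("TLE", "FLE", "PNES", "headache")}
        assert by == {"TLE": 19, "FLE": 32, "PNES": 13, "headache": 14}
        assert sum(m.is_epilepsy for m in metas) == 51
        assert len(metas) == 78

    def test_headache_controls_unmedicated_mostly(self):
        design = CohortDesign()
        metas = cohort_metas(design, np.random.default_rng(1))
        hd = [m for m in metas if m.diagnosis == "headache"]
        assert np.mean([m.n_aed == 0 for m in hd]) >= 0.5

    def test_segment_protocol_tiles_20_minutes(self):
        design = CohortDesign()
        segmap = design.segment_map()
        assert segmap.ordered_labels() == ["pre-Fs", "Fs", "post-Fs", "Hv",
                                           "post-Hv"]
        assert segmap.end == pytest.approx(1200.0)

    def test_cohort_dir_round_trip(self, tmp_path):
        from eegintervals.pipeline import load_cohort

        design = small_design(n_per_group={"TLE": 2, "FLE": 0, "PNES": 2,
                                           "headache": 0})
        recs = simulate_cohort(design, out_dir=tmp_path)
        back = load_cohort(tmp_path)
        assert {r.subject_id for r in back} == {r.subject_id for r in recs}
        orig = {r.subject_id: r for r in recs}
        for r in back:
            step = 1000.0 / 32767
            assert np.abs(r.signal - orig[r.subject_id].signal).max() <= step
            assert r.meta == orig[r.subject_id].meta


class TestNullDesign:
    def test_zero_effect_fields(self):
        d = null_design()
        assert d.epilepsy_alpha_deficit == 0.0
        assert d.epilepsy_jitter_increase == 0.0
        assert d.theta_amp_per_aed_uv == 0.0

    def test_groups_statistically_identical(self):
        design = null_design(
            n_per_group={"TLE": 15, "FLE": 0, "PNES": 15, "headache": 0},
            naed_probs={g: (1, 0, 0, 0)
                        for g in ("TLE", "FLE", "PNES", "headache")},
            segment_durations={"post-Hv": 30.0})
        recs = simulate_cohort(design)
        band = BandPass(4, 13)
        alpha_bins = bins_in_range(77, 125)
        vals = {}
        for r in recs:
            s = subject_spectra(r, [band])[band]
            vals[r.subject_id] = s.p[alpha_bins].sum()
        ep = [v for s, v in vals.items() if s.startswith("TLE")]
        ct = [v for s, v in vals.items() if s.startswith("PNES")]
        assert mannwhitneyu(ep, ct).pvalue > 0.01
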