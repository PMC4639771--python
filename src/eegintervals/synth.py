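"""Synthetic 19-channel interictal EEG cohorts.

The generator produces recordings with the statistical structure the
interval-spectrum markers respond to, so that every pipeline stage can be
exercised and calibrated without patient data:

* a posterior-dominant alpha oscillator (centre frequency ~ N(10, 0.5) Hz
  across subjects) whose instantaneous frequency carries smooth
  Ornstein-Uhlenbeck jitter — cycle-length variability is what the
  interval-spectrum entropies measure, so irregularity is modelled in
  frequency, not amplitude;
* an *epilepsy effect*: multiplicative alpha-amplitude deficit plus an
  increase of the frequency jitter (reduced alpha-interval counts,
  increased spectrum entropy);
* a *drug effect*: an additive fronto-central theta oscillator whose
  amplitude scales with the number of antiepileptic drugs (nAED 0-3),
  producing a dose-dependent rise of theta-range interval counts;
* pink (1/f) background noise per channel, episodic low-frequency
  artifact transients (0.3-2 s half-sine deflections of 100-300 µV with a
  frontal/ocular topography), and an analogue-like first-order 0.5-Hz
  high-pass;
* the standard 20-minute protocol segment structure (pre-Fs, Fs, post-Fs,
  Hv, post-Hv), 250 Hz sampling.

Everything is reproducible from the design seed; each subject derives an
independent stream via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, lfilter

from .io_core import (
    CHANNELS_1020,
    Recording,
    SegmentMap,
    SubjectMeta,
    write_edf,
    write_meta_csv,
)

#: Relative alpha amplitude per electrode (steep posterior gradient; the
#: frontal leads carry almost no alpha, as in eyes-closed adult EEG).
ALPHA_TOPO: dict[str, float] = {
    "O1": 1.0, "O2": 1.0, "T5": 0.85, "T6": 0.85, "P3": 0.8, "P4": 0.8,
    "Pz": 0.8, "T3": 0.5, "T4": 0.5, "C3": 0.5, "C4": 0.5, "Cz": 0.5,
    "F3": 0.18, "F4": 0.18, "Fz": 0.18, "F7": 0.15, "F8": 0.15,
    "Fp1": 0.12, "Fp2": 0.12,
}

#: Relative theta amplitude per electrode (fronto-central dominance;
#: theta owns the frontal leads and contests the central ones).
THETA_TOPO: dict[str, float] = {
    "Fz": 1.0, "F3": 0.9, "F4": 0.9, "Cz": 0.6, "C3": 0.55, "C4": 0.55,
    "Fp1": 0.7, "Fp2": 0.7, "F7": 0.7, "F8": 0.7, "T3": 0.45, "T4": 0.45,
    "P3": 0.5, "P4": 0.5, "Pz": 0.5, "T5": 0.5, "T6": 0.5,
    "O1": 0.4, "O2": 0.4,
}

#: Relative artifact amplitude per electrode (ocular/movement topography).
ARTIFACT_TOPO: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.7, "F8": 0.7, "F3": 0.5, "F4": 0.5,
    "Fz": 0.5, "T3": 0.3, "T4": 0.3, "C3": 0.2, "C4": 0.2, "Cz": 0.2,
    "T5": 0.15, "T6": 0.15, "P3": 0.15, "P4": 0.15, "Pz": 0.15,
    "O1": 0.1, "O2": 0.1,
}

#: 20-minute clinical protocol (seconds per segment).
DEFAULT_SEGMENTS: dict[str, float] = {
    "pre-Fs": 240.0, "Fs": 120.0, "post-Fs": 180.0,
    "Hv": 180.0, "post-Hv": 480.0,
}

DEFAULT_NAED_PROBS: dict[str, tuple[float, ...]] = {
    # epilepsy subgroups mostly treated, many on polytherapy; PNES largely
    # treated too; headache controls unmedicated
    "TLE": (0.10, 0.30, 0.30, 0.30),
    "FLE": (0.10, 0.30, 0.30, 0.30),
    "PNES": (0.15, 0.45, 0.30, 0.10),
    "headache": (0.90, 0.10, 0.0, 0.0),
}


@dataclass(frozen=True)
class CohortDesign:
    """Effect and nuisance parameters of a synthetic cohort.

    Amplitudes are µV at the maximally expressing electrode; frequency
    jitter is the fractional standard deviation of the instantaneous
    oscillator frequency.  ``epilepsy_alpha_deficit`` multiplies alpha
    amplitude by ``1 − deficit`` and ``epilepsy_jitter_increase`` scales
    the jitter SD by ``1 + increase`` in TLE/FLE subjects.
    ``theta_amp_per_aed_uv`` is added per drug taken.  Optional
    ``effect_channels`` / ``effect_segments`` confine the epilepsy
    amplitude deficit to specific electrodes / protocol segments (used to
    probe the channel/segment search; the jitter increase is only applied
    when the effect is unrestricted).
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"TLE": 19, "FLE": 32, "PNES": 13,
                                 "headache": 14})
    naed_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_NAED_PROBS))
    fs: float = 250.0
    segment_durations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENTS))
    alpha_freq_mean: float = 10.0
    alpha_freq_sd: float = 0.3
    alpha_amp_uv: float = 30.0
    alpha_amp_subject_sd: float = 0.20     # lognormal sigma across subjects
    alpha_jitter_sd: float = 0.05
    jitter_subject_sd: float = 0.35    # lognormal spread of per-subject jitter
    jitter_tau_s: float = 0.5
    amp_mod_sd: float = 0.15               # slow lognormal envelope sigma
    amp_mod_tau_s: float = 2.0
    epilepsy_alpha_deficit: float = 0.20
    epilepsy_jitter_increase: float = 0.35
    theta_amp_base_uv: float = 10.0      # baseline theta present in everyone
    theta_amp_subject_sd: float = 0.15   # lognormal sigma across subjects
    theta_amp_per_aed_uv: float = 3.0
    theta_freq_mean: float = 6.0
    theta_freq_sd: float = 0.1
    theta_jitter_sd: float = 0.04
    noise_amp_uv: float = 10.0
    noise_amp_subject_sd: float = 0.30   # lognormal sigma across subjects
    artifact_rate_per_min: float = 2.0
    highpass_hz: float = 0.5
    effect_channels: tuple[str, ...] | None = None
    effect_segments: tuple[str, ...] | None = None
    seed: int = 0

    def segment_map(self) -> SegmentMap:
        out = {}
        t = 0.0
        for label in ("pre-Fs", "Fs", "post-Fs", "Hv", "post-Hv"):
            if label in self.segment_durations:
                dur = float(self.segment_durations[label])
                out[label] = (t, t + dur)
                t += dur
        return SegmentMap(out)

    @property
    def duration(self) -> float:
        return float(sum(self.segment_durations.values()))


def null_design(**overrides) -> CohortDesign:
    """A zero-effect design: identical signal statistics in every group."""
    base = CohortDesign(epilepsy_alpha_deficit=0.0,
                        epilepsy_jitter_increase=0.0,
                        theta_amp_per_aed_uv=0.0)
    return replace(base, **overrides)


def _ou(rng: np.random.Generator, n: int, dt: float, tau: float,
        sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path via its exact AR(1) discretisation."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    innov = rng.standard_normal(n) * sd * np.sqrt(1 - a * a)
    innov[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -a], innov)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                rms: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x * (rms / np.std(x))


def _oscillator(rng: np.random.Generator, n: int, fs: float, f0: float,
                jitter_sd: float, tau: float, amp_sd: float,
                amp_tau: float) -> np.ndarray:
    """Unit-scale oscillator with OU frequency jitter and slow lognormal
    amplitude modulation."""
    dt = 1.0 / fs
    xi = _ou(rng, n, dt, tau, jitter_sd)
    phase = 2 * np.pi * np.cumsum(f0 * (1.0 + xi)) * dt
    env = np.exp(_ou(rng, n, dt, amp_tau, amp_sd))
    return env * np.sin(phase)


def _artifacts(rng: np.random.Generator, n: int, fs: float,
               rate_per_min: float) -> np.ndarray:
    """Poisson-placed half-sine transients (0.3-2 s, 100-300 µV), unit
    topography — scaled per channel by the ocular profile."""
    x = np.zeros(n)
    lam = rate_per_min * (n / fs) / 60.0
    for _ in range(rng.poisson(lam)):
        dur = rng.uniform(0.3, 2.0)
        amp = rng.uniform(100.0, 300.0) * rng.choice([-1.0, 1.0])
        width = int(dur * fs)
        start = rng.integers(0, max(1, n - width))
        x[start:start + width] += amp * np.sin(
            np.pi * np.arange(width) / width)
    return x


def simulate_subject(design: CohortDesign, meta: SubjectMeta,
                     seed_seq: np.random.SeedSequence | int) -> Recording:
    """Generate one 19-channel recording according to the design."""
    if isinstance(seed_seq, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(seed_seq))
    sig_ss, art_ss = seed_seq.spawn(2)
    rng = np.random.default_rng(sig_ss)
    # artifacts draw from their own stream so that changing the artifact
    # rate perturbs nothing else in the subject's signal
    art_rng = np.random.default_rng(art_ss)
    fs = design.fs
    segmap = design.segment_map()
    n = int(round(design.duration * fs))

    f_alpha = rng.normal(design.alpha_freq_mean, design.alpha_freq_sd)
    noise_amp = design.noise_amp_uv * rng.lognormal(
        -design.noise_amp_subject_sd ** 2 / 2, design.noise_amp_subject_sd)
    amp_subject = design.alpha_amp_uv * rng.lognormal(
        -design.alpha_amp_subject_sd ** 2 / 2, design.alpha_amp_subject_sd)
    jitter = design.alpha_jitter_sd * rng.lognormal(
        -design.jitter_subject_sd ** 2 / 2, design.jitter_subject_sd)
    deficit_gain = 1.0
    restricted = (design.effect_channels is not None
                  or design.effect_segments is not None)
    if meta.is_epilepsy:
        if restricted:
            deficit_gain = 1.0  # applied locally below
        else:
            deficit_gain = 1.0 - design.epilepsy_alpha_deficit
            jitter *= 1.0 + design.epilepsy_jitter_increase

    alpha = _oscillator(rng, n, fs, f_alpha, jitter, design.jitter_tau_s,
                        design.amp_mod_sd, design.amp_mod_tau_s)
    theta_amp = (design.theta_amp_base_uv * rng.lognormal(
        -design.theta_amp_subject_sd ** 2 / 2, design.theta_amp_subject_sd)
        + design.theta_amp_per_aed_uv * meta.n_aed)
    if theta_amp > 0:
        f_theta = rng.normal(design.theta_freq_mean, design.theta_freq_sd)
        theta = theta_amp * _oscillator(
            rng, n, fs, f_theta, design.theta_jitter_sd,
            design.jitter_tau_s, design.amp_mod_sd, design.amp_mod_tau_s)
    else:
        theta = 0.0

    # local-effect mask over time (epilepsy deficit in chosen segments only)
    local_mask = np.ones(n)
    if meta.is_epilepsy and restricted:
        segs = (design.effect_segments
                or tuple(segmap.ordered_labels()))
        for label in segs:
            s0, s1 = segmap[label]
            i0, i1 = int(s0 * fs), int(s1 * fs)
            local_mask[i0:i1] = 1.0 - design.epilepsy_alpha_deficit

    signal = np.empty((len(CHANNELS_1020), n))
    artifact = _artifacts(art_rng, n, fs, design.artifact_rate_per_min)
    for k, ch in enumerate(CHANNELS_1020):
        gain = amp_subject * ALPHA_TOPO[ch] * deficit_gain
        if meta.is_epilepsy and restricted:
            if (design.effect_channels is None
                    or ch in design.effect_channels):
                ch_alpha = alpha * local_mask * gain
            else:
                ch_alpha = alpha * gain
        else:
            ch_alpha = alpha * gain
        row = (ch_alpha
               + (theta * THETA_TOPO[ch] if np.ndim(theta) else 0.0)
               + _pink_noise(rng, n, fs, noise_amp)
               + artifact * ARTIFACT_TOPO[ch])
        signal[k] = row

    b, a = butter(1, design.highpass_hz, btype="highpass", fs=fs)
    signal = lfilter(b, a, signal, axis=1)
    return Recording(subject_id=meta.subject_id, fs=fs,
                     channels=list(CHANNELS_1020), signal=signal,
                     segments=segmap, meta=meta)


def cohort_metas(design: CohortDesign,
                 rng: np.random.Generator) -> list[SubjectMeta]:
    """Draw subject metadata (diagnosis groups, nAED) from the design."""
    metas = []
    for group in ("TLE", "FLE", "PNES", "headache"):
        n = int(design.n_per_group.get(group, 0))
        probs = np.asarray(design.naed_probs[group], dtype=float)
        probs = probs / probs.sum()
        for i in range(n):
            n_aed = int(rng.choice(4, p=probs))
            metas.append(SubjectMeta(
                subject_id=f"{group}{i + 1:02d}", diagnosis=group,
                n_aed=n_aed))
    return metas


def simulate_cohort(
    design: CohortDesign,
    out_dir: str | Path | None = None,
    metas: Sequence[SubjectMeta] | None = None,
) -> list[Recording]:
    """Generate a full cohort, optionally writing EDF + sidecars to disk.

    Deterministic given ``design.seed``.  When ``out_dir`` is given, each
    subject is written as ``<id>.edf`` with a shared ``segments.json``
    and a ``meta.csv`` sidecar, consumable by :mod:`eegintervals.io_core`
    unchanged.
    """
    root = np.random.SeedSequence(design.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    if metas is None:
        metas = cohort_metas(design, meta_rng)
    streams = root.spawn(1 + len(metas))[1:]
    recordings = [simulate_subject(design, m, s)
                  for m, s in zip(metas, streams)]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_edf(out / f"{rec.subject_id}.edf", rec)
        design.segment_map().to_json(out / "segments.json")
        write_meta_csv(out / "meta.csv", [r.meta for r in recordings])
    return recordings


def case_control_ids(
    metas: Sequence[SubjectMeta],
) -> tuple[list[str], list[str]]:
    """Epilepsy (TLE+FLE) vs control (PNES+headache) subject ids."""
    cases = [m.subject_id for m in metas if m.is_epilepsy]
    controls = [m.subject_id for m in metas if not m.is_epilepsy]
    return cases, controls


def polytherapy_ids(
    metas: Sequence[SubjectMeta],
) -> tuple[list[str], list[str]]:
    """AED polytherapy (nAED >= 2) vs monotherapy (nAED == 1) ids."""
    cases = [m.subject_id for m in metas if m.n_aed >= 2]
    controls = [m.subject_id for m in metas if m.n_aed == 1]
    return cases, controls
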