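"""From recordings to interval spectra: the per-subject pipeline.

For every protocol segment the channel block is extracted, band-passed
with zero phase, and zero-crossings are detected per channel *within* the
segment (intervals never span a segment boundary).  The per-(channel,
segment) raw histograms are then pooled: over everything for
whole-recording analysis, or kept per (symmetric channel group × segment)
for the two-step channel/segment search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .filters import BandPass, FirFilter, apply_zero_phase_bank, get_filter
from .intervals import (
    IntervalSpectrum,
    build_histogram,
    crossings_to_intervals,
    detect_crossings,
    pool_and_normalize,
)
from .io_core import Recording, extract_segment, group_label, symmetric_channel_pairs


@dataclass
class SpectraConfig:
    """Knobs of the signal→spectrum transform (defaults are the standard
    analysis settings: 4-ms bins over 0-4000 ms, 500-tap filters, rising
    crossing convention, midline singletons included in the search)."""

    convention: str = "rising"
    filter_order: int = 500
    transition_hz: float = 1.0
    bin_width_ms: float = 4.0
    range_ms: float = 4000.0
    include_midline: bool = True


def _segment_histograms(
    rec: Recording,
    bands: Sequence[BandPass],
    cfg: SpectraConfig,
) -> dict[BandPass, dict[tuple[str, str], tuple[np.ndarray, int]]]:
    """Raw pooled histograms per band and (channel group, segment).

    Filters every segment once through the whole band bank, then pools the
    per-channel histograms into symmetric channel groups.
    """
    groups = symmetric_channel_pairs(rec.channels, cfg.include_midline)
    bank = [get_filter(b, rec.fs, cfg.filter_order, cfg.transition_hz)
            for b in bands]
    out: dict[BandPass, dict[tuple[str, str], tuple[np.ndarray, int]]] = {
        b: {} for b in bands}
    for seg in rec.segments.ordered_labels():
        block = extract_segment(rec, seg)
        filtered = apply_zero_phase_bank(block, bank)
        for band, y in zip(bands, filtered):
            for grp in groups:
                counts = None
                overflow = 0
                for ch in grp:
                    row = y[rec.channel_index(ch)]
                    t = detect_crossings(row, rec.fs, cfg.convention)
                    iv = crossings_to_intervals(t)
                    c, o = build_histogram(iv, cfg.bin_width_ms, cfg.range_ms)
                    counts = c if counts is None else counts + c
                    overflow += o
                out[band][(group_label(grp), seg)] = (counts, overflow)
    return out


def subject_spectra(
    rec: Recording,
    bands: Sequence[BandPass],
    cfg: SpectraConfig | None = None,
    per_group_segment: bool = False,
) -> dict:
    """Interval spectra of one subject for each band of a filter bank.

    Returns ``{band: IntervalSpectrum}`` pooled over the whole recording,
    or, with ``per_group_segment``, ``{band: {(group, segment):
    IntervalSpectrum, ..., ("whole", "whole"): IntervalSpectrum}}``.
    """
    cfg = cfg or SpectraConfig()
    hists = _segment_histograms(rec, bands, cfg)
    result: dict = {}
    for band, parts in hists.items():
        if per_group_segment:
            per: dict[tuple[str, str], IntervalSpectrum] = {}
            for (grp, seg), part in parts.items():
                if part[0].sum() == 0:
                    continue  # a silent group/segment cannot be scored
                per[(grp, seg)] = pool_and_normalize(
                    [part], band=band, channel_groups=(grp,),
                    segment_labels=(seg,), subject_id=rec.subject_id,
                    convention=cfg.convention, bin_width_ms=cfg.bin_width_ms)
            per[("whole", "whole")] = _pool_whole(rec, band, parts, cfg)
            result[band] = per
        else:
            result[band] = _pool_whole(rec, band, parts, cfg)
    return result


def _pool_whole(rec, band, parts, cfg) -> IntervalSpectrum:
    groups = sorted({g for g, _ in parts})
    segs = sorted({s for _, s in parts})
    return pool_and_normalize(
        list(parts.values()), band=band, channel_groups=tuple(groups),
        segment_labels=tuple(segs), subject_id=rec.subject_id,
        convention=cfg.convention, bin_width_ms=cfg.bin_width_ms)


def cohort_spectra(
    recordings: Sequence[Recording],
    bands: Sequence[BandPass],
    cfg: SpectraConfig | None = None,
    per_group_segment: bool = False,
) -> dict[str, dict]:
    """``{subject_id: subject_spectra(...)}`` over a cohort."""
    return {rec.subject_id: subject_spectra(rec, bands, cfg, per_group_segment)
            for rec in recordings}


def band_grid(lo_min: int = 0, lo_max: int = 8,
              hi_min: int = 9, hi_max: int = 20) -> list[BandPass]:
    """The 1-Hz passband search grid, lexicographic in (lo, hi)."""
    return [BandPass(lo, hi)
            for lo in range(lo_min, lo_max + 1)
            for hi in range(hi_min, hi_max + 1)
            if lo < hi]
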