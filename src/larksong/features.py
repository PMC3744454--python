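"""Per-syllable acoustic parameters and per-phase summaries.

Spectral parameters are measured on the mean spectrum of each syllable:
the peak frequency (frequency of maximum amplitude), the frequencies
bounding the first, second and third quartiles of spectral energy, and
the bandwidth (maximum minus minimum frequency above a relative level
floor).  Temporal parameters are the syllable duration, the gap to the
next syllable, and the interval (duration + following gap).  Per-phase
summaries add the rhythm (mean per-syllable duration/gap ratio) and the
tempo (syllables per second over the analysed excerpt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import SyllableAnnotation, Waveform, spectrogram, validate_annotations

__all__ = [
    "SyllableFeatures",
    "PhaseSummary",
    "spectral_features",
    "temporal_features",
    "syllable_features",
    "phase_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyllableFeatures:
    """Spectral measurements of one syllable (frequencies in Hz)."""

    peak_freq_hz: float
    q25_hz: float
    q50_hz: float
    q75_hz: float
    bandwidth_hz: float

    def __post_init__(self) -> None:
        if not (self.q25_hz <= self.q50_hz <= self.q75_hz):
            raise ValueError("energy quartiles must be non-decreasing")
        if self.bandwidth_hz < 0:
            raise ValueError("bandwidth must be >= 0")


@dataclass(frozen=True)
class PhaseSummary:
    """Aggregate of all syllables produced during one flight phase."""

    phase: str | None
    n_syllables: int
    means: dict[str, float]  # mean of each per-syllable parameter
    rhythm: float  # mean of per-syllable duration/gap ratios
    rhythm_ratio_of_means: float  # mean duration / mean gap (debug variant)
    tempo: float  # syllables per second over the excerpt
    n_zero_gap_excluded: int = 0


def mean_spectrum(
    w: Waveform,
    a: SyllableAnnotation,
    fft_length: int = 1024,
    overlap_frac: float = 0.75,
    weighting: str = "energy",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean spectrum over the syllable's analysis frames -> (freqs, power).

    ``weighting="energy"`` averages squared magnitudes across frames;
    ``"amplitude"`` averages magnitudes and squares the result.
    """
    if weighting not in ("energy", "amplitude"):
        raise ValueError(f"unknown weighting {weighting!r}")
    i0 = int(round(a.onset_s * w.rate))
    i1 = int(round(a.offset_s * w.rate))
    if not (0 <= i0 < i1 <= len(w.samples)):
        raise ValueError("annotation outside waveform")
    segment = w.samples[i0:i1]
    hop = fft_length - int(round(fft_length * overlap_frac))
    if len(segment) < fft_length + hop:
        raise ValueError(
            f"syllable span of {len(segment)} samples is shorter than two "
            f"analysis frames (need {fft_length + hop})"
        )
    spec = spectrogram(Waveform(segment, w.rate), fft_length, overlap_frac)
    if weighting == "energy":
        power = np.mean(spec.magnitude**2, axis=0)
    else:
        power = np.mean(spec.magnitude, axis=0) ** 2
    return spec.freqs, power


def spectral_features(
    w: Waveform,
    a: SyllableAnnotation,
    floor_db: float = 24.0,
    fft_length: int = 1024,
    overlap_frac: float = 0.75,
    weighting: str = "energy",
) -> SyllableFeatures:
    """Spectral parameters of one annotated syllable.

    The quartile frequency qXX is the smallest frequency at which the
    cumulative spectral energy reaches XX% of the total; the bandwidth is
    the extent of frequencies whose level exceeds ``floor_db`` dB below
    the spectral peak.
    """
    if floor_db <= 0:
        raise ValueError("floor_db is a positive depth below the peak, in dB")
    freqs, power = mean_spectrum(w, a, fft_length, overlap_frac, weighting)
    total = power.sum()
    if total <= 0:
        raise ValueError("syllable has no spectral energy")
    peak_i = int(np.argmax(power))
    cum = np.cumsum(power) / total
    q25, q50, q75 = (float(freqs[np.searchsorted(cum, q)]) for q in (0.25, 0.50, 0.75))
    above = power >= power[peak_i] * 10 ** (-floor_db / 10)
    idx = np.flatnonzero(above)
    bandwidth = float(freqs[idx[-1]] - freqs[idx[0]])
    return SyllableFeatures(
        peak_freq_hz=float(freqs[peak_i]),
        q25_hz=q25,
        q50_hz=q50,
        q75_hz=q75,
        bandwidth_hz=bandwidth,
    )


def temporal_features(annotations: list[SyllableAnnotation]) -> pd.DataFrame:
    """Per-syllable duration, gap and interval (ms); NaN where undefined.

    duration_i = offset_i - onset_i; gap_i = onset_{i+1} - offset_i;
    interval_i = duration_i + gap_i.  The last syllable has no gap or
    interval.
    """
    if not annotations:
        raise ValueError("need at least one annotation")
    validate_annotations(annotations)
    onsets = np.array([a.onset_s for a in annotations])
    offsets = np.array([a.offset_s for a in annotations])
    dur = (offsets - onsets) * 1e3
    gap = np.full(len(annotations), np.nan)
    gap[:-1] = (onsets[1:] - offsets[:-1]) * 1e3
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "offset_s": offsets,
            "label": [a.label for a in annotations],
            "duration_ms": dur,
            "gap_ms": gap,
            "interval_ms": dur + gap,
        }
    )


def syllable_features(
    w: Waveform,
    annotations: list[SyllableAnnotation],
    floor_db: float = 24.0,
    fft_length: int = 1024,
    overlap_frac: float = 0.75,
    weighting: str = "energy",
) -> pd.DataFrame:
    """Temporal + spectral features for every annotated syllable (one row each)."""
    df = temporal_features(annotations)
    spec_rows = []
    for a in annotations:
        sf = spectral_features(w, a, floor_db, fft_length, overlap_frac, weighting)
        spec_rows.append(
            {
                "peak_freq_hz": sf.peak_freq_hz,
                "q25_hz": sf.q25_hz,
                "q50_hz": sf.q50_hz,
                "q75_hz": sf.q75_hz,
                "bandwidth_hz": sf.bandwidth_hz,
            }
        )
    return pd.concat([df, pd.DataFrame(spec_rows, index=df.index)], axis=1)


_SUMMARY_PARAMS = (
    "peak_freq_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "bandwidth_hz",
    "duration_ms",
    "gap_ms",
    "interval_ms",
)


def phase_summary(features: pd.DataFrame, phase: str | None = None) -> PhaseSummary:
    """Average the per-syllable parameters of one phase excerpt.

    Means are taken over syllables with defined values (the last syllable
    contributes no gap/interval).  Rhythm averages per-syllable
    duration/gap ratios, excluding (and counting) zero gaps; the
    ratio-of-means variant is reported alongside.  Tempo divides the
    syllable count by the span from first onset to last offset.
    """
    if len(features) < 2:
        raise ValueError("phase summary needs at least 2 syllables")
    means = {
        p: float(features[p].mean()) for p in _SUMMARY_PARAMS if p in features.columns
    }
    dur = features["duration_ms"].to_numpy()
    gap = features["gap_ms"].to_numpy()
    has_gap = ~np.isnan(gap)
    zero = has_gap & (gap == 0)
    usable = has_gap & (gap > 0)
    n_zero = int(zero.sum())
    if n_zero:
        log.info("rhythm: excluded %d syllable(s) with zero gap", n_zero)
    rhythm = float(np.mean(dur[usable] / gap[usable])) if usable.any() else float("nan")
    mean_gap = float(np.mean(gap[has_gap])) if has_gap.any() else float("nan")
    rom = float(np.mean(dur) / mean_gap) if mean_gap and not np.isnan(mean_gap) else float("nan")
    span = float(features["offset_s"].iloc[-1] - features["onset_s"].iloc[0])
    return PhaseSummary(
        phase=phase,
        n_syllables=len(features),
        means=means,
        rhythm=rhythm,
        rhythm_ratio_of_means=rom,
        tempo=len(features) / span,
        n_zero_gap_excluded=n_zero,
    )
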