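"""Synthetic flight-song study generator.

Emulates a two-phase (ascending / level) aerial-song dataset for several
individuals: per-individual syllable repertoires with group-shared
sequences ("micro-dialects"), label sequences with a controllable
syllable-type versatility, FM-tone audio rendered from those sequences
with phase-dependent frequency and timing parameters, and playback
response tables driven by latent locomotor and vocal factors.

All randomness flows from one master seed: every operation derives its
generator as ``default_rng(SeedSequence([seed, STREAM_ID, *keys]))``, so
identical seeds give bit-identical outputs while distinct operations and
individuals get independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segment import SyllableAnnotation, Waveform
from .sequences import LabelSequence

__all__ = [
    "Repertoire",
    "PhaseParams",
    "SyntheticStudy",
    "ASCENDING_PARAMS",
    "LEVEL_PARAMS",
    "REFERENCE_PHASE_STATS",
    "RESPONSE_MEASURES",
    "generate_repertoire",
    "generate_label_sequence",
    "render_song",
    "simulate_responses",
    "simulate_phase_feature_table",
    "make_study",
]

# Stream ids for per-operation seed derivation.
_STREAM_REPERTOIRE = 1
_STREAM_GROUPSEQ = 2
_STREAM_SEQUENCE = 3
_STREAM_RENDER = 4
_STREAM_RESPONSES = 5
_STREAM_FEATURES = 6
_STREAM_STUDY = 7


def _rng(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


@dataclass(frozen=True)
class Repertoire:
    """One individual's syllable-type inventory and its group's shared sequences."""

    individual_id: str
    syllable_types: frozenset[int]
    group_sequences: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.syllable_types):
            raise ValueError("syllable-type labels must be positive integers")
        for gs in self.group_sequences:
            if not set(gs) <= set(self.syllable_types):
                raise ValueError("group sequence uses labels outside the repertoire")
            if not (3 <= len(gs) <= 10) or len(set(gs)) < 3:
                raise ValueError("group sequences must have length 3-10 and >=3 distinct types")


@dataclass(frozen=True)
class PhaseParams:
    """Generator settings for the song of one flight phase.

    Defaults for the two phases (:data:`ASCENDING_PARAMS`,
    :data:`LEVEL_PARAMS`) are the study conditions: mean syllable duration,
    inter-syllable gap, spectral peak frequency, bandwidth and target
    syllable-type versatility per phase.  ``jitter_cv`` is the coefficient
    of variation of per-syllable durations and gaps around their means.
    """

    phase: str
    mean_syllable_duration_ms: float
    mean_gap_ms: float
    peak_freq_hz: float
    bandwidth_hz: float
    target_sylver: float
    jitter_cv: float = 0.08

    def __post_init__(self) -> None:
        for name in ("mean_syllable_duration_ms", "mean_gap_ms", "peak_freq_hz", "bandwidth_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1.0 <= self.target_sylver <= 10.0):
            raise ValueError("target_sylver must lie in [1, 10]")
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")


#: Phase-specific study conditions (means per phase; ascending song is
#: faster, higher-pitched, narrower-band and more versatile).
ASCENDING_PARAMS = PhaseParams(
    phase="ascending",
    mean_syllable_duration_ms=137.9,
    mean_gap_ms=48.33,
    peak_freq_hz=4074.0,
    bandwidth_hz=1755.0,
    target_sylver=8.309,
)
LEVEL_PARAMS = PhaseParams(
    phase="level",
    mean_syllable_duration_ms=158.9,
    mean_gap_ms=54.0,
    peak_freq_hz=3954.0,
    bandwidth_hz=1859.0,
    target_sylver=6.778,
)

#: Reference per-phase parameter means and standard errors (n = 20 males):
#: {parameter: (ascending_mean, ascending_se, level_mean, level_se)}.
REFERENCE_PHASE_STATS: dict[str, tuple[float, float, float, float]] = {
    "peak_freq_hz": (4074.0, 25.7, 3954.0, 30.2),
    "bandwidth_hz": (1755.0, 30.5, 1859.0, 36.6),
    "q25_hz": (3636.0, 20.5, 3506.0, 25.6),
    "q50_hz": (4128.0, 18.6, 3986.0, 26.7),
    "q75_hz": (4674.0, 17.9, 4495.0, 27.6),
    "duration_ms": (137.9, 2.2, 158.9, 3.0),
    "interval_ms": (186.1, 2.5, 212.5, 3.0),
    "gap_ms": (48.33, 0.7, 54.0, 2.0),
    "rhythm": (2.85, 0.05, 2.976, 0.07),
    "tempo": (5.404, 0.071, 4.743, 0.08),
    "sylver": (8.309, 0.13, 6.778, 0.2),
    "trver": (8.005, 0.12, 7.152, 0.1),
    "totver": (68.91, 1.7, 52.03, 2.11),
}

#: The 11 behavioural response measures recorded per playback trial.
RESPONSE_MEASURES: tuple[str, ...] = (
    "total_movement_duration_s",
    "movement_10_5_duration_s",
    "movement_5_0_duration_s",
    "first_movement_latency_s",
    "approach_10m_latency_s",
    "approach_5m_latency_s",
    "time_10_5_s",
    "time_5_0_s",
    "first_song_latency_s",
    "song_duration_s",
    "n_calls",
)


def generate_repertoire(
    n_types: int,
    n_group_sequences: int = 0,
    group_pool: frozenset[int] | set[int] | tuple[int, ...] = (),
    seed: int = 0,
    individual_id: str = "bird",
    group_seed: int | None = None,
) -> Repertoire:
    """Build one individual's repertoire of ``n_types`` syllable types.

    ``n_group_sequences`` shared sequences (length 3-10, >=3 distinct
    types) are drawn from ``group_pool``; every member of a group built
    with the same ``group_seed`` and pool receives identical group
    sequences, emulating a micro-dialect.  Labels not used by group
    sequences are private to the individual.
    """
    if n_types < 3:
        raise ValueError("a repertoire needs at least 3 syllable types")
    pool = tuple(sorted(set(group_pool)))
    if n_group_sequences > 0 and len(pool) < 3:
        raise ValueError("group_pool needs >=3 labels to form group sequences")
    if any(t <= 0 for t in pool):
        raise ValueError("group_pool labels must be positive")

    rng_g = _rng(group_seed if group_seed is not None else seed, _STREAM_GROUPSEQ)
    group_sequences: list[tuple[int, ...]] = []
    for _ in range(n_group_sequences):
        length = int(rng_g.integers(3, 11))
        d = int(rng_g.integers(3, min(length, len(pool)) + 1))
        types = rng_g.choice(pool, size=d, replace=False)
        seq = list(types) + list(rng_g.choice(types, size=length - d))
        rng_g.shuffle(seq)
        group_sequences.append(tuple(int(x) for x in seq))

    used = sorted({x for gs in group_sequences for x in gs})
    if len(used) > n_types:
        raise ValueError(
            f"group sequences use {len(used)} types but n_types={n_types}"
        )
    rng = _rng(seed, _STREAM_REPERTOIRE)
    base = (max(pool) if pool else 0) + 1
    candidates = np.arange(base, base + 50 * n_types)
    candidates = candidates[~np.isin(candidates, used)]
    private = rng.choice(candidates, size=n_types - len(used), replace=False)
    types = frozenset(used) | frozenset(int(x) for x in private)
    return Repertoire(
        individual_id=individual_id,
        syllable_types=types,
        group_sequences=tuple(group_sequences),
    )


def generate_label_sequence(
    repertoire: Repertoire,
    params: PhaseParams,
    n_syllables: int,
    seed: int = 0,
    group_seq_prob: float = 0.2,
    window: int = 10,
) -> LabelSequence:
    """Emit ``n_syllables`` labels whose windowed SylVer tracks the target.

    The sequence is built window by window: each 10-syllable window uses
    exactly k distinct types, with k randomised between
    floor(target_sylver) and ceil(target_sylver) so the window mean equals
    the target.  Group sequences are embedded verbatim: each appears at
    least once (when the sequence is long enough and the window budget
    allows) and thereafter with probability ``group_seq_prob`` per window.
    """
    if n_syllables < window:
        raise ValueError(f"n_syllables must be >= {window}")
    n_types = len(repertoire.syllable_types)
    kmax = min(window, n_types)
    if params.target_sylver > kmax:
        raise ValueError(
            f"target_sylver={params.target_sylver} exceeds min({window}, n_types={n_types})"
        )
    rng = _rng(seed, _STREAM_SEQUENCE)
    types = np.array(sorted(repertoire.syllable_types))

    if params.target_sylver == 1.0:
        single = int(types[rng.integers(len(types))])
        return LabelSequence(
            labels=(single,) * n_syllables,
            individual_id=repertoire.individual_id,
            phase=params.phase,
        )

    pending = list(repertoire.group_sequences)  # each embedded once, then by chance
    labels: list[int] = []
    while len(labels) < n_syllables:
        k = int(np.floor(params.target_sylver))
        if rng.random() < params.target_sylver - k:
            k += 1
        k = min(max(k, 1), kmax)

        gs: tuple[int, ...] | None = None
        if pending:
            gs = pending[0]
        elif repertoire.group_sequences and rng.random() < group_seq_prob:
            gs = repertoire.group_sequences[rng.integers(len(repertoire.group_sequences))]
        if gs is not None:
            d = len(set(gs))
            if len(gs) > window:
                gs = None
            else:
                # bend this window's distinct count so the sequence plus its
                # k-d extra types fit; only a few windows are affected, so
                # the mean SylVer stays on target
                k = min(max(k, d), d + window - len(gs))
                if pending and pending[0] == gs:
                    pending.pop(0)

        if gs is None:
            win_types = rng.choice(types, size=k, replace=False)
            win = list(win_types) + list(rng.choice(win_types, size=window - k))
            rng.shuffle(win)
        else:
            if k > d:
                extras = list(rng.choice(types[~np.isin(types, list(set(gs)))],
                                         size=k - d, replace=False))
            else:
                extras = []
            win_types = np.array(sorted(set(gs) | {int(x) for x in extras}))
            filler = list(extras) + list(
                rng.choice(win_types, size=window - len(gs) - len(extras))
            )
            rng.shuffle(filler)
            cut = int(rng.integers(len(filler) + 1))
            win = filler[:cut] + list(gs) + filler[cut:]
        labels.extend(int(x) for x in win)

    return LabelSequence(
        labels=tuple(labels[:n_syllables]),
        individual_id=repertoire.individual_id,
        phase=params.phase,
    )


def _fm_shape(label: int) -> tuple[float, float]:
    """Deterministic FM shape (sweep direction, curvature) for a label."""
    r = np.random.default_rng(np.random.SeedSequence([int(label), 9001]))
    direction = 1.0 if r.random() < 0.5 else -1.0
    curvature = float(r.uniform(-0.5, 0.5))
    return direction, curvature


def _render_syllable(
    label: int,
    n_samples: int,
    rate: int,
    params: PhaseParams,
    ramp_ms: float = 5.0,
) -> np.ndarray:
    """One FM-tone burst: a carrier at the peak frequency plus a label-
    specific sweep spanning the phase bandwidth, with raised-cosine ramps.

    The carrier concentrates energy at ``peak_freq_hz`` (so the measured
    spectral peak lands there), the sweep spreads energy across
    ``bandwidth_hz``, and two weak tones accentuate the FM turning points
    at the band edges so the band extent is sharply defined in the
    spectrum regardless of the analysis bin width.
    """
    direction, curvature = _fm_shape(label)
    tau = np.arange(n_samples) / max(n_samples - 1, 1)
    g = (2 * tau - 1) + (curvature / np.pi) * np.sin(2 * np.pi * tau)  # in [-1, 1]
    half_bw = params.bandwidth_hz / 2.0
    inst_freq = params.peak_freq_hz + direction * half_bw * g
    phase = 2 * np.pi * np.cumsum(inst_freq) / rate
    sweep = np.cos(phase)
    t = np.arange(n_samples) / rate
    carrier = np.cos(2 * np.pi * params.peak_freq_hz * t + 0.37 * label)
    edges = np.cos(2 * np.pi * (params.peak_freq_hz - half_bw) * t) + np.cos(
        2 * np.pi * (params.peak_freq_hz + half_bw) * t + 1.1
    )
    x = 0.42 * carrier + 0.42 * sweep + 0.08 * edges

    n_ramp = min(int(round(ramp_ms * 1e-3 * rate)), n_samples // 2)
    if n_ramp > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(n_ramp) / n_ramp)
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    peak = np.max(np.abs(x))
    return x * (0.9 / peak) if peak > 0 else x


def render_song(
    labels: LabelSequence,
    params: PhaseParams,
    sample_rate: int = 22050,
    seed: int = 0,
    noise_snr_db: float | None = None,
) -> tuple[Waveform, list[SyllableAnnotation]]:
    """Render a label sequence to audio with ground-truth annotations.

    Durations and gaps are drawn around the phase means with relative
    jitter ``jitter_cv`` (clipped at 25% of the mean so gaps stay well
    clear of the 25 ms merge rule); at ``jitter_cv=0`` the timing is
    sample-exact.  Optional white noise is added at ``noise_snr_db``.
    """
    if sample_rate < 2 * (params.peak_freq_hz + params.bandwidth_hz):
        raise ValueError(
            f"sample_rate {sample_rate} violates Nyquist for "
            f"peak {params.peak_freq_hz} + bandwidth {params.bandwidth_hz}"
        )
    rng = _rng(seed, _STREAM_RENDER)
    n = len(labels.labels)
    cv = params.jitter_cv
    durs_ms = params.mean_syllable_duration_ms * np.clip(1 + cv * rng.standard_normal(n), 0.25, 4.0)
    gaps_ms = params.mean_gap_ms * np.clip(1 + cv * rng.standard_normal(n - 1), 0.25, 4.0)
    dur_n = np.round(durs_ms * 1e-3 * sample_rate).astype(int)
    gap_n = np.round(gaps_ms * 1e-3 * sample_rate).astype(int)

    pad = int(round(0.05 * sample_rate))  # 50 ms leading/trailing silence
    total = pad + int(dur_n.sum() + gap_n.sum()) + pad
    samples = np.zeros(total)
    annotations: list[SyllableAnnotation] = []
    pos = pad
    for i, label in enumerate(labels.labels):
        burst = _render_syllable(label, int(dur_n[i]), sample_rate, params)
        samples[pos : pos + dur_n[i]] = burst
        annotations.append(
            SyllableAnnotation(pos / sample_rate, (pos + int(dur_n[i])) / sample_rate, label)
        )
        pos += int(dur_n[i])
        if i < n - 1:
            pos += int(gap_n[i])

    if noise_snr_db is not None:
        sig_rms = np.sqrt(np.mean(samples**2))
        noise_rms = sig_rms / 10 ** (noise_snr_db / 20)
        samples = samples + noise_rms * rng.standard_normal(total)
        peak = np.max(np.abs(samples))
        if peak > 1.0:
            samples /= peak
    return Waveform(samples, sample_rate), annotations


def simulate_responses(
    n_subjects: int,
    vocal_effect: float = 0.0,
    seed: int = 0,
    observation_s: float = 160.0,
) -> pd.DataFrame:
    """Simulate the 11-measure playback-response table (2 trials/subject).

    A latent locomotor factor drives the six movement/latency measures
    (latencies loading with the opposite sign to durations) and a latent
    vocal factor drives song latency and song duration.  ``vocal_effect``
    shifts the vocal factor upward for S1 trials (in latent-SD units),
    emulating a stronger singing response when the level-phase song comes
    from the wrong boundary.  The two time-in-zone measures duplicate the
    corresponding movement durations exactly, and calls are rare
    (Poisson, ~0.1 per trial).
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    rng = _rng(seed, _STREAM_RESPONSES)
    rows = []
    lam = 0.90  # latent-factor loading; residual sd = sqrt(1 - lam^2)
    res = np.sqrt(1 - lam**2)
    for subj in range(n_subjects):
        order = [1, 2] if rng.random() < 0.5 else [2, 1]
        for stim, ordn in zip(("S1", "S2"), order):
            loco = rng.standard_normal()
            vocal = rng.standard_normal() + (vocal_effect if stim == "S1" else 0.0)

            def m(mean, scale, factor, sign=1.0):
                z = sign * (lam * factor + res * rng.standard_normal())
                return float(np.clip(mean + scale * z, 0.0, observation_s))

            row = {
                "subject": f"S{subj:02d}",
                "stimulus": stim,
                "order": ordn,
                "total_movement_duration_s": m(30, 12, loco),
                "movement_10_5_duration_s": m(12, 5, loco),
                "movement_5_0_duration_s": m(8, 3, loco),
                "first_movement_latency_s": m(75, 25, loco, sign=-1.0),
                "approach_10m_latency_s": m(95, 25, loco, sign=-1.0),
                "approach_5m_latency_s": m(112, 20, loco, sign=-1.0),
                "first_song_latency_s": m(118, 18, vocal, sign=-1.0),
                "song_duration_s": m(18, 8, vocal),
                "n_calls": int(rng.poisson(0.1)),
            }
            row["time_10_5_s"] = row["movement_10_5_duration_s"]
            row["time_5_0_s"] = row["movement_5_0_duration_s"]
            rows.append(row)
    cols = ["subject", "stimulus", "order", *RESPONSE_MEASURES]
    return pd.DataFrame(rows)[cols]


def simulate_phase_feature_table(
    n_individuals: int = 20,
    n_songs_per_phase: int = 2,
    effect: str = "reference",
    seed: int = 0,
    within_sd_scale: float = 1.0,
) -> pd.DataFrame:
    """Simulate a per-song-excerpt feature table for the phase comparison.

    Each row is one 20 s song excerpt (individual x phase x song) with the
    13 phase-comparison parameters.  Parameter value = phase mean +
    individual effect + within-individual residual, with the between-male
    SD recovered from the reported standard errors (SE * sqrt(20)) and the
    within-male SD set equal to it (scaled by ``within_sd_scale``).
    ``effect="reference"`` uses the per-phase means; ``effect="null"``
    pools the two phase means so there is no phase effect.
    """
    if effect not in ("reference", "null"):
        raise ValueError("effect must be 'reference' or 'null'")
    rng = _rng(seed, _STREAM_FEATURES)
    params = list(REFERENCE_PHASE_STATS)
    rows = []
    between = {p: np.sqrt(20.0) * (REFERENCE_PHASE_STATS[p][1] + REFERENCE_PHASE_STATS[p][3]) / 2
               for p in params}
    b = {p: between[p] * rng.standard_normal(n_individuals) for p in params}
    for i in range(n_individuals):
        for phase_idx, phase in enumerate(("ascending", "level")):
            for song in range(n_songs_per_phase):
                row = {"individual_id": f"M{i:02d}", "phase": phase, "song": song}
                for p in params:
                    asc_m, _, lvl_m, _ = REFERENCE_PHASE_STATS[p]
                    mean = 0.5 * (asc_m + lvl_m) if effect == "null" else (asc_m, lvl_m)[phase_idx]
                    row[p] = mean + b[p][i] + within_sd_scale * between[p] * rng.standard_normal()
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticStudy:
    """A rendered multi-individual, two-phase synthetic song dataset."""

    repertoires: dict[str, Repertoire]
    #: (individual_id, phase, song_index) -> (waveform, annotations, label sequence)
    songs: dict[tuple[str, str, int], tuple[Waveform, list[SyllableAnnotation], LabelSequence]]
    seed: int

    @property
    def individuals(self) -> list[str]:
        return sorted(self.repertoires)

    @property
    def phases(self) -> list[str]:
        return sorted({k[1] for k in self.songs})


def make_study(
    n_individuals: int = 6,
    n_songs: int = 1,
    n_syllables: int = 60,
    n_types: int = 30,
    group_size: int = 3,
    n_group_sequences: int = 2,
    group_pool_size: int = 12,
    phase_params: tuple[PhaseParams, PhaseParams] = (ASCENDING_PARAMS, LEVEL_PARAMS),
    sample_rate: int = 22050,
    seed: int = 0,
    noise_snr_db: float | None = None,
    individual_variation: bool = True,
) -> SyntheticStudy:
    """Generate a full synthetic study: repertoires, sequences and audio.

    Individuals are split into groups of ``group_size``; members of a group
    share a label pool and the group sequences drawn from it.  For every
    individual, ``n_songs`` songs are rendered per phase with the given
    phase parameters.

    With ``individual_variation`` each male carries stable acoustic
    idiosyncrasies — offsets to peak frequency, bandwidth, timing and
    versatility applied identically to both phases, with magnitudes on the
    order of the between-male spread implied by the reference standard
    errors.  Because each offset is shared by a male's two phases, it
    inflates between-individual variance without biasing the within-male
    phase contrast.
    """
    rng = _rng(seed, _STREAM_STUDY)
    repertoires: dict[str, Repertoire] = {}
    songs: dict[tuple[str, str, int], tuple[Waveform, list[SyllableAnnotation], LabelSequence]] = {}
    n_groups = int(np.ceil(n_individuals / group_size))
    for g in range(n_groups):
        # pools for different groups live in label blocks far enough apart
        # that private labels (drawn within 50*n_types of the pool) cannot
        # collide with another group's pool
        base = 1 + g * (group_pool_size + 100 * n_types)
        pool = frozenset(range(base, base + group_pool_size))
        group_seed = int(rng.integers(2**31))
        members = range(g * group_size, min((g + 1) * group_size, n_individuals))
        for i in members:
            ind = f"M{i:02d}"
            rep = generate_repertoire(
                n_types=n_types,
                n_group_sequences=n_group_sequences,
                group_pool=pool,
                seed=int(rng.integers(2**31)),
                individual_id=ind,
                group_seed=group_seed,
            )
            repertoires[ind] = rep
            if individual_variation:
                # stable per-male offsets, identical across phases
                peak_off = 100.0 * rng.standard_normal()
                bw_off = 120.0 * rng.standard_normal()
                dur_fac = float(np.clip(1 + 0.07 * rng.standard_normal(), 0.8, 1.25))
                gap_fac = float(np.clip(1 + 0.10 * rng.standard_normal(), 0.78, 1.3))
                ver_off = float(np.clip(0.6 * rng.standard_normal(), -1.4, 1.4))
            else:
                peak_off = bw_off = ver_off = 0.0
                dur_fac = gap_fac = 1.0
            for phase_p in phase_params:
                kmax = min(10.0, float(n_types))
                ind_params = replace(
                    phase_p,
                    peak_freq_hz=phase_p.peak_freq_hz + peak_off,
                    bandwidth_hz=max(phase_p.bandwidth_hz + bw_off, 200.0),
                    mean_syllable_duration_ms=phase_p.mean_syllable_duration_ms * dur_fac,
                    mean_gap_ms=phase_p.mean_gap_ms * gap_fac,
                    target_sylver=float(
                        np.clip(phase_p.target_sylver + ver_off, 1.0, kmax)
                    ),
                )
                for s in range(n_songs):
                    seq = generate_label_sequence(
                        rep, ind_params, n_syllables, seed=int(rng.integers(2**31))
                    )
                    wav, ann = render_song(
                        seq, ind_params, sample_rate,
                        seed=int(rng.integers(2**31)),
                        noise_snr_db=noise_snr_db,
                    )
                    songs[(ind, ind_params.phase, s)] = (wav, ann, seq)
    return SyntheticStudy(repertoires=repertoires, songs=songs, seed=seed)
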