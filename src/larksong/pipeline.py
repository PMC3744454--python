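"""End-to-end orchestration.

Two entry points mirror the study design:

* :func:`run_phase_comparison` — generate (or load) a two-phase song
  dataset, segment it, extract per-syllable acoustic parameters and
  windowed versatility, summarise per phase, compare phases with
  within-subject tests and a permuted DFA, and compute pairwise
  repertoire sharing with paired permutation tests.
* :func:`run_playback_analysis` — score an 11-measure playback-response
  table: de-duplicate measures, build PCA composite scores, test each
  retained component against stimulus type and presentation order, and
  follow up strongly-loading measures with Wilcoxon signed-rank tests.

Playback stimuli are chimeric: the first 20 s of ascending-phase song
from one neighbour repeated twice, then 20 s from the middle of the
level phase of the other neighbour repeated twice, all parts RMS
equalized — 80 s in total.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import segment as seg
from . import sequences as seqs
from . import stats as st
from . import synth

__all__ = [
    "StudyConfig",
    "Stimulus",
    "select_excerpts",
    "rms_equalize",
    "build_stimulus",
    "run_phase_comparison",
    "run_playback_analysis",
]

log = logging.getLogger(__name__)

#: Parameters entering the per-phase comparison summary.
PHASE_PARAMETERS = (
    "peak_freq_hz",
    "bandwidth_hz",
    "q25_hz",
    "q50_hz",
    "q75_hz",
    "duration_ms",
    "interval_ms",
    "gap_ms",
    "rhythm",
    "tempo",
    "sylver",
    "trver",
    "totver",
)


@dataclass
class StudyConfig:
    """Scenario + analysis settings for a synthetic phase-comparison run."""

    # synthetic scenario
    n_individuals: int = 10
    n_songs: int = 2
    n_syllables: int = 50
    n_types: int = 30
    group_size: int = 3
    n_group_sequences: int = 2
    group_pool_size: int = 12
    sample_rate: int = 22050
    noise_snr_db: float | None = None
    ascending: synth.PhaseParams = field(default_factory=lambda: synth.ASCENDING_PARAMS)
    level: synth.PhaseParams = field(default_factory=lambda: synth.LEVEL_PARAMS)
    # segmentation
    highpass_hz: float = 1600.0
    threshold_db: float = -30.0
    merge_gap_ms: float = 25.0
    min_dur_ms: float = 10.0
    # features
    floor_db: float = 24.0
    fft_length: int = 1024
    overlap_frac: float = 0.75
    # sequences
    window: int = 10
    # stats
    n_permutations: int = 200
    alpha: float = 0.05
    rs_n_mc: int = 10000
    exclude_from_pdfa: tuple[str, ...] = ("gap_ms",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        from .io import load_yaml

        raw = load_yaml(path)
        for key in ("ascending", "level"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = synth.PhaseParams(**raw[key])
        if "exclude_from_pdfa" in raw:
            raw["exclude_from_pdfa"] = tuple(raw["exclude_from_pdfa"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        """Write the scenario (phases, parameters, seed) as a YAML config."""
        from dataclasses import asdict

        from .io import dump_yaml

        raw = asdict(self)
        raw["exclude_from_pdfa"] = list(self.exclude_from_pdfa)
        dump_yaml(path, raw)


@dataclass(frozen=True)
class StimulusPart:
    phase: str
    source_individual: str
    duration_s: float
    repeat_index: int


@dataclass(frozen=True)
class Stimulus:
    waveform: seg.Waveform
    structure: tuple[StimulusPart, ...]

    @property
    def duration_s(self) -> float:
        return self.waveform.duration_s


def select_excerpts(
    phase_spans: dict[str, tuple[float, float]],
    annotations: list[seg.SyllableAnnotation] | None = None,
    excerpt_s: float = 20.0,
) -> dict[str, tuple[float, float]]:
    """Per-phase analysis excerpts.

    The ascending excerpt is the first ``excerpt_s`` of song in that
    phase — measured from the first syllable onset when annotations are
    supplied, else from the phase start.  The level excerpt is centred on
    the midpoint of the level phase.
    """
    out: dict[str, tuple[float, float]] = {}
    for phase, (start, end) in phase_spans.items():
        if end - start < excerpt_s - 1e-9:
            raise ValueError(
                f"phase {phase!r} lasts {end - start:.1f}s, shorter than the "
                f"{excerpt_s:.0f}s excerpt"
            )
        if phase == "ascending":
            t0 = start
            if annotations is not None:
                onsets = [a.onset_s for a in annotations if start <= a.onset_s < end]
                if onsets:
                    t0 = min(onsets)
            t0 = min(t0, end - excerpt_s)
        else:
            mid = 0.5 * (start + end)
            t0 = min(max(mid - excerpt_s / 2, start), end - excerpt_s)
        out[phase] = (t0, t0 + excerpt_s)
    return out


def rms_equalize(
    parts: list[seg.Waveform], target_rms: float | None = None
) -> list[seg.Waveform]:
    """Rescale every part to a common RMS (default: mean of input RMS)."""
    rms = [float(np.sqrt(np.mean(p.samples**2))) for p in parts]
    if any(r == 0 for r in rms):
        raise ValueError("cannot RMS-equalize a silent part")
    target = float(np.mean(rms)) if target_rms is None else target_rms
    return [seg.Waveform(p.samples * (target / r), p.rate) for p, r in zip(parts, rms)]


def build_stimulus(
    asc_excerpt: seg.Waveform,
    level_excerpt: seg.Waveform,
    asc_source: str = "NR",
    level_source: str = "NL",
    repeats: int = 2,
    expected_s: float | None = 20.0,
) -> Stimulus:
    """Chimeric playback stimulus: [ascending x repeats, level x repeats].

    With the defaults (two 20 s excerpts broadcast twice each) the
    stimulus lasts 80 s.  Parts are RMS equalized before concatenation;
    the structure records each part's phase and source individual.
    """
    if asc_excerpt.rate != level_excerpt.rate:
        raise ValueError("excerpt sampling rates differ")
    if expected_s is not None:
        for name, w in (("ascending", asc_excerpt), ("level", level_excerpt)):
            if abs(w.duration_s - expected_s) * w.rate > 1:
                raise ValueError(
                    f"{name} excerpt lasts {w.duration_s:.3f}s, expected {expected_s}s"
                )
    asc, lvl = rms_equalize([asc_excerpt, level_excerpt])
    chunks = [asc.samples] * repeats + [lvl.samples] * repeats
    structure = tuple(
        [StimulusPart("ascending", asc_source, asc.duration_s, r) for r in range(repeats)]
        + [StimulusPart("level", level_source, lvl.duration_s, r) for r in range(repeats)]
    )
    return Stimulus(seg.Waveform(np.concatenate(chunks), asc.rate), structure)


def _transfer_labels(
    detected: list[seg.SyllableAnnotation],
    truth: list[seg.SyllableAnnotation],
) -> list[seg.SyllableAnnotation]:
    """Label each detected syllable from the max-overlap ground-truth one."""
    out = []
    for d in detected:
        best, best_ov = None, 0.0
        for t in truth:
            ov = min(d.offset_s, t.offset_s) - max(d.onset_s, t.onset_s)
            if ov > best_ov:
                best, best_ov = t, ov
        out.append(seg.SyllableAnnotation(d.onset_s, d.offset_s, best.label if best else None))
    return out


def _excerpt_features(
    config: StudyConfig,
    wav: seg.Waveform,
    truth: list[seg.SyllableAnnotation],
    labels: seqs.LabelSequence,
) -> dict[str, float]:
    """Segment one rendered phase song and measure the 13 phase parameters."""
    filtered = seg.highpass(wav, config.highpass_hz)
    detected = seg.segment_syllables(
        filtered, config.threshold_db, config.merge_gap_ms, config.min_dur_ms
    )
    detected = _transfer_labels(detected, truth)
    table = feat.syllable_features(
        filtered, detected, config.floor_db, config.fft_length, config.overlap_frac
    )
    summary = feat.phase_summary(table, labels.phase)
    scores = seqs.window_versatility(labels, window=config.window)
    counts = seqs.window_versatility(labels, window=config.window, trver_mode="count")
    row = dict(summary.means)
    row["rhythm"] = summary.rhythm
    row["tempo"] = summary.tempo
    row["sylver"] = float(np.mean([s.sylver for s in scores]))
    row["trver"] = float(np.mean([s.trver for s in scores]))
    row["totver"] = float(np.mean([s.totver for s in scores]))
    # debug variants of the ambiguous metrics, under distinct names
    row["rhythm_ratio_of_means"] = summary.rhythm_ratio_of_means
    row["trver_count"] = float(np.mean([s.trver for s in counts]))
    row["n_syllables"] = summary.n_syllables
    return row


def _pairwise_rs(
    study: synth.SyntheticStudy, config: StudyConfig
) -> pd.DataFrame:
    """RS per within-group pair, per phase, in syllable and sequence mode."""
    groups: dict[int, list[str]] = {}
    inds = study.individuals
    for i, ind in enumerate(inds):
        groups.setdefault(i // config.group_size, []).append(ind)
    rows = []
    for phase in study.phases:
        pooled: dict[str, seqs.LabelSequence] = {}
        for ind in inds:
            labels: list[int] = []
            for s in range(config.n_songs):
                labels.extend(study.songs[(ind, phase, s)][2].labels)
            pooled[ind] = seqs.LabelSequence(tuple(labels), ind, phase)
        for members in groups.values():
            for a, b in itertools.combinations(members, 2):
                syl = seqs.pairwise_similarity(
                    seqs.syllable_repertoire(pooled[a]), seqs.syllable_repertoire(pooled[b]),
                    mode="syllables",
                )
                cat = seqs.pairwise_similarity(
                    seqs.build_catalog(pooled[a]), seqs.build_catalog(pooled[b])
                )
                for r in (syl, cat):
                    rows.append(
                        {"phase": phase, "id_a": a, "id_b": b, "mode": r.mode,
                         "X": r.X, "Y": r.Y, "Z": r.Z, "RS": r.rs}
                    )
    return pd.DataFrame(rows)


def run_phase_comparison(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Full synthetic phase comparison; returns a JSON-serializable report.

    The report contains the per-parameter phase summary (mean ± SE across
    individuals, within-subject F and p), the pDFA result, and the
    repertoire-sharing comparison between phases.
    """
    study = synth.make_study(
        n_individuals=config.n_individuals,
        n_songs=config.n_songs,
        n_syllables=config.n_syllables,
        n_types=config.n_types,
        group_size=config.group_size,
        n_group_sequences=config.n_group_sequences,
        group_pool_size=config.group_pool_size,
        phase_params=(config.ascending, config.level),
        sample_rate=config.sample_rate,
        seed=config.seed,
        noise_snr_db=config.noise_snr_db,
    )
    rows = []
    for (ind, phase, song), (wav, truth, labels) in sorted(study.songs.items()):
        row = _excerpt_features(config, wav, truth, labels)
        row.update({"individual_id": ind, "phase": phase, "song": song})
        rows.append(row)
    table = pd.DataFrame(rows)

    summary_rows = []
    for param in PHASE_PARAMETERS:
        per_ind = table.groupby(["individual_id", "phase"])[param].mean().unstack()
        f_stat, p = st.within_subject_phase_test(table, param)
        entry = {"parameter": param, "F": f_stat, "p": p}
        for phase in per_ind.columns:
            vals = per_ind[phase]
            entry[f"{phase}_mean"] = float(vals.mean())
            entry[f"{phase}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        summary_rows.append(entry)
    summary = pd.DataFrame(summary_rows)

    screen = st.normality_screen(table, list(PHASE_PARAMETERS))
    pdfa = st.pdfa_crossed(
        table,
        [p for p in PHASE_PARAMETERS],
        n_permutations=config.n_permutations,
        seed=config.seed,
        exclude=config.exclude_from_pdfa,
    )

    rs = _pairwise_rs(study, config)
    rs_tests = {}
    for mode in ("syllables", "sequences"):
        sub = rs[rs["mode"] == mode].pivot_table(
            index=["id_a", "id_b"], columns="phase", values="RS"
        )
        if {"ascending", "level"} <= set(sub.columns) and len(sub) >= 2:
            p = st.paired_permutation_test(
                sub["ascending"].to_numpy(), sub["level"].to_numpy(),
                n_mc=config.rs_n_mc, seed=config.seed,
            )
            rs_tests[mode] = {
                "mean_rs_ascending": float(sub["ascending"].mean()),
                "mean_rs_level": float(sub["level"].mean()),
                "n_pairs": int(len(sub)),
                "p": p,
            }

    report = {
        "seed": config.seed,
        "n_individuals": config.n_individuals,
        "n_rows": int(len(table)),
        "phase_summary": summary.to_dict(orient="records"),
        "normality_screen": screen,
        "pdfa": {
            "n_correct": pdfa.n_correct,
            "n_total": pdfa.n_total,
            "p_value": pdfa.p_value,
            "n_permutations": pdfa.n_permutations,
            "excluded_parameters": list(pdfa.excluded_parameters),
            "discriminant_coefficients": pdfa.discriminant_coefficients,
        },
        "repertoire_sharing": rs_tests,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "feature_table.csv", index=False)
        summary.to_csv(out / "phase_summary.csv", index=False)
        rs.to_csv(out / "repertoire_similarity.csv", index=False)
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def run_playback_analysis(
    responses: pd.DataFrame,
    alpha: float = 0.05,
    loading_threshold: float = 0.5,
    call_count_floor: float = 5.0,
    out_dir: str | Path | None = None,
) -> dict:
    """Score a playback-response table and test stimulus-type effects.

    De-duplicates the 11 measures, builds PCA composite scores
    (eigenvalue > 1 retained), runs within-subject tests of each score
    against stimulus type and presentation order, and follows up measures
    with |loading| >= ``loading_threshold`` on significant components
    with Wilcoxon signed-rank tests on the raw measure.
    """
    n_subjects = responses["subject"].nunique()
    if n_subjects < 4:
        raise ValueError(f"need at least 4 subjects, got {n_subjects}")
    measures = [m for m in synth.RESPONSE_MEASURES if m in responses.columns]
    reduced, dropped = st.dedup_measures(
        responses, measures, count_floor=call_count_floor
    )
    kept = [m for m in measures if m in reduced.columns]
    scores = st.response_pca(reduced, kept)
    tests = st.playback_analysis(scores, reduced)

    followups = []
    wide = reduced.pivot_table(index="subject", columns="stimulus")
    for _, row in tests.iterrows():
        if row["p_stimulus"] >= alpha:
            continue
        comp = row["component"]
        strong = scores.loadings.index[scores.loadings[comp].abs() >= loading_threshold]
        for measure in strong:
            w, p = st.wilcoxon_signed_rank(
                wide[(measure, "S1")].to_numpy(), wide[(measure, "S2")].to_numpy()
            )
            followups.append(
                {"component": comp, "measure": measure, "w_plus": w, "p": p,
                 "mean_s1": float(wide[(measure, "S1")].mean()),
                 "mean_s2": float(wide[(measure, "S2")].mean())}
            )

    report = {
        "n_subjects": int(n_subjects),
        "n_trials": int(len(responses)),
        "dropped_measures": dropped,
        "eigenvalues": [float(e) for e in scores.eigenvalues],
        "retained_components": [f"PC{i + 1}" for i in scores.retained],
        "variance_fraction": [float(v) for v in scores.variance_fraction],
        "loadings": scores.loadings.to_dict(),
        "component_tests": tests.to_dict(orient="records"),
        "wilcoxon_followups": followups,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.scores.to_csv(out / "pc_scores.csv")
        scores.loadings.to_csv(out / "pc_loadings.csv")
        (out / "playback_report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True)
        )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj
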