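"""File formats: mono WAV, label-track TSV, response CSV, YAML config.

Label tracks are plain text, one syllable per line:
``onset_s<TAB>offset_s<TAB>label`` (label may be empty for unassigned).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .segment import SyllableAnnotation, Waveform

__all__ = [
    "read_wav",
    "write_wav",
    "read_labels",
    "write_labels",
    "read_responses",
    "write_responses",
    "load_yaml",
    "dump_yaml",
]


def read_wav(path: str | Path) -> Waveform:
    """Read a mono WAV file; integer PCM is rescaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return Waveform(data, int(rate))


def write_wav(path: str | Path, w: Waveform, pcm16: bool = False) -> None:
    """Write mono WAV as float32 (default) or 16-bit PCM."""
    if pcm16:
        data = np.clip(np.round(w.samples * 32767), -32768, 32767).astype(np.int16)
    else:
        data = w.samples.astype(np.float32)
    wavfile.write(path, w.rate, data)


def read_labels(path: str | Path) -> list[SyllableAnnotation]:
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{line_no}: expected onset<TAB>offset[<TAB>label]")
        label = int(parts[2]) if len(parts) > 2 and parts[2].strip() else None
        out.append(SyllableAnnotation(float(parts[0]), float(parts[1]), label))
    return out


def write_labels(path: str | Path, annotations: list[SyllableAnnotation]) -> None:
    lines = [
        f"{a.onset_s:.6f}\t{a.offset_s:.6f}\t{a.label if a.label is not None else ''}"
        for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_responses(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_responses(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
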