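"""Sequence-level song analysis.

Works on ordered syllable-type label sequences: versatility indices in
10-syllable windows, catalogs of repeated/shared sub-sequences, and the
repertoire-similarity coefficient RS = Z / ((X + Y) - Z).

Versatility indices (per window of 10 syllables):

* ``SylVer`` — number of distinct syllable types (0-10);
* ``TrVer``  — variety of transitions between two *different* syllables,
  i.e. the number of distinct ordered adjacent pairs (a, b) with a != b
  (0-9);
* ``TotVer`` — SylVer x TrVer (0-90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "LabelSequence",
    "VersatilityScores",
    "SequenceCatalog",
    "RepertoireSimilarity",
    "window_versatility",
    "build_catalog",
    "shared_items",
    "repertoire_similarity",
    "syllable_repertoire",
]


@dataclass(frozen=True)
class LabelSequence:
    """Ordered syllable-type labels for one individual in one flight phase."""

    labels: tuple[int, ...]
    individual_id: str = "bird"
    phase: str | None = None

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        if not labels:
            raise ValueError("label sequence must be nonempty")
        if any(x <= 0 for x in labels):
            raise ValueError("syllable labels must be positive integers")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class VersatilityScores:
    window_index: int
    sylver: int
    trver: int

    @property
    def totver(self) -> int:
        return self.sylver * self.trver


@dataclass(frozen=True)
class SequenceCatalog:
    """Distinct sub-sequences of an individual's song with occurrence counts.

    Keys are label tuples of length 3-10 containing at least three distinct
    syllable types; overlapping occurrences are counted.
    """

    individual_id: str
    entries: dict[tuple[int, ...], int] = field(default_factory=dict)
    mode: str = "sequences"

    @property
    def size(self) -> int:
        """Number of distinct sequence types (the X/Y of the RS formula)."""
        return len(self.entries)

    def repeated(self) -> dict[tuple[int, ...], int]:
        """Sub-sequences sung more than once by this individual."""
        return {k: v for k, v in self.entries.items() if v >= 2}


@dataclass(frozen=True)
class RepertoireSimilarity:
    """RS = Z / ((X + Y) - Z) between two individuals' repertoires."""

    X: int
    Y: int
    Z: int
    mode: str

    def __post_init__(self) -> None:
        if self.X < 1 or self.Y < 1:
            raise ValueError("repertoire sizes X, Y must be >= 1")
        if not (0 <= self.Z <= min(self.X, self.Y)):
            raise ValueError(f"shared count Z={self.Z} exceeds min(X={self.X}, Y={self.Y})")
        if self.mode not in ("syllables", "sequences"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def rs(self) -> float:
        return self.Z / ((self.X + self.Y) - self.Z)


def _labels(s: LabelSequence | list[int] | tuple[int, ...]) -> tuple[int, ...]:
    if isinstance(s, LabelSequence):
        return s.labels
    return LabelSequence(tuple(s)).labels


def window_versatility(
    s: LabelSequence | list[int],
    window: int = 10,
    sliding: bool = False,
    trver_mode: str = "distinct",
) -> list[VersatilityScores]:
    """Versatility scores over windows of ``window`` syllables.

    Windows are non-overlapping and consecutive from the start (a trailing
    partial window is dropped); ``sliding=True`` evaluates every start
    position instead.  ``trver_mode`` selects the transition count:
    ``"distinct"`` counts distinct ordered differing pairs (variety of
    transitions); ``"count"`` counts every differing adjacent pair.
    """
    labels = _labels(s)
    if trver_mode not in ("distinct", "count"):
        raise ValueError(f"unknown trver_mode {trver_mode!r}")
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(labels) < window:
        warnings.warn(
            f"sequence of {len(labels)} labels shorter than window {window}; "
            "no versatility scores computed",
            stacklevel=2,
        )
        return []
    starts = range(0, len(labels) - window + 1, 1 if sliding else window)
    out = []
    for i, start in enumerate(starts):
        win = labels[start : start + window]
        pairs = [(a, b) for a, b in zip(win, win[1:]) if a != b]
        trver = len(set(pairs)) if trver_mode == "distinct" else len(pairs)
        out.append(VersatilityScores(window_index=i, sylver=len(set(win)), trver=trver))
    return out


def build_catalog(
    s: LabelSequence | list[int],
    min_len: int = 3,
    max_len: int = 10,
    min_distinct: int = 3,
    strict_adjacent: bool = False,
) -> SequenceCatalog:
    """Catalog every qualifying contiguous sub-sequence with its count.

    A sub-sequence qualifies if its length is in [min_len, max_len] and it
    contains at least ``min_distinct`` distinct syllable types ("at least
    three different syllable types").  ``strict_adjacent=True`` additionally
    requires every adjacent pair within the sub-sequence to differ.
    Overlapping occurrences are counted.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    labels = _labels(s)
    ind = s.individual_id if isinstance(s, LabelSequence) else "bird"
    entries: dict[tuple[int, ...], int] = {}
    n = len(labels)
    for length in range(min_len, min(max_len, n) + 1):
        for start in range(n - length + 1):
            sub = labels[start : start + length]
            if len(set(sub)) < min_distinct:
                continue
            if strict_adjacent and any(a == b for a, b in zip(sub, sub[1:])):
                continue
            entries[sub] = entries.get(sub, 0) + 1
    return SequenceCatalog(individual_id=ind, entries=entries)


def syllable_repertoire(s: LabelSequence | list[int]) -> set[int]:
    """The set of syllable types an individual used (syllable-mode repertoire)."""
    return set(_labels(s))


def shared_items(
    a: SequenceCatalog | set[int],
    b: SequenceCatalog | set[int],
) -> set:
    """Items shared between two repertoires; ``len()`` of the result is Z.

    Both arguments must be of the same mode: two sequence catalogs, or two
    syllable-label sets.
    """
    a_is_cat = isinstance(a, SequenceCatalog)
    b_is_cat = isinstance(b, SequenceCatalog)
    if a_is_cat != b_is_cat:
        raise ValueError("cannot intersect a sequence catalog with a syllable set")
    if a_is_cat:
        return set(a.entries) & set(b.entries)
    return set(a) & set(b)


def repertoire_similarity(
    X: int, Y: int, Z: int, mode: str = "syllables"
) -> RepertoireSimilarity:
    """RS coefficient from repertoire sizes X, Y and shared count Z.

    RS ranges from 0 (nothing shared) to 1 (identical repertoires).
    """
    return RepertoireSimilarity(X=X, Y=Y, Z=Z, mode=mode)


def pairwise_similarity(
    a: SequenceCatalog | set[int],
    b: SequenceCatalog | set[int],
    mode: str | None = None,
) -> RepertoireSimilarity:
    """RS between two repertoires given directly as catalogs or label sets."""
    if mode is None:
        mode = "sequences" if isinstance(a, SequenceCatalog) else "syllables"
    z = len(shared_items(a, b))
    x = a.size if isinstance(a, SequenceCatalog) else len(a)
    y = b.size if isinstance(b, SequenceCatalog) else len(b)
    return RepertoireSimilarity(X=x, Y=y, Z=z, mode=mode)
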