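"""Labels, bag construction and leakage-free patient-level splits.

Stenosis severity is graded on the ordinal clinical scale (none → total
occlusion); the artery-level grade is the maximum over evaluated segments and
the binary task is "moderate or greater" (≥50% luminal obstruction).  Slices
are grouped into fixed-size bags of 36 for multi-instance learning, padding
short bags by cycling the patient's own slices.  Splits are stratified random
70/15/15 partitions at the patient level, repeated with distinct seeds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

BAG_SIZE = 36

ARTERIES = ("LAD", "RCA", "LCX")


class StenosisGrade(enum.IntEnum):
    """Ordinal stenosis severity grade.

    Percent cut-offs: 0 (none), 1-24 (minimal), 25-49 (mild), 50-69
    (moderate), 70-99 (severe), 100 (total occlusion).
    """

    NONE = 0
    MINIMAL = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4
    TOTAL_OCCLUSION = 5


#: Lower percent bound of each grade, in ordinal order.
_GRADE_LOWER_BOUNDS = [
    (100.0, StenosisGrade.TOTAL_OCCLUSION),
    (70.0, StenosisGrade.SEVERE),
    (50.0, StenosisGrade.MODERATE),
    (25.0, StenosisGrade.MILD),
    (1.0, StenosisGrade.MINIMAL),
    (0.0, StenosisGrade.NONE),
]


def grade_from_percent(percent: float) -> StenosisGrade:
    """Map a stenosis percentage (0-100) to its ordinal grade."""
    if not np.isfinite(percent) or percent < 0 or percent > 100:
        raise ValueError(f"stenosis percent must lie in [0, 100], got {percent!r}")
    for lower, grade in _GRADE_LOWER_BOUNDS:
        if percent >= lower:
            return grade
    raise AssertionError("unreachable")


def artery_label(segment_grades: list[StenosisGrade]) -> tuple[StenosisGrade, int]:
    """Artery-level grade = max over segment grades; positive iff ≥ moderate."""
    if not segment_grades:
        raise ValueError("no evaluated segments: segment_grades is empty")
    top = max(StenosisGrade(g) for g in segment_grades)
    return top, int(top >= StenosisGrade.MODERATE)


@dataclass
class PatientRecord:
    patient_id: str
    artery: str
    segment_grades: list[StenosisGrade] = field(default_factory=list)
    slice_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.artery not in ARTERIES:
            raise ValueError(f"artery must be one of {ARTERIES}, got {self.artery!r}")

    @property
    def artery_grade(self) -> StenosisGrade:
        return artery_label(self.segment_grades)[0]

    @property
    def label(self) -> int:
        return artery_label(self.segment_grades)[1]


@dataclass
class Bag:
    """An ordered set of exactly 36 slice references sharing the patient label.

    ``entries`` are slice identifiers; ``replicated_flags[i]`` is True when
    entry *i* is a padding replica rather than an original occurrence.
    """

    patient_id: str
    bag_index: int
    entries: list
    replicated_flags: list[bool]
    label: int

    def __post_init__(self) -> None:
        if len(self.entries) != BAG_SIZE or len(self.replicated_flags) != BAG_SIZE:
            raise ValueError(f"a bag holds exactly {BAG_SIZE} entries")


def make_bags(slice_ids: list, label: int = 0, patient_id: str = "", bag_size: int = BAG_SIZE) -> list[Bag]:
    """Chunk a patient's ordered slices into ceil(n/36) bags of exactly 36.

    A short final (or only) chunk is padded by cycling the patient's original
    slices from the start; padded entries are flagged as replicated.
    """
    n = len(slice_ids)
    if n == 0:
        raise ValueError("cannot build bags from an empty slice list")
    bags = []
    n_bags = math.ceil(n / bag_size)
    for b in range(n_bags):
        chunk = list(slice_ids[b * bag_size : (b + 1) * bag_size])
        flags = [False] * len(chunk)
        pad_idx = 0
        while len(chunk) < bag_size:
            chunk.append(slice_ids[pad_idx % n])
            flags.append(True)
            pad_idx += 1
        bags.append(Bag(patient_id=patient_id, bag_index=b, entries=chunk, replicated_flags=flags, label=label))
    return bags


@dataclass
class SplitAssignment:
    """Leakage-free patient → {train, val, test} partition."""

    assignment: dict[str, str]
    seed: int
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def patients(self, split: str) -> list[str]:
        return [pid for pid, s in self.assignment.items() if s == split]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_patients(
    labels: dict[str, int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified random 70/15/15 patient-level split.

    Within each class the patients are shuffled by ``seed``; the test and
    validation counts are round-half-up of the class size times the split
    fraction, the remainder goes to training.  With the published class
    totals this allocation reproduces the printed per-split positive counts.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("split fractions must sum to 1")
    classes: dict[int, list[str]] = {}
    for pid, y in labels.items():
        classes.setdefault(int(y), []).append(pid)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify the split")
    for y, pids in classes.items():
        if len(pids) < 3:
            raise ValueError(f"class {y} has {len(pids)} patients; need ≥3 to populate all splits")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for y in sorted(classes):
        pids = sorted(classes[y])
        rng.shuffle(pids)
        n = len(pids)
        n_test = _round_half_up(n * fractions[2])
        n_val = _round_half_up(n * fractions[1])
        for pid in pids[:n_test]:
            assignment[pid] = "test"
        for pid in pids[n_test : n_test + n_val]:
            assignment[pid] = "val"
        for pid in pids[n_test + n_val :]:
            assignment[pid] = "train"
    return SplitAssignment(assignment=assignment, seed=seed, fractions=tuple(fractions))


def repeated_splits(
    labels: dict[str, int],
    n_repeats: int = 5,
    base_seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> list[SplitAssignment]:
    """Five (by default) independent stratified splits with seeds base_seed+i."""
    return [split_patients(labels, fractions=fractions, seed=base_seed + i) for i in range(n_repeats)]


def split_counts(labels: dict[str, int], assignment: SplitAssignment) -> dict[str, dict[str, int]]:
    """Per-split total and positive patient counts (bookkeeping helper)."""
    out: dict[str, dict[str, int]] = {s: {"n": 0, "positives": 0} for s in ("train", "val", "test")}
    for pid, split in assignment.assignment.items():
        out[split]["n"] += 1
        out[split]["positives"] += int(labels[pid])
    return out
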