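"""Antibiotic-associated diarrhea (AAD) labeling from stool diaries.

A subject is labeled AAD if their diary records at least one episode of
Bristol Stool Scale type 6 or 7 on any of treatment days 1-3.  A separate
flag marks subjects who would have had their antibiotic stopped early:
three or more watery episodes within a single study day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DiaryRecord",
    "StoolDiary",
    "SubjectLabel",
    "classify_aad",
    "flag_early_stop",
    "label_cohort",
]

#: Bristol types counted as watery stool
WATERY_LEVELS = frozenset({6, 7})
#: treatment days over which the AAD definition applies
TREATMENT_DAYS = frozenset({1, 2, 3})


@dataclass(frozen=True)
class DiaryRecord:
    day: int
    episode_index: int
    bristol: int


@dataclass
class StoolDiary:
    """Per-subject stool diary: one record per bowel-opening episode."""

    subject_id: str
    records: list[DiaryRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        for rec in self.records:
            if not 1 <= rec.bristol <= 7:
                raise ValueError(
                    f"subject {self.subject_id}: Bristol score {rec.bristol} "
                    "outside 1-7"
                )
            key = (rec.day, rec.episode_index)
            if key in seen:
                raise ValueError(
                    f"subject {self.subject_id}: duplicate episode index "
                    f"{rec.episode_index} on day {rec.day}"
                )
            seen.add(key)


@dataclass(frozen=True)
class SubjectLabel:
    subject_id: str
    aad: bool
    early_stop: bool
    n_watery_episodes_d1_3: int
    max_bristol_d1_3: int | None


def classify_aad(
    diary: StoolDiary, watery_levels: frozenset[int] = WATERY_LEVELS
) -> SubjectLabel:
    """Label one subject from their diary.

    AAD = at least one watery (Bristol 6-7) episode on days 1, 2 or 3.
    Subjects with no day 1-3 records are labeled non-AAD with a warning.
    """
    diary.validate()
    window = [r for r in diary.records if r.day in TREATMENT_DAYS]
    if not window:
        warnings.warn(
            f"subject {diary.subject_id}: no diary records on days 1-3; "
            "labeled non-AAD",
            stacklevel=2,
        )
        return SubjectLabel(diary.subject_id, False, False, 0, None)
    max_bristol = max(r.bristol for r in window)
    n_watery = sum(r.bristol in watery_levels for r in window)
    aad = max_bristol in watery_levels
    early = flag_early_stop(diary, watery_levels=watery_levels, _validated=True)
    return SubjectLabel(diary.subject_id, aad, early, n_watery, max_bristol)


def flag_early_stop(
    diary: StoolDiary,
    watery_levels: frozenset[int] = WATERY_LEVELS,
    _validated: bool = False,
) -> bool:
    """True iff some single day in 1-3 has >= 3 watery episodes.

    The protocol's "24-h period" is approximated by a calendar study day,
    the resolution at which diaries record episodes.
    """
    if not _validated:
        diary.validate()
    per_day: dict[int, int] = {}
    for r in diary.records:
        if r.day in TREATMENT_DAYS and r.bristol in watery_levels:
            per_day[r.day] = per_day.get(r.day, 0) + 1
    return any(n >= 3 for n in per_day.values())


def label_cohort(
    diaries: list[StoolDiary], watery_levels: frozenset[int] = WATERY_LEVELS
) -> pd.DataFrame:
    """Label every subject; returns a DataFrame indexed by subject_id."""
    labels = [classify_aad(d, watery_levels=watery_levels) for d in diaries]
    return pd.DataFrame(
        {
            "aad": [l.aad for l in labels],
            "early_stop": [l.early_stop for l in labels],
            "n_watery_episodes_d1_3": [l.n_watery_episodes_d1_3 for l in labels],
            "max_bristol_d1_3": [l.max_bristol_d1_3 for l in labels],
        },
        index=pd.Index([l.subject_id for l in labels], name="subject_id"),
    )
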