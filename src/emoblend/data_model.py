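"""Domain types and CSV I/O for trial-level blended-emotion judgment data.

A *trial* is one participant judging one stimulus. Each stimulus portrays a
pair of emotions (a *blend*) drawn from five categories, at one of three
relative-prominence conditions. Participants rate the stimulus on a subset of
the five emotion scales (0--10); scales they did not select are *missing*,
which is semantically distinct from a rating of 0 and is preserved through
every read/write cycle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The five admissible emotion labels, in their canonical (alphabetical) order.
EMOTIONS: tuple[str, ...] = ("anger", "disgust", "fear", "happiness", "sadness")

#: Index of each emotion in the canonical order.
EMOTION_INDEX: dict[str, int] = {e: i for i, e in enumerate(EMOTIONS)}

#: The three relative-prominence conditions.  ``30:70`` means the stimulus's
#: *second* stored emotion is the more prominent one, ``70:30`` the first,
#: ``50:50`` neither.  The labels denote ordering, not exact percentages.
PROPORTIONS: tuple[str, ...] = ("30:70", "50:50", "70:30")

RATING_COLUMNS: tuple[str, ...] = tuple(f"rating_{e}" for e in EMOTIONS)

CSV_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "stimulus_id",
    "actor_id",
    "emotion_first",
    "emotion_second",
    "proportion",
) + RATING_COLUMNS


class DataError(ValueError):
    """Raised for malformed input data (bad labels, ratings, structure)."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the canonical (alphabetically sorted) key for an emotion pair.

    The blend identity is the unordered pair; prominence is carried separately
    by the proportion condition. Symmetric in its arguments.

    Raises
    ------
    DataError
        If either label is unknown or the two labels are identical.
    """
    for x in (a, b):
        if x not in EMOTION_INDEX:
            raise DataError(f"unknown emotion label: {x!r}")
    if a == b:
        raise DataError(f"degenerate emotion pair: ({a!r}, {b!r})")
    return (a, b) if EMOTION_INDEX[a] < EMOTION_INDEX[b] else (b, a)


def combination_label(a: str, b: str) -> str:
    """Human-readable canonical key, e.g. ``'anger-disgust'``."""
    x, y = canonical_pair(a, b)
    return f"{x}-{y}"


#: The 10 canonical pairwise combinations, alphabetically ordered.
ALL_COMBINATIONS: tuple[tuple[str, str], ...] = tuple(
    (EMOTIONS[i], EMOTIONS[j])
    for i in range(len(EMOTIONS))
    for j in range(i + 1, len(EMOTIONS))
)


@dataclass(frozen=True)
class StimulusSpec:
    """Ground truth for one stimulus: intended blend, prominence, actor."""

    stimulus_id: str
    actor_id: str
    emotion_first: str
    emotion_second: str
    proportion: str

    def __post_init__(self) -> None:
        canonical_pair(self.emotion_first, self.emotion_second)  # validates
        if self.proportion not in PROPORTIONS:
            raise DataError(
                f"stimulus {self.stimulus_id!r}: invalid proportion "
                f"{self.proportion!r} (expected one of {PROPORTIONS})"
            )

    @property
    def combination(self) -> tuple[str, str]:
        return canonical_pair(self.emotion_first, self.emotion_second)

    @property
    def combination_label(self) -> str:
        return "-".join(self.combination)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset((self.emotion_first, self.emotion_second))

    @property
    def more_prominent(self) -> str | None:
        """The intended more-prominent emotion; ``None`` for 50:50."""
        if self.proportion == "70:30":
            return self.emotion_first
        if self.proportion == "30:70":
            return self.emotion_second
        return None

    @property
    def less_prominent(self) -> str | None:
        if self.proportion == "70:30":
            return self.emotion_second
        if self.proportion == "30:70":
            return self.emotion_first
        return None


@dataclass(frozen=True)
class ResponseRecord:
    """One participant x stimulus judgment: selected scales and their ratings.

    ``ratings`` maps emotion label -> rating for *selected* scales only; an
    absent key means the scale was not selected (never a 0).
    """

    participant_id: str
    stimulus_id: str
    ratings: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 1 <= len(self.ratings) <= 5:
            raise DataError(
                f"response ({self.participant_id!r}, {self.stimulus_id!r}): "
                f"{len(self.ratings)} scales selected, expected 1-5"
            )
        for e, r in self.ratings.items():
            if e not in EMOTION_INDEX:
                raise DataError(f"unknown emotion scale {e!r}")
            if not 0 <= r <= 10:
                raise DataError(
                    f"response ({self.participant_id!r}, {self.stimulus_id!r}): "
                    f"rating {r!r} on {e} outside [0, 10]"
                )

    @property
    def selected(self) -> frozenset[str]:
        return frozenset(self.ratings)

    @property
    def k_selected(self) -> int:
        return len(self.ratings)


@dataclass
class Dataset:
    """A study's worth of responses plus the stimulus ground truth.

    ``mode`` is ``'forced2'`` (exactly two scales per response) or ``'free'``
    (any number from 1 to 5).
    """

    stimuli: dict[str, StimulusSpec]
    responses: list[ResponseRecord]
    mode: str = "forced2"

    def __post_init__(self) -> None:
        if self.mode not in ("forced2", "free"):
            raise DataError(f"unknown mode {self.mode!r}")

    def stimulus_for(self, response: ResponseRecord) -> StimulusSpec:
        try:
            return self.stimuli[response.stimulus_id]
        except KeyError:
            raise DataError(
                f"response ({response.participant_id!r}) references unknown "
                f"stimulus {response.stimulus_id!r}"
            ) from None

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.responses:
            seen.setdefault(r.participant_id, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.responses)


def _parse_rating_cell(value: object, row_no: int, column: str) -> float | None:
    """Parse one CSV rating cell: empty -> not selected, else integer 0-10."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        num = float(text)
    except ValueError:
        raise DataError(f"row {row_no}: {column} = {value!r} is not a number")
    if not num.is_integer():
        raise DataError(f"row {row_no}: {column} = {value!r} is not an integer")
    if not 0 <= num <= 10:
        raise DataError(f"row {row_no}: {column} = {value!r} outside [0, 10]")
    return float(num)


def load_dataset(path: str | Path | io.TextIOBase, mode: str = "forced2") -> Dataset:
    """Read a long-format trial CSV into a validated :class:`Dataset`.

    One row per (participant, stimulus); empty rating cells mean *not
    selected*. Errors name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")

    stimuli: dict[str, StimulusSpec] = {}
    responses: list[ResponseRecord] = []
    seen_pairs: set[tuple[str, str]] = set()

    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            spec = StimulusSpec(
                stimulus_id=row_d["stimulus_id"],
                actor_id=row_d["actor_id"],
                emotion_first=row_d["emotion_first"],
                emotion_second=row_d["emotion_second"],
                proportion=row_d["proportion"],
            )
        except DataError as exc:
            raise DataError(f"row {i}: {exc}") from None
        prior = stimuli.setdefault(spec.stimulus_id, spec)
        if prior != spec:
            raise DataError(
                f"row {i}: stimulus {spec.stimulus_id!r} redefined with "
                f"conflicting attributes"
            )

        ratings: dict[str, float] = {}
        for emotion, column in zip(EMOTIONS, RATING_COLUMNS):
            value = _parse_rating_cell(row_d[column], i, column)
            if value is not None:
                ratings[emotion] = value
        if not ratings:
            raise DataError(f"row {i}: no scales selected (need at least 1)")
        if mode == "forced2" and len(ratings) != 2:
            raise DataError(
                f"row {i}: {len(ratings)} scales selected but mode is "
                f"forced2 (exactly 2 required)"
            )
        key = (row_d["participant_id"], spec.stimulus_id)
        if key in seen_pairs:
            raise DataError(f"row {i}: duplicate (participant, stimulus) pair {key}")
        seen_pairs.add(key)
        responses.append(
            ResponseRecord(
                participant_id=row_d["participant_id"],
                stimulus_id=spec.stimulus_id,
                ratings=ratings,
            )
        )
    return Dataset(stimuli=stimuli, responses=responses, mode=mode)


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    """Long-format frame in the canonical CSV column layout."""
    rows = []
    for r in ds.responses:
        s = ds.stimulus_for(r)
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "stimulus_id": r.stimulus_id,
            "actor_id": s.actor_id,
            "emotion_first": s.emotion_first,
            "emotion_second": s.emotion_second,
            "proportion": s.proportion,
        }
        for emotion, column in zip(EMOTIONS, RATING_COLUMNS):
            rating = r.ratings.get(emotion)
            if rating is None:
                row[column] = ""
            elif float(rating).is_integer():
                row[column] = str(int(rating))
            else:
                row[column] = repr(float(rating))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write ``ds`` in the canonical CSV dialect (empty cell = not selected)."""
    dataset_to_frame(ds).to_csv(path, index=False)


def validate(ds: Dataset) -> list[str]:
    """Check dataset invariants; return findings (empty list when clean).

    Hard violations are prefixed ``ERROR:``; design-completeness findings
    (a participant who did not judge every stimulus) are ``WARNING:``.
    """
    findings: list[str] = []
    seen: set[tuple[str, str]] = set()
    for r in ds.responses:
        if r.stimulus_id not in ds.stimuli:
            findings.append(
                f"ERROR: response ({r.participant_id!r}, {r.stimulus_id!r}) "
                f"references a stimulus that is not in the design"
            )
        key = (r.participant_id, r.stimulus_id)
        if key in seen:
            findings.append(f"ERROR: duplicate (participant, stimulus) pair {key}")
        seen.add(key)
        if ds.mode == "forced2" and r.k_selected != 2:
            findings.append(
                f"ERROR: response {key} selected {r.k_selected} scales "
                f"under forced2 mode"
            )
        for e, v in r.ratings.items():
            if not 0 <= v <= 10:
                findings.append(f"ERROR: response {key} rating {e}={v} outside [0, 10]")
    all_stimuli = set(ds.stimuli)
    by_participant: dict[str, set[str]] = {}
    for r in ds.responses:
        by_participant.setdefault(r.participant_id, set()).add(r.stimulus_id)
    for pid, judged in by_participant.items():
        missing = sorted(all_stimuli - judged)
        if missing:
            findings.append(
                f"WARNING: participant {pid!r} missing {len(missing)} "
                f"stimuli: {missing}"
            )
    return findings


def build_stimuli_index(specs: Iterable[StimulusSpec]) -> dict[str, StimulusSpec]:
    index: dict[str, StimulusSpec] = {}
    for s in specs:
        if s.stimulus_id in index:
            raise DataError(f"duplicate stimulus_id {s.stimulus_id!r}")
        index[s.stimulus_id] = s
    return index
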