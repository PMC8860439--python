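"""Annotations of song bouts: ordered labeled segments, and their CSV dialect.

An :class:`Annotation` is the universal interchange object of the package:
an ordered list of non-overlapping ``(onset_s, offset_s, label)`` segments
describing one bout of song.  Onsets and offsets are in seconds from the
start of the bout's audio file.  The on-disk dialect is a UTF-8 CSV with
header ``onset_s,offset_s,label`` and millisecond-precision floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Segment", "Annotation", "read_annotation", "write_annotation"]


@dataclass(frozen=True)
class Segment:
    """One labeled interval of song: ``[onset_s, offset_s)`` in seconds."""

    onset_s: float
    offset_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"segment offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class Annotation:
    """Ordered, non-overlapping labeled segments for one song bout."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.onset_s < prev.offset_s:
                raise ValueError(
                    "segments must be sorted and non-overlapping: "
                    f"{prev} followed by {cur}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.segments == other.segments

    @property
    def labels(self) -> list[str]:
        """The bout's label sequence, in temporal order."""
        return [seg.label for seg in self.segments]

    @property
    def durations_s(self) -> list[float]:
        return [seg.duration_s for seg in self.segments]

    @property
    def gaps_s(self) -> list[float]:
        """Silent intervals between consecutive segments, in seconds."""
        return [
            cur.onset_s - prev.offset_s
            for prev, cur in zip(self.segments, self.segments[1:])
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [s.onset_s for s in self.segments],
                "offset_s": [s.offset_s for s in self.segments],
                "label": [s.label for s in self.segments],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Annotation":
        return cls(
            [
                Segment(float(r.onset_s), float(r.offset_s), str(r.label))
                for r in df.itertuples()
            ]
        )


def write_annotation(path, annotation: Annotation) -> None:
    """Write ``annotation`` as CSV with header ``onset_s,offset_s,label``.

    Times are written with millisecond precision, matching the generator,
    which quantizes all ground-truth times to whole milliseconds.
    """
    df = annotation.to_dataframe()
    df.to_csv(path, index=False, float_format="%.3f", encoding="utf-8")


def read_annotation(path) -> Annotation:
    """Read an annotation CSV written by :func:`write_annotation`."""
    df = pd.read_csv(path, dtype={"label": str}, keep_default_na=False)
    return Annotation.from_dataframe(df)
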