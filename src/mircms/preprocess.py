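"""Raw-read cleaning: adapter trimming, length/junk filtering, tag collapsing.

The cleaning contract mirrors standard small-RNA vendor pipelines: reads are
3'-adapter trimmed, then kept only if 15–32 nt and not "junk" (any N, or one
base making up more than 80% of the read), then collapsed to unique tags with
per-library counts. Tags are what every later stage consumes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import SequenceRecord

MIN_LEN = 15
MAX_LEN = 32
JUNK_MONO_FRACTION = 0.8
MIN_ADAPTER_OVERLAP = 6


class ConfigurationError(ValueError):
    pass


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with raw read counts per library label."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RejectionTally:
    """Why reads were dropped during filtering. Conservation holds:
    input = kept + too_short + too_long + junk."""

    kept: int = 0
    too_short: int = 0
    too_long: int = 0
    junk: int = 0

    @property
    def total_in(self) -> int:
        return self.kept + self.too_short + self.too_long + self.junk


def trim_adapter(
    record: SequenceRecord,
    adapter_3p: str,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    max_mismatches: int = 0,
    keep_untrimmed: bool = True,
) -> SequenceRecord | None:
    """Remove a 3' adapter from a read.

    The longest read suffix matching a prefix of the adapter (at least
    ``min_overlap`` bases, at most ``max_mismatches`` mismatches) is removed.
    If no adapter is found the read is returned unchanged under the default
    keep policy, or dropped (``None``) with ``keep_untrimmed=False``.
    """
    if len(adapter_3p) < min_overlap:
        raise ConfigurationError(
            f"adapter length {len(adapter_3p)} < minimum overlap {min_overlap}"
        )
    seq = record.sequence
    # Full adapter occurrence anywhere, else adapter prefix at the read end.
    best: int | None = None
    for start in range(0, len(seq) - min_overlap + 1):
        overlap = min(len(adapter_3p), len(seq) - start)
        mism = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter_3p[:overlap]) if a != b
        )
        if overlap >= min_overlap and mism <= max_mismatches:
            best = start
            break  # leftmost hit = longest insert-preserving trim of the 3' end
    if best is None:
        return record if keep_untrimmed else None
    trimmed = seq[:best]
    if not trimmed:
        return None
    qual = record.quality[:best] if record.quality is not None else None
    return SequenceRecord(record.identifier, trimmed, qual)


def is_junk(sequence: str) -> bool:
    """Junk: contains N, or a single base composes > 80% of the read."""
    if "N" in sequence:
        return True
    most_common = Counter(sequence).most_common(1)[0][1]
    return most_common / len(sequence) > JUNK_MONO_FRACTION


def filter_reads(
    records: Iterable[SequenceRecord],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[SequenceRecord], RejectionTally]:
    """Keep reads with min_len ≤ length ≤ max_len (bounds inclusive) that are
    not junk; tally every rejection by reason."""
    kept: list[SequenceRecord] = []
    tally = RejectionTally()
    for rec in records:
        n = len(rec.sequence)
        if n < min_len:
            tally.too_short += 1
        elif n > max_len:
            tally.too_long += 1
        elif is_junk(rec.sequence):
            tally.junk += 1
        else:
            tally.kept += 1
            kept.append(rec)
    return kept, tally


def collapse(records: Iterable[SequenceRecord], library_label: str) -> list[SequenceTag]:
    """Collapse filtered reads into unique tags counted for one library.

    Tag order is by decreasing count then sequence, so output is deterministic.
    """
    counts = Counter(rec.sequence for rec in records)
    return [
        SequenceTag(seq, {library_label: n})
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def merge_tags(*tag_sets: Sequence[SequenceTag]) -> list[SequenceTag]:
    """Union tag sets from different libraries, merging count mappings."""
    merged: dict[str, SequenceTag] = {}
    for tags in tag_sets:
        for tag in tags:
            if tag.sequence in merged:
                for lib, n in tag.counts.items():
                    merged[tag.sequence].counts[lib] = (
                        merged[tag.sequence].counts.get(lib, 0) + n
                    )
            else:
                merged[tag.sequence] = SequenceTag(tag.sequence, dict(tag.counts))
    return sorted(merged.values(), key=lambda t: (-t.total_count, t.sequence))


# length -> (redundant read count, unique tag count)
LengthProfile = dict[int, tuple[int, int]]


def length_profile(tags: Iterable[SequenceTag]) -> LengthProfile:
    """Length distribution: length -> (redundant count, unique count).

    Redundant sums raw reads over all libraries; unique counts distinct tag
    sequences. This is the per-library length-histogram stage of read QC.
    """
    redundant: Counter[int] = Counter()
    unique: Counter[int] = Counter()
    for tag in tags:
        redundant[len(tag)] += tag.total_count
        unique[len(tag)] += 1
    return {n: (redundant[n], unique[n]) for n in sorted(unique)}
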