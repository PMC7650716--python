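"""Raw-read cleaning: 3' adapter trimming, quality and length filters, and
collapsing of clean reads into unique tags with per-library counts.

The tag — a unique clean-read sequence with its count in each library —
is the atomic unit of all downstream quantification.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .sequence_io import ReadRecord

MIN_TAG_LEN = 18
MAX_TAG_LEN = 35

#: Minimum adapter-prefix overlap considered a match.
MIN_ADAPTER_OVERLAP = 7
#: Overlaps at or above this length tolerate one mismatch; shorter ones none.
MISMATCH_OVERLAP = 10

DEFAULT_MIN_MEAN_Q = 20.0


@dataclass(frozen=True)
class Tag:
    """A unique clean-read sequence with per-library counts."""

    sequence: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN:
            raise ValueError(
                f"tag length {len(self.sequence)} outside [{MIN_TAG_LEN}, {MAX_TAG_LEN}]"
            )
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("tag has no nonzero count")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class PreprocessStats:
    """Per-library read-accounting ledger; ``raw`` always equals
    ``clean`` plus the three discard buckets."""

    library: str
    raw: int = 0
    clean: int = 0
    discarded_adapter: int = 0
    discarded_quality: int = 0
    discarded_length: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.raw != (
            self.clean + self.discarded_adapter + self.discarded_quality + self.discarded_length
        ):
            raise AssertionError(f"{self.library}: read ledger does not balance")
        if sum(self.length_histogram.values()) != self.clean:
            raise AssertionError(f"{self.library}: length histogram does not total clean")


def trim_adapter(sequence: str, adapter3: str) -> tuple[str, bool]:
    """Trim the 3' adapter, returning ``(insert, found)``.

    The leftmost occurrence of an adapter prefix with overlap >= 7 nt is
    located; overlaps of 7-9 nt must match exactly, overlaps >= 10 nt
    tolerate one mismatch. Without a match the read is returned unchanged
    with ``found=False`` (it may be a full-length insert).
    """
    if len(adapter3) < MIN_ADAPTER_OVERLAP:
        raise ValueError(f"adapter shorter than {MIN_ADAPTER_OVERLAP} nt")
    n = len(sequence)
    for i in range(0, n - MIN_ADAPTER_OVERLAP + 1):
        overlap = min(len(adapter3), n - i)
        allowed = 1 if overlap >= MISMATCH_OVERLAP else 0
        mismatches = 0
        for a, b in zip(sequence[i : i + overlap], adapter3[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return sequence[:i], True
    return sequence, False


def quality_pass(
    quality: Iterable[int], insert_len: int, min_mean_q: float = DEFAULT_MIN_MEAN_Q
) -> bool:
    """True iff the mean PHRED score over the trimmed insert meets the
    threshold (inclusive). An empty insert fails."""
    if insert_len == 0:
        return False
    scores = list(quality)[:insert_len]
    return sum(scores) / len(scores) >= min_mean_q


def length_filter(sequence: str, min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> bool:
    return min_len <= len(sequence) <= max_len


def preprocess_library(
    records: Iterable[ReadRecord],
    library: str,
    adapter3: str,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    require_adapter: bool = False,
) -> tuple[dict[str, int], PreprocessStats]:
    """Clean one library and collapse to unique-sequence counts.

    Each raw read lands in exactly one bucket: discarded for a missing
    adapter (strict mode only), for low mean quality of its insert, for an
    out-of-range insert length, or counted as clean. Clean inserts are
    collapsed into a {sequence: count} table.
    """
    stats = PreprocessStats(library=library)
    counts: Counter[str] = Counter()
    for rec in records:
        stats.raw += 1
        insert, found = trim_adapter(rec.sequence, adapter3)
        if require_adapter and not found:
            stats.discarded_adapter += 1
            continue
        if not quality_pass(rec.quality, len(insert), min_mean_q):
            stats.discarded_quality += 1
            continue
        if not length_filter(insert, min_len, max_len):
            stats.discarded_length += 1
            continue
        stats.clean += 1
        stats.length_histogram[len(insert)] = stats.length_histogram.get(len(insert), 0) + 1
        counts[insert] += 1
    stats.check()
    return dict(counts), stats


def merge_tag_counts(per_library: Mapping[str, Mapping[str, int]]) -> list[Tag]:
    """Merge per-library {sequence: count} tables into a list of tags.

    Every library label appears in every tag's count map (zero-filled), so
    downstream matrices are rectangular. Tags are ordered by decreasing
    total count, then sequence.
    """
    libraries = list(per_library)
    by_seq: dict[str, dict[str, int]] = defaultdict(lambda: {lib: 0 for lib in libraries})
    for lib, counts in per_library.items():
        for seq, n in counts.items():
            by_seq[seq][lib] = n
    tags = [Tag(sequence=seq, counts=c) for seq, c in by_seq.items()]
    tags.sort(key=lambda t: (-t.total(), t.sequence))
    return tags
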