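"""Tag annotation: exact genome mapping, ncRNA category assignment,
mismatch- and offset-tolerant matching against a mature-miRNA catalog,
per-library category summaries, and organelle read-pileup hotspots.

Matching against the catalog is an exhaustive ungapped scan of every
placement of the tag on each mature sequence with 5'/3' end offsets in
[-2, +2] — feasible because catalogs are small — so no seed-and-extend
heuristics are involved and results are exactly reproducible.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .preprocess import PreprocessStats, Tag
from .sequence_io import AnnotationInterval, CatalogEntry, reverse_complement

#: Classification precedence: a tag is assigned to the first matching
#: category. miRNA leads; the organelles and structural RNAs follow;
#: repeats trail so that e.g. a tRNA-overlapping repeat is called tRNA.
CATEGORY_PRECEDENCE = (
    "miRNA",
    "mt",
    "cp",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "lncRNA",
    "mRNA",
    "repeats",
)

UNCLASSIFIED = "unclassified"

MAX_END_OFFSET = 2


@dataclass(frozen=True)
class GenomeHit:
    """An exact occurrence of a tag on a reference contig (0-based
    half-open; minus-strand hits match the reverse complement)."""

    contig: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class MiRNAHit:
    """Assignment of a tag to a mature miRNA.

    ``off5`` is the tag 5' start relative to the mature 5' end (positive =
    tag starts downstream); ``off3`` the tag 3' end relative to the mature
    3' end (positive = tag extends past it). Both are bounded by 2, the
    positional-variant rule.
    """

    tag_seq: str
    mirna_name: str
    family: str
    mismatches: int
    off5: int
    off3: int

    def __post_init__(self) -> None:
        if abs(self.off5) > MAX_END_OFFSET or abs(self.off3) > MAX_END_OFFSET:
            raise ValueError("end offsets exceed the positional-variant bound")


@dataclass(frozen=True)
class OrganelleHotspot:
    """A merged interval of overlapping organelle-mapped tags."""

    contig: str
    start: int
    end: int
    total_tpm: float
    n_tags: int

    @property
    def span_nt(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Exact mapping


class ReferenceIndex:
    """Exact substring search over a set of contigs, both strands."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = dict(contigs)

    @property
    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def find_all(self, seq: str) -> list[GenomeHit]:
        hits: list[GenomeHit] = []
        rc = reverse_complement(seq)
        for name, contig in self._contigs.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = contig.find(query)
                while start != -1:
                    hits.append(GenomeHit(name, start, start + len(query), strand))
                    start = contig.find(query, start + 1)
        return hits


def map_perfect(tag_seq: str, reference: ReferenceIndex) -> list[GenomeHit]:
    """All exact occurrences of the tag on both strands of the reference."""
    return reference.find_all(tag_seq)


# ---------------------------------------------------------------------------
# Category classification


class AnnotationIndex:
    """Per-contig interval trees over category annotations."""

    def __init__(self, intervals: Iterable[AnnotationInterval]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for iv in intervals:
            self._trees[iv.contig].addi(iv.start, iv.end, iv)

    def categories_overlapping(self, hit: GenomeHit, min_overlap: int) -> set[str]:
        tree = self._trees.get(hit.contig)
        if tree is None:
            return set()
        found: set[str] = set()
        for node in tree.overlap(hit.start, hit.end):
            overlap = min(hit.end, node.end) - max(hit.start, node.begin)
            if overlap >= min_overlap:
                found.add(node.data.category)
        return found


def classify_tag(
    tag_seq: str,
    genome_hits: Sequence[GenomeHit],
    annotations: AnnotationIndex,
    mirna_hit: MiRNAHit | None = None,
) -> str:
    """Assign the tag to one ncRNA category by fixed precedence.

    A catalog match wins outright. Otherwise a category applies when any
    genome hit overlaps one of its intervals by at least half the tag
    length; the first category in precedence order wins; tags matching
    nothing are ``unclassified``.
    """
    if mirna_hit is not None:
        return "miRNA"
    # ceil(len/2): an overlap of exactly half the tag length qualifies
    min_overlap = (len(tag_seq) + 1) // 2
    found: set[str] = set()
    for hit in genome_hits:
        found |= annotations.categories_overlapping(hit, min_overlap)
    for category in CATEGORY_PRECEDENCE:
        if category in found:
            return category
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# Catalog matching


def _score_placement(
    tag_seq: str, entry: CatalogEntry, off5: int
) -> tuple[int, int, int] | None:
    """Mismatch count of one ungapped placement, or None when out of bounds.

    Returns (mismatches, off5, off3). Overhang bases beyond the mature are
    validated against the precursor context when available; every
    unvalidatable overhang base counts as a mismatch.
    """
    mature = entry.mature_seq
    lt, lm = len(tag_seq), len(mature)
    off3 = off5 + lt - lm
    if abs(off3) > MAX_END_OFFSET:
        return None
    overlap = min(lm, off5 + lt) - max(0, off5)
    if overlap < lm - MAX_END_OFFSET:
        return None
    precursor = entry.precursor_seq
    anchor = precursor.find(mature) if precursor is not None else -1
    mismatches = 0
    for j, base in enumerate(tag_seq):
        p = off5 + j  # position in mature coordinates
        if 0 <= p < lm:
            if base != mature[p]:
                mismatches += 1
        else:
            # overhang: check against the precursor flank when possible
            if anchor >= 0 and 0 <= anchor + p < len(precursor):
                if base != precursor[anchor + p]:
                    mismatches += 1
            else:
                mismatches += 1
    return mismatches, off5, off3


def match_mirna(
    tag_seq: str, catalog: Sequence[CatalogEntry], max_mm: int = 2
) -> MiRNAHit | None:
    """Best catalog assignment of a tag, or None.

    Every ungapped placement of the tag against every mature with end
    offsets in [-2, +2] is scored; internal mismatches by Hamming distance
    over the overlap, overhangs validated against the precursor. The hit
    minimizing (mismatches, |off5| + |off3|, name) is returned when its
    mismatch count is within ``max_mm``.
    """
    if max_mm not in (0, 2):
        raise ValueError("max_mm must be 0 or 2")
    best: tuple[int, int, str, int, int, CatalogEntry] | None = None
    for entry in catalog:
        for off5 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
            scored = _score_placement(tag_seq, entry, off5)
            if scored is None:
                continue
            mm, o5, o3 = scored
            if mm > max_mm:
                continue
            key = (mm, abs(o5) + abs(o3), entry.name, o5, o3, entry)
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None:
        return None
    mm, _, _, off5, off3, entry = best
    return MiRNAHit(
        tag_seq=tag_seq,
        mirna_name=entry.name,
        family=entry.family,
        mismatches=mm,
        off5=off5,
        off3=off3,
    )


def match_all(
    tags: Sequence[Tag], catalog: Sequence[CatalogEntry], max_mm: int = 2
) -> dict[str, MiRNAHit]:
    """Catalog assignments for a list of tags, keyed by tag sequence."""
    hits: dict[str, MiRNAHit] = {}
    for tag in tags:
        hit = match_mirna(tag.sequence, catalog, max_mm)
        if hit is not None:
            hits[tag.sequence] = hit
    return hits


# ---------------------------------------------------------------------------
# Library summary


#: Column order of the per-library category summary.
SUMMARY_CATEGORIES = (
    "genome-mapped",
    "mt",
    "cp",
    "mRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "lncRNA",
    "repeats",
    "miRNA",
    "other-miRNA",
)


def summarize_library(
    tags: Sequence[Tag],
    library: str,
    classifications: Mapping[str, str],
    mirna_hits: Mapping[str, MiRNAHit],
    genome_mapped: Mapping[str, bool],
    stats: PreprocessStats,
    host_prefix: str = "zma",
) -> dict[str, object]:
    """Read counts and percentages of clean reads per ncRNA category.

    Catalog-matched reads are split between host-species miRNAs (name
    prefix ``host_prefix``) and miRNAs annotated in other plants.
    Percentages are 100 x reads / clean, rounded to 2 decimals.
    """
    if stats.clean == 0:
        raise ValueError(f"{library}: no clean reads; percentages undefined")
    counts = {cat: 0 for cat in SUMMARY_CATEGORIES}
    for tag in tags:
        n = tag.counts.get(library, 0)
        if n == 0:
            continue
        if genome_mapped.get(tag.sequence, False):
            counts["genome-mapped"] += n
        hit = mirna_hits.get(tag.sequence)
        if hit is not None:
            prefix = hit.mirna_name.split("-", 1)[0].lower()
            key = "miRNA" if prefix == host_prefix.lower() else "other-miRNA"
            counts[key] += n
        else:
            cat = classifications.get(tag.sequence, UNCLASSIFIED)
            if cat in counts:
                counts[cat] += n
    row: dict[str, object] = {"library": library, "raw": stats.raw, "clean": stats.clean}
    for cat in SUMMARY_CATEGORIES:
        row[cat] = counts[cat]
        row[f"{cat}_pct"] = category_percentage(counts[cat], stats.clean)
    return row


def category_percentage(reads: int, clean: int) -> float:
    """Percentage of clean reads, rounded to 2 decimals."""
    if clean <= 0:
        raise ValueError("clean read total must be positive")
    return round(100.0 * reads / clean, 2)


# ---------------------------------------------------------------------------
# Organelle hotspots


def organelle_hotspots(
    tag_tpm: Mapping[str, float],
    organelle_index: ReferenceIndex,
    min_total_tpm: float = 0.0,
) -> list[OrganelleHotspot]:
    """Merged read-pileup regions on organelle contigs.

    Tags are exact-mapped to the organelle contigs; overlapping hit
    intervals (either strand) are merged into maximal regions; regions with
    summed tag TPM >= ``min_total_tpm`` are returned sorted by total TPM
    descending.
    """
    by_contig: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for seq, tpm_value in tag_tpm.items():
        for hit in organelle_index.find_all(seq):
            by_contig[hit.contig].append((hit.start, hit.end, seq))
    hotspots: list[OrganelleHotspot] = []
    for contig, spans in by_contig.items():
        spans.sort()
        cur_start, cur_end = spans[0][0], spans[0][1]
        cur_tags: set[str] = {spans[0][2]}
        for start, end, seq in spans[1:]:
            if start < cur_end:  # overlap (half-open intervals)
                cur_end = max(cur_end, end)
                cur_tags.add(seq)
            else:
                hotspots.append(_make_hotspot(contig, cur_start, cur_end, cur_tags, tag_tpm))
                cur_start, cur_end, cur_tags = start, end, {seq}
        hotspots.append(_make_hotspot(contig, cur_start, cur_end, cur_tags, tag_tpm))
    hotspots = [h for h in hotspots if h.total_tpm >= min_total_tpm]
    hotspots.sort(key=lambda h: (-h.total_tpm, h.contig, h.start))
    return hotspots


def _make_hotspot(
    contig: str, start: int, end: int, tags: set[str], tag_tpm: Mapping[str, float]
) -> OrganelleHotspot:
    return OrganelleHotspot(
        contig=contig,
        start=start,
        end=end,
        total_tpm=sum(tag_tpm[t] for t in tags),
        n_tags=len(tags),
    )
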