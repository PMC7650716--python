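"""Collapsing catalog-matched tags into representative miRNA groups.

A representative group is a mature miRNA together with (i) its positional
variants — tags whose 5'/3' ends differ from the mature by at most 2 nt —
and (ii) other mature anchors of the same family whose sequences are
themselves within that end-offset rule of each other (identical paralogs
such as miR167c/d/e/g collapse into one group named miR167cdeg). Group
counts are the sums of member-tag counts per library, and group fold
changes are recomputed from those summed counts — never averaged over
member-level fold changes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import quantify
from .annotation import MAX_END_OFFSET, MiRNAHit, _score_placement
from .preprocess import Tag
from .sequence_io import CatalogEntry, parse_mirna_name


@dataclass
class RepresentativeGroup:
    """A mature anchor set plus its positional-variant tags."""

    group_name: str
    family: str
    anchors: tuple[str, ...]  # catalog names merged into this group
    members: list[tuple[str, MiRNAHit]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


def anchors_compatible(a: CatalogEntry, b: CatalogEntry) -> bool:
    """True when two matures of one family fall under the end-offset rule:
    some ungapped placement with both end offsets in [-2, +2] and zero
    mismatches over the overlap."""
    if a.family != b.family:
        return False
    # Either orientation suffices: the shorter mature's overhang-free
    # placement on the longer one carries the zero-mismatch evidence.
    for query, target in ((a.mature_seq, b), (b.mature_seq, a)):
        for off5 in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
            scored = _score_placement(query, target, off5)
            if scored is not None and scored[0] == 0:
                return True
    return False


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self._parent[x] != x:
            self._parent[x] = self._parent[self._parent[x]]
            x = self._parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[max(ra, rb)] = min(ra, rb)


def merge_anchors(catalog: Sequence[CatalogEntry]) -> dict[str, tuple[str, ...]]:
    """Partition catalog names into merged anchor sets (transitive closure
    of the pairwise compatibility relation within each family)."""
    by_family: dict[str, list[CatalogEntry]] = defaultdict(list)
    for entry in catalog:
        by_family[entry.family].append(entry)
    mapping: dict[str, tuple[str, ...]] = {}
    for entries in by_family.values():
        uf = _UnionFind([e.name for e in entries])
        for i, a in enumerate(entries):
            for b in entries[i + 1 :]:
                if anchors_compatible(a, b):
                    uf.union(a.name, b.name)
        clusters: dict[str, list[str]] = defaultdict(list)
        for e in entries:
            clusters[uf.find(e.name)].append(e.name)
        for names in clusters.values():
            key = tuple(sorted(names))
            for name in names:
                mapping[name] = key
    return mapping


def name_group(member_names: Sequence[str]) -> str:
    """Concatenated group name: family + sorted variant letters.

    {zma-miR398a, zma-miR398b} -> miR398ab; a singleton keeps its own
    suffix (zma-miR408 -> miR408, zma-miR408b -> miR408b).
    """
    parsed = [parse_mirna_name(n) for n in member_names]
    families = {fam for fam, _ in parsed}
    if len(families) != 1:
        raise ValueError(f"group members span families {sorted(families)}")
    family = families.pop()
    suffixes = sorted({suf for _, suf in parsed})
    return family + "".join(suffixes)


def group_variants(
    tags: Sequence[Tag],
    hits: Mapping[str, MiRNAHit],
    catalog: Sequence[CatalogEntry],
) -> list[RepresentativeGroup]:
    """Build representative groups from catalog-matched tags.

    Each tag joins the (possibly merged) anchor set of its best hit; group
    counts are member-count sums per library. Groups are returned sorted by
    name. Tags without a hit are simply absent — they remain ungrouped.
    """
    anchor_sets = merge_anchors(catalog)
    by_anchor: dict[tuple[str, ...], RepresentativeGroup] = {}
    tag_by_seq = {t.sequence: t for t in tags}
    for seq, hit in hits.items():
        key = anchor_sets[hit.mirna_name]
        group = by_anchor.get(key)
        if group is None:
            group = RepresentativeGroup(
                group_name=name_group(key),
                family=hit.family,
                anchors=key,
            )
            by_anchor[key] = group
        group.members.append((seq, hit))
        for lib, n in tag_by_seq[seq].counts.items():
            group.counts[lib] = group.counts.get(lib, 0) + n
    groups = list(by_anchor.values())
    for g in groups:
        g.members.sort(key=lambda m: m[0])
    groups.sort(key=lambda g: g.group_name)
    return groups


def anchor_sequence(group: RepresentativeGroup, tags: Mapping[str, Tag]) -> str:
    """The group's reported sequence: its most abundant member summed over
    libraries; ties broken lexicographically."""
    return min(
        (seq for seq, _ in group.members),
        key=lambda s: (-tags[s].total(), s),
    )


def group_count_matrix(
    groups: Sequence[RepresentativeGroup], libraries: Sequence[str]
) -> pd.DataFrame:
    """Rows-by-libraries raw-count matrix of group sums."""
    return pd.DataFrame(
        {lib: [g.counts.get(lib, 0) for g in groups] for lib in libraries},
        index=[g.group_name for g in groups],
    )


def group_fc(
    group: RepresentativeGroup,
    clean_totals: Mapping[str, int],
    pairs: Sequence[tuple[str, str, str]],
    pseudo: float = quantify.DEFAULT_PSEUDO_TPM,
) -> dict[str, float]:
    """Per-pair fold change recomputed from the group's summed counts."""
    out: dict[str, float] = {}
    for label, treat, ctrl in pairs:
        out[label] = quantify.log2_fc(
            quantify.tpm(group.counts.get(treat, 0), clean_totals[treat]),
            quantify.tpm(group.counts.get(ctrl, 0), clean_totals[ctrl]),
            pseudo,
        )
    return out
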