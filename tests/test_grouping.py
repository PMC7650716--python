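import numpy as np
import pytest

from srnaprofiler import grouping as gr
from srnaprofiler import quantify
from srnaprofiler.annotation import MiRNAHit, match_all
from srnaprofiler.preprocess import Tag
from srnaprofiler.sequence_io import CatalogEntry


class TestNameGroup:
    @pytest.mark.parametrize(
        "members,expected",
        [
            (["zma-miR398a", "zma-miR398b"], "miR398ab"),
            (["zma-miR408"], "miR408"),
            (["zma-miR169c", "zma-miR169r"], "miR169cr"),
            (["zma-miR167c", "zma-miR167d", "zma-miR167e", "zma-miR167g"], "miR167cdeg"),
        ],
    )
    def test_concatenated_names(self, members, expected):
        assert gr.name_group(members) == expected

    def test_cross_family_rejected(self):
        with pytest.raises(ValueError):
            gr.name_group(["zma-miR398a", "zma-miR408"])


def _mk_tag(seq, counts):
    return Tag(seq, counts)


class TestGroupVariants:
    def test_positional_variants_join_their_mature(self, toy_catalog):
        mature = toy_catalog[3].mature_seq  # zma-miR902a
        tags = [
            _mk_tag(mature, {"c": 10, "t": 5}),
            _mk_tag(mature[:-1], {"c": 4, "t": 0}),  # 3' -1 variant
            _mk_tag(mature[1:], {"c": 0, "t": 2}),  # 5' +1 variant
        ]
        hits = match_all(tags, toy_catalog, 2)
        groups = gr.group_variants(tags, hits, toy_catalog)
        g902 = next(g for g in groups if g.family == "miR902")
        assert len(g902.members) == 3
        assert g902.counts == {"c": 14, "t": 7}

    def test_three_nt_short_tag_stays_ungrouped(self, toy_catalog):
        mature = toy_catalog[3].mature_seq
        tags = [_mk_tag(mature[:-3], {"c": 5})]
        hits = match_all(tags, toy_catalog, 2)
        assert mature[:-3] not in hits
        assert gr.group_variants(tags, hits, toy_catalog) == []

    def test_identical_matures_merge_with_concatenated_name(self, toy_catalog):
        mature = toy_catalog[0].mature_seq  # shared by miR901a and miR901b
        tags = [_mk_tag(mature, {"c": 8})]
        hits = match_all(tags, toy_catalog, 2)
        groups = gr.group_variants(tags, hits, toy_catalog)
        (g,) = [g for g in groups if g.family == "miR901"]
        assert g.group_name == "miR901ab"
        assert g.anchors == ("zma-miR901a", "zma-miR901b")

    def test_count_conservation_and_idempotence(self, toy_catalog):
        rng = np.random.default_rng(5)
        mature = toy_catalog[3].mature_seq
        tags = []
        for i, var in enumerate([mature, mature[:-2], mature[2:], mature[1:]]):
            tags.append(_mk_tag(var, {"c": int(rng.integers(1, 50)), "t": int(rng.integers(1, 50))}))
        hits = match_all(tags, toy_catalog, 2)
        groups = gr.group_variants(tags, hits, toy_catalog)
        total_in = sum(t.total() for t in tags if t.sequence in hits)
        assert sum(g.total() for g in groups) == total_in
        again = gr.group_variants(tags, hits, toy_catalog)
        assert [(g.group_name, g.counts) for g in again] == [
            (g.group_name, g.counts) for g in groups
        ]


# ---------------------------------------------------------------------------
# Union-find oracle: transitive closure of the pairwise end-offset relation
# computed by plain BFS over an independently-coded compatibility check.


def oracle_partition(entries):
    def compatible(x, y):
        if x.family != y.family:
            return False
        for a, b in ((x, y), (y, x)):
            sa, sb = a.mature_seq, b.mature_seq
            pre = b.precursor_seq
            anchor = pre.find(sb) if pre else None
            for off5 in range(-2, 3):
                off3 = off5 + len(sa) - len(sb)
                if abs(off3) > 2:
                    continue
                if min(len(sb), off5 + len(sa)) - max(0, off5) < len(sb) - 2:
                    continue
                ok = True
                for j, base in enumerate(sa):
                    p = off5 + j
                    if 0 <= p < len(sb):
                        ok = base == sb[p]
                    elif anchor is not None and 0 <= anchor + p < len(pre):
                        ok = base == pre[anchor + p]
                    else:
                        ok = False
                    if not ok:
                        break
                if ok:
                    return True
        return False

    clusters = []
    unassigned = list(entries)
    while unassigned:
        seed = unassigned.pop()
        cluster = {seed.name}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            rest = []
            for other in unassigned:
                if compatible(cur, other):
                    cluster.add(other.name)
                    frontier.append(other)
                else:
                    rest.append(other)
            unassigned = rest
        clusters.append(frozenset(cluster))
    return set(clusters)


def random_family(rng, family_id, n_members):
    base = "".join(rng.choice(list("ACGT"), size=21))
    entries = []
    for k in range(n_members):
        kind = rng.random()
        if kind < 0.4:  # identical or end-shifted copy of the base
            off5, off3 = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
            seq = base[max(0, off5) : 21 + min(0, off3)]
            if len(seq) < 18:
                seq = base
        elif kind < 0.7:  # internally mutated: not mergeable
            seq = list(base)
            seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
            seq = "".join(seq)
        else:  # unrelated sequence, same family label
            seq = "".join(rng.choice(list("ACGT"), size=21))
        entries.append(
            CatalogEntry(f"zma-miR{family_id}{'abcdefghij'[k]}", f"miR{family_id}", seq, None)
        )
    return entries


def test_merge_anchors_equals_transitive_closure_oracle():
    """200 random variant clusters partition identically to a BFS
    transitive-closure oracle over the pairwise offset relation."""
    rng = np.random.default_rng(99)
    for case in range(200):
        entries = []
        for fam in range(int(rng.integers(1, 4))):
            entries.extend(random_family(rng, 500 + fam, int(rng.integers(1, 5))))
        got = {frozenset(v) for v in gr.merge_anchors(entries).values()}
        assert got == oracle_partition(entries), f"case {case}"


def test_group_fc_matches_pooled_count_fc(toy_catalog):
    group = gr.RepresentativeGroup(
        group_name="miR902a",
        family="miR902",
        anchors=("zma-miR902a",),
        counts={"treat": 60, "ctrl": 30},
    )
    totals = {"treat": 10_000, "ctrl": 10_000}
    fc = gr.group_fc(group, totals, [("p", "treat", "ctrl")], pseudo=1e-9)["p"]
    assert fc == pytest.approx(1.0, abs=1e-6)
    direct = quantify.log2_fc(
        quantify.tpm(60, 10_000), quantify.tpm(30, 10_000), 1e-9
    )
    assert fc == direct


def test_group_fc_equal_counts_zero(toy_catalog):
    group = gr.RepresentativeGroup("miR902a", "miR902", ("zma-miR902a",), counts={"a": 25, "b": 25})
    assert gr.group_fc(group, {"a": 5000, "b": 5000}, [("p", "a", "b")])["p"] == 0.0
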