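import numpy as np
import pytest

from srnaprofiler import annotation as ann
from srnaprofiler.preprocess import PreprocessStats, Tag
from srnaprofiler.sequence_io import AnnotationInterval, CatalogEntry, reverse_complement

# ---------------------------------------------------------------------------
# Independent oracle for catalog matching: enumerate every placement and
# score it from first principles, without touching the implementation's
# scoring helper.


def oracle_match(tag, catalog, max_mm):
    candidates = []
    for entry in catalog:
        mature = entry.mature_seq
        for off5 in range(-2, 3):
            off3 = off5 + len(tag) - len(mature)
            if abs(off3) > 2:
                continue
            overlap = min(len(mature), off5 + len(tag)) - max(0, off5)
            if overlap < len(mature) - 2:
                continue
            anchor = entry.precursor_seq.find(mature) if entry.precursor_seq else None
            mm = 0
            for j in range(len(tag)):
                p = off5 + j
                if 0 <= p < len(mature):
                    mm += tag[j] != mature[p]
                elif anchor is not None and 0 <= anchor + p < len(entry.precursor_seq):
                    mm += tag[j] != entry.precursor_seq[anchor + p]
                else:
                    mm += 1
            if mm <= max_mm:
                candidates.append((mm, abs(off5) + abs(off3), entry.name, off5, off3))
    return min(candidates) if candidates else None


def random_case(rng):
    """A random catalog plus a tag that may or may not derive from it."""
    catalog = []
    for k in range(rng.integers(1, 4)):
        mature = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 25))))
        precursor = None
        if rng.random() < 0.7:
            flank = lambda: "".join(rng.choice(list("ACGT"), size=6))
            precursor = flank() + mature + flank()
        catalog.append(CatalogEntry(f"zma-miR{900 + k}a", f"miR{900 + k}", mature, precursor))
    source = catalog[int(rng.integers(len(catalog)))]
    if rng.random() < 0.3:
        tag = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 27))))
    else:
        mature = source.mature_seq
        off5, off3 = int(rng.integers(-2, 3)), int(rng.integers(-2, 3))
        if source.precursor_seq:
            a = source.precursor_seq.find(mature)
            tag = source.precursor_seq[max(0, a + off5) : a + len(mature) + off3]
        else:
            tag = mature[max(0, off5) : len(mature) + min(0, off3)]
        tag = list(tag)
        for _ in range(int(rng.integers(0, 4))):  # up to 3 substitutions
            pos = int(rng.integers(len(tag)))
            tag[pos] = rng.choice(list("ACGT"))
        tag = "".join(tag)
    return tag, catalog


@pytest.mark.parametrize("max_mm", [0, 2])
def test_match_mirna_equals_exhaustive_oracle(max_mm):
    """200 randomized tag/catalog cases agree with the brute-force
    placement scorer, at both mismatch policies."""
    rng = np.random.default_rng(2024 + max_mm)
    checked = 0
    for _ in range(200):
        tag, catalog = random_case(rng)
        if not 18 <= len(tag) <= 35:
            continue
        expected = oracle_match(tag, catalog, max_mm)
        got = ann.match_mirna(tag, catalog, max_mm)
        if expected is None:
            assert got is None
        else:
            assert got is not None
            assert (got.mismatches, got.mirna_name, got.off5, got.off3) == (
                expected[0],
                expected[2],
                expected[3],
                expected[4],
            )
        checked += 1
    assert checked >= 200 * 0.9


class TestMatchExamples:
    def test_identity(self, toy_catalog):
        hit = ann.match_mirna(toy_catalog[0].mature_seq, toy_catalog, 0)
        assert (hit.mirna_name, hit.mismatches, hit.off5, hit.off3) == ("zma-miR901a", 0, 0, 0)

    def test_three_substitutions_rejected(self, toy_catalog):
        mature = toy_catalog[3].mature_seq
        tag = "AAA" + mature[3:]
        assert mature[:3] != "AAA"
        assert ann.match_mirna(tag, toy_catalog, 2) is None

    def test_three_prime_truncation_is_offset_not_mismatch(self, toy_catalog):
        tag = toy_catalog[3].mature_seq[:-2]
        hit = ann.match_mirna(tag, toy_catalog, 2)
        assert (hit.mirna_name, hit.mismatches, hit.off5, hit.off3) == ("zma-miR902a", 0, 0, -2)

    def test_overhang_validated_by_precursor(self, toy_catalog):
        entry = toy_catalog[3]
        anchor = entry.precursor_seq.find(entry.mature_seq)
        extended = entry.precursor_seq[anchor - 1 : anchor + len(entry.mature_seq) + 1]
        hit = ann.match_mirna(extended, toy_catalog, 0)
        assert (hit.mismatches, hit.off5, hit.off3) == (0, -1, 1)

    def test_unvalidatable_overhang_counts_as_mismatch(self, toy_catalog):
        entry = toy_catalog[2]  # no precursor
        tag = "T" + entry.mature_seq
        hit = ann.match_mirna(tag, toy_catalog, 2)
        assert hit.mirna_name == "zma-miR901c"
        assert hit.mismatches == 1
        assert ann.match_mirna(tag, toy_catalog, 0) is None


class TestMapPerfect:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.genome = "".join(rng.choice(list("ACGT"), size=500))
        self.index = ann.ReferenceIndex({"chr1": self.genome})

    def test_planted_fragment_found(self):
        frag = self.genome[100:124]
        hits = ann.map_perfect(frag, self.index)
        assert ann.GenomeHit("chr1", 100, 124, "+") in hits

    def test_absent_sequence_empty(self):
        assert ann.map_perfect("ACGT" * 8, self.index) == []

    def test_reverse_complement_minus_strand(self):
        frag = reverse_complement(self.genome[200:224])
        hits = ann.map_perfect(frag, self.index)
        assert ann.GenomeHit("chr1", 200, 224, "-") in hits


class TestClassify:
    def _index(self):
        return ann.AnnotationIndex(
            [
                AnnotationInterval("chr1", 100, 200, "+", "tRNA", "t"),
                AnnotationInterval("chr1", 150, 180, "+", "repeats", "r"),
            ]
        )

    def test_precedence_tRNA_over_repeats(self):
        hit = [ann.GenomeHit("chr1", 160, 184, "+")]
        assert ann.classify_tag("A" * 24, hit, self._index()) == "tRNA"

    def test_no_hits_unclassified(self):
        assert ann.classify_tag("A" * 24, [], self._index()) == "unclassified"

    def test_catalog_match_beats_intervals(self):
        hit = [ann.GenomeHit("chr1", 160, 184, "+")]
        mirna_hit = ann.MiRNAHit("A" * 24, "zma-miR1a", "miR1", 0, 0, 0)
        assert ann.classify_tag("A" * 24, hit, self._index(), mirna_hit) == "miRNA"

    def test_half_overlap_required(self):
        # 24 nt tag overlapping the tRNA interval by only 10 nt: too little
        hit = [ann.GenomeHit("chr1", 190, 214, "+")]
        assert ann.classify_tag("A" * 24, hit, self._index()) == "unclassified"
        # 13 nt overlap (>= half the tag) qualifies
        hit = [ann.GenomeHit("chr1", 187, 211, "+")]
        assert ann.classify_tag("A" * 24, hit, self._index()) == "tRNA"


class TestSummarize:
    def test_percentages_from_printed_style_counts(self):
        stats = PreprocessStats(library="lib", raw=120, clean=100)
        stats.length_histogram = {24: 100}
        tags = [
            Tag("A" * 24, {"lib": 40}),
            Tag("C" * 24, {"lib": 50}),
            Tag("G" * 24, {"lib": 10}),
        ]
        hits = {"A" * 24: ann.MiRNAHit("A" * 24, "zma-miR1a", "miR1", 0, 0, 0),
                "G" * 24: ann.MiRNAHit("G" * 24, "osa-miR2a", "miR2", 0, 0, 0)}
        row = ann.summarize_library(
            tags, "lib", {"C" * 24: "rRNA"}, hits,
            {"A" * 24: True, "C" * 24: True, "G" * 24: False}, stats,
        )
        assert row["miRNA"] == 40 and row["miRNA_pct"] == 40.0
        assert row["other-miRNA"] == 10 and row["other-miRNA_pct"] == 10.0
        assert row["rRNA_pct"] == 50.0
        assert row["genome-mapped"] == 90

    def test_zero_clean_errors(self):
        stats = PreprocessStats(library="lib", raw=5, clean=0, discarded_length=5)
        with pytest.raises(ValueError, match="clean"):
            ann.summarize_library([], "lib", {}, {}, {}, stats)

    def test_zero_mirna_reads_zero_pct(self):
        stats = PreprocessStats(library="lib", raw=10, clean=10)
        row = ann.summarize_library([Tag("A" * 20, {"lib": 10})], "lib", {}, {}, {}, stats)
        assert row["miRNA_pct"] == 0.0


class TestHotspots:
    def _org(self):
        rng = np.random.default_rng(11)
        return "".join(rng.choice(list("ACGT"), size=300))

    def test_overlapping_tags_merge_to_53bp_span(self):
        org = self._org()
        index = ann.ReferenceIndex({"mt": org})
        tpm = {org[100:124]: 300.0, org[115:140]: 250.0, org[129:153]: 270.0}
        (hs,) = ann.organelle_hotspots(tpm, index, 100.0)
        assert (hs.contig, hs.start, hs.end, hs.span_nt, hs.n_tags) == ("mt", 100, 153, 53, 3)
        assert hs.total_tpm == pytest.approx(820.0)

    def test_disjoint_regions_stay_separate(self):
        org = self._org()
        index = ann.ReferenceIndex({"mt": org})
        tpm = {org[10:34]: 100.0, org[200:224]: 90.0}
        spots = ann.organelle_hotspots(tpm, index, 10.0)
        assert len(spots) == 2
        assert spots[0].total_tpm >= spots[1].total_tpm  # sorted descending

    def test_below_threshold_omitted(self):
        org = self._org()
        index = ann.ReferenceIndex({"mt": org})
        assert ann.organelle_hotspots({org[10:34]: 5.0}, index, 50.0) == []
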