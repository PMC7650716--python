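"""Synthetic small-RNA study generator with known ground truth.

Builds a toy reference — a nuclear genome with planted miRNA precursors
and background ncRNA intervals, plus mitochondrial and plastid contigs
with configurable read-pileup hotspots — and per-condition FASTQ
libraries. Reads are drawn multinomially: each miRNA's expected fraction
is its baseline fraction scaled by 2^(true log2 fold change), hotspots
contribute their configured TPM, and the background categories share the
remaining probability mass. Because the background absorbs the miRNA
weight shift, the TPM ratio between a treatment and the control library
is an unbiased estimator of the configured truth.

Every draw flows from one numpy Generator seeded from the config, so a
given seed reproduces libraries byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    AnnotationInterval,
    CatalogEntry,
    ReadRecord,
    mirna_family,
    reverse_complement,
    write_annotations,
    write_fasta,
    write_fastq,
)

_BASES = np.array(list("ACGT"))

#: Standard small-RNA 3' sequencing adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

#: Symmetric end-offset profile for isomiR generation: 60% of reads are the
#: exact mature sequence, the rest single- or double-nucleotide 5'/3'
#: positional variants. The real offset distribution of plant isomiRs is
#: not well characterized; this default is deliberately simple.
DEFAULT_ISOMIR_PROFILE: dict[tuple[int, int], float] = {
    (0, 0): 0.60,
    (-1, 0): 0.07,
    (1, 0): 0.07,
    (0, -1): 0.07,
    (0, 1): 0.07,
    (-2, 0): 0.03,
    (2, 0): 0.03,
    (0, -2): 0.03,
    (0, 2): 0.03,
}

#: Background composition loosely mirroring a plant shoot small-RNA
#: library: repeat-derived siRNAs dominate the annotated classes and most
#: reads fall in unannotated (intergenic) genome. The miRNA fraction is
#: carried separately on the config.
DEFAULT_BACKGROUND_FRACTIONS: dict[str, float] = {
    "repeats": 0.18,
    "rRNA": 0.025,
    "tRNA": 0.015,
    "snRNA": 0.03,
    "snoRNA": 0.008,
    "lncRNA": 0.018,
    "mRNA": 0.012,
    "mt": 0.005,
    "cp": 0.015,
    "intergenic": 0.662,
}

#: Insert-length weights for background reads, 18-35 nt with the mode at
#: 24 nt (the siRNA-dominated size profile of plant libraries).
BACKGROUND_LENGTH_WEIGHTS: dict[int, float] = {
    18: 2, 19: 3, 20: 4, 21: 6, 22: 8, 23: 12, 24: 30, 25: 12, 26: 8,
    27: 6, 28: 4, 29: 3, 30: 2, 31: 1.5, 32: 1.2, 33: 1.0, 34: 0.8, 35: 0.6,
}

#: Default organelle pileups: a 53 bp mitochondrial region and a 32 bp
#: plastid region, echoing NADH-dehydrogenase-subunit-2 and trnF-derived
#: small-RNA signatures, with abundances on the order of known hotspots.
DEFAULT_HOTSPOTS: tuple[tuple[str, int, int, float], ...] = (
    ("mt", 400, 53, 800.0),
    ("cp", 1200, 32, 500.0),
)

MATURE_LENGTH = 21
PRECURSOR_FLANK = 15


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``true_log2fc`` maps condition -> {miRNA name -> log2 fold change
    versus the control}; the first condition is the control and must have
    (implicit) fold change 0 everywhere. ``organelle_hotspots`` entries
    are (contig, start, length, abundance_tpm).
    """

    seed: int
    n_mirnas: int = 20
    depth: int = 100_000
    adapter3: str = DEFAULT_ADAPTER3
    conditions: tuple[str, ...] = ("control", "submergence", "drought")
    true_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    isomir_profile: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE)
    )
    mirna_fraction: float = 0.03
    background_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_FRACTIONS)
    )
    organelle_hotspots: tuple[tuple[str, int, int, float], ...] = DEFAULT_HOTSPOTS
    raw_read_length: int = 50

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("n_mirnas must be >= 1")
        if not math.isclose(sum(self.isomir_profile.values()), 1.0, abs_tol=1e-9):
            raise ValueError("isomiR profile probabilities must sum to 1")
        if max(self.isomir_profile, key=self.isomir_profile.get) != (0, 0):
            raise ValueError("the unshifted (0, 0) offset must carry the largest probability")
        for off5, off3 in self.isomir_profile:
            if abs(off5) > 2 or abs(off3) > 2:
                raise ValueError("isomiR offsets must lie in [-2, +2]")
            if MATURE_LENGTH - off5 + off3 < 18:
                raise ValueError("isomiR profile would generate inserts shorter than 18 nt")
        total = self.mirna_fraction + sum(self.background_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"miRNA + background fractions must sum to 1, got {total}")
        for cond in self.true_log2fc:
            if cond not in self.conditions:
                raise ValueError(f"true_log2fc names unknown condition {cond!r}")
        control = self.conditions[0]
        if any(self.true_log2fc.get(control, {}).values()):
            raise ValueError("control condition must have fold change 0 for all miRNAs")

    @property
    def control_condition(self) -> str:
        return self.conditions[0]

    def mirna_names(self) -> list[str]:
        return [f"zma-miR{101 + i}a" for i in range(self.n_mirnas)]


@dataclass
class Reference:
    """The synthetic reference bundle."""

    genome: dict[str, str]
    catalog: list[CatalogEntry]
    annotations: list[AnnotationInterval]
    organelles: dict[str, str]
    intergenic: list[tuple[str, int, int]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_fasta(self.organelles, outdir / "organelles.fa")
        write_fasta({e.name: e.mature_seq for e in self.catalog}, outdir / "mature.fa")
        write_fasta(
            {e.name: e.precursor_seq for e in self.catalog if e.precursor_seq},
            outdir / "hairpin.fa",
        )
        write_annotations(self.annotations, outdir / "annotations.bed")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference(config: SimulationConfig) -> Reference:
    """Deterministically build genome, catalog, annotations, and organelles.

    Each precursor is embedded once in the nuclear genome under a
    miRNA-category interval; every nuclear background category gets two
    disjoint intervals; spacers between features are recorded as
    intergenic source regions; organelle contigs carry whole-contig mt/cp
    intervals plus the configured hotspot source regions.
    """
    rng = np.random.default_rng([config.seed, 0])
    catalog: list[CatalogEntry] = []
    annotations: list[AnnotationInterval] = []
    intergenic: list[tuple[str, int, int]] = []

    pieces: list[str] = []
    pos = 0
    contig = "chr1"

    def spacer(length: int = 120) -> None:
        nonlocal pos
        seq = _random_seq(rng, length)
        pieces.append(seq)
        intergenic.append((contig, pos, pos + length))
        pos += length

    spacer()
    for name in config.mirna_names():
        mature = _random_seq(rng, MATURE_LENGTH)
        precursor = (
            _random_seq(rng, PRECURSOR_FLANK) + mature + _random_seq(rng, PRECURSOR_FLANK)
        )
        catalog.append(
            CatalogEntry(
                name=name,
                family=mirna_family(name),
                mature_seq=mature,
                precursor_seq=precursor,
            )
        )
        pieces.append(precursor)
        annotations.append(
            AnnotationInterval(contig, pos, pos + len(precursor), "+", "miRNA", name)
        )
        pos += len(precursor)
        spacer()

    nuclear_categories = [
        c for c in config.background_fractions if c not in ("mt", "cp", "intergenic")
    ]
    for category in nuclear_categories:
        for k in range(2):
            length = 300
            pieces.append(_random_seq(rng, length))
            annotations.append(
                AnnotationInterval(contig, pos, pos + length, "+", category, f"{category}_{k}")
            )
            pos += length
            spacer()

    genome = {contig: "".join(pieces)}

    organelles: dict[str, str] = {}
    for org in ("mt", "cp"):
        length = 2000
        organelles[org] = _random_seq(rng, length)
        annotations.append(AnnotationInterval(org, 0, length, "+", org, f"{org}_genome"))

    for hs_contig, start, length, _ in config.organelle_hotspots:
        if hs_contig not in organelles:
            raise ValueError(f"hotspot contig {hs_contig!r} is not an organelle contig")
        if start + length > len(organelles[hs_contig]):
            raise ValueError("hotspot region extends past its contig")

    return Reference(
        genome=genome,
        catalog=catalog,
        annotations=annotations,
        organelles=organelles,
        intergenic=intergenic,
    )


def _source_fractions(config: SimulationConfig, condition: str) -> tuple[list[str], np.ndarray]:
    """Expected read fraction per source in one condition.

    Sources are the miRNAs (baseline x 2^FC), the hotspots (TPM / 1e6),
    and the background categories scaled to fill the remainder.
    """
    fc = config.true_log2fc.get(condition, {})
    names = config.mirna_names()
    mirna_p = np.array(
        [config.mirna_fraction / config.n_mirnas * 2.0 ** fc.get(n, 0.0) for n in names]
    )
    hotspot_p = np.array([h[3] / 1e6 for h in config.organelle_hotspots])
    remainder = 1.0 - mirna_p.sum() - hotspot_p.sum()
    if remainder <= 0:
        raise ValueError(
            f"{condition}: miRNA and hotspot weights leave no probability mass "
            "for background reads; lower the fold changes or the miRNA fraction"
        )
    bg_names = list(config.background_fractions)
    bg_conf = np.array([config.background_fractions[c] for c in bg_names])
    bg_p = bg_conf / bg_conf.sum() * remainder
    labels = (
        [f"mirna:{n}" for n in names]
        + [f"hotspot:{i}" for i in range(len(config.organelle_hotspots))]
        + [f"bg:{c}" for c in bg_names]
    )
    return labels, np.concatenate([mirna_p, hotspot_p, bg_p])


def expected_tpm(config: SimulationConfig, condition: str) -> dict[str, float]:
    """Expected mean TPM of each miRNA in one condition."""
    labels, p = _source_fractions(config, condition)
    return {
        label.split(":", 1)[1]: 1e6 * pi
        for label, pi in zip(labels, p)
        if label.startswith("mirna:")
    }


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Ground truth per miRNA and condition: true log2 FC versus the
    control, and expected mean TPM."""
    rows = []
    for condition in config.conditions:
        fc = config.true_log2fc.get(condition, {})
        tpms = expected_tpm(config, condition)
        for name in config.mirna_names():
            rows.append(
                {
                    "mirna": name,
                    "condition": condition,
                    "true_log2fc": fc.get(name, 0.0),
                    "expected_tpm": tpms[name],
                }
            )
    return pd.DataFrame(rows)


def _isomir_sequence(entry: CatalogEntry, off5: int, off3: int) -> str:
    anchor = entry.precursor_seq.find(entry.mature_seq)
    start = anchor + off5
    end = anchor + len(entry.mature_seq) + off3
    return entry.precursor_seq[start:end]


def simulate_library(
    config: SimulationConfig, reference: Reference, condition: str
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one condition's FASTQ reads plus its truth-table rows.

    Per-source counts are one multinomial draw at the configured depth.
    miRNA reads are positional variants cut from the precursor; background
    reads come from category intervals (organelle contigs for mt/cp,
    unannotated spacers for intergenic) with the 24-nt-mode length
    profile and random strand; hotspot reads are subsequences of their
    source region. The 3' adapter is appended and every raw read is
    padded with random bases, or truncated, to a uniform length.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cond_index = config.conditions.index(condition)
    rng = np.random.default_rng([config.seed, 1 + cond_index])

    labels, p = _source_fractions(config, condition)
    counts = rng.multinomial(config.depth, p)

    by_category: dict[str, list[AnnotationInterval]] = {}
    for iv in reference.annotations:
        by_category.setdefault(iv.category, []).append(iv)

    lengths = np.array(list(BACKGROUND_LENGTH_WEIGHTS))
    length_p = np.array(list(BACKGROUND_LENGTH_WEIGHTS.values()), dtype=float)
    length_p /= length_p.sum()

    offsets = list(config.isomir_profile)
    offset_p = np.array([config.isomir_profile[o] for o in offsets])

    catalog_by_name = {e.name: e for e in reference.catalog}
    contig_seq = dict(reference.genome) | dict(reference.organelles)

    inserts: list[str] = []
    for label, n in zip(labels, counts):
        if n == 0:
            continue
        kind, key = label.split(":", 1)
        if kind == "mirna":
            entry = catalog_by_name[key]
            picks = rng.choice(len(offsets), size=n, p=offset_p)
            inserts.extend(_isomir_sequence(entry, *offsets[i]) for i in picks)
        elif kind == "hotspot":
            contig, start, span, _ = config.organelle_hotspots[int(key)]
            seq = contig_seq[contig]
            for _ in range(n):
                read_len = int(
                    rng.choice(lengths[lengths <= span], p=_renorm(length_p[lengths <= span]))
                )
                s = start + int(rng.integers(0, span - read_len + 1))
                inserts.append(seq[s : s + read_len])
        else:  # background category
            if key == "intergenic":
                regions = [
                    (contig, start, end) for contig, start, end in reference.intergenic
                ]
            else:
                regions = [(iv.contig, iv.start, iv.end) for iv in by_category[key]]
            region_idx = rng.integers(0, len(regions), size=n)
            read_lens = rng.choice(lengths, size=n, p=length_p)
            flips = rng.random(size=n) < 0.5
            for ridx, read_len, flip in zip(region_idx, read_lens, flips):
                contig, start, end = regions[ridx]
                read_len = int(min(read_len, end - start))
                s = start + int(rng.integers(0, end - start - read_len + 1))
                frag = contig_seq[contig][s : s + read_len]
                inserts.append(reverse_complement(frag) if flip else frag)

    order = rng.permutation(len(inserts))
    records: list[ReadRecord] = []
    q40 = (40,) * config.raw_read_length
    for serial, idx in enumerate(order):
        raw = inserts[idx] + config.adapter3
        if len(raw) < config.raw_read_length:
            raw += _random_seq(rng, config.raw_read_length - len(raw))
        raw = raw[: config.raw_read_length]
        records.append(
            ReadRecord(id=f"{condition}_{serial}", sequence=raw, quality=q40)
        )

    truth = truth_table(config)
    return records, truth[truth["condition"] == condition].reset_index(drop=True)


def _renorm(p: np.ndarray) -> np.ndarray:
    return p / p.sum()


def write_library(
    config: SimulationConfig, reference: Reference, condition: str, path: str | Path
) -> pd.DataFrame:
    """Simulate one library to a FASTQ file; returns its truth rows."""
    records, truth = simulate_library(config, reference, condition)
    write_fastq(records, path)
    return truth


def recovery_scenario(seed: int) -> SimulationConfig:
    """The fold-change parameter-recovery benchmark.

    20 miRNAs at depth 1e5 over one control and one stress condition, with
    true log2 fold changes in {-3, -1, 0, 1, 3} at multiplicities
    (2, 5, 8, 4, 1) — downregulation-dominated, as plant submergence
    responses are. The miRNA read fraction is 0.70 so that the baseline of
    3500 reads per miRNA puts the three-sigma counting error of the
    strongest depletion at the 0.2-log2-unit tolerance of the benchmark;
    the composition-realistic default fraction cannot resolve fold changes
    that finely at this depth.
    """
    fcs = [-3.0] * 2 + [-1.0] * 5 + [0.0] * 8 + [1.0] * 4 + [3.0] * 1
    config = SimulationConfig(
        seed=seed,
        n_mirnas=20,
        depth=100_000,
        conditions=("control", "stress"),
        mirna_fraction=0.70,
        background_fractions={
            "repeats": 0.12,
            "rRNA": 0.02,
            "tRNA": 0.01,
            "snRNA": 0.02,
            "snoRNA": 0.005,
            "lncRNA": 0.01,
            "mRNA": 0.01,
            "mt": 0.005,
            "cp": 0.01,
            "intergenic": 0.09,
        },
    )
    config.true_log2fc = {"stress": dict(zip(config.mirna_names(), fcs))}
    return config
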