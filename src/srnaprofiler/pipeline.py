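"""End-to-end orchestration of the profiling pipeline on a synthetic study.

Runs every stage in order — simulation, preprocessing, tag merging,
genome mapping, catalog matching, category classification, library
summaries, representative grouping, fold-change calling, hotspot
detection — and returns all intermediate artifacts for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import annotation, grouping, preprocess, quantify, synthetic_data
from .annotation import AnnotationIndex, MiRNAHit, OrganelleHotspot, ReferenceIndex
from .grouping import RepresentativeGroup
from .preprocess import PreprocessStats, Tag
from .synthetic_data import Reference, SimulationConfig


@dataclass
class ScenarioResult:
    """Everything the pipeline computed for one synthetic study."""

    config: SimulationConfig
    reference: Reference
    tags: list[Tag]
    stats: dict[str, PreprocessStats]
    mirna_hits: dict[str, MiRNAHit]
    classifications: dict[str, str]
    summaries: pd.DataFrame
    groups: list[RepresentativeGroup]
    group_counts: pd.DataFrame
    fc_table: pd.DataFrame
    hotspots: list[OrganelleHotspot]
    truth: pd.DataFrame
    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def clean_totals(self) -> dict[str, int]:
        return {lib: s.clean for lib, s in self.stats.items()}

    def recovery_errors(self) -> pd.DataFrame:
        """Estimated minus true group fold change for every miRNA whose
        family-level group exists, one row per (group, condition pair)."""
        truth = self.truth
        rows = []
        name_to_group = {}
        for g in self.groups:
            for anchor in g.anchors:
                name_to_group[anchor] = g.group_name
        for label, treat, _ in self.pairs:
            cond_truth = truth[truth["condition"] == treat]
            for _, t in cond_truth.iterrows():
                group_name = name_to_group.get(t["mirna"])
                if group_name is None or group_name not in self.fc_table.index:
                    continue
                est = float(self.fc_table.at[group_name, label])
                status = str(self.fc_table.at[group_name, f"{label}_status"])
                rows.append(
                    {
                        "mirna": t["mirna"],
                        "group": group_name,
                        "pair": label,
                        "true_log2fc": float(t["true_log2fc"]),
                        "estimated_log2fc": est,
                        "error": est - float(t["true_log2fc"]),
                        "status": status,
                    }
                )
        return pd.DataFrame(rows)


def run_scenario(
    config: SimulationConfig,
    max_mm: int = 2,
    min_raw: int = quantify.DEFAULT_MIN_RAW,
    pseudo: float = quantify.DEFAULT_PSEUDO_TPM,
    threshold: float = quantify.DEFAULT_FC_THRESHOLD,
    min_hotspot_tpm: float = 50.0,
) -> ScenarioResult:
    """Simulate a study under ``config`` and run the full pipeline on it."""
    reference = synthetic_data.make_reference(config)

    per_library: dict[str, dict[str, int]] = {}
    stats: dict[str, PreprocessStats] = {}
    truth_frames = []
    for condition in config.conditions:
        records, truth = synthetic_data.simulate_library(config, reference, condition)
        counts, lib_stats = preprocess.preprocess_library(
            records, condition, config.adapter3
        )
        per_library[condition] = counts
        stats[condition] = lib_stats
        truth_frames.append(truth)
    truth = pd.concat(truth_frames, ignore_index=True)
    tags = preprocess.merge_tag_counts(per_library)

    nuclear_index = ReferenceIndex(reference.genome)
    organelle_index = ReferenceIndex(reference.organelles)
    combined_index = ReferenceIndex(dict(reference.genome) | dict(reference.organelles))
    ann_index = AnnotationIndex(reference.annotations)

    mirna_hits = annotation.match_all(tags, reference.catalog, max_mm)

    classifications: dict[str, str] = {}
    genome_mapped: dict[str, bool] = {}
    for tag in tags:
        hits = combined_index.find_all(tag.sequence)
        genome_mapped[tag.sequence] = any(
            h.contig in reference.genome for h in hits
        )
        classifications[tag.sequence] = annotation.classify_tag(
            tag.sequence, hits, ann_index, mirna_hits.get(tag.sequence)
        )

    summaries = pd.DataFrame(
        [
            annotation.summarize_library(
                tags,
                condition,
                classifications,
                mirna_hits,
                genome_mapped,
                stats[condition],
            )
            for condition in config.conditions
        ]
    )

    groups = grouping.group_variants(tags, mirna_hits, reference.catalog)
    group_counts = grouping.group_count_matrix(groups, list(config.conditions))
    clean_totals = {lib: s.clean for lib, s in stats.items()}
    control = config.control_condition
    pairs = [
        (f"{cond}_vs_{control}", cond, control)
        for cond in config.conditions
        if cond != control
    ]
    fc_table = quantify.fold_change_table(
        group_counts, clean_totals, pairs, pseudo, min_raw, threshold
    )

    # hotspot detection on mean TPM across libraries
    mean_tpm: dict[str, float] = {}
    for tag in tags:
        values = [
            quantify.tpm(tag.counts.get(lib, 0), clean_totals[lib])
            for lib in config.conditions
        ]
        mean_tpm[tag.sequence] = sum(values) / len(values)
    hotspots = annotation.organelle_hotspots(mean_tpm, organelle_index, min_hotspot_tpm)

    return ScenarioResult(
        config=config,
        reference=reference,
        tags=tags,
        stats=stats,
        mirna_hits=mirna_hits,
        classifications=classifications,
        summaries=summaries,
        groups=groups,
        group_counts=group_counts,
        fc_table=fc_table,
        hotspots=hotspots,
        truth=truth,
        pairs=pairs,
    )
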