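"""Bench-side physiology and qPCR formulas.

Relative water content (RWC) of leaf sections, the submergence tolerance
coefficient (STC) of treated versus control seedlings, and the ddCt
relative-expression statistic for stem-loop RT-qPCR with a single
reference assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class LeafWeights:
    """Fresh, turgid, and oven-dry masses (g) of one leaf section."""

    fresh_g: float
    turgid_g: float
    dry_g: float

    def __post_init__(self) -> None:
        if not self.turgid_g >= self.fresh_g >= self.dry_g > 0:
            raise ValueError("expected turgid >= fresh >= dry > 0")


@dataclass(frozen=True)
class CtQuartet:
    """Cycle thresholds for target and reference assays in treatment and
    control samples."""

    ct_target_treat: float
    ct_ref_treat: float
    ct_target_ctrl: float
    ct_ref_ctrl: float


def rwc(weights: LeafWeights) -> float:
    """Relative water content, 100 x (fresh - dry) / (turgid - dry)."""
    denom = weights.turgid_g - weights.dry_g
    if denom <= 0:
        raise ValueError("turgid weight must exceed dry weight")
    return 100.0 * (weights.fresh_g - weights.dry_g) / denom


def stc(
    treated: Sequence[tuple[float, float]], control: Sequence[tuple[float, float]]
) -> float:
    """Submergence tolerance coefficient.

    Each element is one plant's (length, dry weight). The coefficient is
    the ratio of the treated group's summed lengths-plus-dry-weights over
    the control group's — the formula adds the two measurements into one
    scalar per group, so the units are mixed by construction.
    """
    control_sum = sum(length + dry for length, dry in control)
    if control_sum <= 0:
        raise ValueError("control sum must be positive")
    treated_sum = sum(length + dry for length, dry in treated)
    return treated_sum / control_sum


def ddct(q: CtQuartet) -> float:
    """Relative expression by the ddCt method with one reference assay:
    2^-((Ct_target - Ct_ref)_treatment - (Ct_target - Ct_ref)_control)."""
    delta_treat = q.ct_target_treat - q.ct_ref_treat
    delta_ctrl = q.ct_target_ctrl - q.ct_ref_ctrl
    return 2.0 ** -(delta_treat - delta_ctrl)
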