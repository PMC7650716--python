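"""Expression quantification: TPM normalization against library clean-read
totals, log2 fold changes with a pseudocount, the raw-count floor, and
threshold-based differential-expression calls.

The experimental design this mirrors has one pooled library per condition
and no replicates, so DE status is descriptive — a thresholded fold
change — not an inferential test. No p-values are produced anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_MIN_RAW = 50
DEFAULT_FC_THRESHOLD = 1.0
DEFAULT_PSEUDO_TPM = 1.0

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_LOW_COUNT = "low_count"


@dataclass(frozen=True)
class DECall:
    """A differential-expression call for one row and condition pair."""

    id: str
    condition_pair: tuple[str, str]
    fc: float
    status: str


def tpm(raw: float, clean_total: int) -> float:
    """Tags per million: 1e6 x raw / clean_total."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    return 1e6 * raw / clean_total


def tpm_matrix(counts: pd.DataFrame, clean_totals: Mapping[str, int]) -> pd.DataFrame:
    """Columnwise TPM of a rows-by-libraries raw-count matrix."""
    out = counts.astype(float).copy()
    for lib in out.columns:
        out[lib] = out[lib].map(lambda raw: tpm(raw, clean_totals[lib]))
    return out


def log2_fc(tpm_treat: float, tpm_ctrl: float, pseudo: float = DEFAULT_PSEUDO_TPM) -> float:
    """log2((treatment + pseudo) / (control + pseudo)); finite for zeros."""
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((tpm_treat + pseudo) / (tpm_ctrl + pseudo))


def count_floor(raw_counts: Iterable[int], min_raw: int = DEFAULT_MIN_RAW) -> bool:
    """True iff the raw count reaches ``min_raw`` in at least one library."""
    if min_raw < 0:
        raise ValueError("min_raw must be non-negative")
    return max(raw_counts, default=0) >= min_raw


def de_call(fc: float, floor_passed: bool, threshold: float = DEFAULT_FC_THRESHOLD) -> str:
    """Threshold-based DE status; boundaries are inclusive."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not floor_passed:
        return STATUS_LOW_COUNT
    if fc >= threshold:
        return STATUS_UP
    if fc <= -threshold:
        return STATUS_DOWN
    return STATUS_UNCHANGED


def fc_to_ratio(fc: float) -> float:
    """Linear-scale expression ratio, 2^fc."""
    return 2.0**fc


def fold_change_table(
    counts: pd.DataFrame,
    clean_totals: Mapping[str, int],
    pairs: Sequence[tuple[str, str, str]],
    pseudo: float = DEFAULT_PSEUDO_TPM,
    min_raw: int = DEFAULT_MIN_RAW,
    threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Fold changes and DE statuses for a raw-count matrix.

    ``counts`` is rows-by-libraries; ``pairs`` lists
    (label, treatment_library, control_library). The result carries one
    ``<label>`` fold-change column and one ``<label>_status`` column per
    pair. The raw-count floor is evaluated across all libraries once per
    row, as the analysis keeps a row if it is well-measured anywhere.
    """
    tpms = tpm_matrix(counts, clean_totals)
    floor = counts.max(axis=1) >= min_raw
    out = pd.DataFrame(index=counts.index)
    for label, treat, ctrl in pairs:
        fc = [
            log2_fc(tpms.at[row, treat], tpms.at[row, ctrl], pseudo) for row in counts.index
        ]
        out[label] = fc
        out[f"{label}_status"] = [
            de_call(f, bool(floor.at[row]), threshold) for f, row in zip(fc, counts.index)
        ]
    return out
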