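"""Cross-condition analysis over a fold-change matrix.

The matrix has representative-group (or raw-sequence) rows and one log2
fold-change column per treatment/control pair. Operations: extraction of
the stress-responsive set, global fold-change extrema, directional
two-set overlap partitions (the Venn-diagram counts), and the
single-versus-alternated-stress attenuation report.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 1.0


@dataclass(frozen=True)
class VennPartition:
    """Directional partition of rows between two fold-change columns.

    The eight sets are disjoint and cover every row: concordant regulation
    (both_up / both_down), discordant regulation, regulation exclusive to
    one column (split by direction), and neither.
    """

    both_up: frozenset[str]
    both_down: frozenset[str]
    discordant: frozenset[str]
    only_a_up: frozenset[str]
    only_a_down: frozenset[str]
    only_b_up: frozenset[str]
    only_b_down: frozenset[str]
    neither: frozenset[str]

    def counts(self) -> dict[str, int]:
        return {f.name: len(getattr(self, f.name)) for f in fields(self)}

    def total(self) -> int:
        return sum(self.counts().values())


def validate_matrix(matrix: pd.DataFrame) -> None:
    """A fold-change matrix must be rectangular with finite cells."""
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("fold-change matrix contains non-finite cells")


def responsive_set(matrix: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> set[str]:
    """Rows regulated (|FC| >= threshold, inclusive) in at least one column."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    validate_matrix(matrix)
    mask = (matrix.abs() >= threshold).any(axis=1)
    return set(matrix.index[mask])


def fc_extrema(matrix: pd.DataFrame) -> tuple[tuple[float, str], tuple[float, str]]:
    """Global (minimum, maximum) over all cells with their row labels; ties
    resolved in row order."""
    if matrix.empty:
        raise ValueError("fold-change matrix is empty")
    validate_matrix(matrix)
    values = matrix.to_numpy(dtype=float)
    lo = np.unravel_index(np.argmin(values), values.shape)
    hi = np.unravel_index(np.argmax(values), values.shape)
    return (
        (float(values[lo]), str(matrix.index[lo[0]])),
        (float(values[hi]), str(matrix.index[hi[0]])),
    )


def venn2(
    matrix: pd.DataFrame, col_a: str, col_b: str, threshold: float = DEFAULT_THRESHOLD
) -> VennPartition:
    """Directional overlap partition between two condition columns."""
    validate_matrix(matrix[[col_a, col_b]])
    sets: dict[str, set[str]] = {
        "both_up": set(),
        "both_down": set(),
        "discordant": set(),
        "only_a_up": set(),
        "only_a_down": set(),
        "only_b_up": set(),
        "only_b_down": set(),
        "neither": set(),
    }
    for row in matrix.index:
        a, b = float(matrix.at[row, col_a]), float(matrix.at[row, col_b])
        a_dir = 1 if a >= threshold else (-1 if a <= -threshold else 0)
        b_dir = 1 if b >= threshold else (-1 if b <= -threshold else 0)
        if a_dir == 0 and b_dir == 0:
            key = "neither"
        elif a_dir != 0 and b_dir != 0:
            if a_dir == b_dir:
                key = "both_up" if a_dir > 0 else "both_down"
            else:
                key = "discordant"
        elif a_dir != 0:
            key = "only_a_up" if a_dir > 0 else "only_a_down"
        else:
            key = "only_b_up" if b_dir > 0 else "only_b_down"
        sets[key].add(str(row))
    return VennPartition(**{k: frozenset(v) for k, v in sets.items()})


def attenuation_report(
    matrix: pd.DataFrame,
    single_col: str,
    alternated_col: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Per-row comparison of a single-stress response with its alternated
    (sequential two-stress) counterpart.

    ``same_sign``: both fold changes on the same side of zero (or both
    zero). ``attenuated``: same sign, the single-stress response was
    regulated, and the alternated response is smaller in magnitude.
    ``lost``: regulated under the single stress but below threshold under
    the alternated treatment.
    """
    validate_matrix(matrix[[single_col, alternated_col]])
    rows = []
    for row in matrix.index:
        single = float(matrix.at[row, single_col])
        alt = float(matrix.at[row, alternated_col])
        regulated = abs(single) >= threshold
        same_sign = (single > 0 and alt > 0) or (single < 0 and alt < 0) or single == alt == 0.0
        rows.append(
            {
                "id": str(row),
                "fc_single": single,
                "fc_alternated": alt,
                "same_sign": same_sign,
                "attenuated": same_sign and regulated and abs(alt) < abs(single),
                "lost": regulated and abs(alt) < threshold,
            }
        )
    return pd.DataFrame(rows).set_index("id")
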