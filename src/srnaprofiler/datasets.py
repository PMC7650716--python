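"""Bundled reference datasets.

Published summary tables from the maize/teosinte submergence-drought
small-RNA profiling experiment this pipeline mirrors: the representative
miRNA log2 fold-change matrices (single and alternated stress, with the
constitutive qPCR control miR166c flagged) and the per-library read
counts by ncRNA category. Counts only are stored; percentages are always
recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "srnaprofiler.data"


def _load(name: str, index_col: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t").set_index(index_col)


def load_fold_change_matrix(include_constitutive: bool = False) -> pd.DataFrame:
    """Representative-miRNA log2 FC matrix: maize and teosinte under
    submergence and drought (13 responsive rows; optionally the
    constitutive miR166c row)."""
    df = _load("representative_fold_changes.tsv", "mirna")
    if not include_constitutive:
        df = df[df["role"] == "responsive"]
    return df.drop(columns="role")


def load_alternated_matrix(include_constitutive: bool = False) -> pd.DataFrame:
    """Teosinte log2 FC matrix under single and alternated stress
    (submergence, drought, drought-then-submergence,
    submergence-then-drought)."""
    df = _load("alternated_fold_changes.tsv", "mirna")
    if not include_constitutive:
        df = df[df["role"] == "responsive"]
    return df.drop(columns="role")


def load_library_counts() -> pd.DataFrame:
    """Per-library read counts by ncRNA category for the eight maize and
    teosinte libraries (rows: raw, clean, genome-mapped, then the
    categories; columns: libraries)."""
    return _load("library_category_counts.tsv", "category")
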