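"""Small half-open interval utilities shared by the region modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["overlap_pairs", "overlaps_any"]


def overlap_pairs(left: pd.DataFrame, right: pd.DataFrame) -> list[tuple[int, int]]:
    """Index pairs (left positional index, right positional index) of rows
    whose half-open [start, end) intervals overlap by >= 1 bp on the same
    chromosome.  Quadratic per chromosome; tables here are region-scale.
    """
    pairs: list[tuple[int, int]] = []
    lc = left["chrom"].values
    ls = left["start"].values
    le = left["end"].values
    rc = right["chrom"].values
    rs = right["start"].values
    re_ = right["end"].values
    for i in range(len(left)):
        hit = (rc == lc[i]) & (rs < le[i]) & (re_ > ls[i])
        for j in np.flatnonzero(hit):
            pairs.append((i, int(j)))
    return pairs


def overlaps_any(query: tuple[str, int, int], table: pd.DataFrame) -> bool:
    """Does the half-open query interval overlap any interval in ``table``?"""
    chrom, start, end = query
    if table.empty:
        return False
    sub = table[table["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())
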