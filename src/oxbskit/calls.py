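"""Per-CpG beta calling, coverage filtering, context and bin summaries."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["call_beta", "context_summary", "genome_bins", "MalformedRecordError"]

VALID_CONTEXTS = ("CG", "CHG", "CHH")


class MalformedRecordError(ValueError):
    pass


def call_beta(counts: pd.DataFrame, min_cov: int = 10) -> pd.DataFrame:
    """beta = unconverted/total per CpG; sites under ``min_cov`` are dropped.

    Input columns: chrom, pos, unconverted, total.  Duplicate (chrom, pos)
    records and unconverted > total are input errors (reported with the
    offending row number), never merged or clipped silently.
    """
    required = {"chrom", "pos", "unconverted", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if counts.empty:
        return pd.DataFrame(columns=["chrom", "pos", "beta", "coverage"])
    bad = counts.index[counts["unconverted"] > counts["total"]]
    if len(bad):
        raise MalformedRecordError(
            f"unconverted > total at input row {int(bad[0])}"
        )
    dup = counts.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise MalformedRecordError(
            f"duplicate (chrom, pos) record at input row {int(counts.index[dup][0])}"
        )
    kept = counts[counts["total"] >= min_cov]
    out = pd.DataFrame(
        {
            "chrom": kept["chrom"].values,
            "pos": kept["pos"].values,
            "beta": kept["unconverted"].values / kept["total"].values,
            "coverage": kept["total"].values,
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def context_summary(track: pd.DataFrame, contexts: pd.DataFrame) -> pd.DataFrame:
    """Retained-site counts and unweighted mean beta per cytosine context.

    ``contexts`` maps (chrom, pos) -> context in {CG, CHG, CHH}.  Contexts
    with no retained site report count 0 and a NaN mean.
    """
    unknown = set(contexts["context"]) - set(VALID_CONTEXTS)
    if unknown:
        raise ValueError(f"unknown context label(s): {sorted(unknown)}")
    merged = track.merge(contexts, on=["chrom", "pos"], how="left")
    if merged["context"].isna().any():
        raise ValueError("context label missing for some retained sites")
    rows = []
    for ctx in VALID_CONTEXTS:
        sub = merged[merged["context"] == ctx]
        rows.append(
            {
                "context": ctx,
                "n_sites": len(sub),
                "mean_rate": sub["beta"].mean() if len(sub) else math.nan,
            }
        )
    return pd.DataFrame(rows)


def genome_bins(
    track: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Mean beta per genomic bin (half-open bins; last bin truncated).

    Only bins containing at least one retained site are emitted.
    """
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        idx = (sub["pos"].values // bin_size).astype(int)
        for b in np.unique(idx):
            sel = sub["beta"].values[idx == b]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(b * bin_size),
                    "end": int(min((b + 1) * bin_size, size)),
                    "mean_beta": float(sel.mean()),
                    "n_sites": int(len(sel)),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_beta", "n_sites"])
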