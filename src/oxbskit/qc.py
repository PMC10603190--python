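"""Spike-in conversion-rate QC and library depth summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._stats import round2

__all__ = ["SpikeCounts", "conversion_rate", "summarize_conversion", "depth_summary"]

SPIKE_CLASSES = ("C", "5mC", "5hmC", "5fC")


@dataclass(frozen=True)
class SpikeCounts:
    """Spike-in read counts for one library: per class (unconverted, total)."""

    library_id: str
    arm: str  # "bs" | "ox"
    counts: dict[str, tuple[int, int]]

    def __post_init__(self):
        if self.arm not in ("bs", "ox"):
            raise ValueError(f"arm must be 'bs' or 'ox', got {self.arm!r}")
        for klass, (k, n) in self.counts.items():
            if klass not in SPIKE_CLASSES:
                raise ValueError(f"unknown spike class {klass!r}")
            if not (0 <= k <= n):
                raise ValueError(f"invalid counts for {klass}: {k}/{n}")


def conversion_rate(counts: SpikeCounts, klass: str) -> float:
    """Conversion rate in percent: 100 * (total - unconverted) / total.

    Returns NaN (a missing-data marker, excluded from averages) when the
    class has no reads.
    """
    k, n = counts.counts.get(klass, (0, 0))
    if n == 0:
        return math.nan
    return 100.0 * (n - k) / n


def summarize_conversion(
    reports: list[SpikeCounts] | None = None,
    rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-library conversion rates plus per-arm class averages.

    Accepts either raw ``SpikeCounts`` or a pre-computed ``rates`` frame
    with columns (library_id, arm, class, rate).  Returns one row per
    (arm, class) with per-library rate columns, the full-precision
    ``average`` and the 2-decimal ``average_display``.
    """
    if rates is None:
        if not reports:
            raise ValueError("no spike-in reports supplied")
        rows = [
            {
                "library_id": rep.library_id,
                "arm": rep.arm,
                "class": klass,
                "rate": conversion_rate(rep, klass),
            }
            for rep in reports
            for klass in SPIKE_CLASSES
            if klass in rep.counts
        ]
        rates = pd.DataFrame(rows)
    if rates.empty:
        raise ValueError("no spike-in rates supplied")

    out = []
    for (arm, klass), sub in rates.groupby(["arm", "class"], sort=True):
        vals = sub.dropna(subset=["rate"])
        avg = vals["rate"].mean() if len(vals) else math.nan
        row = {"arm": arm, "class": klass}
        row.update(dict(zip(sub["library_id"], sub["rate"])))
        row["average"] = avg
        row["average_display"] = round2(avg) if not math.isnan(avg) else math.nan
        out.append(row)
    return pd.DataFrame(out)


def depth_summary(
    libraries: pd.DataFrame,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Mean fold-depth per arm.

    ``libraries`` needs columns (library_id, arm) plus either ``depth``
    directly or ``clean_bases`` (in which case depth = clean_bases /
    genome_size).
    """
    lib = libraries.copy()
    if "depth" not in lib.columns:
        if genome_size is None or genome_size <= 0:
            raise ValueError("genome_size must be positive to derive depth")
        lib["depth"] = lib["clean_bases"] / genome_size
    rows = []
    for arm, sub in lib.groupby("arm", sort=True):
        mean = sub["depth"].mean()
        rows.append({"arm": arm, "n_libraries": len(sub), "mean_depth": mean,
                     "mean_depth_display": round2(mean)})
    return pd.DataFrame(rows)
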