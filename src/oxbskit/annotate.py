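"""Feature annotation, 30-bin metaprofiles, and feature enrichment.

Enrichment follows the observed/expected convention: the ratio of the
significant fraction among regions falling in a feature to the significant
fraction genome-wide, with a two-sided Fisher exact test per feature and
Benjamini-Hochberg adjustment across features.  The universe defaults to
all tested candidate regions; a genomic-length-based expectation is
available behind ``mode="length"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._intervals import overlap_pairs, overlaps_any
from ._stats import bh_adjust
from .synthgen.annotation import ToyAnnotation

__all__ = ["annotate_feature", "binned_profile", "enrichment", "BinProfile"]

GENE_FEATURES = ("promoter", "5utr", "exon", "intron", "3utr", "gene_body")


def annotate_feature(
    interval: tuple[str, int, int],
    ann: ToyAnnotation,
    features: dict[str, pd.DataFrame] | None = None,
) -> set[str]:
    """Feature labels overlapping a half-open interval.

    CGI shore = within 2 kb of an island, shelf = 2-4 kb away (both
    excluding the island itself); intergenic = no gene-feature overlap.
    """
    if features is None:
        features = ann.feature_intervals()
    labels: set[str] = set()
    for name in GENE_FEATURES:
        if overlaps_any(interval, features[name]):
            labels.add(name)
    in_cgi = overlaps_any(interval, features["cgi"])
    if in_cgi:
        labels.add("cgi")
    else:
        if overlaps_any(interval, features["cgi_shore"]):
            labels.add("cgi_shore")
        elif overlaps_any(interval, features["cgi_shelf"]):
            labels.add("cgi_shelf")
    if not labels & set(GENE_FEATURES):
        labels.add("intergenic")
    return labels


@dataclass
class BinProfile:
    """Across-region mean modification level per bin.

    ``bins`` runs from -flank_bins to n_bins + flank_bins - 1; 0..n_bins-1
    are the body bins, oriented 5' to 3'.
    """

    values: np.ndarray
    bins: np.ndarray
    n_bins: int
    flank_bins: int
    n_regions: int

    def body(self) -> np.ndarray:
        return self.values[self.flank_bins : self.flank_bins + self.n_bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "mean_level": self.values})


def binned_profile(
    levels: pd.DataFrame,
    regions: pd.DataFrame,
    n_bins: int = 30,
    flank: int = 5_000,
    flank_bins: int = 50,
) -> BinProfile:
    """Metaprofile: per region, mean level per bin; then mean across regions.

    ``levels`` has (chrom, pos, value); ``regions`` has (chrom, start, end)
    and optionally ``strand`` (minus-strand regions are flipped so bin 0 is
    at the 5' end).  Regions shorter than ``n_bins`` bp are skipped; empty
    bins are missing values and excluded from across-region means.
    """
    if regions.empty:
        raise ValueError("empty region set")
    total_bins = n_bins + 2 * flank_bins
    sums = np.zeros(total_bins)
    counts = np.zeros(total_bins)
    per_region = np.full(total_bins, np.nan)
    acc = []
    for reg in regions.itertuples(index=False):
        length = reg.end - reg.start
        if length < n_bins:
            continue
        sub = levels[
            (levels["chrom"] == reg.chrom)
            & (levels["pos"] >= reg.start - flank)
            & (levels["pos"] < reg.end + flank)
        ]
        if sub.empty:
            continue
        pos = sub["pos"].values
        val = sub["value"].values
        bin_idx = np.full(len(sub), -1)
        body = (pos >= reg.start) & (pos < reg.end)
        bin_idx[body] = flank_bins + (
            (pos[body] - reg.start) * n_bins // length
        )
        upstream = pos < reg.start
        bin_idx[upstream] = (pos[upstream] - (reg.start - flank)) * flank_bins // flank
        downstream = pos >= reg.end
        bin_idx[downstream] = (
            flank_bins + n_bins + (pos[downstream] - reg.end) * flank_bins // flank
        )
        region_vals = np.full(total_bins, np.nan)
        for b in np.unique(bin_idx):
            if 0 <= b < total_bins:
                region_vals[b] = val[bin_idx == b].mean()
        strand = getattr(reg, "strand", "+")
        if strand == "-":
            region_vals = region_vals[::-1]
        acc.append(region_vals)
    if not acc:
        raise ValueError("no region long enough to profile")
    mat = np.vstack(acc)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        per_region = np.nanmean(mat, axis=0)
    return BinProfile(
        values=per_region,
        bins=np.arange(-flank_bins, n_bins + flank_bins),
        n_bins=n_bins,
        flank_bins=flank_bins,
        n_regions=len(acc),
    )


def enrichment(
    significant: pd.DataFrame,
    features: dict[str, pd.DataFrame],
    universe: pd.DataFrame,
    mode: str = "universe",
) -> pd.DataFrame:
    """Observed/expected enrichment of significant regions per feature.

    ratio = (sig-in-feature / universe-in-feature)
          / (sig-genome-wide / universe-genome-wide)

    with a 2x2 Fisher exact test on {sig, not-sig} x {in-feature, not} and
    BH adjustment across features.  ``mode="length"`` replaces the
    universe-based expectation with the feature's genomic-length fraction.
    """
    if mode not in ("universe", "length"):
        raise ValueError(f"unknown mode {mode!r}")
    n_sig_total = len(significant)
    n_total = len(universe)
    if n_total < n_sig_total:
        raise ValueError("universe must contain the significant set")
    genome_len = None
    if mode == "length":
        genome_len = sum(
            int(df["end"].sub(df["start"]).sum()) for df in features.values()
        )
    rows = []
    for name, table in features.items():
        sig_in = _n_overlapping(significant, table)
        tot_in = _n_overlapping(universe, table)
        row = {"feature": name, "sig_in_feature": sig_in, "total_in_feature": tot_in,
               "sig_total": n_sig_total, "universe_total": n_total}
        if tot_in == 0 or n_sig_total == 0:
            row["ratio"] = np.nan
            row["p_value"] = 1.0
        else:
            if mode == "universe":
                row["ratio"] = (sig_in / tot_in) / (n_sig_total / n_total)
            else:
                feat_len = int(table["end"].sub(table["start"]).sum())
                expected = feat_len / genome_len if genome_len else np.nan
                row["ratio"] = (sig_in / n_sig_total) / expected if expected else np.nan
            table22 = [
                [sig_in, n_sig_total - sig_in],
                [tot_in - sig_in, (n_total - n_sig_total) - (tot_in - sig_in)],
            ]
            row["p_value"] = float(fisher_exact(table22, alternative="two-sided")[1])
        rows.append(row)
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].values)
    return df


def _n_overlapping(regions: pd.DataFrame, table: pd.DataFrame) -> int:
    if regions.empty or table.empty:
        return 0
    hit = {i for i, _ in overlap_pairs(regions, table)}
    return len(hit)
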