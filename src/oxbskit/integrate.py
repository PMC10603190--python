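"""Promoter 5mC/5hmC pattern classification joined with expression.

"Grouped expression" of a set of genes under one condition is the
arithmetic mean of their normalized counts over the genes and the
condition's samples; log2 fold changes add a pseudocount of 1 inside the
log so the formula is defined at zero:

    log2FC = log2(grouped expression tumor + 1) - log2(grouped expression normal + 1)

Percentile splits for signature scores use the inverted-CDF definition so
that with 100 distinct per-sample scores exactly 25 sit strictly above the
75th percentile and 24 strictly below the 25th.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from ._stats import mannwhitney_p, round2
from .synthgen.expression import ExpressionTable

__all__ = [
    "filter_expressed",
    "classify_promoters",
    "pattern_summary",
    "compare_pattern_expression",
    "stratify_by_5hmc",
    "select_top_genes",
    "signature_score",
    "gene_log2fc",
    "grouped_log2fc",
    "genebody_5hmc_analysis",
]

UNIDIRECTIONAL = ("up/up", "down/down")
BIDIRECTIONAL = ("up/down", "down/up")


def filter_expressed(expr: ExpressionTable, min_frac: float = 0.25) -> list[str]:
    """Genes detected (count > 0) in at least ``min_frac`` of all samples."""
    counts = expr.counts
    if counts.empty:
        return []
    need = math.ceil(min_frac * counts.shape[1])
    keep = (counts > 0).sum(axis=1) >= need
    return list(counts.index[keep])


def classify_promoters(pdmr: pd.DataFrame, pdhmr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene joint direction pattern from promoter DMR/DhMR tables.

    Both inputs carry (gene_id, direction, delta_beta).  Genes with both
    marks get one of the four up/down patterns; genes with one mark are
    "partial".  Conflicting duplicate directions for a gene are an error.
    """
    def per_gene(table: pd.DataFrame, what: str) -> pd.DataFrame:
        if table.empty:
            return pd.DataFrame(columns=["gene_id", "direction", "delta_beta"])
        dup = table.groupby("gene_id")["direction"].nunique()
        bad = dup[dup > 1]
        if len(bad):
            raise ValueError(
                f"conflicting {what} directions for gene(s) {list(bad.index)}"
            )
        return table.drop_duplicates("gene_id")[["gene_id", "direction", "delta_beta"]]

    dm = per_gene(pdmr, "5mC").rename(
        columns={"direction": "dm", "delta_beta": "delta_m"}
    )
    dh = per_gene(pdhmr, "5hmC").rename(
        columns={"direction": "dhm", "delta_beta": "delta_h"}
    )
    merged = dm.merge(dh, on="gene_id", how="outer")
    merged["dm"] = merged["dm"].fillna("none")
    merged["dhm"] = merged["dhm"].fillna("none")

    def pattern(row) -> str:
        if row["dm"] == "none" and row["dhm"] == "none":
            return "none"
        if row["dm"] == "none" or row["dhm"] == "none":
            return "partial"
        return f"{row['dm']}/{row['dhm']}"

    merged["pattern"] = merged.apply(pattern, axis=1)
    merged["directionality"] = np.select(
        [merged["pattern"].isin(UNIDIRECTIONAL), merged["pattern"].isin(BIDIRECTIONAL)],
        ["unidirectional", "bidirectional"],
        default="n/a",
    )
    return merged.sort_values("gene_id").reset_index(drop=True)


def pattern_summary(
    classes: pd.DataFrame, log2fc: pd.Series | None = None
) -> dict[str, float]:
    """Counts and percentages per promoter-direction pattern.

    For each 5mC direction among both-marks genes: total, number with the
    matching 5hmC direction, and the percentage (2 decimals).  When
    ``log2fc`` is given, also the percentage of up/up genes with reduced
    expression and of down/down genes with increased expression.
    """
    both = classes[(classes["dm"].isin(["up", "down"])) & (classes["dhm"].isin(["up", "down"]))]
    out: dict[str, float] = {"n_both_marks": int(len(both))}
    for d in ("up", "down"):
        sub = both[both["dm"] == d]
        match = sub[sub["dhm"] == d]
        out[f"n_dm_{d}"] = int(len(sub))
        out[f"n_dm_{d}_matching"] = int(len(match))
        out[f"pct_dm_{d}_matching"] = (
            round2(100.0 * len(match) / len(sub)) if len(sub) else 0.0
        )
    if log2fc is not None:
        for pat, direction, key in (
            ("up/up", "reduced", "expr_down"),
            ("down/down", "increased", "expr_up"),
        ):
            genes = both.loc[both["pattern"] == pat, "gene_id"]
            fc = log2fc.reindex(genes).dropna()
            n = int(len(fc))
            hit = int((fc < 0).sum()) if direction == "reduced" else int((fc > 0).sum())
            out[f"n_{pat}"] = n
            out[f"n_{pat}_{key}"] = hit
            out[f"pct_{pat}_{key}"] = round2(100.0 * hit / n) if n else 0.0
    return out


def gene_log2fc(expr: ExpressionTable, pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2FC of mean normalized counts, tumor vs normal.

    The default pseudocount keeps the formula defined at zero counts; pass
    ``pseudocount=0`` for the bare log-ratio.
    """
    cpm = expr.cpm
    t = cpm[expr.groups["tumor"]].mean(axis=1)
    n = cpm[expr.groups["normal"]].mean(axis=1)
    return np.log2(t + pseudocount) - np.log2(n + pseudocount)


def grouped_log2fc(tumor_mean: float, normal_mean: float, pseudocount: float = 1.0) -> float:
    """log2(grouped tumor expression + pc) - log2(grouped normal expression + pc)."""
    return float(np.log2(tumor_mean + pseudocount) - np.log2(normal_mean + pseudocount))


def compare_pattern_expression(
    classes: pd.DataFrame, log2fc: pd.Series
) -> pd.DataFrame:
    """Unidirectional vs bidirectional expression-change comparisons.

    Compares per-gene log2FC between up/up and up/down, and between
    down/down and down/up, with the exact Mann-Whitney test (normal
    approximation only beyond the exact-size limit).
    """
    rows = []
    for uni, bi in (("up/up", "up/down"), ("down/down", "down/up")):
        fc_uni = log2fc.reindex(classes.loc[classes["pattern"] == uni, "gene_id"]).dropna()
        fc_bi = log2fc.reindex(classes.loc[classes["pattern"] == bi, "gene_id"]).dropna()
        if fc_uni.empty or fc_bi.empty:
            warn(f"comparison {uni} vs {bi} skipped: empty pattern group")
            continue
        rows.append(
            {
                "unidirectional": uni,
                "bidirectional": bi,
                "n_unidirectional": len(fc_uni),
                "n_bidirectional": len(fc_bi),
                "median_log2fc_unidirectional": float(fc_uni.median()),
                "median_log2fc_bidirectional": float(fc_bi.median()),
                "mean_log2fc_unidirectional": float(fc_uni.mean()),
                "mean_log2fc_bidirectional": float(fc_bi.mean()),
                "p_value": mannwhitney_p(fc_uni.values, fc_bi.values),
            }
        )
    return pd.DataFrame(rows)


STRATA = (("high", 0.14, np.inf), ("medium", 0.12, 0.14), ("low", 0.10, 0.12))


def stratify_by_5hmc(
    classes: pd.DataFrame, expr: ExpressionTable, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-stratum expression change of unidirectional genes, binned by
    |delta beta| of the promoter 5hmC alteration.

    high: |d| > 0.14; medium: 0.12 < |d| <= 0.14; low: 0.10 < |d| <= 0.12;
    genes at or below 0.10 are excluded.  Reports the median per-gene
    log2FC and the grouped-expression log2FC per stratum.
    """
    uni = classes[classes["directionality"] == "unidirectional"].copy()
    uni["abs_dh"] = uni["delta_h"].abs()
    fc = gene_log2fc(expr, pseudocount)
    cpm = expr.cpm
    rows = []
    for name, lo, hi in STRATA:
        sel = uni[(uni["abs_dh"] > lo) & (uni["abs_dh"] <= hi)]
        genes = [g for g in sel["gene_id"] if g in cpm.index]
        row = {"stratum": name, "n_genes": len(genes)}
        if genes:
            t = cpm.loc[genes, expr.groups["tumor"]].values.mean()
            n = cpm.loc[genes, expr.groups["normal"]].values.mean()
            row["grouped_log2fc"] = grouped_log2fc(t, n, pseudocount)
            row["median_log2fc"] = float(fc.reindex(genes).median())
        else:
            row["grouped_log2fc"] = np.nan
            row["median_log2fc"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def select_top_genes(
    classes: pd.DataFrame,
    log2fc: pd.Series,
    direction: str,
    k: int = 20,
    min_abs_dh: float = 0.12,
) -> list[str]:
    """Top-k genes by |log2FC| with the matching unidirectional pattern.

    ``direction="up"``: upregulated genes (log2FC > 0) with down/down
    promoters; ``direction="down"``: downregulated genes with up/up
    promoters.  Eligibility additionally requires |delta beta (5hmC)|
    strictly above ``min_abs_dh`` (at least a "medium" alteration).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    pattern = "down/down" if direction == "up" else "up/up"
    sub = classes[
        (classes["pattern"] == pattern) & (classes["delta_h"].abs() > min_abs_dh)
    ]
    fc = log2fc.reindex(sub["gene_id"]).dropna()
    fc = fc[fc > 0] if direction == "up" else fc[fc < 0]
    ranked = pd.DataFrame(
        {"gene_id": list(fc.index), "abs_fc": fc.abs().values}
    ).sort_values(["abs_fc", "gene_id"], ascending=[False, True])
    if len(ranked) < k:
        warn(f"only {len(ranked)} eligible genes for top-{k} ({direction})")
    return list(ranked["gene_id"].head(k))


def signature_score(
    tpm: pd.DataFrame,
    gene_set: list[str],
    hi_pct: float = 75.0,
    lo_pct: float = 25.0,
) -> pd.DataFrame:
    """Per-sample mean log2(TPM + 1) over a gene set, with high/low labels.

    high: score strictly above the ``hi_pct`` percentile of the per-sample
    score distribution; low: strictly below the ``lo_pct`` percentile.
    """
    genes = [g for g in gene_set if g in tpm.index]
    if not genes:
        raise ValueError("empty gene set (no genes found in the TPM table)")
    scores = np.log2(tpm.loc[genes] + 1.0).mean(axis=0)
    hi = np.percentile(scores.values, hi_pct, method="inverted_cdf")
    lo = np.percentile(scores.values, lo_pct, method="inverted_cdf")
    label = np.select(
        [scores.values > hi, scores.values < lo], ["high", "low"], default="mid"
    )
    return pd.DataFrame(
        {"sample": scores.index, "score": scores.values, "label": label}
    )


@dataclass
class GeneBodyAnalysis:
    groups: pd.DataFrame          # group, n_genes, grouped_expression
    eligible_genes: list[str]


def genebody_5hmc_analysis(
    gene_levels: pd.DataFrame,
    expr: ExpressionTable,
    max_promoter_m: float = 0.1,
) -> GeneBodyAnalysis:
    """Grouped expression by promoter/gene-body 5hmC level.

    ``gene_levels`` carries per-gene (gene_id, promoter_m, promoter_h,
    genebody_h) averaged across samples.  Only genes with promoter mean
    5mC < ``max_promoter_m`` enter; each 5hmC summary is split at its
    median (genes exactly at the median go to the "low" group).  Grouped
    expression is the mean normalized count of the group's genes over all
    samples.
    """
    eligible = gene_levels[gene_levels["promoter_m"] < max_promoter_m]
    eligible = eligible[eligible["gene_id"].isin(expr.cpm.index)]
    if len(eligible) < 2:
        raise ValueError("fewer than 2 genes with low promoter 5mC")
    rows = []
    for prefix, col in (("promoter", "promoter_h"), ("genebody", "genebody_h")):
        # stable rank-based median split: the lower half (including genes
        # exactly at the median) goes to "low", so ties never inflate one side
        ordered = eligible.sort_values(col, kind="mergesort")
        n_low = (len(ordered) + 1) // 2
        low = ordered["gene_id"].iloc[:n_low]
        high = ordered["gene_id"].iloc[n_low:]
        for name, genes in ((f"{prefix}_high_5hmc", high), (f"{prefix}_low_5hmc", low)):
            grouped = (
                float(expr.cpm.loc[genes].values.mean()) if len(genes) else np.nan
            )
            rows.append(
                {"group": name, "n_genes": int(len(genes)), "grouped_expression": grouped}
            )
    return GeneBodyAnalysis(
        groups=pd.DataFrame(rows), eligible_genes=list(eligible["gene_id"])
    )
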