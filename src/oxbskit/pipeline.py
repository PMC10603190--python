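"""End-to-end orchestration: simulate -> qc -> call -> estimate -> regions ->
annotate -> integrate, from a single config and seed.

The default toy configuration runs in seconds on one CPU and carries
implanted promoter patterns plus standalone differential regions, so every
downstream stage has recoverable signal.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import calls, dmr, integrate, mlml, qc
from .synthgen import (
    AnnotationConfig,
    ConversionModel,
    EffectSpec,
    ImplantSpec,
    MethylomeConfig,
    ToyAnnotation,
    TrueMethylome,
    generate_annotation,
    generate_true_methylome,
    simulate_expression,
    simulate_study,
)

__all__ = ["default_config", "build_implants", "run_all", "region_recovery", "RunResult"]

PATTERNS = ("up/up", "down/down", "up/down", "down/up")


def default_config() -> dict:
    return {
        "annotation": {
            "chrom_sizes": {"chrA": 300_000, "chrB": 300_000},
            "n_genes": 48,
            "n_intergenic_cgis": 4,
        },
        "methylome": {},
        "conversion": {},
        "depth": 28.0,
        "n_pairs": 4,
        "jitter_sd": 0.01,
        "min_cov": 10,
        "implants": {
            "n_pattern_genes_per_class": 5,
            "n_m": 6,
            "n_h": 6,
            "delta_m": 0.3,
            "delta_h": 0.15,
            "m_span": 1100,
            "h_span": 1000,
        },
        "effects": {},
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_implants(
    ann: ToyAnnotation,
    seed: int,
    n_pattern_genes_per_class: int = 5,
    n_m: int = 6,
    n_h: int = 6,
    delta_m: float = 0.3,
    delta_h: float = 0.15,
    m_span: int = 650,
    h_span: int = 550,
) -> tuple[list[ImplantSpec], dict[str, str]]:
    """Promoter implants realizing the four patterns, plus standalone
    differential regions in gene-free stretches.

    Returns the implant list and the gene -> pattern truth map.
    """
    rng = np.random.default_rng(seed)
    promoters = ann.promoters()
    gene_ids = list(ann.genes["gene_id"])
    needed = 4 * n_pattern_genes_per_class
    if needed > len(gene_ids):
        raise ValueError(f"{needed} pattern genes requested, {len(gene_ids)} available")
    chosen = list(rng.choice(gene_ids, size=needed, replace=False)) if needed else []
    pattern_truth: dict[str, str] = {}
    implants: list[ImplantSpec] = []
    prom = promoters.set_index("gene_id")
    for i, gid in enumerate(chosen):
        pattern = PATTERNS[i // n_pattern_genes_per_class]
        dm_dir, dh_dir = pattern.split("/")
        pattern_truth[gid] = pattern
        row = prom.loc[gid]
        sm = delta_m if dm_dir == "up" else -delta_m
        sh = delta_h if dh_dir == "up" else -delta_h
        implants.append(
            ImplantSpec(row["chrom"], int(row["start"]), int(row["end"]), sm, "m", gid)
        )
        implants.append(
            ImplantSpec(
                row["chrom"], int(row["start"]), int(row["end"]), sh, "h", gid,
                min_base=0.15,
            )
        )

    implants.extend(
        _standalone_implants(ann, rng, n_m, delta_m, m_span, "m")
    )
    implants.extend(
        _standalone_implants(ann, rng, n_h, delta_h, h_span, "h")
    )
    return implants, pattern_truth


def _gene_free_windows(ann: ToyAnnotation, span: int, margin: int = 1_200) -> list[tuple[str, int, int]]:
    """Candidate windows clear of gene loci and promoters."""
    windows = []
    for chrom in sorted(ann.chrom_sizes):
        size = ann.chrom_sizes[chrom]
        occupied = []
        sub = ann.genes[ann.genes["chrom"] == chrom]
        for g in sub.itertuples():
            occupied.append((g.start - margin, g.end + margin))
        occupied.sort()
        cursor = 200
        for s, e in occupied + [(size - 200, size)]:
            while cursor + span <= s:
                windows.append((chrom, cursor, cursor + span))
                cursor += span + 400
            cursor = max(cursor, e)
    return windows


def _standalone_implants(ann, rng, count, delta, span, modality) -> list[ImplantSpec]:
    if count == 0:
        return []
    windows = _gene_free_windows(ann, span)
    if len(windows) < count:
        raise ValueError(f"not enough gene-free windows for {count} {modality} implants")
    idx = rng.choice(len(windows), size=count, replace=False)
    out = []
    for n, i in enumerate(sorted(idx)):
        chrom, start, end = windows[i]
        sign = 1.0 if n % 2 == 0 else -1.0
        base = 0.15 if modality == "h" else 0.0
        out.append(ImplantSpec(chrom, start, end, sign * delta, modality, min_base=base))
    return out


@dataclass
class RunResult:
    config: dict
    seed: int
    annotation: ToyAnnotation = None
    truth: TrueMethylome = None
    pattern_truth: dict = field(default_factory=dict)
    conversion_report: pd.DataFrame = None
    depth_report: pd.DataFrame = None
    estimates: dict = field(default_factory=dict)       # sample -> estimate frame
    beta_m: pd.DataFrame = None                         # sites x samples, p_m
    beta_h: pd.DataFrame = None
    groups: dict = field(default_factory=dict)
    regions_m: pd.DataFrame = None
    regions_h: pd.DataFrame = None
    promoter_m: pd.DataFrame = None
    promoter_h: pd.DataFrame = None
    enrichment_m: pd.DataFrame = None
    expression: object = None
    classes: pd.DataFrame = None
    summary: dict = field(default_factory=dict)
    comparisons: pd.DataFrame = None
    strata: pd.DataFrame = None
    top_up: list = field(default_factory=list)
    top_down: list = field(default_factory=list)
    scores_up: pd.DataFrame = None
    scores_down: pd.DataFrame = None


def run_all(config: dict | None = None, seed: int = 0, outdir=None) -> RunResult:
    cfg = _merge(default_config(), config)
    ss = np.random.SeedSequence(seed)
    s_ann, s_imp, s_truth, s_reads, s_expr = (
        np.random.default_rng(c).integers(2**31) for c in ss.spawn(5)
    )
    res = RunResult(config=cfg, seed=seed)

    # 1. genome + truth
    ann = generate_annotation(AnnotationConfig.from_dict(cfg["annotation"]), s_ann)
    implants, pattern_truth = build_implants(ann, s_imp, **cfg["implants"])
    truth = generate_true_methylome(
        ann, implants, s_truth, MethylomeConfig.from_dict(cfg["methylome"])
    )
    res.annotation, res.truth, res.pattern_truth = ann, truth, pattern_truth

    # 2. reads + spike-ins
    model = ConversionModel(**cfg["conversion"])
    counts, spikes = simulate_study(
        truth, model, cfg["depth"], s_reads, cfg["n_pairs"], cfg["jitter_sd"]
    )

    # 3. QC
    spike_reports = [
        qc.SpikeCounts(
            library_id=sample,
            arm=arm,
            counts={
                r["class"]: (int(r["unconverted"]), int(r["total"]))
                for _, r in tab.iterrows()
            },
        )
        for sample, arms in spikes.items()
        for arm, tab in arms.items()
    ]
    res.conversion_report = qc.summarize_conversion(spike_reports)
    genome_size = sum(ann.chrom_sizes.values())
    depth_rows = [
        {
            "library_id": sample,
            "arm": arm,
            "depth": tab["total"].sum() / (len(tab) or 1),
        }
        for sample, arms in counts.items()
        for arm, tab in arms.items()
    ]
    res.depth_report = qc.depth_summary(pd.DataFrame(depth_rows))

    # 4. per-sample joint estimation (conversion-corrected)
    min_cov = cfg["min_cov"]
    estimates = {
        sample: mlml.estimate_track(
            arms["bs"], arms["ox"], min_cov=min_cov, model=model, sample_id=sample
        )
        for sample, arms in counts.items()
    }
    res.estimates = estimates

    # 5. site x sample matrices on the common site set
    samples = sorted(estimates, key=lambda s: (s[0] != "T", s))
    beta_m = beta_h = None
    for sample in samples:
        est = estimates[sample][["chrom", "pos", "p_m", "p_h"]].rename(
            columns={"p_m": f"m::{sample}", "p_h": f"h::{sample}"}
        )
        beta_m = est if beta_m is None else beta_m.merge(est, on=["chrom", "pos"])
    mat = beta_m
    res.beta_m = mat[["chrom", "pos"] + [f"m::{s}" for s in samples]].rename(
        columns={f"m::{s}": s for s in samples}
    )
    res.beta_h = mat[["chrom", "pos"] + [f"h::{s}" for s in samples]].rename(
        columns={f"h::{s}": s for s in samples}
    )
    groups = {
        "tumor": [s for s in samples if s.startswith("T")],
        "normal": [s for s in samples if s.startswith("N")],
    }
    res.groups = groups

    # 6. differential regions
    res.regions_m = dmr.call_regions(res.beta_m, groups, "m")
    res.regions_h = dmr.call_regions(res.beta_h, groups, "h")

    # 7. promoter intersection + feature enrichment
    promoters = ann.promoters()
    res.promoter_m = dmr.intersect_promoters(res.regions_m, promoters)
    res.promoter_h = dmr.intersect_promoters(res.regions_h, promoters)
    features = ann.feature_intervals()
    if len(res.regions_m):
        universe = pd.concat([res.regions_m, res.regions_h], ignore_index=True)
        res.enrichment_m = annotate_mod.enrichment(res.regions_m, features, universe)

    # 8. expression + integration
    gene_lengths = (ann.genes.set_index("gene_id")["end"] - ann.genes.set_index("gene_id")["start"]).astype(float)
    expr = simulate_expression(
        list(ann.genes["gene_id"]),
        pattern_truth,
        EffectSpec(**cfg["effects"]) if cfg["effects"] else EffectSpec(),
        seed=s_expr,
        n_pairs=cfg["n_pairs"],
        gene_lengths=gene_lengths,
    )
    res.expression = expr
    expressed = integrate.filter_expressed(expr)
    pm_tab = res.promoter_m[res.promoter_m["gene_id"].isin(expressed)]
    ph_tab = res.promoter_h[res.promoter_h["gene_id"].isin(expressed)]
    classes = integrate.classify_promoters(pm_tab, ph_tab)
    res.classes = classes
    fc = integrate.gene_log2fc(expr)
    res.summary = integrate.pattern_summary(classes, fc)
    res.comparisons = integrate.compare_pattern_expression(classes, fc)
    res.strata = integrate.stratify_by_5hmc(classes, expr)
    res.top_up = integrate.select_top_genes(classes, fc, "up")
    res.top_down = integrate.select_top_genes(classes, fc, "down")
    if res.top_up:
        res.scores_up = integrate.signature_score(expr.tpm, res.top_up)
    if res.top_down:
        res.scores_down = integrate.signature_score(expr.tpm, res.top_down)

    if outdir is not None:
        _write_outputs(res, outdir, counts, spikes)
    return res


def region_recovery(
    called: pd.DataFrame, truth: TrueMethylome, modality: str
) -> dict[str, float]:
    """Sensitivity/precision of called regions against the implant truth
    table (same modality and direction, >= 1 bp overlap)."""
    implanted = truth.implanted_regions
    implanted = implanted[implanted["modality"] == modality]
    calls_ = called[called["modality"] == modality] if len(called) else called
    hit_truth = 0
    for t in implanted.itertuples():
        ok = (
            (calls_["chrom"] == t.chrom)
            & (calls_["start"] < t.end)
            & (calls_["end"] > t.start)
            & (calls_["direction"] == t.direction)
        )
        hit_truth += int(ok.any())
    hit_calls = 0
    for c in calls_.itertuples():
        ok = (
            (implanted["chrom"] == c.chrom)
            & (implanted["start"] < c.end)
            & (implanted["end"] > c.start)
            & (implanted["direction"] == c.direction)
        )
        hit_calls += int(ok.any())
    return {
        "n_truth": int(len(implanted)),
        "n_called": int(len(calls_)),
        "sensitivity": hit_truth / len(implanted) if len(implanted) else float("nan"),
        "precision": hit_calls / len(calls_) if len(calls_) else float("nan"),
    }


def _write_outputs(res: RunResult, outdir, counts, spikes) -> None:
    from .io import ensure_dir, write_expression, write_site_counts, write_spikes

    out = ensure_dir(outdir)
    sim = ensure_dir(out / "sim")
    for sample, arms in counts.items():
        for arm, tab in arms.items():
            write_site_counts(tab, sim / f"{sample}.{arm}.counts.tsv")
            write_spikes(spikes[sample][arm], sim / f"{sample}.{arm}.spikes.tsv")
    res.truth.implanted_regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    res.annotation.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    res.conversion_report.to_csv(out / "conversion_report.tsv", sep="\t", index=False)
    res.depth_report.to_csv(out / "depth_report.tsv", sep="\t", index=False)
    for sample, est in res.estimates.items():
        est.to_csv(out / f"{sample}.mlml.tsv", sep="\t", index=False)
    res.regions_m.to_csv(out / "dmr.tsv", sep="\t", index=False)
    res.regions_h.to_csv(out / "dhmr.tsv", sep="\t", index=False)
    res.promoter_m.to_csv(out / "p_dmr.tsv", sep="\t", index=False)
    res.promoter_h.to_csv(out / "p_dhmr.tsv", sep="\t", index=False)
    if res.enrichment_m is not None:
        res.enrichment_m.to_csv(out / "enrichment_m.tsv", sep="\t", index=False)
    write_expression(res.expression.counts, out / "expression_counts.tsv")
    write_expression(res.expression.tpm, out / "expression_tpm.tsv")
    res.classes.to_csv(out / "promoter_classes.tsv", sep="\t", index=False)
    pd.Series(res.summary).to_csv(out / "pattern_summary.tsv", sep="\t", header=False)
    res.comparisons.to_csv(out / "pattern_comparisons.tsv", sep="\t", index=False)
    res.strata.to_csv(out / "strata.tsv", sep="\t", index=False)
    pd.Series(res.top_up, name="gene_id").to_csv(out / "top_upregulated.tsv", sep="\t", index=False)
    pd.Series(res.top_down, name="gene_id").to_csv(out / "top_downregulated.tsv", sep="\t", index=False)
    if res.scores_up is not None:
        res.scores_up.to_csv(out / "signature_scores_up.tsv", sep="\t", index=False)
    if res.scores_down is not None:
        res.scores_down.to_csv(out / "signature_scores_down.tsv", sep="\t", index=False)
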