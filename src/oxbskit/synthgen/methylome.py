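"""True per-CpG methylome with implanted differential regions.

Baseline 5mC is bimodal (low in/near CpG islands and promoters, high in
background); 5hmC is low everywhere (mean ~0.05).  An implant re-levels a
region so that per site tumor = normal + delta exactly, which makes the
group mean difference equal the requested delta by construction while the
(p_m, p_h, p_u) simplex is preserved in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ToyAnnotation

__all__ = ["TrueMethylome", "ImplantSpec", "MethylomeConfig", "generate_true_methylome"]

GROUPS = ("tumor", "normal")


class InfeasibleImplantError(ValueError):
    pass


@dataclass(frozen=True)
class ImplantSpec:
    chrom: str
    start: int
    end: int
    delta: float
    modality: str  # "m" or "h"
    gene_id: str | None = None
    # floor for the re-leveled normal-group base inside the region; lifting
    # low-5hmC regions onto a real base keeps small swings detectable
    min_base: float = 0.0

    def __post_init__(self):
        if self.modality not in ("m", "h"):
            raise ValueError(f"modality must be 'm' or 'h', got {self.modality!r}")


@dataclass
class MethylomeConfig:
    spacing_range: tuple[int, int] = (20, 60)
    # Beta(a, b) parameters for baseline levels
    low_m: tuple[float, float] = (0.6, 8.0)     # CGI / promoter 5mC, mean ~0.07
    high_m: tuple[float, float] = (10.0, 1.8)   # background 5mC, mean ~0.85
    base_h: tuple[float, float] = (2.0, 38.0)   # 5hmC, mean 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "MethylomeConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown methylome config key: {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(getattr(cfg, k), tuple) else v)
        return cfg


@dataclass
class TrueMethylome:
    sites: pd.DataFrame                      # chrom, pos (CpG dyad start)
    p_m: dict[str, np.ndarray]               # group -> per-site 5mC fraction
    p_h: dict[str, np.ndarray]               # group -> per-site 5hmC fraction
    implanted_regions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        for g in GROUPS:
            pm, ph = self.p_m[g], self.p_h[g]
            if (pm < 0).any() or (ph < 0).any() or (pm + ph > 1 + 1e-12).any():
                raise ValueError(f"simplex violated in group {g!r}")

    def site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        s = self.sites
        return ((s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] < end)).values


def _in_intervals(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].values
    chrom = sites["chrom"].values
    for iv in intervals.itertuples():
        mask |= (chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)
    return mask


def generate_true_methylome(
    ann: ToyAnnotation,
    dmr_spec: list[ImplantSpec],
    seed: int,
    config: MethylomeConfig | dict | None = None,
) -> TrueMethylome:
    if config is None:
        config = MethylomeConfig()
    elif isinstance(config, dict):
        config = MethylomeConfig.from_dict(config)
    rng = np.random.default_rng(seed)

    chroms, positions = [], []
    for chrom in sorted(ann.chrom_sizes):
        size = ann.chrom_sizes[chrom]
        n_max = size // config.spacing_range[0] + 2
        gaps = rng.integers(*config.spacing_range, size=n_max, endpoint=True)
        pos = np.cumsum(gaps)
        pos = pos[pos < size - 1]
        chroms.extend([chrom] * len(pos))
        positions.append(pos)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.concatenate(positions)})
    n = len(sites)

    low_regions = pd.concat(
        [ann.cgis, ann.promoters()[["chrom", "start", "end"]]], ignore_index=True
    )
    low_mask = _in_intervals(sites, low_regions)

    pm = np.where(
        low_mask,
        rng.beta(*config.low_m, size=n),
        rng.beta(*config.high_m, size=n),
    )
    ph = rng.beta(*config.base_h, size=n)
    ph = np.minimum(ph, (1.0 - pm) * 0.9)

    # make room for requested 5hmC swings: cap p_m inside h-implant regions
    # so the implant itself stays a pure 5hmC change
    for spec in dmr_spec:
        if spec.modality != "h":
            continue
        mask = (
            (sites["chrom"] == spec.chrom)
            & (sites["pos"] >= spec.start)
            & (sites["pos"] < spec.end)
        ).values
        # keep p_m low enough that p_m + p_h stays clear of 1 even in the
        # lifted group; saturation near 1 truncates the BS signal
        room = abs(spec.delta) + spec.min_base + 3 * _PAD + 0.2
        pm[mask] = np.minimum(pm[mask], 1.0 - room)

    truth = TrueMethylome(
        sites=sites,
        p_m={"tumor": pm.copy(), "normal": pm.copy()},
        p_h={"tumor": ph.copy(), "normal": ph.copy()},
    )

    rows = []
    for spec in dmr_spec:
        n_cpg = _apply_implant(truth, spec)
        rows.append(
            {
                "chrom": spec.chrom,
                "start": spec.start,
                "end": spec.end,
                "modality": spec.modality,
                "delta": spec.delta,
                "direction": "up" if spec.delta > 0 else "down",
                "n_cpg": n_cpg,
                "gene_id": spec.gene_id,
            }
        )
    truth.implanted_regions = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "modality", "delta", "direction", "n_cpg", "gene_id"],
    )
    truth.validate()
    return truth


_PAD = 0.02


def _apply_implant(truth: TrueMethylome, spec: ImplantSpec) -> int:
    mask = truth.site_mask(spec.chrom, spec.start, spec.end)
    n_cpg = int(mask.sum())
    if n_cpg == 0:
        raise InfeasibleImplantError(
            f"implant {spec.chrom}:{spec.start}-{spec.end} covers no CpG site"
        )
    if spec.modality == "m":
        target, other = truth.p_m, truth.p_h
    else:
        target, other = truth.p_h, truth.p_m
    # room left by the other mark, across both groups
    lim = 1.0 - np.maximum(other["tumor"][mask], other["normal"][mask])
    lo = max(0.0, -spec.delta)
    hi = float(np.min(lim)) - max(0.0, spec.delta)
    if hi <= lo:
        raise InfeasibleImplantError(
            f"implant {spec.chrom}:{spec.start}-{spec.end} delta={spec.delta} "
            f"leaves the (p_m, p_h) simplex"
        )
    pad = min(_PAD, (hi - lo) / 4.0)
    # lo + min_base puts the LOWER of the two group levels at min_base
    floor = min(lo + max(pad, spec.min_base), hi - pad)
    normal_vals = np.clip(target["normal"][mask], floor, hi - pad)
    target["normal"][mask] = normal_vals
    target["tumor"][mask] = normal_vals + spec.delta
    return n_cpg
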