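"""Binomial read-count simulation for BS and oxBS library arms.

Per site and arm the probability that a read stays unconverted is

    bs:  (p_m + p_h) * (1 - e_m) + (1 - p_m - p_h) * (1 - c_bs)
    ox:  p_m * (1 - e_m) + p_h * (1 - c_ox) + (1 - p_m - p_h) * (1 - c_bs)

with c_bs the bisulfite conversion rate of unmodified C, c_ox the oxidative
conversion rate of 5hmC, and e_m the inappropriate conversion rate of 5mC
(5hmC behaves like 5mC under plain bisulfite).  Spike-in duplexes of pure
class C / 5mC / 5hmC / 5fC are simulated from the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome import TrueMethylome

__all__ = ["ConversionModel", "simulate_library", "simulate_spikes", "simulate_study"]

ARMS = ("bs", "ox")
SPIKE_CLASSES = ("C", "5mC", "5hmC", "5fC")


@dataclass(frozen=True)
class ConversionModel:
    """Conversion rates per protocol arm; defaults match the spike-in regime."""

    c_bs: float = 0.993   # conversion of unmodified C
    c_ox: float = 0.965   # oxidative conversion of 5hmC (ox arm)
    e_m: float = 0.035    # false conversion of 5mC (and of 5hmC under plain BS)
    c_f_bs: float = 0.595  # conversion of 5fC, BS arm
    c_f_ox: float = 0.922  # conversion of 5fC, ox arm

    def __post_init__(self):
        for name in ("c_bs", "c_ox", "e_m", "c_f_bs", "c_f_ox"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def unconverted_prob(self, p_m: np.ndarray, p_h: np.ndarray, arm: str) -> np.ndarray:
        p_u = 1.0 - p_m - p_h
        if arm == "bs":
            return (p_m + p_h) * (1.0 - self.e_m) + p_u * (1.0 - self.c_bs)
        if arm == "ox":
            return (
                p_m * (1.0 - self.e_m)
                + p_h * (1.0 - self.c_ox)
                + p_u * (1.0 - self.c_bs)
            )
        raise ValueError(f"arm must be 'bs' or 'ox', got {arm!r}")

    def spike_unconverted_prob(self, klass: str, arm: str) -> float:
        if arm not in ARMS:
            raise ValueError(f"arm must be 'bs' or 'ox', got {arm!r}")
        if klass == "C":
            return 1.0 - self.c_bs
        if klass == "5mC":
            return 1.0 - self.e_m
        if klass == "5hmC":
            return 1.0 - self.e_m if arm == "bs" else 1.0 - self.c_ox
        if klass == "5fC":
            return 1.0 - (self.c_f_bs if arm == "bs" else self.c_f_ox)
        raise ValueError(f"unknown spike class {klass!r}")


def _jittered(truth: TrueMethylome, group: str, jitter_sd: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample true levels: group truth plus small biological noise."""
    pm = truth.p_m[group].copy()
    ph = truth.p_h[group].copy()
    if jitter_sd > 0:
        pm = pm + rng.normal(0.0, jitter_sd, size=pm.shape)
        ph = ph + rng.normal(0.0, jitter_sd / 2.0, size=ph.shape)
        pm = np.clip(pm, 0.0, 1.0)
        ph = np.clip(ph, 0.0, 1.0)
        over = pm + ph - 1.0
        scale = np.where(over > 0, 1.0 / (pm + ph + 1e-12), 1.0)
        pm, ph = pm * scale, ph * scale
    return pm, ph


def simulate_library(
    truth: TrueMethylome,
    model: ConversionModel,
    arm: str,
    depth: float,
    seed: int,
    group: str = "normal",
    jitter_sd: float = 0.0,
    sample_levels: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Simulate one library arm: per-CpG (unconverted, total) read counts.

    Coverage is Poisson(depth) per site.  ``sample_levels`` allows paired
    BS/ox arms of one sample to share the same jittered true levels.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    if sample_levels is None:
        pm, ph = _jittered(truth, group, jitter_sd, rng)
    else:
        pm, ph = sample_levels
    q = model.unconverted_prob(pm, ph, arm)
    n = rng.poisson(depth, size=len(q))
    k = rng.binomial(n, q)
    out = truth.sites.copy()
    out["strand"] = "+"
    out["unconverted"] = k
    out["total"] = n
    return out


def simulate_spikes(
    model: ConversionModel,
    arm: str,
    depth: float,
    seed: int,
    n_positions: int = 500,
) -> pd.DataFrame:
    """Aggregate spike-in counts per modification class for one library."""
    rng = np.random.default_rng(seed)
    rows = []
    for klass in SPIKE_CLASSES:
        q = model.spike_unconverted_prob(klass, arm)
        n = rng.poisson(depth, size=n_positions)
        k = rng.binomial(n, q)
        rows.append((klass, int(k.sum()), int(n.sum())))
    return pd.DataFrame(rows, columns=["class", "unconverted", "total"])


def simulate_study(
    truth: TrueMethylome,
    model: ConversionModel,
    depth: float,
    seed: int,
    n_pairs: int = 4,
    jitter_sd: float = 0.01,
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, dict[str, pd.DataFrame]]]:
    """Simulate paired BS/ox libraries for ``n_pairs`` tumor/normal pairs.

    Returns (counts, spikes), each keyed as [sample_id][arm]; sample ids are
    T1..Tn and N1..Nn.
    """
    ss = np.random.SeedSequence(seed)
    counts: dict[str, dict[str, pd.DataFrame]] = {}
    spikes: dict[str, dict[str, pd.DataFrame]] = {}
    for group, prefix in (("tumor", "T"), ("normal", "N")):
        for i in range(1, n_pairs + 1):
            sample = f"{prefix}{i}"
            child = ss.spawn(1)[0]
            lvl_seed, bs_seed, ox_seed, sp_bs, sp_ox = child.spawn(5)
            lvl_rng = np.random.default_rng(lvl_seed)
            levels = _jittered(truth, group, jitter_sd, lvl_rng)
            counts[sample] = {
                "bs": simulate_library(
                    truth, model, "bs", depth,
                    np.random.default_rng(bs_seed).integers(2**31),
                    sample_levels=levels,
                ),
                "ox": simulate_library(
                    truth, model, "ox", depth,
                    np.random.default_rng(ox_seed).integers(2**31),
                    sample_levels=levels,
                ),
            }
            spikes[sample] = {
                "bs": simulate_spikes(
                    model, "bs", depth, np.random.default_rng(sp_bs).integers(2**31)
                ),
                "ox": simulate_spikes(
                    model, "ox", depth, np.random.default_rng(sp_ox).integers(2**31)
                ),
            }
    return counts, spikes
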