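"""Joint 5mC/5hmC estimation from paired BS and oxBS counts.

The model: the BS unconverted fraction estimates p_m + p_h and the oxBS
unconverted fraction estimates p_m.  The constrained maximum of
Binom(k_bs; n_bs, p_m + p_h) * Binom(k_ox; n_ox, p_m) over the probability
simplex has a closed form: the naive subtraction when it is feasible, and
otherwise the boundary p_h = 0 with the pooled estimate
p_m = (k_bs + k_ox) / (n_bs + n_ox), flagged as a conflict.

With a ConversionModel the binomial success probabilities are replaced by
the conversion-adjusted forms and inverted, which de-biases recovery on
simulated data; both arms then share the success probability
(1 - c_bs) + p * (c_bs - e_m) on the p_h = 0 boundary, so the pooled
inversion remains the exact constrained maximum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthgen.reads import ConversionModel

__all__ = ["estimate_site", "estimate_track", "occupancy_summary"]


def _estimate_arrays(
    k_bs: np.ndarray,
    n_bs: np.ndarray,
    k_ox: np.ndarray,
    n_ox: np.ndarray,
    model: ConversionModel | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    f_bs = k_bs / n_bs
    f_ox = k_ox / n_ox
    pooled = (k_bs + k_ox) / (n_bs + n_ox)
    if model is None:
        s_hat = f_bs           # p_m + p_h
        m_hat = f_ox           # p_m
        pooled_m = pooled
    else:
        base = 1.0 - model.c_bs
        a1 = model.c_bs - model.e_m
        a2 = model.c_ox - model.e_m
        s_hat = (f_bs - base) / a1
        # q_ox = base + p_m*a1 + p_h*(c_bs - c_ox)  =>  solve with s = p_m + p_h
        p_h_corr = (base + s_hat * a1 - f_ox) / a2
        m_hat = s_hat - p_h_corr
        pooled_m = (pooled - base) / a1

    p_h = s_hat - m_hat
    p_m = m_hat
    conflict = p_h < 0

    # boundary p_h = 0: pooled estimate of the common level
    p_m = np.where(conflict, pooled_m, p_m)
    p_h = np.where(conflict, 0.0, p_h)

    # residual projections (only reachable with conversion correction)
    neg_m = p_m < 0
    conflict |= neg_m
    p_m = np.where(neg_m, 0.0, p_m)
    p_h = np.where(neg_m, np.clip(s_hat, 0.0, 1.0), p_h)
    over = p_m + p_h > 1.0
    conflict |= over
    p_m_clipped = np.clip(p_m, 0.0, 1.0)
    p_h = np.where(over, 1.0 - p_m_clipped, p_h)
    p_m = p_m_clipped
    return p_m, p_h, conflict


def estimate_site(
    k_bs: int,
    n_bs: int,
    k_ox: int,
    n_ox: int,
    model: ConversionModel | None = None,
) -> tuple[float, float, bool]:
    """Per-site (p_m, p_h, conflict) by constrained maximum likelihood."""
    if n_bs <= 0 or n_ox <= 0:
        raise ValueError("both arms need positive coverage")
    p_m, p_h, conflict = _estimate_arrays(
        np.array([float(k_bs)]),
        np.array([float(n_bs)]),
        np.array([float(k_ox)]),
        np.array([float(n_ox)]),
        model,
    )
    return float(p_m[0]), float(p_h[0]), bool(conflict[0])


def estimate_track(
    bs_counts: pd.DataFrame,
    ox_counts: pd.DataFrame,
    min_cov: int = 10,
    model: ConversionModel | None = None,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Join BS and oxBS count tables on (chrom, pos) and estimate per site.

    Only sites with coverage >= ``min_cov`` in BOTH arms are emitted.  When
    both frames carry a ``sample`` column the ids must agree.
    """
    for df, arm in ((bs_counts, "bs"), (ox_counts, "ox")):
        missing = {"chrom", "pos", "unconverted", "total"} - set(df.columns)
        if missing:
            raise ValueError(f"{arm} counts missing columns {sorted(missing)}")
    if "sample" in bs_counts.columns and "sample" in ox_counts.columns:
        s_bs = set(bs_counts["sample"].unique())
        s_ox = set(ox_counts["sample"].unique())
        if s_bs != s_ox:
            raise ValueError(f"mismatched samples between arms: {s_bs} vs {s_ox}")
    merged = bs_counts.merge(
        ox_counts, on=["chrom", "pos"], suffixes=("_bs", "_ox"), how="inner"
    )
    merged = merged[
        (merged["total_bs"] >= min_cov) & (merged["total_ox"] >= min_cov)
    ]
    if merged.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "p_m", "p_h", "n_bs", "n_ox", "conflict"]
        )
    p_m, p_h, conflict = _estimate_arrays(
        merged["unconverted_bs"].values.astype(float),
        merged["total_bs"].values.astype(float),
        merged["unconverted_ox"].values.astype(float),
        merged["total_ox"].values.astype(float),
        model,
    )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].values,
            "pos": merged["pos"].values,
            "p_m": p_m,
            "p_h": p_h,
            "n_bs": merged["total_bs"].values,
            "n_ox": merged["total_ox"].values,
            "conflict": conflict,
        }
    )
    if sample_id is not None:
        out.insert(0, "sample", sample_id)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def occupancy_summary(estimates: pd.DataFrame, tau: float = 0.0) -> dict[str, float]:
    """Fractions (%) of CpG sites bearing each mark at threshold ``tau``.

    A site bears a mark iff its estimate is strictly greater than tau.
    """
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must be in [0, 1)")
    n = len(estimates)
    if n == 0:
        return {
            "pct_5mc": 0.0,
            "pct_5hmc": 0.0,
            "pct_5mc_with_5hmc": 0.0,
            "pct_5hmc_with_5mc": 0.0,
        }
    has_m = estimates["p_m"].values > tau
    has_h = estimates["p_h"].values > tau
    both = has_m & has_h
    return {
        "pct_5mc": 100.0 * has_m.mean(),
        "pct_5hmc": 100.0 * has_h.mean(),
        "pct_5mc_with_5hmc": 100.0 * both.sum() / has_m.sum() if has_m.any() else 0.0,
        "pct_5hmc_with_5mc": 100.0 * both.sum() / has_h.sum() if has_h.any() else 0.0,
    }
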