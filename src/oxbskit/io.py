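"""Plain-text readers/writers for the pipeline's tabular formats.

Everything is tab-separated.  CpG positions are written 0-based (bedGraph
dialect: chrom, start, end = start + 2); set ``one_based=True`` to shift
on-disk positions by one.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_site_counts",
    "write_site_counts",
    "read_beta_track",
    "write_beta_track",
    "read_spikes",
    "write_spikes",
    "read_expression",
    "write_expression",
    "write_bed",
    "load_config",
]


def write_site_counts(df: pd.DataFrame, path, one_based: bool = False) -> None:
    out = df[["chrom", "pos", "strand", "unconverted", "total"]].copy()
    if one_based:
        out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_site_counts(path, one_based: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if one_based:
        df["pos"] = df["pos"] - 1
    return df


def write_beta_track(track: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["pos"],
            "end": track["pos"] + 2,
            "beta": track["beta"],
            "coverage": track["coverage"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_beta_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "beta": df["beta"],
            "coverage": df["coverage"],
        }
    )


def write_spikes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spikes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
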