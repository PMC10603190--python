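"""Toy genome annotation: chromosomes, gene models, CpG islands.

All coordinates are 0-based, half-open.  Gene models are laid out left to
right along each chromosome with randomized gaps so that gene loci (and the
promoters carved out of the upstream gaps) never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ToyAnnotation", "AnnotationConfig", "generate_annotation"]


class SizingError(ValueError):
    """Requested gene span does not fit on the configured chromosomes."""


@dataclass
class AnnotationConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_genes: int = 200
    gene_len_range: tuple[int, int] = (2_000, 6_000)
    gap_range: tuple[int, int] = (1_500, 4_000)
    promoter_size: int = 1_000
    utr_size: int = 200
    exon_count_range: tuple[int, int] = (2, 5)
    cgi_promoter_frac: float = 0.6
    n_intergenic_cgis: int = 10
    cgi_len_range: tuple[int, int] = (300, 1_000)

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown annotation config key: {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, tuple):
                v = tuple(v)
            setattr(cfg, k, v)
        return cfg


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "tts"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end"]
CGI_COLUMNS = ["chrom", "start", "end"]


@dataclass
class ToyAnnotation:
    """Genome annotation for the synthetic study.

    genes/exons/cgis are data frames with 0-based half-open intervals.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    exons: pd.DataFrame
    cgis: pd.DataFrame
    promoter_size: int = 1_000
    utr_size: int = 200

    def promoters(self) -> pd.DataFrame:
        """Promoter intervals, [TSS - promoter_size, TSS) on the gene strand."""
        rows = []
        for g in self.genes.itertuples():
            if g.strand == "+":
                start, end = g.tss - self.promoter_size, g.tss
            else:
                start, end = g.tss, g.tss + self.promoter_size
            size = self.chrom_sizes[g.chrom]
            rows.append((g.gene_id, g.chrom, max(0, start), min(size, end)))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def gene_bodies(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "start", "end", "strand"]].copy()

    def feature_intervals(self) -> dict[str, pd.DataFrame]:
        """Interval tables per feature class.

        promoter / 5utr / exon / intron / 3utr partition each gene locus
        (with the promoter adjoining it); gene_body, cgi, cgi_shore and
        cgi_shelf are additional overlapping tracks.
        """
        utr5, utr3, exon, intron = [], [], [], []
        for gid, sub in self.exons.groupby("gene_id", sort=True):
            sub = sub.sort_values("start")
            chrom = sub["chrom"].iloc[0]
            strand = self.genes.set_index("gene_id").at[gid, "strand"]
            ivs = list(zip(sub["start"], sub["end"]))
            # introns: gaps between consecutive exons
            for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
                if s1 > e0:
                    intron.append((chrom, e0, s1))
            first, last = ivs[0], ivs[-1]
            if strand == "+":
                u5 = (chrom, first[0], min(first[1], first[0] + self.utr_size))
                u3 = (chrom, max(last[0], last[1] - self.utr_size), last[1])
            else:
                u5 = (chrom, max(last[0], last[1] - self.utr_size), last[1])
                u3 = (chrom, first[0], min(first[1], first[0] + self.utr_size))
            utr5.append(u5)
            utr3.append(u3)
            utr_ivs = {u5[1:], u3[1:]}
            for s, e in ivs:
                # strip the UTR bp off the terminal exons so the features
                # partition the locus
                for us, ue in sorted(utr_ivs):
                    if us <= s < ue:
                        s = min(ue, e)
                    if us < e <= ue:
                        e = max(us, s)
                if e > s:
                    exon.append((chrom, s, e))

        def df(rows):
            return pd.DataFrame(rows, columns=CGI_COLUMNS)

        shores, shelves = self._cgi_flanks()
        return {
            "promoter": self.promoters()[CGI_COLUMNS],
            "5utr": df(utr5),
            "exon": df(exon),
            "intron": df(intron),
            "3utr": df(utr3),
            "gene_body": self.genes[CGI_COLUMNS].copy(),
            "cgi": self.cgis.copy(),
            "cgi_shore": shores,
            "cgi_shelf": shelves,
        }

    def _cgi_flanks(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        shore_rows, shelf_rows = [], []
        for c in self.cgis.itertuples():
            size = self.chrom_sizes[c.chrom]
            shore_rows.append((c.chrom, max(0, c.start - 2_000), c.start))
            shore_rows.append((c.chrom, c.end, min(size, c.end + 2_000)))
            shelf_rows.append((c.chrom, max(0, c.start - 4_000), max(0, c.start - 2_000)))
            shelf_rows.append((c.chrom, min(size, c.end + 2_000), min(size, c.end + 4_000)))
        shore = pd.DataFrame(shore_rows, columns=CGI_COLUMNS)
        shelf = pd.DataFrame(shelf_rows, columns=CGI_COLUMNS)
        return shore[shore.start < shore.end], shelf[shelf.start < shelf.end]

    def validate(self) -> None:
        for name, tab in (("genes", self.genes), ("exons", self.exons), ("cgis", self.cgis)):
            for row in tab.itertuples():
                if row.start < 0 or row.end > self.chrom_sizes[row.chrom] or row.start >= row.end:
                    raise ValueError(f"invalid interval in {name}: {row}")
        # genes on the same chromosome must not overlap
        for _, sub in self.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError("overlapping gene loci")


def generate_annotation(config: AnnotationConfig | dict, seed: int) -> ToyAnnotation:
    """Generate a deterministic toy annotation for a given seed."""
    if isinstance(config, dict):
        config = AnnotationConfig.from_dict(config)
    for chrom, size in config.chrom_sizes.items():
        if size < 10_000:
            raise SizingError(f"chromosome {chrom} shorter than 10 kb")
    rng = np.random.default_rng(seed)

    chroms = sorted(config.chrom_sizes)
    gene_rows, exon_rows, cgi_rows = [], [], []
    margin = config.promoter_size + 200

    if config.n_genes > 0:
        per_chrom = _split_counts(config.n_genes, len(chroms))
        gid = 0
        for chrom, count in zip(chroms, per_chrom):
            size = config.chrom_sizes[chrom]
            cursor = margin
            for _ in range(count):
                glen = int(rng.integers(*config.gene_len_range, endpoint=True))
                gap = int(rng.integers(*config.gap_range, endpoint=True))
                start = cursor + gap
                end = start + glen
                if end + margin > size:
                    raise SizingError(
                        f"requested gene span exceeds {chrom} length {size}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                tss, tts = (start, end) if strand == "+" else (end, start)
                gene_id = f"G{gid:04d}"
                gid += 1
                gene_rows.append((gene_id, chrom, start, end, strand, tss, tts))
                exon_rows.extend(_make_exons(gene_id, chrom, start, end, rng, config))
                if rng.random() < config.cgi_promoter_frac:
                    clen = int(rng.integers(*config.cgi_len_range, endpoint=True))
                    cgi_rows.append(
                        (chrom, max(0, tss - clen // 2), min(size, tss + (clen + 1) // 2))
                    )
                cursor = end

    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        for _ in range(config.n_intergenic_cgis):
            clen = int(rng.integers(*config.cgi_len_range, endpoint=True))
            start = int(rng.integers(0, size - clen))
            cgi_rows.append((chrom, start, start + clen))

    ann = ToyAnnotation(
        chrom_sizes=dict(config.chrom_sizes),
        genes=pd.DataFrame(gene_rows, columns=GENE_COLUMNS),
        exons=pd.DataFrame(exon_rows, columns=EXON_COLUMNS),
        cgis=pd.DataFrame(sorted(cgi_rows), columns=CGI_COLUMNS),
        promoter_size=config.promoter_size,
        utr_size=config.utr_size,
    )
    ann.validate()
    return ann


def _split_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _make_exons(gene_id, chrom, start, end, rng, config) -> list[tuple]:
    n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
    glen = end - start
    n_exons = max(1, min(n_exons, glen // 400))
    # alternate exon/intron blocks of randomized proportions
    weights = rng.uniform(0.5, 1.5, size=2 * n_exons - 1)
    bounds = np.concatenate([[0.0], np.cumsum(weights) / weights.sum()])
    cuts = start + np.rint(bounds * glen).astype(int)
    cuts[-1] = end
    rows = []
    for i in range(n_exons):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if e > s:
            rows.append((gene_id, chrom, s, e))
    return rows
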