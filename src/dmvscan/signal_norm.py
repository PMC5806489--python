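"""Normalization of binned ChIP-seq counts and expression tables.

RPKM: reads per kilobase of bin per million mapped reads. Z-score: subtract
the genome-wide mean RPKM and divide by the genome-wide standard deviation
(population SD, i.e. divide by n — fixed here for reproducibility). Quantile
normalization maps every sample onto the mean sorted profile, then log2 with
a pseudocount.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import ExpressionMatrix, GenomeLayout

__all__ = ["SignalTrack", "rpkm", "zscore", "quantile_normalize", "quantile_normalize_log"]


@dataclass
class SignalTrack:
    """Fixed-width binned signal: per-chromosome value arrays plus an
    optional boolean `covered` mask (bins with usable data); values on
    uncovered bins are ignored by genome-wide statistics when
    covered_only is requested."""

    width: int
    layout: GenomeLayout
    values: dict[str, np.ndarray]
    covered: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for chrom, vals in self.values.items():
            expect = -(-self.layout[chrom] // self.width)
            if len(vals) != expect:
                raise ValueError(f"{chrom}: {len(vals)} bins, expected {expect}")

    def mask(self, chrom: str) -> np.ndarray:
        if self.covered is None:
            return np.ones(len(self.values[chrom]), dtype=bool)
        return self.covered[chrom]

    def flat(self, covered_only: bool = True) -> np.ndarray:
        parts = [
            self.values[c][self.mask(c)] if covered_only else self.values[c]
            for c in self.values
        ]
        return np.concatenate(parts) if parts else np.empty(0)

    def with_values(self, values: dict[str, np.ndarray]) -> "SignalTrack":
        return SignalTrack(self.width, self.layout, values, self.covered)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, vals in self.values.items():
                clen = self.layout[chrom]
                m = self.mask(chrom)
                for i in np.flatnonzero(m):
                    start = int(i) * self.width
                    fh.write(f"{chrom}\t{start}\t{min(start + self.width, clen)}\t{vals[i]:.6g}\n")


def rpkm(track: SignalTrack, total_mapped_reads: int) -> SignalTrack:
    """count / ((bin width / 1000) * (total mapped reads / 1e6)) per bin."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    scale = (track.width / 1000.0) * (total_mapped_reads / 1e6)
    return track.with_values({c: v / scale for c, v in track.values.items()})


def zscore(track: SignalTrack, covered_only: bool = True) -> SignalTrack:
    """Genome-wide Z-score; error on constant tracks or < 2 bins.

    Uses the population SD over covered bins (all bins with
    covered_only=False); uncovered bins are transformed with the same
    affine map but excluded from the statistics.
    """
    flat = track.flat(covered_only=covered_only)
    if flat.size < 2:
        raise ValueError("need at least 2 bins for a Z-score")
    mu = float(flat.mean())
    sd = float(flat.std())  # population SD (ddof=0)
    if sd == 0:
        raise ValueError("constant track: Z-score undefined")
    return track.with_values({c: (v - mu) / sd for c, v in track.values.items()})


def quantile_normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization: every column is mapped onto the mean
    of the sorted columns; ties receive the average of the reference values
    at their tied ranks.
    """
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if frame.isna().any().any():
        raise ValueError("gene sets differ across samples (missing values present)")
    n = len(frame)
    reference = np.sort(frame.to_numpy(), axis=0).mean(axis=1)
    ranks = frame.rank(method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def quantile_normalize_log(
    expr: ExpressionMatrix | pd.DataFrame,
    pseudocount: float = 1.0,
) -> ExpressionMatrix | pd.DataFrame:
    """Quantile-normalize then log2(x + pseudocount); preserves the input type."""
    frame = expr.fpkm if isinstance(expr, ExpressionMatrix) else expr
    out = np.log2(quantile_normalize(frame) + pseudocount)
    if isinstance(expr, ExpressionMatrix):
        return ExpressionMatrix(out, expr.sample_lineage.to_dict())
    return out
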