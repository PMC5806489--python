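"""Fixed-width binned methylation tracks with the coverage filter applied.

Methylation in a bin is coverage-weighted: (sum methylated) / (sum total)
over all CpGs in the bin ("methylated CpG versus total CpG"), not the mean
of per-site ratios. Bins whose summed CpG read coverage falls below
`min_total_coverage` — the same >=5 filter used for the 200-bp QC bins —
or that contain no CpG are missing (NaN).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genomic_io import GenomeLayout, MethylCalls

__all__ = ["BinnedTrack", "bin_methylation", "mean_methylation", "cg_density"]

#: defaults used throughout: 200-bp QC bins and the 1-kb DMV-caller track,
#: both requiring summed CpG coverage >= 5.
QC_BIN_WIDTH = 200
DMV_BIN_WIDTH = 1000
MIN_BIN_COVERAGE = 5


def n_bins(chrom_len: int, width: int) -> int:
    return -(-chrom_len // width)  # ceil division


@dataclass
class BinnedTrack:
    """Per-chromosome arrays of bin methylation with supporting counts.

    values[chrom][i] is the methylation of bin [i*width, (i+1)*width) or NaN
    if missing; meth/total carry the summed read counts so region means can
    stay coverage-weighted.
    """

    width: int
    layout: GenomeLayout
    values: dict[str, np.ndarray]
    meth: dict[str, np.ndarray]
    total: dict[str, np.ndarray]

    def covered(self, chrom: str) -> np.ndarray:
        return ~np.isnan(self.values[chrom])

    def n_covered_bins(self) -> int:
        return int(sum(self.covered(c).sum() for c in self.values))

    def to_bedgraph(self, path: str | Path) -> None:
        """Write covered bins as bedGraph (missing bins omitted)."""
        with open(path, "w") as fh:
            for chrom, vals in self.values.items():
                clen = self.layout[chrom]
                for i in np.flatnonzero(~np.isnan(vals)):
                    start = int(i) * self.width
                    fh.write(f"{chrom}\t{start}\t{min(start + self.width, clen)}\t{vals[i]:.6g}\n")


def bin_methylation(
    calls: MethylCalls,
    layout: GenomeLayout,
    width: int = DMV_BIN_WIDTH,
    min_total_coverage: int = MIN_BIN_COVERAGE,
) -> BinnedTrack:
    """Aggregate per-CpG counts into fixed-width bins.

    Bin value = sum(meth) / sum(total) over the bin's CpGs; bins with no
    CpG or summed total below `min_total_coverage` are NaN. The last,
    possibly partial, bin of each chromosome is kept.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if min_total_coverage < 0:
        raise ValueError("min_total_coverage must be >= 0")
    values: dict[str, np.ndarray] = {}
    meths: dict[str, np.ndarray] = {}
    totals: dict[str, np.ndarray] = {}
    for chrom in calls.chroms:
        if chrom not in layout:
            raise ValueError(f"chromosome {chrom!r} absent from genome layout")
    for chrom in layout.chroms:
        nb = n_bins(layout[chrom], width)
        pos, meth, total = calls.sites(chrom)
        idx = pos // width
        m = np.bincount(idx, weights=meth, minlength=nb)
        t = np.bincount(idx, weights=total, minlength=nb)
        n = np.bincount(idx, minlength=nb)
        ok = (n > 0) & (t > 0) & (t >= min_total_coverage)
        values[chrom] = np.where(ok, m / np.maximum(t, 1), np.nan)
        meths[chrom] = m.astype(np.int64)
        totals[chrom] = t.astype(np.int64)
    return BinnedTrack(width=width, layout=layout, values=values, meth=meths, total=totals)


def mean_methylation(obj, chrom: str, start: int, end: int, weighted: bool = True) -> float:
    """Mean methylation of [start, end): coverage-weighted over CpGs for
    MethylCalls, unweighted over covered overlapping bins for a BinnedTrack.

    Returns NaN when nothing in the region is covered.
    """
    if isinstance(obj, MethylCalls):
        pos, meth, total = obj.sites(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        if hi == lo:
            return float("nan")
        m, t = meth[lo:hi], total[lo:hi]
        if weighted:
            return float(m.sum() / t.sum()) if t.sum() else float("nan")
        ok = t > 0
        return float((m[ok] / t[ok]).mean()) if ok.any() else float("nan")
    if isinstance(obj, BinnedTrack):
        vals = obj.values[chrom]
        lo = start // obj.width
        hi = n_bins(end, obj.width)
        window = vals[lo:hi]
        if weighted:
            m = obj.meth[chrom][lo:hi]
            t = obj.total[chrom][lo:hi]
            cov = ~np.isnan(window)
            return float(m[cov].sum() / t[cov].sum()) if t[cov].sum() else float("nan")
        return float(np.nanmean(window)) if (~np.isnan(window)).any() else float("nan")
    raise TypeError(f"unsupported object {type(obj).__name__}")


def cg_density(positions: np.ndarray, start: int, end: int) -> float:
    """CpG sites per 100 bp in [start, end), counted from a sorted position list."""
    if end <= start:
        raise ValueError("region must have positive length")
    lo, hi = np.searchsorted(np.asarray(positions), [start, end])
    return 100.0 * (hi - lo) / (end - start)
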