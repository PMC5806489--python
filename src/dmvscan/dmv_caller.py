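"""DNA-methylation-valley calling by sliding-window scan and merge.

A 5-kb window slides in 1-kb steps over a 1-kb binned methylation track;
every window whose mean methylation (over covered bins) is below 0.15
qualifies, and the union of overlapping/book-ended qualifying windows forms
the called valleys. All valleys are therefore at least one window long.
Windows with too few covered bins are skipped — they neither qualify nor
break a valley — so CpG deserts cannot seed valleys on their own.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinnedTrack
from .genomic_io import IntervalSet

__all__ = ["DmvRecord", "call_dmvs", "dmv_summary", "dmvs_to_intervalset"]

DEFAULT_WINDOW = 5000
DEFAULT_STEP = 1000
DEFAULT_MAX_METH = 0.15
DEFAULT_MIN_COVERED_BINS = 3


@dataclass(frozen=True)
class DmvRecord:
    chrom: str
    start: int
    end: int
    mean_meth: float
    n_covered_bins: int
    id: str

    @property
    def length(self) -> int:
        return self.end - self.start


def call_dmvs(
    track: BinnedTrack,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_meth: float = DEFAULT_MAX_METH,
    min_covered_bins_per_window: int = DEFAULT_MIN_COVERED_BINS,
    merge_bookended: bool = True,
    weighted_window_mean: bool = False,
) -> list[DmvRecord]:
    """Call DMVs on a binned methylation track.

    A window qualifies when it has >= `min_covered_bins_per_window` covered
    bins and its mean over covered bins (unweighted by default; coverage-
    weighted with `weighted_window_mean`) is strictly below `max_meth`.
    Qualifying windows that overlap — or, with `merge_bookended` (default),
    that touch end-to-start — are merged; each valley spans from the start
    of its first qualifying window to the end of its last. Windows never
    extend past a chromosome end, so tails shorter than one window are not
    scanned, and windows on different chromosomes never merge.
    """
    width = track.width
    if window % width or step % width:
        raise ValueError(f"window ({window}) and step ({step}) must be multiples of the bin width ({width})")
    if not 0 <= max_meth <= 1:
        raise ValueError("max_meth must be in [0, 1]")
    w = window // width
    s = step // width

    records: list[DmvRecord] = []
    for chrom in track.layout.chroms:
        vals = track.values[chrom]
        clen = track.layout[chrom]
        # last start index with the window fully inside the chromosome (bp)
        max_start = (clen - window) // width
        if max_start < 0:
            continue
        starts = np.arange(0, max_start + 1, s)
        if len(starts) == 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(vals, w)[starts]
        ncov = (~np.isnan(windows)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            if weighted_window_mean:
                mw = np.lib.stride_tricks.sliding_window_view(track.meth[chrom].astype(float), w)[starts]
                tw = np.lib.stride_tricks.sliding_window_view(track.total[chrom].astype(float), w)[starts]
                cov = ~np.isnan(windows)
                tsum = (tw * cov).sum(axis=1)
                means = np.where(tsum > 0, (mw * cov).sum(axis=1) / np.maximum(tsum, 1), np.nan)
            else:
                means = np.nansum(windows, axis=1) / np.maximum(ncov, 1)
        qualifies = (ncov >= min_covered_bins_per_window) & (means < max_meth)
        qstarts = starts[qualifies]
        if len(qstarts) == 0:
            continue
        # group qualifying windows into valleys
        if merge_bookended:
            breaks = np.flatnonzero(qstarts[1:] > qstarts[:-1] + w)
        else:
            breaks = np.flatnonzero(qstarts[1:] >= qstarts[:-1] + w)
        group_bounds = np.concatenate([[0], breaks + 1, [len(qstarts)]])
        for lo, hi in zip(group_bounds[:-1], group_bounds[1:]):
            first, last = int(qstarts[lo]), int(qstarts[hi - 1])
            b0, b1 = first, last + w
            region_vals = vals[b0:b1]
            cov = ~np.isnan(region_vals)
            m = int(track.meth[chrom][b0:b1][cov].sum())
            t = int(track.total[chrom][b0:b1][cov].sum())
            records.append(
                DmvRecord(
                    chrom=chrom,
                    start=b0 * width,
                    end=b1 * width,
                    mean_meth=m / t if t else float("nan"),
                    n_covered_bins=int(cov.sum()),
                    id="",
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start))
    return [
        DmvRecord(r.chrom, r.start, r.end, r.mean_meth, r.n_covered_bins, f"DMV{i + 1:05d}")
        for i, r in enumerate(records)
    ]


def dmvs_to_intervalset(dmvs: list[DmvRecord], layout=None) -> IntervalSet:
    return IntervalSet.from_records(
        [(d.chrom, d.start, d.end, d.id, d.mean_meth) for d in dmvs], layout=layout
    )


def dmv_summary(dmvs: list[DmvRecord]) -> pd.Series:
    """Count, length quartiles and genome bp covered, as a Series."""
    lengths = np.array([d.length for d in dmvs], dtype=float)
    if len(lengths) == 0:
        return pd.Series(
            {"count": 0, "total_bp": 0, "length_min": np.nan, "length_q1": np.nan,
             "length_median": np.nan, "length_q3": np.nan, "length_max": np.nan}
        )
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return pd.Series(
        {
            "count": len(lengths),
            "total_bp": int(lengths.sum()),
            "length_min": float(lengths.min()),
            "length_q1": float(q1),
            "length_median": float(med),
            "length_q3": float(q3),
            "length_max": float(lengths.max()),
        }
    )


def write_dmvs(dmvs: list[DmvRecord], bed_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """BED4 of the valleys plus an optional TSV sidecar with the evidence."""
    with open(bed_path, "w") as fh:
        for d in dmvs:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.id}\n")
    if tsv_path is not None:
        pd.DataFrame(
            [
                {"id": d.id, "chrom": d.chrom, "start": d.start, "end": d.end,
                 "length": d.length, "mean_meth": d.mean_meth, "n_covered_bins": d.n_covered_bins}
                for d in dmvs
            ]
        ).to_csv(tsv_path, sep="\t", index=False)
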