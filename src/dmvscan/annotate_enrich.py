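"""Annotation of DMVs against chromatin features, knockout-vs-wild-type
methylation change, transcription-factor site density meta-profiles with
length-matched random controls, and CG-density-stratified score comparison.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genomic_io as gio
from .binning import cg_density
from .genomic_io import GenomeLayout, IntervalSet, MethylCalls

log = logging.getLogger(__name__)

__all__ = [
    "chromatin_state",
    "partition_cgi",
    "methylation_change",
    "MetaProfile",
    "site_density_profile",
    "random_length_matched_controls",
    "control_densities",
    "region_site_density",
    "enrichment_test",
    "stratified_score_compare",
    "overlap_percentage",
]


# ---------------------------------------------------------------------------
# chromatin state


def chromatin_state(
    dmvs: IntervalSet,
    k4_peaks: IntervalSet,
    k27_peaks: IntervalSet,
    polycomb_peaks: IntervalSet | None = None,
) -> pd.DataFrame:
    """Per-DMV state in {K4-only, K27-only, K4+K27, none} by any (>=1 bp)
    overlap, plus a `polycomb` flag for overlap with the Polycomb peak set
    (e.g. EED binding)."""
    k4 = gio.overlaps_any(dmvs, k4_peaks)
    k27 = gio.overlaps_any(dmvs, k27_peaks)
    state = np.where(k4 & k27, "K4+K27", np.where(k4, "K4-only", np.where(k27, "K27-only", "none")))
    ids = [rec.name or f"{rec.chrom}:{rec.start}-{rec.end}" for rec in dmvs]
    out = pd.DataFrame({"state": state}, index=pd.Index(ids, name="id"))
    if polycomb_peaks is not None:
        out["polycomb"] = gio.overlaps_any(dmvs, polycomb_peaks)
    return out


def partition_cgi(dmv, cgis: IntervalSet) -> tuple[IntervalSet, IntervalSet]:
    """Split a valley into its CpG-island and non-CGI parts; the two part
    sets tile the valley exactly."""
    chrom, start, end = gio._record_fields(dmv)
    one = IntervalSet.from_records([(chrom, start, end)])
    return gio.intersect(one, cgis), gio.subtract(one, cgis)


# ---------------------------------------------------------------------------
# KO - WT methylation change


def _parts_mean(calls: MethylCalls, parts: IntervalSet) -> float:
    """Coverage-weighted mean over a set of (disjoint) parts; NaN if no reads."""
    m = t = 0
    for rec in parts:
        dm, dt, _ = calls.region_counts(rec.chrom, rec.start, rec.end)
        m += dm
        t += dt
    return m / t if t else float("nan")


def methylation_change(
    wt_calls: MethylCalls,
    ko_calls: MethylCalls,
    regions: IntervalSet,
    cgis: IntervalSet,
    hyper_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per region: WT and KO coverage-weighted methylation, the change
    delta = KO - WT, the same quantities restricted to the region's CGI and
    non-CGI parts, and a `hypermethylated` flag (delta >= hyper_threshold).

    Regions without coverage in either methylome get NaN and are logged.
    """
    rows = []
    for rec in regions:
        rid = rec.name or f"{rec.chrom}:{rec.start}-{rec.end}"
        whole = IntervalSet.from_records([(rec.chrom, rec.start, rec.end)])
        cgi_parts, noncgi_parts = partition_cgi(rec, cgis)
        row = {"id": rid, "chrom": rec.chrom, "start": rec.start, "end": rec.end}
        for label, parts in (("", whole), ("cgi_", cgi_parts), ("noncgi_", noncgi_parts)):
            m_wt = _parts_mean(wt_calls, parts)
            m_ko = _parts_mean(ko_calls, parts)
            row[f"{label}m_wt"] = m_wt
            row[f"{label}m_ko"] = m_ko
            row[f"{label}delta"] = m_ko - m_wt
        if np.isnan(row["delta"]):
            log.warning("region %s has no CpG coverage in WT or KO; delta undefined", rid)
        row["hypermethylated"] = bool(row["delta"] >= hyper_threshold) if np.isfinite(row["delta"]) else False
        rows.append(row)
    columns = ["id", "chrom", "start", "end",
               "m_wt", "m_ko", "delta",
               "cgi_m_wt", "cgi_m_ko", "cgi_delta",
               "noncgi_m_wt", "noncgi_m_ko", "noncgi_delta",
               "hypermethylated"]
    return pd.DataFrame(rows, columns=columns).set_index("id")


# ---------------------------------------------------------------------------
# TF-site density meta-profile and length-matched random controls


@dataclass
class MetaProfile:
    """Mean site density (sites per kb) in scaled body bins flanked by
    fixed-width bins; positions run upstream flank, body, downstream flank."""

    flank_bp: int
    body_bins: int
    flank_bin_bp: int
    density: np.ndarray  # length 2*n_flank_bins + body_bins
    control_mean: np.ndarray | None = None
    control_lo: np.ndarray | None = None  # empirical 2.5% null quantile
    control_hi: np.ndarray | None = None  # empirical 97.5% null quantile

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    def to_frame(self) -> pd.DataFrame:
        nf, nb = self.n_flank_bins, self.body_bins
        segment = ["upstream"] * nf + ["body"] * nb + ["downstream"] * nf
        out = pd.DataFrame({"bin": np.arange(len(self.density)), "segment": segment,
                            "density_per_kb": self.density})
        if self.control_mean is not None:
            out["control_mean"] = self.control_mean
            out["control_q025"] = self.control_lo
            out["control_q975"] = self.control_hi
        return out


def _midpoints_by_chrom(sites: IntervalSet) -> dict[str, np.ndarray]:
    out = {}
    for chrom, (starts, ends) in sites.per_chrom().items():
        out[chrom] = np.sort((starts + ends) // 2)
    return out


def _profile_counts(
    mids: Mapping[str, np.ndarray],
    regions: IntervalSet,
    flank_bp: int,
    body_bins: int,
    flank_bin_bp: int,
) -> np.ndarray:
    nf = flank_bp // flank_bin_bp
    total = np.zeros(2 * nf + body_bins)
    for rec in regions:
        pos = mids.get(rec.chrom, np.empty(0, np.int64))
        edges_up = rec.start - flank_bp + flank_bin_bp * np.arange(nf + 1)
        edges_body = np.linspace(rec.start, rec.end, body_bins + 1)
        edges_down = rec.end + flank_bin_bp * np.arange(nf + 1)
        widths = np.concatenate(
            [np.full(nf, flank_bin_bp), np.diff(edges_body), np.full(nf, flank_bin_bp)]
        )
        edges = np.concatenate([edges_up[:-1], edges_body, edges_down[1:]])
        counts = np.diff(np.searchsorted(pos, edges))
        total += counts / (widths / 1000.0)
    return total / max(len(regions), 1)


def site_density_profile(
    sites: IntervalSet,
    regions: IntervalSet,
    flank_bp: int = 20000,
    body_bins: int = 20,
    flank_bin_bp: int = 1000,
) -> MetaProfile:
    """Mean site density (midpoints per kb) around regions: each region body
    is rescaled to `body_bins` bins; flanks are absolute-bp bins."""
    if len(regions) == 0:
        raise ValueError("no regions to profile")
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    mids = _midpoints_by_chrom(sites)
    density = _profile_counts(mids, regions, flank_bp, body_bins, flank_bin_bp)
    return MetaProfile(flank_bp, body_bins, flank_bin_bp, density)


def _placement_weights(lengths: np.ndarray, layout: GenomeLayout) -> tuple[list[str], np.ndarray]:
    chroms = layout.chroms
    sizes = np.array([layout[c] for c in chroms], dtype=float)
    return chroms, sizes


def _sample_positions(
    length: int,
    layout: GenomeLayout,
    rng: np.random.Generator,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom index, start) for `size` uniform placements of one length,
    chromosomes weighted by the number of valid start positions."""
    chroms = layout.chroms
    slots = np.array([max(layout[c] - length + 1, 0) for c in chroms], dtype=float)
    if slots.sum() == 0:
        raise ValueError(f"no chromosome can hold a region of length {length}")
    p = slots / slots.sum()
    cidx = rng.choice(len(chroms), size=size, p=p)
    starts = (rng.random(size) * slots[cidx]).astype(np.int64)
    return cidx, starts


def random_length_matched_controls(
    regions: IntervalSet,
    layout: GenomeLayout,
    n_draws: int = 1,
    seed: int | np.random.Generator = 0,
    exclude: IntervalSet | None = None,
    max_tries: int = 1000,
) -> list[IntervalSet]:
    """For each draw, place every region's length uniformly at random on the
    genome (chromosome chosen proportionally to the available start
    positions), avoiding `exclude` by rejection sampling. Fully determined
    by the seed; the control length multiset equals the region lengths.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    excl = gio._merged_per_chrom(exclude) if exclude is not None and len(exclude) else None
    chroms = layout.chroms
    draws = []
    for _ in range(n_draws):
        rows = []
        for rec in regions:
            length = rec.end - rec.start
            for attempt in range(max_tries):
                cidx, starts = _sample_positions(length, layout, rng, 1)
                chrom, start = chroms[int(cidx[0])], int(starts[0])
                if excl is not None:
                    bs, be = excl.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
                    lo = np.searchsorted(be, start, side="right")
                    if lo < len(bs) and bs[lo] < start + length:
                        continue
                rows.append((chrom, start, start + length, rec.name))
                break
            else:
                raise RuntimeError(
                    f"could not place a control for region {rec.name or rec} after {max_tries} tries"
                )
        draws.append(IntervalSet.from_records(rows, layout=layout))
    return draws


def region_site_density(sites: IntervalSet | Mapping[str, np.ndarray], regions: IntervalSet) -> float:
    """Site midpoints inside the regions per kb of region length."""
    mids = sites if isinstance(sites, Mapping) else _midpoints_by_chrom(sites)
    count = 0
    bp = 0
    for rec in regions:
        pos = mids.get(rec.chrom, np.empty(0, np.int64))
        lo, hi = np.searchsorted(pos, [rec.start, rec.end])
        count += hi - lo
        bp += rec.end - rec.start
    return count / (bp / 1000.0) if bp else float("nan")


def control_densities(
    sites: IntervalSet,
    regions: IntervalSet,
    layout: GenomeLayout,
    n_draws: int,
    seed: int | np.random.Generator = 0,
    exclude: IntervalSet | None = None,
) -> np.ndarray:
    """Site density of `n_draws` length-matched random control sets.

    Without an exclusion set the placements are drawn fully vectorized;
    with one, the rejection-sampling path of
    `random_length_matched_controls` is used.
    """
    mids = _midpoints_by_chrom(sites)
    if exclude is not None and len(exclude):
        draws = random_length_matched_controls(regions, layout, n_draws, seed, exclude)
        return np.array([region_site_density(mids, d) for d in draws])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = layout.chroms
    lengths = regions.lengths()
    total_kb = lengths.sum() / 1000.0
    counts = np.zeros(n_draws)
    for length in lengths:
        cidx, starts = _sample_positions(int(length), layout, rng, n_draws)
        for ci in np.unique(cidx):
            sel = cidx == ci
            pos = mids.get(chroms[int(ci)], np.empty(0, np.int64))
            s = starts[sel]
            counts[sel] += np.searchsorted(pos, s + length) - np.searchsorted(pos, s)
    return counts / total_kb


def enrichment_test(observed_density: float, control_densities_: np.ndarray) -> dict:
    """Empirical enrichment p-value with add-one smoothing and fold change.

    p = (1 + #{controls >= observed}) / (1 + n); fold = observed / mean
    control density (NaN-flagged when the control mean is zero).
    """
    controls = np.asarray(control_densities_, dtype=float)
    if controls.size < 100:
        raise ValueError("need at least 100 control draws")
    n = controls.size
    p = (1 + int((controls >= observed_density).sum())) / (1 + n)
    mean_c = controls.mean()
    fold = observed_density / mean_c if mean_c > 0 else float("nan")
    return {"p": p, "fold": fold, "observed": observed_density,
            "control_mean": mean_c, "n_controls": n}


# ---------------------------------------------------------------------------
# stratified score comparison and group overlap percentages


def region_score_table(regions: IntervalSet, cpg_positions: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """One row per scored region with its CG density (sites per 100 bp
    computed from the CpG position lists) — input for
    `stratified_score_compare`."""
    rows = []
    for rec in regions:
        if rec.score is None:
            raise ValueError(f"region {rec.name or rec} lacks a score")
        pos = cpg_positions.get(rec.chrom, np.empty(0, np.int64))
        rows.append(
            {"name": rec.name, "cg_density": cg_density(pos, rec.start, rec.end),
             "score": float(rec.score)}
        )
    return pd.DataFrame(rows)


def stratified_score_compare(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    n_strata: int = 4,
) -> pd.DataFrame:
    """Compare score distributions of two region tables within CG-density
    strata. Both inputs need `cg_density` and `score` columns; strata are
    quantile bins of the pooled CG densities. Empty strata are reported
    with n=0.
    """
    for df, label in ((set_a, "set_a"), (set_b, "set_b")):
        if not {"cg_density", "score"} <= set(df.columns):
            raise ValueError(f"{label} needs 'cg_density' and 'score' columns")
    pooled = np.concatenate([set_a["cg_density"].to_numpy(), set_b["cg_density"].to_numpy()])
    edges = np.quantile(pooled, np.linspace(0, 1, n_strata + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    rows = []
    for k in range(n_strata):
        for label, df in (("a", set_a), ("b", set_b)):
            dens = df["cg_density"].to_numpy()
            sel = (dens >= edges[k]) & (dens < edges[k + 1]) if k < n_strata - 1 else (dens >= edges[k])
            scores = df.loc[sel, "score"].to_numpy()
            rows.append(
                {
                    "stratum": k,
                    "set": label,
                    "n": int(sel.sum()),
                    "median": float(np.median(scores)) if len(scores) else float("nan"),
                    "q1": float(np.percentile(scores, 25)) if len(scores) else float("nan"),
                    "q3": float(np.percentile(scores, 75)) if len(scores) else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def overlap_percentage(
    dmv_sets_by_group: Mapping[str, IntervalSet],
    features: IntervalSet,
) -> pd.DataFrame:
    """Per group: percentage of DMVs overlapping >= 1 bp of the feature set
    (e.g. super-enhancers). Empty groups report NaN with n = 0."""
    rows = []
    for label, dmvs in dmv_sets_by_group.items():
        n = len(dmvs)
        hits = int(gio.overlaps_any(dmvs, features).sum()) if n else 0
        rows.append(
            {"group": label, "n": n, "n_overlapping": hits,
             "percent": 100.0 * hits / n if n else float("nan")}
        )
    return pd.DataFrame(rows).set_index("group")
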