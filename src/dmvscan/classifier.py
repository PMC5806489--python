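"""Classification of DMVs into constant and dynamic groups.

Group I valleys keep a constant (low) methylation level across tissues.
Dynamic valleys — those containing at least one entire tissue-specific
differentially methylated region (tsDMR, length strictly over 2 kb) or
with more than half of their bp covered by tsDMRs — are split by the sign
of the Pearson correlation between per-lineage methylation and the
per-lineage expression of their dynamically expressed gene: negative ->
group II, positive -> group III. Dynamic valleys without a usable dynamic
gene stay "dynamic-unassigned" rather than being forced into a group.

With only four lineage values the correlation coefficient carries no
meaningful p-value; only its sign is used, its magnitude is reported as
evidence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genomic_io as gio
from .binning import mean_methylation
from .genomic_io import ExpressionMatrix, IntervalSet, MethylCalls

__all__ = [
    "DEFAULT_LINEAGES",
    "is_dynamic_dmv",
    "is_dynamic_gene",
    "associate_genes",
    "meth_expr_correlation",
    "lineage_methylation",
    "classify_dmvs",
    "DmvClassification",
]

DEFAULT_LINEAGES = ("blood", "endoderm", "mesoderm", "ectoderm")

GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"
UNASSIGNED = "dynamic-unassigned"


def is_dynamic_dmv(
    dmv,
    tsdmrs: IntervalSet,
    min_tsdmr_len: int = 2000,
    min_cover: float = 0.5,
) -> tuple[bool, dict]:
    """Is a valley dynamic? True when it fully contains a tsDMR longer than
    `min_tsdmr_len` (strict) or when tsDMRs cover strictly more than
    `min_cover` of its bp. Returns (flag, evidence dict).
    """
    chrom, start, end = gio._record_fields(dmv)
    usable = gio.filter_by_length(tsdmrs, min_tsdmr_len) if len(tsdmrs) else tsdmrs
    ts, te = usable.restrict_chrom(chrom)
    contains = bool(np.any((ts >= start) & (te <= end)))
    cover = gio.coverage_fraction((chrom, start, end), usable) if len(usable) else 0.0
    return contains or cover > min_cover, {"contains_tsdmr": contains, "tsdmr_cover": cover}


def is_dynamic_gene(
    fpkm_by_lineage: Sequence[float] | Mapping[str, float] | pd.Series,
    min_peak: float = 2.0,
    fold: float = 3.0,
    max_rest_mean: float = 2.0,
    n_lineages: int = 4,
) -> bool:
    """Dynamically expressed gene rule: the highest lineage FPKM is at least
    `min_peak`, the mean of the other lineages is at most `max_rest_mean`,
    and the peak is at least `fold` times that mean.
    """
    if isinstance(fpkm_by_lineage, Mapping):
        values = np.asarray(list(fpkm_by_lineage.values()), dtype=float)
    else:
        values = np.asarray(fpkm_by_lineage, dtype=float)
    if values.size != n_lineages:
        raise ValueError(f"expected {n_lineages} lineage values, got {values.size}")
    peak = values.max()
    rest = np.delete(values, int(values.argmax()))
    rest_mean = rest.mean()
    return bool(peak >= min_peak and rest_mean <= max_rest_mean and peak >= fold * rest_mean)


def associate_genes(
    dmvs: Sequence,
    tss_set: IntervalSet,
    max_dist: int = 0,
) -> dict[str, list[str]]:
    """DMV id -> gene ids whose TSS (interval start) lies inside the valley
    extended by `max_dist` on each side; ordered by distance then gene id.
    """
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in tss_set.df.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        tss_by_chrom[chrom] = (
            sub["start"].to_numpy()[order],
            sub["name"].to_numpy()[order],
        )
    out: dict[str, list[str]] = {}
    for dmv in dmvs:
        chrom, start, end = gio._record_fields(dmv)
        dmv_id = getattr(dmv, "id", None) or getattr(dmv, "name", None) or f"{chrom}:{start}-{end}"
        pos, names = tss_by_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, object)))
        lo, hi = np.searchsorted(pos, [start - max_dist, end + max_dist])
        hits = []
        for p, g in zip(pos[lo:hi], names[lo:hi]):
            dist = 0 if start <= p < end else min(abs(p - start), abs(p - (end - 1)))
            hits.append((dist, str(g)))
        out[dmv_id] = [g for _, g in sorted(hits)]
    return out


def meth_expr_correlation(
    meth_by_lineage: Sequence[float],
    fpkm_by_lineage: Sequence[float],
) -> float:
    """Pearson correlation of lineage methylation vs lineage FPKM.

    NaN (flagged undefined) when either vector is constant; error for n < 3.
    """
    m = np.asarray(meth_by_lineage, dtype=float)
    f = np.asarray(fpkm_by_lineage, dtype=float)
    if m.shape != f.shape:
        raise ValueError("lineage vectors differ in length")
    if m.size < 3:
        raise ValueError("need at least 3 lineages for a correlation")
    if np.std(m) == 0 or np.std(f) == 0:
        return float("nan")
    return float(np.corrcoef(m, f)[0, 1])


def lineage_methylation(
    dmvs: Sequence,
    calls_by_lineage: Mapping[str, MethylCalls],
    lineages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """DMV x lineage coverage-weighted mean methylation table."""
    lineages = list(lineages) if lineages is not None else list(calls_by_lineage)
    rows = {}
    for dmv in dmvs:
        chrom, start, end = gio._record_fields(dmv)
        dmv_id = getattr(dmv, "id", None) or getattr(dmv, "name", None) or f"{chrom}:{start}-{end}"
        rows[dmv_id] = {
            lin: mean_methylation(calls_by_lineage[lin], chrom, start, end) for lin in lineages
        }
    if not rows:
        return pd.DataFrame(columns=lineages)
    return pd.DataFrame.from_dict(rows, orient="index")[lineages]


@dataclass
class DmvClassification:
    """Per-DMV label with supporting evidence.

    table columns: label, dynamic, contains_tsdmr, tsdmr_cover, gene, r.
    Labels partition the valley set: I + II + III + dynamic-unassigned.
    """

    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(
            [GROUP_I, GROUP_II, GROUP_III, UNASSIGNED], fill_value=0
        )

    def ids_in_group(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="id")


def classify_dmvs(
    dmvs: Sequence,
    tsdmrs: IntervalSet,
    meth_by_lineage: pd.DataFrame,
    expr: ExpressionMatrix,
    gene_map: Mapping[str, list[str]],
    min_tsdmr_len: int = 2000,
    min_cover: float = 0.5,
    dynamic_gene_kwargs: dict | None = None,
) -> DmvClassification:
    """Assign each DMV to group I, II, III or dynamic-unassigned.

    meth_by_lineage: DMV id x lineage mean methylation (columns define the
    lineage order; expression lineage means are aligned to it). When several
    associated genes are dynamic the one with the largest |r| decides; exact
    ties, r = 0 or undefined r leave the valley dynamic-unassigned.
    """
    lineages = list(meth_by_lineage.columns)
    expr_means = expr.lineage_means()
    missing = [lin for lin in lineages if lin not in expr_means.columns]
    if missing:
        raise ValueError(f"expression table lacks lineages {missing}")
    expr_means = expr_means[lineages]
    dyn_kwargs = dict(n_lineages=len(lineages))
    dyn_kwargs.update(dynamic_gene_kwargs or {})

    rows = []
    for dmv in dmvs:
        chrom, start, end = gio._record_fields(dmv)
        dmv_id = getattr(dmv, "id", None) or getattr(dmv, "name", None) or f"{chrom}:{start}-{end}"
        if dmv_id not in meth_by_lineage.index:
            raise ValueError(f"no lineage methylation for DMV {dmv_id}")
        meth = meth_by_lineage.loc[dmv_id]
        if meth.isna().any():
            raise ValueError(f"missing lineage methylation mean for DMV {dmv_id}")
        dynamic, evidence = is_dynamic_dmv(dmv, tsdmrs, min_tsdmr_len, min_cover)
        label, gene, r = GROUP_I, None, float("nan")
        if dynamic:
            label = UNASSIGNED
            candidates = []
            for g in gene_map.get(dmv_id, []):
                if g not in expr_means.index:
                    continue
                fpkm = expr_means.loc[g]
                if is_dynamic_gene(fpkm.to_numpy(), **dyn_kwargs):
                    candidates.append((g, meth_expr_correlation(meth.to_numpy(), fpkm.to_numpy())))
            usable = [(g, r_) for g, r_ in candidates if np.isfinite(r_) and r_ != 0]
            if usable:
                best_abs = max(abs(r_) for _, r_ in usable)
                best = [(g, r_) for g, r_ in usable if abs(r_) == best_abs]
                signs = {np.sign(r_) for _, r_ in best}
                if len(best) == 1 or len(signs) == 1:
                    gene, r = best[0]
                    label = GROUP_II if r < 0 else GROUP_III
        rows.append(
            {
                "id": dmv_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "label": label,
                "dynamic": dynamic,
                "contains_tsdmr": evidence["contains_tsdmr"],
                "tsdmr_cover": evidence["tsdmr_cover"],
                "gene": gene,
                "r": r,
            }
        )
    columns = ["id", "chrom", "start", "end", "label", "dynamic",
               "contains_tsdmr", "tsdmr_cover", "gene", "r"]
    table = pd.DataFrame(rows, columns=columns).set_index("id")
    return DmvClassification(table)
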