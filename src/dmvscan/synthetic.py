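"""Seeded synthetic genomes, methylomes, expression tables, feature sets and
wild-type/knockout pairs with a known truth set.

The generator emulates the statistical structure the valley analysis
assumes: a mostly highly methylated background (Beta-distributed site
levels, mean ~0.8), CpG-dense island blocks that stay unmethylated,
planted hypomethylated valleys of 5-40 kb (lengths on the 1-kb grid so the
caller's bin resolution — not sub-bin placement — is what recovery tests
measure), tissue dynamics confined to tsDMR blocks inside group II/III
valleys, binomial bisulfite sampling at Poisson read coverage, and a WT/KO
pair whose methylation gain is restricted to the non-CGI parts of
Polycomb-like (group I/III) valleys.

Randomness comes from one root seed split into fixed named substreams, so
regenerating one component never perturbs another.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    ExpressionMatrix,
    GenomeLayout,
    IntervalSet,
    MethylCalls,
    write_bed,
    write_methyl_calls,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_truth",
    "simulate_methylomes",
    "simulate_expression",
    "simulate_ko_pair",
    "simulate_features",
    "simulate_all",
    "write_truth",
]

# named RNG substreams (spawn keys off the root seed)
_S_LAYOUT, _S_CPG, _S_METH, _S_EXPR, _S_KO, _S_FEATURES = 0, 1, 2, 3, 4, 5
_S_COVERAGE_BASE = 100  # + lineage index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass
class SimulationConfig:
    """The stated world. Defaults: a 10-Mb two-chromosome genome carrying 50
    valleys (70% constant / 20% group II / 10% group III), four lineages at
    Poisson(30) read coverage, background CpG every ~100 bp (every ~12 bp in
    islands), background methylation Beta(8, 2), valleys at 0.05, a KO gain
    of 0.3 on non-CGI Polycomb-valley parts, and 3-fold TF-site enrichment
    inside valleys over a 2e-4 sites/bp background."""

    seed: int = 0
    chrom_lengths: tuple = (5_000_000, 5_000_000)
    lineages: tuple = ("blood", "endoderm", "mesoderm", "ectoderm")
    samples_per_lineage: int = 2
    n_valleys: int = 50
    valley_len_range: tuple = (5_000, 40_000)  # snapped to the 1-kb grid
    group_props: tuple = (0.7, 0.2, 0.1)  # I, II, III
    min_gap: int = 10_000
    valley_meth: float = 0.05
    dynamic_high_meth: float = 0.35
    cgi_meth: float = 0.02
    background_beta: tuple = (8.0, 2.0)  # mean 0.8
    cpg_spacing_bg: float = 100.0  # geometric mean, bp
    cpg_spacing_cgi: float = 12.0
    coverage_lambda: float = 30.0
    n_background_cgis: int = 20
    bg_cgi_len_range: tuple = (500, 2000)
    n_bg_tsdmrs: int = 10
    bg_tsdmr_len_range: tuple = (2_500, 6_000)
    n_short_tsdmrs: int = 5  # < 2 kb, must be ignored by the classifier
    peak_fpkm_range: tuple = (6.0, 30.0)
    basal_fpkm_range: tuple = (0.0, 1.5)
    flat_fpkm_range: tuple = (0.5, 4.0)
    expr_noise_sd: float = 0.1  # log-normal sigma on sample FPKM
    n_background_genes: int = 20
    ko_delta: float = 0.3
    tf_background_rate: float = 2e-4  # sites per bp
    tf_fold: float = 3.0
    se_frac_group2: float = 0.6
    se_frac_other: float = 0.1

    def __post_init__(self) -> None:
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if not 0 <= self.ko_delta <= 1 - self.valley_meth:
            raise ValueError("ko_delta must lie in [0, 1 - valley methylation]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fields = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
        return cls(**fields)


@dataclass
class TruthSet:
    """Everything the generator planted, for downstream oracle checks."""

    layout: GenomeLayout
    valleys: IntervalSet  # names V0001.. ; df carries a 'group' column
    groups: dict[str, str]  # valley id -> I / II / III
    peak_lineage: dict[str, str]  # dynamic valley id -> lineage of lowest/highest meth
    tsdmrs: IntervalSet
    cgis: IntervalSet
    cpg_positions: dict[str, np.ndarray]
    true_meth: dict[str, dict[str, np.ndarray]]  # lineage -> chrom -> per-site level
    valley_lineage_meth: pd.DataFrame  # valley x lineage true site-mean methylation
    genes: pd.DataFrame  # gene, valley_id, chrom, tss, dynamic + lineage mean FPKM cols
    tss: IntervalSet
    polycomb_ids: list[str]  # groups I and III: the Polycomb-like valleys
    wt_true_meth: dict[str, np.ndarray]  # chrom -> per-site WT level (KO pair)

    def valley_set(self, ids: list[str] | None = None) -> IntervalSet:
        df = self.valleys.df
        if ids is not None:
            df = df[df["name"].isin(ids)].reset_index(drop=True)
        return IntervalSet(df, layout=self.layout)


# ---------------------------------------------------------------------------
# truth construction


def _place_valleys(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    layout_chroms = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    sizes = np.asarray(config.chrom_lengths, dtype=float)
    # proportional allocation, remainders to the largest chromosomes
    quota = config.n_valleys * sizes / sizes.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts)):
        if counts.sum() == config.n_valleys:
            break
        counts[i] += 1
    lmin, lmax = config.valley_len_range
    rows = []
    for chrom, clen, k in zip(layout_chroms, config.chrom_lengths, counts):
        if k == 0:
            continue
        lens = rng.integers(lmin // 1000, lmax // 1000 + 1, size=k) * 1000
        needed = lens.sum() + (k + 1) * config.min_gap
        if needed > clen:
            raise ValueError(
                f"{chrom}: cannot fit {k} valleys totalling {lens.sum()} bp plus gaps in {clen} bp"
            )
        slack = clen - needed
        extra = rng.random(k + 1)
        extra = np.floor(extra / extra.sum() * slack).astype(int)
        cursor = 0
        for j in range(k):
            cursor += config.min_gap + int(extra[j])
            start = (cursor // 1000) * 1000  # keep valley edges on the bin grid
            rows.append((chrom, start, start + int(lens[j])))
            cursor = start + int(lens[j])
    return rows


def _valley_internals(start: int, end: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(CGI block, tsDMR block) inside a valley: a CpG island near the 5'
    end and a dynamic block (> 2 kb, > half the valley) in the 3' part."""
    length = end - start
    cgi_len = min(max(int(0.15 * length), 500), 2000)
    cgi = (start + 200, start + 200 + cgi_len)
    ts_start = start + int(0.35 * length)
    tsdmr = (ts_start, end - 200)
    return cgi, tsdmr


def _sample_outside(
    rng: np.random.Generator,
    layout: GenomeLayout,
    length: int,
    occupied: dict[str, tuple[np.ndarray, np.ndarray]],
    margin: int = 3000,
    max_tries: int = 1000,
) -> tuple[str, int]:
    chroms = layout.chroms
    sizes = np.array([layout[c] for c in chroms], dtype=float)
    p = sizes / sizes.sum()
    for _ in range(max_tries):
        chrom = chroms[int(rng.choice(len(chroms), p=p))]
        start = int(rng.integers(0, layout[chrom] - length))
        s, e = start - margin, start + length + margin
        bs, be = occupied.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        lo = np.searchsorted(be, s, side="right")
        if lo >= len(bs) or bs[lo] >= e:
            return chrom, start
    raise RuntimeError("could not place a background feature clear of the valleys")


def simulate_truth(config: SimulationConfig) -> TruthSet:
    """Lay out the genome: valleys with groups, CGIs, tsDMRs, CpG positions,
    true per-site methylation per lineage, genes and the WT truth for the
    knockout pair. Deterministic in config.seed."""
    layout = GenomeLayout({f"chr{i + 1}": L for i, L in enumerate(config.chrom_lengths)})
    rng = _rng(config.seed, _S_LAYOUT)

    valley_rows = _place_valleys(config, rng)
    n = len(valley_rows)
    # group labels: largest-remainder counts, then a seeded shuffle
    quota = np.asarray(config.group_props) * n
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts)):
        if counts.sum() == n:
            break
        counts[i] += 1
    labels = np.repeat(["I", "II", "III"], counts)
    rng.shuffle(labels)

    ids = [f"V{i + 1:04d}" for i in range(n)]
    groups = dict(zip(ids, labels))
    peak_lineage = {
        vid: config.lineages[int(rng.integers(len(config.lineages)))]
        for vid, lab in groups.items()
        if lab in ("II", "III")
    }

    cgi_rows: list[tuple[str, int, int, str]] = []
    tsdmr_rows: list[tuple[str, int, int, str]] = []
    valley_cgi: dict[str, tuple[int, int]] = {}
    valley_tsdmr: dict[str, tuple[int, int]] = {}
    for vid, (chrom, s, e) in zip(ids, valley_rows):
        cgi, tsdmr = _valley_internals(s, e)
        cgi_rows.append((chrom, cgi[0], cgi[1], f"CGI_{vid}"))
        valley_cgi[vid] = cgi
        if groups[vid] in ("II", "III"):
            tsdmr_rows.append((chrom, tsdmr[0], tsdmr[1], f"tsDMR_{vid}"))
            valley_tsdmr[vid] = tsdmr

    occupied: dict[str, list] = {}
    for chrom, s, e in valley_rows:
        occupied.setdefault(chrom, []).append((s, e))
    occ = {
        chrom: (np.array([s for s, _ in rows], np.int64), np.array([e for _, e in rows], np.int64))
        for chrom, rows in occupied.items()
    }

    for i in range(config.n_background_cgis):
        length = int(rng.integers(*config.bg_cgi_len_range))
        chrom, start = _sample_outside(rng, layout, length, occ)
        cgi_rows.append((chrom, start, start + length, f"CGIbg{i + 1:03d}"))
    for i in range(config.n_bg_tsdmrs):
        length = int(rng.integers(*config.bg_tsdmr_len_range))
        chrom, start = _sample_outside(rng, layout, length, occ)
        tsdmr_rows.append((chrom, start, start + length, f"tsDMRbg{i + 1:03d}"))
    for i in range(config.n_short_tsdmrs):
        length = int(rng.integers(500, 1999))
        chrom, start = _sample_outside(rng, layout, length, occ, margin=0)
        tsdmr_rows.append((chrom, start, start + length, f"tsDMRshort{i + 1:03d}"))

    valleys = IntervalSet.from_records(
        [(chrom, s, e, vid) for vid, (chrom, s, e) in zip(ids, valley_rows)], layout=layout
    )
    valleys.df["group"] = [groups[nm] for nm in valleys.df["name"]]
    cgis = IntervalSet.from_records(cgi_rows, layout=layout)
    tsdmrs = IntervalSet.from_records(tsdmr_rows, layout=layout)

    # CpG positions: background geometric spacing plus dense island spacing
    rng_cpg = _rng(config.seed, _S_CPG)
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in layout.chroms:
        clen = layout[chrom]
        n_bg = int(clen / config.cpg_spacing_bg * 1.3) + 10
        gaps = rng_cpg.geometric(1.0 / config.cpg_spacing_bg, size=n_bg)
        pos = np.cumsum(gaps) - 1
        pos = pos[pos < clen]
        dense = []
        cs, ce = cgis.restrict_chrom(chrom)
        for s, e in zip(cs, ce):
            m = int((e - s) / config.cpg_spacing_cgi * 1.5) + 5
            g = rng_cpg.geometric(1.0 / config.cpg_spacing_cgi, size=m)
            p = s + np.cumsum(g) - 1
            dense.append(p[p < e])
        allpos = np.concatenate([pos] + dense) if dense else pos
        cpg_positions[chrom] = np.unique(allpos).astype(np.int64)

    # true methylation: background Beta, islands low, valleys low,
    # dynamic tsDMR blocks modulated per lineage
    rng_m = _rng(config.seed, _S_METH)
    a, b = config.background_beta
    base: dict[str, np.ndarray] = {
        chrom: rng_m.beta(a, b, size=len(cpg_positions[chrom])) for chrom in layout.chroms
    }
    for chrom in layout.chroms:
        pos = cpg_positions[chrom]
        cs, ce = cgis.restrict_chrom(chrom)
        for s, e in zip(cs, ce):
            lo, hi = np.searchsorted(pos, [s, e])
            base[chrom][lo:hi] = config.cgi_meth

    true_meth: dict[str, dict[str, np.ndarray]] = {
        lin: {chrom: base[chrom].copy() for chrom in layout.chroms} for lin in config.lineages
    }
    wt_true: dict[str, np.ndarray] = {chrom: base[chrom].copy() for chrom in layout.chroms}

    for vid, (chrom, s, e) in zip(ids, valley_rows):
        pos = cpg_positions[chrom]
        lo, hi = np.searchsorted(pos, [s, e])
        cgi_s, cgi_e = valley_cgi[vid]
        in_cgi = (pos[lo:hi] >= cgi_s) & (pos[lo:hi] < cgi_e)
        for lin in config.lineages:
            seg = true_meth[lin][chrom][lo:hi]
            seg[~in_cgi] = config.valley_meth
            true_meth[lin][chrom][lo:hi] = seg
        wt_seg = wt_true[chrom][lo:hi]
        wt_seg[~in_cgi] = config.valley_meth
        wt_true[chrom][lo:hi] = wt_seg
        if groups[vid] in ("II", "III"):
            ts_s, ts_e = valley_tsdmr[vid]
            in_ts = (pos[lo:hi] >= ts_s) & (pos[lo:hi] < ts_e) & ~in_cgi
            for lin in config.lineages:
                is_peak = lin == peak_lineage[vid]
                if groups[vid] == "II":
                    level = config.valley_meth if is_peak else config.dynamic_high_meth
                else:  # group III: methylation is high where the gene is on
                    level = config.dynamic_high_meth if is_peak else config.valley_meth
                seg = true_meth[lin][chrom][lo:hi]
                seg[in_ts] = level
                true_meth[lin][chrom][lo:hi] = seg

    vl_meth = pd.DataFrame(
        {
            lin: [
                float(true_meth[lin][chrom][slice(*np.searchsorted(cpg_positions[chrom], [s, e]))].mean())
                for (chrom, s, e) in valley_rows
            ]
            for lin in config.lineages
        },
        index=ids,
    )

    # genes: one promoter gene per valley + flat background genes
    rng_e = _rng(config.seed, _S_EXPR)
    gene_rows = []
    tss_rows = []
    for vid, (chrom, s, e) in zip(ids, valley_rows):
        gene = f"gene_{vid}"
        tss = s + 100
        row = {"gene": gene, "valley_id": vid, "chrom": chrom, "tss": tss,
               "group": groups[vid], "dynamic": groups[vid] in ("II", "III")}
        if row["dynamic"]:
            peak = peak_lineage[vid]
            for lin in config.lineages:
                row[lin] = (
                    float(rng_e.uniform(*config.peak_fpkm_range))
                    if lin == peak
                    else float(rng_e.uniform(*config.basal_fpkm_range))
                )
        else:
            flat = float(rng_e.uniform(*config.flat_fpkm_range))
            for lin in config.lineages:
                row[lin] = flat
        gene_rows.append(row)
        tss_rows.append((chrom, tss, tss + 1, gene))
    for i in range(config.n_background_genes):
        chrom, start = _sample_outside(rng_e, layout, 1, occ, margin=1000)
        gene = f"geneBG{i + 1:03d}"
        flat = float(rng_e.uniform(*config.flat_fpkm_range))
        row = {"gene": gene, "valley_id": None, "chrom": chrom, "tss": start,
               "group": None, "dynamic": False}
        row.update({lin: flat for lin in config.lineages})
        gene_rows.append(row)
        tss_rows.append((chrom, start, start + 1, gene))

    genes = pd.DataFrame(gene_rows).set_index("gene")
    tss = IntervalSet.from_records(tss_rows, layout=layout)
    polycomb_ids = [vid for vid in ids if groups[vid] in ("I", "III")]

    return TruthSet(
        layout=layout,
        valleys=valleys,
        groups=groups,
        peak_lineage=peak_lineage,
        tsdmrs=tsdmrs,
        cgis=cgis,
        cpg_positions=cpg_positions,
        true_meth=true_meth,
        valley_lineage_meth=vl_meth,
        genes=genes,
        tss=tss,
        polycomb_ids=polycomb_ids,
        wt_true_meth=wt_true,
    )


# ---------------------------------------------------------------------------
# observation sampling


def _sample_calls(
    true_m: Mapping[str, np.ndarray],
    cpg_positions: Mapping[str, np.ndarray],
    layout: GenomeLayout,
    lam: float,
    rng: np.random.Generator,
) -> MethylCalls:
    """Binomial counts at Poisson coverage; sites with zero sampled reads
    are omitted, as in real data."""
    data = {}
    for chrom in sorted(cpg_positions):
        pos = cpg_positions[chrom]
        total = rng.poisson(lam, size=len(pos))
        meth = rng.binomial(total, np.clip(true_m[chrom], 0, 1))
        keep = total > 0
        data[chrom] = (pos[keep], meth[keep], total[keep])
    return MethylCalls(data, layout=layout)


def simulate_methylomes(
    config: SimulationConfig,
    truth: TruthSet | None = None,
) -> tuple[dict[str, MethylCalls], TruthSet]:
    """Per-lineage observed methylomes plus the truth set."""
    if truth is None:
        truth = simulate_truth(config)
    calls = {}
    for k, lin in enumerate(config.lineages):
        rng = _rng(config.seed, _S_COVERAGE_BASE + k)
        calls[lin] = _sample_calls(
            truth.true_meth[lin], truth.cpg_positions, truth.layout, config.coverage_lambda, rng
        )
    return calls, truth


def simulate_expression(truth: TruthSet, config: SimulationConfig) -> ExpressionMatrix:
    """Gene x sample FPKM with log-normal sample noise around the planted
    lineage means; dynamic genes satisfy the dynamic-gene rule by
    construction, background/constant genes violate at least one clause."""
    rng = _rng(config.seed, _S_EXPR + 50)
    lineages = list(config.lineages)
    samples = [f"{lin}_{i + 1}" for lin in lineages for i in range(config.samples_per_lineage)]
    lineage_of = {s: s.rsplit("_", 1)[0] for s in samples}
    means = truth.genes[lineages]
    noise = rng.lognormal(mean=0.0, sigma=config.expr_noise_sd, size=(len(means), len(samples)))
    fpkm = pd.DataFrame(
        means[[lineage_of[s] for s in samples]].to_numpy() * noise,
        index=means.index,
        columns=samples,
    )
    return ExpressionMatrix(fpkm, lineage_of)


def simulate_ko_pair(
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[MethylCalls, MethylCalls]:
    """WT/KO methylome pair: the KO gains `ko_delta` on the non-CGI parts
    of Polycomb-like (group I/III) valleys and is unchanged elsewhere; both
    are resampled independently at the configured coverage."""
    from .genomic_io import subtract

    ko_true = {chrom: arr.copy() for chrom, arr in truth.wt_true_meth.items()}
    flagged = truth.valley_set(truth.polycomb_ids)
    gain_regions = subtract(flagged, truth.cgis)
    for rec in gain_regions:
        pos = truth.cpg_positions[rec.chrom]
        lo, hi = np.searchsorted(pos, [rec.start, rec.end])
        ko_true[rec.chrom][lo:hi] = np.clip(ko_true[rec.chrom][lo:hi] + config.ko_delta, 0, 1)
    rng_wt = _rng(config.seed, _S_KO)
    rng_ko = _rng(config.seed, _S_KO + 1)
    wt = _sample_calls(truth.wt_true_meth, truth.cpg_positions, truth.layout,
                       config.coverage_lambda, rng_wt)
    ko = _sample_calls(ko_true, truth.cpg_positions, truth.layout,
                       config.coverage_lambda, rng_ko)
    return wt, ko


def simulate_features(truth: TruthSet, config: SimulationConfig) -> dict[str, IntervalSet]:
    """Peak and site sets mirroring the annotation inputs.

    H3K4me3 peaks sit on every valley promoter; H3K27me3 and EED peaks
    cover the Polycomb-like valleys; TF sites are a uniform Poisson field
    at `tf_background_rate` with `tf_fold`-times that rate inside valleys;
    super-enhancers preferentially overlap group II valleys; and every CGI
    gets a score (deamination-rate-like), lower for CGIs inside valleys.
    """
    rng = _rng(config.seed, _S_FEATURES)
    layout = truth.layout
    k4_rows, k27_rows, eed_rows, se_rows = [], [], [], []
    for rec in truth.valleys:
        vid = rec.name
        tss = int(truth.genes.loc[f"gene_{vid}", "tss"])
        k4_rows.append((rec.chrom, max(tss - 1000, 0), tss + 1000, f"K4_{vid}"))
        if vid in truth.polycomb_ids:
            k27_rows.append((rec.chrom, max(rec.start - 500, 0),
                             min(rec.end + 500, layout[rec.chrom]), f"K27_{vid}"))
            eed_rows.append((rec.chrom, rec.start, rec.end, f"EED_{vid}"))
        frac = config.se_frac_group2 if truth.groups[vid] == "II" else config.se_frac_other
        if rng.random() < frac:
            se_rows.append((rec.chrom, max(rec.start - 2000, 0),
                            min(rec.start + 4000, layout[rec.chrom]), f"SE_{vid}"))

    # TF sites: background field + extra density inside valleys
    site_pos: dict[str, np.ndarray] = {}
    for chrom in layout.chroms:
        clen = layout[chrom]
        n_bg = rng.poisson(config.tf_background_rate * clen)
        pos = rng.integers(0, clen, size=n_bg)
        extra = []
        vs, ve = truth.valleys.restrict_chrom(chrom)
        for s, e in zip(vs, ve):
            k = rng.poisson((config.tf_fold - 1.0) * config.tf_background_rate * (e - s))
            if k:
                extra.append(rng.integers(s, e, size=k))
        allpos = np.concatenate([pos] + extra) if extra else pos
        site_pos[chrom] = np.unique(allpos)
    tf_rows = [
        (chrom, int(p), int(p) + 1) for chrom in layout.chroms for p in site_pos[chrom]
    ]

    cgi_df = truth.cgis.df.copy()
    in_valley = np.zeros(len(cgi_df), dtype=bool)
    vsets = truth.valleys
    from .genomic_io import overlaps_any

    in_valley = overlaps_any(truth.cgis, vsets)
    cgi_df["score"] = rng.normal(0.5, 0.03, size=len(cgi_df)) - 0.15 * in_valley

    return {
        "k4_peaks": IntervalSet.from_records(k4_rows, layout=layout),
        "k27_peaks": IntervalSet.from_records(k27_rows, layout=layout),
        "eed_peaks": IntervalSet.from_records(eed_rows, layout=layout),
        "super_enhancers": IntervalSet.from_records(se_rows, layout=layout),
        "tf_sites": IntervalSet.from_records(tf_rows, layout=layout),
        "cgi_scores": IntervalSet(cgi_df, layout=layout),
    }


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator component off one seed; returns a dict with
    truth, calls_by_lineage, expression, wt, ko and the feature sets."""
    calls, truth = simulate_methylomes(config)
    expr = simulate_expression(truth, config)
    wt, ko = simulate_ko_pair(truth, config)
    features = simulate_features(truth, config)
    return {
        "truth": truth,
        "calls_by_lineage": calls,
        "expression": expr,
        "wt": wt,
        "ko": ko,
        "features": features,
    }


def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    """Write the planted truth as BED/TSV files into `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.layout.to_file(outdir / "genome.chrom.sizes")
    write_bed(truth.valleys, outdir / "valleys.bed")
    truth.valleys.df[["name", "chrom", "start", "end", "group"]].to_csv(
        outdir / "valley_groups.tsv", sep="\t", index=False
    )
    write_bed(truth.tsdmrs, outdir / "tsdmrs.bed")
    write_bed(truth.cgis, outdir / "cgis.bed")
    write_bed(truth.tss, outdir / "tss.bed")
    truth.valley_lineage_meth.to_csv(outdir / "valley_lineage_meth.tsv", sep="\t", index_label="id")
    truth.genes.to_csv(outdir / "genes.tsv", sep="\t")
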