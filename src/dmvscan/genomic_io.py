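"""Containers and I/O for genomic intervals, per-CpG methylation calls and
expression tables, plus the interval algebra shared by the whole pipeline.

Coordinates are 0-based, half-open (BED convention) everywhere internally;
1-based dialects (Bismark-style CpG reports) are converted at the reader
boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "MethylCalls",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_methyl_calls",
    "write_methyl_calls",
    "filter_by_length",
    "merge",
    "subtract",
    "intersect",
    "coverage_fraction",
    "overlaps_any",
    "jaccard",
]


# ---------------------------------------------------------------------------
# genome layout


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length in bp.

    Chromosome names are unique by construction (dict keys); all lengths
    must be positive.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", dict(self.lengths))
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return int(self.lengths[chrom])

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chrom-sizes file (chrom<TAB>length)."""
        lengths: dict[str, int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length', got {raw!r}")
            if parts[0] in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {parts[0]!r}")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.lengths.items():
                fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# intervals


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A sorted set of half-open genomic intervals with optional name/score/strand.

    Intervals within one set may overlap unless the set was union-merged;
    all algebra routines union-merge their *second* operand before
    computing, so downstream fraction arithmetic never double-counts bp.
    """

    _COLUMNS = ("chrom", "start", "end", "name", "score", "strand")

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = df.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"IntervalSet requires a {col!r} column")
        for col in ("name", "score", "strand"):
            if col not in df.columns:
                df[col] = None
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"empty or inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        if layout is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in layout:
                    raise ValueError(f"chromosome {chrom!r} absent from genome layout")
                if (sub["end"] > layout[chrom]).any():
                    raise ValueError(f"interval beyond end of {chrom} (length {layout[chrom]})")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self.df = df[list(self._COLUMNS) + [c for c in df.columns if c not in self._COLUMNS]]
        self.layout = layout
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- construction helpers

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple | Interval],
        layout: GenomeLayout | None = None,
    ) -> "IntervalSet":
        rows = [Interval(*rec) for rec in records]
        df = pd.DataFrame(rows, columns=list(Interval._fields))
        if df.empty:
            df = pd.DataFrame(columns=list(Interval._fields))
        return cls(df, layout=layout)

    @classmethod
    def empty(cls, layout: GenomeLayout | None = None) -> "IntervalSet":
        return cls.from_records([], layout=layout)

    # -- basic protocol

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        for row in self.df.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end), row.name, row.score, row.strand)

    @property
    def is_empty(self) -> bool:
        return len(self.df) == 0

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def total_bp(self) -> int:
        """Sum of interval lengths after union-merging (bp covered)."""
        return int(sum(self.merge().lengths()))

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends) arrays, sorted by start."""
        if self._per_chrom is None:
            out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
            self._per_chrom = out
        return self._per_chrom

    def has_overlaps(self) -> bool:
        for starts, ends in self.per_chrom().values():
            if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
                return True
        return False

    def merge(self) -> "IntervalSet":
        """Union-merge overlapping and book-ended intervals (drops name/score)."""
        rows = []
        for chrom in sorted(self.per_chrom()):
            starts, ends = self.per_chrom()[chrom]
            for s, e in zip(*_merge_arrays(starts, ends)):
                rows.append((chrom, int(s), int(e)))
        return IntervalSet.from_records(rows, layout=self.layout)

    def restrict_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self.per_chrom().get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union-merge sorted interval arrays (book-ended intervals coalesce)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


def merge(a: IntervalSet) -> IntervalSet:
    return a.merge()


def _record_fields(record) -> tuple[str, int, int]:
    if isinstance(record, tuple) and not hasattr(record, "chrom"):
        chrom, start, end = record[:3]
    else:
        chrom, start, end = record.chrom, record.start, record.end
    return str(chrom), int(start), int(end)


def _subtract_one(start: int, end: int, bs: np.ndarray, be: np.ndarray) -> list[tuple[int, int]]:
    """Pieces of [start, end) not covered by the merged intervals (bs, be)."""
    lo = np.searchsorted(be, start, side="right")
    pieces: list[tuple[int, int]] = []
    cursor = start
    for s, e in zip(bs[lo:], be[lo:]):
        if s >= end:
            break
        if s > cursor:
            pieces.append((cursor, int(s)))
        cursor = max(cursor, int(e))
    if cursor < end:
        pieces.append((cursor, end))
    return pieces


def _intersect_one(start: int, end: int, bs: np.ndarray, be: np.ndarray) -> list[tuple[int, int]]:
    lo = np.searchsorted(be, start, side="right")
    pieces: list[tuple[int, int]] = []
    for s, e in zip(bs[lo:], be[lo:]):
        if s >= end:
            break
        pieces.append((max(start, int(s)), min(end, int(e))))
    return pieces


def _merged_per_chrom(b: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        chrom: _merge_arrays(starts, ends) for chrom, (starts, ends) in b.per_chrom().items()
    }


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Maximal sub-intervals of each `a` record not covered by `b`.

    `b` is union-merged first; record names of `a` are carried onto the
    resulting pieces.
    """
    bm = _merged_per_chrom(b)
    rows = []
    for rec in a:
        bs, be = bm.get(rec.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        for s, e in _subtract_one(rec.start, rec.end, bs, be):
            rows.append((rec.chrom, s, e, rec.name))
    return IntervalSet.from_records(rows, layout=a.layout)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Overlapping pieces of each `a` record with the union of `b`."""
    bm = _merged_per_chrom(b)
    rows = []
    for rec in a:
        bs, be = bm.get(rec.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        for s, e in _intersect_one(rec.start, rec.end, bs, be):
            rows.append((rec.chrom, s, e, rec.name))
    return IntervalSet.from_records(rows, layout=a.layout)


def coverage_fraction(record, b: IntervalSet) -> float:
    """Fraction of `record` covered by the union of `b`, in [0, 1]."""
    chrom, start, end = _record_fields(record)
    bs, be = _merge_arrays(*b.restrict_chrom(chrom))
    covered = sum(e - s for s, e in _intersect_one(start, end, bs, be))
    return covered / (end - start)


def overlaps_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean per `a` record: does it overlap >= 1 bp of `b`?"""
    bm = _merged_per_chrom(b)
    flags = np.zeros(len(a), dtype=bool)
    for i, rec in enumerate(a):
        bs, be = bm.get(rec.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        lo = np.searchsorted(be, rec.start, side="right")
        flags[i] = lo < len(bs) and bs[lo] < rec.end
    return flags


def filter_by_length(a: IntervalSet, min_len: int) -> IntervalSet:
    """Keep records strictly longer than `min_len` bp; order preserved."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    keep = (a.df["end"] - a.df["start"]) > min_len
    return IntervalSet(a.df[keep].reset_index(drop=True), layout=a.layout)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """bp-level Jaccard index between the unions of two interval sets."""
    inter = intersect(a.merge(), b).total_bp()
    union = a.total_bp() + b.total_bp() - inter
    return inter / union if union else float("nan")


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    expects_score: bool = False,
    merge_overlaps: bool = False,
) -> IntervalSet:
    """Read a BED3/4/5(/6) file into an IntervalSet.

    With merge_overlaps=True, overlapping records are union-merged with a
    logged warning (names and scores are dropped on the merged set) — the
    fraction arithmetic downstream assumes disjoint features.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith(("#", "track", "browser")):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: empty interval ({start} >= {end})")
        name = parts[3] if len(parts) > 3 else None
        score = None
        if len(parts) > 4 and parts[4] not in (".", ""):
            score = float(parts[4])
        elif expects_score and len(parts) <= 4:
            raise ValueError(f"{path}:{lineno}: score column expected but absent")
        strand = parts[5] if len(parts) > 5 else None
        rows.append((parts[0], start, end, name, score, strand))
    iset = IntervalSet.from_records(rows, layout=layout)
    if merge_overlaps and iset.has_overlaps():
        log.warning("%s: overlapping intervals union-merged on load", path)
        iset = iset.merge()
    return iset


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in iset:
            cols = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.name is not None or rec.score is not None:
                cols.append("." if rec.name is None else str(rec.name))
            if rec.score is not None:
                cols.append(repr(float(rec.score)))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# methylation calls


class MethylCalls:
    """Per-CpG-site methylated/total read counts, strand-merged, sorted.

    Stored as per-chromosome arrays (pos, meth, total) with positions
    strictly increasing; this is the raw methylome every downstream step
    consumes.
    """

    def __init__(self, data: Mapping[str, tuple], layout: GenomeLayout | None = None):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(data):
            pos, meth, total = (np.asarray(x) for x in data[chrom])
            pos = pos.astype(np.int64)
            meth = meth.astype(np.int64)
            total = total.astype(np.int64)
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: CpG positions not strictly increasing")
            if (meth < 0).any() or (total < meth).any():
                raise ValueError(f"{chrom}: require 0 <= methylated <= total at every site")
            if layout is not None:
                if chrom not in layout:
                    raise ValueError(f"chromosome {chrom!r} absent from genome layout")
                if len(pos) and pos[-1] >= layout[chrom]:
                    raise ValueError(f"{chrom}: CpG position beyond chromosome end")
            self._data[chrom] = (pos, meth, total)
        self.layout = layout

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layout: GenomeLayout | None = None) -> "MethylCalls":
        data = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("pos")
            data[chrom] = (sub["pos"].to_numpy(), sub["meth"].to_numpy(), sub["total"].to_numpy())
        return cls(data, layout=layout)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @property
    def n_sites(self) -> int:
        return int(sum(len(pos) for pos, _, _ in self._data.values()))

    def sites(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64)),
        )

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites(chrom)[0]

    def region_counts(self, chrom: str, start: int, end: int) -> tuple[int, int, int]:
        """(sum methylated, sum total, n sites) over CpGs in [start, end)."""
        pos, meth, total = self.sites(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return int(meth[lo:hi].sum()), int(total[lo:hi].sum()), int(hi - lo)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "total": total})
            for chrom, (pos, meth, total) in self._data.items()
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
        return pd.concat(frames, ignore_index=True)


def read_methyl_calls(
    path: str | Path,
    dialect: str = "bedgraph-counts",
    layout: GenomeLayout | None = None,
    one_based: bool | None = None,
) -> MethylCalls:
    """Read per-CpG calls.

    dialect="bedgraph-counts": 5 columns (chrom, start, end, meth, total),
    0-based half-open.

    dialect="cpg-report": Bismark-style per-strand rows
    (chrom, pos, strand, count_meth, count_unmeth[, context...]); positions
    are 1-based unless one_based=False. The two strands of one CpG are
    merged onto the plus-strand C (0-based position), counts summed.
    """
    path = Path(path)
    if dialect == "bedgraph-counts":
        records: dict[str, list[tuple[int, int, int]]] = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip() or raw.startswith(("#", "track")):
                continue
            parts = raw.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns for bedgraph-counts")
            chrom, start, meth, total = parts[0], int(parts[1]), int(parts[3]), int(parts[4])
            if meth > total:
                raise ValueError(f"{path}:{lineno}: methylated count {meth} > total {total}")
            records.setdefault(chrom, []).append((start, meth, total))
    elif dialect == "cpg-report":
        if one_based is None:
            one_based = True
        acc: dict[str, dict[int, list[int]]] = {}
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns for cpg-report")
            chrom, pos, strand = parts[0], int(parts[1]), parts[2]
            meth, unmeth = int(parts[3]), int(parts[4])
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if one_based:
                pos -= 1
            if strand == "-":
                pos -= 1  # G of the CpG; fold onto the plus-strand C
            elif strand != "+":
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            cell = acc.setdefault(chrom, {}).setdefault(pos, [0, 0])
            cell[0] += meth
            cell[1] += meth + unmeth
        records = {
            chrom: [(pos, m, t) for pos, (m, t) in sorted(sites.items())]
            for chrom, sites in acc.items()
        }
    else:
        raise ValueError(f"unknown methylation-call dialect {dialect!r}")

    data = {}
    for chrom, rows in records.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
        data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return MethylCalls(data, layout=layout)


def write_methyl_calls(calls: MethylCalls, path: str | Path) -> None:
    """Write in the bedgraph-counts dialect (chrom, start, end, meth, total)."""
    with open(path, "w") as fh:
        for chrom in calls.chroms:
            pos, meth, total = calls.sites(chrom)
            for p, m, t in zip(pos, meth, total):
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{m}\t{t}\n")


# ---------------------------------------------------------------------------
# expression


class ExpressionMatrix:
    """Gene x sample FPKM table plus a sample -> lineage map."""

    def __init__(self, fpkm: pd.DataFrame, sample_lineage: Mapping[str, str]):
        if (fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = [s for s in fpkm.columns if s not in sample_lineage]
        if missing:
            raise ValueError(f"samples without a lineage label: {missing}")
        self.fpkm = fpkm.astype(float)
        self.sample_lineage = pd.Series({s: sample_lineage[s] for s in fpkm.columns})

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for lin in self.sample_lineage:
            seen.setdefault(lin, None)
        return list(seen)

    def lineage_means(self) -> pd.DataFrame:
        """Gene x lineage mean FPKM (unweighted mean over a lineage's samples)."""
        return self.fpkm.T.groupby(self.sample_lineage).mean().T[self.lineages]

    def write(self, fpkm_path: str | Path, lineage_path: str | Path) -> None:
        self.fpkm.to_csv(fpkm_path, sep="\t", index_label="gene")
        self.sample_lineage.rename("lineage").to_csv(lineage_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, fpkm_path: str | Path, lineage_path: str | Path) -> "ExpressionMatrix":
        fpkm = pd.read_csv(fpkm_path, sep="\t", index_col=0)
        fpkm.index.name = None
        lin = pd.read_csv(lineage_path, sep="\t", index_col=0)["lineage"]
        return cls(fpkm, lin.to_dict())
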