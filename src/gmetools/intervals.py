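"""Genomic-interval engine and anchor (GME) identification.

Intervals are carried as pandas DataFrames with columns
``chrom, start, end`` plus optional ``id`` and ``score`` (0-based half-open
coordinates). Set operations (union-merge, overlap) are delegated to
pyranges; this module owns validation, the multi-track anchor-calling rule,
and bin arithmetic.

Anchors here are Gene Mobility Elements (GMEs): short accessible elements
that are simultaneously chromatin-accessible across developmental stages
(ATAC) and bound by Polycomb-group factors and the nucleoporin Nup93
(ChIP). The calling rule is: merge the union of stage ATAC peaks, keep
merged peaks supported by at least ``min_stages`` stages, then require
overlap with every supplied ChIP track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .genome import GenomeSpec

BED_COLUMNS = ["chrom", "start", "end", "id", "score", "strand"]


def _to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    out = pd.DataFrame(
        {"Chromosome": df["chrom"].astype(str), "Start": df["start"], "End": df["end"]}
    )
    for col in df.columns:
        if col not in ("chrom", "start", "end"):
            out[col] = df[col].to_numpy()
    return pr.PyRanges(out)


def _from_pyranges(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def validate_intervals(df: pd.DataFrame, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Check interval invariants; returns the frame unchanged on success."""
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError("interval frame needs chrom, start, end columns")
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise ValueError(f"invalid interval(s) at row(s) {list(bad[:5])}: need 0 <= start < end")
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            length = genome.chrom_length(str(chrom))  # KeyError if unknown
            if (sub["end"] > length).any():
                row = sub.index[sub["end"] > length][0]
                raise ValueError(f"row {row}: interval on {chrom} extends past length {length}")
    return df


def read_intervals(
    path: str | Path,
    format: str = "bed",
    one_based: bool = False,
    genome: GenomeSpec | None = None,
) -> pd.DataFrame:
    """Read a BED or narrowPeak file into an interval frame.

    narrowPeak uses columns 1-3 for coordinates; the remaining standard
    columns are retained as metadata. ``one_based`` shifts starts down by
    one for lists shipped with 1-based inclusive starts.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if one_based:
                start -= 1
            if end <= start or start < 0:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            rec = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) > 3:
                rec["id"] = fields[3]
            if len(fields) > 4:
                try:
                    rec["score"] = float(fields[4])
                except ValueError:
                    rec["score"] = np.nan
            if format == "narrowPeak" and len(fields) >= 10:
                rec["signal"] = float(fields[6])
                rec["pvalue"] = float(fields[7])
                rec["summit"] = int(fields[9])
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"] if not rows else None)
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    else:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
    return validate_intervals(df, genome)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals as BED (up to 6 columns, tab-separated)."""
    out = df.copy()
    if "id" not in out.columns:
        out["id"] = "."
    if "score" not in out.columns:
        out["score"] = 0
    out["strand"] = out["strand"] if "strand" in out.columns else "."
    out = out[["chrom", "start", "end", "id", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class AnchorSet:
    """Sorted, id-bearing anchor intervals plus calling provenance."""

    intervals: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.intervals
        validate_intervals(df)
        if "id" not in df.columns:
            df = df.copy()
            df["id"] = [f"anchor_{i:05d}" for i in range(1, len(df) + 1)]
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ValueError("duplicate anchor ids")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path: str | Path, **kw) -> "AnchorSet":
        return cls(read_intervals(path, **kw), provenance={"source": str(path)})

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.intervals, path)


def _overlap_mask(targets: pd.DataFrame, others: pd.DataFrame, min_overlap: int = 1) -> np.ndarray:
    """Boolean per target row: overlaps `others` by >= min_overlap bp."""
    if len(targets) == 0 or len(others) == 0:
        return np.zeros(len(targets), dtype=bool)
    t = targets[["chrom", "start", "end"]].copy()
    t["_row"] = np.arange(len(t))
    joined = _to_pyranges(t).join(_to_pyranges(others[["chrom", "start", "end"]]))
    mask = np.zeros(len(targets), dtype=bool)
    if len(joined) == 0:
        return mask
    jdf = joined.df
    ov = np.minimum(jdf["End"], jdf["End_b"]) - np.maximum(jdf["Start"], jdf["Start_b"])
    hit = jdf.loc[ov >= min_overlap, "_row"].unique()
    mask[hit] = True
    return mask


def merge_union(tracks: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union-merge intervals pooled across tracks (bookended runs coalesce)."""
    pooled = pd.concat([t[["chrom", "start", "end"]] for t in tracks], ignore_index=True)
    if len(pooled) == 0:
        return pooled
    merged = _from_pyranges(_to_pyranges(pooled).merge())
    return merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_anchors(
    atac_stages: Sequence[pd.DataFrame],
    chip_tracks: Sequence[pd.DataFrame],
    min_stages: int = 2,
    require_all_chip: bool = True,
    min_overlap: int = 1,
    stage_names: Sequence[str] | None = None,
    chip_names: Sequence[str] | None = None,
) -> AnchorSet:
    """Identify anchors: stage-consistent accessible peaks bound by all ChIP factors.

    The merged union of the three stage ATAC peak sets is the candidate
    universe; a candidate counts a stage as supporting if any of that
    stage's peaks overlaps it. Candidates supported by >= ``min_stages``
    stages and overlapping every ChIP track (or any one, with
    ``require_all_chip=False``) become anchors, keeping the merged ATAC
    coordinates.
    """
    if len(atac_stages) != 3:
        raise ValueError(f"expected exactly 3 ATAC stage peak sets, got {len(atac_stages)}")
    if len(chip_tracks) == 0:
        raise ValueError("need at least one ChIP peak set")
    candidates = merge_union(atac_stages)
    if len(candidates) == 0:
        return AnchorSet(candidates.assign(id=pd.Series(dtype=str)))
    support = np.zeros(len(candidates), dtype=int)
    for stage in atac_stages:
        support += _overlap_mask(candidates, stage, min_overlap)
    keep = support >= min_stages
    chip_hits = np.column_stack(
        [_overlap_mask(candidates, chip, min_overlap) for chip in chip_tracks]
    )
    keep &= chip_hits.all(axis=1) if require_all_chip else chip_hits.any(axis=1)
    out = candidates.loc[keep].reset_index(drop=True)
    out["id"] = [f"anchor_{i:05d}" for i in range(1, len(out) + 1)]
    prov = {
        "atac_stages": list(stage_names) if stage_names else [f"stage_{i}" for i in range(3)],
        "chip_tracks": list(chip_names) if chip_names else [f"chip_{i}" for i in range(len(chip_tracks))],
        "min_stages": min_stages,
        "require_all_chip": require_all_chip,
        "min_overlap": min_overlap,
    }
    return AnchorSet(out, provenance=prov)


def bins_containing(anchors: AnchorSet, genome: GenomeSpec) -> tuple[np.ndarray, int, int]:
    """Distinct bin ids overlapped by >=1 anchor, their count, and the genome bin total.

    An anchor straddling a bin boundary marks every bin it touches.
    """
    validate_intervals(anchors.intervals, genome)
    ids: set[int] = set()
    for row in anchors.intervals.itertuples(index=False):
        ids.update(genome.bin_range(row.chrom, int(row.start), int(row.end)))
    arr = np.array(sorted(ids), dtype=np.int64)
    return arr, len(arr), genome.n_bins


def anchor_width_stats(anchors: AnchorSet, ddof: int = 1) -> dict[str, float]:
    """Width summary (bp): min, max, mean, sd (sample sd by default)."""
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    widths = (anchors.intervals["end"] - anchors.intervals["start"]).to_numpy(dtype=float)
    sd = float("nan") if (ddof == 1 and len(widths) < 2) else float(np.std(widths, ddof=ddof))
    return {
        "min": float(widths.min()),
        "max": float(widths.max()),
        "mean": float(widths.mean()),
        "sd": sd,
        "n": int(len(widths)),
    }
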