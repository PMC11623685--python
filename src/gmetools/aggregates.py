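"""Anchor-pair aggregate analysis and virtual-4C network statistics.

Pile-ups average (2k+1)x(2k+1) contact-matrix windows centered on a set of
bin pairs: all anchor-anchor pairs (PESCAn), called significant contacts
(APA), or diagonally shifted positions (backgrounds). Virtual-4C networks
are the per-viewpoint contact sets extracted from the significant-contact
list, from which anchor-contact fractions and the pairwise shared-contact
statistic are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .hicmat import ContactMatrix


@dataclass
class Submatrix:
    """Averaged pile-up window; center cell (k, k) is the pair itself."""

    values: np.ndarray
    n_pairs: int
    mode: str  # cis | trans
    background_offset: int | None = None  # bp, None for the signal window

    @property
    def k(self) -> int:
        return self.values.shape[0] // 2

    @property
    def center(self) -> float:
        return float(self.values[self.k, self.k])

    def to_frame(self) -> pd.DataFrame:
        k = self.k
        idx = [f"{d:+d}" for d in range(-k, k + 1)]
        return pd.DataFrame(self.values, index=idx, columns=idx)


def _window_average(
    M: ContactMatrix,
    pairs: Iterable[tuple[int, int]],
    flank_k: int,
    mode: str,
    shift_bins: int = 0,
) -> Submatrix:
    """Average windows centered at (i + shift, j + shift) over the given pairs.

    Windows clipped at chromosome edges are dropped; cells falling on masked
    bins are averaged over the pairs where they are defined.
    """
    g = M.genome
    size = 2 * flank_k + 1
    total = np.zeros((size, size))
    count = np.zeros((size, size))
    n_used = 0
    cache: dict[tuple[str, str], np.ndarray] = {}
    for bi, bj in pairs:
        ca, ia = g.bin_location(bi)[0], bi - g.chrom_offset(g.bin_location(bi)[0])
        cb, jb = g.bin_location(bj)[0], bj - g.chrom_offset(g.bin_location(bj)[0])
        ia, jb = ia + shift_bins, jb + shift_bins
        na, nb = g.chrom_nbins(ca), g.chrom_nbins(cb)
        if not (flank_k <= ia < na - flank_k and flank_k <= jb < nb - flank_k):
            continue
        if (ca, cb) not in cache:
            cache[(ca, cb)] = M.dense_block(ca, cb)
        win = cache[(ca, cb)][ia - flank_k: ia + flank_k + 1, jb - flank_k: jb + flank_k + 1]
        finite = np.isfinite(win)
        total[finite] += win[finite]
        count += finite
        n_used += 1
    if n_used == 0:
        raise ValueError(
            f"no eligible {mode} windows (flank_k={flank_k}, shift={shift_bins} bins): "
            "all pairs filtered or clipped"
        )
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / count, np.nan)
    return Submatrix(values, n_pairs=n_used, mode=mode)


def anchor_pairs(
    genome: GenomeSpec,
    anchor_bins: Sequence[int],
    mode: str = "cis",
    min_dist: int = 0,
) -> list[tuple[int, int]]:
    """Ordered anchor-bin pairs: cis (i < j, same chromosome, >= min_dist bp
    apart) or trans (different chromosomes)."""
    bins = np.sort(np.unique(np.asarray(anchor_bins, dtype=np.int64)))
    ci = genome.bin_chrom_index(bins)
    out = []
    for a in range(len(bins)):
        for b in range(a + 1, len(bins)):
            same = ci[a] == ci[b]
            if mode == "cis" and same:
                if (bins[b] - bins[a]) * genome.bin_size >= min_dist:
                    out.append((int(bins[a]), int(bins[b])))
            elif mode == "trans" and not same:
                out.append((int(bins[a]), int(bins[b])))
    return out


def pescan(
    M: ContactMatrix,
    anchor_bins: Sequence[int],
    flank_k: int = 5,
    min_dist: int | None = None,
    mode: str = "cis",
) -> Submatrix:
    """All-vs-all anchor pile-up on an O/E or balanced matrix.

    ``min_dist`` defaults to 0 for O/E input and 300 kb for balanced input
    (on a balanced matrix short-range pairs would be dominated by distance
    decay; O/E has it divided out).
    """
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be cis or trans")
    if flank_k < 1:
        raise ValueError("flank_k must be >= 1")
    if min_dist is None:
        min_dist = 0 if M.kind == "obs_exp" else 300_000
    pairs = anchor_pairs(M.genome, anchor_bins, mode=mode, min_dist=min_dist)
    return _window_average(M, pairs, flank_k, mode)


def shifted_background(
    M: ContactMatrix,
    anchor_bins: Sequence[int],
    offsets: Sequence[int] = (100_000, 500_000, 1_000_000),
    flank_k: int = 5,
    min_dist: int | None = None,
    mode: str = "cis",
) -> dict[int, Submatrix]:
    """Pile-ups at diagonally shifted positions, one per offset (bp)."""
    bs = M.genome.bin_size
    for off in offsets:
        if off % bs != 0:
            raise ValueError(f"offset {off} is not a multiple of the bin size {bs}")
    if min_dist is None:
        min_dist = 0 if M.kind == "obs_exp" else 300_000
    pairs = anchor_pairs(M.genome, anchor_bins, mode=mode, min_dist=min_dist)
    out = {}
    for off in offsets:
        sub = _window_average(M, pairs, flank_k, mode, shift_bins=off // bs)
        sub.background_offset = off
        out[off] = sub
    return out


def apa(significant: pd.DataFrame, M: ContactMatrix, flank_k: int = 5) -> Submatrix:
    """Aggregate peak analysis: pile-up centered on called significant contacts."""
    if len(significant) == 0:
        raise ValueError("empty significant-contact list")
    pairs = list(zip(significant["bin_i"].astype(int), significant["bin_j"].astype(int)))
    return _window_average(M, pairs, flank_k, mode="contacts")


# -- virtual 4C networks -----------------------------------------------------------


@dataclass
class NetworkMap:
    """Undirected contact adjacency over bins, with a designated anchor set."""

    adjacency: dict[int, set[int]] = field(default_factory=dict)
    anchor_bins: set[int] = field(default_factory=set)

    def neighbors(self, bin_id: int) -> set[int]:
        return self.adjacency.get(bin_id, set())

    @property
    def viewpoints(self) -> list[int]:
        return sorted(self.adjacency)


def build_networks(significant: pd.DataFrame, anchor_bins: Sequence[int]) -> NetworkMap:
    """Adjacency map from a significant-contact list (self-contacts dropped)."""
    net = NetworkMap(anchor_bins=set(int(b) for b in anchor_bins))
    for bi, bj in zip(significant["bin_i"].astype(int), significant["bin_j"].astype(int)):
        if bi == bj:
            continue
        net.adjacency.setdefault(bi, set()).add(bj)
        net.adjacency.setdefault(bj, set()).add(bi)
    return net


def gme_fraction(net: NetworkMap, viewpoint: int) -> float:
    """Fraction of a viewpoint's contacts that are anchor bins."""
    nbrs = net.neighbors(viewpoint)
    if not nbrs:
        raise ValueError(f"viewpoint {viewpoint} has no contacts")
    return len(nbrs & net.anchor_bins) / len(nbrs)


def fraction_cohorts(net: NetworkMap) -> dict:
    """Anchor-viewpoint vs non-anchor-viewpoint anchor-contact fractions.

    Returns both distributions, their medians, and a two-sided rank-sum p.
    Isolated bins never appear in the adjacency, so every viewpoint has
    >= 1 contact by construction.
    """
    anchor_fr, other_fr = [], []
    for v in net.viewpoints:
        (anchor_fr if v in net.anchor_bins else other_fr).append(gme_fraction(net, v))
    res = {
        "anchor_fractions": np.array(anchor_fr),
        "other_fractions": np.array(other_fr),
        "anchor_median": float(np.median(anchor_fr)) if anchor_fr else np.nan,
        "other_median": float(np.median(other_fr)) if other_fr else np.nan,
    }
    if anchor_fr and other_fr:
        res["p_value"] = float(stats.mannwhitneyu(anchor_fr, other_fr, alternative="two-sided").pvalue)
    else:
        res["p_value"] = np.nan
    return res


def network_overlap_stat(net: NetworkMap, jaccard: bool = False) -> dict:
    """Shared-contact proportion for every ordered anchor pair.

    For anchor viewpoints V, W the compared sets are each side's anchor
    contacts with the partner removed, S_V = (N(V) & anchors) - {W}; the
    proportion is |S_V & S_W| / |S_V| (viewpoint-normalized) or the Jaccard
    index of S_V and S_W. Pairs are classed V-C when W is a direct contact
    of V and V-NC otherwise. Anchors with no anchor contacts (and pairs
    with an empty compared set) are excluded; the count is reported.
    """
    anchors = sorted(b for b in net.anchor_bins if net.neighbors(b) & net.anchor_bins)
    n_excluded = len([b for b in net.anchor_bins if b in net.adjacency]) - len(anchors)
    rows = []
    asets = {v: net.neighbors(v) & net.anchor_bins for v in anchors}
    for v in anchors:
        for w in anchors:
            if v == w:
                continue
            s_v = asets[v] - {w}
            s_w = asets[w] - {v}
            if not s_v:
                continue
            shared = len(s_v & s_w)
            denom = len(s_v | s_w) if jaccard else len(s_v)
            rows.append({
                "viewpoint": v, "partner": w,
                "pair_class": "V-C" if w in net.neighbors(v) else "V-NC",
                "shared": shared, "denominator": denom,
                "proportion": shared / denom if denom else np.nan,
            })
    table = pd.DataFrame(rows, columns=["viewpoint", "partner", "pair_class",
                                        "shared", "denominator", "proportion"])
    vc = table.loc[table["pair_class"] == "V-C", "proportion"]
    vnc = table.loc[table["pair_class"] == "V-NC", "proportion"]
    out = {
        "table": table,
        "vc_median": float(vc.median()) if len(vc) else np.nan,
        "vnc_median": float(vnc.median()) if len(vnc) else np.nan,
        "n_excluded_anchors": n_excluded,
    }
    if len(vc) and len(vnc):
        out["p_value"] = float(stats.mannwhitneyu(vc, vnc, alternative="two-sided").pvalue)
    else:
        out["p_value"] = np.nan
    return out
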