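"""Insulation-based TAD analysis and contact-distance bootstrap nulls.

The separation score of a bin measures how strongly contacts cross it: for
a ladder of window sizes, the mean balanced contact between the regions
immediately upstream and downstream of the bin is z-scored per chromosome
per window size and averaged across window sizes. TAD borders are
significant local minima of this score; domains span between the midpoints
of consecutive borders (with leading/trailing segments to the chromosome
ends), so the genome is tiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .genome import GenomeSpec
from .hicmat import ContactMatrix


@dataclass
class BootstrapResult:
    """Observed statistic, resampled statistics, and the add-one bootstrap p.

    p = (1 + #{s >= s0}) / (N + 1), always in (0, 1].
    """

    s0: float
    samples: np.ndarray
    seed: int | None = None

    @property
    def N(self) -> int:
        return len(self.samples)

    @property
    def p(self) -> float:
        return (1 + int(np.sum(self.samples >= self.s0))) / (self.N + 1)

    def to_dict(self) -> dict:
        return {"s0": self.s0, "N": self.N, "p": self.p, "seed": self.seed}


@dataclass
class TADSet:
    """Called borders (bin-sized intervals), derived domains, per-bin scores."""

    genome: GenomeSpec
    borders: pd.DataFrame  # chrom, start, end, bin_id, score
    domains: pd.DataFrame  # chrom, start, end, id
    scores: np.ndarray = field(repr=False, default=None)  # per global bin, NaN undefined

    @property
    def border_bins(self) -> np.ndarray:
        return self.borders["bin_id"].to_numpy(dtype=np.int64)


def _diamond_means(block: np.ndarray, w: int) -> np.ndarray:
    """Mean contact between the w bins upstream and w bins downstream of each
    bin (NaN-aware); NaN where the window does not fit."""
    n = block.shape[0]
    out = np.full(n, np.nan)
    finite = np.isfinite(block)
    vals = np.where(finite, block, 0.0)
    # summed-area tables for O(1) block sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = np.cumsum(np.cumsum(vals, axis=0), axis=1)
    cnt = np.zeros((n + 1, n + 1))
    cnt[1:, 1:] = np.cumsum(np.cumsum(finite, axis=0), axis=1)

    def block_sum(tab, r0, r1, c0, c1):  # rows [r0, r1), cols [c0, c1)
        return tab[r1, c1] - tab[r0, c1] - tab[r1, c0] + tab[r0, c0]

    for b in range(w, n - w):
        s = block_sum(sat, b - w, b, b + 1, b + w + 1)
        c = block_sum(cnt, b - w, b, b + 1, b + w + 1)
        if c > 0:
            out[b] = s / c
    return out


def tad_separation_score(
    M: ContactMatrix,
    min_depth: int = 75_000,
    max_depth: int = 2_500_000,
    step: int = 25_000,
) -> np.ndarray:
    """Per-bin multi-window separation (insulation) score on a balanced matrix.

    Returns one value per global bin (NaN where no window fits). Lower
    scores mean stronger insulation.
    """
    g = M.genome
    bs = g.bin_size
    for name, v in (("min_depth", min_depth), ("max_depth", max_depth), ("step", step)):
        if v % bs != 0:
            raise ValueError(f"{name} must be a multiple of the bin size")
    if max_depth <= min_depth:
        raise ValueError("max_depth must exceed min_depth")
    windows = list(range(min_depth // bs, max_depth // bs + 1, step // bs))
    scores = np.full(g.n_bins, np.nan)
    for chrom in g.chrom_names:
        n = g.chrom_nbins(chrom)
        if n < 2 * windows[0] + 1:
            continue  # chromosome too short for even the smallest window
        block = M.dense_block(chrom)
        zs = []
        for w in windows:
            if n < 2 * w + 1:
                continue
            m = _diamond_means(block, w)
            ok = np.isfinite(m)
            if ok.sum() < 2:
                continue
            mu, sd = m[ok].mean(), m[ok].std()
            # a (numerically) flat field carries no insulation signal
            flat = sd <= 1e-8 * max(abs(mu), np.abs(m[ok]).max(), 1e-300)
            z = np.full(n, np.nan)
            z[ok] = 0.0 if flat else (m[ok] - mu) / sd
            zs.append(z)
        if zs:
            stack = np.vstack(zs)
            cnt = np.isfinite(stack).sum(axis=0)
            mean_z = np.where(cnt > 0, np.nansum(np.where(np.isfinite(stack), stack, 0.0),
                                                 axis=0) / np.maximum(cnt, 1), np.nan)
            sl = g.chrom_slice(chrom)
            scores[sl.start: sl.start + n] = mean_z
    return scores


def call_borders(
    scores: np.ndarray,
    genome: GenomeSpec,
    q: float = 0.05,
    min_prominence: float = 0.1,
) -> TADSet:
    """TAD borders from separation-score minima with an empirical FDR filter.

    Candidate borders are local minima of the score; each candidate's
    prominence is compared with the empirical distribution of consecutive-bin
    score changes on the same genome (the no-border null), and candidates
    pass Benjamini-Hochberg at level *q* (with a prominence floor). Borders
    are single bins; domains cut at border midpoints and tile every
    chromosome.
    """
    cand = []  # (global_bin, prominence, score)
    null_deltas = []
    for chrom in genome.chrom_names:
        sl = genome.chrom_slice(chrom)
        s = scores[sl]
        ok = np.isfinite(s)
        if ok.sum() < 3:
            continue
        sf = s[ok]
        idx = np.flatnonzero(ok)
        null_deltas.append(np.abs(np.diff(sf)))
        peaks, props = signal.find_peaks(-sf, prominence=0)
        for p_i, prom in zip(peaks, props["prominences"]):
            cand.append((sl.start + idx[p_i], float(prom), float(sf[p_i])))
    border_rows = []
    if cand and null_deltas:
        null = np.sort(np.concatenate(null_deltas))
        proms = np.array([c[1] for c in cand])
        # empirical p: fraction of null deltas at least as large, add-one
        n_ge = len(null) - np.searchsorted(null, proms, side="left")
        pvals = (1 + n_ge) / (1 + len(null))
        order = np.argsort(pvals)
        m = len(pvals)
        passed = np.zeros(m, dtype=bool)
        thresh = 0
        for rank, i in enumerate(order, start=1):
            if pvals[i] <= q * rank / m:
                thresh = rank
        passed[order[:thresh]] = True
        passed &= proms >= min_prominence
        for (b, prom, sc), ok_ in zip(cand, passed):
            if ok_:
                chrom, st, en = genome.bin_location(b)
                border_rows.append({"chrom": chrom, "start": st, "end": en,
                                    "bin_id": b, "score": sc, "prominence": prom})
    borders = pd.DataFrame(border_rows, columns=["chrom", "start", "end", "bin_id",
                                                 "score", "prominence"])
    borders = borders.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    domains = _domains_from_borders(borders, genome)
    return TADSet(genome, borders, domains, scores)


def _domains_from_borders(borders: pd.DataFrame, genome: GenomeSpec) -> pd.DataFrame:
    rows = []
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        sub = borders[borders["chrom"] == chrom]
        mids = sorted(int(s) + genome.bin_size // 2 for s in sub["start"])
        cuts = [0] + [m for m in mids if 0 < m < length] + [length]
        for k in range(len(cuts) - 1):
            rows.append({"chrom": chrom, "start": cuts[k], "end": cuts[k + 1],
                         "id": f"{chrom}_TAD_{k + 1}"})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])


def border_overlap(A: TADSet, B: TADSet, slack: int = 0) -> float:
    """Fraction of A's borders with a B border within ``slack`` bins (0 = same bin)."""
    if A.genome != B.genome:
        raise ValueError("TAD sets come from different genomes")
    a = A.border_bins
    if len(a) == 0:
        return float("nan")
    b = np.sort(B.border_bins)
    if len(b) == 0:
        return 0.0
    pos = np.searchsorted(b, a)
    near = np.zeros(len(a), dtype=bool)
    for off in (0, -1):
        k = np.clip(pos + off, 0, len(b) - 1)
        cand = b[k]
        same_chrom = A.genome.bin_chrom_index(cand) == A.genome.bin_chrom_index(a)
        near |= (np.abs(cand - a) <= slack) & same_chrom
    return float(near.mean())


def annotate_tads(contacts: pd.DataFrame, tads: TADSet) -> pd.DataFrame:
    """Assign each contact to its encompassing TADs and count crossed borders.

    Cis contacts get the domain ids of both bins (by bin midpoint), the
    number of border bins strictly between them, and an intra/inter label;
    trans contacts are labelled ``trans``.
    """
    g = tads.genome
    border_bins = np.sort(tads.border_bins)
    dom = tads.domains

    def domain_of(bin_id: int) -> str:
        chrom, st, en = g.bin_location(int(bin_id))
        mid = (st + en) // 2
        sub = dom[(dom["chrom"] == chrom) & (dom["start"] <= mid) & (mid < dom["end"])]
        return sub["id"].iloc[0]

    out = contacts.copy()
    tad_i, tad_j, crossed, label = [], [], [], []
    for r in out.itertuples(index=False):
        if getattr(r, "is_trans", False) or r.chrom_i != r.chrom_j:
            tad_i.append(domain_of(r.bin_i))
            tad_j.append(domain_of(r.bin_j))
            crossed.append(-1)
            label.append("trans")
            continue
        ti, tj = domain_of(r.bin_i), domain_of(r.bin_j)
        lo, hi = sorted((int(r.bin_i), int(r.bin_j)))
        nb = int(np.searchsorted(border_bins, hi, side="left")
                 - np.searchsorted(border_bins, lo, side="right"))
        tad_i.append(ti)
        tad_j.append(tj)
        crossed.append(nb)
        label.append("intra" if ti == tj else "inter")
    out["tad_i"], out["tad_j"] = tad_i, tad_j
    out["borders_crossed"], out["label"] = crossed, label
    return out


def bootstrap_median_distance(
    anchor_contacts: pd.DataFrame,
    pool: pd.DataFrame,
    N: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> BootstrapResult:
    """Bootstrap null for the median cis distance of a contact subset.

    s0 is the median distance of the anchor contacts; each replicate draws
    the same number of contacts from the pool (without replacement by
    default) and records its median distance.
    """
    k = len(anchor_contacts)
    if k == 0:
        raise ValueError("empty anchor contact set")
    dist_pool = pool["distance"].to_numpy(dtype=float)
    if not with_replacement and len(dist_pool) < k:
        raise ValueError(f"pool ({len(dist_pool)}) smaller than sample size ({k})")
    s0 = float(np.median(anchor_contacts["distance"].to_numpy(dtype=float)))
    rng = np.random.default_rng(seed)
    samples = np.empty(N)
    for r in range(N):
        draw = rng.choice(dist_pool, size=k, replace=with_replacement)
        samples[r] = np.median(draw)
    return BootstrapResult(s0=s0, samples=samples, seed=seed)
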