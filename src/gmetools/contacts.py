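"""Significant-contact calling on binned Hi-C matrices.

The chain is: distance-stratified raw upper-tail Poisson p-values for every
eligible bin pair (cis pairs at or beyond a lower distance bound, plus all
trans pairs), followed by local smoothing with an aggregated Cauchy
combination over each pair's lattice neighborhood, then a fixed p-value
threshold. Records travel as a pandas DataFrame with columns
``chrom_i, bin_i, chrom_j, bin_j, count, lam, distance, is_trans, p_raw,
p_act``; bin ids are global, ``distance`` is bp (-1 for trans).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import GenomeSpec
from .hicmat import ContactMatrix, ExpectedProfile

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16

RECORD_COLUMNS = [
    "chrom_i", "bin_i", "chrom_j", "bin_j",
    "count", "lam", "distance", "is_trans", "p_raw", "p_act",
]


@dataclass(frozen=True)
class SignificanceConfig:
    """Parameters of the significance chain.

    lowerbound
        Minimum cis distance considered, bp (default 50 kb: shorter-range
        pairs are dominated by polymer proximity).
    h
        Smoothing bandwidth in bins (default 11, the recommended value at
        25 kb resolution).
    prefilter_p
        Raw p-value cutoff selecting which records receive a smoothed
        p-value (neighbors beyond the cutoff still contribute to smoothing).
    alpha
        Final threshold on the smoothed p-value.
    """

    lowerbound: int = 50_000
    h: int = 11
    prefilter_p: float = 0.05
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= self.prefilter_p < 1):
            raise ValueError("need 0 < alpha <= prefilter_p < 1")
        if self.h < 0 or self.lowerbound < 0:
            raise ValueError("h and lowerbound must be non-negative")


def raw_contact_pvalues(
    M: ContactMatrix,
    biases: np.ndarray,
    expected: ExpectedProfile,
    cfg: SignificanceConfig = SignificanceConfig(),
    include_trans: bool = True,
) -> pd.DataFrame:
    """Upper-tail Poisson p-value for every eligible bin pair.

    The Poisson mean of raw pair (i, j) is the balanced expected value at
    the pair's stratum divided by the product of the pair's biases
    (balanced = b_i * raw * b_j, so raw expectation = E / (b_i * b_j)).
    A zero count gives p_raw = 1 exactly.
    """
    if M.kind != "raw":
        raise ValueError("raw_contact_pvalues expects a raw matrix")
    if biases is None:
        raise ValueError("biases are required (run kr_balance first)")
    g = M.genome
    if cfg.lowerbound % g.bin_size != 0:
        raise ValueError("lowerbound must be a multiple of the bin size")
    lb_bins = cfg.lowerbound // g.bin_size
    S = M.symmetric()
    frames = []
    names = g.chrom_names
    for ai, ca in enumerate(names):
        sa = g.chrom_slice(ca)
        ba = biases[sa]
        # cis pairs at distance >= lb_bins
        n = sa.stop - sa.start
        block = np.asarray(S[sa, sa].todense())
        iu, ju = np.triu_indices(n, k=lb_bins)
        lam = expected.cis[ca][ju - iu] / (ba[iu] * ba[ju])
        ok = np.isfinite(lam)
        frames.append(pd.DataFrame({
            "chrom_i": ca, "bin_i": sa.start + iu[ok],
            "chrom_j": ca, "bin_j": sa.start + ju[ok],
            "count": block[iu[ok], ju[ok]], "lam": lam[ok],
            "distance": (ju[ok] - iu[ok]) * g.bin_size, "is_trans": False,
        }))
        if not include_trans:
            continue
        for cb in names[ai + 1:]:
            sb = g.chrom_slice(cb)
            bb = biases[sb]
            block = np.asarray(S[sa, sb].todense())
            ii, jj = np.meshgrid(np.arange(block.shape[0]), np.arange(block.shape[1]), indexing="ij")
            ii, jj = ii.ravel(), jj.ravel()
            lam = expected.trans_expected(ca, cb) / (ba[ii] * bb[jj])
            ok = np.isfinite(lam)
            frames.append(pd.DataFrame({
                "chrom_i": ca, "bin_i": sa.start + ii[ok],
                "chrom_j": cb, "bin_j": sb.start + jj[ok],
                "count": block[ii[ok], jj[ok]], "lam": lam[ok],
                "distance": -1, "is_trans": True,
            }))
    rec = pd.concat(frames, ignore_index=True)
    rec["count"] = rec["count"].round().astype(np.int64)
    rec["p_raw"] = stats.poisson.sf(rec["count"] - 1, rec["lam"])
    rec.loc[rec["count"] == 0, "p_raw"] = 1.0
    rec["p_act"] = np.nan
    return rec[RECORD_COLUMNS]


def _cauchy_combine_block(p_block: np.ndarray, mask: np.ndarray, h: int) -> np.ndarray:
    """Gaussian-weighted Cauchy combination at every lattice point of a block.

    Only lattice points carrying a record (mask) contribute; the kernel is
    exp(-(di^2+dj^2)/(2 h^2)) truncated at Chebyshev radius h.
    """
    di, dj = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    kernel = np.exp(-(di**2 + dj**2) / (2.0 * max(h, 1) ** 2)) if h > 0 else np.ones((1, 1))
    p = np.clip(p_block, P_FLOOR, P_CEIL)
    t = np.where(mask, np.tan((0.5 - p) * np.pi), 0.0)
    w = mask.astype(float)
    t_sum = ndimage.convolve(t, kernel, mode="constant", cval=0.0)
    w_sum = ndimage.convolve(w, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = t_sum / w_sum
    return 0.5 - np.arctan(stat) / np.pi


def act_smooth(
    records: pd.DataFrame,
    genome: GenomeSpec,
    cfg: SignificanceConfig = SignificanceConfig(),
) -> pd.DataFrame:
    """Fill ``p_act`` by local Cauchy combination within each chromosome(-pair) block.

    Records with ``p_raw <= prefilter_p`` receive a smoothed p-value; every
    computed record contributes to its neighbors' combinations regardless of
    its own p. Cis and trans blocks are smoothed on their own (i, j)
    lattices and never mix.
    """
    rec = records.copy()
    h = cfg.h
    for (ca, cb), sub in rec.groupby(["chrom_i", "chrom_j"], sort=False):
        sa, sb = genome.chrom_slice(ca), genome.chrom_slice(cb)
        na, nb = sa.stop - sa.start, sb.stop - sb.start
        p_block = np.ones((na, nb))
        mask = np.zeros((na, nb), dtype=bool)
        li = sub["bin_i"].to_numpy() - sa.start
        lj = sub["bin_j"].to_numpy() - sb.start
        p_block[li, lj] = sub["p_raw"].to_numpy()
        mask[li, lj] = True
        p_act = _cauchy_combine_block(p_block, mask, h)[li, lj]
        rec.loc[sub.index, "p_act"] = p_act
    rec.loc[rec["p_raw"] > cfg.prefilter_p, "p_act"] = np.nan
    return rec


def filter_significant(
    records: pd.DataFrame,
    alpha: float = 0.01,
    fdr: bool = False,
) -> pd.DataFrame:
    """Keep records with a smoothed p-value below alpha.

    With ``fdr=True`` a Benjamini-Hochberg correction is applied to the
    smoothed p-values first (off by default: the standard chain thresholds
    the raw smoothed p at 0.01).
    """
    rec = records.dropna(subset=["p_act"])
    p = rec["p_act"].to_numpy()
    if fdr and len(p):
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        qvals = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(p)
        q[order] = qvals
        keep = q < alpha
    else:
        keep = p < alpha
    out = rec.loc[keep].sort_values(["chrom_i", "bin_i", "chrom_j", "bin_j"], kind="mergesort")
    return out.reset_index(drop=True)


def write_bedpe(records: pd.DataFrame, genome: GenomeSpec, path: str | Path) -> None:
    """Write contacts as BEDPE: chrom1 start1 end1 chrom2 start2 end2 count p_raw p_act."""
    rows = []
    for r in records.itertuples(index=False):
        c1, s1, e1 = genome.bin_location(int(r.bin_i))
        c2, s2, e2 = genome.bin_location(int(r.bin_j))
        rows.append((c1, s1, e1, c2, s2, e2, r.count, r.p_raw, r.p_act))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
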