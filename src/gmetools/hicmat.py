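"""Binned Hi-C contact matrices: container, I/O, balancing, Obs/Exp, SCC.

The container stores the upper triangle (bin_i <= bin_j) of a symmetric
genome-wide matrix on the global bin index of a :class:`~gmetools.genome.GenomeSpec`.
Matrix *kind* tracks the transform applied: ``raw`` counts, ``balanced``
(Knight-Ruiz corrected), or ``obs_exp`` (balanced value over the
distance-stratified expected).

Balancing biases are multiplicative: the balanced value of a pair is
``b_i * M_ij * b_j`` and unmasked row sums of the balanced matrix equal 1.
Bins with zero marginal count, and optionally the lowest-coverage quantile,
are masked (bias NaN) before balancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import ndimage

from .genome import GenomeSpec


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ContactMatrix:
    genome: GenomeSpec
    mat: sp.csr_matrix  # upper triangle only (i <= j)
    kind: str = "raw"
    biases: np.ndarray | None = None  # per-bin, NaN where masked

    def __post_init__(self) -> None:
        n = self.genome.n_bins
        if self.mat.shape != (n, n):
            raise ValueError(f"matrix shape {self.mat.shape} does not match genome ({n} bins)")
        if self.kind not in ("raw", "balanced", "obs_exp"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    # -- constructors ------------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        genome: GenomeSpec,
        bin_i: np.ndarray,
        bin_j: np.ndarray,
        values: np.ndarray,
        kind: str = "raw",
        biases: np.ndarray | None = None,
    ) -> "ContactMatrix":
        bin_i = np.asarray(bin_i, dtype=np.int64)
        bin_j = np.asarray(bin_j, dtype=np.int64)
        lo, hi = np.minimum(bin_i, bin_j), np.maximum(bin_i, bin_j)
        n = genome.n_bins
        m = sp.coo_matrix((np.asarray(values, dtype=float), (lo, hi)), shape=(n, n))
        m.sum_duplicates()
        return cls(genome, m.tocsr(), kind=kind, biases=biases)

    @classmethod
    def read_coo(cls, path: str | Path, genome: GenomeSpec, kind: str = "raw") -> "ContactMatrix":
        """Read a text COO matrix: ``chrom1 start1 chrom2 start2 value`` per line."""
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["chrom1", "start1", "chrom2", "start2", "value"],
            dtype={"chrom1": str, "chrom2": str},
        )
        bi = np.array([genome.bin_id(c, s) for c, s in zip(df["chrom1"], df["start1"])])
        bj = np.array([genome.bin_id(c, s) for c, s in zip(df["chrom2"], df["start2"])])
        return cls.from_arrays(genome, bi, bj, df["value"].to_numpy(), kind=kind)

    def write_coo(self, path: str | Path) -> None:
        coo = self.mat.tocoo()
        rows = []
        for i, j, v in zip(coo.row, coo.col, coo.data):
            c1, s1, _ = self.genome.bin_location(int(i))
            c2, s2, _ = self.genome.bin_location(int(j))
            rows.append((c1, s1, c2, s2, v))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    # -- basic views -------------------------------------------------------------

    @property
    def total(self) -> float:
        """Sum over distinct bin pairs (upper triangle, diagonal once)."""
        return float(self.mat.sum())

    def symmetric(self) -> sp.csr_matrix:
        d = sp.diags(self.mat.diagonal())
        return (self.mat + self.mat.T - d).tocsr()

    def dense_block(self, chrom_a: str, chrom_b: str | None = None) -> np.ndarray:
        """Symmetric dense block for one chromosome (cis) or a chromosome pair.

        Masked bins (bias NaN) are returned as NaN rows/columns when biases
        are set.
        """
        sa = self.genome.chrom_slice(chrom_a)
        sb = self.genome.chrom_slice(chrom_b) if chrom_b else sa
        block = np.asarray(self.symmetric()[sa, sb].todense(), dtype=float)
        if self.biases is not None:
            mask_a = np.isnan(self.biases[sa])
            mask_b = np.isnan(self.biases[sb])
            block[mask_a, :] = np.nan
            block[:, mask_b] = np.nan
        return block

    def scaled(self, factor: float) -> "ContactMatrix":
        return replace(self, mat=(self.mat * factor).tocsr())


@dataclass
class ExpectedProfile:
    """Distance-stratified expected values of a balanced matrix.

    ``cis[chrom][d]`` is the mean balanced value over all unmasked bin pairs
    of *chrom* at separation d bins (true-zero semantics: pairs with no
    stored contact count as zeros). ``trans[(a, b)]`` is the mean over the
    whole chromosome-pair block.
    """

    genome: GenomeSpec
    cis: dict[str, np.ndarray] = field(default_factory=dict)
    trans: dict[tuple[str, str], float] = field(default_factory=dict)

    def cis_expected(self, chrom: str, dist_bins: np.ndarray) -> np.ndarray:
        return self.cis[chrom][np.asarray(dist_bins)]

    def trans_expected(self, chrom_a: str, chrom_b: str) -> float:
        key = (chrom_a, chrom_b) if (chrom_a, chrom_b) in self.trans else (chrom_b, chrom_a)
        return self.trans[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "distance_bins": d, "expected": e}
            for c, vec in self.cis.items()
            for d, e in enumerate(vec)
        ]
        return pd.DataFrame(rows)


# -- Knight-Ruiz balancing ---------------------------------------------------------


def _kr_core(A: sp.csr_matrix, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer Newton iteration for x with diag(x) A diag(x) 1 = 1."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    v = x * (A @ x)
    rk = e - v
    rho_km1 = float(rk @ rk)
    rout = rold = rho_km1
    n_mvp = 0
    while np.sqrt(rout) > stop_tol:
        k = 0
        y = e.copy()
        inner_tol = max((eta**2) * rout, stop_tol**2)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > inner_tol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = float(rk @ Z)
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / float(p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = float(rk @ Z)
            if k > max_iter:
                break
        x = x * y
        v = x * (A @ x)
        rk = e - v
        rho_km1 = float(rk @ rk)
        rout = rho_km1
        n_mvp += k + 1
        if n_mvp > max_iter:
            raise ConvergenceError(
                f"KR balancing did not converge after {n_mvp} matrix-vector products "
                f"(residual {np.sqrt(rout):.3e})"
            )
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / np.sqrt(rout))
    return x


def kr_balance(
    M: ContactMatrix,
    tol: float = 1e-6,
    max_iter: int = 3000,
    mask_quantile: float = 0.005,
) -> np.ndarray:
    """Knight-Ruiz biases for a raw matrix; masked bins get NaN.

    Bins with zero marginal, and bins in the lowest ``mask_quantile`` of
    nonzero coverage, are masked before balancing. Returned biases satisfy
    ``rowsum(diag(b) M diag(b)) == 1`` on unmasked bins to within *tol*.
    """
    if M.kind != "raw":
        raise ValueError("kr_balance expects a raw matrix")
    S = M.symmetric()
    marg = np.asarray(S.sum(axis=1)).ravel()
    if not np.any(marg > 0):
        raise ValueError("matrix is entirely zero")
    keep = marg > 0
    if mask_quantile > 0 and keep.sum() > 2:
        cut = np.quantile(marg[keep], mask_quantile)
        keep &= marg > cut if (marg[keep] > cut).sum() >= 2 else marg >= cut
    idx = np.flatnonzero(keep)
    sub = S[np.ix_(idx, idx)].tocsr()
    # rows emptied by masking cannot be balanced
    sub_marg = np.asarray(sub.sum(axis=1)).ravel()
    while (sub_marg == 0).any():
        idx = idx[sub_marg > 0]
        sub = S[np.ix_(idx, idx)].tocsr()
        sub_marg = np.asarray(sub.sum(axis=1)).ravel()
    x = _kr_core(sub, tol=tol, max_iter=max_iter)
    biases = np.full(M.genome.n_bins, np.nan)
    biases[idx] = x
    return biases


def balance(M: ContactMatrix, **kw) -> ContactMatrix:
    """Return the KR-balanced matrix (masked bins dropped from storage)."""
    b = kr_balance(M, **kw)
    coo = M.mat.tocoo()
    vals = coo.data * b[coo.row] * b[coo.col]
    ok = np.isfinite(vals)
    m = sp.coo_matrix((vals[ok], (coo.row[ok], coo.col[ok])), shape=M.mat.shape).tocsr()
    return ContactMatrix(M.genome, m, kind="balanced", biases=b)


def as_balanced(M: ContactMatrix) -> ContactMatrix:
    """Treat a raw matrix as already balanced (unit biases).

    For data with flat per-bin coverage -- e.g. simulated matrices with no
    technical bias -- KR balancing has no coverage signal to remove and will
    instead absorb part of any genuine marginal structure (such as planted
    anchor-pair enrichment) into the bias vector. In that setting the
    downstream expected/O-E machinery should run on the raw counts directly;
    this helper relabels them with unit biases.
    """
    if M.kind != "raw":
        raise ValueError("as_balanced expects a raw matrix")
    return ContactMatrix(M.genome, M.mat, kind="balanced",
                         biases=np.ones(M.genome.n_bins))


def normalize_smallest(matrices: list[ContactMatrix]) -> list[ContactMatrix]:
    """Scale every matrix so its total equals the smallest input total."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to normalize")
    g0 = matrices[0].genome
    if any(m.genome != g0 for m in matrices[1:]):
        raise ValueError("matrices are binned on different genomes")
    target = min(m.total for m in matrices)
    return [m.scaled(target / m.total) for m in matrices]


# -- observed / expected -----------------------------------------------------------


def expected_profile(M: ContactMatrix) -> ExpectedProfile:
    """Distance-stratified expected values from a balanced matrix."""
    if M.kind != "balanced":
        raise ValueError("expected_profile wants a balanced matrix")
    prof = ExpectedProfile(M.genome)
    for chrom in M.genome.chrom_names:
        block = M.dense_block(chrom)
        n = block.shape[0]
        exp = np.empty(n)
        for d in range(n):
            diag = np.diagonal(block, offset=d)
            exp[d] = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
        prof.cis[chrom] = exp
    names = M.genome.chrom_names
    for ai, ca in enumerate(names):
        for cb in names[ai + 1:]:
            block = M.dense_block(ca, cb)
            prof.trans[(ca, cb)] = float(np.nanmean(block)) if np.isfinite(block).any() else np.nan
    return prof


def obs_exp(M: ContactMatrix) -> tuple[ContactMatrix, ExpectedProfile]:
    """Observed-over-expected transform of a balanced matrix.

    Stored entries are divided by the expected at their distance stratum
    (cis) or chromosome-pair mean (trans); entries in strata with zero or
    undefined expected are dropped. Unstored pairs remain zero, i.e. an
    observed zero maps to O/E zero.
    """
    prof = expected_profile(M)
    coo = M.mat.tocoo()
    ci = M.genome.bin_chrom_index(coo.row)
    cj = M.genome.bin_chrom_index(coo.col)
    vals = np.full(coo.data.shape, np.nan)
    names = M.genome.chrom_names
    for a in np.unique(ci):
        for b in np.unique(cj[ci == a]):
            sel = (ci == a) & (cj == b)
            if a == b:
                d = coo.col[sel] - coo.row[sel]
                exp = prof.cis[names[a]][d]
            else:
                exp = prof.trans_expected(names[a], names[b])
            vals[sel] = coo.data[sel] / exp
    ok = np.isfinite(vals) & (vals != 0)
    m = sp.coo_matrix((vals[ok], (coo.row[ok], coo.col[ok])), shape=M.mat.shape).tocsr()
    return ContactMatrix(M.genome, m, kind="obs_exp", biases=M.biases), prof


# -- HiCREP stratum-adjusted correlation -------------------------------------------


@dataclass(frozen=True)
class SCCParams:
    """HiCREP parameters: smoothing half-window h (bins), distance bounds (bp)."""

    h: int = 10
    lbr: int = 75_000
    ubr: int = 250_000

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.lbr >= self.ubr:
            raise ValueError("lbr must be < ubr")


def scc(A: ContactMatrix, B: ContactMatrix, params: SCCParams = SCCParams()) -> float:
    """Stratum-adjusted correlation coefficient between two matrices.

    Both cis maps are mean-filter smoothed with a (2h+1)-wide window, then
    Pearson correlations are computed per distance stratum within
    [lbr, ubr] and combined with weights N_d * sqrt(var_A * var_B)
    (Cochran-Mantel-Haenszel-style weighting).
    """
    if A.genome != B.genome:
        raise ValueError("matrices are binned on different genomes")
    if A.kind != B.kind:
        raise ValueError("matrices must share a kind (both raw or both balanced)")
    bs = A.genome.bin_size
    d_lo = max(1, -(-params.lbr // bs))
    d_hi = params.ubr // bs
    if d_hi < d_lo:
        raise ValueError(f"no distance strata between {params.lbr} and {params.ubr} bp")
    size = 2 * params.h + 1
    xs: dict[int, list[np.ndarray]] = {d: [] for d in range(d_lo, d_hi + 1)}
    ys: dict[int, list[np.ndarray]] = {d: [] for d in range(d_lo, d_hi + 1)}
    for chrom in A.genome.chrom_names:
        da = np.nan_to_num(A.dense_block(chrom))
        db = np.nan_to_num(B.dense_block(chrom))
        if params.h > 0:
            da = ndimage.uniform_filter(da, size=size, mode="nearest")
            db = ndimage.uniform_filter(db, size=size, mode="nearest")
        for d in range(d_lo, min(d_hi, da.shape[0] - 1) + 1):
            # drop h positions at each diagonal end: their smoothing windows
            # are clipped, which injects a deterministic edge artefact shared
            # by both matrices and inflates the null correlation
            xd = np.diagonal(da, offset=d)
            yd = np.diagonal(db, offset=d)
            if params.h > 0 and len(xd) > 2 * params.h + 2:
                xd, yd = xd[params.h:-params.h], yd[params.h:-params.h]
            xs[d].append(xd)
            ys[d].append(yd)
    num = den = 0.0
    for d in range(d_lo, d_hi + 1):
        if not xs[d]:
            continue
        x = np.concatenate(xs[d])
        y = np.concatenate(ys[d])
        vx, vy = x.var(), y.var()
        if vx == 0 or vy == 0 or len(x) < 2:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        w = len(x) * np.sqrt(vx * vy)
        num += w * r
        den += w
    if den == 0:
        raise ValueError("no informative strata in the requested distance range")
    return num / den
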