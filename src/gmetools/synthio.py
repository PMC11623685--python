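"""Synthetic datasets with planted, recorded ground truth.

Every generator here emulates the *structure* of one input to the analysis
pipeline -- multi-stage peak tracks containing planted anchors, a
distance-decay Hi-C matrix with planted TAD blocks and multiplicative
anchor-anchor enrichment, two-stage DamID tracks with an additive
lamina-association shift at anchors, and per-focus microscopy tables. The
distributional choices (power-law decay, Poisson counts, Gaussian DamID
noise) are explicit stand-ins chosen for testability, not fitted models of
any real dataset; planted parameters are recorded in a
:class:`SyntheticTruth` so downstream stages can be checked for recovery.

All randomness flows from explicit integer seeds; no global RNG state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec
from .hicmat import ContactMatrix
from .intervals import AnchorSet, validate_intervals
from .lamina import DamIDTrack


def default_genome(bin_size: int = 25_000) -> GenomeSpec:
    """Three-chromosome toy genome (5 + 4 + 3 Mb, 480 bins at 25 kb)."""
    return GenomeSpec.from_dict(
        {"chrA": 5_000_000, "chrB": 4_000_000, "chrC": 3_000_000}, bin_size
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by all generators.

    ``anchor_enrichment = 1`` and ``damid_shift = 0`` define null datasets.
    """

    anchors: pd.DataFrame  # chrom, start, end, id
    tad_blocks: pd.DataFrame  # chrom, start, end
    decay_exponent: float = 1.0  # cis contact frequency ~ distance^-alpha
    tau: float = 2.0  # within-TAD multiplicative factor
    anchor_enrichment: float = 1.0  # e, multiplicative on anchor-anchor bin pairs
    depth: float = 8e6  # total expected contact count
    trans_fraction: float = 0.1  # trans mass as a fraction of cis mass
    damid_shift: float = 0.0  # delta, log2 units added at anchor bins late
    noise_sd: float = 0.2  # sigma, log2 units
    seed: int = 0

    def validate(self, genome: GenomeSpec) -> None:
        validate_intervals(self.anchors, genome)
        validate_intervals(self.tad_blocks, genome)
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        if self.tau < 1 or self.anchor_enrichment < 1:
            raise ValueError("tau and anchor enrichment must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def anchor_bins(self, genome: GenomeSpec) -> np.ndarray:
        """Bins overlapped by any anchor (an anchor straddling a boundary
        marks both bins)."""
        ids: set[int] = set()
        for r in self.anchors.itertuples(index=False):
            ids.update(genome.bin_range(r.chrom, int(r.start), int(r.end)))
        return np.array(sorted(ids), dtype=np.int64)

    def to_manifest(self, path: str | Path) -> None:
        d = asdict(self)
        d["anchors"] = self.anchors.to_dict("records")
        d["tad_blocks"] = self.tad_blocks.to_dict("records")
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def make_truth(
    genome: GenomeSpec | None = None,
    n_anchors: int = 40,
    anchor_enrichment: float = 1.0,
    tau: float = 2.0,
    decay_exponent: float = 1.0,
    depth: float = 8e6,
    trans_fraction: float = 0.1,
    damid_shift: float = 0.0,
    noise_sd: float = 0.2,
    tad_size_bins: tuple[int, int] = (8, 25),
    seed: int = 0,
) -> tuple[GenomeSpec, SyntheticTruth]:
    """Place anchors and TAD blocks on a genome and bundle the parameters.

    Anchors are non-overlapping, at most one per bin, with widths drawn to
    mimic short regulatory elements (lognormal around ~450 bp, clipped to
    [68, 2200] bp). TAD blocks tile each chromosome with bin-aligned borders
    and sizes uniform in ``tad_size_bins``.
    """
    if genome is None:
        genome = default_genome()
    rng = np.random.default_rng(seed)
    bs = genome.bin_size
    # TAD blocks: tile each chromosome with random bin-aligned block widths
    blocks = []
    for chrom in genome.chrom_names:
        n = genome.chrom_nbins(chrom)
        pos = 0
        while pos < n:
            w = int(rng.integers(tad_size_bins[0], tad_size_bins[1] + 1))
            end_bin = min(pos + w, n)
            blocks.append({"chrom": chrom,
                           "start": pos * bs,
                           "end": min(end_bin * bs, genome.chrom_length(chrom))})
            pos = end_bin
    tad_blocks = pd.DataFrame(blocks)
    # anchors: one per distinct randomly chosen bin, width ~ lognormal
    nbins_per_chrom = np.array([genome.chrom_nbins(c) for c in genome.chrom_names])
    all_bins = np.arange(genome.n_bins)
    if n_anchors > genome.n_bins:
        raise ValueError(
            f"cannot place {n_anchors} non-overlapping anchors in {genome.n_bins} bins"
        )
    chosen = rng.choice(all_bins, size=n_anchors, replace=False)
    rows = []
    for k, b in enumerate(np.sort(chosen)):
        chrom, bst, ben = genome.bin_location(int(b))
        width = int(np.clip(rng.lognormal(np.log(420), 0.55), 68, 2200))
        width = min(width, ben - bst)
        start = bst + int(rng.integers(0, ben - bst - width + 1))
        rows.append({"chrom": chrom, "start": start, "end": start + width,
                     "id": f"anchor_{k + 1:05d}"})
    anchors = pd.DataFrame(rows)
    truth = SyntheticTruth(
        anchors=anchors, tad_blocks=tad_blocks,
        decay_exponent=decay_exponent, tau=tau,
        anchor_enrichment=anchor_enrichment, depth=depth,
        trans_fraction=trans_fraction, damid_shift=damid_shift,
        noise_sd=noise_sd, seed=seed,
    )
    truth.validate(genome)
    return genome, truth


# -- peak tracks ---------------------------------------------------------------------

ATAC_STAGES = ("stage10", "stage12", "stage14")
CHIP_TRACKS = ("ez", "psc", "pho", "nup93")


def simulate_peak_tracks(
    genome: GenomeSpec,
    truth: SyntheticTruth,
    n_decoys: int = 0,
    seed: int | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame]:
    """Stage ATAC and factor ChIP peak sets containing the planted anchors.

    Every truth anchor appears as a peak in at least two of the three ATAC
    stages and in all four ChIP tracks (peak coordinates coincide with the
    anchor, so the anchor caller recovers the planted intervals exactly).
    Each decoy violates exactly one calling condition -- present in a single
    ATAC stage, or missing one ChIP track -- and the violation is logged.

    Returns (atac_tracks, chip_tracks, decoy_log).
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    atac: dict[str, list] = {s: [] for s in ATAC_STAGES}
    chip: dict[str, list] = {c: [] for c in CHIP_TRACKS}
    for r in truth.anchors.itertuples(index=False):
        iv = {"chrom": r.chrom, "start": int(r.start), "end": int(r.end)}
        n_stages = 3 if rng.random() < 0.7 else 2
        for s in rng.choice(ATAC_STAGES, size=n_stages, replace=False):
            atac[s].append(iv)
        for c in CHIP_TRACKS:
            chip[c].append(iv)
    # decoys: placed in bins free of anchors, with a recorded violation
    occupied = set(truth.anchor_bins(genome))
    free_bins = np.array([b for b in range(genome.n_bins) if b not in occupied])
    if n_decoys > len(free_bins):
        raise ValueError(
            f"genome too small: {n_decoys} decoys requested but only "
            f"{len(free_bins)} anchor-free bins are available"
        )
    decoy_rows = []
    if n_decoys:
        decoy_bins = rng.choice(free_bins, size=n_decoys, replace=False)
        for k, b in enumerate(np.sort(decoy_bins)):
            chrom, bst, ben = genome.bin_location(int(b))
            width = int(np.clip(rng.lognormal(np.log(420), 0.55), 68, min(2200, ben - bst)))
            start = bst + int(rng.integers(0, ben - bst - width + 1))
            iv = {"chrom": chrom, "start": start, "end": start + width}
            if rng.random() < 0.5:
                violation = "single_atac_stage"
                atac[str(rng.choice(ATAC_STAGES))].append(iv)
                for c in CHIP_TRACKS:
                    chip[c].append(iv)
            else:
                missing = str(rng.choice(CHIP_TRACKS))
                violation = f"missing_chip:{missing}"
                for s in ATAC_STAGES:
                    atac[s].append(iv)
                for c in CHIP_TRACKS:
                    if c != missing:
                        chip[c].append(iv)
            decoy_rows.append({**iv, "id": f"decoy_{k + 1:05d}", "violation": violation})
    cols = ["chrom", "start", "end"]
    atac_df = {s: pd.DataFrame(v, columns=cols).sort_values(cols[:2], kind="mergesort")
               .reset_index(drop=True) for s, v in atac.items()}
    chip_df = {c: pd.DataFrame(v, columns=cols).sort_values(cols[:2], kind="mergesort")
               .reset_index(drop=True) for c, v in chip.items()}
    decoy_log = pd.DataFrame(decoy_rows, columns=cols + ["id", "violation"])
    return atac_df, chip_df, decoy_log


# -- Hi-C ----------------------------------------------------------------------------


def _block_id_per_bin(genome: GenomeSpec, tad_blocks: pd.DataFrame) -> np.ndarray:
    """Index of the TAD block containing each bin's start (-1 if none)."""
    out = np.full(genome.n_bins, -1, dtype=np.int64)
    for k, r in enumerate(tad_blocks.itertuples(index=False)):
        off = genome.chrom_offset(r.chrom)
        b0 = off + int(r.start) // genome.bin_size
        b1 = off + (int(r.end) - 1) // genome.bin_size + 1
        out[b0:b1] = k
    return out


def simulate_hic(
    genome: GenomeSpec,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> ContactMatrix:
    """Poisson contact matrix with distance decay, TAD blocks, and anchor enrichment.

    Expected cis weight for bin pair (i, j): ``max(d, 1)^-alpha * tau^[same
    TAD block] * e^[both bins contain an anchor]``, with d the bin
    separation. Trans pairs get a constant base weight (times the anchor
    factor) scaled so total trans mass is ``trans_fraction`` of cis mass.
    Weights are normalized to sum to ``depth`` and counts drawn
    independently Poisson; the matrix is symmetric, stored upper-triangular.
    """
    truth.validate(genome)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    e = truth.anchor_enrichment
    is_anchor = np.zeros(genome.n_bins, dtype=bool)
    is_anchor[truth.anchor_bins(genome)] = True
    block_of = _block_id_per_bin(genome, truth.tad_blocks)

    cis_weights = []  # (rows, cols, w) per chromosome
    cis_mass = 0.0
    for chrom in genome.chrom_names:
        sl = genome.chrom_slice(chrom)
        n = sl.stop - sl.start
        iu, ju = np.triu_indices(n)
        d = np.maximum(ju - iu, 1).astype(float)
        w = d ** (-truth.decay_exponent)
        gi, gj = sl.start + iu, sl.start + ju
        same_block = (block_of[gi] == block_of[gj]) & (block_of[gi] >= 0)
        w = w * np.where(same_block, truth.tau, 1.0)
        w = w * np.where(is_anchor[gi] & is_anchor[gj], e, 1.0)
        cis_weights.append((gi, gj, w))
        cis_mass += w.sum()

    trans_weights = []
    trans_raw_mass = 0.0
    names = genome.chrom_names
    for ai, ca in enumerate(names):
        sa = genome.chrom_slice(ca)
        for cb in names[ai + 1:]:
            sb = genome.chrom_slice(cb)
            gi = np.repeat(np.arange(sa.start, sa.stop), sb.stop - sb.start)
            gj = np.tile(np.arange(sb.start, sb.stop), sa.stop - sa.start)
            w = np.where(is_anchor[gi] & is_anchor[gj], e, 1.0)
            trans_weights.append((gi, gj, w))
            trans_raw_mass += w.sum()
    trans_scale = (
        truth.trans_fraction * cis_mass / trans_raw_mass if trans_raw_mass > 0 else 0.0
    )

    total_mass = cis_mass + trans_scale * trans_raw_mass
    rate = truth.depth / total_mass
    bi_all, bj_all, counts_all = [], [], []
    for gi, gj, w in cis_weights:
        lam = w * rate
        c = rng.poisson(lam)
        nz = c > 0
        bi_all.append(gi[nz]); bj_all.append(gj[nz]); counts_all.append(c[nz])
    for gi, gj, w in trans_weights:
        lam = w * rate * trans_scale
        c = rng.poisson(lam)
        nz = c > 0
        bi_all.append(gi[nz]); bj_all.append(gj[nz]); counts_all.append(c[nz])
    return ContactMatrix.from_arrays(
        genome,
        np.concatenate(bi_all), np.concatenate(bj_all),
        np.concatenate(counts_all).astype(float),
        kind="raw",
    )


# -- DamID ---------------------------------------------------------------------------


def simulate_damid(
    genome: GenomeSpec,
    truth: SyntheticTruth,
    seed: int | None = None,
) -> tuple[DamIDTrack, DamIDTrack]:
    """Early and late log2-ratio tracks with the planted shift at anchor bins.

    early ~ Normal(0, sigma) per bin; late = early + delta at anchor bins
    plus fresh Normal(0, sigma) noise everywhere.
    """
    truth.validate(genome)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sigma = truth.noise_sd
    early = rng.normal(0.0, sigma, genome.n_bins)
    late = early + rng.normal(0.0, sigma, genome.n_bins)
    late[truth.anchor_bins(genome)] += truth.damid_shift
    return (DamIDTrack(genome, early, stage="early"),
            DamIDTrack(genome, late, stage="late"))


# -- microscopy foci -----------------------------------------------------------------


def simulate_foci(
    n_nuclei: int,
    p_on: float,
    p_near: float,
    seed: int = 0,
    n_embryos: int = 1,
    condition: str = "ctrl",
    near_threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-focus lamina-proximity table: label (on | near | interior) and
    distance to the lamina in um.

    "on" foci touch the lamina (distance 0), "near" foci lie within
    ``near_threshold`` um, "interior" foci beyond it.
    """
    if p_on < 0 or p_near < 0 or p_on + p_near > 1:
        raise ValueError("need p_on, p_near >= 0 and p_on + p_near <= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_nuclei)
    labels = np.where(u < p_on, "on", np.where(u < p_on + p_near, "near", "interior"))
    dist = np.empty(n_nuclei)
    near = labels == "near"
    interior = labels == "interior"
    dist[labels == "on"] = 0.0
    dist[near] = rng.uniform(0, near_threshold, near.sum())
    # interior distances: anywhere up to a few um into the nucleus
    dist[interior] = rng.uniform(near_threshold, 2.5, interior.sum())
    # guard the open/closed ends of the "near" interval
    dist[near] = np.nextafter(dist[near], near_threshold)
    return pd.DataFrame({
        "focus": np.arange(n_nuclei),
        "embryo": np.arange(n_nuclei) % max(n_embryos, 1),
        "condition": condition,
        "label": labels,
        "distance": dist,
    })
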