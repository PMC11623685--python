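"""Lamina-association analysis: DamID log-ratio tracks, stage differentials,
site scoring with bootstrap nulls, and the microscopy-derived table statistics.

A DamID track holds per-bin log2(Dam::Lamin / Dam) values on a genome's bin
grid; positive values mean lamina proximity. Mobilization of a site set to
the lamina between stages is scored as the mean differential (late - early)
signal over the bins each site overlaps, compared against the genome-wide
baseline and against resampled site sets drawn from a pool of accessible
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .domains import BootstrapResult
from .genome import GenomeSpec
from .intervals import AnchorSet


@dataclass
class DamIDTrack:
    genome: GenomeSpec
    values: np.ndarray  # one per global bin, NaN = missing
    stage: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError("track length does not match genome bin count")

    def to_bedgraph(self, path: str | Path) -> None:
        rows = []
        for b, v in enumerate(self.values):
            if np.isfinite(v):
                chrom, st, en = self.genome.bin_location(b)
                rows.append((chrom, st, en, v))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome: GenomeSpec, stage: str = "") -> "DamIDTrack":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"], dtype={"chrom": str})
        vals = np.full(genome.n_bins, np.nan)
        for r in df.itertuples(index=False):
            vals[genome.bin_id(r.chrom, int(r.start))] = r.value
        return cls(genome, vals, stage=stage)


def damid_log2(
    lamin_cov: np.ndarray,
    dam_cov: np.ndarray,
    genome: GenomeSpec,
    pseudocount: float = 1.0,
    stage: str = "",
) -> DamIDTrack:
    """Per-bin log2((Dam::Lamin + pc) / (Dam + pc)) after library-size scaling.

    The Dam-only track is the reference: the fusion library is rescaled to
    the Dam library total before the ratio, so sequencing the fusion library
    deeper (or shallower) leaves the track unchanged, and equal totals mean
    no rescaling at all.
    """
    lamin = np.asarray(lamin_cov, dtype=float)
    dam = np.asarray(dam_cov, dtype=float)
    if lamin.shape != dam.shape or lamin.shape != (genome.n_bins,):
        raise ValueError("coverage tracks must both match the genome bin count")
    tl, td = lamin.sum(), dam.sum()
    if tl <= 0 or td <= 0:
        raise ValueError("zero-total coverage track")
    vals = np.log2((lamin * td / tl + pseudocount) / (dam + pseudocount))
    return DamIDTrack(genome, vals, stage=stage)


def differential(late: DamIDTrack, early: DamIDTrack) -> DamIDTrack:
    """Per-bin late - early; missing in either stage stays missing."""
    if late.genome != early.genome:
        raise ValueError("tracks are binned on different genomes")
    return DamIDTrack(late.genome, late.values - early.values,
                      stage=f"{late.stage}-{early.stage}")


def score_sites(diff: DamIDTrack, sites: AnchorSet) -> tuple[pd.DataFrame, dict]:
    """Mean differential per site plus the genome-wide baseline.

    Each site's score is the unweighted mean of the differential over the
    bins it overlaps. Sites are classed against the baseline: ``baseline``,
    ``>1SD`` or ``>2SD`` above the genome-wide mean; sites whose bins are
    all missing are classed ``missing``.
    """
    g = diff.genome
    defined = np.isfinite(diff.values)
    if not defined.any():
        raise ValueError("differential track has no defined bins")
    baseline = {"mean": float(diff.values[defined].mean()),
                "sd": float(diff.values[defined].std()),
                "n_bins": int(defined.sum())}
    rows = []
    for r in sites.intervals.itertuples(index=False):
        bins = list(g.bin_range(r.chrom, int(r.start), int(r.end)))
        v = diff.values[bins]
        v = v[np.isfinite(v)]
        score = float(v.mean()) if len(v) else np.nan
        if np.isnan(score):
            cls = "missing"
        elif score > baseline["mean"] + 2 * baseline["sd"]:
            cls = ">2SD"
        elif score > baseline["mean"] + 1 * baseline["sd"]:
            cls = ">1SD"
        else:
            cls = "baseline"
        rows.append({"id": r.id, "score": score, "classification": cls})
    return pd.DataFrame(rows), baseline


def _site_scores(diff: DamIDTrack, intervals: pd.DataFrame) -> np.ndarray:
    g = diff.genome
    out = np.empty(len(intervals))
    for k, r in enumerate(intervals.itertuples(index=False)):
        bins = list(g.bin_range(r.chrom, int(r.start), int(r.end)))
        v = diff.values[bins]
        v = v[np.isfinite(v)]
        out[k] = v.mean() if len(v) else np.nan
    return out


def bootstrap_site_sets(
    diff: DamIDTrack,
    anchors: AnchorSet,
    pool: AnchorSet,
    N: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap null for the mean site differential.

    s0 is the mean score of the anchor set; each replicate draws
    ``len(anchors)`` sites from the pool without replacement and records the
    mean of their scores. p follows the add-one formula of
    :class:`~gmetools.domains.BootstrapResult`.
    """
    n_sites = len(anchors)
    if len(pool) < n_sites:
        raise ValueError(f"pool ({len(pool)}) smaller than anchor set ({n_sites})")
    s0_scores = _site_scores(diff, anchors.intervals)
    s0 = float(np.nanmean(s0_scores))
    pool_scores = _site_scores(diff, pool.intervals)
    rng = np.random.default_rng(seed)
    samples = np.empty(N)
    for r in range(N):
        idx = rng.choice(len(pool_scores), size=n_sites, replace=False)
        samples[r] = np.nanmean(pool_scores[idx])
    return BootstrapResult(s0=s0, samples=samples, seed=seed)


# -- microscopy-derived tabular statistics ------------------------------------------


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided equal-variance (pooled) t-test between two condition samples."""
    res = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b))}


def foci_lamina_proportion(
    foci: pd.DataFrame,
    near_threshold: float = 0.4,
) -> pd.DataFrame:
    """Per-embryo proportion of foci at the lamina ((on + near) / total).

    A focus counts as "on" when its ``label`` says so (or distance is 0) and
    as "near" when 0 < distance <= ``near_threshold`` um. Expects columns
    ``distance`` (um) and optionally ``label``, ``embryo``, ``condition``.
    Embryos with zero foci simply do not appear. Use
    :func:`pooled_ttest` on the per-embryo proportions of two conditions.
    """
    if len(foci) == 0:
        raise ValueError("empty foci table")
    df = foci.copy()
    if "embryo" not in df.columns:
        df["embryo"] = 0
    if "condition" not in df.columns:
        df["condition"] = "all"
    if "label" in df.columns:
        at_lamina = df["label"].isin(["on", "near"])
    else:
        at_lamina = df["distance"] <= near_threshold
    df["_at_lamina"] = at_lamina.to_numpy()
    out = (
        df.groupby(["condition", "embryo"])
        .agg(n_foci=("_at_lamina", "size"), n_lamina=("_at_lamina", "sum"))
        .reset_index()
    )
    out["proportion"] = out["n_lamina"] / out["n_foci"]
    return out


def corrected_intensity(
    membrane_samples: np.ndarray,
    background_samples: np.ndarray,
) -> dict:
    """Background-corrected reporter intensities for one embryo.

    Each membrane sample has the embryo's mean background subtracted; the
    per-embryo corrected mean is the statistic carried into the
    cross-condition pooled t-test (:func:`pooled_ttest`).
    """
    mem = np.asarray(membrane_samples, dtype=float)
    bg = np.asarray(background_samples, dtype=float)
    if len(mem) == 0 or len(bg) == 0:
        raise ValueError("membrane and background sample lists must be non-empty")
    corrected = mem - bg.mean()
    return {"corrected": corrected, "mean": float(corrected.mean()),
            "background_mean": float(bg.mean()), "n": len(mem)}
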