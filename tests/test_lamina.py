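import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gmetools as gt
from gmetools.genome import GenomeSpec
from gmetools.intervals import AnchorSet
from gmetools.lamina import DamIDTrack, _site_scores


@pytest.fixture
def genome():
    return GenomeSpec.from_dict({"a": 100_000, "b": 50_000}, 25_000)  # 4 + 2 bins


def iv(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["id"] = [f"s{i}" for i in range(len(df))]
    return AnchorSet(df)


# -- log-ratio track ------------------------------------------------------------------


def test_damid_log2_arithmetic(genome):
    lamin = np.array([8.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    dam = np.array([2.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    # totals: 10 and 10 (equal) -> no rescaling; bin 0: log2(9/3)
    track = gt.damid_log2(lamin, dam, genome)
    assert track.values[0] == pytest.approx(np.log2(9 / 3))
    ident = gt.damid_log2(dam, dam, genome)
    assert np.allclose(ident.values, 0.0)


def test_damid_log2_library_scaling_invariance(genome):
    rng = np.random.default_rng(0)
    lamin = rng.integers(0, 50, genome.n_bins).astype(float)
    dam = rng.integers(1, 50, genome.n_bins).astype(float)
    base = gt.damid_log2(lamin, dam, genome).values
    scaled = gt.damid_log2(lamin * 10, dam, genome).values
    assert np.allclose(base, scaled)
    with pytest.raises(ValueError):
        gt.damid_log2(np.zeros(genome.n_bins), dam, genome)


def test_differential_antisymmetry(genome):
    rng = np.random.default_rng(1)
    a = DamIDTrack(genome, rng.normal(size=genome.n_bins), "late")
    b = DamIDTrack(genome, rng.normal(size=genome.n_bins), "early")
    d1 = gt.differential(a, b)
    d2 = gt.differential(b, a)
    assert np.allclose(d1.values, -d2.values)
    assert np.allclose(gt.differential(a, a).values, 0.0)
    other = GenomeSpec.from_dict({"a": 100_000}, 25_000)
    with pytest.raises(ValueError):
        gt.differential(a, DamIDTrack(other, np.zeros(4)))


def test_bedgraph_round_trip(genome, tmp_path):
    vals = np.array([0.5, -1.25, np.nan, 2.0, 0.0, np.nan])
    t = DamIDTrack(genome, vals, "x")
    p = tmp_path / "t.bedgraph"
    t.to_bedgraph(p)
    back = DamIDTrack.from_bedgraph(p, genome)
    assert np.allclose(back.values, vals, equal_nan=True)


# -- site scoring ---------------------------------------------------------------------


def test_score_sites_values_and_classes(genome):
    diff = DamIDTrack(genome, np.array([0.5, 1.5, 0.0, 0.0, 0.0, 0.0]), "d")
    sites = iv([("a", 20_000, 30_000),   # spans bins 0 and 1 -> mean 1.0
                ("a", 60_000, 61_000)])  # bin 2 -> 0.0
    table, baseline = gt.score_sites(diff, sites)
    assert table["score"].tolist() == [1.0, 0.0]
    # uniform track: every site scores the constant and is baseline class
    diff_c = DamIDTrack(genome, np.full(genome.n_bins, 0.7), "d")
    table_c, base_c = gt.score_sites(diff_c, sites)
    assert (table_c["score"] == 0.7).all()
    assert (table_c["classification"] == "baseline").all()
    assert base_c["mean"] == pytest.approx(0.7)
    assert base_c["sd"] == pytest.approx(0.0, abs=1e-12)


def test_score_sites_sd_classification(genome):
    vals = np.array([0.0, 0.0, 0.0, 0.0, 10.0, 0.0])
    diff = DamIDTrack(genome, vals, "d")
    sites = iv([("b", 0, 100), ("a", 0, 100)])  # bin 4 (=10) and bin 0 (=0)
    table, baseline = gt.score_sites(diff, sites)
    hot = table.set_index("id").loc["s0"]
    assert hot["classification"] == ">2SD"
    cold = table.set_index("id").loc["s1"]
    assert cold["classification"] == "baseline"


def test_score_sites_missing(genome):
    vals = np.full(genome.n_bins, np.nan)
    vals[0] = 1.0
    diff = DamIDTrack(genome, vals, "d")
    table, _ = gt.score_sites(diff, iv([("a", 30_000, 31_000)]))
    assert table["classification"].iloc[0] == "missing"
    with pytest.raises(ValueError):
        gt.score_sites(DamIDTrack(genome, np.full(genome.n_bins, np.nan)), iv([("a", 0, 10)]))


def test_planted_shift_recovery():
    """delta = 0.8 at >= 500 anchor bins is recovered within 0.05."""
    big = GenomeSpec.from_dict({"c1": 15_000_000, "c2": 15_000_000}, 25_000)
    genome, truth = gt.make_truth(genome=big, n_anchors=500, damid_shift=0.8,
                                  noise_sd=0.2, seed=4)
    early, late = gt.simulate_damid(genome, truth)
    diff = gt.differential(late, early)
    table, _ = gt.score_sites(diff, AnchorSet(truth.anchors.copy()))
    assert table["score"].mean() == pytest.approx(0.8, abs=0.05)


# -- site-set bootstrap ---------------------------------------------------------------


def random_pool(genome, n, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        b = int(rng.integers(0, genome.n_bins))
        chrom, s, e = genome.bin_location(b)
        st = s + int(rng.integers(0, e - s - 100))
        rows.append({"chrom": chrom, "start": st, "end": st + 100, "id": f"p{k}"})
    return AnchorSet(pd.DataFrame(rows))


def test_bootstrap_site_sets_floor_when_shift_dominates():
    genome, truth = gt.make_truth(n_anchors=60, damid_shift=2.0, noise_sd=0.1, seed=3)
    early, late = gt.simulate_damid(genome, truth)
    diff = gt.differential(late, early)
    anchors = AnchorSet(truth.anchors.copy())
    pool = random_pool(genome, 400)
    res = gt.bootstrap_site_sets(diff, anchors, pool, N=500, seed=5)
    assert res.p == 1 / 501
    with pytest.raises(ValueError):
        gt.bootstrap_site_sets(diff, anchors, random_pool(genome, 10), N=10, seed=0)


def test_bootstrap_site_sets_null_uniform():
    genome, truth = gt.make_truth(n_anchors=60, damid_shift=0.0, seed=11)
    early, late = gt.simulate_damid(genome, truth)
    diff = gt.differential(late, early)
    pool = random_pool(genome, 400, seed=2)
    ps = []
    for seed in range(100):
        idx = np.random.default_rng(500 + seed).choice(400, 60, replace=False)
        sub = AnchorSet(pool.intervals.iloc[idx].reset_index(drop=True))
        ps.append(gt.bootstrap_site_sets(diff, sub, pool, N=199, seed=seed).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# -- microscopy statistics -------------------------------------------------------------


def test_foci_proportion_arithmetic():
    foci = pd.DataFrame({
        "label": ["on"] * 20 + ["near"] * 10 + ["interior"] * 20,
        "distance": [0.0] * 20 + [0.2] * 10 + [1.0] * 20,
    })
    out = gt.foci_lamina_proportion(foci)
    assert out["proportion"].iloc[0] == pytest.approx(0.6)
    far = pd.DataFrame({"distance": [0.5, 0.9, 2.0]})
    assert gt.foci_lamina_proportion(far)["proportion"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        gt.foci_lamina_proportion(pd.DataFrame({"distance": []}))


def test_foci_simulated_estimate():
    foci = gt.simulate_foci(5000, p_on=0.4, p_near=0.2, seed=2)
    out = gt.foci_lamina_proportion(foci)
    assert out["proportion"].iloc[0] == pytest.approx(0.6, abs=0.02)
    none = gt.simulate_foci(1000, p_on=0.0, p_near=0.0, seed=2)
    assert gt.foci_lamina_proportion(none)["proportion"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        gt.simulate_foci(10, p_on=0.7, p_near=0.5, seed=0)


def test_corrected_intensity_and_ttest():
    res = gt.corrected_intensity([90.0, 100.0, 110.0], [25.0, 30.0, 35.0])
    assert res["mean"] == pytest.approx(70.0)
    with pytest.raises(ValueError):
        gt.corrected_intensity([], [1.0])
    # pooled t statistic matches the hand formula on a 3-point toy
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
    got = gt.pooled_ttest(a, b)
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert got["t"] == pytest.approx(t_hand)


def test_ttest_null_calibration():
    rng = np.random.default_rng(0)
    rejections = 0
    for _ in range(200):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        if gt.pooled_ttest(a, b)["p"] < 0.05:
            rejections += 1
    assert rejections / 200 < 0.1  # ~5% expected
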