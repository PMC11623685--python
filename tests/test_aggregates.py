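import numpy as np
import pandas as pd
import pytest

import gmetools as gt
from gmetools.aggregates import NetworkMap, anchor_pairs
from gmetools.genome import GenomeSpec
from gmetools.hicmat import as_balanced


def contacts_frame(pairs):
    return pd.DataFrame({"bin_i": [p[0] for p in pairs], "bin_j": [p[1] for p in pairs]})


# -- pile-ups ------------------------------------------------------------------------


def test_pescan_null_flat(null_dataset):
    genome, truth, M = null_dataset
    OE, _ = gt.obs_exp(as_balanced(M))
    sub = gt.pescan(OE, truth.anchor_bins(genome), flank_k=5, mode="cis")
    assert sub.center == pytest.approx(1.0, abs=0.1)
    assert np.nanmean(sub.values) == pytest.approx(1.0, abs=0.1)


def test_pescan_recovers_enrichment_cis_and_trans(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    ab = truth.anchor_bins(genome)
    cis = gt.pescan(OE, ab, flank_k=5, mode="cis")
    trans = gt.pescan(OE, ab, flank_k=5, mode="trans")
    assert cis.center == pytest.approx(3.0, rel=0.15)
    assert trans.center == pytest.approx(3.0, rel=0.15)
    # flanks stay near 1
    flank = cis.values.copy()
    flank[cis.k, cis.k] = np.nan
    assert np.nanmean(flank) == pytest.approx(1.0, abs=0.15)


def test_pescan_distance_filter():
    g = GenomeSpec.from_dict({"c": 20 * 25_000}, 25_000)
    # two anchors 8 bins apart; min_dist 300 kb = 12 bins excludes the pair
    pairs = anchor_pairs(g, [5, 13], mode="cis", min_dist=300_000)
    assert pairs == []
    assert anchor_pairs(g, [5, 13], mode="cis", min_dist=200_000) == [(5, 13)]


def test_pescan_errors_when_no_pairs(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    with pytest.raises(ValueError, match="no eligible"):
        gt.pescan(OE, [0], flank_k=5, mode="cis")  # single anchor, no pair


def test_shifted_background_null_and_offsets(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    ab = truth.anchor_bins(genome)
    bgs = gt.shifted_background(OE, ab, flank_k=5, mode="cis")
    assert set(bgs) == {100_000, 500_000, 1_000_000}
    for off, bg in bgs.items():
        assert bg.background_offset == off
        assert bg.center == pytest.approx(1.0, abs=0.2)
    with pytest.raises(ValueError, match="multiple"):
        gt.shifted_background(OE, ab, offsets=[110_000])


def test_signal_over_background_estimates_e(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    ab = truth.anchor_bins(genome)
    sig = gt.pescan(OE, ab, flank_k=5, mode="cis")
    bg = gt.shifted_background(OE, ab, flank_k=5, mode="cis")
    bgc = np.mean([b.center for b in bg.values()])
    assert sig.center / bgc == pytest.approx(3.0, rel=0.15)


def test_apa_single_contact_is_window(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    sub = gt.apa(contacts_frame([(20, 60)]), OE, flank_k=2)
    c, _, _ = genome.bin_location(20)
    block = OE.dense_block(c)
    off = genome.chrom_offset(c)
    expected = block[20 - off - 2: 20 - off + 3, 60 - off - 2: 60 - off + 3]
    assert np.allclose(sub.values, expected, equal_nan=True)
    assert sub.n_pairs == 1
    with pytest.raises(ValueError):
        gt.apa(contacts_frame([]), OE)


def test_apa_center_above_corners(enriched_oe):
    genome, truth, M, OE, _ = enriched_oe
    ab = truth.anchor_bins(genome)
    pairs = anchor_pairs(genome, ab, mode="cis", min_dist=100_000)
    sub = gt.apa(contacts_frame(pairs), OE, flank_k=5)
    corners = [sub.values[0, 0], sub.values[0, -1], sub.values[-1, 0], sub.values[-1, -1]]
    assert sub.center > np.nanmean(corners)


def test_edge_clipped_windows_dropped():
    g = GenomeSpec.from_dict({"c": 20 * 25_000}, 25_000)
    iu, ju = np.triu_indices(20)
    M = gt.ContactMatrix.from_arrays(g, iu, ju, np.ones(len(iu)), kind="obs_exp")
    # pair at the chromosome edge: window would clip, pair dropped
    with pytest.raises(ValueError):
        gt.apa(contacts_frame([(0, 19)]), M, flank_k=3)
    sub = gt.apa(contacts_frame([(0, 19), (5, 12)]), M, flank_k=3)
    assert sub.n_pairs == 1


# -- networks ------------------------------------------------------------------------


def test_build_networks_adjacency_and_symmetry():
    net = gt.build_networks(contacts_frame([(1, 2), (1, 3), (5, 5)]), anchor_bins=[1])
    assert net.neighbors(1) == {2, 3}
    assert net.neighbors(2) == {1}
    assert 5 not in net.adjacency  # self-contact dropped
    for v, nbrs in net.adjacency.items():
        for w in nbrs:
            assert v in net.neighbors(w)


def test_gme_fraction():
    net = gt.build_networks(
        contacts_frame([(0, k) for k in range(1, 11)]), anchor_bins=[1, 2]
    )
    assert gt.gme_fraction(net, 0) == pytest.approx(0.2)  # 2 anchors of 10 contacts
    net_all = gt.build_networks(contacts_frame([(0, 1), (0, 2)]), anchor_bins=[0, 1, 2])
    assert gt.gme_fraction(net_all, 0) == 1.0
    with pytest.raises(ValueError):
        gt.gme_fraction(net, 99)


def test_fraction_cohorts_enriched_network():
    rng = np.random.default_rng(0)
    anchors = set(range(0, 60))
    others = set(range(60, 300))
    pairs = []
    for v in anchors:  # anchor viewpoints contact anchors at 2x the rate
        pairs += [(v, int(w)) for w in rng.choice(sorted(anchors - {v}), 8, replace=False)]
        pairs += [(v, int(w)) for w in rng.choice(sorted(others), 8, replace=False)]
    for v in others:
        pairs += [(v, int(w)) for w in rng.choice(sorted(anchors), 4, replace=False)]
        pairs += [(v, int(w)) for w in rng.choice(sorted(others - {v}), 12, replace=False)]
    net = gt.build_networks(contacts_frame(pairs), anchor_bins=sorted(anchors))
    res = gt.fraction_cohorts(net)
    assert res["anchor_median"] > res["other_median"]
    assert res["p_value"] < 0.01


# -- shared-contact statistic ---------------------------------------------------------


def test_network_overlap_schematic_4_of_8_vs_1_of_8():
    """Two panels: a contacting pair sharing 4 of the viewpoint's 8 other
    contacts, and a non-contacting pair sharing 1 of the viewpoint's 8."""
    V, C = 0, 1
    shared = [10, 11, 12, 13]
    v_only = [14, 15, 16, 17]
    c_only = [20, 21, 22, 23]
    pairs = [(V, C)]
    pairs += [(V, x) for x in shared + v_only]   # V: C plus 8 others
    pairs += [(C, x) for x in shared + c_only]   # C: V plus 8 others
    V2, NC = 2, 3
    v2_contacts = [40, 41, 42, 43, 44, 45, 46, 47]        # 8 contacts
    nc_contacts = [40, 50, 51, 52, 53, 54, 55]            # shares bin 40 with V2
    pairs += [(V2, x) for x in v2_contacts]
    pairs += [(NC, x) for x in nc_contacts]
    anchors = sorted({b for p in pairs for b in p})
    net = gt.build_networks(contacts_frame(pairs), anchor_bins=anchors)
    table = gt.network_overlap_stat(net)["table"]
    vc = table[(table.viewpoint == V) & (table.partner == C)].iloc[0]
    assert vc.pair_class == "V-C"
    assert (vc.shared, vc.denominator) == (4, 8)
    assert vc.proportion == pytest.approx(4 / 8)
    vnc = table[(table.viewpoint == V2) & (table.partner == NC)].iloc[0]
    assert vnc.pair_class == "V-NC"
    assert (vnc.shared, vnc.denominator) == (1, 8)
    assert vnc.proportion == pytest.approx(1 / 8)


def test_network_overlap_cliques():
    cl1 = list(range(10, 16))
    cl2 = list(range(30, 36))
    pairs = [(a, b) for k, cl in enumerate((cl1, cl2)) for i, a in enumerate(cl) for b in cl[i + 1:]]
    net = gt.build_networks(contacts_frame(pairs), anchor_bins=cl1 + cl2)
    res = gt.network_overlap_stat(net)
    t = res["table"]
    assert (t.loc[t.pair_class == "V-C", "proportion"] == 1.0).all()
    assert (t.loc[t.pair_class == "V-NC", "proportion"] == 0.0).all()
    assert res["vc_median"] == 1.0 and res["vnc_median"] == 0.0
    # jaccard mode agrees on these extremes
    rj = gt.network_overlap_stat(net, jaccard=True)
    assert rj["vc_median"] == 1.0 and rj["vnc_median"] == 0.0
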