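# gmetools

Anchor-centric genome-organization analysis for binned Hi-C, peak and DamID
data, built around Gene Mobility Elements (GMEs): short chromatin-accessible
elements bound by Polycomb-group factors and the nucleoporin Nup93 that
mediate developmentally timed relocation of their target genes to the nuclear
lamina in *Drosophila* neural progenitors.

The package is for computational biologists who have peak calls
(BED/narrowPeak), binned contact matrices (text COO) and binned DamID
coverage, and want to

1. **call anchors** — merge stage ATAC peaks, keep those supported by ≥2 of 3
   stages, and intersect with every ChIP track (E(z), Psc, Pho, Nup93);
2. **quantify anchor-pair interaction structure** — Knight–Ruiz balancing,
   distance-stratified observed/expected, all-vs-all pile-ups (PESCAn/APA)
   with shifted backgrounds, HiCREP-style reproducibility (SCC);
3. **call significant contacts** — an upper-tail Poisson test against the
   distance-stratified expected, smoothed by a local aggregated Cauchy
   combination, thresholded at p < 0.01;
4. **relate contacts to TADs** — multi-window insulation scores, border
   calling, inter/intra-TAD annotation, and bootstrap nulls on median
   contact distance;
5. **score lamina mobilization** — differential (late − early) Lamin-DamID
   log₂ ratios at anchor sites, with genome-wide baselines and resampled
   site-set bootstrap nulls — plus the tabular microscopy statistics
   (lamina-proximity proportions, background-corrected reporter intensity,
   pooled-variance t-tests).

A first-class synthetic-data module (`gmetools.synthio`) generates every
input with planted, recorded ground truth — anchors inside multi-stage peak
tracks, a distance-decay Hi-C matrix with TAD blocks and multiplicative
anchor–anchor enrichment, two-stage DamID tracks with an additive
lamina shift — so the whole pipeline is testable end to end without any
external download.

## Core statistics

With balanced contact values v(i,j) and the per-chromosome distance-stratified
expected E(d), the observed/expected value is v(i,j)/E(|j−i|). Raw-count
significance uses the upper Poisson tail P(X ≥ c) at mean
λ(i,j) = E(d)/(b_i·b_j), where b are the balancing biases. Local smoothing is
the aggregated Cauchy combination over the lattice neighborhood N(i,j) within
Chebyshev radius h:

    T = Σ_k w_k · tan((0.5 − p_k)·π) / Σ_k w_k ,   w_k = exp(−(Δi² + Δj²) / 2h²)
    p_act = 0.5 − arctan(T)/π

Bootstrap p-values use the add-one estimator p = (1 + #{s ≥ s₀}) / (N + 1)
over N resampled statistics s against the observed s₀.

## Worked example

```python
import numpy as np
import gmetools as gt
from gmetools.hicmat import as_balanced

# synthetic study: 12-Mb genome, 40 planted anchors, 3x anchor-pair enrichment
genome, truth = gt.make_truth(anchor_enrichment=3.0, seed=1)
M = gt.simulate_hic(genome, truth)
atac, chip, _ = gt.simulate_peak_tracks(genome, truth, n_decoys=10)

anchors = gt.call_anchors(list(atac.values()), list(chip.values()))
bins, n_bins, total = gt.bins_containing(anchors, genome)
# -> anchors called: 40   anchor bins: 40 / 480

OE, prof = gt.obs_exp(as_balanced(M))          # simulated data: flat coverage
pile = gt.pescan(OE, bins, flank_k=5, mode="cis")
bg = gt.shifted_background(OE, bins, flank_k=5, mode="cis")
# -> pile-up center: 2.97 over 219 pairs
# -> background centers: 100 kb: 1.00, 500 kb: 0.97, 1 Mb: 0.93

rec = gt.act_smooth(gt.raw_contact_pvalues(M, np.ones(genome.n_bins), prof), genome)
sig = gt.filter_significant(rec, alpha=0.01)
# -> 5508 significant contacts

tads = gt.call_borders(gt.tad_separation_score(gt.balance(M)), genome)
ann = gt.annotate_tads(sig, tads)
# -> 27 TAD borders; 1208 inter-TAD contacts (22% of significant)

early, late = gt.simulate_damid(
    genome, gt.make_truth(anchor_enrichment=3.0, damid_shift=0.8, seed=1)[1])
table, base = gt.score_sites(gt.differential(late, early), anchors)
# -> mean anchor differential: 0.815 (genome baseline 0.055 +/- 0.312)
```

The pile-up center over its shifted backgrounds (≈3.0) recovers the planted
anchor enrichment; the anchor DamID differential (≈0.8 log₂ units above a ~0
baseline) recovers the planted lamina shift.

The same flow is available from a shell via the `gmetools` command
(`simulate`, `call-anchors`, `balance`, `obs-exp`, `scc`, `call-contacts`,
`pescan`, `call-tads`, `annotate-tads`, `bootstrap-distance`, `damid-diff`,
`score-sites`, `bootstrap-sites`, `foci-score`, `gfp-score`); run
`gmetools --help`.

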