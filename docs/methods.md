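# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinates and binning

All coordinates are 0-based, half-open (BED convention); a reader toggle
(`one_based=True`) is provided for deposited lists shipped with 1-based
starts. A `GenomeSpec` assigns global bin ids contiguously chromosome by
chromosome with `ceil(length / bin_size)` bins per chromosome; the default
bin size is 25 kb, the working resolution of all downstream analyses. An
interval overlapping two bins marks both bins as containing it (elements up
to ~2 kb can straddle a 25-kb boundary).

## Anchor (GME) calling

Candidates are the union-merge of the three stage ATAC peak sets. A candidate
counts a stage as supporting if any peak of that stage overlaps it; candidates
with ≥ `min_stages` (default 2) supporting stages that also overlap **every**
supplied ChIP track become anchors, keeping the merged ATAC coordinates.
Overlap means ≥ 1 bp (configurable). Requiring *all* ChIP tracks is the
default because the reference element is bound by all four factors; an
`require_all_chip=False` mode (CLI `--any-chip`) implements the laxer
reading, since multi-set intersection diagrams are ambiguous about which
regions were kept. Width statistics report the sample SD by default
(`ddof=1`); a single interval therefore has undefined SD, flagged as NaN.

## Contact matrices

Matrices are symmetric, stored upper-triangular on the global bin index, with
a `kind` tag (`raw`, `balanced`, `obs_exp`). I/O is a plain-text COO format
(`chrom1 start1 chrom2 start2 value`); pyramid/multi-resolution containers
are out of scope.

**Balancing.** Knight–Ruiz scaling (inner–outer Newton iteration with a
conjugate-gradient core) finds positive biases b with
`rowsum(diag(b)·M·diag(b)) = 1` on unmasked bins; the row-sum target of 1 is
a convention recorded with the matrix. Bins with zero marginal are always
masked; additionally the lowest 0.5% of nonzero coverage is masked before
balancing (`mask_quantile`, configurable), mirroring the implicit filtering
of standard correction tools. Non-convergence raises with the residual.

**Balancing on simulated data.** KR equalizes marginals, so any *genuine*
marginal structure — such as a planted multiplicative anchor-pair enrichment,
which inflates anchor-bin marginals by construction — is partly absorbed into
the biases (with 40 anchor bins among 480 and e = 3 the absorption is ~35%
of the pile-up signal). Real libraries need KR because technical coverage
bias dominates; the simulator plants no coverage bias, so recovery and
calibration experiments run the expected/O-E machinery on raw counts with
unit biases via `as_balanced` (the estimator is unbiased there, as the
acceptance results show). Both routes are exposed; the CLI flag is
`--no-kr`.

**Expected and O/E.** The cis expected at distance d is the mean balanced
value over *all* unmasked bin pairs of the chromosome at that separation —
true-zero semantics: pairs without a stored contact count as zeros. The
expected is computed per whole chromosome (the major chromosome arms of the
fly genome are separate sequences already); trans expected is the mean over
each chromosome-pair block. O/E divides stored entries by their stratum
expected, so every cis diagonal of the O/E matrix has mean 1 by construction
and an observed zero maps to O/E zero.

**Reproducibility (SCC).** Both cis maps are mean-filter smoothed with a
(2h+1)-wide window, then per-distance-stratum Pearson correlations within
[lbr, ubr] are combined with weights N_d·sqrt(var_A·var_B). Defaults follow
the standard choice at 25 kb: h = 10, lbr = 75 kb, ubr = 250 kb. The h
positions at each end of every stratum diagonal are dropped: their smoothing
windows are clipped at the matrix corner, which injects a deterministic edge
artefact shared by both replicates and inflates the null correlation on
small matrices.

## Significant-contact calling

Records are computed for **every** valid bin pair — cis pairs at
≥ `lowerbound` (default 50 kb, below which polymer proximity dominates) and
all trans pairs — not only pairs with nonzero counts; conditioning on
count ≥ 1 would make the smoothing neighborhoods anti-conservative. The raw
p-value is the upper Poisson tail P(X ≥ c) at λ = E(stratum)/(b_i·b_j); a
zero count gives p = 1 exactly. The Poisson tail replaces the binomial of
spline-based callers: at Hi-C sparsity the two are numerically
indistinguishable and the Poisson needs no total-count coupling — a declared
simplification.

Smoothing is an aggregated Cauchy combination with Gaussian weights
`exp(−(Δi²+Δj²)/2h²)` truncated at Chebyshev radius h (default h = 11 at
25 kb). The exact kernel shape is this package's choice; the bandwidth
semantics are documented here rather than inherited. p-values are clipped to
[1e-300, 1 − 1e-16] before the tangent transform. Records with
p_raw ≤ 0.05 (`prefilter_p`) receive a smoothed value while *all* computed
records contribute to their neighbors' combinations; the alternative — 
pre-filtering before neighborhood construction — would discard most of each
neighborhood and is not implemented. Cis and trans blocks are smoothed on
their own lattices and never mix. The final threshold is p_act < 0.01 with
no multiple-testing correction (a Benjamini–Hochberg option exists but is
off by default, matching the fixed-threshold convention).

Calibration note: the type-I test uses a *fully* null simulation
(e = 1 **and** τ = 1). A simulation with TAD blocks is not null for this
test — block-internal pairs are genuinely enriched over the
distance-stratified expected and are correctly called at depth.

## Pile-ups and networks

PESCAn averages the (2k+1)² O/E window (default k = 5, an 11×11 window at
25 kb) over all ordered anchor-bin pairs (cis: same chromosome, i < j,
≥ `min_dist` apart; trans: different chromosomes). `min_dist` defaults to 0
on O/E input and 300 kb on balanced input, where distance decay would
dominate short-range windows. Shifted backgrounds average windows centered
at (i+Δ, j+Δ) for Δ ∈ {100 kb, 500 kb, 1 Mb}. Windows clipped at chromosome
edges are dropped, never padded — padding would bias the average toward
interior values; cells on masked bins are averaged over the pairs where they
are defined. APA is the same average centered on called significant contacts.

Virtual-4C networks are built from the significant-contact list by default
(a flag admits all nonzero pairs); adjacency is undirected with self-contacts
dropped. The anchor-contact fraction of a viewpoint v is
|N(v) ∩ anchors| / |N(v)|; cohorts (anchor vs non-anchor viewpoints) are
compared with a two-sided rank-sum test.

**Shared-contact statistic.** For anchor viewpoints V, W the compared sets
are each side's anchor contacts with the partner removed,
S_V = (N(V) ∩ anchors) \ {W}; the reported proportion is |S_V ∩ S_W| / |S_V|
(viewpoint-normalized; a Jaccard option normalizes by |S_V ∪ S_W|). Removing
the partner makes the statistic measure *third-party* contact sharing: a
clique of mutually contacting anchors scores exactly 1 for its internal
pairs, and two disjoint cliques score exactly 0 across cliques. Pairs are
classed V-C (W is a direct contact of V) or V-NC; anchors with no anchor
contacts are excluded with a logged count.

## TAD analysis

The separation score of bin b is the mean balanced contact between the w-wide
regions immediately upstream and downstream of b, z-scored per chromosome per
window size and averaged over window sizes w from `min_depth` to `max_depth`
in `step` increments (defaults 75 kb, 2.5 Mb, 25 kb). A numerically flat
field (SD below 1e-8 of the field scale) scores exactly 0 rather than
amplifying float noise. Chromosomes shorter than the smallest window are
skipped.

Borders are local minima of the score. Each candidate's prominence (depth
below its flanking maxima, via standard peak finding; plateau ties resolve to
the plateau midpoint) is assigned an empirical p-value against the
distribution of consecutive-bin score changes on the same genome, followed by
Benjamini–Hochberg at q = 0.05 and a prominence floor (0.1 z units). This
border-significance scheme is a declared stand-in for external callers whose
exact test is not public; its recall is validated on simulations only.
Borders are single bins; domains cut at border midpoints and tile each
chromosome end to end (so k borders give k+1 domains), and internal domain
boundaries reconstruct the border bins exactly. Domain ids number
sequentially along each chromosome. Border overlap between two sets is the
fraction of one set's border bins coinciding with the other's (strict =
same bin; `slack` allows ±n bins).

Contact annotation assigns each cis contact the domains of its two bins (by
bin midpoint), the number of border bins strictly between them, and an
intra/inter label; trans contacts are labelled `trans`.

## Bootstrap nulls

All bootstrap p-values use the add-one estimator
p = (1 + #{s ≥ s₀}) / (N + 1) with N = 10 000 by default, so p ∈ (0, 1] with
floor 1/(N+1). Replicates draw *without* replacement by default (drawing a
comparable set from the pool); a with-replacement mode exists. The
median-distance null resamples inter-TAD significant contacts; the DamID null
resamples site sets of the anchor-set size from a pool of accessible regions.
The p-value is invariant to monotone transforms of the statistic.

## DamID and lamina scoring

Tracks are per-bin log₂(Dam::Lamin / Dam) values. The fusion library is
scaled to the Dam reference library's total before the ratio (so deeper
sequencing of the fusion library leaves the track unchanged and equal totals
mean no rescaling), then a pseudocount of 1 is added to both sides — both
conventions are this package's choices, recorded here. The pipeline works on
binned coverage, not restriction-fragment units; fragment-level processing is
upstream of its scope, and per-site scores are unweighted means over the
bins a site overlaps (a length-weighted option exists). The stage
differential is the per-bin late − early value, missing wherever either
stage is missing. Site classes compare the site score with the genome-wide
baseline mean: `baseline`, `>1SD`, `>2SD`; fully-missing sites are classed
`missing` and counted.

Microscopy-derived statistics are tabular only: the lamina proportion of an
embryo is (#on + #near)/#total with "near" meaning a focus–lamina distance in
(0, 0.4] µm; reporter intensities subtract the embryo's mean background from
each membrane sample; condition comparisons use two-sided pooled-variance
(equal-variance) t-tests on per-embryo values.

## Synthetic data: what it emulates, and what it does not

The generator plants: anchors (widths lognormal around ~450 bp clipped to
[68, 2200] bp, at most one per bin) inside multi-stage peak tracks; TAD
blocks tiling each chromosome (8–25 bins wide) with a within-block factor τ;
a cis contact model `max(d,1)^-α · τ^[same block] · e^[both anchor bins]`
with Poisson counts; a constant trans base rate scaled so trans mass is 10%
of cis mass (there is no accepted trans decay model; the constant exists so
trans pile-ups are exercisable); and two-stage DamID tracks
(early ~ N(0, σ); late = early + δ·[anchor] + fresh N(0, σ)).

Defaults, chosen once as realistic study conditions: α = 1.0 (the typical
magnitude of the Hi-C decay slope), τ = 2, depth = 8×10⁶ expected contacts
on the 480-bin default genome (matching the per-bin coverage of a deeply
sequenced merged-replicate map of ~10⁸ contacts over ~5.5×10³ bins), σ = 0.2
log₂ units, δ = 0 unless planted. `e = 1, τ = 1, δ = 0` define null
datasets. Every generator takes one explicit integer seed; no global RNG
state is used or mutated.

The simulator does **not** emulate: technical coverage bias (GC,
mappability, restriction-site density), so balancing is exercised on
separate randomized matrices rather than on the planted-signal simulations
(see the balancing note above); distance-dependent TAD nesting or loop
extrusion stripes; fragment-level DamID chemistry; read-level noise. Passing
recovery tests therefore demonstrates that the *estimators* are correct and
calibrated under the stated generative model — not that real libraries meet
that model. Quantities that depend on a specific real dataset (numbers of
elements genome-wide, observed contact distances, border overlaps between
particular replicates) are not reproducible from simulations and are not
asserted anywhere; the corresponding operations are validated on constructed
fixtures with hand-computed answers instead.

## Numerical details

- p-values clipped to [1e-300, 1 − 1e-16] before the Cauchy tangent transform.
- KR stops when the residual norm falls below tol/2 (default tol 1e-6,
  max 3000 matrix–vector products); biases of masked bins are NaN.
- Sample SD (`ddof=1`) for width statistics; population SD for genome-wide
  DamID baselines (a whole-population summary).
- Insulation plateaus (exactly tied minima) resolve to the plateau midpoint.
- Degenerate inputs raise informative errors rather than returning silently:
  empty anchor sets, zero-total coverage, pools smaller than the sample size,
  pile-ups with every window clipped.

## Problem sizes

Simulation-based checks run on a three-chromosome 12-Mb toy genome (480 bins
at 25 kb; 1200–3600 bins for DamID-specific checks needing ≥500 or 859
sites), 10 replicate seeds per stochastic quantity, and N = 10 000 bootstrap
replicates where a floor of 1/(N+1) ≈ 1e-4 is probed (199–500 otherwise).
These sizes give Monte-Carlo errors comfortably below the tolerances tested
while keeping the full suite under a minute of compute.
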