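# Methods

This note records the models implemented in `g4hub`, the assumptions they
make, the defaults and why, and what the synthetic-data validation does and
does not demonstrate.

## Coordinate model and interval algebra

All coordinates are BED-convention 0-based half-open `[start, end)`, which
matches the input files and removes off-by-one ambiguity.  Chromosome names
are taken literally (no `chr1`/`1` aliasing).  `merge`, `subtract`,
`intersect` and `count_overlapping` are implemented as per-chromosome sorted
sweeps and are tested for exact agreement with boolean-mask brute force on
toy chromosomes, and against `bedtools` as an independent oracle.  Overlap
means >= 1 bp by default; the threshold is exposed (`min_overlap`) because
published peak-overlap analyses rarely state theirs, and nested/duplicated
peaks are deliberately not deduplicated beyond what `merge` does.

## Randomization enrichment

The null model for "are TF peaks at G4 sites?" confines random placements to
a workspace of comparably accessible chromatin (DNase-hypersensitive
regions).  Each query interval keeps its length and is placed uniformly over
all legal start positions across workspace segments, weighting each segment
by `segment_length - interval_length + 1`; placements are independent, so
randomized intervals may overlap each other.  Intervals longer than every
segment are excluded and tallied.  The *query* (G4/control/consensus set) is
randomized rather than the TF sets so a single null ensemble of `N`
randomized copies serves every subject — this keeps a screen over hundreds
of TFs cheap and makes per-TF results directly comparable.

Per subject: `fold = observed / mean(null)` and add-one empirical p-values
`p_enrich = (1 + #{null >= obs})/(N + 1)` (never exactly 0), `p_deplete`
symmetric.  `N` defaults to 1000 and is seeded.  The statistic is the query
interval count; total overlap bp is available behind `statistic="bp"`.
Benjamini-Hochberg adjustment is provided as a post-hoc column but not
applied by default, since the enrichment screen is reported as raw empirical
p-values.  No GC- or chromatin-state-matched randomization is attempted
beyond the workspace constraint.

**Edge effects (known property).**  The null law places interval copies
uniformly over *legal start positions*, under which positions near segment
boundaries are covered less often than interior positions.  If the real
query sites preferentially occupy segment interiors (as G4s in DHS peaks
do, and as the synthetic generator reproduces), a subject made of wide
random peaks registers a small positive fold (about +13% with 150 bp
subjects in 800 bp segments) that reflects geometry, not association.
Calibration checks therefore randomize the query as well, making the
no-association null exactly true; enrichment *estimates* are unaffected
because observed and null share the same subject realization.

Control sites reproduce the "G-rich but unfolded" comparison: potential-G4
intervals that overlap promoters and open chromatin but touch no folded-G4
peak (whole interval dropped on any contact).  Condition comparisons
collapse replicate datasets per TF by maximum fold and summarise with
Spearman's coefficient (Pearson correlation of mid-ranks, average ranks for
ties), plus a count of TFs exceeding a fold-ratio threshold (default 2).

## Strand-aware profiles

Signal tracks are step functions (bedGraph semantics); profile values are
mean coverage per bin, computed exactly from the track integral rather than
by sampling.  Anchors are G4 peaks; the anchor point is the floor midpoint;
the window is +/-1000 bp in 10 bp bins by default (figure-scale resolution;
configurable).  G4 strand is assigned from strand-split potential-G4 maps:
plus-only -> `+`, minus-only -> `-`, both/neither -> `.`; unstranded anchors
are treated as plus-strand and included (excludable).  With
`strand_aware=True` the bin vector of a minus-strand anchor is reversed, so
positive offsets consistently mean "downstream of the structure" — an
R-loop-like signal planted 140 bp downstream on the opposite strand peaks
at +140 bp in the oriented frame and at -140 bp genomically on minus-strand
anchors.  `profile_max_offset` reports the bin-midpoint offset of the
maximum (ties break toward 0, then negative; flat profiles are flagged), and
`summit_offsets` provides the alternative peak-midpoint-to-anchor summary,
since published "centered within +/-20 bp" statements do not say which of
the two was used.  Both feed `count_centered`.

## Hubs and expression

Promoters are fixed windows upstream of the TSS (default 1 kb,
strand-mirrored, clipped at chromosome ends; an optional downstream
extension stands in for 5'UTRs, which would otherwise require a transcript
model the pipeline does not need).  Analyses restrict to DHS-positive
promoters; a promoter is G4-positive if it overlaps a folded-G4 peak.
Distinct-TF counts collapse replicate datasets by label.  Two counting modes
exist because the published convention is ambiguous: on the G4 footprint for
G4-positive genes (library default) or on the whole promoter window for
every gene (`count_on="promoter"`).  The footprint mode compares a ~40 bp
region against a 1000 bp window and therefore under-counts G4 promoters
whenever diffuse background binding is present; the synthetic-data ledger
and the pipeline summaries use the width-matched promoter mode for that
reason.

Expression is log10(TPM + 0.01); the pseudocount keeps zero-expression genes
rankable.  Group comparisons use the Mann-Whitney rank-sum test with
mid-ranks, tie-corrected variance and 0.5 continuity correction; for pooled
sample sizes <= 12 the p-value comes from exact enumeration of all
`C(n1+n2, n1)` group assignments, which remains valid under ties.
TF-count bins default to 0, 1-10, 11-25, 26-50, 51-100, >100 (configurable);
substituting a polymerase-occupancy column for TPM reuses the same code
path.  No causal machinery is implied: co-occupancy is a population-level
average, and many TFs "bound at the same G4" is expected to reflect dynamic
competition across cells, not a single complex.

## Binding models

Concentrations are nM throughout; the free-ligand (no depletion)
approximation is used everywhere, appropriate for plate assays with trace
immobilised target.  Saturation: `signal = background + A_max L/(Kd + L)`,
fit by least squares with initialisation `background = min`,
`A_max = max - min`, `Kd` = concentration at half-max by linear
interpolation; asymptotic SEs from the fit covariance; unidentifiable or
bound-pinned fits raise/flag.  Competition assumes mutually exclusive
one-site binding of TF (affinity `K_T`, free concentration `T`) and ligand
(affinity `K_P`): `theta(P) = (T/K_T)/(1 + T/K_T + P/K_P)`.  The IC50 is
defined relative to the zero-dose occupancy (matching "signal reduction"
readouts) and has the closed form `IC50 = K_P (1 + T/K_T)`, a Cheng-Prusoff
style amplification that reduces to `K_P` as `T -> 0`.  Dose-response fits
use `bottom + (top-bottom)/(1 + (P/IC50)^h)` with the Hill slope fixed at 1
(free slope optional); fitted IC50s outside the measured dose range are
flagged rather than trusted.  Multi-site, cooperative and kinetic models are
out of scope.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
nucleotide sequence.  Layout: gene and intergenic sites on a jittered grid
whose minimum spacing (`2 * upstream + 200`) guarantees that promoter
windows and promoter-DHS blocks of different genes never interact — this is
what makes the ledger's bookkeeping exact.  Defaults: 3 chromosomes x 2 Mb,
600 genes (70% with open promoters), 900 intergenic DHS segments of 800 bp,
300 G4s of 30-60 bp (all inside the DHS workspace; 40% in promoters, 80 bp
upstream of the TSS), stranded OQ intervals padding every G4 plus 50% extra
structure-free OQ sites, 12 TFs with planted folds spanning 1-8 plus an
R-loop-like set displaced +140 bp with strand flip, and
`log10 TPM = 0.5 + 0.08 * tf_count + N(0, 0.5)`.  These scales run the full
pipeline in well under a minute.

Planting: each TF peak is independently centered (with +/-5 bp jitter) on a
uniformly chosen G4 with probability `p`, else placed uniformly over legal
workspace starts.  `p` is solved by root-finding from the closed-form
expected-overlap equation

`E[O](p) = sum_j 1 - (1 - p kappa_j / n_g4 - (1-p) h_j)^n`,

where `h_j` is the exact probability that one uniform placement overlaps G4
`j` (computed with segment clipping) and `kappa_j` the exact fraction of
jitter draws for which a targeted peak overlaps its G4 (0 for the offset
R-loop mode, whose targeting probability is therefore set directly).  The
ledger stores `E[O]`, its Poisson-binomial SD, and an *exact* null mean
computed from the realized peak union by counting legal start positions
(expand each union piece left by `L-1`, merge, intersect with per-segment
legal ranges) — so "expected fold" is analytic, not a rerun of the pipeline.
The maximum plantable fold is roughly `1/(n_g4 * beta)` with `beta` the
per-peak hit probability, because targeted peaks inflate the null mean too;
the solver raises when a requested fold is infeasible.

Dataset size for recovery studies is a statistical choice: the observed
overlap is a Poisson-binomial draw, so the relative scatter of a fold
estimate is about `sqrt((1-q)/(n_g4 q))` for hit fraction `q`.  At the
default toy scale that is ~25% for an unenriched TF — fine for ordering,
useless for tight recovery — so the fold-recovery study
(`fold_ladder_config`) uses 10 x 2 Mb chromosomes, 4000 G4s and 12 x 8000
peaks, bringing the scatter to 2-5% against a +/-15% acceptance band, with
folds 1-12 all below the geometry's feasibility ceiling (~17).

Assay simulators add multiplicative Gaussian noise to exact model curves
(`signal * (1 + N(0, cv))`), with replicate structure and seeds.  A
lightweight expression simulator (Bernoulli G4 status; Poisson TF counts,
rates 8 vs 2; linear log-TPM effect) backs the power/size studies of the
rank-sum comparison without regenerating genomes.

All randomness flows from one seed through named per-component substreams
(`default_rng([seed, stream])`), so the same seed yields a byte-identical
bundle and any single output can be regenerated stably.

**What passing tests do and do not show.**  The generator plants uniform
background and independent peaks; real ChIP data have correlated peak
placement, GC- and mappability-driven artifacts, replicate structure and
antibody-specific biases, none of which are modeled.  Recovery of planted
folds, offsets and binding constants validates the estimators and their
calibration under the stated model — it does not certify genome-scale
numbers from real data, which additionally depend on peak calling and on
workspace choice.

## Numerical choices and degenerate inputs

Empirical p-values use the add-one rule and are never 0; the KS-based
uniformity check tolerates the `1/(N+1)` grid.  Anchors whose profile window
leaves the chromosome are dropped and counted; all-dropped raises.  Flat
profiles, flat dose-response curves, all-tied rank-sum inputs, empty subject
sets and constant Spearman vectors are flagged or raised rather than
silently propagated.  Randomized placements use integer sampling over legal
starts (no float rounding).  Spearman is clipped to [-1, 1] against
floating-point drift.  `curve_fit` runs with positivity bounds; a saturation
fit pinned at a bound is flagged `at_bound`.

## Known limitations

Interval randomization ignores GC content, mappability and chromatin-state
matching beyond the workspace; segment-edge geometry can mimic weak
enrichment for wide subjects (see above).  The competition model's `K_P` for
a G4 ligand and the effective nuclear TF concentration are order-of-magnitude
inputs, so predicted chromatin IC50s inherit that uncertainty.  Exact
rank-sum enumeration is limited to pooled n <= 12 (924 assignments); beyond
that the normal approximation with continuity correction is used, which is
accurate to within 2x of permutation p-values at n ~ 30 per group.  The CLI
consumes only the text formats described (BED3-6, 4-column bedGraph, TSV
tables); BAM/bigWig and sequence-level analysis are out of scope.
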