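# Methods

This note documents the models, conventions and design choices behind
`dhssremodel`, in the spirit of a statistical package's model
documentation.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and counting conventions

All coordinates are 0-based half-open `[start, end)`; BED input is native
and 1-based formats are converted on read.  Sequencing tags are reduced
to their 5′-end position at load time, and a tag belongs to a window iff
its 5′ end lies inside it — the cut-site semantics of DNase tags, where
the 5′ end marks the nuclease cut.  DNase tag strand is ignored for
counting (a cut is a strandless event); CAGE tags keep strand because a
TSS is directional.  Chromosome names match by exact string equality; no
"chr" aliasing is attempted.

## The two-scale binomial window model

The scan uses big windows of 10,000 bp advancing by 9,600 bp and small
windows of 500 bp advancing by 400 bp (so consecutive windows overlap by
400 bp and 100 bp respectively).  Both tilings start at position 0 — the
simplest deterministic phase, under which every small window is fully
contained in exactly one big window (a tested property).  Windows running
past a chromosome end are truncated there, and truncated small windows
shorter than one step (400 bp) are dropped.

Within a big window the small-window count of one condition is modelled
as Binomial(N, p), N the big-window count and p = l/L.  When a
mappability track is supplied, l and L are the numbers of uniquely
mappable positions in the windows instead of raw lengths; without a
track, raw lengths are used.  The synthetic generator always emits a
track so the corrected path is exercised.

The two conditions are pooled by scaling the treatment (VPA) terms by the
library-size ratio r = N_tot,veh / N_tot,VPA and combining variances in
quadrature (the conditions are independent):

    z_norm = (n_veh + r n_VPA − E_veh − r E_VPA)
             / sqrt(σ_veh² + r² σ_VPA²).

Windows with σ_norm = 0 (empty big windows, or p ∈ {0,1}) carry no
evidence and are skipped rather than scored 0; scoring them 0 would
distort the calibration distribution below.  In the limit where one
condition is empty, z_norm reduces to the single-condition binomial
z-score (tested numerically).

## Empirical FDR calibration

Simultaneously with each real small-window count, a random count
n_rand ~ Binomial(N, p) is drawn per condition from the fitted null and
combined into z_rand by the identical formula.  The per-condition draw
mirrors the fact that the real statistic pools two independently sampled
conditions.  The cutoff is the smallest value c on a 0.1-spaced grid
(spanning all observed z values) with

    FDR(c) = #{z_rand ≥ c} / max(1, #{z_norm ≥ c}) ≤ 0.05.

The 0.1 grid matches the coarse precision at which such cutoffs are
conventionally reported (e.g. 5.5 on genome-scale libraries); a
data-independent fallback of 5.5 is applied only when calibration is
explicitly disabled or finds no qualifying cutoff.  Random draws come
from a seeded generator, so scans are bit-reproducible; changing only the
seed changes z_rand but never z_norm.

Small windows with z_norm at or above the cutoff are merged
(overlap-transitively) into DHSS clusters.  Cluster tag counts are then
**recounted over the merged span** — summing window counts would
double-count tags in the 100 bp overlaps.

## Differential classification

Each cluster is tested with one-tailed Fisher's exact tests in both
directions on the table [[n_VPA, N_tot,VPA − n_VPA], [n_veh, N_tot,veh −
n_veh]], and Benjamini–Hochberg is applied separately per direction over
all clusters.  Clusters with q < 0.05 in the VPA direction are
`vpa_induced`, in the vehicle direction `vehicle_specific`, otherwise
`shared`; the two one-tailed tests on the same table cannot both reject,
so the statuses partition the set.  The same construction classifies TSS
clusters as induced / downregulated / non-induced.

Note the test is *compositional*: it compares each region's share of its
library.  When a treatment adds signal at many loci under a fixed
sequencing depth, unchanged loci fall below their library-share
expectation and can be flagged in the vehicle direction.  This is visible
on the synthetic data and is a property of the published design, not an
artifact of this implementation.

## Statistical primitives

All tests live in `dhssremodel.stats`, implemented directly on
log-gamma / error-function primitives and validated against independent
oracles (exact-rational hypergeometric enumeration, rank enumeration,
per-term binomial summation, and a second statistics library):

* Fisher's exact test works entirely in log space; the motivating
  contingency table has a ~1.5-million margin, where factorials overflow.
* Wilcoxon rank-sum uses exact enumeration for pooled samples of at most
  12 observations without ties (deterministic for small fixtures) and the
  tie- and continuity-corrected normal approximation otherwise.
* The two-sample KS p-value uses the asymptotic Kolmogorov distribution
  with effective size n_x n_y / (n_x + n_y).
* The qPCR statistic is ΔCt = Ct(digested) − Ct(undigested), compared
  between conditions with Welch's two-tailed t test.  One published panel
  says only "two-tailed t test"; the unequal-variance form is used for
  both (the pooled-variance variant is exposed as an option).
* p-values are reported at full precision, with no 2.2e−16 floor.

## Promoter and annotation conventions

A coding gene's promoter runs from 1 kb upstream of the TSS to the
translation start, in transcript orientation.  For non-coding models the
ATG-based definition is undefined; the surrogate [TSS − 1 kb, TSS +
500 bp) is used and flagged.  Genomic categories use the fixed precedence
promoter > gene body > intergenic.  Repeat assignment takes the
overlapping repeat with the greatest overlap (ties: longer repeat, then
leftmost), with an any-overlap variant for class membership counts.
Distances are edge-to-edge gaps (overlap = 0), binned at < 1 kb
(proximal), 1 kb–1 Mb inclusive (semi-distal) and > 1 Mb (distal);
interval-to-interval rather than point-to-interval distance is used where
the convention is ambiguous.

The enhancer-overlap binomial test computes its null probability
analytically under uniform placement: for one chromosome the favourable
start positions for an interval of the mean query length m cover at most
coverage + n_enhancers·(m − 1) bases.  A seeded randomization alternative
(`distance_ks_vs_random`) compares observed nearest distances against
uniformly re-placed intervals with the same length distribution.

## Motif scanning

JASPAR count matrices (both the bare and the `A [ ... ]` row-label
dialects) are converted to log2 odds against a uniform background with a
split pseudocount of 0.8 (a common toolkit default; configurable — no
value is prescribed by the source analyses).  A window's similarity is
the relative score (score − min)/(max − min); hits require ≥ 0.8 by
default.  Both strands are scanned, windows containing N are skipped, and
overlapping hits all count (no masking rule is prescribed).  Group
comparisons use raw per-region hit counts with the one-tailed Wilcoxon
test; a length-normalised option exists because group length
distributions may differ.

## Synthetic data generator

The generator emulates the downstream form of a two-condition
DNase + CAGE experiment at desk scale.  Defaults: 3 chromosomes × 2 Mb,
90 % mappable (random 200 bp blocks masked), 120 genes, 3,000 repeats
with class mix SINE 0.55 / LINE 0.25 / LTR 0.15 / DNA 0.05, 30 % of
SINEs carrying an embedded forkhead-like consensus, 60 intergenic
enhancers, 300 planted accessible regions (10-fold over background, 25 %
with an extra 5-fold in VPA only), and ~200,000 DNase / ~100,000 CAGE
tags per library.

Generator-specific choices not fixed elsewhere: planted regions are
500–1,500 bp long (bracketing the 500 bp analysis window) and at least
5 kb apart, so merged clusters never bridge regions with different truth
labels; DNase backgrounds are homogeneous Poisson over mappable
positions (tags never fall on unmappable bases); library totals are
Poisson around the configured depth.  CAGE promoter counts are
independent per-gene Poisson draws — up-regulated promoters therefore
show the configured fold change in raw counts and the library totals
float, as real libraries do.  Promoter shapes are assigned 50/50 sharp
(5′ ends Normal(TSS, 20 bp)) and broad (Uniform(TSS ± 150 bp)); 10 % of
tags are uniform background.  A small synthetic qPCR panel (8 primers at
induced sites, 8 at random sites, triplicate, two conditions) rounds out
the bundle so the full pipeline produces every table.

What the generator does **not** emulate: covariate structure in the
background (GC, chromatin domains), fragment-length effects, replicate
structure, multi-mapping ambiguity, or coupling between induced regions
and motif-bearing SINEs.  Passing recovery tests therefore demonstrate
the correctness of the inference machinery under its own model, not
performance on real libraries.

## Problem sizes and numerics

The default synthetic scale (≈15,000 scored windows, ≈400,000 tags per
run) was chosen so a full pipeline run takes seconds and the replicated
FDR studies (20 null replicates, 10 planted replicates) finish in well
under a minute each; all reported error rates are averaged over those
replicates with Monte-Carlo standard errors.  Ties in BH use the
standard step-up with a stable sort; the calibration grid includes its
endpoint; cluster `max_z` is the maximum window z over the merged span.

## Known limitations

* No replicate-aware modelling: libraries are pooled, as in the original
  design.
* The caller has no local background beyond the 10 kb window and no
  peak-shape model; very broad enriched domains merge into single
  clusters.
* The compositional behaviour of the Fisher classification (above) means
  `vehicle_specific` counts are inflated whenever treatment adds signal
  under fixed depth.
* The analytic enhancer null treats query placements as independent
  uniform draws; clustered query sets violate this.
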