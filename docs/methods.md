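# Methods

## The network score

The score summarises a sample's position on the basal-like axis using an
8-gene interaction network around ALDH1A3.  The network has 13 edges; each
gene's weight counts its edge share (a bidirectional edge contributes 0.5 to
each endpoint, a directed edge 0.5 to its target), giving the default
numerators ALDH1A3 3, FAM3C 2.5, PMEPA1 2, EMP1 1.5, MCC 1.5, IRS2 1,
MAML2 1, SP100 0.5 (total 13).  Coefficients are the weights normalised to
sum to 1; the percentage form is rounded half-up to two decimals.  Two
published renderings of this weighting differ only by exchanging the EMP1
and PMEPA1 values; the formula-block weighting above is the default, and
`default_network(figure1f_weights=True)` selects the exchanged variant.
Both sum to 13, so every other coefficient is identical between them.

Per gene, samples in the top half of cohort expression get an indicator of
+1, the bottom half −1.  "Top half" is implemented as a rank split: the
`floor(n/2)` lowest-ranked samples take −1, so with odd *n* the +1 side is
one sample larger.  Ties are broken by stable sample order (policy `low`:
the earlier of tied samples takes the lower rank; `high` reverses this), and
a constant gene vector is rejected rather than silently split.  Because
indicators depend only on ranks, the score is invariant under any strictly
increasing per-gene transform — FPKM, TPM, log-scale or microarray
intensities all give the same result, which is why the score can be applied
across heterogeneous cohorts without cross-platform calibration.  Indicators
are computed within the analysed sample set (per cohort, not per stratum).

The score is the coefficient-weighted sum of indicators and lies in
[−1, +1].  The cohort is split at the median score; samples exactly at the
median go to the Low group by default (conservative toward the high-risk
call), configurable to High.

## Marker discovery

The module-derivation route splits samples by the anchor gene (default
ALDH1A3) with 1-D k-means, k = 2, 10 restarts and a fixed seed; the cluster
with the higher centroid is "positive" regardless of cluster ids.  The
original derivation does not state the feature space of the clustering or
the differential-expression criteria, so the defaults here are deliberate
choices: clustering on the anchor gene alone, and a Wilcoxon rank-sum test
with Benjamini–Hochberg correction (α = 0.05) plus an absolute mean log2
difference floor (default 1), chosen because the rank-sum test is
distribution-free and behaves consistently across microarray and RNA-seq
inputs.  Per-dataset marker sets are intersected exactly, with all Venn
region cardinalities reported (regions partition the union, so their counts
sum to it).  The module summary is the Spearman correlation matrix with
off-diagonal p-values BH-adjusted jointly across pairs.

## Subtype consensus

Each classification scheme is a set of k disjoint per-subtype gene lists
with one subtype designated unfavourable.  Samples are clustered by rank-k
NMF (scikit-learn, Frobenius loss, random initialisation) of the
signature-gene submatrix, keeping the best of 20 restarts by reconstruction
error; each sample joins the component with its largest coefficient.  A
scheme is refused when fewer than 10 of its genes match the matrix, with the
matched count reported.  Clusters are then named by correlating cluster
centroids with each subtype's indicator vector and taking the one-to-one
assignment maximising total correlation (Hungarian algorithm); the original
analysis does not state its cluster-naming rule, so this mapping is this
package's interpretation, validated against brute-force permutation search
in the tests.

The package ships three synthetic default schemes (k = 2, 3, 4, matching the
generator's planted blocks, with basal-like / quasi-mesenchymal / squamous
as the unfavourable arms); the published PDAC signature lists are inputs
(GMT) rather than redistributed content.  A sample is consensus-aggressive
when at least `threshold` schemes (default 3) call it unfavourable.
Association with the High/Low score groups uses a 2×2 chi-squared test
without continuity correction, falling back to Fisher's exact test when any
expected cell is below 5, plus a Welch t-test of scores by aggressiveness.

## Survival

Kaplan–Meier product-limit estimation and the two-group log-rank test are
delegated to `lifelines` behind validated wrappers (non-negative times,
binary events, exactly two non-empty groups, at least one event).  Ties at
event times use the standard aggregate-at-time formulation with censoring
processed after events.  No Cox model is fitted by default; the group
comparison is the analysis of record, matching how score groups are
evaluated.

## The synthetic generators

The generators define the study conditions for all property-based checks;
they emulate statistical structure, not assay physics.

**Cohort** (`CohortSpec`): genes × samples on log2 scale.  Per-gene baselines
are uniform on [3, 10] with Gaussian noise (default SD 1).  The 8 network
genes follow a one-factor model `x = sqrt(ρ)·f + sqrt(1−ρ)·ε` (scaled by the
noise SD), so each pair of module genes has Pearson correlation exactly ρ
(default 0.6) before any subtype shift; the corresponding Spearman
correlation of the Gaussian pair, (6/π)·arcsin(ρ/2) ≈ 0.58, is what the
correlation tests check against.  Basal-like samples (default fraction 0.4,
close to the aggressive-arm prevalence typical of PDAC cohorts) additionally
get a log2 shift (default 2, a strong but realistic module effect) on the
network genes and on the aggressive-arm signature block of each scheme;
non-basal samples express one randomly chosen non-aggressive block per
scheme.  Values are clipped at zero so the matrix is valid NMF input without
further transformation.  The planted block sizes (24/~20/25 genes per
subtype for the k = 2/3/4 schemes) are of the same order as published
signature lists while keeping the default matrix small.

**Survival** (`SurvivalSpec`): exponential event times with hazard
`h₀·(HR if group = 1)` and independent exponential censoring (default
baseline 0.05 per time unit, hazard ratio 2.5, censor rate 0.02 — roughly
the hazard contrast a strongly prognostic expression split shows).  The
closed-form exponential MLE (events / exposure per arm) recovers log(HR)
within sampling error, which the tests verify at n = 500.

**Peaks** (`PeakSimSpec`): genes are laid out in equal per-chromosome slots
with margins larger than the TSS window plus the peak half-width, so TSS
windows never overlap and a peak planted in one gene's window is always
nearest to that gene.  Exactly `round(f·m)` of the `m` designated DE genes
(defaults f = 0.58, m = 709) receive one 300-bp peak with midpoint inside
TSS ± window; remaining peaks are rejection-sampled outside every TSS
window.  This makes the downstream overlap fraction exactly `round(f·m)/m`
by construction — an invariant, not an approximation — which is how the
411/709 round trip is checked.

What the generators do **not** emulate: count noise and library-size
effects, batch structure, gene–gene correlation outside the planted module
and blocks, realistic gene-length/TSS geometry, peak-width and signal
distributions, and informative censoring.  Passing tests therefore
demonstrate the correctness of the arithmetic and the recoverability of
planted structure under the stated model, not performance on real cohorts.

## Peak annotation choices

Peak position is the interval midpoint (summit-level data are not
modelled).  Each peak is assigned the gene with the nearest TSS; distance is
signed strand-aware (upstream negative).  Feature classes are exclusive
under the precedence promoter > exonic > intronic > distal intergenic, with
the promoter defined as TSS ± 2 kb by default (configurable; the window is a
convention, not a measured quantity).  Exon intervals are optional — without
them, gene-body peaks are classed intronic.  Whether published DE × peak
overlap percentages used nearest-gene or window-based assignment is
unstated; this package uses nearest-TSS with the promoter-window filter and
documents it as its convention.  All coordinates are 0-based half-open (BED
convention) throughout, including the gene-annotation TSV.

## Determinism and numerics

Every generator derives independent sub-streams from one integer seed via
`numpy.random.SeedSequence.spawn`, so outputs are bit-reproducible and
adding a consumer does not perturb the others.  NMF restarts draw their
per-restart seeds from the same mechanism (kept below 2³¹).  Percentages are
rounded half-up (decimal arithmetic, not banker's rounding) to match
two-decimal reporting.  The pipeline writes a manifest with SHA-256
checksums of every artifact; the determinism test asserts checksum equality
across reruns.

## Problem sizes used in the checks

The acceptance-level checks run at n = 200 samples for cohort-level recovery
(NMF consensus, score enrichment), 1000 replicates at n = 100 for log-rank
type-I calibration and 100 replicates at n = 200 for power, and the default
toy genome (4 × 30 Mb chromosomes, 1500 genes, 2000 peaks) for the overlap
round trip.  These sizes give stable statistics at interactive runtimes and
are the package's reference configuration for its own validation.

## Known limitations

- The edge list of the 8-gene network is not machine-readable from its
  source; the per-gene numerators are authoritative and edge-list mode is
  validation-only, under the one allocation rule (0.5 per endpoint of a
  bidirectional edge, 0.5 to a directed edge's target) consistent with a
  13-edge total of 13.
- The EMP1/PMEPA1 weighting ambiguity cannot be resolved from the available
  description; both variants are provided and every other coefficient is
  unaffected.
- NMF cluster naming by centroid correlation is an interpretation; with weak
  or absent planted structure the assignment can be unstable even though it
  is deterministic for a fixed seed.
- Real-cohort results (survival separation, consensus concordance rates,
  observed overlap percentages) depend on access-controlled datasets and are
  represented here only through their synthetic structural analogues.
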