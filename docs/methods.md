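# Methods

## The measurement model

A viewpoint 3C screen quantifies each anchor–fragment pair as relative
crosslinking `PCR_E/PCR_C`: the capture-PCR band intensity on crosslinked,
digested, religated chromatin over the intensity of the same nested primer
pair on a control template made by digesting and religating naked genomic
DNA at high concentration. Because the control template is linkage-free,
the ratio cancels primer efficiency and gel/densitometry units; the package
therefore treats intensities as arbitrary-unit inputs (no background
subtraction or qPCR efficiency correction) and works with the ratio only.
Captures carry at least three biological replicates; pairs with fewer are
rejected rather than scored.

Distances between fragments are center-to-center, matching how screen
results are conventionally plotted. Coordinates are 0-based half-open
everywhere; fragment ids are `chrom:start-end`.

## The null model and the loop test

Linkage background decays with separation approximately as a power law, so
the reference ("expected") curve is an ordinary least-squares fit of
`log(ratio)` on `log(d)` over background captures — individual capture
measurements, not per-fragment means, so the residual standard deviation
`σ̂` estimates per-capture noise. Known or suspected loop pairs can be
masked from the fit, and captures at the detection floor are excluded (a
floor value means "no capture", not an intensity). Beyond the largest
fitted distance the curve is held flat at its end value: long-range
background is already at its minimum there, and extrapolating the power law
further would understate it; such evaluations are flagged.

A fragment with `n` uncensored replicate log-ratios of mean `x̄` is tested
one-sided against the curve prediction `log f(d)` with the pooled error

```
t = (x̄ − log f(d)) / (σ̂ · sqrt(1/n + 1/N + (x − x̄_fit)² / S_xx)),  df = N − 2
```

where `N`, `x̄_fit`, `S_xx` are the size and log-distance moments of the
fit. This is the classical comparison of a new group mean against a
regression prediction using the model-wide error — the same family as the
least-squares-means contrasts produced by standard statistics packages —
and it is exactly calibrated when replicate noise and background scatter
share one scale, which the test suite verifies. A per-fragment alternative
(`variance="replicate"`: replicate SE with the curve residual added in
quadrature, df = n−1) is available; it is markedly more conservative at
n = 3 because of the heavy t-tail, and is not the default. Identical
replicates (sd 0) are handled in both modes: the curve term alone carries
the test.

Because every fragment in a dataset is tested against the *same* fitted
curve, p-values share the curve's estimation error; the realized
false-positive fraction in one dataset therefore varies somewhat more
across datasets than a binomial count would, while remaining correct on
average. Screen-wide multiplicity is handled by Benjamini–Hochberg
q-values; reporting both p and q keeps single-fragment results comparable
with raw-p conventions. The final call additionally requires the observed
mean ratio to be at least `min_fold` (default 2) times the expected value,
preventing significance-without-magnitude calls at large n; `min_fold=1`
restores pure-significance behaviour. The regime label splits calls at
100 kb (configurable): beyond that, linkage background is minimal and
captures are intrinsically more specific.

## Domain segmentation and boundaries

Repressive-mark tracks are regridded to uniform bins (coverage-weighted
mean) and segmented on `log(1+signal)` by a two-state Gaussian HMM:
means initialised at the 25th/75th signal percentiles, shared variance
initialised at the track variance, symmetric sticky transitions (0.99),
EM capped at 200 iterations with tolerance 1e-6, Viterbi decoding, no
random restarts — the segmentation is fully deterministic. The higher-mean
state is "enriched". Runs shorter than `min_domain_bins` (default 5,
suppressing single-bin flicker comparable to visual browser smoothing) are
reassigned to their flanks, shortest first. A contrast-free track yields a
single domain — labeled "depleted" by convention, since enrichment is a
contrast claim — and no boundaries. Boundaries are the junctions between
adjacent opposite-state domains; locus ends never count. Consensus across
marks is computed on the union of domain edges ("any" = enriched in at
least one mark; "all" = in every mark), so marks need not share binning
exactly, only extent.

## Colocalization and selectivity

The boundary-colocalization claim is tested by permutation: the statistic
is the number of boundaries with at least one called-anchor midpoint within
`tolerance_bp` (default 5 kb — tethering-element fragments span roughly
5–9 kb, so boundary-within-fragment is the natural scale), and the null
re-places anchor midpoints uniformly in the locus (optionally excluding
blacklist intervals such as transcription units). The empirical p uses the
+1 correction and can never fall below `1/(n_permutations+1)`.

Selectivity among insulator-bound sites is an exact hypergeometric tail:
of `T` tested fragments, `N` overlap a candidate insulator site and `m`
were called; `P[X ≥ k]` is the chance a random m-subset hits at least the
observed `k` candidates. The candidate universe is deliberately restricted
to *tested* fragments, since unscreened sites could never have been called.
Sites are classed from their bound-protein combination: class I if dCTCF is
present, class II if SuHw is present (both labels may apply), GAF for
GAF-only sites.

## Enhancer-blocking scores

Embryos are scored as the H1-domain over NEE-domain reporter ratio. The
published four-category scale anchors no-block at H/N ≤ 1 and strong block
at H/N ≥ 5 but gives only point values (2 and 4) for weak and medium;
classification therefore uses the midpoint cut-offs 1, 3, 5 — the minimal
interval extension preserving all printed anchors — and the cut-offs are
configurable. Construct QC follows the assay design: at least 50 embryos
from at least 3 independent insertion lines, with per-line category tables
reported for heterogeneity inspection. Construct comparisons use the
two-sided Wilcoxon rank-sum on the continuous ratios (the categories are a
visualisation of the same ratios): a tandem construct significantly lower
than the single-insulator reference is a **bypass** verdict, significantly
higher is **augmentation**, otherwise no-change; two identical constant
samples are reported as a degenerate test. Note that a construct whose
true ratio sits exactly at a category cut (e.g. a neutral spacer at
H/N = 1) will split between the adjacent categories under measurement
noise; the median ratio, not the modal category, is the robust summary.

## The synthetic generator

The generator emulates the study conditions end to end with known truth.
Defaults: a 500 kb locus, viewpoint at 250 kb, 40 EcoRI fragments
(= 39 screened targets), three loop partners planted at −184 kb, +50 kb
and +146 kb from the viewpoint with 5-fold enrichment, each on its own
~6 kb fragment (flanking cut sites at ±3 kb, matching the few-kb size of
real tethering-element fragments and making truth distances exact).

Captures follow `mu(d) = a · (d/1000)^b · e` with `a = 100` (the expected
ratio at 1 kb — the scale constant is defined at 1 kb separation so that
the default floor and decay produce paper-like behaviour: background ≈ 0.9
at 50 kb and ≈ 0.19 at 184 kb, dropping below the floor only past
~560 kb), `b = −1.2`, lognormal replicate noise `σ = 0.2`, 3 replicates,
and a detection floor of 0.05 at which values are reported and flagged
censored rather than dropped. The control intensity `PCR_C` is lognormal
around a constant and distance-independent, as a religated-genomic control
should be. A separate reference capture set (500 single captures,
log-uniform distances 1–200 kb) emulates the independent background data a
reference curve is fit from. None of a/b/σ are estimates of any real
locus's curve — the real decay parameters are unpublished — they are
plausible 3C-scale stand-ins, and everything downstream is tested as
recovery of *these* generative values.

Mark tracks are domain means plus Gaussian noise truncated at zero
(default noise 1.8 = 20% of the default 10-vs-1 level gap), with domain
boundaries placed at the loop anchors so that colocalization is true by
construction. Insulator sites include the three loop anchors plus nine
non-looping class-I sites (thirteen candidate fragments in all), so the
default selectivity is 3 called of 13 bound — the generator's version of
"few of the many similarly bound sites loop". Embryo ratios are lognormal
mixtures per construct (spacer ≈ 1, single insulators 4.5–5.5, bypass
pairings ≈ 1.2, augmenting pairing 7.5).

What the generator does **not** emulate: PCR chemistry and primer
thermodynamics, gel densitometry artefacts, polymer-physics contact
variance beyond the lognormal noise, read-level sequencing, mappability or
copy-number structure in the tracks, tissue mixtures in embryo staining,
and orientation mechanisms of insulator pairing (orientation is a label
only). Passing tests therefore demonstrate correctness of the statistics
under the stated generative assumptions, not robustness to every artefact
of real gel-based 3C data.

## Validation suite and problem sizes

The package asserts about itself (tests) and reports (acceptance script):
slope recovery within ±0.1 over 200 fits of 500 background captures;
all-3-recovered/zero-false loop calling in ≥ 90% of 200 screen replicates;
type-I fraction at p ≤ 0.05 within the 99% binomial band over 2000 null
fragments; both boundaries of a 3-domain track (300 bins, 20% noise)
within ±2 bins in ≥ 95% of 200 tracks; permutation-p validity
(P(p ≤ α) ≤ α + 1/(n_perm+1)) over 1000 null replications with 99
permutations each; and exact agreement of digestion, BH and hypergeometric
results with brute-force oracles. These sizes keep the whole suite and the
acceptance script to seconds on one CPU while leaving Monte-Carlo error
well below the asserted margins.

## Known limitations

The exact linear-model contrast behind the original "LSMeans" p-values is
not specified anywhere; the pooled regression-prediction t-test is this
package's explicit, calibrated stand-in, and published per-fragment
p-values (e.g. a raw P < 0.0016 for a single fragment) cannot be
reproduced without the underlying densitometry data. The boundary caller
operationalises what was originally a by-eye judgement; its thresholds
(`min_domain_bins`, consensus rule) are reported with results rather than
asserted as anyone's visual criteria. The permutation null treats anchors
as exchangeable uniform positions; genomic covariates (GC, fragment size)
would need a matched-shuffle null on real data.
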