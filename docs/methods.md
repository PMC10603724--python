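# Methods

`caprapop` re-implements, as one tested pipeline, the genomic
characterization workflow used for small-ruminant breed surveys on ~50K SNP
chips: quality control and cohort construction, per-breed diversity,
individual- and breed-level distance geometry, runs of homozygosity (ROH)
and the genomic inbreeding coefficient F_ROH, LD-based effective population
size, two-group selection-signature scans, and a heart-girth body-weight
model.  Because survey genotypes of this kind are typically available only
on request, the package ships a generative simulator whose ground truth is
what every downstream stage is validated against.

## Genotype model and quality control

Genotypes are diploid codes 0/1/2 (copies of the designated alternate
allele, the minor allele of the source file; ties broken toward the
lexicographically larger symbol) with −1 for missing, held with the SNP map
(1-based bp, chromosomes 1–29 for the goat autosomes) and per-sample
metadata.  QC applies, in a fixed order chosen to make the report
reproducible: (1) restriction to autosomes, (2) removal of samples with call
rate < 95%, (3) removal of SNPs with call rate < 95%, (4) removal of SNPs
with MAF < 0.1% (the threshold is read literally as 0.001; both are
configurable).  QC is idempotent.

Direct relatives are excluded with an allele-sharing kinship proxy: for a
pair, the mean per-SNP similarity s = mean(1 − |g_i − g_j|/2) over jointly
called SNPs is normalized by its unrelated expectation at the cohort allele
frequencies, s0 = 1 − 2pq(1 − pq), giving φ = (s − s0)/(1 − s0).
Analytically φ = 1 for duplicates, ≈ (1 − 2pq)/(2(1 − pq)) ≈ 0.33–0.37 for
parent–offspring, and 0 for unrelated pairs, so the default threshold 0.25
flags first-degree relationships.  Flagged pairs are resolved greedily:
repeatedly remove the sample in the most flagged pairs (ties: higher
missingness, then lexicographic id).  Breed capping (default 35 per breed)
subsamples uniformly at random under a caller-supplied seed, since the
original selection criterion of such reductions is generally tool-internal.

## Synthetic cohorts

The simulator follows the Balding–Nichols model: per SNP an ancestral
frequency p ~ U(0.05, 0.95); breed b with differentiation parameter F_b
draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F); genotypes are
Binomial(2, breed frequency).  Default configuration mirrors the survey the
pipeline was designed around: 15 breeds with the census sizes of
`caprapop.study` (total 515), 48,039 SNPs on 29 autosomes of 85 Mb — about
one SNP per 50 kb, a realistic ~50K-chip density on the ~2.5 Gb goat
autosome — 1% missingness, per-breed F = 0.08 (mid-range differentiation
for Italian goat breeds), and 10 first-degree pairs created by copying one
gamete from a parent.  SNPs are unlinked apart from planted features; this
keeps the Ne module's expectations clean (LD for its tests is injected in
closed form instead).  Planted ROH overwrite an interval with a sampled
homozygous haplotype; trait contrasts split the cohort in half and shift
window allele frequencies by ±δ/2 (clamped), re-drawing genotypes inside the
window only.  A truth record retains every latent quantity.  Tests and the
analysis drivers use scaled-down cohorts (typically 2–6 breeds, 500–10,000
SNPs, 1–6 chromosomes) with the same per-SNP densities, chosen so each
check is statistically decisive at desk scale.

Emitted cohorts are recoded at the end so the designated alternate is the
observed minor allele — exactly the designation the PED/MAP reader derives —
which makes write→read round trips bit-exact.

## Diversity and distances

Per breed, He_l = 2p_l(1 − p_l) and Ho_l = heterozygote fraction among
non-missing calls; breed-level He/Ho are means over SNPs with ≥1 callable
genotype, and F_IS = (He − Ho)/He, with 0 at He = 0.  An optional
2n/(2n − 1) small-sample correction for He is off by default.  This
aggregate definition matches published per-breed tables to within rounding
in most cases, but tools differ in per-locus weighting, so only
tolerance-level agreement with any specific published table is expected.

IBS distance between individuals is 1 minus mean allele sharing
(2 − |g_i − g_j|)/2 over jointly called SNPs.  Reynolds' breed distance uses
the multi-locus ratio of sums θ = Σ 2(p−q)² / Σ 2[1 − (pq + (1−p)(1−q))]
(the weighting of the original estimator), with D = −ln(1 − θ) and θ capped
at 1 − 1e−12 before the log.  Dendrograms use Saitou–Nei neighbor joining;
negative branch lengths are clamped to zero with the deficit moved to the
sibling edge, preserving the pair's path length.  Bootstrap supports
resample SNP columns with replacement (default B = 100) and report, per
internal edge of the full-data tree, the fraction of replicate trees
containing the same bipartition.  Note that supports are only meaningful
when the truth is hierarchical; exchangeable simulated breeds are
near-equidistant and correctly yield weak supports.  MDS is classical
principal coordinates: double-center −½JD²J, eigendecompose, scale the top-k
eigenvectors by √λ; negative eigenvalues (non-Euclidean input) produce
zero-filled axes and a warning.

## Runs of homozygosity

The detector is window-based with ten parameters (defaults in parentheses):
windows of `windef` (20) consecutive SNPs stepped by `interval` (5) along
each chromosome — one whole-chromosome window when a chromosome has fewer
than `windef` SNPs — qualify when they contain at most `hetallowed` (0)
heterozygotes and `maxmiss` (2) missing calls.  A SNP is a candidate when at
least `ROHquartile` (0.99) of its covering windows qualify.  Maximal
candidate runs are split at adjacent-SNP gaps above `maxInternalGap`
(500 kb) and accepted when they have ≥ `minNsnp` (10) SNPs, span ≥
`minKblength` (1000 kb) between their first and last SNP, and average ≤
`density` (500) kb per SNP.  `maxNsnp` (30) is accepted in the parameter set
but deliberately inert: no defensible reading caps a run at 30 SNPs when the
minimum length is 1 Mb on a 50K chip.  These parameter names circulate with
several in-house tools whose exact semantics are unpublished; the definition
above is this package's fixed, tested meaning for them, and equality with
any particular published F_ROH table is therefore not claimed.

A structural consequence of requiring (at `ROHquartile` ≈ 1) that *every*
covering window qualify is edge attenuation: windows straddling a segment
boundary contain heterozygous flanking SNPs and fail, so a detected run
starts roughly one window width (`windef` − 1 SNPs) inside the true tract at
each end.  At ~50 kb chip spacing that is ~1 Mb per side, which is why
recovery experiments for 2 Mb tracts use denser synthetic maps (~3 kb
spacing, attenuation < 5% per side) and why short-class F_ROH is
conservatively biased at chip density.  Detection is validated against an
independent exhaustive enumerator (pure-loop re-derivation of the rule) on
thousands of randomized small fixtures.

F_ROH is the summed accepted-segment length divided by the SNP-covered
autosome length Σ(last bp − first bp + 1), reported in total and in length
classes up to 2 / 2–4 / 4–8 / 8–16 / >16 Mb; longer classes indicate more
recent inbreeding.  The first class absorbs anything below 2 Mb so the class
masses always sum exactly to the total, even under non-default parameters
that admit segments shorter than 1 Mb.

## Effective population size

Dosage r² (squared Pearson correlation over jointly called samples) is
collected for intra-chromosomal pairs within a distance cap, mapped to
recombination distance c = Mb × (cM/Mb)/100 (default 1 cM/Mb), binned, and
corrected for sample size by subtracting 1/(2n).  Under the Sved relation
E[r²] ≈ 1/(α + 4Ne·c), each bin yields Ne = (1/(4c))(1/r²_adj − α) at time
t = 1/(2c) generations ago; α defaults to 1 (no mutation adjustment).  Bins
are built from a target generation axis (e.g. 13…983) via c = 1/(2t) with a
±10% multiplicative window.  Bins with non-positive adjusted r² are flagged
undefined rather than extrapolated.  The implementation is pinned by a
closed-form round trip (injected Sved r² recovers Ne within 1% for
Ne ∈ {50, 200, 1000}) and by an unlinked-SNP negative control.

## Selection scans

Per-SNP F_ST uses Wright's two-population form on group frequencies:
p̄ = (p_a + p_b)/2, H_T = 2p̄(1 − p̄), H_S = mean within-group gene
diversity, F_ST = (H_T − H_S)/H_T (0 when H_T = 0, clamped to [0, 1]),
undefined where either group has fewer than two callable samples.  The
delta H-score is |incidence_a − incidence_b|, where incidence is the
fraction of a group's animals whose accepted ROH cover the SNP; the absolute
value is used because a single top tail is retained.  `select_top` flags
exactly floor(fraction × defined SNPs) records (fraction 0.01 by default;
48,039 defined values give 480 flags), ordering by value with a stable
(chromosome, bp) tie-break.  Flagged SNPs map onto user-supplied gene
intervals (BED input, 0-based half-open on disk, converted to 1-based
inclusive internally) with an optional flank; genes hit by both statistics
form the consensus list.  Power checks show a δ = 0.6 trait window reaches
the F_ST top 1% essentially always at n = 39 + 39, and reaches the
*consensus* list only when the trait window also carries group-differential
homozygosity (a swept shared haplotype), which is the biologically intended
reading of agreement between the two statistics.  Under δ = 0 the flagged
SNPs are uniform over the genome (chi-square calibration).

## Phenotypes

Body weight is predicted from heart girth by BW = 0.0127·HG² − 0.69·HG +
14.7 (kg, HG in cm), strictly increasing for HG > ~27.2 cm, so medians and
quartiles commute through it on the adult range; the mean does not (mean of
a convex transform ≠ transform of the mean).  Trait descriptives report
mean, linear-interpolation quartiles (numpy's default; the
`averaged_inverted_cdf` method is available because SAS-style tools define
quartiles differently), sample SD, t-based 95% CI of the mean, and
bias-corrected skewness and excess kurtosis; constant vectors flag the shape
moments as undefined rather than dividing by zero.

## Pipeline policy

The orchestrated run mirrors the two-dataset design of breed surveys: after
QC and relative exclusion, the *uncapped* cohort feeds ROH, F_ROH, Ne and
selection scans, while the breed-capped cohort feeds diversity, distances,
trees and MDS.  Every stage writes its animal counts to a manifest
(conservation: in = out + removed), the full configuration is serialized
with the outputs, and a single seed drives every stochastic step, making
manifests byte-reproducible.

## Known limitations

- SNP independence in the simulator means LD-based Ne cannot be validated
  end-to-end from genotypes; it is validated in closed form.
- The ROH parameter semantics are this package's own fixed definition of an
  under-specified parameter vocabulary; published F_ROH tables computed with
  other tools will differ, mostly through edge attenuation and `maxNsnp`.
- Bootstrap supports are not comparable to published trees whose resampling
  scheme and replicate count are unreported.
- The relatedness proxy is a stand-in for pedigree or PI_HAT-style
  estimators; it is calibrated for first-degree detection, not for
  estimating kinship coefficients.
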