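# Methods

This note records the models behind `strainsweep`, the conventions and
numerical choices the implementation makes where the underlying methods
admit more than one reading, and what the synthetic-data tests do and do
not establish about real data.

## Read-cloud impurity model

A read cloud is the set of reads sharing one droplet barcode.  With
high-molecular-weight input, each droplet captures several ~10 kb DNA
fragments, usually from different species, so co-occurrence of two loci
in a cloud is weak evidence of linkage on its own.  We model the chance
co-occurrence of sites i and j in cloud μ as

    P_{i,j,μ} = p_i · p_j · F(D_μ),

where D_μ is the cloud's read count.  The two ingredients are estimated
from the data themselves:

* p_i is the *per-cloud detection rate* of site i — the fraction of all
  clouds containing at least one read at that site.  (The per-timepoint
  read-share simplex over species is also retained, as the natural
  abundance summary, but the null uses detection rates: under a
  fragments-per-droplet process with n fragments per cloud, detection of
  a feature scales like E[n]·w and pair co-occurrence like E[n(n−1)]·w²,
  so products of detection rates with F ≈ E[n(n−1)|D]/E[n]² are
  self-consistent, while products of read shares would be off by roughly
  the squared reads-per-fragment.)
* F(D) is estimated by binning clouds by D (logarithmic bins holding at
  least 50 clouds, greedily merged), dividing the mean number of distinct
  species pairs per cloud by Σ_{s<s'} p_s p_s', monotonizing with
  weighted pool-adjacent-violators, and interpolating linearly in log D
  with constant extrapolation.

The per-cloud effective species number is
S_μ = sqrt(k / Σ_s (r_s/R)²) — the geometric mean of detected richness k
and the inverse Simpson index — so a uniform k-species cloud scores
exactly k.  Detection requires at least one read (a species with zero
reads does not count).  The un-rooted ratio is available behind a flag
for sensitivity analyses.

Barcode error correction merges a barcode into the largest
already-accepted cloud within edit distance 1 (substitutions and indels),
processing barcodes in decreasing-count order with lexicographic
tie-breaks; merge targets are always roots, so merges never chain.
Candidates are found by deletion-signature hashing and verified with
edlib.

## Sharing tests and the four-gamete classification

Pairs of same-species SNVs enter testing when their minor-allele
frequency among clouds exceeds 0.1 and they share at least 12 clouds
across all timepoints.  The sharing p-value is the upper tail of the
number of chance co-occurrences: exact Poisson-binomial enumeration when
at most 20 candidate clouds exist, otherwise a Poisson tail with
λ = Σ_μ P_{i,j,μ} = p_i p_j Σ_μ F(D_μ).  The screen keeps pairs with
Bonferroni-corrected p < 0.1.

For screened pairs, each of the four allele-combination cells (a cloud
votes with its majority allele at each site; ties are dropped) is tested
against its own impurity expectation, using per-allele detection rates.
The number of significant cells maps to two/three/four-haplotype
categories; the four-haplotype p-value is the largest of the four cell
p-values (all cells must be elevated), with Benjamini–Hochberg q-values
across tested pairs.  Cells are tested unconditionally on the total
shared count; conditioning is a possible refinement we did not adopt.

## SNV trajectories and sweep detection

Frequencies are plug-in estimates f̂ = A/D from unique read-cloud counts;
timepoints with D below 10 unique clouds are treated as missing (this
matches roughly 10-fold coverage at the inclusion threshold).  Panels are
polarized so the reference allele is the cohort-consensus allele
(prevalence ties and missing prevalences are left untouched and
flagged), and SNVs are retained when the alternate allele reaches 10%
frequency in at least one timepoint.  Site diversity is the fraction of
core-genome sites with 0.2 < f < 0.8, strict inequalities.

A SNV difference between timepoints t1 < t2 is a *minor* allele moving
from below 0.2 to above 0.7 (strict): either the alternate allele rises,
or the reference allele does (f̂ falling from above 0.8 to below 0.3).
The two-sided form matters: after cohort polarization, the fingerprint
alleles of a displaced resident strain fall, and their displacement is a
sweep of the complementary allele.  The ensemble null probability per SNV
is

    max_{f0 ∈ {0.01..0.99}} [ P(f̂1 ≤ 0.2) P(f̂2 ≥ 0.7) + P(f̂1 ≥ 0.8) P(f̂2 ≤ 0.3) ]

under binomial sampling at the observed depths — maximizing over the
constant true frequency is conservative.  The ensemble p-value is the
Poisson upper tail of the observed candidate count at the summed null
probabilities, and the whole candidate set is declared at p < 0.05 and
expected/observed < 0.1.

Backbone confirmation lists, per allele, the core genes sharing at least
3 distinct clouds with reads carrying that allele ("frequently shared";
the small floor suppresses singleton impurity noise): positive when both
alleles have more than two thirds of these genes from the SNV's own
species, negative when either allele has more than a third from another
species, unconfirmed otherwise.

## Haplotype clustering

For SNVs i, j over their T shared non-missing timepoints,

    d_ij± = (1/T) Σ_t 2 (D_i + D_j) (f̂_i − f̂_j±)² / [ (f̂_i + f̂_j±)(2 − f̂_i − f̂_j±) ],

with f̂_j− = 1 − f̂_j; terms with zero numerator and denominator
contribute 0.  Under pure binomial noise at equal true frequencies each
term has expectation ≈ 2, so the clustering threshold d* = 3.5 sits above
the null mean; we adopt it unchanged.  UPGMA (scipy, average linkage)
runs on d_ij = min(d_ij⁺, d_ij⁻) with a maximum-distance cut at d*;
pairs with no shared timepoints get a large sentinel distance (1e9).
Member orientations propagate from the anchor SNV (lowest genomic
coordinate) along the minimum spanning tree of d, flipping across edges
where d⁻ < d⁺; exact ties keep the anchor's orientation and are counted
as conflicts.  Pooled cluster counts sum oriented alternate counts and
depths over members (missing timepoints contribute nothing), and the
cluster is globally polarized to start at or below frequency 0.5 — a
display convention for "derived" orientation, not a claim about ancestry.

## Wright–Fisher drift HMM and the neutrality test

The latent haplotype frequency follows
df = s_e(τ) f(1−f) dτ + sqrt(f(1−f)/N_e(τ)) dW, observed through
A_t ~ Binomial(D_t, f(τ_t)).  **N_e is parameterized per day** — the unit
of the sampling times — not per generation; gut generation rates are
unknown in situ, so N_e here is a drift intensity on calendar time.

Numerics: the latent state lives on a grid of 101 uniform interior
frequencies plus absorbing endpoints {0, 1} (103 states; configurable).
One inter-sample interval is a single Gaussian jump with variance
f(1−f)Δτ/N_e integrated over grid bins, overflow assigned to the
absorbing endpoints; halving the grid spacing changes fixture
log-likelihoods by under 1%.  The forward algorithm starts from a uniform
prior; a timepoint with D = 0 emits probability 1.  Λ(N_e) is maximized
over 25 log-spaced values spanning 10¹–10⁷ per day, ties resolved to the
larger N_e (less drift).  The piecewise variant assigns each inter-sample
interval to the epoch containing its midpoint and maximizes per-epoch
N_e by coordinate ascent from the constant-N_e optimum; empty epochs are
reported as undetermined.

The neutrality test simulates `reps` (≥ 100) trajectories from the fitted
constant-N_e HMM — grid-state chain started at the state nearest the
posterior-mean frequency of the first observation, binomial emissions at
the data's depths — and refits each over the same N_e grid.  The raw
bootstrap p-value (fraction of replicates whose refitted maximum
log-likelihood is at most the observed Λ(N̂_e), with the +1/(reps+1)
correction) is *conservative and under-dispersed* when N_e is weakly
identified, because the statistic's null distribution shifts with the
refitted N_e and with the trajectory's proximity to the frequency
boundaries, and the plug-in N̂_e is noisy.  The default p-value therefore
compares residuals after regressing the bootstrap statistics on
[1, log N̂_e(replicate), Σ_t log(f̂(1−f̂) + 1/2D)] — a control-variate
pivotalization that restores near-uniform null p-values (verified by
simulation in the acceptance suite) without affecting strong rejections.
The unadjusted comparison remains available (`adjust=False`).

When drift is negligible, time-varying selection is the plug-in
logit-slope s_e(τ_t) = [logit f̂_t − logit f̂_{t−1}]/(τ_t − τ_{t−1}),
which reproduces the observed trajectory exactly on re-integration.
Frequencies are clamped to [1/(2D), 1 − 1/(2D)] when depths are supplied,
avoiding infinities at boundary observations.

## Private markers and event labels

A SNV is private when its alternate or reference allele has cohort
prevalence exactly 0.  Preserved: the private allele stays above 0.8 in
at least 80% of non-missing timepoints and never drops below 0.5.
Disrupted: the SNV is temporally variable and the private allele is the
displaced (ancestral) one.  Both rules can leave markers unclassified;
all three counts are reported.  dN/dS uses only 1D (nonsynonymous) and 4D
(synonymous) degeneracy classes, changes over panel site totals; it is
undefined with no 4D changes.

Event labels are configurable heuristics distilled from exemplar
behaviors: replacement when more than half the classified markers are
disrupted and the sweep carries at least 1000 SNVs (genome-wide strain
differences); modification when under 10% of markers are disrupted, the
sweep is small, *and* dN/dS is at least 1 or undefined — a
marker-preserving sweep with strongly purifying dN/dS instead suggests
imported (recombined) between-host variation and is labelled
intermediate, as is everything else.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the methods assume:
lognormal rank abundances with an antibiotic window (per-species log10
fold effects, exponential relaxation afterwards); a two-strain panel with
shared alleles, Beta-distributed cohort prevalences and private markers;
Wright–Fisher trajectories integrated by drift-exact/Euler–Maruyama
splitting (the selection part advances exactly in logit space per
sub-step, so the zero-noise output is the logistic closed form to
machine precision); binomial counts at depths proportional to abundance
× total coverage; and read clouds built from 1+Poisson fragments per
droplet, exponential ~10 kb fragments, uniform background reads plus one
read at every spanned SNV position, with ground-truth fragment and strain
labels retained.

It does not emulate: sequencing error profiles or barcode whitelists
(barcode correction is tested on constructed inputs), mapping artifacts,
reference bias, gene gain/loss or structural variation, within-species
recombination, or more than two strains per species.  Passing tests on
this generator therefore establish internal statistical correctness and
calibration under the stated model — not robustness to mapping error or
to strain structures the model excludes.

Default problem sizes (50 species, 19 weekly timepoints, 60-SNV panels,
800 clouds per timepoint, 100–200 bootstrap replicates) were chosen so a
full study runs in well under a minute on one core while keeping every
statistical regime of interest populated; all are configuration fields.

## Known limitations

* The impurity F(D) estimator assumes between-species sharing is
  impurity-dominated; true cross-species linkage (e.g. transferred
  elements) would inflate the null and make the linkage tests
  conservative.
* N_e and s_e are effective, per-day parameters confounded with linked
  selection elsewhere in the genome; the HMM tests *constant drift*, not
  neutrality in a genome-wide sense.
* The bootstrap calibration adjustment is validated under the simulated
  study conditions; for very short series (under ~6 timepoints) the
  regression has little to work with and the raw, conservative p-value is
  effectively recovered.
* Event labels are heuristics; the package reports the underlying counts
  (markers, SNVs, dN/dS, initial frequencies) so users can apply their
  own judgment.
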