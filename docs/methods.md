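# Methods

`wheatdiv` analyses biallelic SNP panels genotyped on collections of inbred
(single-seed-descent, SSD) wheat lines, the typical substrate of genebank
diversity studies: a few hundred accessions split into historical landraces
and modern cultivars, genotyped on an array of ~15-20K mapped markers across
the 21 chromosomes of hexaploid wheat. This note records the models,
conventions and numerical choices behind each stage, and what the synthetic
generator does and does not emulate.

## Data model and QC

Calls are stored in a 4-state code (HOM_A, HET, HOM_B, MISSING) in an
accessions x markers `int8` matrix. SSD lines are effectively homozygous, so
residual HET calls are treated as genuine residual heterozygosity rather
than error in frequency computations (one copy of each allele), but as
*ambiguous* wherever a single-sequence (haploid) reading is needed —
nucleotide diversity and haplotype extraction (below).

QC removes a marker when its missing fraction exceeds `max_missing` (default
0.10) **or** its heterozygosity exceeds `max_het` (default 0.05), with strict
inequalities: a marker exactly at a threshold survives. The two criteria
flag distinct assay failures, hence the OR. Missingness is computed over all
accessions; heterozygosity over *called* genotypes (0 when nothing is
called), since a HET excess is a property of the successful assays. The MAF
filter (default < 0.01, applied after QC) uses diploid allele counting with
HET contributing one copy of each allele; all-missing markers count as MAF 0
and are removed with a log entry. Both filters are idempotent and invariant
to accession order, and never touch the accession set.

## Marker statistics

For a biallelic marker with allele frequencies (p, q):

* expected heterozygosity `H = 1 - p^2 - q^2 = 2pq` (max 0.5);
* polymorphic information content `PIC = 1 - (p^2 + q^2) - 2 p^2 q^2`
  (Botstein's biallelic form, so `PIC <= H`);
* discriminating power `D = 1 - sum_i g_i (N g_i - 1)/(N - 1)` over the
  observed genotype-pattern frequencies `g_i` among the `N` called
  accessions (Tessier) — the probability that two randomly drawn accessions
  differ at the marker.

`D` requires per-marker genotype-pattern counts, so the implementation takes
the genotype matrix rather than a frequency table. Reported collection
means exclude markers with undefined frequency. Note that some published
marker-index tools emit `H` values above the biallelic bound of 0.5; no
biallelic closed form reproduces such values, so these statistics are
reported under the explicit formulas above and printed means from other
encodings are not comparison targets.

MAF classes use bins `[0, 0.05)` (rare), `[0.05, 0.15]` (intermediate,
closed on both ends), `(0.15, 0.5]` (common); the boundary convention is
fixed here because "< 0.05" and "> 0.15" leave the boundaries themselves
open.

## Nucleotide diversity

Each SSD line is read as one haploid sequence. At a marker, the sample is
the set of homozygous, non-missing lines (HET lines are ambiguous for a
haploid reading and are excluded at that site). With `n` such lines and
allele frequency `p` among them, the marker contributes the unbiased average
pairwise difference `n/(n-1) * 2 p (1-p)`; per-chromosome pi divides the sum
of contributions by the physical chromosome length (built-in IWGSC RefSeq
v1.0 size estimates, overridable by a user chromosome table), matching the
"per site, scaled by chromosome size" convention. Genome-wide pi pools
numerators and lengths over the 21 chromosomes. Windowed pi tiles each
chromosome with half-open 1-based windows (default 3 Mb), divides by the
actual (possibly truncated, last) window length, and therefore aggregates
*exactly* to per-chromosome pi. BED exports convert to 0-based half-open
coordinates.

Because the markers are array SNPs, pi over physical length is orders of
magnitude below sequencing-based estimates; it is a *relative* diversity
track (landraces vs moderns, region vs region), not an absolute per-bp
diversity. No multiple-hit correction is applied (divergence << 1).

## Novel-polymorphism accumulation

The baseline allele profile is the per-marker union of alleles carried by a
reference collection (all modern cultivars, or the Western-modern subset).
Adding accessions one at a time, each step counts markers where the incoming
accession carries at least one allele absent from the running profile, then
folds its alleles in. Counting is marker-level: a marker counts once per
step even if both alleles arrive simultaneously at an empty-profile marker.
Markers whose baseline profile is empty (all baseline calls missing) count
as novel on first observation by default; `count_empty_profile=False`
ignores them instead. The final profile is provably order-invariant; the
per-step curve is not, so a seeded random-permutation mode reports mean ± sd
over permutations. Country summaries use linear-interpolation quartiles.

## LD and haplotype blocks

Inbred mode: each line homozygous and non-missing at both markers of a pair
contributes one two-locus haplotype; HET or MISSING excludes the line for
that pair. No EM phasing is needed or implemented. From the four haplotype
counts, `D = p_AB - p q`, `Dmax` is the sign-appropriate bound, and
`D' = |D|/Dmax`; a monomorphic margin makes the pair uninformative.

The D' confidence bounds follow the likelihood construction used by
CI-based block finders: with the allele margins fixed at their observed
values, the multinomial likelihood of the four counts is evaluated on the
D' grid `{0, step, ..., 1}` (default step 0.001, sign taken from the point
estimate; probabilities clipped at 1e-12; log-likelihoods normalized to a
unit mass), and the 5% / 95% cumulative-mass grid points are the bounds.
Endpoints move by at most one grid step under 10x refinement.

Pair classes use the canonical thresholds: strong LD when `ci_low >= 0.70`
and `ci_high >= 0.98`; recombination when `ci_high < 0.90`; otherwise
uninformative. A candidate interval is a block when its endpoint pair is
strong and at least 95% of its informative pairs (strong + recombination)
are strong; two-marker candidates need only their single pair. Candidates
are accepted greedily by decreasing marker span with leftmost tie-break —
deterministic and input-order-free. Markers below MAF 0.05 are excluded
from the search; the maximum block span is unlimited by default (wheat
array maps are sparse and LD is long-ranged) but configurable.
Size-dependent threshold variants found in some implementations are
deliberately not replicated. Block haplotype diversity is Nei's
`Hd = n/(n-1) (1 - sum h_i^2)` over complete (homozygous, non-missing)
multilocus haplotypes; undefined (flagged None) below two complete lines.

## Clustering post-processing

Q-matrices and log-probabilities are parsed from either a native
STRUCTURE-style output or a plain CSV dialect; membership rows off unit sum
by more than 1e-3 are renormalized with a warning.

* **deltaK**: per replicate index r, `L''_r(K) = L_r(K+1) - 2 L_r(K) +
  L_r(K-1)`; `deltaK = mean_r |L''_r(K)| / sd(L(K))` with the sample sd over
  replicates. Replicates are paired by sorted lnP within each K (the
  pairing only matters for the per-replicate variant; a mean-curve variant
  is available via `per_replicate=False`). Equal replicate counts over a
  contiguous K range are required; deltaK is undefined (NaN) at the range
  endpoints and where sd = 0.
* **Label alignment**: CLUMPP-style, the column permutation minimizing the
  summed squared difference to a reference run, solved exactly by the
  Hungarian assignment on the K x K column-cost matrix. Alignment is used
  for averaging and plotting only — deltaK, the Puechmaille estimators and
  hard assignment are label-free.
* **Puechmaille estimators**: per run, a cluster is genuine under the mean
  (median) criterion when at least one predefined sampling group (country
  or region — exposed as a parameter) has mean (median) membership >= 0.5
  in it. MedMeaK/MaxMeaK/MedMedK/MaxMedK are the median/max over runs of the
  per-run counts; the per-K table is reported in full and the scalar
  estimators are read at the largest K (medians over runs floored to stay
  integer counts). Genuineness uses >=, while single-accession hard
  assignment uses strict > (threshold 0.50), mirroring the different
  phrasings of the two rules.

## Demography

Skyline exports are matched order-free and case-insensitively on
time/median/upper/lower columns. `percent_reduction(a, b) = 100 (1 - b/a)`
is signed (positive = decline) and composes multiplicatively in retention.
`erosion_summary` takes the start level from a plateau proxy — the maximum
median within the first half of the calendar window — and the end level at
the last time point inside the window; when a trajectory is piecewise
constant the proxy equals the plateau itself, so printed medians pass
through unchanged. `detect_declines` reports maximal strictly-decreasing
runs whose endpoint reduction reaches the threshold, so two drops separated
by a plateau are two intervals.

## Synthetic data: what it emulates, and what it does not

`simulate_panel` draws ancestral frequencies `p_m ~ U(0.05, 0.95)`,
population frequencies from the Balding-Nichols beta
`Beta(p(1-F)/F, (1-p)(1-F)/F)` (so `Var = F p(1-p)`), per-accession
admixture from region-specific Dirichlet priors, and each line's haploid
allele as a Bernoulli of its admixture-weighted frequency, recorded as a
homozygous genotype; HET and MISSING are then injected independently at
fixed rates. The shipped default recipe (`data/default_panel.yaml`)
mirrors the target panel: 199 landraces from 6 countries + 67 moderns (27
Western), 15,808 markers placed proportionally to chromosome length,
K_true = 6 with landrace countries admixed over four ancestral groups and
moderns dominated by the other two, F = 0.25 (strong drift typical of
differentiated crop germplasm groups), missing rate 0.02 and HET rate 0.01
(realistic post-QC array residuals).

`simulate_blocked_panel` plants LD: markers are partitioned into blocks and
every line draws one of `h` pool haplotypes per block (default h = 4),
independently between blocks. Pool haplotypes use a nested-split
construction (each marker assigns its minor allele to a random prefix of
the ordered pool), which guarantees that at most three of the four gametes
occur for any in-block pair — within-block |D'| is exactly 1 while allele
frequencies still vary. This models "few common haplotypes, no internal
recombination"; it does not model partial intra-block recombination or
inter-block decay of LD with distance.

`simulate_structure_runs` produces replicate Q-matrices as Dirichlet draws
(concentration kappa, default 50) around the true admixture — merged
columns below K_true, near-zero padded columns above — with columns
randomly permuted per run, and lnP curves that are synthetic by design: a
piecewise-linear mean (slope 800 before K_true, 30 after, base -50,000)
with Gaussian replicate noise (sd 15). Their only contract is the peak
location and noise scale; no likelihood is computed.

What passing tests show, and don't: recovery results demonstrate that the
estimators behave correctly under the stated generative model (admixture
Dirichlet structure, free recombination between markers, noise-free
clustering around truth). They do not demonstrate robustness to array
ascertainment bias, genotyping error structure, pedigree relatedness, or
MCMC pathologies of real clustering runs — all upstream of this package.

## Problem sizes and seeds

The test suite and the acceptance script run scaled-down panels chosen to
make the statistical checks sharp while staying quick: 150 accessions x
2,000 markers for K-recovery and pi calibration (6 groups, K_true = 3, 10
replicates per K over K = 1..6, kappa = 50), 21 planted blocks x 150 lines
for boundary recovery, 80 accessions x 500 markers at F = 0.3 for PCA
separation, and 200 random instances (<= 12 markers, <= 30 lines) for the
block-finder/enumeration equivalence check. All generators are pure
functions of (config, seed); the acceptance script derives per-analysis
child seeds from its single `--seed`.

Calibration conventions: pi agreement is asserted within 3 Monte-Carlo
standard errors of the exact finite-sample expectation computed from the
simulation truth; planted-boundary recovery requires >= 90% of planted
block edges within one marker of a detected edge; PCA separation requires a
positive PC1 silhouette against the true population labels.

## Known limitations

* No imputation, phasing, or EM-based haplotype estimation for
  heterozygous material; heterozygous calls are excluded wherever a haploid
  reading is required.
* pi uses physical length as denominator; with array SNPs this is a
  relative track, not an absolute per-bp estimate.
* The block finder is O(m^2) CI computations per chromosome — adequate for
  array densities, not for sequencing-scale maps.
* Clustering MCMC, tree inference and coalescent skyline inference are out
  of scope; the package post-processes their outputs.
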