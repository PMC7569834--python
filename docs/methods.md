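# Methods

## Scope and data model

The pipeline operates on a biallelic SNP panel of inbred diploid lines
(`GenotypeMatrix`: samples × sites of alternate-allele dosages 0/1/2 with a
missing sentinel), a sample→group map with non-fixing reference-line
flags, per-plot seed-isotope measurements (δ¹⁵N, δ¹³C in ‰), and optional
GFF3 gene annotation. All internal intervals are 0-based half-open; VCF
and GFF3 coordinates are converted at the file boundary. Chromosome labels
are treated as opaque strings, and chromosome length is inferred as the
maximum observed position rounded up to a whole window, so no assembly
index is required.

## Quality control and imputation

`read_vcf` drops multiallelic and non-SNP records, then removes sites with
minor-allele frequency ≤ 0.01 (computed on non-missing chromosomes only)
or missingness above 0.2 (configurable). A heterozygous call contributes
one alternate chromosome; no phasing is used anywhere, since every
statistic is frequency-based. Missing dosages can be filled by
`impute_missing`, which substitutes the site's modal non-missing dosage
(ties resolved to the lower dosage, so the operation is deterministic);
sites with no typed call are dropped. This simple rule replaces
model-based imputation deliberately: at the <3% missingness typical of
array data the modal fill changes windowed statistics negligibly, and it
keeps the pipeline self-contained and reproducible.

## Windowed diversity and Tajima's D

Per-site diversity is the fraction of chromosome pairs carrying different
alleles, 2c(n−c)/(n(n−1)) for alternate count c among n non-missing
chromosomes. Windowed π divides the within-window sum by the full window
size in bp (1 Mb non-overlapping tiles by default), so monomorphic
positions implicitly contribute zero; with array densities of ~6–10 SNPs
per Mb this puts per-window π in the 10⁻⁷–10⁻⁶ range. "Sliding" windows
default to step = size, the behaviour of the standard windowed-scan tools;
an explicit smaller step is available. Windows without SNPs are omitted,
and genome-wide means run over defined windows only.

Tajima's D uses the standard constants derived from the window's modal
non-missing chromosome count (after imputation this is exactly twice the
sample count; the mode is a stable choice under scattered missingness,
which the sources leave unspecified). D is undefined (NaN) when a window
has no segregating site, and such windows are excluded from averages. Note
that array panels are ascertained toward common variants, which inflates
k̂ relative to S/a₁; strongly positive genome-mean D on array data is an
ascertainment signature, not evidence of balancing selection on its own.

## Weir–Cockerham F_ST

`fst_site_components` implements the 1984 two-population variance
components for diploids from (typed diploid count, alternate frequency,
observed heterozygote frequency) per group: among-population a,
among-individual b, within-individual c. Windowed (default 100 bp, so
effectively per-marker on array data) weighted F_ST is Σa/Σ(a+b+c); the
unweighted mean of per-site ratios is reported alongside. Negative
estimates are reported as computed — clamping would bias window and
genome averages — and the outlier threshold (0.5) operates on raw weighted
values. Sites where a group has fewer than two typed diploids are skipped
with a log message.

## Selection screens

The diversity-ratio caller flags windows where group-A π strictly exceeds
`ratio_threshold` (default 3) times group-B π, provided the window is
defined in both groups. A zero group-B π qualifies whenever group-A π is
positive; the ratio is recorded as infinite (a zero-diversity denominator
is the strongest possible contrast). Qualifying windows that share a
boundary on the same chromosome are merged, and merged spans shorter than
`min_length` (default 25 kb) are dropped — with 1 Mb tiles the length rule
never filters, but it matters for smaller windows. The 3× rule is applied
window-by-window, consistent with per-window diversity tables.

The F_ST caller emits markers with weighted F_ST strictly above the
threshold and attaches a centered candidate flank of ±50 kb (100 kb
total), clipped at the chromosome start, intersecting user-supplied gene
intervals when given. No multiple-testing correction is applied: the
screen is a fixed-threshold rule, not a p-value procedure.

Group contrasts of windowed statistics use the Welch two-sample t-test
with Satterthwaite degrees of freedom, treating windows as independent
observations. Neighbouring windows are spatially autocorrelated, so these
p-values are anti-conservative; the comparison is reported for fidelity
with common practice and should be read descriptively.

## Isotope traits

%Ndfa follows the ¹⁵N natural-abundance method. The reference δ¹⁵N is the
mean over reference-line plots within the same environment; B (the δ¹⁵N of
plants whose entire N is fixed from the atmosphere) is a required
configuration scalar with no default, because it is a growth-room
calibration specific to the germplasm — `estimate_b_value` averages such
measurements when they exist. Estimates are not clamped: values outside
[0, 100] are flagged, preserving the error structure for recovery
analyses. An optional per-environment centering of δ¹⁵N exists but is off
by default; raw values are used unless a normalization is explicitly
requested. Δ¹³C is computed in fractional units and returned in ‰ with
δ¹³C_air defaulting to −8‰ (configurable); it is strictly decreasing in
plant δ¹³C, so lower Δ¹³C means higher water-use efficiency.

Trait correlation matrices are pairwise-complete Pearson coefficients,
with cells backed by fewer than three complete pairs left undefined. The
genotype × trait biplot standardizes traits (zero mean, unit variance,
genotypes with missing cells dropped) and decomposes by SVD; scores are
U·S and loadings V·S/√(n−1), so loading inner products approximate trait
correlations and acute/obtuse vector angles track their signs.

## Structure and relatedness

Pairwise distance is the allele-sharing p-distance: Σ|dᵢ−dⱼ|/2 over
jointly typed sites divided by their count. (A nucleotide-substitution
distance is not well defined for biallelic array dosages; the p-distance
is the transparent analogue, so tree branch lengths are in expected
allele differences per site.) Neighbor joining is the classic Saitou–Nei
agglomeration with deterministic tie-breaking (first minimal Q entry in
row-major order); negative branch lengths are clamped to zero with the
deficit transferred to the sibling edge. Bootstrap support resamples site
columns with replacement, rebuilds the tree, and reports the fraction of
replicates containing each internal bipartition of the full-data tree;
the generator is seeded, so supports are reproducible. PCA centers each
site by its mean dosage (missing values imputed to that mean), with an
optional 1/√(p(1−p)) frequency scaling off by default; variance-explained
fractions are computed over all components and sum to one.

## Synthetic study conditions

The genotype generator is frequency-based rather than coalescent: the
scans are tested against *planted* diversity ratios and frequency gaps,
and a Balding–Nichols-style construction controls those targets directly.
Defaults emulate an array-genotyped bean panel: 29 + 29 lines in two
subpopulations plus 14 admixed individuals (72 total), 11 chromosomes of
50 Mbp, 5398 biallelic sites, inbreeding F = 0.98 (beans are predominantly
self-pollinating; heterozygotes are rare), 2% missing calls, and a planted
20.1% of sites below the MAF 0.01 floor so default filtering leaves
exactly 4314 sites. The baseline allele-frequency law is a symmetric
Beta(2, 2) rescaled to [0.10, 0.90]: genotyping arrays are ascertained for
common variants, and the explicit sub-floor class supplies the rare tail.
Background between-group divergence uses Balding–Nichols θ = 0.01.

Five 3 Mb regions with a 4× group-A/group-B heterozygosity ratio are
planted (30 SNPs each, matching background density). Within regions the
group-A frequency is drawn in [0.15, 0.25] and the group-B frequency
solves 2p(1−p) = h_A/multiplier on the branch nearest p_A. The modest
absolute diversity mirrors windowed scan tables, where called windows sit
below the genome-wide mean, and it keeps the forced between-group
frequency gap small enough that planted diversity regions do not
masquerade as F_ST outliers. Ten outlier sites with frequency gaps of 1.0
or 0.9 are planted on four chromosomes. Realized minor-allele counts of
non-floor sites are kept above the MAF threshold by bounded resampling,
so the planted site classes are realized exactly.

The isotope generator runs the natural-abundance model forward: true
%Ndfa per genotype is Normal(group mean, 6) clipped to [5, 95] with group
means 46.4 (landrace-like) and 40.1 (participatory-bred), mirroring a
published trial contrast at 22 + 22 genotypes; δ¹⁵N_ref is +3.0‰, B is
−2.0‰ (a typical growth-room calibration; the sources do not print one),
plot noise is Normal(0, 0.2‰), and three plots per genotype plus four
reference plots emulate a replicated trial. δ¹³C is the exact inverse of
the discrimination formula at each genotype's true Δ¹³C, so zero-noise
data invert exactly (machine precision), and at 0.2‰ noise the mean
absolute %Ndfa recovery error is ≈ 2 points over 70 genotypes.

A separate neutral null (`simulate_neutral_panel`) draws independent loci
from the standard constant-size coalescent with infinite-sites binary
mutations (msprime), pairs haplotypes into outbred diploids, and places
each locus on its own chromosome; the genome-mean Tajima's D of this panel
is ~0 up to the statistic's small finite-sample bias and Monte-Carlo
error, which is the appropriate null for the D machinery.

What the generator does **not** emulate: linkage disequilibrium and
recombination maps (sites are independent given frequencies), mutation-
model realism, genotyping-intensity artifacts, field-trial design
structure (lattice blocks, spatial trends), and genotype × environment
interaction. Passing recovery tests therefore demonstrates correctness of
the estimators and callers under the assumed frequency model, not
robustness to LD or trial-design confounding on real data.

## Numerical choices and degenerate inputs

- Tie-breaks are always deterministic: modal imputation picks the lower
  dosage, NJ picks the first minimal Q pair, the final NJ star clamps
  negative lengths at zero.
- Welch's test returns t = 0, p = 1 when both samples are constant and
  equal; a constant-but-different pair returns p at the smallest positive
  float rather than zero.
- `percent_ndfa` raises when the reference δ¹⁵N equals B (zero
  denominator); `ndfa_table` raises when an environment lacks reference
  plots or its reference mean does not exceed B.
- F_ST windows are emitted only when Σ(a+b+c) > 0; per-site ratios with
  non-positive denominators are excluded from the window's mean-ratio
  summary.
- PCA and biplot component requests beyond the matrix rank are truncated
  with a log message; variance fractions are non-increasing by
  construction of the SVD.
- Simulation problem sizes used by the test suite and the acceptance
  script (20 scan replicates, 5 null and isotope replicates, 150 neutral
  loci) were chosen to put Monte-Carlo error comfortably inside the
  asserted margins while keeping a full run in the tens of seconds.

## Known limitations

- The Welch comparisons over windows inherit spatial autocorrelation (see
  above); no block-resampling correction is implemented.
- The 25 kb minimum region length is inert at the default 1 Mb window
  size; it only binds for finer grids.
- p-distance trees are not calibrated to substitutions per site; branch
  lengths are comparable within a panel, not across studies.
- The %Ndfa calculation is only as good as the B calibration and the
  assumption that the reference line's δ¹⁵N tracks plant-available soil N
  in each environment.
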