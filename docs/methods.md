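# Methods

This note records the statistical model behind each stage of `sebpanel`,
the defaults and why they were chosen, and what the synthetic cohorts do
and do not establish about real data.

## Data model

Genotypes are unphased diploid calls over the alphabet {A, C, G, T},
stored as order-normalised allele pairs; a half-call (`./1`) carries no
usable diploid information for the downstream statistics and is treated
as missing. Coordinates are 1-based as in VCF. GENEPOP export codes
alleles A=01, C=02, G=03, T=04 (missing `0000`) so files are
byte-reproducible. Readers never drop records silently: records a reader
cannot represent (indels, symbolic alleles) are counted and reported in
`meta["rejected_records"]`.

The CSV genotype-table dialect (`read_table`) is this package's own
documented layout — individual, group, then one two-character column or
two single-allele columns per locus — since supplementary genotype files
in this field have no standard format.

## Panel discovery

A locus is diagnostic for a pair of groups when every typed individual
of one group is homozygous for one allele and every typed individual of
the other group homozygous for a different allele. Three gates apply,
all *strict* inequalities:

| gate | default | meaning |
|---|---|---|
| `min_qual` | 500 | Phred-scaled site quality from variant calling |
| `min_depth` | 20× | per-group coverage at the locus |
| `min_contig_length` | 20 kb | only longer contigs contribute, one SNP each |

Coverage is interpreted as the **group mean depth** over typed calls,
since selection operates on species units rather than individual fish; a
stricter per-individual mode (`per_individual_depth=True`) is available.
Fixation is required among *typed* individuals only; `max_group_missing`
(default 0) bounds the untyped fraction a group may have before the
locus is disqualified, because with missing data "every individual is
homozygous" is only as strong as the fraction actually observed.
Contig thinning keeps the highest-QUAL candidate per eligible contig
(ties to the smallest position), which keeps retained markers far apart
and effectively unlinked. Raising any gate can only shrink the panel
(unit-tested monotonicity).

## Per-locus statistics

* H_O: fraction of heterozygous typed individuals.
* H_E: plain gene diversity 1 − Σpᵢ² over observed allele frequencies
  (GenAlEx convention). This matches the published 47-SNP table — e.g. a
  printed MAF of 0.485 gives H_E = 2·0.485·0.515 = 0.500 at 3 decimals.
  Nei's unbiased variant (×2N/(2N−1)) is available behind
  `unbiased_he=True`.
* F = (H_E − H_O)/H_E, computed from unrounded values and undefined
  (NaN) at monomorphic loci; printed tables round to 3 decimals, which
  explains small discrepancies when recomputing F from rounded H_O/H_E.
* HWE: the biallelic exact test by full enumeration over heterozygote
  counts conditional on the allele counts, two-sided in the standard
  "sum all configurations no more probable than the observed" sense.
  Sample sizes in this setting (≤ a few hundred) make enumeration exact
  and fast, so no Monte Carlo approximation is used. The star coding in
  printed tables is `***` p<0.001, `**` p<0.01, `ns` otherwise.
* Genotypic LD: G statistic on the genotype×genotype table of
  individuals typed at both loci, null distribution by permuting one
  column; p = (1+#{G_perm ≥ G_obs})/(n_perm+1), so the smallest
  attainable p with 999 permutations is 0.001. The statistic and scheme
  are this package's choice (the source analyses report no LD numbers);
  type-I error is verified by simulation.

## Species assignment

The rule engine scores each species signature by exact genotype matches
over non-missing loci; the unique best rule is accepted only when its
conflict and missing counts are within `max_conflicts`/`max_missing`
(defaults 0/0 — a deployment panel should not guess). Heterozygotes at
rule loci are conflicts, not half matches: in a fixed-difference panel a
heterozygote indicates error, contamination or hybridity and must
surface in the output. Unknown signatures return UNASSIGNED with
diagnostics rather than a forced call.

The likelihood assigner computes, per group, Σ log P(genotype | HWE,
group frequencies) over typed loci, flooring each allele frequency at
ε = 1/(2N+1) (N = the group's typed count at that locus) so that alleles
unseen in the reference sample contribute a large but finite penalty.
`min_margin` (default 2.0 nats ≈ a 7-fold likelihood ratio) guards
against assigning when two groups are nearly equally likely.

## Divergence

Chord distance per locus: f_l = Σⱼ√(x_lj·y_lj) (clipped to [0,1]),
d_l = (2/π)√(2(1−f_l)); a reciprocally fixed locus gives the maximum
(2/π)√2 ≈ 0.9003. Published implementations differ in where the average
over loci is taken; the default here averages the per-locus distances
(`aggregate="mean"`), and averaging the cosines inside the square root
is available as `aggregate="pooled"`. Because the variant used by older
tree programs is not documented, published branch lengths are not
reproduced as reference values — the machinery is validated on closed
forms and additive matrices instead.

Neighbor joining follows Saitou–Nei exactly: join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), branch lengths
vᵢ = d/2 + (rᵢ−rⱼ)/(2(n−2)), finishing at a trifurcating root for the
unrooted tree. Ties are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf), which makes
the algorithm deterministic. Branch lengths are kept raw internally —
additive matrices are reproduced to machine precision — and floored at
zero only when writing Newick. Newick output is canonical (children
sorted by smallest descendant leaf, lengths at 6 decimals, integer
bootstrap percentages as internal labels), so write→read→write is
byte-stable.

Bootstrap support resamples **loci** with replacement (the resampling
unit the tree is built from), recomputes chord distances and NJ per
replicate, and reports the percentage of replicates containing each
internal leaf bipartition of the full-data tree. Loci are resampled in
sorted-id order, making supports invariant to the column order of the
input.

PCA uses allele dosage (copies of the lexicographically first observed
allele, 0/1/2), mean imputation of missing dosages, column centring
without variance scaling (the common genotype-PCA default), and an SVD;
axis signs are fixed by making each axis' largest-magnitude loading
positive. Percent variance per axis is the eigenvalue share ×100 and
sums to 100 over the returned axes.

## Synthetic cohorts

`SimulationConfig` defaults describe the reference scenario used
throughout the tests and the acceptance script: four groups of 30
individuals named after the four *Sebastes* units, 3 diagnostic loci per
group pair (18 total), 40 shared polymorphic loci, 40× mean depth with
negative-binomial overdispersion (size 5) — reduced-representation
coverage is far more variable than Poisson — and no missing calls or
errors unless requested. Within groups, genotypes are two independent
allele draws (Hardy–Weinberg); a diagnostic locus for (G1,G2) is fixed
for opposite alleles in G1/G2 and held at 0.5/0.5 in the other groups so
it is diagnostic for exactly its pair. Shared-locus group frequencies
are Beta draws around a uniform ancestral frequency (concentration 10)
clipped to [0.1, 0.9]; the clipping keeps shared loci polymorphic in
expectation in every group, so a shared locus cannot drift into a
spurious reciprocal fixation in a finite sample. Every locus sits on its
own contig with length uniform on 25–90 kb (eligible for thinning), site
qualities uniform on 600–3000, genotyping errors are uniform redraws
over the locus' three genotypes, and missing calls get depth 0.

What the generator does **not** emulate: linkage (every locus is
independent, so contig thinning is exercised structurally, not against
real LD), coalescent ancestry and allele-frequency correlation between
groups, depth-dependent genotype error, and null alleles. Passing tests
therefore demonstrate correctness of the algorithms under their stated
model, not robustness to those real-data complications.

## Published reference table

The package ships the printed per-locus summary of the published 47-SNP
redfish panel (`sebpanel.published`) and uses it for internal-consistency
checks only: H_E recomputed from the printed MAF, F recomputed where
H_O = 0, and the reported ranges (min H_E 0.053, max H_O 0.363, min F
0.273). The underlying individual genotypes are not distributed, so
statistics that require them (e.g. the published PCA variance fractions
or tree branch lengths) are demonstrated on synthetic cohorts instead.

## Problem sizes

The test suite and acceptance script run the reference cohort
(120 × 58), a 1000-replicate locus bootstrap on a 4-group cohort, an
exhaustive HWE sweep over all genotype configurations with ≤ 20
individuals, exhaustive topology enumeration at 6 taxa, and 200-pair
permutation-test calibration at 199 permutations each; all sizes were
chosen so the full suite completes in well under a minute while keeping
every check exact or within stated Monte Carlo bands.
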