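# Methods

## Model and assumptions

The analysis treats each nucleus as an independent observer of its
genotype. At a true germline heterozygous SNP, a nucleus is *called*
heterozygous with probability p_het < 1 because whole-genome-amplified
single-cell material suffers allelic dropout (ADO): one allele fails to
amplify and the site is called homozygous. Empirically p_het ≈ 0.8 in
targeted snDNA-seq panels, and — crucially — it is assumed equal in cells
with and without the somatic anchor variant, because dropout is a property
of the chemistry, not of the clone. Any systematic difference in
per-cell heterozygous proportion (Prop_het) between anchor-positive (GoF)
and anchor-reference (WT) cells over a genomic region is therefore
attributed to biology, i.e. somatic LOH in some or all GoF cells.

Cells homozygous or missing at the anchor are excluded from both groups:
a homozygous anchor call is itself commonly an ADO artifact, and a missing
call carries no clone information. This costs ~25% of true clone cells at
default noise levels but protects the contrast.

The framework deliberately does not distinguish copy-neutral from
copy-loss LOH from read depth; depth per amplicon per nucleus is too
variable for that inference at panel scale.

## The rank-sum test and its conventions

For each bin, the defined Prop_het values of GoF and WT cells are compared
with a one-sided Wilcoxon rank-sum test (alternative: GoF stochastically
smaller). Conventions, each configurable:

* **Exact vs asymptotic.** When both groups have ≤ 8 defined values the
  p-value is the exhaustive permutation tail over all C(m+n, m)
  relabelings of the pooled midranks (ties handled exactly). Larger groups
  use the tie-corrected normal approximation with continuity correction —
  slightly conservative, which is the right direction for a screen whose
  hits trigger manual review.
* **Minimum cells.** A bin is tested only when both groups have ≥ 5 cells
  with a defined Prop_het (all-missing cells are dropped). Untested bins
  are reported as such and do not enter the Bonferroni family size.
* **Families.** The window bins (all sliding windows of k = 4 consecutive
  within-arm SNPs; step 1, so every 4-SNP region is covered) and the arm
  bins form separate Bonferroni families; m is the number of bins actually
  tested in the family. Significance defaults to adjusted p < 0.05.
* **Bins never span a centromere**; a position exactly at the centromere
  boundary belongs to the p arm.

## Genotype calling and germline-SNP selection

Raw calls are re-derived per cell from depth (DP), genotype quality (GQ)
and alternate-allele fraction (VAF): MISSING unless DP ≥ 10 and GQ ≥ 30;
then REF when VAF ≤ 5%, HET when 15% ≤ VAF < 95%, HOM when VAF ≥ 95%, and
MISSING in the ambiguous 5–15% band rather than forced to a neighbouring
code. The panel is then reduced to variants genotyped in ≥ 75% of cells,
mutant (HET or HOM) in ≥ 50% of *genotyped* cells (counting among
genotyped cells makes the filter robust to cell-level missingness
differences), present in dbSNP, and single-nucleotide (indels align and
call unreliably). The somatic anchor cannot meet germline-oriented filters
and is whitelisted through all of them. When a TSV input carries no GQ the
quality gate passes everything and a warning is logged.

## Power model

Per-cell Prop_het over a k-SNP bin is modelled as Binomial(k, p)/k with
p = p_het in WT cells and p_het − δ in LOH cells (no missingness). The
required number of GoF cells solves the one-sample noncentral-t equation:
find the smallest n with P(T > t_{1−α*, n−1}) ≥ power for
T ~ nct(df = n−1, nc = d√n), d = δ/sd, then takes the ceiling.

Two conventions were genuinely open and were fixed as a package default:

* the **Bernoulli SD** is the per-SNP value √(p(1−p)) = 0.4 at p = 0.8
  (not the per-bin √(p(1−p)/k));
* the **rejection quantile** is taken at α/2 = 0.005, i.e. a two-sided
  criterion at the stated α = 0.01.

This is the unique standard combination under which the model yields 30
cells at δ = 0.3 and 63 at δ = 0.2 simultaneously — the reference
operating points. Both conventions remain configurable
(`sd_convention`, `two_sided_criterion`), and every power report states
the calibration in use. `simulate_power` provides a Monte-Carlo oracle:
it draws the binomial Prop_het populations and applies the package's own
rank-sum test at the same rejection level; at the analytic n the empirical
power comfortably exceeds 0.85 (0.97–0.99 in the shipped checks).

## Deletion-missingness test

A homozygous deletion leaves no template, so every SNP inside it drops
out together. After restricting to high-confidence region variants (mean
depth strictly > 50) and well-genotyped cells (> 50% of panel genotypes
present), each GoF cell is scored 1 iff *all* region SNPs are MISSING.
The count k of n is tested against the WT all-missing rate p0 with the
upper-tail binomial P(X ≥ k | n, p0). When no WT cell is all-missing,
p0 is floored at half a pseudo-count, 1/(2·n_WT) — the test must not
return p = 0 from a finite control group; the floor is configurable.

## Haplotype bias

Random ADO picks the retained allele independently per cell, while true
LOH retains one parental haplotype clone-wide. For each germline-HET SNP
in a called LOH region with ≥ 5 homozygous GoF calls, the package reports
max(hom_ref, hom_alt)/total homozygous per group, expected ≈ 1 under LOH
and ≈ 0.5 under dropout. Because a REF call only means "homozygous
reference" where the germline is heterozygous, sites qualify via a WT
consensus (called HET in ≥ 50% of genotyped WT cells) unless an external
truth set is supplied.

## Confounded-SNP flags

SNPs inside called LOH regions whose GoF heterozygous proportion exceeds
0.8 contradict the call and are annotated (never removed) with the three
known mechanisms: overlap with a panel indel, heterozygosity for two
alternate alleles at the locus (recorded when multi-allelic VCF records
are split), or proximity within 10 bp of a panel indel.

## Co-mutation doublet null

Mutant calls for co-mutation testing are read-count based (depth > 20 at
all tested loci — cells failing depth anywhere are dropped from the joint
analysis — alternate count > 10, alternate fraction > 0.1; HET and HOM
count alike). Enrichment is a two-tailed Pearson chi-squared test without
continuity correction; the doublet null works as follows. A clone carrying
a heterozygous somatic variant has cell fraction f = 2·VAF (from
single-cell data f is estimated directly as the mutant-cell fraction).
With Poisson(λ) droplet loading, the multiplet fraction among observed
barcodes is (1 − e^−λ − λe^−λ)/(1 − e^−λ); a doublet is a cross-clone
pair with probability 2·f_A·f_B, so the expected double-mutant count is
n·doublet_frac·2·f_A·f_B, compared to the observed count by an upper-tail
Poisson test. The pairing factor 2 is validated against a brute-force
droplet co-encapsulation simulation in the test-suite rather than assumed.
λ is not identifiable from a processed genotype matrix and defaults to
0.1 (~5% multiplets, typical of droplet platforms). The triple-mutant
extension drops ubiquitous variants (f ≈ 1) before forming the
expectation — so it reduces exactly to the pairwise formula when one
variant is carried by all cells — and otherwise requires a triplet
droplet, with expectation n·triplet_frac·3!·f_A·f_B·f_C.

## Synthetic-data generator

The generator emulates the statistical structure the analysis consumes,
not the sequencing chemistry. Defaults define the study conditions used
throughout validation:

| parameter | default | rationale |
|---|---|---|
| panel | 2 chromosomes × 2 arms × 25 SNPs + 1 indel + anchor on a 3rd chromosome | anchor and LOH on different chromosomes, as in the motivating disease setting |
| n_wt / n_gof | 100 / 30 | 30 variant cells is the power model's detection floor at δ = 0.3 |
| ado_rate | 0.2 | reproduces the ~80% heterozygous-call rate at germline sites |
| missing_rate | 0.05 | residual per-site dropout beyond the depth gates |
| depth_mean, dispersion | 80, 4 (negative binomial) | deep targeted panels; heavy-tailed per-amplicon variation |
| doublet_rate | 0.05 | typical droplet multiplet fraction |
| seq_error | 0.001 | per-read miscall rate at homozygous sites |
| loh_site_penetrance | 1.0 | full-region LOH; set to δ/(1 − ado_rate) to inject an absolute Prop_het reduction δ |

Generation order: true alt dosage per cell × site (germline sites 0.5;
anchor 0.5 in clone cells; copy-neutral LOH replaces carrier-cell dosage
with the retained-haplotype allele, phase drawn once per site so the
retained haplotype is consistent across the clone) → symmetric ADO at
heterozygous sites → negative-binomial depth, halved in copy-loss regions
of carriers and zeroed with high probability (or deterministically, for
the deletion scenario's fast path) → binomial alternate reads → doublet
barcodes formed by adding the read counts of a random partner cell →
genotype calling through the standard thresholds. All randomness flows
from one seed; identical configurations are bitwise-reproducible.

What the generator does **not** model — and what passing tests therefore
do not show about real data: ADO correlation along amplicons (real
dropout is locally correlated; treating sites independently makes the
rank-sum slightly optimistic about effective SNP counts per bin),
amplicon- and GC-specific dropout bias, barcode collisions beyond two
nuclei, contamination/index hopping, and mapping artifacts at indels
(panel indels exist but their alignment pathology is not simulated).

## Validation problem sizes

The shipped statistical checks use 200 seeded replicates for the
family-wise type-I error of the arm-level scan (observed 0.02 against a
0.07 bound at α = 0.05) and 200 for truth recovery at the δ = 0.3,
30-vs-100-cell operating point (observed 1.00, bound 0.85, with the
injected arm also the minimal-p arm); 100 fixtures for exact-permutation
equivalence; 25 replicates each for the deletion scenario and its null;
100 for the doublet-null calibration; 1000 Monte-Carlo draws for the
power cross-check. These sizes keep the full suite under a minute while
leaving wide margins to the bounds.

## Known limitations

* The approach requires a reliable somatic anchor; lesions without one
  cannot be partitioned.
* LOH on the anchor's own chromosome is entangled with dropout of the
  anchor itself and is effectively untestable by this contrast.
* Arm-level bins assume LOH spans most of the arm; focal events between
  the 4-SNP window and arm scales lose power at low SNP density.
* Bonferroni across sliding windows is conservative because adjacent
  windows overlap heavily.
* The doublet null depends on an externally supplied loading rate λ.
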