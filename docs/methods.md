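# Methods

## Coordinate frame and gold-standard model

All analysis runs in 1-based positions of the concatenated ARS-exon coding
sequence per locus (546 bases for class-I-style loci spanning exons 2+3, 270
for class-II-style loci spanning exon 2). VCF records are translated into
this frame on ingest through an ordered exon map; on minus-strand loci, CDS
position 1 maps to the highest genomic coordinate of the first coding exon
and REF/ALT bases are reverse-complemented into CDS space. FE is
nevertheless defined for the reference-genome (index) allele: in CDS space
that allele is represented by its reverse complement, so the frequency is
unchanged. The genomic-to-CDS mapping is round-trip tested over random exon
maps on both strands.

Sequence-based typings are allele names with 1–4 colon-separated numeric
fields. An allele call may be ambiguous in two ways that this package treats
identically: an explicit `/`-separated candidate list, and a
lower-than-full-resolution name, which stands for every catalog entry
sharing the prefix. Each chromosome copy is expanded to the position-wise
union of its candidates' ARS sequences (a *consensus* whose ambiguous
positions hold base sets). Genotypic ambiguity — uncertainty about which
allele *pair* a typing supports — is not modelled: each reported copy is
expanded independently, a simplification that can understate within-copy
correlations of ambiguous sites. Expression-suffixed names (N, L, …) are
rejected rather than silently handled; they denote variation outside this
data model.

## Comparison and correction rules

At each site, an ambiguous gold base set whose intersection with the NGS
allele pair is non-empty is replaced by a base from that intersection
("correction toward the call set"); when both copies are ambiguous the
resolution maximizing the subsequent match is chosen, which is the only
reading of the rule that never punishes ambiguity. Correction is applied
per site independently; no information flows between sites of one
individual. A corrected genotype matches when the two NGS alleles can be
assigned one-to-one to the gold copies, each allele a member of its copy's
base set — so a homozygous call (A, A) requires A on *both* gold copies.
This pairing semantics is checked exhaustively against a brute-force
enumeration of both assignments for all small genotype configurations.

Missing NGS genotypes are excluded from comparisons and from NGS frequency
denominators. Gold copies whose ambiguity cannot be resolved (no
intersection, or missing NGS data) contribute fractionally to gold
frequencies — 1/|set| of a reference allele per copy — which avoids
directional bias from unresolved ambiguity.

## Frequency statistics

FEᵢ = f(i, NGS) − f(i, gold) per site; MAE is the per-gene mean of |FEᵢ|.
Classification thresholds: overestimated FE > 0.1, underestimated
FE < −0.1, well estimated |FE| < 0.01, intermediate otherwise; a site is
*unreliable* when |FE| > 0.1 in at least two populations (population
frequencies pool individuals, the "global" column pools everyone; samples
without a population label join only the global pool). Direction counts for
the per-locus binomial test classify each flagged site by the sign of its
pooled FE; the alternative convention (majority sign across populations) is
not implemented because the pooled sign is well defined even when
populations disagree. The binomial test is the exact minimum-likelihood
two-sided test (`scipy.stats.binomtest`), verified against direct
enumeration for all n ≤ 20. Pearson correlations use the t-distribution
p-value with n − 2 df and refuse constant vectors; p-values are reported at
full floating-point precision with no floor above underflow.

## Window statistics

Windows span ±25 bases around a SNP, truncated at the CDS boundaries (no
padding), and are built on the concatenated ARS sequence, so a class-I
window may span the exon-2/exon-3 junction; allele and index sequences live
in the same frame, so the comparison stays aligned, but physical reads do
not cross the intron — a documented approximation. One window is built per
chromosome copy of every sampled individual (930 diploids → 1860 windows
per SNP). The mismatch count excludes the central site. Residually
ambiguous flanking positions count as matches when the index base is among
the possible bases (conservative); copies whose *central* base is ambiguous
are excluded from both groups.

The REF-vs-ALT comparison uses a one-tailed Mann-Whitney U test. For small
groups (both ≤ 50 and total ≤ 100) the p-value is exact: a dynamic program
over doubled midranks enumerates the full permutation distribution,
handling ties exactly; this is cross-checked against brute-force
enumeration for group sizes ≤ 8 and against scipy's exact method in the
tie-free case. Larger groups use the tie-corrected normal approximation
with continuity correction (`scipy.stats.mannwhitneyu`).

## The synthetic-data generator

The generator emulates the benchmark's statistical structure:

* **Reference and pool.** A uniform-random ARS sequence of length L = 546
  (class-I-like, two 273-bp exons). Background SNPs are placed at density
  0.12 per base (matching the observed 35–66 SNPs per ARS region across
  classical loci), each with one ALT base and a carrier fraction drawn from
  a low-skewed Beta(0.8, 4) clipped to [0.02, 0.5]. Focal SNPs (defaults:
  CDS 100, 220, 340, 460 with ALT pool fractions 0.35–0.50) additionally
  give every ALT-carrying allele δ = 3 perfectly linked flanking variants
  within the read window — the haplotype structure that produces mapping
  bias. The default pool holds 4096 alleles (catalog-scale; classical HLA
  loci have thousands of known ARS alleles), 10% of which belong to "twin"
  pairs differing at exactly one background site and sharing a 2-field name
  prefix; twins are the ambiguity partners.
* **Populations.** 12 populations × 78 diploids by default (the 930-sample
  scale); per-population allele frequencies are symmetric Dirichlet draws
  (concentration 2.0 over the pool, i.e. near-uniform). Each copy becomes an
  ambiguity set (true allele + twin) with probability 0.1 where a twin
  exists; each individual's locus is missing from the gold table with
  probability 0.02.
* **Reads and calls.** Reads at a site are fixed (2w+1)-windows of the
  underlying haplotype (w = 25). A read with m mismatches to the index —
  central site *included*, since a mapper cannot know which site is focal —
  survives with probability (1−λ)ᵐ; per copy, surviving reads are
  Poisson(c/2 × retention) with mean depth c = 8. Surviving reads report
  the copy's base, flipped to a uniform other base with probability
  ε = 0.005. The genotype is the maximum-likelihood diploid call among
  {hom REF, het, hom ALT} under a symmetric-error read model; zero
  surviving reads yield homozygous REF by default (mimicking
  reference-biased integrated call sets; configurable to missing). The
  depth table records surviving-read counts.

Mean depth 8 is deliberately above the ~2× of typical low-coverage
population data: the generator calls genotypes per site without the
imputation and haplotype-sharing machinery that production call sets use,
and at 2× the zero-read fallback would dominate the frequency error even
without mapping loss. At depth 8 the caller is near-exact when λ = 0, so
measured FE isolates the mapping-loss mechanism itself.

Two deliberate asymmetries: the retention model counts the central mismatch
while the analysis-side window statistic excludes it; and base-call errors
can produce spurious heterozygotes under ML calling (a single discordant
read outweighs its ε/3 error probability), so deterministic-limit
statements (e.g. λ = 1 forcing all-REF calls) hold exactly only at ε = 0.

All randomness flows from one seed through spawned generators; repeated
runs are bit-identical, including written files.

## What the generator does and does not emulate

It reproduces: ambiguous and low-resolution allele calls, per-population
frequency variation, linked flanking variation around biased SNPs, loss of
ALT-bearing reads increasing with haplotype divergence, Poisson depth, and
reference-biased no-call behaviour. It does not reproduce: realistic
read-length/fragment geometry, paralogous mapping (the second *HLA* failure
mode), imputation-driven error correlation across sites and samples,
coalescent allele genealogies, or a skewed allele-frequency spectrum. The
last point matters for the window test: with near-uniform catalog-scale
frequencies, sampled chromosome copies are nearly all distinct alleles and
the copy-weighted rank-sum test is calibrated (measured type-I rate ≈ 0.05
at α = 0.05). Real HLA samples repeat common alleles heavily; duplicated
copies violate the test's independence assumption and make it
anti-conservative, a caveat that applies equally to copy-weighted window
tests on real data. Passing calibration here therefore certifies the
statistical machinery, not the independence structure of real samples.

## Replicate experiment scales

The replicated experiments (`refbias.experiments`) use ~200 individuals per
replicate: 4 populations × 50 for the null calibration (200 replicates) and
the λ-profile (100 replicates per λ, common seeds across the grid for a
paired comparison), and 12 populations × 17 for mechanism recovery (100
replicates), where per-population flagging needs many populations. These
scales put Monte-Carlo error well below the probed effect sizes (null 3 × MC
SE ≈ 0.001 against planted FE effects of 0.1–0.4) while a full sweep runs in
seconds. Flag rate is reported as the fraction of (focal site, replicate)
pairs flagged.

## Numerical choices and degenerate inputs

Genotype-likelihood terms use `xlogy` so ε = 0 is exact; ML ties (measure
zero for ε > 0) resolve in the fixed order hom-REF, het, hom-ALT. The exact
rank-sum DP works on doubled midranks to stay in integers. Empty inputs —
no genotypes at a site, empty FE lists, empty rank-sum groups, all-zero
mismatch counts, constant correlation vectors — raise `ValueError` rather
than returning NaN; pipeline-level correlations degrade to NaN with a
logged warning when a run has too few usable sites. Sites present in the
VCF but monomorphic in the gold catalog are still compared (the gold
contributes its fixed base). VCF ingest skips indels, multiallelic records
and out-of-exon positions with per-reason counts.

## Known limitations

Windows may span exon junctions (above); genotypic ambiguity is not
modelled; the direction test's pooled-sign site classification is one of
two defensible readings; depth is recorded at called sites only (the
generator has no off-site reads); and the generator's uniform allele
spectrum understates the pseudo-replication present in real samples.
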