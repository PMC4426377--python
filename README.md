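# refbias

Benchmarking NGS SNP genotype calls against gold-standard HLA typings —
genotype concordance with ambiguity resolution, allele-frequency error
statistics, and tests for reference-allele mapping bias.

## The problem

Short-read variant calling against a single reference index is unreliable in
highly polymorphic regions such as the classical *HLA* genes: reads carrying
alternative alleles, especially alleles embedded in divergent haplotypes, map
less efficiently than reads matching the reference, so genotype calls and
allele-frequency estimates drift toward the reference allele. `refbias` is a
toolkit for quantifying that failure mode by benchmarking an NGS call set
(VCF) against sequence-based typing of the same samples, treated as a gold
standard. It is aimed at population geneticists who need to know which SNPs
in a call set have trustworthy frequencies before using them downstream.

The gold standard arrives as HLA-style allele names per individual
(`B*35:03`, possibly ambiguous lists such as `B*35:02/B*35:03/B*35:04`).
The package expands names to their ARS (antigen recognition site) exon
coding sequences via an allele catalog, builds per-copy consensus sequences
in which ambiguous positions carry base *sets* (e.g. A/T), and deconstructs
the diploid typing into per-site genotypes on a 1-based coordinate frame
over the concatenated ARS exons.

## Statistics computed

* **Genotype concordance.** At each site in each individual, ambiguous gold
  base sets intersecting the NGS allele pair are first resolved toward the
  NGS call; a genotype then matches only if both NGS alleles can be paired
  one-to-one with the gold chromosome copies. Overall, per-site and
  per-individual mismatch rates are reported, plus the fraction of sites
  that concentrate half of all mismatches.
* **Frequency error.** Per site *i*, FEᵢ = f(i, NGS) − f(i, gold) for the
  reference allele; per gene, MAE = (1/n) Σ |FEᵢ|. Sites are classified as
  *overestimated* (FE > 0.1), *underestimated* (FE < −0.1), *well estimated*
  (|FE| < 0.01) or intermediate, and flagged *unreliable* when |FE| > 0.1 in
  two or more populations. An exact two-sided binomial test asks whether
  flagged sites deviate equally often toward REF and ALT.
* **Mapping-bias windows.** For every chromosome copy in the sample, a 51-bp
  window (25 bp each side, truncated at CDS edges) is cut around each SNP;
  mismatches to the index sequence are counted excluding the central site.
  REF- vs ALT-centered window groups are compared per site class with a
  one-tailed Mann-Whitney U test (exact, tie-aware enumeration for small
  groups; tie-corrected normal approximation otherwise).
* **Correlates.** Sequencing depth by match status, depth vs |FE|, site
  heterozygosity H = 2p(1−p) vs FE and |FE|, and the impact on the H
  distribution of removing unreliable sites.

A synthetic-data generator closes the loop: it builds an allele pool over a
synthetic ARS sequence with designated focal SNPs whose ALT haplotypes carry
δ linked flanking differences, samples diploid populations, and produces NGS
calls under a per-read mapping-loss model — a read with *m* mismatches to
the index survives with probability (1−λ)ᵐ — so every pipeline stage is
testable end to end without external data.

## Worked example

`examples/02_simulate_benchmark.py` simulates 360 diploids in 6 populations
under mapping loss λ = 0.3 with δ = 3 linked flanking variants at four focal
SNPs, writes the bundle in standard formats (VCF, gold TSV, catalog FASTA,
exon map, depth table) and runs the full pipeline on the files:

```
simulated 360 diploids over 82 SNPs (mapping loss lambda=0.3, linked flanks delta=3)
genotype mismatch rate: 13.3% over 28946 comparisons
23.2% of sites hold half of all mismatches
MAE: {'SYN': 0.04225108823326194}
unreliable sites (|FE|>0.1 in >=2 populations): [('SYN', 78), ('SYN', 94), ('SYN', 99),
 ('SYN', 100), ('SYN', 200), ('SYN', 213), ('SYN', 219), ('SYN', 220), ('SYN', 339),
 ('SYN', 340), ('SYN', 344), ('SYN', 365), ('SYN', 442), ('SYN', 460), ('SYN', 467),
 ('SYN', 470)]
direction counts (REF-skewed, ALT-skewed): {'SYN': [16, 0]} binomial p: {'SYN': 3.0517578125e-05}
```

All four focal sites (100, 220, 340, 460) and their linked flanking variants
are flagged; every flagged site is skewed toward the reference allele, and
the binomial direction test rejects symmetric deviation — the signature of
reference-allele mapping bias. The other examples walk through allele-name
parsing and consensus building (`01`), the flanking-window test on a
hand-built haplotype set (`03`), and the replicated null-calibration /
mechanism-recovery experiments (`04`).

A thin CLI wraps the same machinery:

```bash
refbias simulate --out fixture/
refbias report --vcf fixture/calls.vcf --gold fixture/gold.tsv \
    --catalog fixture/catalog.fasta --exon-map fixture/exon_map.json \
    --depth fixture/depth.tsv --out results/
```

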