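# probeaudit

Probe-SNP auditing for Illumina Infinium DNA-methylation arrays.

## The problem

Each CpG on a methylation array is read through a 50-bp hybridization
probe plus a single-base extension (SBE) — a 51-position genomic
footprint. A common SNP inside that footprint can change hybridization
efficiency, and a SNP on the CpG dinucleotide itself (probe index 0 or 1)
can abolish the CpG on one haplotype, so an "unmethylated" readout is
really a genotype. In cohorts that mix genetic ancestries — African-American
cohorts analysed with local-ancestry (LA) aware models in particular —
probe SNPs that are strongly differentiated between the ancestral
populations masquerade as ancestry-specific methylation effects.

`probeaudit` is a toolkit for detecting and quantifying this failure mode:

1. **Probe regions** — derive each probe's 51-bp window from a manifest
   (CpG id, chromosome, MAPINFO coordinate, targeted strand F/R, Infinium
   type I/II) with a signed probe-index system in which index 0 is always
   the targeted cytosine. For reverse-strand probes the targeted C is the
   *minus-strand* C at plus-strand position `p + 1` — the position that
   naïve region definitions miss.
2. **Variants** — read biallelic SNVs from a VCF with a population panel
   and keep those with minor-allele frequency ≥ 5% in *either* reference
   population (EUR or AFR style super-populations).
3. **Cross-reference** — intersect regions with SNPs; at the Type I SBE
   position only colour-channel-switching SNPs (pairs other than A/T and
   C/G) are retained.
4. **Differentiation** — per-site Weir–Cockerham
   θ = a / (a + b + c) from the among-population (a),
   between-individual (b) and within-individual (c) variance components,
   using observed heterozygosity; θ ≥ 0.1 flags a strongly differentiated
   probe SNP.
5. **Bias diagnostics** — probe-SNP enrichment among meQTL CpGs, Welch
   t-tests on θ and on effect magnitudes, accounting of CpGs whose CpG
   site is disrupted by a differentiated SNP, and OLS polynomial
   regression of effect magnitude |β| (or ancestry effect difference
   Δ = |β_EUR − β_AFR|) on probe-SNP distance with sequential nested
   F-tests (F = (RSS₍ₖ₋₁₎ − RSSₖ) / (RSSₖ / (n − k − 1))) to pick the
   degree.
6. **Synthetic fixtures** — a generator that plants all of this structure
   (Balding–Nichols two-population divergence, distance-dependent effect
   sizes) so the whole pipeline is testable without any downloads.

## Worked example

Generate fixtures at the default study conditions and audit them:

```bash
probeaudit simulate --seed 1 --out-dir fixtures/
probeaudit audit \
    --manifest fixtures/manifest.csv --vcf fixtures/variants.vcf \
    --panel fixtures/panel.txt --meqtl fixtures/meqtl.tsv \
    --out-dir run/
```

which prints

```
probe-SNP CpG fraction: meQTL 0.351 vs non-meQTL 0.164
```

meaning 35.1% of the 946 meQTL-associated CpGs carry at least one common
probe SNP versus 16.4% of the other 1554 CpGs — the planted enrichment
(37.5% vs 16.1%) recovered to within sampling error. `run/report.json`
holds the full diagnostics; in this run the meQTL probe SNPs have median
θ = 0.16 against 0.002 for the rest (Welch mean difference 0.22), a cubic
is selected for the |β|–distance regression (R² = 0.53 at n = 332 CpGs)
and a quadratic for the Δ–distance regression (R² = 0.51 at n = 57),
matching the generating models. Intermediates (`regions.bed`, `snps.tsv`,
`hits.tsv`, `fst.tsv`) are written alongside, and each stage is also
available as its own subcommand (`regions`, `snps`, `crossref`, `fst`,
`bias-report`) that chains to the identical report.

The same run against real data needs only a manifest CSV, a VCF plus
sample panel, and a meQTL table
(`cpg_id  snp_id  beta[  beta_eur  beta_afr]`).

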