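# Methods

## Probe-region model

An Infinium assay probe hybridizes to 50 bases adjacent to its target
cytosine and is read out by single-base extension (SBE). The auditable
footprint is therefore 51 genomic positions. We use a signed probe-index
coordinate system anchored at the target cytosine:

* index 0 — the targeted C. For forward (F) probes this is the manifest
  coordinate `pos`; for reverse (R) probes the targeted C lies on the
  minus strand, i.e. plus-strand position `pos + 1`. Treating `pos + 1`
  as index 0 for R probes is the load-bearing detail: a pipeline that
  anchors both strands at `pos` silently misses CpG-site SNPs on every
  reverse-strand probe.
* index 1 — the other base of the CpG dinucleotide. Indices 0 and 1
  together are the *CpG-disrupting* positions: a SNP there removes the
  CpG on one haplotype.
* Type II probes interrogate the C at the extension position, so their
  window covers indices 0..50. Type I probes extend one base before the
  C; by default their window is −1..49 with the SBE at index −1. Because
  manifest vendors describe the Type I geometry with varying clarity, the
  window placement is a configurable convention (`type1_window`):
  `sbe_minus1` (default) or `same_as_type2`. Under both, 51 positions are
  audited and indices 0/1 are the CpG.

Distance is defined as |probe index|, so a Type I SBE hit reports
distance 1; the `at_sbe_position` flag preserves the distinction from the
guanine at index +1. Internally all intervals are 0-based half-open;
every user-facing coordinate is 1-based inclusive, with the conversion
confined to `ProbeRegion` construction.

## Variant handling

Only biallelic SNVs are used; indels, multiallelic and symbolic records
are skipped (decomposing multiallelics would require an allele-matching
policy with no principled default here). Phased and unphased genotypes
are equivalent; half-calls count as missing. Frequencies are computed
from genotypes, not from VCF INFO fields, so the same code path serves
arbitrary cohorts. The headline filter keeps SNPs with minor-allele
frequency ≥ 5% (inclusive) in at least one of the listed populations;
a single-population segregation mode (`freq_in_pop`, minor-allele
symmetric) supports checks like "segregates at ≥ 1% in ASW".

At the Type I SBE position, only colour-channel-switching substitutions
(unordered pairs other than {A,T} and {C,G}) can corrupt the readout, so
same-channel SNPs there are dropped; the rule does not apply to Type II
probes or to body positions.

## Weir–Cockerham θ

Per-site differentiation uses the 1984 variance-component estimator for
r = 2 populations with *observed* heterozygote fractions (no
Hardy–Weinberg assumption), returning the components (a, b, c) and
θ = a/(a+b+c). Design choices:

* θ is undefined (None/NaN), never silently 0, when a+b+c = 0
  (monomorphic in both populations).
* Negative estimates are reported as-is; clamping would distort the
  medians and Welch tests downstream.
* "Strongly differentiated" means θ ≥ 0.1, inclusive.
* Per-site values are the primary surface because the diagnostics operate
  on distributions of θ. A `multilocus_theta` helper implements the
  standard combined form (sum the components across sites, divide once).
  The two aggregations differ materially: the average of per-site ratio
  estimates sits well below the generating divergence (≈0.21 when the
  truth is 0.3 in our simulations — a Jensen-inequality effect inherent
  to ratio estimators, not a finite-sample artifact), while the combined
  form recovers it. Any single-number summary should therefore use
  `multilocus_theta`; only distribution summaries (medians, group tests)
  should use the per-site values.

## Bias diagnostics

* Group comparisons use Welch's unequal-variance two-sided t-test with a
  Welch–Satterthwaite CI. Welch is the default because equal variances
  cannot be assumed between probe-SNP and non-probe-SNP groups.
* Effect sizes enter as magnitudes |β|; the ancestry-specific difference
  is Δ = |β_EUR − β_AFR|. Records lacking ancestry-specific effects are
  excluded from Δ analyses with the exclusion count reported.
* Distance regressions use one point per CpG: the representative
  (nearest-to-cytosine) retained hit supplies the distance, and the
  strongest association supplies the magnitude when a CpG has several.
  Ties in distance break by higher θ, then lexicographic SNP id, making
  every rollup invariant to input order.
* Polynomial degrees 1..3 are fitted by OLS with intercept; the degree is
  chosen by forward sequential F-tests at α = 0.05: escalation continues
  while each step (k vs k−1) is significant and stops at the first
  failure, with the linear fit as the floor. All step statistics are
  reported. No multiple-testing correction is applied to these
  diagnostics; p-values are raw.
* Disruption accounting counts a meQTL CpG when a retained hit at probe
  index 0 or 1 has θ ≥ 0.1; the association-level fraction counts every
  meQTL record on counted CpGs, and the reported median θ is over each
  counted CpG's highest-θ qualifying hit.

## Synthetic generator

The generator's defaults are the study conditions the diagnostics are
designed for, at desk scale:

| parameter | default | role |
| --- | --- | --- |
| probes / meQTL CpGs | 2500 / 946 | ≈354 meQTL probe SNPs, matching the ≈350-point regression regime |
| probe-SNP rates | 0.375 meQTL, 0.161 non-meQTL | planted enrichment |
| divergence F | 0.30 meQTL-probe SNPs, 0.01 otherwise | Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) per population |
| samples | 100 diploids per population | genotypes ~ Binomial(2, p_pop) (HWE) |
| CpG-site planting | 27% of planted SNPs at index 0/1 | drives the disruption accounting and the non-linearity |
| |β| model | 2.2 − 0.24d + 0.0093d² − 1.05·10⁻⁴d³ + N(0, 0.9²), floored at 0 | cubic in distance d, explaining ≈0.4 of variance at n ≈ 350 |
| Δ model | 1.8 − 0.08d + 0.001d² + N(0, 0.8²), floored at 0 | quadratic, over a 135-CpG LA-aware subset (58 with probe SNPs) |
| baselines | \|N(0.55, 0.4²)\| for β, \|N(0.4, 0.35²)\| for Δ | CpGs without probe SNPs |

The cubic was chosen to stay positive over d ∈ [0, 50] (a steep drop from
the CpG site, a plateau, and a late bend), and its noise level to put the
cubic R² near the ~0.4 regime these diagnostics face in practice while
keeping the cubic term reliably detectable at n ≈ 350. Planted probe SNPs
are rejection-sampled until their *sample* MAF reaches 5% in at least one
population, so the audit's frequency filter cannot silently erode the
planted enrichment; CpG-site SNPs attract extra associations
(1 + Poisson(0.8) vs 1 + Poisson(0.25)) so association-level impact
exceeds CpG-level impact, as artifact amplification produces in practice.
One seeded `numpy` generator drives every draw; identical configs give
byte-identical files.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, rare variants and realistic site-frequency spectra, bisulfite
conversion or intensity-level chemistry, cross-reactive probes, and
local-ancestry tract structure. Passing tests therefore certify the
audit's arithmetic, filters and statistics — not robustness to every
property of real array data.

## Numerical choices and degenerate inputs

* R² is reported as 0 when the response is constant (TSS = 0); a perfect
  fit reports an infinite F with p = 0; identical-RSS steps give F = 0
  and are rejected.
* Rank-deficient polynomial designs (all distances equal) and groups with
  < 2 values or zero variance raise errors naming the offending input.
* The `bias-report` subcommand parses the Fst table with round-trip float
  precision so the manual subcommand chain reproduces `audit` bit for bit.
* Problem sizes in the test suite and acceptance script (500-SNP
  divergence recovery, 200/1000 model-selection replicates, one
  default-scale end-to-end run) were chosen as the smallest sizes at
  which the statistical contracts are sharp.

## Known limitations

* Only r = 2 populations; no haploid mode; no confidence intervals on θ.
* Multiallelic sites are skipped rather than decomposed.
* CH (non-CpG) probes, control probes and cross-reactive-probe detection
  are out of scope.
* The Type I window placement is a convention (configurable), not a fact
  derivable from manifests alone.
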