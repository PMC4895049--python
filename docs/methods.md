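# Methods

## What the package computes

`ecoscan` implements the population-genomic toolkit used to characterize a
recent ecotype radiation: masking and site-eligibility bookkeeping,
outgroup polarization and a derived-mutation TMRCA clock, windowed
differentiation/diversity landscapes, PBS selection scans with enrichment
tests, four- and three-population admixture statistics, and X-versus-
autosome effective-size scaling. A coalescent simulator generates cohorts
with the statistical structure these methods assume, so every statistic is
validated against a known truth table.

## Statistical definitions

**FST.** Per site, the Hudson/Bhatia method-of-moments components are

    N = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    D = p1(1−p2) + p2(1−p1)

with `n` the number of sampled alleles. Windows report ΣN/ΣD (ratio of
sums), which is robust to varying sample size and nearly unbiased; site
numerators may be negative and are deliberately not clamped so the window
aggregate stays unbiased. Sites monomorphic across both populations
contribute (0, 0).

**Dxy** is `p1·q2 + p2·q1` summed over sites and divided by covered bases;
invariant sites carry frequency zero. **π** uses the unbiased per-site
heterozygosity `2p(1−p)·n/(n−1)`, normalized the same way.

**PBS.** Pairwise window FST values are transformed to branch-scaled
divergences `T = −log(1 − FST)` and combined for the trio (A, B, C) as
`PBS_A = (T_AB + T_AC − T_BC)/2`, the allele-frequency branch length
private to A. Negative pairwise FST is clamped to 0 before the log
(sampling noise must not create negative branch scale); window FST is
capped at 1 − 1e-12 so fixed-difference windows stay finite. Negative PBS
values are reported unclamped. Outliers are features at or above the
empirical 99.9th (or 99.99th) percentile, computed as an order statistic
(`method="higher"`) with ties included; a warning is emitted when fewer
than 1,000 features make that percentile unstable.

**Enrichment.** The top 1% of per-SNP FST values (ties included) is
cross-tabulated by genomic category (exon > intron > 25-kb gene flank >
intergenic, by precedence) against FST bins (default width 0.1 on [0, 1]).
Pearson residuals `(obs − exp)/√exp` are flagged two-sided at α = 0.05
Bonferroni-corrected over the tested cells; cells with expected < 1 are
excluded from testing. Expectations come from row/column independence, or
from per-bin background category shares when a background SNP table is
supplied. Gene-term enrichment is a one-sided Fisher exact test computed
via the hypergeometric tail, with Bonferroni-adjusted p-values; term
databases are user-supplied.

**Admixture.** With per-site derived frequencies for (P1, P2, P3, O),
`ABBA = (1−p1)p2p3(1−p4)` and `BABA = p1(1−p2)p3(1−p4)`, and
`D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`. After polarization the outgroup is fixed
ancestral (p4 = 0); a genotyped outgroup population may be named instead.
`f3(T; A, B)` averages `(c−a)(c−b) − c(1−c)/(n_c−1)` (the last term is the
finite-sample correction). Standard errors come from a delete-one jackknife
over contiguous blocks of 1,000 SNPs (the remainder folds into the last
block); with equal-size blocks, delete-one and weighted jackknives
coincide. Quartet tables carry uncorrected Z scores; interpret families of
quartets with that in mind.

**TMRCA.** For a derived-mutation count D of one mutation class observed
over L screened sites, `t = D/(L·μ_class)` years, where the class rate
splits the total substitution rate μ by the Ts/Tv ratio κ:
`μ_tv = μ/(1+κ)`, `μ_ti = μ·κ/(1+κ)`. Confidence bounds evaluate the same
formula at the rate HPD endpoints (a faster clock gives a younger age, so
the endpoints swap). L is exposed explicitly: it is the number of screened
third-codon positions with complete data, not the number of variants, and
published analyses often apply additional missing-data corrections to it —
so the package never hard-codes any particular interval.

**X/autosome scaling.** `μ_X = μ_A·2(2+α)/(3(1+α))` for a male-to-female
mutation rate ratio α > 0; the attainable ratio μ_X/μ_A is the open
interval (2/3, 4/3), so `invert_alpha` reports "infeasible" outside it
rather than extrapolating. Ne trajectories are stepwise-constant
(right-continuous), matching how sequential-coalescent output is drawn;
no interpolation is applied. The ratio series summary reports crossings of
0.75, the neutral X/autosome expectation.

## Masking and filter conventions

- The mask is the union of repeat intervals, numt intervals, and sites
  whose cohort-wide read depth strictly exceeds 200× (such pileups behave
  like unmasked repeats). Provenance counts attribute each masked site to
  the first source in the order repeat → numt → depth; the union itself is
  order-invariant, and numt sites already inside repeats add nothing.
- Masked fractions are stored at full precision and displayed at two
  decimals; the identity `fraction·genome/100 = sites` holds exactly.
- The structure filter keeps autosomal sites genotyped in ≥40 individuals
  with minor-allele frequency ≥5% (inclusive boundary: "below 5%" is
  removed). The window coverage filter requires strictly more than 10 kb
  covered by ≥5 individuals in every population.
- The third-codon MAF cutoff of 0.1 is applied to the derived-allele
  frequency by default (the filter guards against sequencing error in a
  polarized analysis); a `frequency="minor"` switch folds it instead.
- Mixed-state sites (transversion in one lineage, transition in another)
  are counted in the transversion class total; the within-lineage Ts/Tv
  excludes them by default and an `include_mixed` flag adds them — both
  conventions round to the same ratio at realistic counts. The simulator is
  biallelic, so simulated data never produce mixed sites; the field exists
  so multi-allelic tallies can be represented.

## The synthetic scenario

`build_paper_scenario` encodes a five-population radiation. Backward in
time: B1 and B2 merge at 1,500 generations, their ancestor joins C at
3,000, the Antarctic ancestor joins the resident at 5,000, and that
lineage joins the transient at 7,000. The paper trail for the real system
gives only the qualitative ordering (transient oldest, Antarctic clade
youngest) and the bottleneck scale (founder Ne below 1,000, down to tens),
so the quantitative choices here are the package's own:

| population | founder bottleneck (start gen, Ne) | recent Ne |
| --- | --- | --- |
| transient | 6,850–7,000, Ne 400 | 15,000 |
| resident | 4,650–5,000, Ne 80 | 15,000 |
| Antarctic ancestor | 4,900–5,000, Ne 600 | 20,000 |
| C | 2,960–3,000, Ne 900 | 25,000 |
| B1 / B2 | 1,460–1,500, Ne 900 / 950 | 25,000 |

One directional pulse (fraction 0.1) flows from the resident lineage into
the transient at 1,000 generations. Rates: μ = 2.34 × 10⁻⁸ per site per
generation, recombination 10⁻⁸, generation time 25.7 years (so the root
sits near 180 thousand years), mutation model HKY with κ = 7.6, which
yields a genome-wide Ts/Tv near 3.8 under equal base frequencies. The
default genome is 5 chromosomes × 2 Mb, scaled by a single `scale` factor;
48 diploid individuals (10/10/7/11/10) mirror the cohort structure the
statistics are meant for.

Two calibration trade-offs are deliberate. The resident's very deep founder
bottleneck (Ne 80 for 350 generations) supplies the population-specific
allele-frequency variance that makes a 10% pulse detectable by the
D-statistic at desk-scale genome sizes. Conversely the Antarctic trio's
bottlenecks are brief and mild, and their recent Ne generous
(diversity ≈ 2 × 10⁻³/bp, a few-fold above the real cohort's ≈ 9 × 10⁻⁴),
so that 50-kb windows contain enough independent genealogies for stable
percentile tails — which is what lets a 0.5 frequency displacement stand
out above the drift background. Genome-wide FST between the simulated
Antarctic pairs lands near 0.1, the same order as the real radiation's
youngest pairs, but matching the real FST matrix is explicitly not a goal.

Annotations are deterministic: genes tiled every 150 kb (8 exons × 200 bp,
1.8-kb introns, 25-kb flanks), with third-codon positions defined as every
third base of each exon on the + strand. Repeat-like intervals (~5% of each
chromosome) are seeded randomly, and simulated read depth (Poisson around
2× per individual, 4-fold inflated inside repeats) feeds the >200× masking
rule. Outgroup mislabelling is available (`outgroup_error`) but defaults to
0 so printed-arithmetic checks stay exact.

What the generator does **not** emulate: genotype likelihood uncertainty
from low-coverage reads (genotypes are exact), linked selection, base
quality or mapping artifacts beyond the depth proxy, multi-allelic and
mixed-state sites, and the real cohort's allele-frequency spectrum. Tests
that pass on these cohorts therefore validate the statistical machinery
and its contracts, not inference accuracy on low-coverage sequencing data.

**Sweep spiking** displaces derived frequencies as `p' = p + s(1−p)` by
flipping exactly `round(s · n_anc)` ancestral alleles per site (seeded), so
the displacement is exact up to integer rounding and `s = 1` fixes the
region. Spiked regions are recorded in the dataset's truth table.

## Numerical and degenerate-input conventions

- Windows are 0-based half-open, tiled by default, sliding when a step is
  given; the final partial window at a chromosome end is kept.
- Zero-denominator windows (no variation in either population) report FST
  as NaN and are flagged rather than silently dropped.
- Percentile thresholds use the `"higher"` order statistic so "top k of n"
  is exact under distinct values and tie-inclusive otherwise; with all
  values equal, everything ties at the threshold and is returned.
- The jackknife requires ≥2 blocks; a leave-one-out zero denominator (all
  informative sites in one block) raises rather than returning Z = ∞.
- `estimate_tstv` signals zero transversions as an error, and
  `shared_derived_fraction` signals a focal individual with no derived
  alleles, instead of returning silent zeros.
- Pipeline outputs are pure functions of (inputs, config, seed): tables are
  written with a config-hash/seed header, floats through a fixed `%.10g`
  format, and a rerun reproduces byte-identical files.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to exercise every code path with stable statistics:
10–15 Mb genomes for the 20-replicate calibration suites (neutral π vs
4·Ne·μ; D-statistic null and 10%-pulse detection; sweep detection at the
99.9th PBS percentile; TMRCA recovery on a two-population split with a
closed-form expected accumulation span), 1–2 Mb genomes for worked
examples, and a 0.1-scale (5 × 200 kb) genome for the end-to-end pipeline
determinism check.

## Known limitations

- Statistics operate on genotype-derived allele frequencies; the
  genotype-likelihood machinery appropriate to 2× sequencing data is out
  of scope, so applying the package to real low-coverage cohorts requires
  externally estimated frequencies.
- The D-statistic and f3 block jackknife assumes blocks longer than the
  correlation scale of linkage; with very few SNPs the block count (and
  hence the SE) becomes unreliable, and the code errors below 2 blocks
  rather than guessing.
- Exon-level PBS requires ≥2 SNPs per exon; singleton exons are reported
  but excluded from percentile ranking.
- The TMRCA clock inherits the usual caveats of interspecific rate
  estimates and of sharing of derived mutations under gene flow; it is an
  order-of-magnitude instrument, which is why L and the rate HPD are
  explicit arguments.
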