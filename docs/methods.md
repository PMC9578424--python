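# Methods

This note records the models, estimators and numerical choices behind
`mutaccum`, and what the simulators do and do not emulate.

## Mutation-rate estimation

The MA design assumes mutations arrive as a Poisson process in
site·divisions: conditional on line *i* passing *Tᵢ* cell divisions with
*Nᵢ* analyzed sites, its mutation count is Poisson(μ·Nᵢ·Tᵢ). The pooled
estimator μ̂ = m/Σ(Nᵢ·Tᵢ) is the MLE under that model. Two uncertainty
summaries are reported because both are standard in MA work:

* **SEM** — the sample SD (n−1 denominator) of per-line rates mᵢ/(Nᵢ·Tᵢ),
  divided by √n. It reflects between-line dispersion, including any
  overdispersion the Poisson model would miss.
* **Exact Poisson CI** — the Garwood construction via χ² quantiles,
  low = χ²_{α/2}(2m)/2D and high = χ²_{1−α/2}(2m+2)/2D with D = Σ(Nᵢ·Tᵢ),
  and low = 0 when m = 0. This interval is conservative: its true coverage
  is ≥ the nominal level and noticeably above it at small counts
  (97.96% at a true mean of 5; 95.26% at 50, computed exactly from the
  Poisson pmf). Tests of empirical coverage must account for that
  conservatism — it is a property of the construction, not a defect of the
  implementation.

Per-line analyzed sites default to the full genome length when per-line
site tables are unavailable; this shifts third-digit agreement of rate
estimates and is logged by the pipeline.

Indel rates share the all-sites denominator with base substitutions.
Conditional spectrum rates divide each collapsed class count by the
origin-pair site count (A/T sites for A:T-origin classes, G/C sites
otherwise) times Σ Tᵢ. The 4-fold-degenerate rate restricts both numerator
and denominator to third-codon positions whose three alternative bases
encode the same amino acid; positions covered by more than one gene are
excluded, since degeneracy in one reading frame does not imply neutrality
in an overlapping frame.

## Effective population size of the transfer regime

A single-colony transfer grows one cell to a colony by roughly binary
fission, so per-generation sizes are 2⁰, 2¹, …, 2^(g−1) within a cycle of
g divisions. The cycle's effective size is the harmonic mean,
Ne = g / Σᵢ wᵢ2⁻ⁱ, with a fractional final generation weighted by g−⌊g⌋.
Ne(1) = 1, Ne is constant at 1 for g ≤ 1, increases monotonically above
that, and approaches g/2 for large g; g = 27.48 gives Ne ≈ 13.74. The
estimator choice (harmonic mean over an exponential growth trajectory) is
this package's own, adopted because it is the textbook treatment of
fluctuating population size and reproduces the regime's reported magnitude.

## Annotation and site counting

Codon effects use bacterial translation table 11 (Biopython's table),
strand-aware: minus-strand genes complement the alleles before codon
substitution. Start-codon special cases are ignored. Stop codons are kept
in site counting, with stop→stop counted synonymous, so fractional
synonymous + nonsynonymous sites equal 3 × codons for every CDS including
its terminator. Indels are classified by length only, never syn/nonsyn.

Site opportunities follow the Nei–Gojobori construction: each codon
position contributes the fraction of its three substitutions that are
synonymous, optionally weighted by a 6-class spectrum (each directed change
weighted by its collapsed-class probability). Uniform weights are the
default; passing the observed spectrum matters whenever the spectrum is
transition-rich, because transitions at third positions are
disproportionately synonymous — with a transition-biased spectrum, uniform
weighting overstates the neutral nonsynonymous:synonymous ratio and biases
Ka/Ks downward (~12% in our neutral simulations).

Mutations falling in ≥2 CDS features are labelled "overlap", counted once
in totals, and attributed to every overlapping gene for gene-level tests.
A record whose reference allele disagrees with the genome is flagged
(`ref_mismatch`) and kept; its codon effect is left unset because the
surrounding codon cannot be trusted.

## Contingency and neutrality tests

2×2 contrasts use the Pearson statistic with Yates continuity correction by
default, with each |O−E| reduced by 0.5 **and floored at 0** — small
spectrum tables routinely have deviations under half a count, where the
floored statistic is exactly 0. (SciPy's correction shifts observed counts
toward expectation and can overshoot, so the statistic is computed here;
SciPy is used as a cross-check where the floor is inactive.) The
nonsynonymous:synonymous neutrality test is a 1-df goodness-of-fit against
the expected ratio r:1 treated as known without error.

## Selection scans

The hotspot test assumes mutational homogeneity along the genome: under the
null, a gene of length L receives Poisson(M·L/L_total) of the M observed
mutations. P-values are inclusive upper tails, Bonferroni-multiplied by the
number of annotated genes (default; the number of hit genes is an option —
the multiplier choice is logged). This is conservative and deterministic.

Ka/Ks counts observed mutation events per fractional site with no
multiple-hit (Jukes–Cantor) correction, appropriate for sparse
within-experiment counts. Genes with zero synonymous events get a
pseudo-Ks: a least-squares regression *through the origin* of synonymous
count on synonymous sites across genes with ≥1 synonymous event, evaluated
at the target gene's synonymous sites and floored at half a count. The
floor keeps tiny genes from implying an absurdly small Ks; flagged records
mark calibrated ratios. Population allele-frequency summaries average over
variant sites only (>5% detection threshold by default, strict inequality),
since frequency-zero sites are unobservable in population calls; intergenic
variants are grouped under a nearest-gene pseudo-label.

## Phenotypes

EOP is the plain CFU ratio and may exceed 1. The MIC is operationalized as
the lowest tested concentration from which every concentration upward has
zero CFU in all replicates — the machine-checkable proxy for "no visible
growth", robust to a spurious all-zero row below a growing one. Growth
rates are log-linear least-squares slopes over a window, defaulting to
densities between 10% and 90% of the curve maximum (the exponential phase
of a batch culture); at least 3 points are required. MIC fold-change
cohorts are summarized by mean and sample SD.

## Simulators

**Reference genomes** are i.i.d. base draws at a configurable GC fraction
(default 0.508, the *E. coli* chromosome's) with evenly spaced,
non-overlapping, fixed-length CDSs on random strands. Real genomes have
operon structure, codon bias and repeats; none of that is emulated, so
passing tests demonstrate estimator correctness, not robustness to genomic
heterogeneity.

**MA lines** draw per-line Poisson counts at rate × sites × divisions
(defaults: 200 lines, 27.48 divisions/transfer × 40 transfers, BPS rate
1.45×10⁻¹⁰ and indel rate 1.94×10⁻¹¹ per site per division, the
transition-rich 6-class spectrum of the emulated control data, full
chromosome length 4,641,652 bp; tests use shorter genomes with
proportionally raised rates). Each mutation draws its collapsed class from
the spectrum, a reporting strand at random, then a uniform site among
positions carrying the matching reference base. Sampling the class first
makes realized class proportions unbiased for the configured probabilities
regardless of genome composition (sampling sites first and conditioning the
alt on the reference base would tie class proportions to the genome's
A/T:G/C balance). Mutations are clonal singletons; configurations expecting
more than 10% of the genome mutated per line are refused, as the
no-multiple-hit assumption would fail. Indels are single-base with a VCF
anchor base.

**Serial-transfer evolution** uses a scaled census (default 10⁵ cells, not
the study-scale ~10¹¹): each daily cycle is 10 deterministic doublings from
the bottleneck (1:1000 dilution ⇒ ~100 founder cells) followed by binomial
resampling of every segregating site at the bottleneck — the dominant noise
source under 1000-fold dilution. Selection acts deterministically each
generation as p′ = p(1+s)/(1+ps) at designated loci; new mutations enter at
rate × current population size (genome-wide uniformly, plus a focused
supply at resistance loci, default 10⁻⁴ per replication — illustrative, as
the emulated study estimates no selection coefficients). Loci evolve
independently: no linkage, clonal interference or hitchhiking. Because the
census is fixed, population extinction cannot occur in this
frequency-space formulation. Configuring one generation per cycle with a
bottleneck of Ne cells reduces the model to a textbook Wright–Fisher chain,
which is how drift variance is validated against p(1−p)[1−(1−1/Ne)ᵗ].

**Plating assays** draw replicate CFU counts as Poisson(EOP × inoculum).

All generators are bit-reproducible under a fixed seed (NumPy Generator
streams; the pipeline derives per-stage streams from one root seed via
`SeedSequence.spawn`).

## Problem sizes used in tests and analyses

Tests run on 10⁵–2×10⁵ bp genomes with rates scaled so cohorts accumulate
~100–10⁴ mutations, 200 replicate experiments for coverage/FWER checks,
2000 replicate populations for drift variance, and 100 populations for
sweep detection; the bundled analysis drivers use a 200 kb genome, 60 MA
lines per group and 12+12 evolved populations. These sizes are the
package's choice of desk-scale defaults giving each check clear statistical
power.

## Known limitations

* Per-line analyzed-site heterogeneity is not modelled; the genome-length
  fallback slightly understates per-line rates when real coverage is
  incomplete.
* The neutrality expectation's construction (uniform vs spectrum-weighted,
  codon-usage effects) changes the χ² statistic's third digit; both options
  are exposed because the right choice depends on the data in hand.
* Ka/Ks on sparse counts is a detection statistic, not an estimate of the
  dN/dS of codon models; no phylogenetic correction is attempted.
* The evolution simulator's independent-locus approximation overstates the
  efficiency of selection when many selected lineages would compete in a
  clonal genome.
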