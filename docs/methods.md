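# Methods

This note records the models behind `bsamap`, the defaults and why they
were chosen, and what the synthetic experiments do and do not establish.

## Study design emulated

A biparental cross for a qualitative, monogenic, fully recessive trait:
two inbred parents, an F1, and an F2 of several hundred plants. Two bulks
of 30 plants each — one per phenotypic extreme — are sequenced to roughly
30× per pool, and per-SNP allele depths in the two pools are the input of
the genome scan. Codominant markers (CAPS/InDel) genotyped on the same F2
narrow the locus; a coding deletion in the candidate gene is classified
for its protein-level effect; qPCR quantifies the candidate's expression.
Every one of these inputs can be generated synthetically with a planted
ground truth, which is how the pipeline is validated.

## Meiosis and population model (`simdata`)

Gametes follow the Haldane model: the crossover count per chromosome is
Poisson with mean equal to the genetic length in Morgans, breakpoints are
uniform on the physical length, and there is no crossover interference.
This is the simplest standard model and the only assumption the analysis
downstream actually uses (it fixes the recombination fraction
r = (1 − e^(−2d))/2 between loci at genetic distance d). Each F2
individual is the sum of two independent gametes; the phenotype is a
deterministic recessive function of the causal genotype — no phenocopies,
no misphenotyping, no missing genotypes. Real data violate all three in
small ways; consequences are discussed under Limitations.

The default genome is deliberately compact: 3 chromosomes × 30 Mb ×
1.2 Morgan with 1,500 evenly spaced SNPs each (one per 20 kb). This keeps
genome scans fast while preserving the two scales that matter — windows
much shorter than chromosomes, and marker spacing much tighter than the
linkage decay length. Physical size and SNP density enter the analysis
only through window occupancy, so a larger genome changes runtime, not
behaviour.

Bulk sequencing: bulk membership is the first 30 individuals of each
phenotype in population order (deterministic given the seed — no hidden
randomness); the bulk's allele frequency at a SNP is the exact mean of
its members' genotypes; read depth per SNP per pool is Poisson(30) by
default ("fixed" is available); the alternate-read count is binomial at
the bulk frequency. The long parent's allele is written as the reference
allele, so at the causal SNP the short bulk has index exactly 1. No
sequencing error, mapping bias or duplicate structure is modelled.

## Segregation tests (`segregation`)

Uncorrected Pearson chi-square with expected counts proportional to the
ratio weights, p from the chi-square survival function with df =
classes − 1. No Yates correction: the recorded family statistics
(0.110, 0.078, 0.069, 0.058, 0.200) are exactly the uncorrected values.
`test_standard_ratios` tries every standard ratio compatible with the
class count (3:1 and 1:1 for two classes, 1:2:1 for three) and reports
the largest-p fit.

## The delta-SNP-index scan (`bsaseq`)

- SNP index = alt/(ref+alt) per pool; zero-depth SNPs are missing and
  excluded from windows.
- Default filters: per-pool total depth ≥ 7 and max-pool index ≥ 0.3.
  Low-depth indices are too noisy to average, and a SNP matching the
  reference in both bulks carries no signal; both thresholds are
  configurable and reported per rule.
- Windows: 1-based, anchored at 1, [start, start + 1 Mb) advancing 10 kb,
  unweighted mean of member SNP indices (a depth-weighted mean is not
  implemented; with the depth filter in place weighting changes window
  means by far less than their sampling error). Δ = mean_L − mean_S, so
  with the short-parent allele as alternate the causal peak is negative:
  E[Δ] = 1/3 − 1 = −2/3 at the locus.
- Null model: two-stage binomial. A bulk of b plants drawn from an F2
  with no segregating locus has allele count k ~ Binomial(2b, ½); reads
  are Binomial(depth, k/2b). The Δ of two such independent pools is
  simulated 10,000 times per read depth and the empirical
  (1±conf)/2-quantiles are the bounds. Windows look up the bounds of the
  nearest simulated depth, using their mean per-SNP per-pool depth.
  Because the single-SNP Δ lives on a discrete lattice (multiples of
  1/depth), interpolated empirical quantiles sit slightly outside the
  nominal mass and realized coverage runs ≈0.5 percentage points above
  nominal; this conservatism is inherent to empirical quantiles on
  discrete statistics.
- Region calling: windows whose Δ escapes the bounds with a consistent
  sign over ≥ 3 consecutive windows are merged into maximal runs
  (min_consecutive = 3 suppresses single-window noise); each region
  reports its extreme-|Δ| window as the peak. Because adjacent windows
  share 99% of their SNPs, separate called runs can overlap genomically;
  they are reported as called, without post-merging.

Note the null bounds are per-window pointwise bounds: with ~9,000
windows genome-wide, isolated excursions are expected under the null,
and with 30-plant bulks the linkage signal around a real locus is broad
(the recessive excursion spans many megabases). The scan is a
localization tool, not a genome-wide-error-controlled test; the
fine-mapping stage is what sharpens the interval.

## Fine mapping (`finemap`)

Under the recessive model a marker co-locating with the trait must
satisfy short ⇒ B and long ⇒ A/H in every individual. A marker violated
by ≥ 1 individual lies across a crossover from the locus; the interval is
bounded by the nearest violated markers flanking the consistent stretch,
falling back to the outermost marker on a side with no violation (no
information beyond it). Violations are attributed to recombination only
— there is no phenotyping-error tolerance, so a single mis-scored plant
can mislocalize the interval on real data (see Limitations). Individuals
missing at a marker are excluded there, not imputed. The interval length
convention is end − start (the flanking coordinates 1,850,884 and
1,859,409 give 8,525 bp). CAPS digestion scans the forward strand only
(CAPS enzymes have palindromic sites), cutting at every occurrence of
the recognition sequence, overlapping ones included, on the uncut
coordinate frame.

## Indel effect (`seqeffect`)

Coordinates are 1-based inclusive on the CDS (a deletion "502–514"
removes 13 bases). Frameshift iff length mod 3 ≠ 0. Translation uses the
standard genetic code from position 1 to the first stop; a domain is
lost iff its last residue exceeds the mutant protein length, flagged
partial when the truncation falls inside it. Ambiguity codes are
rejected rather than guessed. The CDS fixture generator engineers a
reference/mutant pair by rejection-sampling the post-deletion codons
until the shifted frame stops at exactly the requested residue count
(default 173 of 399; cap 10,000 iterations), with one domain placed
upstream and one downstream of the truncation.

## Expression (`quantexpr`)

Livak 2^−ΔΔCT with amplification efficiency fixed at 2: replicates are
averaged on the Ct scale, ΔCt = target − reference per sample, ΔΔCt is
taken against the calibrator (whose fold is exactly 1), and replicate
spread propagates as sd(ΔCt) = √(sd_t² + sd_r²) into the band
2^−(ΔΔCt ± sd). With Ct noise of sd s and r replicates the estimator is
lognormal with mean inflated by exp((ln 2)²·4s²/2r) — about 1.3% at
s = 0.2, r = 3 — which the noisy-generator test accounts for.
Efficiency-corrected (Pfaffl) and multi-reference normalization are out
of scope. Reference gene and calibrator are required inputs.

## Validation experiments and their scope

The 40-seed recovery experiment (n = 400 F2, 30/30 bulks, Poisson(30)
depth, 10,000-rep CIs) checks that the called region contains the
planted locus and that the causal-SNP Δ matches −2/3 within Monte-Carlo
error. The window mean at the locus is attenuated toward zero by
recombination with SNPs up to half a window away (bias ≈ 5r̄/3 ≲ 0.02),
so the Mendelian comparison uses the causal SNP's own Δ; both statistics
are reported. Passing these experiments shows the pipeline's arithmetic
and calibration are right under its own assumptions; it does not show
robustness to sequencing error, reference bias, phenotyping error or
segregation distortion, none of which the generator produces.

## Numerical and convention details

- All randomness flows from one integer seed per operation; pipeline
  stages derive child seeds via `SeedSequence`, masked below 2³¹.
- Internal coordinates are 1-based closed everywhere; BED conversion
  (start − 1) happens only in the writer.
- Chi-square p-values are accurate to the survival function (checked to
  1e−6 against quadrature of the density).
- Degenerate inputs: zero-depth SNPs → missing; empty windows → NaN with
  n_snps = 0; empty marker list → phenotype-only table; empty region
  list → header-only BED.

## Known limitations

- Single fully-penetrant recessive locus only; no quantitative traits,
  no multi-locus models, no dominance series.
- No sequencing error or alignment artifact model; SNP filtering
  thresholds are therefore exercised only lightly by synthetic data.
- Fine mapping has no tolerance for phenotyping error.
- The null CI construction is per-SNP at a given depth, not conditioned
  on per-window SNP counts; window-level inference is therefore
  conservative in width but pointwise in multiplicity.
- The G′-type smoothed statistics used by some QTL-seq pipelines are not
  implemented; the scan is the plain window-mean Δ statistic.
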