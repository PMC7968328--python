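# Methods notes

## Model and assumptions

Endosperm is triploid (2 maternal : 1 paternal genome copies), so under
purely dosage-driven expression the maternal fraction of informative
reads at a gene is 2/3.  The pipeline treats each gene × library count
pair (m, p) as a draw whose expectation under the null is (2n/3, n/3)
and tests it with the Pearson goodness-of-fit statistic on one degree of
freedom, no continuity correction.  The statistic is sign-free, so the
chi-square upper tail is the two-sided p-value for deviation in either
direction; directionality enters only through the MEG/PEG ratio gates.
Assumptions inherited from the experimental design: parents are fully
homozygous inbred lines; diagnostic SNPs behave independently enough
that summing read counts over a gene's SNPs is a reasonable gene-level
tally (a read spanning k SNPs contributes k times — per-locus tallying,
a known mild pseudo-replication); the VCFs and alignments derive from
uniquely mapped reads (we re-enforce this with primary/MAPQ/NH filters
on the SAM path but trust the upstream caller for VCFs).

## Decision rules and their order

1. **Depth gate** — every library (2 crosses × 3 replicates) needs ≥ 10
   informative reads, else the gene is `insufficient` for that stage.
   Applying this before testing keeps the FDR denominator to genes that
   could in principle be called.
2. **Test** — chi-square per cross on within-cross pooled counts;
   combined p = max(p₁, p₂).  The maximum is the conservative
   combination matching the requirement that imprinting replicate in
   both reciprocal orientations (it is the p-value of the
   intersection-union test "deviates in both crosses").
3. **FDR** — Benjamini–Hochberg per stage over depth-passing genes.
   Whether the original analysis adjusted per cross, per stage or
   globally is not documented; per-stage is recorded in the output
   metadata as this package's choice.
4. **Ratio gates** — MEG: pooled m ≥ 10·p in *both* crosses; PEG:
   pooled p ≥ 1.5·m in both.  Gates are multiplicative on integer
   counts, so boundaries are exact and a zero denominator is harmless
   (m ≥ 10·0 holds, as it should when the paternal allele is silent).
   The 10:1 ratio equals maternal fraction 10/11 ≈ 90.9 %, which
   satisfies the looser "≥ 90 %" description sometimes used for MEGs;
   counts in the [90.0 %, 90.9 %) band fail the operative ratio rule.
5. **Replicate consistency** — maternal fraction > 2/3 (MEG) or
   paternal fraction > 1/3 (PEG) in every individual replicate of both
   crosses.  This is the per-replicate reading of "biased in three
   biological replicates": the test is run on pooled counts for power,
   while per-replicate direction guards against single-library
   artifacts.  Failures are reported separately in `reasons`.

For genes that end up `biallelic`, the `reasons` flags evaluate the gate
family (MEG vs PEG) matching the direction of the overall pooled bias,
since reporting both directions' failures would be noise.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's *design*: two homozygous lines
(default names ZS11/Y6), reciprocal crosses × 3 replicates × 2 stages
(20/25 DAP), ~19 chromosomes (10 A + 9 C), diagnostic SNPs inside
genes, triploid 2:1 dosage, MEGs at maternal fraction 0.98, PEGs at
paternal fraction 0.75 (comfortably above the 0.6 floor so power is
high at default depth), clustered placement of half the imprinted
genes, LTR/Copia-skewed TE enrichment in 5-kb flanks, and log-normal
tissue FPKM with an endosperm-specific subset.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `depth_mean` | 60 | informative reads per gene per library |
| `overdispersion` (rho) | 0.02 | beta-binomial intra-class correlation; 0 = binomial. No empirical estimate exists for this design; 0.02 is a plausible mild overdispersion, documented as a choice, not a fit |
| `frac_meg` / `frac_peg` | 0.05 / 0.005 | MEG:PEG imbalance mirrors the ~20:1 ratio seen in endosperm surveys |
| `meg_maternal_frac` / `peg_paternal_frac` | 0.98 / 0.75 | effect sizes |
| `stage_switch_frac` | 0.15 | fraction of imprinted genes imprinted in only one stage |
| `cluster_frac`, `cluster_size_range` | 0.5, (3, 5) | clustered share of imprinted genes and run lengths |
| `te_flank_boost` | 4 | TE placement rate multiplier in imprinted-gene flanks |
| `corrupt_frac` | 0.02 | sites damaged (depth 9 in one library, or one het replicate) to exercise the SNP screen |

Deliberately **not** simulated: raw reads, alignment error, mapping/
reference bias, genotyping error beyond the two corruption modes, DNA
methylation, and any correlation between imprinting and expression
level.  Passing tests therefore demonstrate correctness of the
statistical machinery and bookkeeping under the stated generative
model, not robustness to alignment artifacts in real data.

Determinism: every artifact is a pure function of `SimConfig`; RNG
streams are keyed per component (annotation, truth, variants, hybrid,
TE, expression) so adding draws to one stage does not shift another.
Parental VCF depths are floored at 10 reads so that, at corruption 0,
every simulated site passes the screen by construction.

## Numerical and convention choices

* Coordinates are 1-based inclusive everywhere (GFF3/VCF convention);
  BED is converted at the file boundary only.
* A SNP inside overlapping genes counts toward each gene (documented
  double-count contract), and interval ends are inclusive.
* "Homozygous in ≥ 2 replicates" is read conservatively: ≥ 2 concordant
  homozygous calls *and* no contradicting call (het or opposite
  homozygote) in any remaining replicate; missing calls are neutral.
  The ≥ 10-read rule uses DP per supporting library, not the AD sum.
* Sliding windows start at position 1 with 0.1-Mb steps; terminal
  windows are truncated at the last gene rather than dropped.  Window
  membership is by gene start coordinate, preventing double counting
  across merged windows.  Window enrichment is the hypergeometric upper
  tail against the whole placed-gene universe (the source analysis
  names only "p < 0.05"); discreteness makes the scan conservative
  (measured null significant-window rate ≈ 3 % at α = 5 %).
* TE enrichment tests gene-level presence/absence in a 2×2 chi-square
  without continuity correction; normalized counts are raw TE hits per
  100 genes per group.  A TE overlapping a flank by any amount counts.
* Expression comparisons use Welch's t on log2(FPKM + 1); fold-change
  screening uses pseudocount 0.01, so a 0/0 gene has log2FC = 0.
* BH q-values are computed by the standard step-up rule and verified
  against statsmodels in the tests.

## Problem sizes used in validation

Recovery and calibration experiments run at: 5,000 biallelic + 500 MEG
+ 50 PEG genes, depth 60, rho 0, one stage, one SNP per gene, 10 seeds
(measured: 100 % MEG and PEG sensitivity, 0 false discoveries); null
window calibration with 1,000 genes on one 20-Mb chromosome, 50
randomly placed imprinted genes, 200 replicates; TE null calibration
with 200 seeds of a reduced two-chromosome genome.  These sizes are the
package's own validation choices and are deliberately smaller than a
full transcriptome while keeping every rate estimate's Monte-Carlo
error well below the margins being checked.

## Known limitations

* Pooling counts within a cross before testing discards between-
  replicate variance; the per-replicate direction gate only partially
  compensates.  A beta-binomial likelihood-ratio test would model this
  properly but is outside the scope of the implemented method.
* Per-locus read tallying double-counts reads spanning several SNPs.
* The hypergeometric window test treats genes as exchangeable across
  the genome; regional gene-density differences are only partially
  absorbed by conditioning on the window's total gene count.
* Homolog pairing relies on a user-supplied pair table; no orthology
  inference is performed.
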