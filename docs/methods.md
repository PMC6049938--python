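# Methods

## Problem and model

The pipeline asks, genome-wide, whether genes whose nascent transcription
drops in a mutant lacking the cytoplasmic 5'-3' exoribonuclease (which
stabilizes a class of antisense lncRNAs, the XUTs) are enriched for an
antisense XUT partner. It consumes strand-specific nascent-transcription
read positions (NET-Seq), a feature annotation distinguishing mRNAs and
XUTs, and a two-condition, two-replicate design, and produces:

1. a per-gene differential call (attenuated or not),
2. an antisense pairing (gene has >= 1 opposite-strand overlapping XUT),
3. the 2x2 classification into classes 1-4 and a chi-square independence
   test with the share of attenuated genes that carry an asXUT,
4. TSS-anchored metagene profiles (nascent signal per strand; H4ac/H3
   ChIP ratios) and per-feature mutant/WT signal-ratio densities.

## Differential test

Counts per gene (sense-strand tags within the annotated interval) are
modeled as NB with variance mu + alpha mu^2.

* **Size factors** — median-of-ratios: factor_j = median over features of
  count_fj / geometric-mean_f, over features positive in all samples.
  The estimator assumes most features are unchanged. In the pipeline the
  factors are computed on the *full* quantified feature set (mRNAs plus
  XUTs, whose nascent synthesis is expected unchanged) and only mRNAs
  are tested; with a large attenuated fraction this anchors the median
  on unchanged features. A residual composition bias remains when the
  attenuated fraction is large (see Limitations).
* **Dispersion** — per-feature method of moments on normalized counts
  within each condition, alpha_c = max(0, (s^2 - xi*mu)/mu^2) with
  xi = mean(1/s_j) removing depth-dependent shot noise, averaged across
  conditions; a gamma-family regression of these estimates on the base
  mean (alpha(mu) = a0 + a1/mu) provides a trend, and the final value is
  the per-feature **maximum** of raw and trend estimates. The maximum
  rule is deliberately conservative for 2 vs 2 designs, where raw
  moment estimates have one degree of freedom each.
* **Wald test** — two-sided on ln(mu_mut) - ln(mu_wt) with the delta
  method and Var(normalized count) = q/s_j + alpha q^2. A condition mean
  of zero is floored at 0.5 normalized counts inside the statistic; the
  reported log2 fold-change applies a 0.5 pseudocount only when one
  condition mean is zero. Features with no counts in either condition
  are flagged untestable and excluded from testing and from the class
  partition.
* **Multiple testing** — Benjamini-Hochberg step-up with monotonicity
  enforcement; attenuation = adjusted p < alpha (default 0.05) AND
  log2FC < 0. Raw-p thresholding is available as an option and both
  p-values are always reported.

Measured calibration (see the test suite): on null NB data (2 vs 2, mean
200, dispersion 0.05, 2000 features) the raw-p false-positive fraction
at 0.05, pooled over three simulations, is ~0.03-0.04 — slightly
conservative, as intended by the maximum-sharing rule.

## Pairing and classification

A gene has an asXUT iff some XUT on the same chromosome and opposite
strand overlaps its annotated interval by >= `min_overlap` nt (default 1,
the most permissive reading; the threshold is exposed for sensitivity
analyses, including TSS-region-restricted variants). Pairing is
many-to-many. Classes: 1 = attenuated with asXUT, 2 = attenuated
without, 3 = unchanged with, 4 = unchanged without; the four classes
partition the tested genes. Independence of the two labels is tested by
Pearson chi-square on the 2x2 table (df = 1, expected cells =
row x column / total, upper-tail p). No Yates correction by default —
class counts in the intended regime are in the hundreds, where the
correction is negligible; a flag enables it. The summary proportion is
class1 / (class1 + class2) as a percentage to one decimal (undefined and
reported as such when no gene is attenuated).

## Metagenes and densities

Profiles aggregate log2(signal + epsilon) over TSS +/- W (default
W = 1000 nt, epsilon = 1 normalized tag) across genes, with minus-strand
windows coordinate-reversed so +x is always downstream. The 95%
confidence band is the normal-approximation SEM across genes
(1.96 * sd / sqrt(n)); genes whose window crosses a chromosome edge are
kept with per-position n tracking (positions with n < 2 report a missing
CI). ChIP ratio profiles sum both strands per position before
log2((IP + eps)/(H3 + eps)). Ratio densities use per-feature mean tag/nt
with a pseudocount on both terms and a Gaussian KDE (Scott bandwidth)
evaluated on a grid spanning the data +/- 4 bandwidths, so the density
integrates to 1 up to quadrature error; a degenerate (zero-spread)
sample is represented as a narrow Gaussian. Box statistics use type-7
(linear-interpolation) quantiles and Tukey whiskers at 1.5 IQR.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale. Defaults (chosen once):

| parameter | default | rationale |
|---|---|---|
| genes per class | 150 each | enough for stable class counts, fast |
| WT means (classes 1-4) | 2000, 1500, 100, 400 tags | class 1 highly expressed, 20:1 over class 3; class 2 high (growth-linked genes), class 4 mid |
| attenuation fold (classes 1-2) | 3x | comfortable desk-scale recovery |
| NB dispersion | 0.05 | typical for good biological duplicates |
| replicates | 2 vs 2 | the study design |
| library multipliers | 1.0, 1.2, 0.9, 1.1 | exercise size factors |
| gene lengths | U(1000, 2000) nt | yeast-like |
| XUT geometry | opposite strand, 50% overlap, spans the gene TSS + 200 nt upstream | TSS-proximal antisense signal |
| XUT nascent mean | 150 tags, equal in both conditions | lncRNA synthesis unchanged |
| XUT RNA stabilization | 4x in the mutant (RNA modality only) | stabilization, not transcription |
| H3 level / NDR depth | 20 per nt; depths 0.8, 0.6, 0.5, 0.4 (sigma 100 nt) | promoter nucleosome depletion, deepest for class 1 |
| H4ac enhancement (WT) | 4.0, 4.0, 1.5, 1.2 (sigma 150 nt) | TSS-proximal acetylation similar for classes 1-2 |
| H4ac enhancement (mutant) | class 1 reduced to 1.5 | acetylation loss at attenuated asXUT genes |

Counts are NB(mean x condition factor x library multiplier, alpha), tags
scattered uniformly along features (a 5'-peaked option exists, off by
default); ChIP tracks are per-nucleotide Poisson around the parametric
promoter shapes, stored unstranded. All randomness derives from the
config seed through named substreams; identical (seed, config) gives
byte-identical files.

**Independence (null-calibration) mode** assigns the attenuated subset
*and* each gene's expression level at random, independent of asXUT
presence. Randomizing only attenuation is not enough: with class-linked
expression levels, detection power would still differ between asXUT
groups and the chi-square p could not be uniform. In this mode the
pipeline's enrichment p is uniform across simulations (KS test over 200
seeds).

Note the default balanced design (equal class sizes) itself encodes
independence of the two labels — it is the null-structure dataset. A
genuinely enrichment-bearing dataset needs unbalanced classes (e.g.
150/150/50/250, giving 50% vs 17% asXUT share), as used in the
reproduction script.

## Problem sizes

Validation runs use: 600 genes + 300 XUTs per simulated study; three
simulations for recovery and calibration checks; 200 simulations
(counts-level, no per-nucleotide coverage) for the null-uniformity
check; 2000 features x 3 simulations for type-I calibration; 10^4-2x10^4
shuffles for the permutation oracle of the chi-square test.

## What the synthetic data does not capture

Real NET-Seq has positional structure (promoter-proximal pausing,
termination peaks), mappability gaps, overlapping and nested genes,
varying per-gene dispersions, and an annotation-dependent tested-gene
universe; the generator has none of these, so passing tests demonstrate
the statistical machinery is correct under the stated model, not that
the biological conclusions transfer to arbitrary real data. The
genome-wide published numbers (723 attenuated genes, 175 class-1 genes,
chi-square P = 0.03) depend on the deposited sequencing data and the
external XUT annotation and are not reproduced at desk scale; the one
printed quantity that is exactly reproducible from the class sizes —
the 24.2% asXUT share among attenuated genes — is recomputed by the
reproduction script.

## Known limitations and numerical choices

* Median-of-ratios assumes most features unchanged. With the synthetic
  default (a third of features attenuated), a residual composition bias
  of ~+0.3 log2 units remains on unchanged features even with XUT-row
  anchoring; reported fold-changes are correspondingly compressed. In
  the intended regime (~14% attenuated) the bias is negligible.
* The chi-square p uses the continuous df=1 tail; against the exact
  discrete conditional null it deviates by up to ~0.03 at mid-range p
  for n ~ 200 (it approximates the mid-p). Use the permutation or an
  exact test for small tables — the code refuses tables with a zero
  expected cell.
* The Wald test uses normal quantiles with plug-in dispersions; with two
  replicates per condition this is only calibrated in combination with
  the conservative maximum-sharing dispersion rule (measured above).
* NET-Seq read polarity defaults to the 3' end of the nascent transcript
  (the polymerase position); 5'-end and full-read modes are switchable,
  and all results in the synthetic validation are mode-agnostic because
  tags are scattered uniformly.
* Cross-condition coverage comparisons (ratio densities, WT-vs-mutant
  metagenes) scale samples by their size factors, not by raw library
  size, to avoid composition bias.
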