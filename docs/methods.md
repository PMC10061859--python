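# Methods

## Scientific setting

Promoter CpG islands (CGIs) in embryonic stem cells fall into three broad
chromatin states when profiled for H3K4me1, H3K4me3 and H3K27me3:

* **low** — little of any mark, DNA-hypermethylated, silent genes;
* **bivalent / trivalent** — high H3K4me3 and H3K27me3, with H3K4me1
  additionally elevated *over the CGI body* (an "untypical" unimodal
  profile). These genes are poised and tissue-restricted;
* **active** — high H3K4me3, no H3K27me3, and the typical bimodal H3K4me1
  profile: high at the 1 kb shores flanking the CGI, low over the body.

Upon differentiation or PRC2/LSD1 perturbation, bivalent promoters lose
H3K27me3, and this loss is accompanied by a change in the H3K4me1 promoter
pattern: either the shore shoulders collapse (**bimodal loss, biloss**) or
they appear (**bimodal gain, bigain**). The two groups behave differently
transcriptionally, and the histone deltas at promoters and nearest
enhancers predict which genes become tissue-specific. This package
implements that analysis chain as a reusable, tested pipeline, exercised
end-to-end on a synthetic genome in which every label is planted and
therefore checkable.

## Pipeline stages

1. **Promoter CGIs** (`intervals`). A promoter CGI is a CGI of 200–5000 bp
   with ≥ 1 bp overlap with a TSS ± 1 kb window (`[tss − 1000, tss + 1000)`,
   BED coordinates). It is linked to the gene whose TSS is nearest the CGI
   midpoint; exact midpoint ties break by lexicographic gene id. Enhancers
   are H3K4me1 peaks whose midpoint lies > 5 kb from every TSS; each gene
   keeps its nearest surviving peak (ties go to the leftmost). Distances
   are midpoint-to-TSS: the shared midpoint convention keeps the distal
   filter and the nearest-assignment symmetric. Strand is ignored for CGI
   geometry — shores are genomic left/right, so strand-flipping would swap
   shore identity for minus-strand genes; none of the downstream statistics
   distinguish left from right, so this has no effect here.

2. **Signal matrices** (`signal`). Each promoter row is 20 bins over the
   left shore (1 kb, 50 bp bins), 20 bins over the CGI body rescaled by
   exact fractional-basepair averaging, and 20 bins over the right shore.
   Bin values are mean input-adjusted coverage; negatives are clamped to 0,
   missing spans count as 0, shores running off a contig are zero-filled
   and logged. Bin counts are configurable; 20/20 resolves the shore
   shoulder (which peaks ~500 bp from the CGI edge) while keeping matrices
   small. The bin statistic is the mean, asserted exact against a
   bp-resolution oracle; no smoothing is applied.

3. **Three-class partition** (`partition`). Features are the per-mark
   matrices, winsorized at the matrix-wide 99th percentile and
   column-standardized per mark (so no high-amplitude mark dominates the
   Euclidean metric), concatenated, and clustered with k-means (k = 3,
   k-means++ seeding, 10 restarts, fixed seed; best inertia wins).
   Cluster roles are assigned by signal, not index: *bivalent* = highest
   mean H3K27me3 body signal, *active* = higher mean H3K4me3 of the rest,
   *low* = remainder; ties beyond 1e-9 are refused rather than broken
   arbitrarily. Overlap between two partitions (e.g. the three-mark
   "trivalent" definition vs the H3K4me3+H3K27me3 "traditional" one) is
   reported per matched role as |A∩B|/|A| and |A∩B|/|B| plus the full 3×3
   contingency — the form of the published 94%/73% statistic. Roles, not a
   Hungarian count matching, align the clusters, because the comparison of
   interest is between *bivalent* definitions.

4. **H3K4me1 patterns and transitions** (`patterns`). Per condition, two
   one-dimensional 2-means clusterings — body means and shore means — are
   each labelled high/low by cluster mean. The 2×2 combination maps to
   three patterns: body high → untypical_unimodal (body elevation defines
   the trivalent state, whatever the shores do); body low + shores high →
   typical_bimodal; both low → flat. Between paired conditions, H3K27me3
   loss is a body-mean drop of at least the loss threshold — by default
   half the condition-1 bivalent-cluster median body H3K27me3, an explicit
   numeric stand-in for what is a visual heatmap judgement in practice.
   A shore-level flip high→low is biloss, low→high is bigain; the
   transition flag requires loss AND a flip. Patterns are classified per
   condition and differenced (rather than clustering WT and KO rows
   jointly), which keeps each condition's call self-contained.

5. **Expression** (`expression`). Tau is the Yanai specificity index,
   tau = Σ(1 − x_i/max x)/(N − 1), computed on log2(x+1)-transformed
   medians by default (the transform is a flag). Tissue-specific genes
   must (1) have the tissue within their top-5 expression ranks
   (competition ranking; ties share the best rank, so the criterion is
   permissive under ties) and (2) exceed the within-tissue 90th percentile
   of all genes' expression, strictly. The percentile is taken over all
   genes, not expressed genes only. DE tables are filtered at
   |log2FC| ≥ cut and p ≤ cut, both inclusive; the headline thresholds are
   (2, 0.05) for tissue contrasts and (1.2, 0.1) for the KO contrast.
   Group contrasts (biloss vs bigain log2FC) use the two-sided Wilcoxon
   rank-sum test and an uncorrected 2×2 chi-square of up/down × group;
   raw p-values are reported, no multiplicity correction, since each
   contrast is a single headline test. The chi-square is undefined (NaN)
   when a table margin is empty — at the default planted effects
   (biloss ≈ N(0.5, 0.3)) almost nothing is called "down", so this occurs
   by design rather than error.

6. **Association** (`association`). For a focal tissue, one row per gene
   with both a promoter CGI and an assigned enhancer: outcome = membership
   in that tissue's specific set; predictors = tissue-minus-ESC deltas of
   the three promoter marks (body means) and the two enhancer marks
   (H3K4me1, H3K27ac). Predictors are standardized and the scaling
   recorded, so forest-plot odds ratios are comparable across marks and
   raw-scale coefficients recoverable. The fit is unpenalized
   maximum-likelihood logistic regression (Newton scoring); Wald 95% CIs
   are coef ± 1.96·SE exponentiated to the OR scale. Perfect or
   quasi-separation is raised as an error naming the most suspect
   predictor, never silently regularized. One model is fit per focal
   tissue.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions for every property check.

**Geometry.** Non-overlapping slots along toy chromosomes, one promoter
each: a CGI (length uniform in 400–1200 bp by default, within the
admissible 200–5000 bp), its TSS inside the island (midpoint ± length/4
jitter), 1 kb shores, and one 800 bp enhancer centred 6 kb downstream of
the TSS — beyond the 5 kb distal cut-off yet closer to its own TSS than to
any neighbour's, so nearest-enhancer assignment recovers the planted
pairing exactly. Gene↔promoter is 1:1 (real genomes are many:many; the
linking rules are exercised separately on irregular fixtures). Infeasible
packings raise a sizing error naming the required chromosome length.

**Signal shapes.** Coverage = a flat plateau at the class/mark body
amplitude across the CGI, Gaussian shoulders peaking mid-shore (500 bp from
the edge, sd 200 bp) at the shore amplitude, baseline 0.5 elsewhere.
Default amplitudes (body/shore): low 0.5/0.5 for all marks; bivalent
H3K4me1 10/–, H3K4me3 10/4, H3K27me3 10/6; active H3K4me1 2/10, H3K4me3
14/6, H3K27me3 at baseline. Bivalent H3K4me1 shores are 8 (high) or 2
(low): biloss promoters start high and drop in the perturbed condition,
bigain promoters start low and rise; other bivalent promoters stay low.
In the perturbed (KO) condition every bivalent promoter's H3K27me3 falls
to baseline, emulating complete PRC2 loss. Enhancer H3K4me1/H3K27ac are
plateaus (8 baseline; 9.5/11 in the perturbed condition at enhancers of
tissue-specific genes) with per-gene, per-condition Gaussian amplitude
jitter (sd 1.5) so induced and basal enhancer activity overlap like real
loci instead of separating perfectly — without it the logistic fit is
degenerate by construction.

**Noise.** Per-basepair negative binomial around the shape
(mean = shape × depth scale, size r = 10, so variance = μ + μ²/10),
chosen because ChIP coverage is over-dispersed relative to Poisson. The
real tracks' noise law is unknown; NB is a stand-in, not a claim about the
data. `dispersion: null` gives the exact noiseless limit used by the
oracle tests. All streams are seeded per (seed, mark, condition), making
every output byte-deterministic.

**Expression.** Class-constant levels (active 50, bivalent 5, low 0.5,
TPM-like); bivalent background genes are expressed in only 2 of the
tissues (poised genes are tissue-restricted, which gives the class its
high Tau); planted specific genes (15 per tissue by default, drawn from
the bivalent class first) get 1000 in the target tissue and 0.1 elsewhere.
This noiseless construction makes both selection criteria hold exactly.
With multiplicative noise enabled (`expression_noise_sd > 0`) the planted
genes still satisfy both criteria, but the top expression decile of
uniformly-expressed genes then also crosses the strict 90th-percentile
cut — an inherent property of the percentile rule at few tissues, not an
implementation artifact; recovery is then approximate rather than exact.
The KO DE table draws log2FC per transition group — biloss N(0.5, 0.3),
bigain N(2.0, 0.3), background N(0, 0.2) — with p = 1e-6 for transition
genes and uniform null p-values otherwise.

**What passing does and does not show.** The generator plants cleanly
separated classes with homogeneous within-class shapes, independent
noise, 1:1 gene–promoter–enhancer wiring, and no replicate structure,
mappability artifacts, copy-number effects or input-normalization error.
Recovery of planted truth certifies that the estimators implement their
definitions and are calibrated under their own assumptions; it does not
certify performance on real tracks, where class boundaries are graded and
the noise is structured.

## Problem sizes and numerical choices

* Default study conditions: 600 promoters, 2 chromosomes, classes in equal
  thirds, 25%/25% of bivalent promoters planted biloss/bigain, 6 tissues.
* Large-scale checks: the three-class recovery runs 20 replicates of a
  3,000-promoter genome (ARI ≥ 0.9 at default noise, = 1 noiseless) and
  pattern/transition recovery runs 5 replicates of an 1,800-promoter
  genome with 200 planted promoters per transition group; both use the
  enhancer-free layout, which changes intergenic spacing only.
* Logistic calibration: 200 replicates at n = 2,000 for parameter recovery
  (|bias| ≤ 0.1, pooled 95% CI coverage within [0.92, 0.98] over the
  1,000 intervals) and 200 null replicates for the 5% ± 2% type-I check.
  Pooling the coverage across the five coefficients keeps the band's
  Monte-Carlo noise (~0.7%) well inside its width; per-coefficient
  coverage at 200 replicates fluctuates ± 1.5%.
* Binning is exact (fractional-bp integral), so matrix oracles use 1e-9
  tolerances; tau uses 1e-12 against the direct formula; the 2×2 logistic
  check uses 1e-8 against the closed-form log odds ratio.
* k-means determinism: fixed seed, 10 restarts, lowest inertia; both
  1-D pattern clusterings refuse constant inputs instead of returning an
  arbitrary split.

## Known limitations

* Shores are genomic, not transcription-oriented (see stage 1).
* The loss threshold is a explicit numeric rule standing in for a visual
  heatmap criterion; sensitivity to it can be probed via the config.
* With few tissues the top-5 rank criterion is weak, and the percentile
  criterion alone drives selection; the rule only becomes selective at
  GTEx-scale tissue panels.
* The per-tissue logistic model needs enough positive genes per tissue to
  be well-posed; with a handful of positives quasi-separation is expected
  and surfaced as an error.
* DESeq2-style DE fitting, peak calling, read simulation and enrichment
  analyses are out of scope; DE tables and peak calls are inputs.
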