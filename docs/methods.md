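# Methods

## Scope and data model

`lnclink` implements the analysis chain of a two-condition (control vs
case) bulk RNA-seq comparison of lncRNAs and mRNAs with very few
replicates (default 3 + 3), followed by lncRNA target inference and
validation. Internally all genomic coordinates are 0-based half-open;
GTF input (1-based closed) is converted on read and back on write, so a
single convention governs the 10-kb cis rule. Sequences are held in DNA
letters; RNA `U` is mapped to `T` once at input. Gene length for RPKM is
the summed exon length (`exon_length_bp`), not the genomic span.

## Quantification

RPKM[g, j] = count[g, j] / (mapped_reads_millions[j] × exon_length_bp[g]/1000).
Mapped totals come from the sample table when supplied and otherwise
default to column sums / 10⁶ (mapping totals are often unavailable in
published tables). Downstream correlation and clustering work on
log₂(RPKM + 1).

## Differential expression

The count model is negative binomial with mean μ and dispersion α,
Var = μ + αμ².

* **Size factors** are DESeq-style median-of-ratios over genes with
  positive counts in every sample, rescaled to geometric mean 1. A
  dataset without any such gene raises an error suggesting a pseudocount.
* **Dispersion** is estimated per gene by method of moments on
  within-condition normalized counts, α̂ = max(0, (v − m)/m²), averaged
  across the two conditions; all-zero genes receive the global fallback
  (median of the positive α̂).
* **Moderation.** The Wald test uses max(α̂_g, global median of positive
  α̂). With three replicates per group the raw moment estimator is
  extremely noisy and frequently zero, which makes the naive Wald test
  anti-conservative (empirical null rejection ≈ 0.12 at nominal 0.05 in
  our simulations); flooring at the global median restores near-nominal
  behaviour (≈ 0.05) while leaving genuinely overdispersed genes
  conservative. This is the same spirit as the conservative
  "maximum of gene-wise and fitted" rule of early DESeq.
* **Test.** log₂FC = log₂((x̄_case + c)/(x̄_control + c)) with pseudocount
  c = 0.5 to keep fold changes finite at zero counts. The standard error
  comes from the delta method on the NB variance of each group mean,
  Var(x̄) = n⁻² Σⱼ (μ/sⱼ + αμ²), and z = log₂FC/SE is referred to a
  standard normal, two-sided. A closed-form Wald test was chosen over an
  exact NB test for transparency and testability; its calibration is
  checked by simulation rather than assumed.
* **Selection.** Significant ⇔ |log₂FC| > 1 and BH-adjusted p < 0.05,
  both inequalities strict ("fold change > 2", "padj < 0.05"). "Fold
  change > 2" is applied symmetrically in both directions.

Hierarchical clustering of samples or genes uses average linkage on
d = 1 − Pearson r of log₂(x + 1); ties are broken by lexicographic item
id so the dendrogram is deterministic, and zero-variance profiles are
assigned r = 0 (d = 1) with a logged warning.

## Target prediction

* **cis.** Distance is the gap between gene spans (overlap ⇒ 0),
  strand-agnostic; a pair is reported when the gap is strictly below
  10 kb. A TSS–TSS metric is available behind `metric="tss"` for users
  who prefer promoter-centric distances.
* **trans.** "Sequence match" is realized as the best Smith–Waterman
  local alignment between the lncRNA and the reverse complement of the
  mRNA (equivalently: scoring antiparallel base pairing), match +2,
  mismatch −3, linear gap −5, all configurable. The alignment engine is
  Biopython's `PairwiseAligner`; tests verify it against an independent
  exhaustive recursion on short sequences.
* **Duplex energy.** G = Σ per-column energies: G:C −3, A:U −2, G:U
  wobble −1 (wobble on by default), +1 per mismatch or gap column. This
  additive model follows the unlabeled energy scale of the inclusion
  rule G < −20; it is not a nearest-neighbour thermodynamic ΔG°₃₇ and
  should not be compared against one.
* **E-values.** Local alignment scores of shuffled sequence pairs follow
  a Gumbel law; a maximum-likelihood Gumbel fit (location μ̂, scale β̂) on
  ≥ 500 shuffled-pair scores gives λ = 1/β̂ and K = e^(λμ̂)/(m·n), so
  e(S) = K·m·n·e^(−λS) estimates the expected number of chance hits at
  score ≥ S. Calibration is seeded (default 1729) and reproducible.
* **Retention rule.** e < 1e−5 and G < −20, both strict; hits are sorted
  by ascending e and re-checked against both thresholds on output.

## Integration

Predicted targets are intersected with the significantly DE mRNAs before
enrichment and network construction. The co-expression network tests only
the predicted lncRNA→target connections (not all pairs), keeping an edge
when signed Pearson r of log₂(RPKM+1) across all samples exceeds the
threshold (default 0.95, strict); `absolute=True` switches to |r| for
users who read the inclusion rule as magnitude. Node attributes record
molecule kind and DE direction (the red/green up/down convention of
co-expression figures); networks are exported as SIF (+ attribute
sidecar) and GraphML rather than rendered.

Enrichment is a one-sided hypergeometric over-representation test per
gene set, computed exactly in log space via the survival function, with
BH adjustment across sets, set-size bounds [3, 2000], and a default
universe of all annotated genes with nonzero counts. This is a local
stand-in for web-service GO/KEGG/chemicals analyses: the plain
hypergeometric, not DAVID's EASE-adjusted variant, and no GO-DAG
propagation.

Cross-species comparison maps mouse target genes through a many-to-one
ortholog table and intersects with a human DE list; unmapped mouse ids
are reported, never dropped silently.

## qPCR

ΔCt = Ct_target − Ct_reference per sample (technical replicates averaged
first); ΔΔCt = mean ΔCt(case) − mean ΔCt(control); fold change = 2^−ΔΔCt.
Group-mean ΔΔCt was chosen as the primary estimate; per-sample
2^−(ΔCt − mean control ΔCt) values are also emitted for bar-graph-style
summaries since conventions differ between labs. Groups are compared by
classical one-way ANOVA (for two groups F = t² exactly), and agreement
with sequencing is summarized by OLS of qPCR log₂FC on RNA-seq log₂FC.

## Synthetic data generator

The generator emulates the study conditions end to end and records a
ground-truth sidecar:

* **Design.** 3 control + 3 case samples; 60 lncRNAs + 120 mRNAs by
  default (large enough for stable FDR behaviour while keeping the
  all-pairs trans alignment fast on one CPU); per-sample size factors
  log-uniform on [0.5, 2]; per-gene base means log-uniform on [50, 2000];
  NB dispersion α = 0.1 — a typical bulk-RNA-seq biological
  overdispersion for a small animal cohort.
* **DE genes.** 25% of genes are planted DE at |log₂FC| = 2 with random
  direction.
* **cis pairs.** Planted pairs are placed adjacently with a gap drawn
  uniformly from [0, 9999] bp; all other neighbouring genes are separated
  by ≥ 25 kb (> 2× the 10-kb rule), so the planted pairs are exactly the
  ground-truth positives of the cis rule.
* **trans pairs.** Each planted trans lncRNA carries the exact reverse
  complement of a 30-nt segment of its partner mRNA inside otherwise
  i.i.d. uniform ACGT sequence (lncRNA 300 nt, mRNA 500 nt). A perfect
  30-mer scores S = 60, far above the chance-score regime of these
  sequence lengths, so the E-value filter separates cleanly. Optional
  decoy pairs with short (12-nt) complements can be planted to probe
  specificity; they are off by default.
* **Correlation blocks.** Block members (non-DE genes at high base mean,
  default 5 × 10⁴) share a lognormal latent factor on the count mean. The
  log₂-scale loading τ is solved self-consistently from
  r = τ²/(τ² + v(τ)), where the per-gene noise v(τ) includes the
  lognormal inflation of E[1/μ] when the factor swings low; realized
  pairwise Pearson r on log₂ expression then tracks `corr_target`
  (mean ≈ 0.989 at target 0.99 over 30 simulations). Block genes are
  deliberately non-DE: at α = 0.1 and n = 6, a pair cannot
  simultaneously carry enough shared variance for r > 0.95 and little
  enough within-group variance for its own DE call — the two planted
  structures are therefore carried by different genes.
* **Anchor pair.** One lncRNA–mRNA pair is planted to survive every
  stage: both genes DE in the same direction, placed in cis, given a
  trans complement, and drawn with a shared Gaussian copula on the NB
  noise (ρ = 0.995) so their expression correlation clears r > 0.95
  robustly without distorting either gene's NB marginal or DE effect.
  Its mRNA's ortholog is always included in the synthetic human DE list.
* **qPCR plates.** Reference Ct constant (15 cycles) + N(0, 0.15²)
  noise; target Ct = baseline − log₂(fold change) for case samples, so a
  noise-free plate reproduces the planted fold change exactly.
* **Seeding.** One RNG stream per artifact (genome, counts, qPCR) is
  spawned from the master seed, so artifacts can be regenerated
  independently and byte-identically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artifacts (GC/length bias, mapping
ambiguity), mRNA splice structure (genes are single-exon), realistic
mean–dispersion trends (α is constant), compositional library effects,
batch effects, and any real ortholog or gene-set structure. Recovery
rates on this generator certify the pipeline's correctness, not its
field performance.

## Problem sizes and numerical choices

The test-suite and reproducibility-script simulations use the default
180-gene dataset (20 seeds for recovery averages), a 5,000-gene null for
type-I calibration, and 40 × 40 random enrichment queries on a 2,000-gene
universe with 150–300-member sets (large sets keep the discrete
hypergeometric p-values near-uniform under the null). padj values are
clipped at 1e−300 before −log₁₀ for volcano coordinates. All
floating-point table output uses `%.6g`, which makes repeated runs
byte-identical.

## Known limitations

* The Wald test's normal reference is approximate at n = 3 + 3; its
  calibration is verified empirically under the generator's null, not
  guaranteed analytically.
* The duplex energy scale is model-internal; the −20 threshold is only
  meaningful relative to the pair energies above.
* Gumbel calibration assumes the shuffled-score distribution is in the
  local-alignment extreme-value regime; very short or highly biased
  sequences would need a recalibration.
* With six samples, an r > 0.95 filter has high sampling variance: even a
  true r = 0.99 pair falls below 0.95 in a few percent of datasets. This
  is a property of the published inclusion rule at this sample size, not
  of the implementation.
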