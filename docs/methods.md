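# Methods

## Generative model

The simulator emulates a yeast decapping-activator deletion panel — WT,
*scd6Δ*, *edc3Δ*, *scd6Δedc3Δ* — assayed by RNA-seq, ribosome profiling
(RPF), CAGE, framed 5′P degradome sequencing and Pol II ChIP.

**Steady state.** Each gene has a synthesis rate `s` (lognormal, median 10,
σ=1 on the log scale) and a baseline decay rate `k₀` (lognormal, median
0.2, σ=0.5). Abundance is `s / k`, where the operative decay rate `k`
depends on genotype through the gene's targeting class:

| class | decapping active when | panel behaviour |
|---|---|---|
| `untargeted` | never | constant abundance |
| `redundant_s6e3` | Scd6 **or** Edc3 present | up only in the double mutant |
| `edc3_exclusive` | Edc3 present | up in *edc3Δ* and the double |
| `dhh1_pat1_like`, `concerted` | always (their loss needs *dhh1/pat1* genotypes outside this panel) | constant within the panel |

Active decapping multiplies decay by `decay_effect` (uniform on [3, 6] by
default) and divides translational efficiency by `te_effect` (uniform on
[1.8, 4]). Default class proportions: 70% untargeted, 12% redundant, 4%
Edc3-exclusive, 9% Dhh1/Pat1-type, 5% concerted — chosen so the called
double-mutant up-set is roughly a tenth of the transcriptome, the scale
seen in decapping-mutant transcriptomes. Two replicates per genotype and
2×10⁶ reads per sample per assay are the default study design.

**Assay expectations.** RNA ∝ abundance; RPF ∝ abundance × TE; CAGE ∝
abundance × capped fraction; 5′P ∝ abundance × (1 − capped fraction +
0.05); Pol II ∝ synthesis only. The capped fraction is drawn per gene and
genotype: U(0.30, 0.60) while decapping is active, U(0.75, 0.95) when
repression is relieved or the gene is untargeted. 5′P totals are split
into the three codon frames with protected-frame probability
`(1 + 2p)/3`, where `p ∈ [0,1]` is the gene's periodicity parameter
(p = 0 gives uniform frames).

**ESR co-regulation.** A configurable fraction (default 10%) of
untargeted genes is labelled iESR or rESR and receives a common log₂
shift (default ±1.0 in the double mutant) scaled by genotype severity
(0 in WT, 0.25 in singles, 1 in the double). The magnitude of this
indirect stress signature is a free parameter of the generator, not an
estimate of the real effect; it exists so that ESR filtering and ESR
signature scoring have something to detect.

**Counts and spike-ins.** Counts are negative binomial with gene-wise
dispersion `dispersion_base` (default 0.05; variance μ + αμ²; Poisson
when α=0). Each sample's read budget (depth × lognormal jitter, σ=0.1) is
split between genes and spikes in proportion to cellular content: a fixed
absolute spike amount (5% of the WT signal) competes with a
genotype-dependent total mRNA pool, so global mRNA-per-cell shifts are
encoded in spike recovery exactly as in an ERCC or heterologous-chromatin
experiment. Spike species carry only technical noise (dispersion 0.005,
lognormal abundance profile σ=1): exogenous standards have no biological
replicate variance, and giving them gene-level dispersion would make
total-recovery normalization far noisier than its real-data counterpart.
The true per-sample reads-per-cellular-unit factors are stored so tests
can assert normalization recovery. Randomness uses a master seed with
named substreams per assay, so the whole dataset is byte-reproducible and
one assay's draws are insensitive to changes in another's parameters.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: positional coverage, UMIs, mappability and GC
bias, batch effects, outlier replicates, mean-dependent dispersion
trends, correlated dispersion between RNA and RPF libraries of the same
lysate, transcriptional feedback (Pol II is independent of decay by
construction), and any growth-rate coupling beyond the stylized ESR
shift.

## Differential testing

Size factors are DESeq2-style median-of-ratios (reference = genes
positive in all samples). The Wald test compares normalized group means
with a 0.5 pseudocount: `log2FC = log2((μ̂₁+½)/(μ̂₀+½))`, with
delta-method variance `[(1/n₁)(1/μ̂₁+α) + (1/n₀)(1/μ̂₀+α)] / ln(2)²` and a
two-sided normal p-value. Genes with mean normalized count < 10 across
the contrast are untested (a qualitative analog of independent
filtering). The TE test subtracts the mRNA from the RPF log₂ change and
adds their variances; the two libraries are treated as independent
because their covariance is unidentifiable from separate library preps.
BH correction is applied per contrast and per measure, NA-tolerant
(untested genes excluded from m). No fold-change shrinkage or outlier
handling: the test stays transparent and oracle-checkable.

**Dispersion estimation.** Per-gene method-of-moments estimates
`(s² − m)/m²`, pooled across genotype groups with ≥2 replicates, are
shrunk toward a global trend level. Two numerical choices here matter and
were the product of explicit calibration analysis:

1. *Trend level.* The per-gene moment ratio is biased a few percent low at
   two replicates (the m² denominator is noisy), and naive least-squares
   or median fits inherit or worsen that bias. The level is instead the
   ratio of pooled unbiased moment sums, Σ(s²−m) / Σ(m²−s²/n), with one
   GLS-style reweighting pass (inverse squared NB variance at a pilot
   level) in which each group's contribution is weighted by the *other*
   groups' means — weighting a gene's residual by its own noisy mean
   correlates weight and residual and biases the level low by ~2%.
2. *Shrinkage weight.* The weight on the per-gene estimate is estimated
   empirically (moment-matched empirical Bayes): the across-gene variance
   of the raw estimates in excess of their analytic sampling noise (exact
   NB cumulants, delta method; deliberately conservative at large α)
   measures true dispersion heterogeneity, and the per-gene weight is
   `spread / (spread + noise)`. Homogeneous data collapse onto the trend;
   a simulated 0.01/0.3 dispersion mixture reopens the weight.

With two replicates per group these choices keep the Wald and TE tests'
type-I error at 0.049–0.053 against a nominal 0.05 (pooled over ten
2000-gene null simulations); a fixed-weight 50/50 blend of the raw
estimate and the trend was measured at 0.075–0.10 and abandoned.

## Set operations

"Significant" for sector classification means membership in the
thresholded set (>1.5-fold, FDR<0.05 by default), mirroring how the
regulated sets are defined. The sector map: significant only in the
double mutant → `redundant_double_only`; one single + double →
`single_shared`; one single only → `single_exclusive`; opposite
directions in the two singles → `opposite_in_other_single`; anything else
(including all-three) → `unclassified`. Up-sets are filtered of iESR
genes and down-sets of rESR genes before classification, since the ESR is
an indirect slow-growth signature. Venn reconstruction from published
totals solves the linear system `nA − a_only − abc = ab + ac` (cyclic)
in closed form and rejects non-integer or negative solutions. Shared
fractions are reported rounded to whole percent with raw values retained.
The hypergeometric universe for enrichment is the set of genes passing
the testing filter in the relevant comparison.

## Decapping-state metrics

C/T = (CAGE TPM + ½) / (RNA TPM + ½), replicates combined by geometric
mean because ratios are multiplicative. CAGE and RNA are normalized
independently, so C/T is meaningful only up to a global constant —
comparisons between genes or genotypes are valid, absolute capped
fractions are not. CPI = log₂((protected-frame count + ½) / (mean of the
other two frames + ½)); the metric is cited in the literature without a
printed formula, and this zero-centered form (0 under uniform frames,
scale-invariant as the pseudocount vanishes) is this package's
interpretation — exact numeric CPI values from other studies are not
comparison targets. Frame 0 is the generator's protected frame.

## Decomposition

`percell_fc = spikein_normalized_fc × ribosome_factor` and
`decay_component_fc = percell_fc / polII_fc`, asserted as exact
identities on every result object; per-cell values are reported to two
significant figures alongside raw values. The ribosome factor is an
external assumption (0.7 for real decapping-mutant data, from the ~30%
reduction in ribosome content measured in a decapping-enzyme deletion),
supplied as a knob rather than estimated. In simulation mode the
pipeline uses 1.0 because the generator holds ribosome content constant;
tests that recover `decay_effect` from the decomposition rely on that.
Decomposition operates on set-level medians by default; per-gene mode
works but carries the full per-gene NB noise (~16% at dispersion 0.05,
independent of depth).

## Reporting statistics

Notched box summaries use type-7 (linear interpolation) quartiles and
notches at median ± 1.58·IQR/√n, the standard McGill convention; both
conventions are pinned so tests can assert exact values. Profile
clustering is complete-linkage on Euclidean distance after dropping
incomplete rows and clipping log₂ changes to (−5, 5); column associations
are Spearman ρ.

## Problem sizes

Defaults throughout (2000 genes, 2 replicates, 2×10⁶ reads, ten pooled
2000-gene null replicates for calibration checks) are desk-scale choices:
large enough that set-level medians and false-positive rates are stable
to a few percent, small enough that the full suite and the acceptance
script each run in seconds.

## Known limitations

The Wald test is slightly anticonservative (~0.051 empirical type-I at
n=2+2) because the normal reference ignores the residual uncertainty of
the dispersion level; with ≥3 replicates this vanishes. Real DESeq2
results will differ in detail (shrinkage, Cook's filtering, CR-adjusted
dispersions), so gene counts from real datasets are context, not targets.
Edc3-exclusive targets are modeled as repressed whenever Edc3 is present,
which makes them significant in both *edc3Δ* and the double mutant
(`single_shared`), whereas real Edc3-exclusive sets can also show
double-mutant epistasis masking. The C/T ratio inherits CAGE's TSS-level
biases in real data; the simulator does not model them.
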