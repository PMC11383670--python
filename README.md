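# decaptools

Simulation and analysis of **functional redundancy among mRNA decapping
activators** from multi-omics count data.

In budding yeast, the decapping activators Scd6, Edc3, Dhh1 and Pat1
stimulate removal of the mRNA 5′ cap and/or repress translation of their
target transcripts. A classic genetic signature of redundancy is a
transcript that is unchanged in either single deletion (*scd6Δ*, *edc3Δ*)
but up-regulated in the double mutant (*scd6Δedc3Δ*). Detecting and
interpreting that signature from sequencing data requires several layers
of analysis that this package implements as a tested, reusable pipeline:

- a **ground-truthed simulator** of the four-genotype panel measured by
  five count assays (RNA-seq, ribosome-profiling RPFs, CAGE, framed 5′P
  degradome ends, Pol II ChIP), with ERCC-style and heterologous-chromatin
  spike-ins, built on the steady-state model *abundance = synthesis / decay*
  and negative-binomial counts;
- **normalization**: median-of-ratios size factors, TPM, and spike-in
  scaling that puts samples on an absolute per-total-RNA scale;
- **differential testing**: a transparent negative-binomial Wald test for
  mRNA/RPF changes (log₂ fold change of normalized group means, delta-method
  standard error `Var(log2 FC) = Σ_groups (1/n)(1/μ + α) / ln(2)²`), a
  translational-efficiency shift test `Δlog₂TE = Δlog₂RPF − Δlog₂mRNA`,
  Benjamini–Hochberg FDR, and threshold-based set calling
  (>1.5-fold at FDR<0.05 for abundance; >1.41-fold at FDR<0.10 for TE);
- **set operations**: environmental-stress-response (ESR) filtering,
  three-set Venn arithmetic (including reconstruction of pairwise overlaps
  from published totals/exclusives/triple counts), hypergeometric overlap
  enrichment, and epistasis-sector classification
  (`redundant_double_only`, `single_shared`, `single_exclusive`, ...);
- **decapping-state metrics**: the capped/total (C/T) ratio from paired
  CAGE and RNA-seq TPMs — a relative proxy for the capped fraction of each
  transcript — and the codon protection index (CPI), the log₂ enrichment
  of 5′P ends in the ribosome-protected codon frame;
- **transcription-vs-decay decomposition**: per-cell correction of
  spike-normalized fold changes by a ribosome-content factor, then division
  by the Pol II occupancy fold change to isolate the stabilization
  component: `percell_fc = spikein_fc × ribosome_factor`,
  `decay_component_fc = percell_fc / polII_fc`.

## Worked example

The decomposition arithmetic on set-level medians (fold changes as
printed by `decaptools analyze decompose`):

```sh
$ decaptools analyze decompose --mrna-fc 2.79 --polii-fc 1.2 --ribosome-factor 0.7
percell_fc      1.953   (reported 2.0)
polII_fc        1.2
decay_component_fc      1.627   (reported 1.6)
```

A 2.79-fold spike-normalized increase in median mRNA abundance becomes a
2.0-fold increase per cell after correcting for a 30% reduction in
ribosome (hence bulk RNA) content, and dividing out the 1.2-fold rise in
Pol II occupancy leaves a 1.6-fold stabilization component — most of the
mRNA increase is not explained by transcription.

End-to-end on simulated data (2000 genes, 4 genotypes × 2 replicates,
2×10⁶ reads per sample, seed 7):

```python
import decaptools as dt
cfg = dt.PipelineConfig(simulation=dt.SimulationConfig(seed=7))
summary = dt.analyze_dataset(dt.simulate(cfg.simulation), cfg)
```

prints (via the report fields):

```text
mRNA_up sets (scd6d, edc3d, double): 0 81 317
redundant recall %: 97.9
ESR medians (iESR, rESR): 0.83 -1.15
C/T WT: all 0.90 up-set 0.55
C/T double: all 0.97 up-set 0.99
decomposition up-set: mrna_fc 4.47 polII_fc 0.99 decay_component 4.52
```

Reading this: almost no genes are called in the *scd6Δ* single mutant, a
few dozen Edc3-exclusive targets in *edc3Δ*, and a large up-set in the
double mutant; 97.9% of the truly redundant simulated targets are
classified `redundant_double_only`. The iESR/rESR medians recover the
simulated indirect stress signature (+0.83/−1.15 log₂). Decapping targets
have a low capped fraction in WT (C/T 0.55 vs bulk 0.90) that is restored
in the double mutant (0.99 vs 0.97). Because the simulation perturbs only
decay, Pol II fold change is ≈1 and the decay component carries the whole
effect.

The same run from the shell: `decaptools report --out run/ --seed 7`
(writes all stage tables and `results/summary.json`);
`decaptools simulate --out data/ --seed 7` writes the raw count tables.

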