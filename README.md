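# methylotype

Tumor gene-expression inference from dual 5mC/5hmC cell-free DNA
methylomes, with outcome association and longitudinal resistance
phenotyping.

Plasma cell-free DNA (cfDNA) from cancer patients is a mixture of
tumor-derived DNA (ctDNA) and normal, mostly hematopoietic DNA.
"6-base" sequencing resolves 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) separately at each CpG, and the two
marks carry complementary expression information: gene-body 5hmC rises
with transcription while promoter 5mC falls.  This package turns those
two signals into a per-gene, per-sample *inferred expression Z-score*
and carries that readout through survival screening, longitudinal
change statistics, and a 2-D latent trajectory map of treatment
resistance — the whole pipeline exercised end-to-end on a seeded
synthetic cohort with known ground truth.

## The model

Gene-level bulk fractions are pooled CpG counts over the gene body
(5hmC) and the promoter window, 1 kb upstream to 5 kb downstream of the
TSS (5mC).  With sample ctDNA purity `p_s` and a gene-wise buffy-coat
background `m_{g,t(s)}^N` matched on timepoint class `t(s) ∈ {BL, TR}`,
the two-component mixture is inverted per gene:

```
5hmC:  m_{g,s}^T = (m_{g,s}^bulk − (1 − p_s)·m_{g,t(s)}^N) / p_s

5mC:   CN_{g,s}^T = p_s·CN_{g,s}^tumor,   CN_s^N = (1 − p_s)·CN^N
       m_{g,s}^T = (m_{g,s}^bulk·(CN_{g,s}^T + CN_s^N) − m_{g,t(s)}^N·CN_s^N) / CN_{g,s}^T
```

where `CN^N` is 2 on autosomes and 1 on X/Y (male cohort).  Tumor
promoter 5mC is re-oriented as the depleted fraction
`d_{g,s}^T = 1 − m_{g,s}^T`, so both marks increase with expression.
Each mark is standardized gene-wise against the baseline cohort
(`Z^M`, `Z^H`), and the equally weighted composite

```
C_{g,s} = (Z_{g,s}^M + Z_{g,s}^H) / 2
```

is the transcriptome-like readout.  Restaging and progression samples
are scored against the same baseline anchors ("baseline-anchored"
scores), so later-timepoint values read as change in baseline standard
deviations.  Samples with ctDNA fraction < 0.1 are ctDNA-negative and
are never deconvolved.

Downstream, the package provides gene-wise Cox proportional-hazards
screening against rPFS/OS, Spearman-ranked preranked GSEA, Fisher exact
and Kaplan-Meier/log-rank statistics, Shannon diversity for clonotype
repertoires and subclone CCFs, a gene-wise exposure mixed model
(`z ~ Exposed + (1 | Case)`), paired ΔgeneZ change vectors and their
RMS, resistance-axis classification (cumulative CCF shift > 0.1;
rPFS < 2 months), empirical-Bayes moderated group tests, and a
multiblock sparse-PLS latent map with arm geometry.

## Worked example

```python
import numpy as np
import methylotype as mt

truth = mt.simulate_truth_matrices(mt.SimConfig(seed=7))
meta = truth.meta

background = mt.background_profile(truth.buffy_hmc, truth.buffy_mc, meta)
decon = mt.deconvolve_cohort(
    truth.bulk_hmc, truth.bulk_mc, background, meta, truth.gene_cn, truth.cn_normal
)
anchors = mt.baseline_stats(decon, meta)
z = mt.anchored_scores(decon, anchors, meta)

sample = z.composite.columns[0]
r = np.corrcoef(z.composite[sample], truth.true_z.loc[z.composite.index, sample])[0, 1]
print(f"sample {sample}: purity {meta.loc[sample, 'purity']:.2f}, "
      f"corr(composite Z, true expression Z) = {r:.3f}")

lmm = mt.fit_exposure_lmm(
    mt.GeneZMatrix(None, None, z.composite.loc[truth.programs["exposure"]],
                   "baseline_anchored"),
    meta,
)
print(f"exposure shift: median beta = {lmm['beta'].median():.2f} "
      f"(planted 0.80, median SE {lmm['se'].median():.2f})")

labels = mt.resistance_labels(truth.ccf, truth.survival)
print(f"resistance labels: {int(labels['high_ccf'].sum())} clonal-remodeling, "
      f"{int(labels['rapid'].sum())} rapid-progression cases")
```

prints

```
sample C01-BL: purity 0.77, corr(composite Z, true expression Z) = 0.999
exposure shift: median beta = 0.82 (planted 0.80, median SE 0.15)
resistance labels: 8 clonal-remodeling, 8 rapid-progression cases
```

The first line says the composite Z-score reconstructs this sample's
true latent expression almost perfectly across 400 genes at 77%
purity; the second that the gene-wise mixed model recovers the +0.8σ
expression shift planted at treated timepoints; the third that the
CCF-shift and rPFS thresholds label exactly the planted resistance
arms.

A `methylotype` command-line tool mirrors the library
(`simulate`, `validate`, `aggregate`, `deconvolve`, `infer-expression`,
`associate`, `longitudinal`, `trajectory`); see `methylotype --help`.

## Layout

```
src/methylotype/
  io_formats.py            readers/writers, gene copy-number assignment
  signal_aggregation.py    CpG → gene-level fractions, RNA normalization
  tumor_deconvolution.py   purity/CN-adjusted tumor-normal deconvolution
  expression_inference.py  baseline anchors, composite & anchored Z
  outcome_association.py   Cox screen, GSEA, Fisher/KM, diversity
  longitudinal_dynamics.py exposure LMM, ΔgeneZ/ΔRMS, CCF shift, eBayes
  trajectory_integration.py regulator scores, multiblock sPLS, arm geometry
  synthetic_data.py        seeded cohort generator with ground truth
  cli.py                   thin command-line surface
docs/methods.md            model, generator and design notes
```
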