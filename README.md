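# methylhap

Methylation haplotype blocks for tissue and cell-free DNA methylomes:
block discovery, haplotype-load scoring, differential-marker selection,
classification, and survival validation — with a built-in synthetic-cohort
generator so the whole pipeline is testable without any external data.

## The problem

Bisulfite sequencing reads carry the joint methylation state of neighbouring
CpGs on single DNA molecules. In tumours (the motivating application is
hepatocellular carcinoma and the prediction of microvascular invasion, MVI),
aberrant methylation tends to occur in *consecutive runs* on the same
molecule. Two statistics capture this:

* A **methylation haplotype block (MHB)** is a maximal run of consecutive
  CpGs in which every adjacent pair is in tight linkage,
  r² > 0.5, where r² is the squared Pearson correlation of the two binary
  call vectors over reads covering both sites.
* The **methylated haplotype load (MHL)** of a block with *l* CpGs is

  ```
  MHL = Σᵢ wᵢ · P(MHᵢ) / Σᵢ wᵢ ,   wᵢ = i³,  i = 1..l
  ```

  where P(MHᵢ) is the fraction of all contiguous length-*i* sub-haplotypes
  (windows) that are fully methylated. The cubic weight rewards long
  consecutive methylated runs. The **un-methylated haplotype load (UMHL)**
  is the mirror statistic on fully un-methylated windows.

On top of these, the pipeline reproduces a complete marker-discovery study
design: detection/variability filter cascade, one-sided Wilcoxon tests with
Benjamini–Hochberg FDR control, random-forest classifiers (500 trees,
repeated stratified 3-fold cross-validation), transfer of a tissue-trained
model to plasma (circulating tumour DNA), and Kaplan–Meier / log-rank
validation of predicted MVI groups against survival.

Intended users: computational epigenomics researchers who want a tested,
reusable implementation of MHB/MHL analysis, and methodologists who need a
generative test bed with known ground truth.

## Worked example

```python
import methylhap as mh
from methylhap.markers import FilterConfig, scaled_min_detected, select_markers

# a small synthetic cohort: tissue + plasma, spiked differential blocks
cohort = mh.simulate_cohort(mh.demo_spec(seed=0))
matrix = mh.score_cohort(cohort.haplotypes, cohort.regions)
print(f"{matrix.data.shape[0]} samples x {matrix.data.shape[1]} blocks")

markers = select_markers(
    matrix, cohort.metadata,
    FilterConfig(min_detected_per_sample=scaled_min_detected(250),
                 test="signed_rank"),
    contrast="tumor_vs_normal",
)
print(f"{markers['mhb_id'].nunique()} differential blocks at FDR < 0.05")

tissue = cohort.metadata.query("specimen == 'tissue'")
cv = mh.cross_validate(
    matrix.data.loc[tissue.index, markers["mhb_id"].unique()],
    tissue["tumor_status"], mh.ModelConfig(seed=7), positive_label="tumor",
)
print(f"tumor-vs-normal AUC {cv.mean_auc:.3f} "
      f"(95% CI {cv.ci_lower:.3f}-{cv.ci_upper:.3f}, 10 repeats)")
```

prints

```
56 samples x 250 blocks
6 differential blocks at FDR < 0.05
tumor-vs-normal AUC 1.000 (95% CI 1.000-1.000, 10 repeats)
```

The cohort contains 16 normal and 16 tumour tissues plus plasma samples; the
generator spiked 6 tumour-differential blocks, and the paired signed-rank
cascade recovers exactly those 6. Because the demo preset uses a large
methylation shift, the cross-validated random forest separates the groups
perfectly.

The same analysis is available from the shell:

```bash
methylhap pipeline --preset demo --seed 11 --out run/
```

which writes every intermediate artefact (haplotype files, regions BED,
MHL/UMHL matrices, marker tables, cross-validation results, plasma
predictions, MVI calls, Kaplan–Meier tables) plus a `manifest.json` with
parameters, per-stage seeds and output hashes. Two runs with the same seed
are byte-identical.

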