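# tumortyper

Predicting the cancer type of a tumour sample from the genes it has
altered. Patients with cancer of unknown primary — metastatic disease whose
tissue of origin cannot be established histologically — have poor survival,
and a DNA-based classifier offers a route to a diagnosis: somatic point
mutations (SPMs) and copy-number alterations (CNAs) called from tumour
sequencing carry enough class-specific signal to separate a broad range of
cancer types, provided the two alteration kinds are combined and the gene
panel is chosen well.

`tumortyper` implements that analysis as a reusable pipeline for
biostatisticians working with gene-level alteration calls:

* **Binary feature matrices.** Each tumour sample becomes a row of binary
  features: one column per gene for SPMs, and two columns per gene for
  CNAs (amplification and deletion as independent events, with no high/low
  level distinction). Matrices are sanitised — all-zero columns, all-zero
  rows, and duplicated CNA columns removed — and the SPM and CNA blocks can
  be analysed separately or concatenated.
* **Feature ranking.** The primary engine is multiclass SVM recursive
  feature elimination (SVM-RFE): fit one-vs-rest linear SVMs, score each
  feature *j* by ∑ₖ w²ₖⱼ over the K class weight vectors, discard the
  lowest-scoring feature, repeat; the reverse elimination order is the
  importance ranking. L1-regularised multinomial logistic regression
  (selection via the regularisation path) and random-forest permutation
  importance with backward elimination are provided as comparators, plus a
  frequency-matched random baseline whose expected accuracy is ∑ᵢ pᵢ².
* **Resampling evaluation.** A stratified quarter of the samples is
  reserved untouched for final validation; the remaining development set
  is split 4/5 train : 1/5 test, 50 times by default. Accuracy-vs-panel-size
  curves, per-class precision and recall
  (precisionᵢ = correct *i* / predicted *i*, recallᵢ = correct *i* /
  actual *i*), and 95 % confidence half-widths 1.96·sd/√n are averaged over
  the repeats.
* **Stability selection.** Because each resampled training set yields a
  different ranking, the final panel is chosen by counting how often each
  feature appears in the per-repeat top-*m* lists and keeping the most
  frequently selected features — then validating that fixed panel once on
  the untouched holdout.
* **Synthetic ground truth.** A planted-signal generator (K classes, each
  with a private set of informative features altered at rate `p_signal`
  over a sparse `p_background` noise floor, split across SPM and CNA
  blocks) gives every stage a known answer, so panel recovery and the
  benefit of combining alteration types are directly measurable.

## Worked example

Run the full pipeline on the bundled generator (6 cancer types × 60
samples, 5 informative genes per type split evenly between SPM and CNA
blocks, 300 background features):

```python
from tumortyper import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", mode="combined", seed=1,
                     n_repeats=10, size_grid=(10, 20, 30, 50),
                     top_m=30, panel_size=30,
                     synthetic=SyntheticConfig())
run_pipeline(cfg)
```

or equivalently `tumortyper run --config cfg.yaml`. The run directory
contains the sanitised matrix, one ranking per repeat, the accuracy curve,
per-class metrics, the stability table and a plain-text report:

```
mode: combined   seed: 1   samples: 360   features: 330   repeats: 10

Accuracy vs panel size (mean over repeats, 95% CI half-width):
  n=   10  acc=0.7519 +/- 0.0356
  n=   20  acc=0.9130 +/- 0.0154
  n=   30  acc=0.9556 +/- 0.0135
  n=   50  acc=0.9833 +/- 0.0114
...
Selected panel (30 features): 18 SPM, 12 CNA
Holdout accuracy with selected panel: 0.9667
```

Reading: with only 10 genes the classifier reaches 75 % test accuracy,
climbing towards saturation as more top-ranked genes are added; the
30-feature stability-selected panel — a mix of mutation and copy-number
markers, 28 of the 30 being genuinely planted signal genes here — classifies
the held-out quarter at 96.7 %, against a chance baseline of ∑pᵢ² ≈ 16.7 %
for six balanced classes.

The command-line surface exposes the individual stages too:
`tumortyper simulate`, `build-matrix`, `rank`, `report`. File inputs are
plain TSV: a 3-column call table (`sample_id  gene  kind`), MAF-like
mutation tables, GISTIC-style thresholded copy-number tables, and
one-symbol-per-line gene and exclusion lists (e.g. for removing pseudogenes
and non-coding genes).

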