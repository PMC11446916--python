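# emdmn

Quantification of **Emerin-rich micronuclei** in fluorescence microscopy
images, and of the **9-gene Emerin-pauperization transcriptomic score**, as
a tested, reusable Python pipeline.

Micronuclei (MN) are small chromatin bodies that sit beside a cell's main
nucleus. In prostate cancer, a subset of MN accumulates the inner-nuclear-
membrane protein Emerin (EMD) to a level well above that of the nuclear
envelope (NE) — the *Emerin-rich* class — apparently draining ("pauperizing")
Emerin from the NE and marking an invasive, poor-prognosis phenotype. This
package implements the quantitative machinery for studying that phenotype:

- **Image arm** — ImageJ-style auto-thresholding (Otsu / Intermodes / Yen on
  256-bin histograms, with an 8-bit minimum-threshold floor), particle
  analysis (area, perimeter, circularity 4πA/P², solidity), nucleus
  segmentation from DAPI, per-nucleus NE reference intensity over a boundary
  ring, MN detection with a 0.2–12 µm² size gate, Emerin-rich vs NE-level
  classification by the MN/NE intensity ratio, per-field *Emerin-rich MN per
  nucleus* statistics, and cohort stratification at the fixed quartile
  cutoffs 0.07538 / 0.1280 / 0.1861.
- **Phenotype metrics** — DAPI-content and NE/cytoplasm intensity ratios,
  nuclear morphometry, focal-adhesion sizing from paxillin, signed
  MTOC–nucleus distance from pericentrin, structure-tensor F-actin
  coherency (λ₁−λ₂)/(λ₁+λ₂), spheroid shape with invading-cell counting,
  and migration-path statistics from exported tracks.
- **Transcriptomic arm** — nCounter-style background correction (mean + 2 SD
  of negative controls) and sequential positive-control / housekeeping
  normalization, Mann–Whitney differential expression with median-based
  log2FC, the pauperization score (mean log₂ count of *CXCR4, APOE, SPARC,
  VIM, GSN, ANXA2P2, SFRP1, COL18A1, FN1*), upper-quartile classification,
  and survival association (Kaplan–Meier, log-rank, Cox hazard ratio).
- **Synthetic data** — phantom fields with planted nuclei, NE rims and MN of
  both intensity classes (with full ground truth), and expression/survival
  cohorts with a prescribed hazard ratio, so every stage is benchmarked
  against known truth without external data.

## Worked example

Simulate three phantom fields, quantify them, and score a synthetic cohort:

```bash
emdmn simulate field --seed 1 --n-fields 3 --out fields
emdmn quantify --images fields --out report
emdmn simulate cohort --seed 1 --out cohort
emdmn score --matrix cohort/expression.csv --survival cohort/survival.csv --out scored
```

The quantify step prints (ground-truth JSON files alongside the TIFFs are
picked up automatically and scored):

```
{"n_fields": 3, "n_mn_total": 24, "concordance": {"mean_recall": 1.0, "mean_precision": 1.0, "mean_class_accuracy": 1.0}}
```

and `report/fields.csv` holds the per-field counts:

```
field,n_nuclei,n_rich,n_ne_level,n_dropped_unassigned,rich_per_nucleus,stratum
field_00001,20,4,4,0,0.2,>=p75
field_00002,20,4,4,0,0.2,>=p75
field_00003,20,4,4,0,0.2,>=p75
```

Each default field plants 20 nuclei and 4 + 4 MN; all 8 are recovered and
correctly classified, giving 4/20 = 0.2 Emerin-rich MN per nucleus, which
falls in the top stratum of the fixed cohort cutoffs. The score step prints
the cohort-level survival association for the upper-quartile score split:

```
{"n_samples": 500, "n_high": 125, "hr": 1.548, "ci95": [1.154, 2.077], "logrank_p": 0.0033}
```

125/500 samples are flagged high (strict upper-quartile rule); the fitted
hazard ratio of ~1.5 for the high-score group reflects the simulated
hazard ratio of 1.75, attenuated because the quartile split imperfectly
recovers the planted group.

The same functionality is available as a library, e.g.:

```python
from emdmn import PhantomParams, generate_field, quantify_field

field, truth = generate_field(PhantomParams(seed=1))
summary, records, nuclei = quantify_field(field)
print(summary.rich_per_nucleus)   # 0.2
```

## Scope notes

Tissue-cohort clinical constants (the stratification cutoffs, the 0.85
Emerin-negative cell fraction) are fixed configuration values, not
quantities this package re-derives. The optional TCGA PRAD reproduction
(9-gene score, upper-quartile split, Cox on disease-free survival) runs
only when a locally downloaded expression matrix and survival table are
placed under `data/tcga/`.
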