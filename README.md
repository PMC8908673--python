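# pdoniche

Analytics for niche-factor dependency studies in pancreatic ductal
adenocarcinoma (PDAC) patient-derived organoids (PDOs), built for groups that
run organoid drug screens and want the full quantitative chain — from raw
microarray intensities and plate luminescence to subtype calls, dependency
scores and drug-sensitivity statistics — as tested, scriptable Python.

PDAC organoids differ in how much they depend on microenvironmental ("niche")
factors such as Wnt3a, R-spondin (RSPO1), Noggin, EGF, FGF10 and A83-01.
Well differentiated (Grade 1) lines typically grow only when niche factors are
supplied, are transcriptionally "Classical", and are comparatively resistant
to gemcitabine but sensitive to statins; poorly differentiated (Grade 3) lines
grow in serum, score "Basal-like", and show the opposite drug profile. The
package implements every quantitative step of that analysis:

* **Expression subtyping** — log2 transform + quantile normalization of a
  gene x sample matrix; per-gene z-scores across samples; total score
  `T = sum(z_basal) - sum(z_classical)` with `T >= 0 -> Basal-like`
  (Moffitt-style two-signature classification); Pearson-correlation ranking
  of genes against a per-sample score with top-k/bottom-k extraction.
* **Niche-dependency scoring** — blank-subtracted luminescence, day-10/day-0
  proliferation fold changes, score = fold(niche medium)/fold(serum medium),
  factor-dropout responses, High/Low subtype split.
* **Dose-response** — robust four-parameter-logistic (4PL) fit on the
  log10-dose axis (soft-L1 loss, multi-start, free Hill sign), EC50, area
  under the fitted curve over log10 dose (AUC; larger = more resistant),
  unpaired two-tailed t-tests between subtypes and Spearman correlation of
  niche score vs AUC.
* **Organoid imaging** — Otsu threshold, hole filling, 8-connected
  components on calibrated images; objects of 2000 um^2 and more count as
  organoids (inclusive); stain-positive area fraction for
  immunohistochemistry.
* **ddCt qPCR** — relative expression `2^(-ddCt)` normalized to a reference
  gene and baseline condition.
* **Synthetic study generator** — a seeded 8-organoid scenario (3 Grade 1,
  3 Grade 2, 2 Grade 3) that emits every input table with known ground truth,
  so the entire pipeline runs and is testable with no external data.

The model-shaped components are scikit-learn estimators
(`QuantileNormalizer`, `MoffittSubtypeClassifier`, `FourPLRegressor`) and
compose with sklearn pipelines; the module-level functions are thin wrappers
over them.

## Worked example

Run the default simulated study end to end (library route; `pdoniche run
--config run.yaml` is the CLI equivalent):

```python
from pdoniche import RunConfig, default_scenario, run_pipeline

scenario = default_scenario(seed=0)
cfg = RunConfig(outdir="demo_run", seed=0, simulate=scenario,
                params={"include_samples": scenario.include_samples})
report = run_pipeline(cfg)
```

Selected numbers this run prints (from `demo_run/report.json`):

```
subtype labels:
  PDO565: total=-45.63 -> Classical      PDO578: total=+41.21 -> Basal-like
  PDO571: total=-37.40 -> Classical      PDO580: total=+46.64 -> Basal-like
  PDO585: total=-38.88 -> Classical      PDO497: total=+43.56 -> Basal-like
  PDO573: total=-51.45 -> Classical      PDO501: total=+41.94 -> Basal-like
niche scores (fold_niche / fold_serum):
  PDO571: 5.49 High   PDO585: 4.26 High   PDO565: 3.48 High
  PDO580: 0.71 Low    PDO501: 0.53 Low    PDO497: 0.43 Low
gemcitabine AUC:  Low=400.3  High=594.3  p=0.0005  Spearman rho=+0.83
simvastatin AUC:  Low=463.7  High=314.5  p=0.0001  Spearman rho=-0.94
mevalonate genes in top-1000 correlated set: 15 of 15
qPCR RSPO3 fold (vs 2D serum culture): 3D_SM=1.04, 3D_PDO-CM=7.29
imaging: organoid_g1 count=5 total=16796 um^2 (>= 2000 um^2 rule)
```

Reading: Grade 1 lines classify Classical and carry high niche-dependency
scores; the Low-dependency group has the smaller gemcitabine AUC (more
sensitive, p < 0.01 by unpaired t-test) while the High group is the more
statin-sensitive one; all mevalonate-pathway genes land in the top-1000
positively correlated set; and organoid counting applies the inclusive
2000 um^2 rule.

## Command-line interface

```
pdoniche simulate --out DIR --seed N          # write a full synthetic study
pdoniche classify --expr X.tsv --basal s.gmt:basal --classical s.gmt:classical
pdoniche correlate --expr X.tsv --scores scores.csv --k 1000
pdoniche niche-score --growth growth.csv [--threshold X]
pdoniche drc-fit --data dr.csv --reference-dose 0.001
pdoniche drc-compare --sens sens.tsv --subtypes labels.csv
pdoniche quantify-images --dir imgs/ --min-area 2000
pdoniche qpcr --data ct.csv --target RSPO3 --baseline 2D_SM
pdoniche run --config run.yaml               # full pipeline
```

See `docs/methods.md` for the models, noise assumptions, parameter defaults
and known limitations.
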