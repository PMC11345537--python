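# glioslide

Tile-based deep-learning analysis of glioblastoma H&E slides: spatial
mapping of transcriptional subtypes, a histology-derived survival risk
score, and quantification of the tumor microenvironment — packaged with a
synthetic cohort generator so the entire pipeline is testable on a desk.

## The problem

Glioblastoma (IDH–wild-type) is histologically heterogeneous, yet routine
H&E slides carry little formally established prognostic information. Two
tile-level predictions address this:

* **TS head** — a 3-neuron softmax layer on a frozen convolutional
  backbone predicts the tumor's transcriptional-subtype fraction vector
  *(classical, mesenchymal, proneural)*, trained with squared error
  against bulk-derived subtype admixtures. Per-tile winner-takes-all
  calls map the subtypes spatially; samples with a component ≥ 0.70 carry
  a *predominant* subtype label.
* **RS head** — a 1-neuron linear layer produces a risk score *r* trained
  with the negative log Cox partial likelihood over mini-batch risk sets

  L = −(1/d) Σ_{i: δᵢ=1} [ rᵢ − log Σ_{j: tⱼ ≥ tᵢ} exp(rⱼ) ],

  with Breslow handling of ties and d the number of events. Tile scores
  are z-scored per validation fold; tiles with z > 1 are *high-risk*, and
  a patient is called high-risk when ≥ 25 % of their tiles are high-risk.

Around these sit the standard stages: overlap tiling of annotated slides
with per-tile region fractions (tumor / necrosis / preexisting brain /
bleeding / scar), >50 %-tumor tile filtering and <50-tile patient
exclusion, H&E-specific augmentation, two-phase training (frozen backbone,
then fine-tuning of the last convolutions), Kaplan–Meier / Cox / log-rank /
permutation statistics, whole-slide heatmaps, and nucleus-level
morphometrics (cellularity per mm², circularity 4πA/P², marker densities
per mm², stained-area fractions).

Because the original slide cohorts are not required here, the
`synthcohort` module generates annotated H&E-like slides whose phenotype
is tied to a latent risk score and a subtype mixture (cellularity medians
6146/5484/5321 per mm², mesenchymal-skewed immune infiltration, risk-linked
pleomorphism and CD8 depletion) and whose survival follows a Weibull
proportional-hazards model with age, sex and radiochemotherapy covariates.

## Worked example

```python
from glioslide.synthcohort import SynthConfig, generate_cohort
from glioslide.pipeline import run_cv_pipeline
from glioslide.training import TrainConfig
from glioslide.stats import harrell_c, km_logrank

cfg = SynthConfig.test_profile(seed=11, n_patients=60)   # 512 px slides
cohort = generate_cohort(cfg, markers=())
result = run_cv_pipeline(cohort, tile_px=64, overlap_px=8, k=5,
                         train_config=TrainConfig.desk(seed=0))

calls = result.patient_calls
clin = cohort.clinical.set_index("patient_id")
t = clin.loc[calls.patient_id, "surv_time_years"]
e = clin.loc[calls.patient_id, "event"]
print("patient-level c-index:", round(harrell_c(t, e, calls.mean_rs_z), 3))
print(calls.risk_group.value_counts().to_dict())
print("log-rank p:", km_logrank(t, e, calls.risk_group)[2])
dom = calls[calls.true_subtype != "mixed"]
print("predominant-subtype accuracy:",
      round((dom.pred_subtype == dom.true_subtype).mean(), 3))
```

Output of this exact run:

```
patient-level c-index: 0.733
{'low': 45, 'high': 15}
log-rank p: 6.59000510416089e-05
predominant-subtype accuracy: 0.741
```

The trained risk head ranks the 60 synthetic patients with concordance
0.733, the 25 %-cutoff risk groups separate survival at p < 10⁻⁴, and the
subtype head identifies the predominant subtype in 74 % of
predominant-subtype patients, far above the permuted-label null (≈ 45 %).

A thin CLI covers the file-facing steps:

```bash
glioslide generate --out cohort/ --n-patients 12 --seed 7
glioslide tile --slide cohort/slides/P000.png --masks cohort/masks \
    --tile 64 --overlap 8 --out sheet.csv
glioslide microenv --slide cohort/slides/P000.png --masks cohort/masks \
    --markers cohort/markers/P000_CD8.csv --out summary.csv
```

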