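# ccflow

Quantification of choriocapillaris (CC) flow impairment around geographic
atrophy (GA) on en-face OCT angiography, and of its association with lesion
growth.

## The problem

In late dry age-related macular degeneration, GA lesions enlarge at very
different speeds between eyes. The choriocapillaris — the capillary bed
directly under the retinal pigment epithelium — shows *flow voids* on OCTA
(pixels whose decorrelation signal falls below a local threshold), and the
density of those voids immediately outside the atrophy border is a candidate
predictor of how fast the lesion will grow. `ccflow` implements the full
measurement chain for that question, for image-analysis researchers working
with en-face CC angiograms and co-registered GA masks:

1. **Shadow compensation** — the flow image is multiplied by the smoothed,
   inverted structural image, undoing the signal attenuation that drusen and
   other RPE changes cast over the CC in both channels.
2. **Binarization** — the Phansalkar local threshold
   `t = m · (1 + p·e^(−q·m) + k·(s/R − 1))`, with `m`, `s` the mean and SD
   over a circular window (radius 15 px on a 1024 px / 6 mm grid), marks
   each pixel below `t` as a flow void.
3. **Ring regions** — the Euclidean distance map of the background from the
   union of all GA foci carves two concentric 500 µm rings outside the
   lesion edge: the *para-atrophy* region (0–500 µm) and the *peri-atrophy*
   region (500–1000 µm).
4. **Flow-void metrics** — `FV_OUT`, `FV_500`, `FV_1000` are the void
   percentages over all non-lesion pixels and the two rings;
   `ΔFV = FV_500 − FV_1000` isolates the local excess of impairment at the
   lesion edge from the eye-wide level and from the physiologic decline of
   void density with distance from the fovea.
5. **Growth rate** — lesion areas at two visits give the square-root
   transformed yearly growth rate `yGR = (√A₂ − √A₁)/FU` (mm/yr), which is
   independent of baseline lesion size (a circle growing at edge speed `v`
   has `yGR = √π · v` at any radius).
6. **Cohort statistics** — Pearson correlations, inter-grader ICC(2,1), and
   generalized estimating equations (Gaussian, identity link, exchangeable
   correlation within patient, sandwich SEs): a univariable screen over the
   candidate covariates, then one multivariable model on the survivors.

Because no public OCTA dataset accompanies this protocol, the package ships
a first-class **synthetic cohort generator** (`ccflow.synthetic`) that
renders structure/flow image pairs, GA masks at two visits, and cohort
tables with known ground truth — the coupling between peri-lesional void
excess and lesion edge speed is injected by construction, so the whole
pipeline can be validated by recovery.

## Worked example

```python
from ccflow import (SyntheticConfig, generate_cohort, BinarizationParams)
from ccflow.run import analyze_bundles, run_stats

cfg = SyntheticConfig(n_patients=20, eyes_per_patient=2, grid_px=512, seed=1)
bundles, truth, cohort = generate_cohort(cfg)
results = analyze_bundles(bundles, bin_params=BinarizationParams(radius_px=8))
report = run_stats(results)
print(round(report["summary"]["mean_dfv"], 3),
      {k: round(v, 3) for k, v in report["correlations"]["dfv"].items()})
```

which prints (the same numbers the `analysis/` scripts report; the
underlying p-value is 1.5e-15):

```
3.513 {'r': 0.903, 'p': 0.0}
```

Forty synthetic eyes with a para-ring void excess drawn from U[0, 0.10]
show a mean ΔFV of 3.5 percentage points, and the pipeline-recovered
correlation between yGR and ΔFV is r = 0.90 — the injected growth/flow-void
coupling, seen end-to-end through rendering, compensation, binarization and
ring measurement. The GEE screen puts the univariable ΔFV slope at
B = 0.135 (SE 0.012) mm/yr per percentage point.

The same study can be run as numbered scripts:

```bash
python analysis/01_simulate.py   # images to scratch/, tables to results/
python analysis/02_analyze.py    # per-eye pipeline -> results/results.csv
python analysis/03_stats.py      # correlations + GEE -> results/table1.csv
```

or from the CLI (`ccflow simulate / analyze / stats / qc`).

## Layout

- `src/ccflow/` — the library: `image`, `pipeline`, `geometry`, `metrics`,
  `stats`, `synthetic`, `run`, `cli`.
- `analysis/` — the numbered study drivers.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests (brute-force
  oracles for the binarization and the distance-map rings included).
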