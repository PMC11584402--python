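# smpc

Single-molecule protein–protein-interaction (PPI) profiling of the
BCL2 family, and linear-model prediction of BH3-mimetic drug efficacy.

BH3 mimetics (ABT-199/venetoclax targeting BCL2, AZD-5991 targeting
MCL1) kill cancer cells by displacing pro-apoptotic proteins from the
binding groove of anti-apoptotic BCL2-family proteins. Whether a given
acute-myeloid-leukaemia (AML) sample responds depends on how its
BCL2-family interaction network is wired: how much of each
anti-apoptotic protein (BCL2, BCLxL, MCL1) exists, which partner
complexes (e.g. BCL2–BAX, BCLxL–BAK) it currently holds, and how much
unoccupied capacity remains. This package implements the computational
chain that turns single-molecule pull-down/co-IP (SMPC) fluorescence
images of those complexes into a per-sample efficacy score, for
computational biologists who want to study or extend that chain. All
inputs can be generated synthetically with known ground truth, so the
whole pipeline is testable end to end without any experimental data.

## What it computes

**Counting.** A field of view (FOV) is a 100 × 100 µm² image of
surface-captured molecules. Frames are averaged, background subtracted,
and diffraction-limited spots counted as thresholded local maxima —
up to a ceiling (default 12,000/FOV) beyond which spots overlap. Above
the ceiling, counts are extrapolated from the integrated fluorescence
intensity via a linear calibration fitted in the countable regime.

**Assays.** Three metric kinds per sample, 22 metrics total: total bait
levels (LV), bait–partner complex counts (CPX), and probe-binding-assay
counts (PBA, the unoccupied bait pool). Titrating a PBA probe yields the
dissociation constant through the single-site isotherm

    occupancy = [probe] / (Kd + [probe]).

BH3 profiling quantifies mitochondrial depolarization from JC-1
fluorescence AUCs, normalised between DMSO and FCCP controls:

    depolarization = 1 − (AUC_sample − AUC_FCCP) / (AUC_DMSO − AUC_FCCP).

**Efficacy target.** Viability (%) over a 0–1 µM drug titration is
fitted with a 4-parameter logistic; the normalised sensitivity score is

    ex vivo AUC = 1 − AUC / Maximal AUC  ∈ [0, 1],

with samples at or above 0.61 labelled responsive.

**Model.** Metrics are floored (100 spots, or 10⁷ a.u. for the three
intensity-type metrics) and log2-transformed. Single metrics are
screened by OLS with an upper-tail F-test; a driver/resistance panel
(for ABT-199: BCL2-BIM_BH3 PBA and BCL2-BAX CPX positive, BCLxL-BAK CPX
negative) is fitted jointly, or discovered by a Lasso train/test
ensemble that retains only models classifying all held-out samples
correctly. Scores are evaluated by ROC analysis, MSE, a confusion
matrix at the 0.61 threshold, and a two-sided Mann–Whitney test.

## Worked example

Simulate a 32-sample cohort with a known ground-truth model
(coefficients 0.12 / 0.157 / −0.05 per log2 unit), refit the panel and
evaluate it:

```sh
$ smpc simulate --out demo --seed 1
ROC AUC 0.958  MSE 0.0025  sens 75.0%  spec 95.8%
```

`demo/report.json` then contains the refitted model, e.g.

```json
"combined_model": {
  "metrics": ["BCL2-BIM_BH3 PBA", "BCL2-BAX CPX", "BCLxL-BAK CPX"],
  "coefficients": [0.117, 0.163, -0.041],
  "intercept": -1.214,
  "pearson_r": 0.968,
  "p_value": 6.2e-17
}
```

— the OLS refit recovers the generating coefficients to within their
sampling error, correlates with the simulated ex vivo AUC at R = 0.97,
and separates responders (score ≥ 0.61) with ROC AUC 0.96. The same
chain is available from Python; for instance a counting-noise titration
generated at Kd = 10 nM and refitted:

```python
>>> from smpc.synthetic import gen_titration
>>> from smpc.assays import fit_kd
>>> s = gen_titration(10.0, [1, 3, 10, 30, 100, 300], n_baits=2000,
...                   noise_model="binomial", seed=7)
>>> fit_kd(s, n_bootstrap=1000, seed=7)
Kd = 10.41 nM  (95% CI 9.91–10.96 nM)
```

Other subcommands: `count-spots` (TIFF → counts CSV), `fit-kd`, `bh3`,
`efficacy`, `fit-model`, `ensemble`, `predict`, `report`.

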