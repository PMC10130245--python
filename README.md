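# stentbench

Quantitative stent-appearance analysis for CT detector comparisons, run
entirely on synthetic data.

Metal vascular stents are hard to image with conventional
energy-integrating CT (EIDCT): blur and partial volume make the struts
"bloom", diameters read wrong, and two overlapping stents merge into one.
Photon-counting detectors (PCCT) promise smaller effective pixels and
sharper images. `stentbench` is for imaging scientists who want to study
exactly this comparison on a desk: it generates ground-truth
stented-vessel phantoms, degrades them through a configurable linear CT
system model, measures the three standard stent metrics from HU line
profiles, and runs the reader/statistics layer that such comparisons
report.

## The metrics

All three are computed from HU profiles on axial slices, at three axial
locations per stent, and reported as mean ± SD:

* **Diameter accuracy** — peak-to-peak: on diametral lines through the
  stent center, the distance between the two outermost strut peaks
  (sub-pixel parabolic refinement); reported as mean absolute error
  against the known diameter *d*.
* **Blooming** — from the strut peak's half-maximum crossing radii
  r_in, r_out (half-max relative to the local background on each side),
  apparent areas A = πr² give
  `blooming % = (A_out − A_in) / A_out × 100`.
* **Inter-stent distinction** — on a profile crossing one strut of each
  of two adjacent stents:
  `distinction % = (peak − trough) / (peak − minimum) × 100`,
  where *peak* is the mean strut-peak height, *trough* the HU minimum in
  the gap and *minimum* the soft-tissue background.

Systems are compared with a paired t-test (continuous metrics) and a
Wilcoxon signed-rank test (ordinal 1–5 reader scores, simulated from the
measured image quality); reader reliability is summarized with the
two-way mixed consistency ICC for the mean of two raters, ICC(C,2).

See `docs/methods.md` for the full model description and its limitations.

## Worked example

```python
from stentbench import preset_config, run_experiment, ExperimentConfig
from stentbench.pipeline import pooled_means

result = run_experiment(ExperimentConfig(master_seed=1))
print(pooled_means(result.measurements.query("metric != 'diameter_mm'"))
      .round(3).to_string(index=False))
```

prints (seed 1, default configuration):

```
         metric  fov  system   mean    sd  n
   abs_error_mm   50   eidct  0.027 0.014 12
   abs_error_mm   50 si_pcct  0.007 0.006 12
   abs_error_mm  150   eidct  0.044 0.021 12
   abs_error_mm  150 si_pcct  0.021 0.021 12
   blooming_pct   50   eidct 32.866 4.725 12
   blooming_pct   50 si_pcct 18.204 2.882 12
   blooming_pct  150   eidct 36.006 5.273 12
   blooming_pct  150 si_pcct 20.156 3.154 12
distinction_pct   50   eidct 40.830 0.385  3
distinction_pct   50 si_pcct 88.853 0.367  3
distinction_pct  150   eidct 27.618 0.545  3
distinction_pct  150 si_pcct 84.984 0.651  3
```

Each row pools one metric over stents × locations for one system at one
reconstruction FOV. The photon-counting presets measure diameters about
twice as accurately, show roughly half the blooming, and keep the two
femoral stents clearly separable (85–89% distinction vs 28–41%) — the
sharper detector wins on every metric at both FOVs, and
`result.report` carries the paired-test p-values and ICCs that quantify
it.

The same experiment is available from the shell:

```bash
stentbench run-all --seed 1 --out run/
# or stage by stage, producing identical artifacts:
stentbench image --seed 1 --out run/
stentbench measure --run-dir run/
stentbench compare --run-dir run/
```

which writes the reconstructed volumes (NIfTI), tidy per-location and
per-line CSVs, simulated reader scores, the summary report (CSV + JSON)
and a run log with every seed and the config hash.

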