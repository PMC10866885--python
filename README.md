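# rtkquant

Quantitative analysis of receptor tyrosine kinase (RTK) behaviour at the
plasma membrane from fluorescence microscopy, built around three assays used
to study how VEGF receptors are activated:

1. **Single-cell dose–response** — transient transfection produces cells
   spanning a wide range of receptor surface density. Per cell, the membrane
   intensity of the expression channel (mCherry-tagged receptor) and of the
   phospho-tyrosine channel (FITC immunostain) is measured from a pair of
   hand-drawn ROIs as `I_m = I_ROI1 − I_ROI2` (whole cell minus interior).
   Cells are binned by expression, and the phospho-vs-expression relation is
   fitted with a linear model (ligand-dependent activation: phosphorylation
   proportional to receptor density) against a nested quadratic model
   (ligand-independent activation: supra-linear rise above a critical
   density), selected by an F-test. Slope ratios between constructs give the
   relative fraction of receptor phosphorylated.
2. **Confocal FRAP** — a 1.2 µm spot on the membrane is photobleached and
   the recovery by lateral diffusion timed. After background and photofading
   correction,
   `F_corrected(t) = (F_ROI − F_bg) / (F_total − F_bg)`, normalised to the
   prebleach level, the recovery is fitted with
   `f(t) = offset + A(1 − e^(−kt))`, `k = 0.69 / t_half`. With the effective
   bleach radius `r_e` measured from the Gaussian profile of the first
   post-bleach frame, the diffusion coefficient follows the modified
   Soumpasis relation `D_confocal = 0.25 · r_e² / t_half`. Slower
   `D_confocal` indicates a larger oligomer; samples are classified
   monomer-like or dimer-like against control populations by t-tests.
3. **Phosphorylation kinetics** — densitometric time courses after ligand
   stimulation are max-normalised; the rise rate is the 0-to-peak linear
   slope (arb. units/min), the decay half-life comes from an exponential
   anchored at the observed peak, and responses are classified transient
   versus sustained with censoring (`t_half > window`) when the signal never
   falls to half its peak inside the observation window.

A particle-based Brownian-dynamics simulator (2-D periodic membrane patch,
Gaussian confocal bleach, photofading, shot noise), a two-channel cell
population renderer with configurable activation laws, and a rise/decay
time-course generator provide synthetic inputs with known ground truth for
every pipeline.

The fitting cores are scikit-learn style estimators
(`RecoveryCurveFitter`, `BleachProfileFitter`, `ActivationModelSelector`,
`KineticsFitter`) with `fit`, `get_params`/`set_params` and fitted
attributes; the module-level functions named above are thin wrappers.

## Worked example

Simulate one FRAP acquisition at D = 0.02 µm² s⁻¹ and run the full
analysis:

```sh
$ frap-simulate --d 0.02 --seed 5 --out demo
wrote demo_traces.csv and demo_profile.csv
$ frap-fit --traces demo_traces.csv --profile demo_profile.csv --out demofit
          trace        A        k  t_half_s  t_half_full_s   offset  residual_sd  no_recovery   r_e_um  D_confocal_um2_s  r_e_below_nominal
demo_traces.csv 0.371805 0.045245 15.250376      17.438053 0.594217      0.04275        False 1.170512            0.0196               True
```

The spot fell to 0.59 of its prebleach level, recovered with amplitude 0.37
and rate k = 0.045 s⁻¹, and the fitted curve crosses half of full recovery
at 17.4 s; with the measured effective radius r_e = 1.17 µm this gives
`D_confocal = 0.25 · r_e²/t_half = 0.0196 µm² s⁻¹`, within 2% of the
simulated truth.

Kinetics on a synthetic slow-phosphorylating receptor (rise 0.07 min⁻¹,
decay half-life 14 min):

```sh
$ simulate-timecourse --rise-slope 0.07 --t-half 14 --seed 2 --out tc.csv
$ kinetics-fit --table tc.csv --window 60 --out kin.csv
construct  rise_rate  rise_rate_se    t_half  censored  peak_time     class
synthetic   0.069843      0.003174 13.446506     False       15.0 transient
```

The rise rate and decay half-life are recovered within the noise and the
response is classified transient (uncensored half-life below half the
60-min window).

The other entry points are `quantify-cells` (per-cell membrane intensities,
binning, activation-model selection from TIFF images + ROI JSON) and
`simulate-cells` (synthetic two-channel populations with ground truth).

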