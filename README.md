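# escrt-kinetics

Quantification of ESCRT recruitment dynamics at HIV Gag budding sites in
high-speed TIRF movies, together with a synthetic-data generator that makes
every stage of the analysis testable without real microscopy data.

The analysis pipeline:

1. **Detection** — difference-of-Gaussians spot detection with subpixel
   centroids on the Gag reference channel (imaged only at the start and end
   of the record); stationary start/end pairs become event sites, which are
   colocalized with the ESCRT channels.
2. **Photometry** — aperture photometry (circular aperture, median-of-annulus
   local background, Gaussian encircled-energy correction) yields per-site
   intensity traces; a cohort is normalized by a single scalar so the mean of
   per-trace maxima equals 10000 a.u.
3. **Kinetics** — each trace is segmented into three phases (sigmoidal
   assembly, plateau, sigmoidal disassembly) and each sigmoidal phase is fit
   with the Boltzmann growth equation
   `I(t) = A1 + (A2 − A1)/(1 + exp(−(t − t0)/dx))`. Derived per event:
   assembly/disassembly rates (max slope `(A2−A1)/(4·dx)`, a.u./s), retention
   time (90%-of-range assembly completion to 90% disassembly onset), and total
   assembly time (10→90% rise, `ln(81)·dx`). Traces with no decline before the
   record ends are flagged locked (censored retention).
4. **Phenotyping** — events are classified by the late-minus-early
   disassembly-onset delay (delayed late channel vs co-disassembly vs locked);
   cohorts are summarized and conditions compared by the fold change of mean
   normalized maxima with a bootstrap interval (WT vs ATP-depleted requires a
   shared normalization scale).

The **synthetic-data module** renders cohorts of stationary sub-diffraction
spots (integrated Gaussian PSF, Poisson + Gaussian camera noise) whose
three-phase kinetics are drawn from the published condition summaries
(plateau 4900 ± 1300 a.u. WT vs 9900 ± 3300 a.u. under ATP depletion,
late-channel retention 15 s, 10 s assembly time, 80/20 phenotype mixture,
300 frames at 0.2 s — or one frame per 5 s for ATP protocols).

## CLI

```bash
# render a synthetic cohort (TIFF stacks + ground-truth CSV + config JSON)
escrt-kinetics simulate --n-events 10 --condition WT --seed 7 --out sim/

# stage by stage
escrt-kinetics detect --gag sim/gag.tif --out sites.csv
escrt-kinetics traces --gag sim/gag.tif --early sim/early.tif --late sim/late.tif --out run/
escrt-kinetics fit --traces run/traces.csv --out run/fits.csv
escrt-kinetics report --fits run/fits.csv --out run/

# or end-to-end from a YAML config
escrt-kinetics run --config pipeline.yaml --out results/

# simulate + analyze + score parameter recovery against ground truth
escrt-kinetics benchmark --n-events 20 --seed 1 --out bench/
```

`traces --shared-scale other/scale_factors.json` reuses another cohort's
normalization factors, which is required when comparing intensities across
conditions (e.g. WT vs ATP-depleted).

Python API: see `escrt_kinetics` top-level exports (`simulate_cohort`,
`render_movie`, `detect_spots`, `extract_trace`, `normalize_traces`,
`analyze_trace`, `classify_event`, `compare_conditions`,
`run_pipeline_on_movies`, `run_synthetic_benchmark`, ...).

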