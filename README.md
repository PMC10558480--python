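# seasonfc

Seasonal-variation analysis of resting-state brain activity: from
region-averaged BOLD time series to fALFF, gray-matter/white-matter
functional connectivity, quarter-coded cosinor periodicity inference,
environmental-covariate regression, and binary-graph network topology —
with a synthetic cohort simulator so the whole chain is testable end to
end without any imaging data.

## Who this is for

Resting-state fMRI studies that pool subjects scanned across the year face
a quiet confound: measures of spontaneous brain activity drift with the
seasons. `seasonfc` implements the analysis needed to quantify that drift
on a four-season cohort of region-averaged signals, and ships a simulator
that injects a *known* seasonal effect so every stage of the pipeline can
be validated against ground truth.

## The measures and the model

Given timepoints × regions matrices (gray-matter regions and white-matter
bundles, TR-sampled):

- **fALFF** — per region, a Welch power spectrum of the normalized,
  *unfiltered* signal; fALFF is the fraction of power above 0.01 Hz lying
  in the 0.01–0.08 Hz band. Subject-level summaries are the means over GM
  and over WM regions.
- **Functional connectivity** — Pearson correlation between
  bandpass-filtered (0.01–0.1 Hz), unit-variance region signals;
  Fisher-Z transformed (z = artanh r) and summarized as mean |Z|
  globally (GM–WM), within tissue (GM–GM, WM–WM), per functional-network
  submatrix of the WM × GM matrix, and per GM region averaged over WM.
- **Network topology** — each square correlation matrix (GM–GM, WM–WM,
  GM ∪ WM) is thresholded at r = 0.2 and binarized; the graph is
  summarized by density, transitivity tr(X³)/(Σᵢⱼ(X²)ᵢⱼ − tr(X²)),
  global efficiency ⟨1/dᵢⱼ⟩, and characteristic path length over
  reachable pairs.
- **Seasonal inference** — with acquisition quarters coded
  t = 0,1,2,3 (winter → autumn) and ω = 2π/4, every sex-adjusted measure
  y is fit per subject as

      y(t) = A·cos(ωt + ϑ) + c = a·sin(ωt) + b·cos(ωt) + c,

  and the joint F-test of (a, b) with df (2, n−3) quantifies annual
  periodicity; one-way season ANOVA (Cohen's f), pooled-t pairwise
  contrasts (Cohen's d), and an OLS regression on season-year mean
  temperature and daylength complete the battery.

## Worked example

```python
import seasonfc as sf

sim = sf.SimulationConfig(
    n_per_season=(30, 25, 23, 24), n_gm_regions=12, n_wm_regions=8,
    n_networks=3, n_timepoints=512, loading_scale=1.2, noise_sd=0.8,
    amp_true=0.25, phase_true=sf.autumn_peak_phase(), seed=42,
)
cfg = sf.PipelineConfig(simulation=sim, threshold_mode="absolute",
                        transitivity_zero_denominator="zero",
                        make_figures=False, seed=42)
bundle = sf.run_pipeline(cfg)
fit = bundle.stats["fc_gm_wm"]["cosinor"]
```

The simulated cohort carries a 25% autumn-peaking gain on its shared
low-frequency component. The run prints, for global GM–WM mean |Z|:

```
global GM-WM mean |Z|: ANOVA F=8.958, p=0.0000, Cohen's f=0.524
cosinor: A=0.0310, phase=1.577 rad, F=13.50 (df (2, 99)), p=6.54e-06
fitted peak quarter: autumn
summer vs autumn: t=-2.707, p=9.56e-03, d=-0.790
 measure season  n     mean      sem
fc_gm_wm winter 30 0.629617 0.006549
fc_gm_wm spring 25 0.601478 0.009333
fc_gm_wm summer 23 0.629657 0.008898
fc_gm_wm autumn 24 0.663454 0.008756
```

The fitted phase ϑ ≈ π/2 places the cosine peak at t = 3 — the injected
autumn maximum — the periodicity F-test is decisive, and the pairwise
contrast (ordered summer, autumn, hence the negative sign) confirms autumn
connectivity exceeds summer. Group means show the autumn peak directly.

A thin CLI wraps the same functions:

```bash
seasonfc simulate --out cohort/                 # write a synthetic cohort
seasonfc run --config pipeline.json             # full analysis to disk
seasonfc metrics --cohort cohort/ --out m.csv   # graph metrics only
seasonfc report --results results/              # significant effects
```

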