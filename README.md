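# lowpet

Low-injected-activity dynamic brain PET: frame-truncation count reduction,
reference-tissue quantification, and agreement statistics.

## The problem

Reducing the injected activity of a PET radiopharmaceutical is desirable
(ALARA, paediatric and longitudinal imaging) but reduces detected
coincidences and therefore degrades quantification. A practical way to
study this without re-scanning anyone is to re-bin list-mode data: insert a
delay at the start of every acquisition frame and keep only the tail, so a
fraction *f* of the events survives while the frame grid is preserved. The
question is how the standard outcome measures of dynamic brain PET —
the binding potential **BP_ND** from the simplified reference tissue model
(SRTM) and the standardised uptake value ratio **SUVR** — behave as *f*
shrinks.

`lowpet` implements that whole experiment as a reusable, tested pipeline
for two tracer settings: a D2/D3-receptor tracer quantified with SRTM
against the cerebellum, and a synaptic-density (SV2A) tracer quantified
with SRTM and SUVR against the centrum semiovale pseudo-reference. Because
the underlying human scans are not public, the package ships a synthetic
cohort generator with the same statistical structure (90-min, 31-frame
schedule; C-11 decay; Poisson frame counts that scale with the retained
window), plus ingestion of user-supplied regional TAC tables in a
documented CSV dialect.

## The model

The acquisition is binned into 31 frames (8 × 15 s, 3 × 60 s, 5 × 120 s,
15 × 300 s; 90 min total). Seven published truncation schemes (1/2 … 1/15)
map each original frame duration to a retained duration and delay; the
lookup is stored verbatim because its rounding is not uniform.

SRTM expresses a target-region curve through the reference curve:

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · (C_R ⊗ e^{−k2a t}),
    k2a = k2 / (1 + BP_ND)

and is fitted by a basis-function search over `k2a` (100 log-spaced nodes
in [0.006, 0.6] min⁻¹, linear solve for the other two parameters, bounded
1-D refinement). SUVR is the duration-weighted mean concentration of the
target over a late window (default 60–90 min) divided by that of the
reference.

Each low-activity dataset is compared with the full-activity dataset per
region: coefficient of variation across subjects, signed mean paired bias,
Bland–Altman limits of agreement, and a normality-gated test (one-way
ANOVA with Bonferroni-corrected scheme-vs-full comparisons when every
group passes Shapiro–Wilk and Levene; Kruskal–Wallis with corrected
rank-sum follow-up otherwise).

## Worked example

Simulate a paired 5-subject SV2A-tracer cohort at full activity and at
1/15 of the activity, then fit SRTM for one subject's striatum:

```python
from lowpet import NoiseModel, make_cohort, fit_srtm, compute_suvr

cohort = make_cohort("UCBJ", 5, ["full", "1/15"], NoiseModel(seed=42))
ds = cohort["1/15"][0]
res = fit_srtm(ds.tacs["striatum"], ds.tacs["centrum_semiovale"])
print(res.summary())
```

```
SRTM fit results
==============================================
target region:                     striatum
reference:                centrum_semiovale
frames:    31    weights: uniform
WRSS: 16462    converged: True
negative BP_ND flag: False
----------------------------------------------
param             estimate       std err
r1                 0.59299          0.54
k2_per_min         0.23821         0.127
bp_nd               2.7103         0.641
k2a_per_min       0.064202        0.0407
==============================================
```

At 1/15 of the counts the fit still converges here, but the estimate has
drifted from this subject's true BP_ND of 2.828 and the standard errors
are wide — exactly the degradation the experiment quantifies. The full
experiment (simulate → truncate → fit → summarise) is one call:

```python
from lowpet import ExperimentConfig, run_experiment
from lowpet.stats import pivot_bias_table

cfg = ExperimentConfig(seed=12345, tracer="UCBJ", n_subjects=5,
                       outcomes=["BPnd"],
                       scheme_labels=["full", "1/2", "1/5", "1/15"])
res = run_experiment(cfg)
print(pivot_bias_table(res.summary, "BPnd").head(6))
```

```
scheme_label       1/2     1/5    1/15
region
accumbens        0.059   0.294   0.488
brainstem        0.059   0.114   0.256
caudate          0.040   0.179   0.295
cerebellum      -0.003   0.128   0.607
frontal_cortex  -0.006   0.059   0.405
hippocampus     -0.022   0.081   0.033
```

Each entry is the mean paired difference (low-activity BP_ND minus
full-activity BP_ND) across subjects: bias grows as the retained activity
fraction shrinks.

The same pipeline is available from the shell:

```sh
lowpet scheme show 1/15          # print the truncation lookup
lowpet config init -o cfg.yaml   # write all defaults
lowpet run --config cfg.yaml --out results/
lowpet simulate --seed 6 --tracer PHNO --subjects 5 --out work/
lowpet fit work/tacs --out work/outcomes.csv
lowpet stats work/outcomes.csv --out work/summary.csv
```

## Layout

- `lowpet.framing` — frame schedules, the truncation lookup, mid-time
  conventions
- `lowpet.simulate` — plasma input, reference/target forward models,
  Poisson frame counting, paired cohorts
- `lowpet.kinetics` — `SRTM` model / `SRTMResults`, SUVR
- `lowpet.stats` — CV, bias, Bland–Altman, gated group comparison
- `lowpet.experiment` — configuration, orchestration, dataset CSV/JSON I/O
- `lowpet.cli` — command-line interface

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
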