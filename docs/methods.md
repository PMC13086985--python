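# Methods

## Scope and design

`lowpet` studies how reference-tissue outcome measures of dynamic brain
PET degrade when the injected activity is reduced. The count reduction is
emulated the way a list-mode re-binning does it: every acquisition frame
keeps only its tail (a delay is inserted at the frame start), so events
rejected for one activity fraction are rejected consistently for all of
them and datasets are paired within subject. The package operates entirely
on regional time–activity curves (TACs); there is no image domain — no
voxels, reconstruction, attenuation, scatter, randoms or motion.

## Frame schedule and truncation schemes

The full acquisition is 31 contiguous frames over 5400 s
(8 × 15 s, 3 × 60 s, 5 × 120 s, 15 × 300 s). The seven low-activity
schemes (labels 1/2, 1/3, 1/4, 1/5, 1/6, 1/10, 1/15) are stored as a
verbatim lookup from original frame duration to (retained duration,
delay). The lookup is intentionally *not* derived from a rounding rule:
the published scheme rounds inconsistently across rows (15 s at 1/2 keeps
7 s, at 1/4 keeps 4 s), and fidelity to the printed scheme was preferred
over an inferred rule. Consequently the total retained time equals
`f × 5400 s` exactly only for the 1/3 and 1/5 rows; all invariants are
asserted against the stored table, not the idealised product. For
fractions outside the eight labels, `make_custom_scheme` uses
`max(1 s, round(duration × f))` — an extension, never applied to the
canonical labels.

### Mid-time conventions

A truncated frame's data physically live in the retained window
`[start + delay, start + duration]`. Two conventions are exposed for the
mid-time recorded in the TAC:

- `retained_window` (default): mid-time of the retained window,
  `start + delay + retained/2`. This is the physically correct timestamp.
- `original_frame`: the full-frame mid-time `start + duration/2`. This
  reproduces the timing bias a truncation-based re-reconstruction incurs
  when the frame-timing metadata is left untouched: late-window data are
  modelled as if acquired earlier, which biases kinetic fits. With noise
  disabled this bias is purely systematic and therefore seed-independent;
  the test suite pins both properties.

## The synthetic cohort generator

The generator's purpose is to produce TACs with the statistical structure
the low-activity analysis rests on, not to reproduce any particular
subject.

**Plasma input.** A tri-exponential bolus model
`Cp(t) = (A1·τ − A2 − A3)e^{l1 τ} + A2 e^{l2 τ} + A3 e^{l3 τ}`,
`τ = t − t0`, zero before the appearance delay `t0`. Defaults
(A1 = 851.1 kBq mL⁻¹ min⁻¹, A2 = 21.9, A3 = 20.8 kBq mL⁻¹,
l1 = −4.1339, l2 = −0.1191, l3 = −0.01043 min⁻¹, t0 = 0.5 min) are a
conventional bolus shape. The input exists only so that a realistic
reference curve can be generated; no arterial model is used for
quantification.

**Reference region.** One-tissue kinetics,
`C_R = K1′ · (Cp ⊗ e^{−k2′ t})`. Defaults: cerebellum
K1′ = 0.35 mL cm⁻³ min⁻¹, k2′ = 0.15 min⁻¹; centrum semiovale (white
matter, lower flow) K1′ = 0.15, k2′ = 0.12.

**Target regions.** SRTM forward model per region. The per-region truth
values (R1 ≈ 0.85–1.45, k2 ≈ 0.28–0.36 min⁻¹; BP_ND ≈ 0.45–2.5 for the
D2/D3 preset, 1.6–3.4 for the SV2A preset) are implementer-chosen
plausible values — they are configuration defaults, not measurements, and
nothing in the package value-matches against them; all validation is
recovery- and property-based. Per subject, truth parameters receive mild
lognormal biological jitter (CV 10% on BP_ND, 5% on R1 and k2) and the
injected activity is drawn from the tracer preset's normal distribution
(134.2 ± 20.3 MBq and 228.6 ± 58.3 MBq), scaling the input amplitude.

**Count noise.** Noise is Poisson at the frame-count level, not Gaussian
on concentration, because the physical consequence of a reduced injected
activity is fewer detected coincidences. Expected counts in a window are

    μ = S · ∫_window C(t) · e^{−λt} dt,

with C the decay-corrected concentration, λ the C-11 decay constant
(half-life 20.38 min = 1223 s) and S an effective scanner sensitivity in
counts per (kBq mL⁻¹ s). The decay-corrected concentration is recovered
as `counts / (S ∫_window e^{−λt} dt)`, which is unbiased for the
decay-weighted mean concentration over the window.

S is the one genuinely free parameter: injected activities map to
region-level counts only through scanner, reconstruction and
region-of-interest specifics that are not modelled here. The default
S = 0.05 was calibrated once so that the simulated dispersion matches the
reported magnitudes for this experimental design — full-activity BP_ND
CVs in the 10–20% range and low-activity CVs growing into the tens of
percent — and then frozen. It should be read as a noise-equivalent
sensitivity of a modest region-of-interest TAC, not a hardware constant.

**Pairing across fractions.** Per subject and region, expected counts are
laid out on a 1-s micro-grid over the whole acquisition and a single
Poisson draw is made. Every scheme then sums the *same* micro-draws over
its retained windows. This honours the consistently-rejected /
consistently-included property of list-mode delays: a reduced dataset's
frame counts can never exceed the full dataset's, and fraction datasets
differ only through the retained windows and the shared noise
realisation, never through truth parameters. Because pairing requires one
draw per (subject, region), sub-seeds are derived per subject and region
(via `numpy` seed sequences from the master seed); schemes deliberately
share them.

**Noise modes.** Three modes are exposed: `poisson` (draws), `expected`
(deterministic expected counts, hence window-averaged concentrations) and
`none` (the continuous model concentration sampled at the retained-window
mid-time; no counts). `none` is the idealised noise-free limit used by
the null analyses; `expected` preserves the counting chain without
variance.

**Thinning oracle.** `thin_counts` replaces each frame count by a
Binomial(count, f) draw — an independent count-reduction mechanism used
to cross-validate the truncation simulator: for constant activity and no
decay the two agree in expectation at the exact-fraction rows.

## Quantification

**SRTM.** Basis-function estimation: for each candidate `k2a` on a
100-node log-spaced grid spanning 0.006–0.6 min⁻¹ (brackets plausible
apparent efflux for both tracer settings; configurable), the model is
linear in `(R1, φ = k2 − R1·k2a)` and solved by weighted least squares;
the best node is refined by bounded 1-D minimisation (objective tolerance
1e-8; ties broken toward the lowest `k2a`). The reference curve is
reconstructed on a 1-s grid by a cubic spline through the frame samples,
anchored at `C_R(0) = 0` with zero slope, and all convolutions use an
exact piecewise-linear-by-exponential recursion (O(n), no large
exponentials). Weights are uniform by default; `duration` weights
(∝ frame duration) are provided because regional-analysis packages
differ on this and neither choice is canonical.

Fits return estimates with approximate Gauss–Newton standard errors
(delta method for BP_ND), the weighted residual sum of squares,
a convergence flag (false when the optimum pins to a grid boundary with a
non-flat objective) and a `negative_bp_flag`. Negative fitted BP_ND is a
real phenomenon of low-count reference-tissue fitting — truth values are
non-negative by construction, fitted values need not be — and the flag
lets downstream analyses count such fits rather than hide them.

**SUVR.** Duration-weighted mean concentration of the target over frames
whose mid-times fall in the window, divided by the same for the
reference. The default window is 3600–5400 s (60–90 min), a late-scan
pseudo-equilibrium convention for these tracers; it is configurable
because the convention is not universal.

Noiseless forward-simulated TACs are recovered to ~1e-5 relative error in
all three SRTM parameters (the test suite asserts 1e-3 across the
documented truth ranges), and both outcomes are exactly invariant under
joint rescaling of target and reference.

## Statistics

Per (outcome, region, scheme): CV = 100 × sample SD / mean (n−1
denominator throughout, matching common statistical-package defaults);
signed mean paired bias versus the full-activity dataset (negative biases
are meaningful and preserved; absolute display is presentation only);
Bland–Altman mean difference with mean ± 1.96 × SD limits of agreement
(the mean difference equals the bias exactly, by construction and by
test).

Significance testing is gated: if every scheme's group passes
Shapiro–Wilk (p > 0.05) *and* Levene's test across groups passes
(p > 0.05), a one-way ANOVA is used with Bonferroni-adjusted pairwise
scheme-vs-full t-tests; non-normality in any group or variance
heterogeneity routes to Kruskal–Wallis with Bonferroni-adjusted pairwise
rank-sum follow-up. The conservative OR-gate is a design choice where the
underlying reporting is ambiguous about which family applied when. The
Bonferroni factor m is the number of scheme-vs-full comparisons (7 for
the full design); adjusted p = min(1, m × raw p). α = 0.05, two-sided,
throughout. Subjects are treated as a one-way (not repeated-measures)
factor; with the paired Bland–Altman/bias analyses alongside, this is the
more conservative choice and a possible divergence from the original
analysis. Groups smaller than n = 3 get CV/bias/Bland–Altman but no test
(p reported as missing); constant groups short-circuit to p = 1 rather
than feeding degenerate input to the tests.

## Numerical choices

- Fine grid: 1-s steps over 0–5400 s for all quadrature; forward-model
  accuracy ~0.1% against independent ODE and trapezoidal-convolution
  oracles (asserted in tests).
- Micro-bin counting uses bin centres with overlap weights, so retained
  windows aligned to integer seconds (all canonical schemes) are summed
  exactly and the truncation/thinning expectation identity is exact for
  constant activity.
- The tri-exponential input cancels exactly at onset; the float residue
  is clamped to zero. Decay constant λ = 0 is allowed (turns decay
  weighting off), which makes count expectations exactly proportional to
  retained time.
- Degenerate inputs: an identically-zero reference is rejected; a target
  equal to the reference fits to BP_ND = 0, R1 = 1 regardless of the
  (unidentified) `k2a`.

## What the generator does and does not emulate

It emulates: the frame schedule and truncation geometry, C-11 decay,
fraction-scaled Poisson counting with within-subject pairing,
between-subject biological variability, and SRTM-consistent kinetics.

It does not emulate: image reconstruction (OSEM bias and variance at low
counts), region-of-interest size (a single scalar sensitivity treats all
regions as equally count-rich), partial-volume effects, motion, scatter,
randoms or dead time. Two consequences matter for interpreting results:

1. **Noise-free null floor.** With noise disabled and retained-window
   mid-times, every scheme's outcomes should equal the full-activity
   outcomes. They do — up to the information limit of 31-frame sampling.
   The retained-window mid-times genuinely shift between schemes, so the
   fit reconstructs the reference curve from samples at different
   times (BP_ND residual ~2e-5) and the SUVR window averages samples
   taken up to ~2.3 min later within each late frame (residual ~2e-3,
   about 0.05% of the SUVR value). These floors are reported by the
   acceptance script and pinned by tests; they are properties of frame
   sampling, not implementation error.
2. **SUVR stability at very low fractions.** In image data, late-window
   region means pool many voxels and remain stable even at 1/15 of the
   counts, which is why SUVR is reported as the robust outcome. A single
   scalar sensitivity cannot reproduce that: at the calibrated S the
   late retained windows at 1/15 hold only a few counts, so the simulated
   SUVR becomes noisier than the fitted BP_ND. The package therefore
   demonstrates SUVR's *expectation*-level robustness (its noise-free
   value is nearly scheme-invariant) but not its empirical variance
   advantage; modelling the latter would require region-volume or
   image-domain noise structure, which is out of scope.

## Problem sizes

The shipped analyses use cohorts of 5 subjects (SV2A preset, 13 regions)
and 10 subjects (D2/D3 preset, 8 regions) across all eight schemes —
520 and 640 fits respectively — which reproduce the qualitative findings
(bias grows monotonically toward 1/15; negative-BP fits appear at very
low fractions for low-binding regions) in seconds on one CPU. Monte-Carlo
checks (type-I behaviour: 300–400 replicates of 8 groups × n = 10;
estimator unbiasedness: 200–300 replicates) are sized to give standard
errors comfortably below the effects they bound.
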