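# Methods

## Scope and data model

The package treats a ripening trial as a factorial design: maturity
group at harvest (A mature green, B breaker, C turning, D pink, E light
red, F full red) × treatment arm (control vs gaseous 1-MCP, "SF") ×
storage day, with ~20 fruits per group and arm over a two-week window.
Group F is an absolute control: fully ripe at harvest and never
treated. The statistical unit is the fruit-day; features are the
colorimeter green–red coordinate a*, the DA chlorophyll index, acoustic
stiffness, and the machine-vision descriptors (mean/normalized RGB and
the two PQS coordinates).

## Image chain

**White balance.** Per-channel gains map the median of the white
region (supplied, or auto-detected as saturation ≤ 12 % and value
≥ 0.65) to a common reference level of 240 — just below the 8-bit
ceiling so gains above 1 do not clip. The white region must contain at
least 100 pixels and no zero-median channel; violations raise with the
offending channel named.

**HSV.** Standard hexcone conversion (scikit-image); hue reported in
degrees [0, 360), saturation in percent [0, 100]. Achromatic pixels get
hue 0 and saturation 0; they can never pass the saturation threshold,
so the convention is inert downstream.

**Saturation threshold.** Otsu's criterion on the integer-percent
histogram (101 bins). Ties in the between-class variance — systematic
for two-level histograms — are resolved to the midpoint of the optimal
plateau. If the two classes the threshold induces have mean saturations
closer than 5 points, the histogram is judged unimodal (a
background-only frame) and segmentation is refused rather than
returning a noise split; a fixed threshold can be configured instead.
The ROI is strictly-above-threshold, so glare and gray background are
excluded by construction.

**Hue spectrum.** 1° bins (360 of them), circular indexing, each ROI
pixel contributing its saturation. `raw_sum` conserves total ROI
saturation exactly and is used in conservation tests; `per_pixel`
(default for analysis) divides by ROI pixel count so fruit size and
count do not confound the spectrum scale.

## PQS gravity point

The spectrum is read as a piecewise-constant polar curve r(θ) and
summarized by the area centroid of the enclosed region, computed
sector-exactly: A = ½Σr²Δθ, X = (1/3A)Σr³cosθΔθ, Y = (1/3A)Σr³sinθΔθ,
with θ at bin centers. Closed-form anchors used in tests: a constant
full-circle spectrum maps to the origin; a half-disk to (4/3π, 0); a
single thin sector to (2r/3)(cos θ, sin θ). At 1° bins the midpoint
rule carries an irreducible relative bias Δθ²/24 ≈ 1.3 × 10⁻⁵, which
the tests assert as a bound; refinement to 0.1° bins reaches 10⁻⁶
absolute agreement. An independent Monte-Carlo oracle (rejection
sampling in the bounding disk) cross-checks the closed form to within
three standard errors.

**Axis orientation.** The pipeline default is raster ("screen")
orientation — y pointing down, equivalently Y = −(1/3A)Σr³sinθΔθ.
This is a deliberate design choice: with hue running 110° (green) →
60° (yellow) → 8° (red) during ripening, the mathematical convention
makes PQS-Y *fall* with ripening, whereas quality work reports the PQS
Y coordinate co-varying positively with redness measures (strong
positive association with a*, negative with normalized green). Screen
orientation reproduces that empirical sign structure while changing
nothing else (X is identical; rotation/scale/mirror properties hold in
both). `orientation="math"` is available wherever textbook geometry is
wanted.

**Scaling.** PQS is applied to the `per_pixel` spectrum: the gravity
point is degree-1 homogeneous in the spectrum scale, so a raw-sum
spectrum would confound fruit area with color. An optional hue arc
restricts the centroid to an informative segment; the default is the
full circle.

## Instrument indices

I_AD = A₆₇₀ − A₇₂₀ (chlorophyll-a absorption peak minus reference).
Values outside the meter's 0–5 range are flagged, never clamped —
clamping would destroy the index's antisymmetry in its arguments.
Stiffness S = scale · f² · m^(2/3) with f in Hz and m in g. With raw Hz
the quantity is of order 10⁵–10⁶ for fruit-sized resonators, while
bench instruments report 2–8 g^(2/3) s⁻²; the default instrument scale
10⁻⁶ (f effectively in kHz) maps to the reported band without altering
the formula, and is configurable.

## Statistics

* **ANOVA**: fixed-effects OLS with sum-to-zero contrasts and Type III
  sums of squares (the SPSS convention this workflow is usually run
  under), supporting 2–3 factors with user-selected pairwise
  interactions; the shipped design is group × treatment × day with all
  pairwise terms and no three-way term. Constant responses report
  F = 0; perfect fits report F at the float cap rather than infinity.
  Requested interactions with an empty design cell fail naming the
  cell — which is why group F is excluded from any design containing
  the treatment factor.
* **Levene** (center = mean by default, median available) routes each
  response: homogeneous variances → Tukey HSD (studentized range,
  Tukey–Kramer for unequal n); heterogeneous → Games–Howell (Welch t,
  Welch–Satterthwaite df, studentized-range reference via q = t√2).
  Games–Howell accepts either raw samples or (mean, SD, n) summaries,
  so published tables can be re-analyzed directly.
* **Compact letters**: insert-and-absorb; levels connected by adjusted
  p ≥ α share a letter. α = 0.05 throughout.
* **Correlations**: Pearson and Spearman with pairwise-complete rows
  and two-sided p; Spearman is the primary cross-instrument panel
  because chlorophyll decay is saturating, hence monotone but
  nonlinear in the color coordinates.

When reconstructing published day-14 letter displays from summary
statistics, the per-cell sample size is n = 40 readings (20 fruits × 2
measurement points per fruit, the published protocol). This choice is
load-bearing: at n = 20 (fruit-level averaging without the reported
SDs shrinking correspondingly) several published borderline splits —
a* control C vs D, treated D vs E, DA-index B vs C — fall below
significance, and the test suite documents that sensitivity
explicitly.

## Synthetic study generator

Each fruit carries a latent ripeness u ∈ [0, 1] following a logistic
curve u(t) = 1/(1 + ((1−u₀)/u₀)e^(−kt)) with group starting points
u₀ = 0.02, 0.10, 0.25, 0.45, 0.65, 1.0 (A–F) and base rate
k = 0.45 d⁻¹. 1-MCP multiplies k by (1 − ρ·e_g), ρ = 0.9, with group
efficacies e = 1.0, 1.0, 0.6, 0.3, 0.2 (A–E): strongest for
mature-green and breaker fruit, which have not passed their climacteric
ethylene peak. Observables derive monotonically from u:

* a* = −15 + 41·u + N(0, 2²) — spans the observed green-to-red band;
  noise-free day-14 values put group-A control above +15 and group-A
  treated below 0, the published sign split;
* DA = 1.32·e^(−6.1u) + N(0, 0.02²), floored at 0 — initial values
  span ~1.3 (mature green) down to ~0.003 (full red), and the floor
  mirrors the physical impossibility of negative chlorophyll;
* S = 1.8 + (S₀ − 1.8)(1 − u)·e^(−0.02t) + N(0, 0.3²), S₀ ~ U(5, 8) —
  monotone softening from the published initial band toward the 2–4
  end-of-storage band, with a slow u-independent senescence term;
* surface hue 115° − 107°·u, saturation 45 + 25·u %.

Masses are N(110, 5²) g clipped to 100–120 g; resonance frequency is
back-derived from S and mass so the readings CSV is self-consistent.
Sampling days default to 0, 2, 5, 7, 9, 12, 14.

**Rendering.** A fruit disk (default 40 px diameter in a 64 px frame)
with wrapped-normal hue (σ = 6°) and truncated-normal saturation
(σ = 8, clipped to ≥ 20 %) on a near-white background (≤ ~6 %
saturation), optional color cast (exercising white balance) and a
specular glare spot rendered near-white. The returned tally is the
per-degree saturation mass of the final quantized 8-bit frame over the
true fruit mask, computed at generation time with the package's own
HSV conversion: 8-bit quantization makes an independently-coded
conversion disagree at exact bin boundaries (e.g. hue 60° whenever
R = B), so the renderer's bookkeeping shares the conversion and the
conservation tests exercise mask, binning and accumulation. The HSV
conversion itself is validated separately against analytic hexcone
anchors.

**What the generator does not emulate.** Lighting gradients and
shadows, fruit-to-fruit shape/texture variation, camera noise and JPEG
chroma artifacts, multi-fruit frames with touching fruit, spoilage
events, and any mechanistic ethylene biochemistry. Passing tests
therefore demonstrate correctness of the measurement and analysis
chain under controlled conditions, not field robustness.

## Numerical and design notes

* Problem sizes in the test suite (e.g. 25-seed correlation panels,
  1000-rep null calibration at n = 20/arm, 100-render segmentation
  sweeps, 10⁵-sample Monte-Carlo oracles) are chosen so the full suite
  completes in a few minutes on one CPU while keeping binomial /
  Monte-Carlo error well inside the asserted tolerances.
* Monte-Carlo agreement is asserted at 3 standard errors per
  coordinate with a fixed spawned seed sequence; z-scores are standard
  normal under correctness, so occasional ~2–3 excursions are expected
  and the fixed seeds make the check reproducible.
* The 15-fruit multi-sample frames of a real acquisition are processed
  either as one pooled ROI or via user-supplied per-fruit crops; no
  instance segmentation is attempted.
* Determinism: a single integer seed drives trajectory noise, render
  sampling (via spawned child sequences) and the acceptance script;
  regenerating a study with the same seed is byte-identical, including
  PNGs.

## Known limitations

* Published F statistics and correlation magnitudes from any specific
  real trial are not reproducible from summary statistics alone; the
  package targets structure (signs, significance patterns, letter
  displays) and exact worked examples instead.
* Games–Howell equals Tukey HSD exactly only for two groups with equal
  variances and n; for k > 2 the error degrees of freedom differ by
  construction (pairwise Welch vs pooled), so agreement is asymptotic.
* Otsu segmentation assumes a bimodal saturation histogram (vivid
  fruit on a pale background); strongly desaturated fruit or colored
  backgrounds call for the fixed-threshold override.
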