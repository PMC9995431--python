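# Methods

## Scope and model

`pollindex` assesses trace-element contamination of soils (here the
Zn/Cu/Pb/Cr/Ni/Cd panel typical of road-traffic emissions) against a
geochemical background, with the full family of indices used in
environmental geochemistry, and provides the descriptive and multivariate
statistics that usually accompany such assessments.  The worked system is
a roadside transect flanking a noise barrier: stations along the road
crossed with perpendicular distances on the windward ("left") and road
("right") sides of the screen, with field replicates per station.

### Individual indices

For a measured concentration `Cn` (mg/kg dry soil), background `Bn` and
toxic-response factor `Tr`:

* geoaccumulation index `Igeo = log2(Cn / (1.5 Bn))` — the 1.5 factor
  absorbs natural background fluctuation; 7 classes (ids 0–6);
* single pollution index `PI = Cn / Bn` — 5 classes (ids 1–5);
* ecological risk factor `Er = Tr · PI` — 5 categories.

The identity `Igeo = log2(PI / 1.5)` holds exactly and is asserted to
1e-12 in the tests.  All three are strictly increasing in `Cn`, so the
median of the index equals the index of the median (exactly for odd
sample sizes; up to quantile interpolation otherwise).

### Integrated indices

From the per-sample PI vector: `PI_sum` (sum), `PI_avg` (mean),
`PI_vector` (root mean square), `PLI` (geometric mean), `PI_Nemerow =
sqrt((PI_avg² + PI_max²)/2)` and `PIN = Σ class(PI)² · PI` with `class`
the integer PI class id 1–5.  `RI = Σ Tr·PI` sums ecological risk over
elements.  Directly from concentrations against the effects-range
benchmarks: `CSI = Σ W (√(Cn/ERL) + (Cn/ERM)²)` and `MERMQ = mean(Cn/ERM)`.
For any non-negative PI vector `PLI ≤ PI_avg ≤ PI_vector ≤ PI_max` and
`PI_max/√2 ≤ PI_Nemerow ≤ PI_max` (AM–GM/AM–QM); both chains are
property-tested.

Two notational choices deserve a note.  The CSI formula is implemented
with the exponents on the ratios (`(Cn/ERL)^½`, `(Cn/ERM)²`), the only
dimensionally coherent reading, and with decimal weights
(0.075/0.075/0.251/0.215/0.134/0.25, summing to 1); a "printed" weight
variant with three-digit integer weights for Pb/Ni/Cr is selectable in
`ReferenceTable.ucc_default(csi_weights="printed")` because that reading
circulates in part of the literature.  MERMQ follows the printed formula
exactly; published summary values of MERMQ in the calibration survey are
not reproducible from that formula applied to the survey's own
concentration summaries, and the package makes no attempt to guess an
undocumented variant.

### Classification

Every scheme is an ordered interval map, closed on the left and open on
the right (`[a, b)`), which deterministically resolves the overlapping
shorthand of the index literature ("PI = 1–2", "PI = 2–3"); PI exactly 1
is "low pollution", PI_Nemerow exactly 1 "slight pollution".  PLI has an
exact-value class ("baseline" at 1).  `Igeo` at `Cn = 0` is below the
scale: tables report the lowest class with a `below_scale` flag and a NaN
value so CSV outputs stay finite.  RI uses the five printed categories
(low < 90 … highly strong > 720).

### Reference constants

Defaults: upper-continental-crust backgrounds
(Cu 28, Zn 67, Pb 17, Ni 47, Cr 92, Cd 0.09 mg/kg), Hakanson
toxic-response factors (Cu 5, Zn 1, Pb 5, Ni 5, Cr 2, Cd 30), ERL/ERM
sediment-quality guidelines (Cu 34/270, Zn 150/410, Pb 46.7/218,
Ni 20.9/51.6, Cr 81/370, Cd 1.2/9.6).  Units are fixed as mg/kg dry soil
throughout; there is no unit inference.  Custom tables load from YAML and
are validated (positivity, ERL < ERM); an index requested without its
constants fails early, naming the index and the element.

## Statistics

* Quartiles by linear interpolation between order statistics; adjusted
  Fisher–Pearson skewness and bias-corrected excess kurtosis (pandas
  conventions, matching mainstream statistics software); CV = SD/mean.
* Shapiro–Wilk for normality (3 ≤ n ≤ 5000), Mann–Whitney U (two-sided,
  tie-corrected) for two-group comparison, Spearman (average ranks) or
  Pearson correlation with p-values; |r| > 0.7 labelled strong,
  0.4–0.7 moderate.  All through scipy.
* Hierarchical clustering with Ward's minimum-variance criterion.  Merge
  heights are reported on the squared-Euclidean Ward *cost* scale — the
  increase in within-cluster sum of squares at each merge — obtained from
  scipy's Euclidean-scale heights via `h²/2`.  On this scale heights are
  monotone and sum to the total sum of squares about the grand centroid
  (both asserted), and 3-leaf instances match a brute-force evaluation of
  the Ward criterion.  `element_profile_clustering` builds per-element
  vectors of median PI per sampling distance (per side) and clusters the
  elements; a Cd-like element whose PI is an order of magnitude above the
  rest separates at the top split.

## Synthetic transect generator

The generator emulates the study conditions of the calibration survey so
the pipeline is testable without its raw samples (the survey deposits
none):

* **Layout** — 11 along-road stations every 150 m; perpendicular
  distances −0.5/−2.5/−5/−10/−20/−50 m (left) and +0.5/+2.5/+10/+20/+50 m
  (right); 6 replicates per station; 121 site-level samples after
  aggregation (66 left, 55 right).
* **Marginals** — lognormal per element and side, parameterised by the
  survey's published per-side medians and CVs
  (σ² = ln(1+CV²), μ = ln(median)).  Lognormality reflects the survey's
  mean > median and strong positive skewness throughout.
* **Dependence** — Gaussian copula targeting the published Spearman
  matrix; rank targets convert to latent Pearson correlations via
  ρ = 2 sin(π r_s/6), with eigenvalue-clipping nearest-PSD repair (error
  if the repair must move any entry by more than 0.1).
* **Spatial pattern** — a multiplicative Gaussian bump in log-distance,
  peaking at 2.5 m on the left (windward) side and 50 m on the right with
  multiplier 2 and log-width 0.4 (a narrow bump that localises the peak
  at the named station).  Two calibrations keep the configured marginals
  honest: the per-element lognormal σ is solved from
  `exp(σ²) = (1+CV²)/(1+cv_f²)` so the bump's own spread `cv_f` is part
  of the target CV rather than added on top, and the profile is rescaled
  so the side-wide mixture median equals the target median (solved by
  root-finding on the mixture CDF).  The peak multiplier is capped per
  element so the bump contributes at most half of the squared marginal
  variability — an element with a small configured CV cannot, by
  construction, carry a large deterministic spatial swing (this is what
  the low-CV Ni marginal on the left side implies), and the cap keeps
  both calibrations feasible and the copula dependence alive.  With all
  CVs set to 0 the cap removes the bump entirely and every sample equals
  its configured median.
* **Replicates** — median-1 lognormal dispersion at CV 8% around the
  site value, inside the 10% field-QC rule the survey states.  Observed
  replicate CVs scatter around 8%; `aggregate_replicates` reports them
  and a `cv_ok` compliance flag but performs no exclusion.
* **Reproducibility** — one `numpy` Generator seeded from a single
  integer; identical seeds give bit-identical tables.

What the generator does *not* emulate: wind-dispersion physics, the exact
per-distance medians of the survey's spatial figures, within-survey
spatial autocorrelation along the road, and any replicate-level QC
truncation.  Passing recovery tests therefore shows the pipeline recovers
the imposed marginal/dependence/spatial structure, not that real
transect data look exactly like this.

### Verified recovery (problem sizes used)

The acceptance checks run the generator at ~10⁴ sites per side for
marginal recovery (medians within 2%, CVs within 5%), 100 study-scale
replicas (n = 66 on the left) for rank-correlation recovery (≥ 90% of
element pairs within ±0.15 of target) and for structural recovery (Cd
separates at the top dendrogram split in ≥ 95% of replicas).  These sizes
give comfortable Monte-Carlo margins while keeping the default suite
fast.

## Numerical and design notes

* Published summary tables round to 2 decimals; when those rounded values
  are used as inputs, tolerances in the acceptance tests propagate the
  ±0.005 input rounding (e.g. a Cd mean of 6.51 mg/kg carries ±0.056 on
  its PI because Bn = 0.09) plus quantile-interpolation slack for
  even-sized medians.
* The left side of the calibration survey has n = 66 (even), so
  index-of-median equals median-of-index only up to interpolation; the
  right side (n = 55) commutes exactly.
* Integrated indices are computed per site on replicate means by default;
  elements missing in a row reduce `n_effective` (recorded per record),
  and a strict mode requires the full panel.
* `PLI` returns 0 when any PI is 0 (geometric-mean convention, no epsilon
  substitution).
* Degenerate inputs: empty PI vectors, NaN classification inputs,
  non-positive backgrounds, and ERL ≥ ERM configurations all raise with
  specific messages rather than propagating silently.

## Known limitations

* CSI and MERMQ are nonlinear in concentration, so their published
  summary cells cannot be recovered from concentration summaries (means
  and medians do not commute with them); they are computed per sample
  only.
* The Spearman p-values use scipy's t-approximation; for n < 10 exact
  permutation values would differ.
* The generator imposes one spatial profile per side (element overrides
  available) and no along-road trend.
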