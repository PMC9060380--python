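# Methods

This note documents the models, parameter choices and numerical decisions
behind `otolithsr`, and what the synthetic-data validation does and does
not demonstrate about real data.

## The measurement model

A laser transect across a sectioned otolith, ablated at 5 µm/s with a
35 µm spot and read at 0.5 s cadence, yields beam intensities (volts) at
m/z 82–88. The package treats the recorded voltages as the sum of:

* Sr ion beams at 84, 86, 87, 88 in natural proportions except for the
  radiogenic ⁸⁷Sr that carries the signal of interest;
* a ⁸⁵Rb beam plus its ⁸⁷Rb isobar in the natural ⁸⁷Rb/⁸⁵Rb ratio
  (0.38562);
* Ca-dimer (CaCa⁺) and Ca-argide (CaAr⁺) molecular interferences whose
  isotopologue patterns over m/z 80–88 follow the natural abundances of Ca
  and Ar — m/z 82 and 83 receive only these species, which is what makes
  them usable as monitors;
* a constant gas blank per mass;
* exponential-law mass fractionation: a measured isotope ratio relates to
  truth as `R_meas = R_true · (m_num/m_den)^(−β)`, with β drifting slowly
  in time; and multiplicative shot noise per reading.

### Reduction chain (order fixed)

1. **Blank**: per-mass means over the final 30 s of the pre-ablation blank
   phase are subtracted from ablation readings. Negative results are kept
   (clipping would bias downstream means); ratios are only formed where
   v86 exceeds 10× the blank SD.
2. **Ca interferences**: the two amplitudes reproducing the blank-corrected
   v82/v83 are solved from a 2×2 system and their patterns subtracted at
   m/z 84–88. The system is nearly singular — both species' 82/83
   signature reduces to the ⁴²Ca/⁴³Ca abundance ratio because each pairs
   dominantly with ⁴⁰Ca or ⁴⁰Ar (determinant ≈ −9×10⁻⁵) — so per-reading
   solutions amplify channel noise by ~10⁴. Since the ablated Ca flux is
   effectively constant within a run, amplitudes are estimated from a
   centred rolling mean of v82/v83 (default window 101 readings; window 1
   recovers the literal per-reading solve, and on noiseless input the two
   are identical). Amplitudes are floored at zero; if one species goes
   negative its monitor channel is attributed entirely to the other.
3. **Rb stripping**: β is estimated per bracketing standard from its
   ⁸⁷Sr/⁸⁶Sr via the exponential law
   (`β = ln(R_true/R_meas)/ln(m87/m86)`), interpolated linearly in time to
   each reading, and the predicted measured ⁸⁷Rb,
   `v85 · 0.38562 · (m87Rb/m85Rb)^(−β)`, is subtracted from v87. The −β
   exponent follows from the same fractionation convention that defines β:
   a measured v85 predicts a *measured* (fractionated) ⁸⁷Rb. Rb is assumed
   to fractionate like Sr. Negative v85 is treated as zero Rb.
4. **Bracketing**: each reading's ratio is multiplied by
   certified / (time-linear interpolation of the bracketing standards'
   measured ratios). For linear β drift this is exact to first order; the
   residual curvature term is O((Δβ·ln m-ratio)²) ≈ 10⁻⁹. The SRM 987
   certified value defaults to 0.710248 (community consensus) and is
   configurable.

The chain is idempotent on a clean run, and on noiseless simulated runs
across β ∈ [−0.1, 0.1], Rb/Sr ≤ 10⁻³, and nonzero dimer/argide/drift it
recovers the true ratio to ≲5×10⁻⁹ (the residual is interpolation error,
not a correction bias).

## Profile processing

* **Cropping** re-zeros positions at the estimated core; distance is
  elapsed ablation time × 5 µm/s.
* **Concentration**: Sr mg/kg = (2055 / mean FEBs-1 ⁸⁸Sr volts) × v88.
  With the default simulated sensitivity the FEBs-1 standard reads
  14.82 V, placing the habitat thresholds 6.13 / 12.26 V at ≈850 / ≈1700
  mg/kg.
* **GMV alignment**: if some run of ≥10 consecutive readings exceeds
  12.26 V, a single additive offset `0.70918 − mean(ratio at those
  readings)` shifts the whole series. Additive was chosen over
  multiplicative (a multiplicative mode exists behind
  `ClassifierConfig.align_mode`) because the shift is small (≲10⁻⁴) and an
  additive offset preserves all ratio differences exactly, which the
  distinctness rule depends on. Ten *consecutive* readings are required so
  a single noisy spike cannot shift a whole profile. After alignment,
  sub-marine readings falling inside the GMV band are counted and logged —
  estuarine water legitimately sits near the GMV (see below), so this is
  advisory, not an error.
* **Age axis**: piecewise linear through (0, 0) and (annulus_i, i years),
  extrapolated past the last annulus at the last inter-annulus rate but
  capped at one extra year: outer annuli of old fish are condensed to a few
  µm and extrapolating them is unreliable.

## Smoothing

Each transect is fit by penalized least squares on a cubic B-spline basis
of dimension k = 100 over the standardized position axis (so results are
invariant to µm↔mm rescaling), with a second-order coefficient-difference
penalty weighted by λ = 0.6 — the P-spline formulation. The difference
rows are divided differences on the Greville sites scaled by the interior
knot spacing: on the uniform interior this is the classic second
difference, and its null space is exactly the straight lines, so λ → ∞
yields the least-squares line while λ → 0 with k = n interpolates. k is
read as basis dimension (at n ≈ 850 the distinction from interior-knot
count is immaterial). The 95% band uses the Bayesian posterior covariance
σ²(XᵀX + λP)⁻¹ with σ² from residuals on n − edf degrees of freedom. At
the default settings, edf ≈ 70 on an 850-point transect; simulated
calibration gives mean pointwise coverage ≈ 0.96 and fit RMSE ≈ 0.27× the
noise SD.

## Classification

Habitat is read per reading from the corrected ⁸⁸Sr beam: below 6.13 V
freshwater, above 12.26 V marine, between them estuarine; boundary values
belong to the lower state (the rules are strict inequalities on the upper
side). Runs shorter than `min_state_run` = 10 readings (25 µm ≈ the laser
spot) are absorbed into their neighbours, so noise spikes and the
maternally derived core zone never register as habitat shifts.

Ratio criteria are evaluated on the spline fit, not raw readings — the
fit's pointwise SD (~5×10⁻⁵ at default noise) is what makes the ±6×10⁻⁵
GMV band usable. Quantifications the rules require but that are inherently
qualitative in visual workflows:

* "near the GMV" → within ±0.00006 (the GMV's 2 SD);
* "relatively constant" natal ratio → rolling SD of the fit ≤ 0.00003 over
  a 10-reading window;
* "isotopically distinct" regions → |Δ mean| strictly > 0.00005.

The **natal region** search skips a leading core zone whose state
disagrees with the first persistent state (maternal marine-like signal,
searched within 60 µm of the core), then takes the earliest stable
freshwater window before age 1, extended while stability holds. If no
freshwater window exists before age 1 — the semi-anadromous case — the
earliest stable window of any state is used; without that fallback the
natal-at-GMV rule could never fire. The **juvenile region** spans natal
end to the earlier of the first annulus and marine entry. **Marine entry**
is the first run of ≥10 readings with v88 > 12.26 V *and* fitted ratio
within the GMV band, floored to whole years.

Decision order: natal mean inside the GMV band → type 4 (this precedence
means a fish with marine-like earliest chemistry is semi-anadromous even
if it later shows marine plateaus); else with an entry age: < 1 → type 1,
≥ 1 with all-freshwater age-0 → type 2, ≥ 1 with ≥10 estuarine age-0
readings → type 3; else estuarine (or unconfirmed elevated) states
anywhere → type 5, otherwise type 6. Every profile receives exactly one
type or an explicit `undetermined` outcome (e.g. no stable natal window),
which is excluded from summaries with its reason logged.

## Cohort summaries

Percentages are integers rounded half away from zero — the convention
under which whole-fish counts reproduce printed cohort percentages
exactly (e.g. counts 13/14/9/17/2/6 of 61 → 21/23/15/28/3/10, anadromous
59%, nonanadromous 13%). Migration-age tables report per-type rows over
entry ages 0–4 with 5-and-older pooled; region tables report
mean/median/min/max/SE of per-otolith region means with their own N, which
can be smaller than the classification N when a region is undetectable.
Pooled cross-type age percentages are deliberately not emitted: they
depend on which types enter the denominator and are a common source of
arithmetic inconsistency.

## The synthetic generator

The generator is the package's ground truth and encodes the study
conditions:

* **Trajectories**: archetypes per type over a 20-year lifespan — type 1
  enters the sea at age 0.45–0.8 after a freshwater natal (0.15–0.3 y) and
  rearing phase; type 2 stays freshwater through age 0 and enters at age
  1/2/3/5 with probabilities 10/14, 1/14, 2/14, 1/14; type 3 moves to the
  estuary at age 0.25–0.5 and enters at age 1 or 2 (5/9, 4/9); type 4 is
  estuarine from hatch and alternates estuarine/marine residences; type 5
  alternates freshwater/estuarine and never goes to sea; type 6 is a
  single freshwater segment.
* **Water chemistry**: conservative two-end-member mixing between river
  water and seawater (0.70918, 7.9 mg/L Sr). Because seawater carries
  ~100× more Sr, estuarine mixtures sit within a few 10⁻⁵ of the GMV in
  ratio while intermediate in Sr — the physical reason the semi-anadromous
  natal rule works. Freshwater end-members: anadromous natal reaches
  0.7103–0.7109, nonanadromous 0.7110–0.71125, coastal streams feeding the
  type-4 estuary 0.7095–0.7105 at 0.03–0.07 mg/L; rearing habitats differ
  from natal by 1–3×10⁻⁴, comfortably beyond the 5×10⁻⁵ distinctness
  threshold.
* **Otolith Sr**: `2000 · (water Sr / 7.9)^0.274` mg/kg, pinning marine
  otolith Sr at ~2000 mg/kg (≈14.4 V) and freshwater at 400–730 mg/kg
  (3–5.3 V), so the 6.13/12.26 V thresholds are meaningful. The exponent
  stands in for the saturating physiological uptake of Sr with salinity.
* **Geometry**: annuli on a decaying-increment growth curve
  `r(a) = R∞(1 − e^(−Ka))`, K ∈ [0.22, 0.28] /y, core-to-edge 2125 µm
  (850 readings); the first year occupies ~22% of the transect and outer
  annuli condense below the reading spacing, as in old fish.
* **Maternal signal**: types 1–4 (sea-run mothers) carry a marine-like
  core zone of 15 µm, below the persistence filter's span, which the natal
  search must skip.
* **Spot smearing**: the plasma sees a Sr-weighted 35 µm moving average of
  the growth record; the recorded truth profile is the post-smearing one,
  since that is what the otolith-plus-laser system presents.
* **Instrument defaults**: sensitivity 14.82 V per FEBs-1 (see above),
  β = −0.5 with 0.01/h drift, 0.2% sensitivity drift/h, Rb at 2×10⁻⁴ of
  the ⁸⁸Sr beam, dimer/argide 2/1 mV at their monitor masses, gas blanks
  of 3–10 mV, and 10⁻⁴ relative noise per reading — representative of
  Faraday-cup statistics at 1–15 V beams with 0.5 s integrations.
  Standards bracket each run at 30-minute spacing.

**What passing synthetic tests shows — and does not.** The oracle tests
demonstrate that the reduction inverts exactly the distortions it models,
that the classifier implements its rules faithfully (100% archetype
recovery noise-free; ≥95% under default noise), and that the smoother's
bands are calibrated for Gaussian noise around smooth truths. Real
otoliths add effects the generator does not emulate: physiological lag and
vital effects in Sr uptake (the generator equilibrates instantly),
within-habitat seasonal ratio variability, Kr blank structure at m/z
84/86, detector drift that is not smooth, cracks and inclusions (handled
only via the advisory jump screen and manual quality flags), and ambiguity
in visually read annuli. Classification accuracy on real material will
therefore be bounded by those factors, not by the numbers reported here.

## Problem sizes and runtime

Validation uses 50 simulated runs for the reduction sweep, a 60-otolith
cohort (10 per type) for classifier recovery, and 200 transects for band
coverage; the whole suite runs in well under a minute on one CPU. These
sizes give binomial SEs of a few percent on recovery/coverage estimates,
adequate for the pass bands used.

## Known limitations

* λ is fixed at 0.6; no data-driven smoothing selection is provided.
* The distinctness rule is applied to region means without propagating the
  spline's posterior covariance between regions.
* The Ca-interference partition between dimer and argide is statistically
  fragile by construction (near-collinear monitors); only the summed
  correction at m/z 86–88 is well determined, which is what the ratio
  depends on.
* Age assignment inherits any error in the supplied annuli positions;
  annulus reading itself is out of scope.
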