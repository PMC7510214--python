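# Methods

## The screening problem

SMA is autosomal recessive; in > 95 % of cases the cause is a homozygous
deletion of *SMN1* exon 7. The near-identical paralog *SMN2* (distinguished
in exon 7 by the c.840 C→T substitution) is always present — complete
absence of both genes is lethal — and its copy number modifies severity and
treatment eligibility. A newborn screen therefore needs to (i) detect
*SMN1*-exon-7 absence from a crude DBS extract, (ii) confirm a successful
reaction via the *SMN2* signal, (iii) avoid detecting carriers, and (iv)
leave *SMN2* quantification to a confirmatory assay. This package models
that two-tiered design and the synthetic data needed to exercise it.

## Melt-curve model

Fluorescence for one well on a temperature grid T is

    F(T) = q(b) · [ B + A1·σ((Tm1' − T)/w) + A2·σ((Tm2 − T)/w)
                      + Aq·σ((TmQ − T)/w) ] + ε(T)

* σ is the standard logistic function — each probe–amplicon duplex
  dissociates as a sigmoid of shared width `w` (`transition_width_c`,
  default 1.0 °C). The logistic was chosen over, say, an error-function
  transition because its derivative peak has the closed form A/(4w) at Tm,
  which the test suite uses as an independent oracle.
* Tm1' = 63 °C + `probe_region_tm_shift_c`: probe-region variants can only
  *lower* the melting temperature (any mismatch destabilises the duplex),
  so the shift is constrained ≤ 0. Tm2 = 56 °C, TmQ = 49 °C.
* **Plateau amplitudes.** Asymmetric PCR driven to completion yields a
  fixed amount of probe-bound product, so with input DNA D (ng),
  `S = A_tot·D/(D + k)` is split between *SMN1* and *SMN2* by copy
  proportion — `A1/A2 = c1/c2` — and the Q competitor takes the complement
  `Aq = A_tot·k/(D + k)`. Absolute copy number cancels: genotypes (1,1) and
  (2,2) produce identical noiseless curves, which is precisely the
  carrier-masking behaviour the assay is designed for.
* `k` (`q_competition_k`, 0.5 ng) places Q-peak dominance below D ≈ 1 ng,
  about 10 % of a saturated-punch yield, matching the Q fragment's role as
  a low-input alarm rather than a routine signal.
* Quenching: blood pigment quenches Cy5, modelled as
  `q(b) = exp(−0.7·max(0, b − 1))` where b is relative spot saturation
  (b = 1 saturated, b = 2 oversaturated → 50 % signal). Direction is the
  physically established fact; the magnitude is a package choice.
* Noise ε is additive Gaussian, default sd 0.03 (0.3 % of the total
  amplitude 10). Melt instruments integrate fluorescence over slow
  temperature ramps, so per-point noise is small; at this level the SD074
  control's *SMN1* peak (height ≈ 0.38) stands ≥ 8 sd above the presence
  threshold while all rule boundaries the cohort exercises keep ≥ 5 sd
  margins. Grid: 45–75 °C at 0.2 °C.

Cohort nuisance parameters (configurable; invented, as no per-punch yield
distributions are published for this chemistry): DNA yield per 1.5 mm punch
lognormal with median 5 ng and log-sd 0.25; spot saturation normal
(mean 1.0, sd 0.1, truncated at 0.2); controls use 5 ng of synthetic DNA
with no blood.

## Derivative and peak calling

−dF/dT is computed with a cubic Savitzky–Golay filter over a 3.0 °C window.
Measured on noiseless logistic transitions, this keeps the peak-height bias
≤ 1.6 % for w ∈ [0.8, 1.6] (the 2 % oracle tolerance in the tests) while
attenuating fluorescence noise by ≈ 0.76× into the derivative; a quadratic
fit over 1 °C would amplify it 1.6× and drown the SD074 threshold peak.

Peak windows are *SMN1* [62.0, 64.5], *SMN2* [55.0, 57.5], Q [47.5, 50.5] °C.
They are asymmetric on purpose: each lower edge sits ≥ 6 °C above the next
cooler transition, where that transition's shoulder has decayed below any
sane threshold, and only the low side needs guarding because variants only
shift peaks down. A peak is **present** iff the window contains an interior
local maximum of the derivative exceeding `presence_factor` (default 6)
times the noise floor. The floor is the larger of (i) the MAD-based
dispersion of −dF/dT over grid regions ≥ 3 °C away from every window and
(ii) a fluorescence-noise estimate from robust second differences of the
raw curve propagated through the filter's exact noise gain — the regional
MAD alone rests on ~38 strongly autocorrelated points and its sampling
error otherwise produces sporadic false "peaks" on *SMN1*-null wells. Pure
shoulders (windowed maximum on the window edge, no interior local maximum)
are recorded but treated as absent.

## First-tier decision rules and plate QC

Per specimen well, in order: (1) Q height strictly above both SMN heights →
RETEST; (2) *SMN2* present, *SMN1* absent → SECOND_TIER (putative SMA);
(3) *SMN2* present and *SMN1* height ≤ the plate's SD074 reference (mean of
its two SD074 *SMN1* heights) → SECOND_TIER (ratio ≥ 5); (4) otherwise
NORMAL. The SD074 comparison is inclusive so that a well exactly at the 1:5
design ratio is referred. A well with no peak at all is an assay failure →
RETEST. Retests are re-simulated with a fresh punch (new DNA yield and
saturation); wells still uninterpretable after `max_rounds` escalate to
SECOND_TIER — in screening, ambiguity must err toward confirmation.

A plate is interpretable only if both blanks show a dominant Q peak with no
SMN peaks, both SD075 wells show *SMN2* without *SMN1*, and both SD074
wells show both peaks with *SMN1* < *SMN2*. Failed plates are excluded from
metrics and reported.

## MLPA model and copy-number calling

Probe height `h_p = s·k_p·c_p·(1 + ε_p)`: per-sample lognormal scale s,
run-fixed probe efficiency k_p, target copy number c_p (reference probes:
2), multiplicative noise with CV 0.05. The synthetic panel (the real kit's
probe list is proprietary) carries 2 probes per SMN exon class (*SMN1*/
*SMN2* × exon 7/8) plus 10 reference probes; exon-8 copies mirror exon-7
(whole-gene events), and exon-7/exon-8 disagreement is flagged.

Normalization is a deterministic two-stage median scheme (the commercial
analysis software is proprietary): divide by the sample's median reference
probe height (cancels s), then by the per-probe median of the same
statistic over ≥ 3 diploid reference samples (cancels k_p). Copy calls:
per-class median ratio r, call `round(2r)` if |2r − round(2r)| ≤ 0.4, else
AMBIGUOUS → one MLPA retest. At CV 0.05 the 2-copy call sits ≈ 5 sd inside
its band; Monte-Carlo recovery over the validation cohort's genotype range
is ≥ 99 % (tested at 500 replicates), exact at CV 0.

## Pipeline, metrics, determinism

`run_validation` chains cohort → plates → melt analysis → tier-1 calls
(with retest resolution) → MLPA on *every* sample → metrics. Truth is the
generator genotype; a sample is predicted positive when tier 1 refers it
and MLPA confirms zero *SMN1* copies. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), concordance = fraction of samples where tier-1
*SMN1*-absence equals MLPA-confirmed *SMN1* = 0. Point-mutation SMA cases
(flagged `smn1_nonfunctional`) are reported as designed misses rather than
scored — the assay cannot and does not claim to see them. All randomness
descends from one seed through spawned NumPy streams; identical inputs give
byte-identical JSON reports. The full 422-sample run takes well under ten
seconds on one CPU, so no scaling-down was needed anywhere.

## What the synthetic data does not show

The generator reproduces the *statistical structure* the decision rules
assume — ratio-only amplitudes, Q competition, quenching, control-well
design, MLPA proportionality. It does not model real melt chemistry:
temperature-calibration drift between instruments, well-to-well optical
gain variation, heteroscedastic probe noise, partial-gene deletions,
primer-site variants (as opposed to probe-site), or cross-contamination.
Passing the validation-level tests therefore demonstrates that the decision
algorithm is correct and fail-safe under its stated assumptions, not that a
physical assay achieves these error rates; the published wet-lab study is
the evidence for the latter. Retest rates here are ≈ 0 by construction
(clean DNA-yield distribution) — real platform-dependent retest rates of
0.2–1.2 % reflect instrument effects this model does not include.
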