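# smnscreen

A tested, fully synthetic implementation of a two-tiered newborn-screening
algorithm for spinal muscular atrophy (SMA) on dried-blood-spot (DBS)
specimens:

1. **First tier — melt-curve genotyping.** A single fluorescent probe
   hybridises to asymmetrically amplified *SMN1*/*SMN2* exon-7 amplicons and
   to a mismatched "Q" competitor oligonucleotide. The negative derivative
   −dF/dT of the dissociation curve shows up to three peaks — *SMN1*
   (~63 °C), *SMN2* (~56 °C) and Q (~49 °C). A well with a clear *SMN2* peak
   but no *SMN1* peak (or an *SMN1* peak at or below the SD074 threshold
   control, i.e. an *SMN2*:*SMN1* copy ratio ≥ 5) is referred for
   confirmation; a dominant Q peak means too little input DNA and triggers a
   retest.
2. **Second tier — MLPA confirmation.** Multiplex ligation-dependent probe
   amplification profiles are normalized by a two-stage median scheme and
   integer *SMN1*/*SMN2* exon-7 copy numbers are called as
   `round(2 × ratio)` with an ambiguity band.

Because the probe reads only the *SMN1*:*SMN2* copy **ratio** (the
asymmetric PCR runs to plateau), carriers with ratios like 1:1 or 1:2 are
deliberately indistinguishable from non-carriers — a regulatory requirement
for newborn screening. The *SMN1* peak is designed as the hottest
transition: sequence variants under the probe can only lower a melting
temperature, so a variant pushes the peak *out* of the *SMN1* window and the
sample fails safe toward referral (possible false positive, never a false
negative). The deliberate blind spot — the 2–5 % of SMA caused by intragenic
point mutations rather than exon-7 deletion — is modelled and reported as
"designed misses".

No real screening data are bundled. The `synth` module generates the whole
study: genotype cohorts (with DNA-yield, spot-saturation and blood-quenching
variation), 96-well plates carrying 2 blank + 2 SD074 (1:5 ratio) + 2 SD075
(*SMN1*-null) control reactions, per-well melt curves, and MLPA probe
tables, so the complete decision procedure is exercisable end to end.

Intended audience: assay developers and screening-lab bioinformaticians who
want an executable, testable model of ratio-based melt-curve screening and
its failure modes.

## Worked example

```python
from smnscreen import VALIDATION_COHORT_COMPOSITION, run_validation

result = run_validation(VALIDATION_COHORT_COMPOSITION, seed=1)
print(result.summary_text())
```

```
Two-tiered SMA screening — cohort summary
  samples analysed        : 422
  screen positive (tier 1): 47
  controls referred       : 0
  wells retested          : 0
  sensitivity             : 100.0%
  specificity             : 100.0%
  tier concordance        : 100.0%
  MLPA copy-number table (SMN1, SMN2) -> count:
    (0, 1): 1
    (0, 2): 13
    (0, 3): 27
    (0, 4): 6
    ...
```

The cohort is 422 specimens with the genotype cross-tabulation of the
published Dutch validation study (47 samples with zero *SMN1* exon-7
copies, 375 controls). All 47 *SMN1*-null samples — and no controls — are
referred by the melt-curve tier, the MLPA tier confirms every referral and
recovers both copy numbers for every sample (the table above reproduces the
input composition exactly), and sensitivity, specificity and between-tier
concordance are all 100 %.

The same run is available from the shell, along with the individual
pipeline stages:

```sh
smnscreen run --seed 1 --out report/
smnscreen simulate --seed 1 --out sim/          # cohort, plates, curves, MLPA
smnscreen screen --curves sim/melt_curves.csv --plates sim/plates.csv --out calls/
smnscreen mlpa --profiles sim/mlpa_profiles.csv --out mlpa_calls.csv
smnscreen evaluate --truth sim/cohort.csv --tier1-calls calls/tier1_calls.csv \
    --mlpa-calls mlpa_calls.csv
```

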