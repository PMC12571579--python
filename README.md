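# her2calib

Analysis pipeline for multi-laboratory HER2 immunohistochemistry (IHC)
surveys built on bead calibrators. It is written for the people who run and
evaluate such surveys — proficiency-testing organisations, IHC laboratories
validating HER2-low assays, and methodologists studying how analytic
sensitivity shapes diagnostic accuracy.

## The problem

HER2 IHC assays were designed to flag *over*-expression (3+) for anti-HER2
therapy. Antibody-drug conjugates changed the question: eligibility now
hinges on distinguishing HER2 0 from ultralow (tabulated as 0.5) and 1+ —
the faint end of the scale, where assays were never validated and no gold
standard exists. Two quantitative tools make the problem tractable:

1. **Analytic sensitivity (LOD).** Calibrator slides carry 8-µm microbeads
   bearing defined HER2 peptide concentrations (ten spots spanning
   26–1400 × 10³ molecules per cell-equivalent, plus five negative-control
   spots). After staining, per-spot chromogen intensity *y* follows a
   sigmoid in concentration *x*; its rising region is fitted as

       y = a·ln x + b

   and the lower limit of detection is the concentration whose predicted
   intensity equals the negative-control mean plus three SDs:

       LOD = exp((y* − b) / a),   y* = μ_neg + 3·σ_neg

   Baseline points (intensity no greater than the negative mean) and
   saturating plateau points are excluded; at least three points must
   remain.

2. **Dynamic range.** With no reference assay for HER2-low, one can ask
   whether scores *respond to sensitivity*: group laboratories into LOD
   bins (centre ± 5,000), compute each bin's aggregate consensus TMA score,
   and regress aggregate score on bin centre. A slope of zero means the
   scores ignore analytic sensitivity; a negative slope (scores falling as
   LOD rises) is a working dynamic range. Slopes are compared between
   readout methods (pathologist vs image analysis) with t tests.

Diagnostic accuracy closes the loop: over-expression calls are scored
against gene amplification by in situ hybridisation (HER2/CEP17 ratio ≥ 2),
and HER2-low treatment decisions against the consensus of a laboratory
group selected by LOD, with exact Clopper–Pearson intervals on sensitivity,
specificity, predictive values and accuracy = (TN+TP)/(TN+FP+FN+TP).

Because the physical slides and pathologist readouts of such a survey are
not shippable, a synthetic-data module generates all inputs with known
ground truth: rendered calibrator images, a lab cohort spanning LODs of
roughly 5,000–80,000 molecules per cell-equivalent, an 80-core TMA with 20
cores per score category, reader noise (manual ≫ image analysis), and ISH
ratios correlated with latent expression. See `docs/methods.md` for the
model and its limits.

## Worked example

```python
from her2calib import (SimConfig, simulate_study, LabCriterion,
                       consensus_scores, trastuzumab_confusion,
                       diagnostic_metrics, bin_labs, dynamic_range_slope,
                       compare_slopes)
from her2calib.consensus import select_labs

study = simulate_study(SimConfig(seed=1))
labs = study["labs"]

# accuracy of the predicate-sensitivity group against ISH
group = select_labs(labs, LabCriterion.interval(30_000, 60_000, readout="manual"))
cons = consensus_scores(study["scores"], group, include_ultralow=True)
m = diagnostic_metrics(trastuzumab_confusion(cons, study["ish"]))

# dynamic range per readout arm
bins = bin_labs(labs)
ia = dynamic_range_slope(bins, study["scores"], labs, True, "image_analysis")
man = dynamic_range_slope(bins, study["scores"], labs, True, "manual")
```

prints, via the obvious formatting:

```
predicate-range group: 21 labs
confusion: TP=17 TN=47 FP=0 FN=3
sensitivity 0.850 (95% CI 0.6211-0.9679)
specificity 1.000 (95% CI 0.9245-1.0000)
IA slope -0.0158 per 1,000 molecules (p=0.0027)
manual slope -0.0015 per 1,000 molecules (p=0.1944)
slope ratio 10.4, compare_slopes p=0.0022
```

Read it as: laboratories with LODs in the 30,000–60,000 band call
gene-amplified cores almost perfectly (three false negatives are injected
ISH-discordant cases), yet their *manual* HER2-low scores barely move with
sensitivity (slope ≈ 0, p = 0.19). Image-analysis readout of the same
staining tracks sensitivity strongly — a roughly ten-fold steeper slope,
significantly different from the manual one (p = 0.002). The signs are
negative because sensitivity increases as LOD decreases.

The same stages are scriptable from a shell:

```bash
her2calib simulate --seed 1 --out run/
her2calib dynrange --scores run/scores.csv --labs run/labs.csv --readout image_analysis
her2calib accuracy --scores run/scores.csv --labs run/labs.csv --ish run/ish.csv
her2calib report --seed 1 --out run/   # full bundle with report.json
```

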