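# Methods

This note documents the models behind `her2calib`: what each stage assumes,
which parameters matter, what the synthetic data do and do not emulate, and
the numerical choices that keep the pipeline well-posed.

## 1. Calibrator model and LOD estimation

### Measurement model

A calibrator slide carries fifteen bead spots: ten concentrations of a
HER2 peptide (26, 40, 60, 90, 140, 210, 320, 500, 850, 1400 × 10³ molecules
per cell-equivalent; an 8-µm bead stands in for one tumour cell) and five
negative-control spots bearing an irrelevant peptide. Chromogen intensity
is measured per bead as the dot product of the background-subtracted RGB
signal with the unit DAB absorbance profile (0.268, 0.570, 0.776 before
normalisation), so more chromogen gives a larger value. The sign convention
is a deliberate choice — it makes "intensity" monotone in analyte and the
+3 SD detection threshold well-defined.

Bead segmentation is a circle Hough transform over Canny edges, restricted
to an allowable radius range known from the magnification (default 5–8 px
for the synthetic slides, whose beads render at radius 6). Three gates keep
the segmentation clean, each deterministic:

* an absolute accumulator floor (default 0.3: at least 30% of a candidate
  circle's perimeter must be supported by edge pixels) in addition to the
  relative peak threshold, so weak phantom votes cannot win on an
  otherwise faint slide;
* a cross-radius dedup (peak separation is only enforced within one radius
  slice of the Hough stack, so one bead can fire at several radii; the
  strongest accumulator per location wins);
* greedy overlap removal: circles are visited in decreasing accumulator
  order (ties broken by position) and kept only if their centre is at
  least `tolerance × (r1 + r2)` from every kept circle (default 1.0).
  The result is a maximal conflict-free subset — verified against brute
  force in the tests.

Intensities are sampled on a disk eroded by one pixel and capped at the
lower radius bound, so a detection fitted slightly outside a bead never
samples boundary pixels. Beads are assigned to the nearest spot centre
within the spot radius; anything farther is discarded as a segmentation
artefact. Duplicate slides are averaged spot-wise (arithmetic mean of spot
means; the operation is symmetric).

### LOD

The spot means trace a sigmoid in concentration: a baseline where the assay
detects nothing, a rising region, a saturation plateau. The rising region
is fitted by least squares as `y = a·ln x + b` and the LOD is the
concentration where the fitted line crosses `y* = μ_neg + 3 σ_neg`
(limit-of-blank convention: ~99% probability of exceeding background).
Negative statistics pool the per-spot means and SDs weighted by bead count.

Point classification, in order:

* **Baseline** — intensity no greater than the negative mean. The
  comparison uses the mean alone, not `y*`; including near-baseline points
  in a log fit is the single most damaging failure mode, because the
  log-line passes far below the clipped baseline at low concentrations.
  Since a measured spot mean has finite precision, the comparison carries a
  numerical guard of three standard errors of the spot mean (≈ 0.04
  chromogen units on a noise-free synthetic slide — two orders of magnitude
  below the +3 SD detection threshold, which it must never be confused
  with).
* **Plateau** — the largest suffix of at least two points whose consecutive
  increments stay below 5% (configurable) of the observed dynamic span.
  That rule is blind to a *single* saturating point whose increment from
  the last rising point is still large, so a second pass trims the tail:
  while the highest remaining point falls below the line fitted to the
  rising set by more than the same measurement tolerance, it is relabelled
  plateau. Trimming stops before the rising set would drop below three
  points.
* **Slope** — everything else; at least three points are required
  (`InsufficientSlopePoints` otherwise), and when more than five exist all
  are used.

LODs below the lowest calibrator concentration are legitimate
extrapolations of the fitted line and are flagged
(`extrapolated_below_lowest`), not rejected. Only a single-slide LOD is
computed; precision-profile LOD variants need replicate slides that a
one-slide-per-lab survey does not have.

## 2. Consensus scoring

Scores live on the 5-level scale {0, 0.5 (ultralow), 1, 2, 3}. The
consensus of a laboratory group is the per-core mean, rounded to the
nearest member of the active score set; exact midpoints round *down* (the
conservative direction — positivity is never inflated by a tie). With the
ultralow category active the target set is {0, 0.5, 1, 2, 3}: a mean of
0.7 rounds to 0.5. Without it, ultralow inputs are tabulated as HER2 0
before averaging — that is how standard scoring guidelines treat faint
staining — and the target set is {0, 1, 2, 3}: a mean of 0.7 rounds to 1.
A consequence, asserted on simulated surveys, is that including the
ultralow category never lowers the aggregate TMA score.

Laboratory selection criteria are closed intervals (both ends inclusive),
strict one-sided bounds (`> 40,000`, `< 20,000` — matching how mismatch
scenarios are phrased), or assay-name predicates, each stackable with a
readout restriction. Cores unscored by the selected group are excluded from
aggregates, never imputed.

## 3. Dynamic range

Laboratories are grouped into LOD bins (centre ± 5,000 molecules per
cell-equivalent, inclusive; default centres 10,000–60,000 in steps of
10,000). A lab may belong to two adjacent bins when centres are closer than
twice the halfwidth — overlapping windows are accepted. Each bin's
aggregate is the mean of per-core rounded consensus scores over its member
labs, one readout arm at a time; mixing readout methods inside a regression
is disallowed because the manual/IA contrast is the analysis of interest.

The dynamic-range statistic is the OLS slope of aggregate score on bin
centre, with a t test of slope = 0 on n − 2 df. Two slopes are compared
with `t = (b1 − b2)/√(se1² + se2²)` and Welch–Satterthwaite df. Orientation:
sensitivity rises as LOD falls, so a working dynamic range appears as a
*negative* slope in LOD units; magnitudes are compared as |slope|.
Degenerate fits (zero residual) report se = 0, p = 0 for a non-zero slope
and p = 1 for a zero slope, rather than NaN.

Per-score decompositions report, per bin, the fraction of cores at each
consensus level (fractions sum to 1 by construction) with a per-level OLS
trend. The HER2 0 fraction is the one that tracks sensitivity even under
manual readout: less sensitive assays leave more cores scoreless.

## 4. Diagnostic accuracy

For over-expression, the gold standard is gene amplification: HER2/CEP17
ratio ≥ 2.0 (copy-number subtleties of the full guideline groups are out of
scope). An IHC call is positive at 3+, or at 2+ when reflex ISH is
amplified. Non-evaluable cores are excluded.

For HER2-low there is no reference assay, so the gold standard is the
rounded consensus of a laboratory group selected by LOD, mapped through a
treatment rule. The default rule reconstructs antibody-drug-conjugate
eligibility: treat at ultralow/1+/2+ (0.5 only when the category is
active); 3+ routes to the anti-HER2-signalling pathway (no-treat here); a
2+ resolved amplified by ISH is likewise routed away when ISH is supplied.
The rule is plain data (`TreatmentRule`), so alternatives are pluggable,
and its outputs are checked against exhaustive enumeration over the
score × ISH product space.

Metrics: sensitivity tp/(tp+fn), specificity tn/(tn+fp), PPV tp/(tp+fp),
NPV tn/(tn+fn), accuracy (tn+tp)/total — each with an exact Clopper–Pearson
interval from beta quantiles (lower bound 0 at k = 0, upper bound 1 at
k = n). A metric with a zero denominator is reported as NaN, never as 0
or 1. Per-lab accuracy profiles map each laboratory's own scores through
the rule against the gold decisions and are ordered by LOD.

## 5. The synthetic study

The generator produces the survey the analysis stages assume, with known
ground truth. Its defaults are the package's reference conditions.

**Cores.** 80 TMA cores, 20 per intended category 0–3+. Latent expression
is log-normal per category with medians 15,000 / 100,000 / 350,000 /
1,500,000 molecules per cell-equivalent and log-SD 0.5: category medians
are well separated while adjacent categories overlap in the tails, as
graded clinical material does. These are conventions — nothing is known
about the true within-category distribution of expression in real tissue.

**Labs.** Four assay families: the unmodified predicate assay
(18 labs, LOD 54,436 ± 19,569 — a 36% inter-laboratory CV), a
protocol-optimised variant (12, 40,000 ± 8,000), an alternative detection
system (12, 25,000 ± 5,000) and a high-sensitivity monoclonal kit
(12, 12,000 ± 4,000); draws are truncated at 3,000. Every physical lab
yields a manual arm and an image-analysis arm over the same staining (same
true LOD), mirroring a survey in which both readouts see the same slides.

**Scores.** The noise-free score is a monotone step function of
latent/LOD: 0 below the effective detection limit, then 0.5 / 1 / 2 / 3 at
ratio thresholds 1, 2, 6, 20. Observed scores add Gaussian reader noise on
the score scale (SD 0.5 manual, 0.1 image analysis) and snap to the nearest
valid level, ties down. Manual readout additionally has a **visual
detection floor**: its effective sensitivity is max(assay LOD, 45,000),
because a pathologist cannot appreciate staining the eye does not resolve,
however sensitive the chemistry. This floor, not the noise, is what
flattens the manual dynamic range: i.i.d. zero-mean reader noise averages
out of a consensus over the many labs in a bin, whereas a perceptual floor
is shared by every manual reader and survives averaging. The floor sits in
the 30,000–60,000 band that visual scoring was historically matched to.
Lowering a lab's LOD never lowers any noise-free score.

**ISH.** Cores above 700,000 molecules draw a ratio ≥ 2, the rest < 2;
with probability 0.04 a core draws from the other side (gene amplification
without protein, or vice versa), reproducing the handful of discordant
cases such surveys report. A fraction 7/80 of cores is non-evaluable.

**Calibrator images.** 500 × 300 8-bit RGB, white background, 24 beads of
radius 6 px per spot on a jittered grid with guaranteed non-overlap
(anti-aliasing off, integer centres — segmentation recovery is exactly
checkable). The dose-response is `a·ln x + b` with slope 60 chromogen units
per ln-unit, clipped to baseline 40 (background staining) and plateau 250,
and anchored so the curve crosses `μ_neg + 3·σ_total` exactly at the
requested true LOD, where `σ_total = √(σ_neg² + σ_bead²)` is the blank
variability the estimator will actually measure (designed spread 2 plus
per-bead Gaussian noise, default 10.5 = 5% of the dynamic span). Negative
beads carry a deterministic zero-mean, unit-sample-SD pattern scaled by
σ_neg, so measured negative statistics equal designed ones even at zero
noise. Pixels are `255 − intensity·DAB` with stochastic rounding to 8 bits,
keeping the pixel-mean unbiased well below one chromogen unit. The baseline
of 40 keeps the faintest beads ~3.6 SD away from invisibility under default
noise; at a lower baseline the zero floor censors the negative distribution
and biases the LOD.

Under these conditions the full image pipeline recovers true LODs of
10,000/30,000/60,000 within 0.3% noise-free and within 10% per slide pair
at the default noise (verified over 20 seeds in the tests).

**Reproducibility.** All randomness flows from one root seed; each stage
draws from a substream derived by a CRC-32-hashed string label, so partial
re-runs are bit-identical and adding a stage never perturbs another.

### What the generator does not emulate

No tissue morphology, cell segmentation or stain chemistry; no spatial
heterogeneity within a core; no inter-observer structure beyond one noise
SD plus one shared floor per readout method; no drift within a staining
run; ISH ratios depend on latent expression only. Passing tests therefore
show that the *analysis* is correct under the stated data model — they do
not validate the data model against real slides, and effect sizes (slope
ratios, accuracy drops) are qualitative, not calibrated to any particular
cohort.

## 6. Problem sizes and runtimes

Default analyses use the 80-core, 54-lab (108-arm) survey; LOD recovery
tests render 2 slides × 23 parameter/seed combinations (each slide
segments 360 beads); the coverage check of the exact binomial interval uses
10,000 replicates at n = 20, p = 0.8. The full suite runs in well under a
minute on one CPU.

## 7. Known limitations

* The LOD estimator assumes a monotone response; a non-monotone slide
  (e.g. prozone effects) would be mislabelled rather than rejected.
* The saturating-tail trim assumes the plateau is approached from below;
  an overshooting response would defeat it.
* The manual visual-detection floor is a single shared constant; real
  readers vary, and the floor's value (45,000) is a design choice, not an
  estimate from data.
* Consensus rounding discards within-group dispersion; two groups with
  identical consensus but different spread are indistinguishable
  downstream.
* The default treatment rule is a reconstruction of trial eligibility
  logic, clearly labelled as such; site-specific rules should be supplied
  explicitly.
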