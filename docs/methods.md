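# Methods

This note documents the statistical procedures, the forward models behind
the synthetic-data generators, the numerical choices, and the limitations a
user should know before trusting the calls on real data.

## Exometabolome screen

For compound *i* with control replicates *x* and treated replicates *y*
(non-negative LC–MS responses, ≥ 2 per group):

- log₂FC_i = log₂((ȳ + ε) / (x̄ + ε)), with the pseudo-count ε applied only
  when one of the group means is zero. ε defaults to half the smallest
  positive response in the whole table ("auto"); it exists to keep fold
  changes finite without inflating compounds that were measured cleanly.
  Compounds that are zero in *both* groups are flagged not-evaluable and
  excluded downstream (they still count as "unchanged" in partition sums).
- CV per group = 100 · sd(ddof=1) / mean, in percent.
- A compound passes the filter iff |log₂FC| > 0.5 **and**
  max(CV_control, CV_treated) < 30 %. Passing compounds are *consumed*
  (negative) or *secreted* (positive); everything else is *unchanged*.

Choices worth noting: the fold-change threshold is applied to |log₂FC| with
the sign carrying the direction, and the CV gate uses the *worse* of the two
groups because the assay description does not say which group it applies to
— gating on the maximum is the conservative reading, and it is configurable.
No multiple-testing correction is applied by default (the screen is a
threshold filter, not a hypothesis test); a Benjamini–Hochberg option exists
in the uptake stage for users who want FDR control across a grid.

## Oocyte uptake calls

Pipeline per transporter × compound condition, against the GFP-only control
pools for the same compound:

1. **Per-oocyte normalization**: response / n_oocytes, so pools of 7 and 10
   oocytes contribute on a common scale; condition means are means of
   per-oocyte values.
2. **Outlier QC**: Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by
   linear interpolation between order statistics (numpy's default
   convention — fixed and matched by the test oracles). Sets of fewer than
   4 values are never trimmed: quartiles of 2–3 points carry no spread
   information. Removal is a single pass ("identify, remove, redo the
   statistics"); note that re-applying the rule to the kept values of a
   small set can flag further points, because removing an extreme shrinks
   the fences — the single pass is the documented behavior.
3. **Test**: two-sided equal-variance Student's *t*-test on per-oocyte
   values (Welch behind a flag). Zero-variance degeneracies resolve
   deterministically (equal means ⇒ p = 1, separated ⇒ p = 0).
4. **Direction**: p ≤ α and log₂FC > 0 ⇒ import; p ≤ α and log₂FC < 0 ⇒
   export *if* the control shows endogenous background (one-sided test of
   control values above a blank level, default 0), else indeterminate — with
   empty control oocytes an expressed exporter has nothing to deplete, so a
   negative shift is uninterpretable. α defaults to 0.05 with stars at
   0.05 / 0.01 / 0.001.

## Transport mode

Import calls are refined by comparing intracellular concentration to the
medium, assumed constant at its nominal 2 mM (substrate in excess, medium
volume ≫ oocyte volume). Per-oocyte amounts convert to concentration via
c_in = amount / (response_per_mM · V_oocyte); with the default unity
calibration and 1 µL volume only concentration *ratios* are meaningful,
which is all the classification uses. The test is a one-sided one-sample
Student's *t* of the replicate c_in values against c_medium:
**concentrative** iff log₂(mean c_in / c_medium) > 0 and p ≤ α, otherwise
**equilibrative** (a non-significant excess, a zero, or any deficit all fall
on the equilibrative side — concentrative is the strict claim requiring
evidence). All-zero replicates report a −∞ log₂FC sentinel.

Background correction: if the GFP control itself tests significantly above
the medium, the raw call is flagged `background_biased`. The corrected
concentration is max(mean_T − mean_GFP, 0); its significance uses
replicate-wise differences (pools paired by rank, falling back to
mean-subtraction when pool counts differ) so control spread propagates into
the corrected test. Raw and corrected calls are always reported side by
side; correction can only lower the concentration, never raise it.

## Growth phenotyping

**Max OD** is the maximum of the 3-point running-median-smoothed curve
(endpoints kept), which suppresses single-point spikes at the cost of at
most one sample of smoothing tolerance.

**μ_max** comes from sliding-window least-squares fits of ln OD vs time
(window of 5 points ≈ 100 min at 20-min sampling) over windows whose
smoothed ODs all exceed `od_floor` (default 0.01). Two estimators:

- `window_max`: the steepest window slope — the classic recipe. On noisy
  data it is biased upward, sometimes badly: additive OD noise of sd σ
  becomes ln-scale noise σ/OD, largest exactly in the low-OD windows where
  the slope is steepest, and taking a maximum over many noisy slopes
  selects the noise.
- `extrapolated` (default): for logistic-like growth the instantaneous
  slope of ln OD falls linearly with density, d ln OD/dt = μ(1 − OD/K).
  Window slopes with mean OD between 10 % and 80 % of the curve maximum are
  regressed against their mean OD with weights ∝ OD² (the inverse ln-scale
  noise variance), and μ_max is the intercept at OD → 0. This uses only
  windows where the ln transform is well behaved and corrects their
  attenuation instead of maximizing over them. On noiseless exponential or
  logistic input the two estimators agree with the true rate to well under
  1 %; on triplicate-averaged curves with OD noise sd 0.02 the extrapolated
  estimator holds a median error below 2 % where the plain maximum errs by
  ~15 %. Fewer than three usable windows fall back to `window_max`.

Replicates sharing a time grid should be pointwise-averaged before fitting
(`average_replicates` / `average=True`), which suppresses OD noise by √n
where it hurts most.

**LC50** is defined on a growth metric (Max OD by default, μ_max
selectable) relative to the zero-concentration condition. A four-parameter
logistic metric(c) = bottom + (top − bottom)/(1 + (c/EC50)^h) is fit by
least squares (p0: bottom 0, top 100 %, EC50 at the median tested
concentration, h = 2; bounds keep bottom < 50 % < top); the LC50 is where
the fitted curve crosses 50 % of the untreated metric. If the fit fails or
never crosses 50 %, monotone linear interpolation between bracketing
concentrations is used and the method is recorded. The series must include
c = 0 and at least 4 distinct concentrations; an all-equal metric is a
"no dose effect" error rather than a number.

**Strain comparisons** are per-metric two-sided equal-variance *t*-tests of
mutant vs reference replicate metric values, reporting mutant − reference
differences with star levels; fewer than two replicates on a side is
not-evaluable.

## Synthetic-data generators

The generators define the conditions under which the pipeline's recovery is
demonstrated; they emulate the statistical structure of the assays, not the
instruments.

- **Serum screen**: baselines log-uniform over [10⁴, 10⁷] (typical LC–MS
  peak-area scales); true effects uniform in |log₂FC| ∈ [0.8, 2] applied
  negatively to consumed and positively to secreted compounds (defaults:
  1,000 compounds, 20 % consumed, 15 % secreted); replicate noise
  multiplicative lognormal with mean exactly 1 at the given CV (default
  15 %, n = 3 per group). Class counts are exact by construction.
- **Oocyte assay**: expected intracellular concentration per condition is
  background + A·c_med·(1 − e^(−kt)) for importers (first-order saturable
  uptake; A is the asymptotic accumulation ratio, A = 1 equilibrative,
  A > 1 concentrative), β·background for exporters (export is only
  measurable against a nonzero endogenous background), and background
  otherwise, with background = background_ratio · c_med. A GFP control at
  the background level is always emitted per compound. Pool response =
  pool_size · V_oocyte · C_in · lognormal(1, CV). The kinetic form and the
  1 µL oocyte volume are modeling choices — the assay itself yields a
  single timepoint and no volume, and all calls depend only on ratios.
- **Growth**: logistic OD(t) = K/(1 + ((K − od0)/od0)e^(−μt)) with both μ
  and K Hill-inhibited by 1/(1 + (c/LC50)^h), so the Max OD dose curve has
  its half-point exactly at the planted LC50 (default 2.45 mM, h = 2,
  μ0 = 0.4 h⁻¹, K0 = 1.2, od0 = 0.01, 72 h sampled every 20 min, Gaussian
  OD noise sd 0.02 truncated at zero, triplicate).

What the generators do **not** model: retention-time/adduct artifacts,
missing-at-random dropouts, inter-batch drift, correlated replicate errors,
oocyte-to-oocyte expression variability within a pool, lag phases or
diauxie, or compound precipitation at high dose. Passing recovery tests
therefore demonstrates the correctness and calibration of the statistical
pipeline under well-behaved noise, not robustness to every failure mode of
real LC–MS or plate-reader data.

## Problem sizes and reproducibility

The recovery harnesses use 1,000 screen compounds, 500 mixed + 1,000 null
oocyte conditions, 200 + 200 mode conditions, 200 noisy triplicate growth
batches, and a 7-concentration triplicate dose series — sizes at which the
binomial uncertainty of the measured rates is a small fraction of the
margins being checked, while a full run stays under a minute on one core.
Every stochastic step draws from `numpy.random.default_rng` seeded from a
single run seed (sub-seeds via `SeedSequence`), so identical configuration
and seed reproduce outputs bit for bit; the pipeline report records a
config hash, the seed, and the package version.

## Known limitations

- The significance default is per-comparison α = 0.05, matching how the
  assay's results are reported; across large transporter × compound grids
  users should enable the BH option.
- The IQR trim is uninformative below n = 4 and single-pass by design (see
  above); heavy-tailed replicate sets can retain mild outliers.
- The mode call inherits the unity response calibration: absolute
  intracellular concentrations are only as good as `response_per_mM`, but
  concentrative/equilibrative boundaries depend only on the ratio to the
  medium measured in the same units.
- LC50 extrapolation outside the tested concentration range is refused
  rather than extrapolated.
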