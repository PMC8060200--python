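# Methods

This note documents the models and procedures implemented in `trialwave`,
the parameter choices that matter, and the limits of what the simulation
experiments demonstrate.

## Trial-frequency decomposition

The analysis treats a subject's reaction times as a discrete series sampled
once per trial.  "Frequency" is therefore measured in cycles per trial:
0.05 cycles/trial is one full fluctuation every 20 trials, and the Nyquist
limit on the trial index is 0.5 cycles/trial.

For each grid frequency `f_G` a complex Gabor (Morlet) kernel is built:

    G(Δt) = (1 / (√(2π) σ_G)) · exp(−Δt² / (2 σ_G²) + i 2π f_G Δt)

* `σ_G = 0.5 / f_G` trials — the envelope width scales inversely with
  frequency, so every kernel carries the same number of oscillation cycles
  (a constant-Q filter bank, two cycles within ±2σ).
* The nominal support is `4 σ_G` trials, realized as the nearest odd tap
  count ≥ `4 σ_G` so the kernel has an exact center tap.  An odd, symmetric
  support makes the transform phase-centered on each trial and
  deterministic; the Gaussian tails truncated at ±2σ carry < 5% of the
  envelope mass.
* The frequency grid runs from `1/T` to `f_max` in steps of `1/T`
  (`0.0033` cycles/trial for the default 300-trial session).  `f_max`
  defaults to the Nyquist 0.5 and is configurable.

Choices where the design was genuinely open:

* **Mean-centering.**  The series is centered on the subject's mean RT
  before convolution.  Without centering, the ~1200 ms DC offset dominates
  every low-frequency coefficient and the map shows the mean, not the
  fluctuations.
* **Edge handling.**  The centered series is zero-padded.  Every bin whose
  kernel support extends past an edge is flagged in a cone-of-influence
  (COI) mask.  The full `T × F` map is always produced; statistics include
  COI bins by default (they carry attenuated but real signal) and can
  exclude them with a switch.
* **Power definition.**  Power is the squared modulus of the complex
  coefficient with no per-frequency renormalization beyond the
  `1/(√(2π)σ_G)` prefactor in the kernel itself.  Units are therefore
  arbitrary (ms² scaled by the kernel norm); all comparisons in the package
  are relative, so only consistency matters.

The convolution implementation is checked bin-for-bin against a naive
double-loop inner-product oracle (relative agreement ~1e-14, asserted at
1e-9 in the tests).

## Scoring the time-estimation task

Responses to the 1200 ms target are classified correct `[1000, 1400]`,
early `[400, 1000)`, late `(1400, 2000]`, missed otherwise or when no press
occurred.  The window edges at 1000/1400 ms are counted as correct and the
outer edges 400/2000 ms as early/late; the convention makes the four
classes an exact partition and is asserted by a sweep test.

`mean_rt`/`sd_rt` are computed by default over the scored (non-missed)
responses with the sample (n−1) denominator.  A `rt_over="present"` option
computes them over every key press instead; the distinction matters because
restricting to the 400–2000 ms window truncates the tails of a
high-variability response distribution and caps the attainable SD (see
*Calibration* below).

The wavelet transform needs a contiguous series, so missed trials are
filled by linear interpolation between the nearest valid neighbors (edge
gaps copy the nearest valid value).  Imputation is the minimal-assumption
gap fill that preserves series length; a validity mask records the imputed
positions so downstream statistics can discount them.  Sessions with fewer
than two valid trials are rejected.

## Cluster-based permutation comparison

Two groups of maps are compared in two steps:

1. **Bin level.**  Per bin, an unequal-variance (Welch) two-sample t for
   independent groups — group sizes in practice differ — or a paired t on
   per-subject differences.  The null is built by relabeling: uniformly
   random group-label permutations (independent) or independent sign flips
   per pair (paired), `n_shuffle` times.  Two-sided p-values use the
   add-one estimator `p = (1 + #{|t*| ≥ |t|}) / (1 + n_shuffle)`, so no p
   is ever 0 and the smallest attainable p is `1/(n_shuffle+1)`.  Bins with
   `p < alpha_bin` are marked.  Degenerate bins (zero variance in every
   subject) get `p = 1`.
2. **Cluster level.**  Marked bins of like t-sign are joined into connected
   components (4-connectivity on the trial × frequency grid by default;
   8 configurable) and each cluster's **mass** — the sum of its t values —
   is referred to the null distribution of the maximum |mass| per shuffled
   map, each shuffled map being thresholded by the same rank rule.  The
   max-statistic construction controls the family-wise error across the
   whole map at `alpha_cluster`.

Implementation details that affect exactness:

* **Symmetric thresholding.**  The observed map joins the shuffled maps in
  one reference pool of `n_shuffle + 1` t-maps; every map, observed or
  shuffled, marks a bin significant when its |t| ranks within the same
  top-K of that pool.  Under the null all `n_shuffle + 1` maps are
  exchangeable, so the procedure's family-wise error is exact up to the
  discreteness of the estimator.  Measured on 1,000 null cohorts
  (n = 10/group, 100 trials, 500 shuffles, bin threshold 0.01): 5.2%
  false-alarm rate at the nominal 5%.
* **Exhaustive enumeration.**  When the design admits no more distinct
  relabelings than `n_shuffle` (≤ `C(n, n_a)` independent, `2^n` paired),
  all of them are enumerated and `p = #{|t*| ≥ |t|}/N` with the identity
  included — exact p-values, verified against brute-force enumeration.
  Enumerated designs contain mathematically tied |t| values (complementary
  assignments); |t| is quantized to float32 before ranking so such ties
  survive floating-point summation-order noise.
* **Cluster statistic.**  Mass (sum of t) rather than extent: it rewards
  both strong and large effects and is the common default for this family
  of tests.  Sign-separated clusters with two-sided p throughout.
* **Attainability.**  `alpha_bin` must exceed the smallest attainable
  permutation p; otherwise no bin can ever be marked and the test is
  vacuous.  The engine logs an explicit warning in that case.  The
  production configuration (5000 shuffles, `alpha_bin = 0.001`) is
  attainable; the scaled-down validation runs (500 shuffles) use
  `alpha_bin = 0.01` for the same reason.  Family-wise error control holds
  at any attainable cluster-forming threshold; the threshold trades
  sensitivity between focal-strong and broad-weak effects.

Defaults: `n_shuffle = 5000`, `alpha_bin = 0.001`, `alpha_cluster = 0.05`,
4-connectivity, two-sided, COI bins included.

## Synthetic data

The generator emulates 300-trial time-estimation sessions (three blocks of
100; block structure is bookkeeping only — no block effects are modeled).

**Generative model.**  RTs are Gaussian around a group mean with a tonic
noise SD; intermittent variability is modeled as randomly placed,
non-overlapping burst epochs inside which the noise SD is multiplied by a
constant.  Each trial is independently missed (no key press) with a fixed
probability.  Draws are clipped at 0 ms.  This is the minimal model that
produces the "intermittent, strong variability" phenotype while leaving
tonic level, burst structure, and missingness independently controllable;
it deliberately omits feedback-driven learning, autocorrelated (e.g. AR or
1/f) noise, RT skew (log-normal/ex-Gaussian shape), and fatigue or practice
trends across blocks.  Passing tests therefore demonstrate properties of
the *analysis* under controlled variability structure, not that real
patient data look like these draws.

**Archetype profiles** (`generate_profile`) make "same SD, different
structure" exact: after drawing the kind-specific deviation process
(uniform i.i.d. noise; sparse bursts: 3 epochs × 20 trials at 5× SD; dense
bursts: 6 epochs × 10 trials at 3× SD; slow drift: 0.01 cycles/trial
sinusoid with random phase plus 0.4-weight noise), deviations are centered
and rescaled so the sample SD equals the target exactly, then the mean is
added.  Separability of the four archetypes is operationalized as: both
burst kinds exceed uniform in maximal 20-trial windowed SD; sparse-burst
trial-marginal wavelet power is higher inside its epochs than outside; the
drift kind has a larger below-0.02-cycles/trial power fraction than
uniform.  All three hold in ≥ 95% of seeds (measured: 100%).

**Calibration.**  The control-like group uses mean RT 1171 ms, tonic SD
247 ms, 1% misses.  The patient-like group uses mean RT 1137 ms, tonic SD
247 ms plus 4 bursts of 16 trials at 3× SD and 4% misses; the implied
session SD is `247·√(1 + (64/300)·8) ≈ 406 ms`, and the realized SD over
all key presses averages ~400 ms across subjects.  Restricted to the
scored 400–2000 ms window the same sessions show an SD near 280 ms: the
window truncates the burst tails, and no within-window Gaussian mixture
can reach an SD of ~400 ms there without emptying the window.  A cohort
whose *scored* SD is that large must be strongly bimodal within the
window — a feature of real patient data this Gaussian-burst generator does
not reproduce, and a known limitation.

**Tonic shift.**  `apply_tonic_shift` adds a constant to every present RT.
Because both the sample SD and the mean-centered wavelet transform are
translation-invariant, the power map is unchanged (to 1e-9 relative, when
no response crosses a classification boundary into missingness) while
accuracy counts move — the dissociation between a shifted overall response
level and an unchanged fluctuation profile.

**Seeding.**  All randomness flows from `numpy` `SeedSequence`s: cohorts
spawn one child stream per subject from a master seed, and the experiment
drivers derive independent sub-seeds (< 2³¹) per replicate.  Identical
seeds reproduce results bit-for-bit.

## Validation experiment sizes

The simulation battery (`trialwave.experiments`, run by the test suite and
by `scripts/acceptance.py`) uses problem sizes chosen to finish in minutes
on one CPU while keeping the binomial uncertainty of the measured rates
informative:

* family-wise error: 200 null cohorts, n = 10/group, 100 trials,
  500 shuffles, bin threshold 0.01; the pass band is the binomial 95%
  interval around 0.05 (±0.030 at 200 replicates);
* detection power: 50 cohorts, n = 20/group, 300 trials, a 2× tonic-SD
  burst over trials 100–160; detection means a significant cluster whose
  trial span intersects the burst;
* oracle agreement: series up to 64 trials, full grids;
* archetype separability: 100 seeds;
* exact-permutation agreement: independent designs up to C(8,4) = 70 and
  paired designs up to 2⁶ = 64 relabelings.

## Known limitations

* The generative model is Gaussian and trialwise-independent outside
  bursts; real RT series are right-skewed and autocorrelated.
* Burst epochs have hard edges and constant multipliers; real attentional
  lapses presumably wax and wane.
* The scored-window SD of the patient-like group underestimates targets
  derived from strongly bimodal empirical distributions (see
  *Calibration*).
* Power maps are compared bin-by-bin after a common grid; sessions of
  different lengths cannot be mixed in one comparison.
* The per-bin permutation null is computed per bin, not pooled across
  bins; a pooled variant is not implemented.
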