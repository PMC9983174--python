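# Methods

## Model

`reopair` treats the within-sample ordering of an ordered feature pair
(*a*, *b*) — *E_a > E_b* versus *E_a ≤ E_b* — as one binary qualitative
feature. The working assumptions are:

- In a reference ("control") phenotype, some pair orderings are nearly
  invariant across individuals (held in ≥ 95% of samples by default).
- Disease ("case") samples perturb a subset of these orderings; a pair
  whose ordering distribution differs significantly between phenotypes
  carries diagnostic signal.
- Technical variation (batch, scanner gain, normalisation, partial
  degradation) acts approximately as a strictly increasing transform *per
  sample* and therefore cannot change any within-sample ordering. This is
  the design premise that makes the final classifier a true single-sample
  rule: predictions are a function of pairwise comparisons inside one
  expression vector only.

The pipeline is deliberately free of randomness: screening, coverage
growth, activity scoring, panel selection and prediction are all
deterministic given their inputs. The only seeded operations are the
synthetic-data generator and the optional balanced-subsampling pre-step of
`discover`.

## Tie convention

Exact expression ties (*E_a = E_b*) count as *E_a ≤ E_b* everywhere: in
fractions, contingency counts, coverage and votes. The two patterns then
partition every sample, and all stages agree on the boundary. One
asymmetry follows deliberately: a sample whose panel votes split exactly
at the threshold is called *case* ("more than *t*" is strict).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `stability_threshold` | 0.95 | min fraction of control samples holding *E_a > E_b* for a stable pair; lower (e.g. 0.8) admits more pairs in harder contrasts |
| `fdr` | 0.05 | BH false-discovery level for reversal tests, over the stable-pair family |
| `delta_p_threshold` | 1.0 | min ΔP = *P*ctrl − *P*case for candidates; 1.0 keeps only complete reversals, 0.7 is a workable preset when none exist |
| `sd_multiple` (QC) | 2.0 | outlier cut in SDs of per-sample mean correlation |
| `vote_threshold` | ⌊panel/2⌋ | control votes that must be strictly exceeded to call control |

The vote threshold is an explicit model field rather than a hidden
convention because published pair-voting rules are not uniform: "more than
3 of 5" is stricter than a bare majority, while "more than 16 of 32" *is*
the strict majority. Both are expressible by setting the field; the
pipeline default is strict majority.

## Screening details

- All *n*(*n*−1) ordered pairs are enumerated, lexicographically by
  (*a*, *b*) feature id. This order also defines every downstream
  tie-break ("first wins") and the meaning of "the first *N* pairs" in
  direct mode, so whole runs are reproducible bit for bit.
- Only pairs stable as *E_a > E_b* in controls are tested for reversal;
  ΔP is signed, not absolute.
- The Fisher test is two-sided (the hypothesis is "the distributions
  differ", not a one-directional shift); p-values come from
  `scipy.stats.fisher_exact` and are cached per (n₁, m₁) since margins are
  fixed within one screen.
- BH adjustment is a ~10-line step-up shared by the screening and
  differential-expression modules; a property test checks it against
  statsmodels' `fdr_bh` on random vectors.
- Threshold comparisons on count ratios (`≥ stability_threshold`,
  `≥ delta_p_threshold`) subtract a 1e-12 guard so that exact fractions
  like 19/20 cannot fall on the wrong side of a binary decision through
  floating-point rounding. Both inclusive thresholds are deliberate: a
  pair holding in exactly 95% of controls is stable, ΔP exactly at the
  cut is a candidate.
- Pair counting is blocked over features (64 rows at a time), so a
  2550-feature × 150-sample screen needs ~25 MB of transient booleans
  rather than the ~6.5M-pair × sample tensor.

## QC details

Pearson correlation is computed on intensities as provided (no log), per
phenotype within one matrix, and the outlier rule runs in a single pass:
the criterion describes one cut, and iterating it would re-anchor the
bounds on a shrinking set. Spread is the sample SD (ddof = 1) of the
per-sample mean correlations; a sample exactly on the boundary is
retained ("outside" is strict). A zero-variance sample has no defined
correlation and is removed and reported as degenerate; means for the
remaining samples are taken over their defined correlations only. Missing
values anywhere are a hard error — the intended inputs are complete
platform matrices, and the method defines no imputation.

## Panel selection details

Coverage growth stops at the first round whose best gain is zero; a
zero-gain candidate is never skipped in favour of a later one. Activity
ranking sorts by score descending with enumeration order breaking ties.
For *k*-selection, every prefix of the ranking is evaluated on the same
training samples used for screening (the procedure defines no held-out
split), and an undefined PPV or NPV (empty predicted class) counts as 0 in
the geometric mean — conservative, and recorded as-is in the k-curve. The
selected *k* is the smallest one attaining the global maximum.

## Synthetic cohorts

The generator plants the structure the method assumes, for testing without
any external data:

- Feature levels are log-normal: per-feature baseline log2 level
  ~ N(8, 1.5), i.i.d. Gaussian observation noise (SD `noise_sd`, default
  0.3) in log space, intensities 2^x.
- A planted stable pair separates its two features' levels by
  δ = √2·σ·Φ⁻¹(hold fraction), which makes the *expected* control fraction
  hit the target; realised fractions are Binomial(n, target)/n and are
  recorded in the ground truth. Reversed pairs use the analogous
  separation in the case group targeting *P*case = hold − ΔP (clamped at
  0). With `noise_sd = 0` the planted fractions are exactly 1 and 0.
- Planted pairs sit on well-separated log2-level tiers (16 + 3·k) above
  the null features' range. The tier spacing dwarfs the within-pair
  separations and the noise, so a planted reversal cannot drag a feature
  across any other feature's level: the set of truly reversed pairs is
  exactly the planted set, which is what makes exact-recovery tests
  meaningful. Defaults (200 features, 50+50 samples, 20 stable / 10
  reversed planted pairs) mirror a modest profiling study arm.
- Distortions (`per_sample_scale`, `log`, `batch_shift`) are strictly
  increasing per sample and applied last; they must leave every screen and
  prediction bit-identical, and tests assert exactly that.
- Outlier injection appends rank-reversed copies of the phenotype mean
  profile (the highest-expressed feature gets the lowest value), with a
  ±1% multiplicative jitter to avoid exact ties — strongly anti-correlated
  with every genuine sample, the situation the QC rule targets.

What the generator does **not** emulate: realistic platform intensity
distributions, correlation structure among features (features are
independent given their levels), compositional effects, or missingness.
Passing tests therefore demonstrate correctness of the algorithms under
the method's own assumptions, not performance on real serum profiles.

## Differential expression

Classic equal-variance two-sample Student's t per feature (Welch and log2
variants behind flags), BH over all tested features. Zero variance in both
groups makes the statistic undefined; such features are reported with
t = 0, p = 1 and logged rather than dropped, so the BH family stays the
full feature set.

## Known limitations

- Greedy maximum coverage is a heuristic; it is locally optimal (verified
  against one-step deviations and brute force on small instances) but not
  globally so, and no weighted or cross-validated variant is provided.
- Panel-size selection reuses the training samples; with few samples the
  k-curve is optimistically biased and external validation is essential.
- The screen's Fisher p-values are conditioned on pair stability assessed
  on the same controls, a mild selection effect inherent to the procedure.
- Performance: screening is O(n²·s) in features × samples; 2550 features
  are fine, but ~10⁴+ features would need the stability threshold applied
  before pairing or a sparser enumeration.
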