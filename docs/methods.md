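# Methods

## Model and assumptions

`wrda` targets the common short-longitudinal design in metabolomics: two
groups (control C, model/case M), N = 5–10 time points, and a few samples
per group per point. The discriminability of a feature is measured by the
weighted relative-difference accumulation

    wRDA(f) = D(f) / (S(f) + ε),
    D(f) = Σ_i ω_i |μ_C,f(i) − μ_M,f(i)|,
    S(f) = Σ_i ω_i (σ_C,f(i) + σ_M,f(i)),

a time-course analogue of the SAM relative-difference score: a numerator
that accumulates between-group mean separation along the trajectory, a
denominator that accumulates within-group scatter, and a small regularizer
ε that keeps near-constant features from exploding the ratio. The statistic
only uses first and second moments per stratum; it assumes nothing about
the shape of the trajectories, but it does assume that per-stratum means
and SDs are meaningful (i.e., intensities are roughly unimodal within a
stratum, which is why the preprocessing stage removes dropout-ridden
features and corrects gross spikes first).

The w²RDA extension inserts a weight k_j over sampling times (collection
batches) within each time point. S is ω- and k-weighted in the same way as
D, so scores are invariant to a common rescaling of the weights when ε = 0,
and invariant for any ε when weights are normalized (the default). The
reduction w²RDA → wRDA at p_i = 1, k = (1) is exact and is enforced by
test.

Two formula choices were genuinely open and are isolated in
`scoring._accumulate` so an alternative is a one-line swap: S is
ω-weighted (not a plain sum of SDs), and k applies outside the absolute
mean difference. Both choices preserve the D/S scale symmetry above, which
is what makes the score comparable across weight schemes in the grid
search.

## Parameters

| parameter | default | meaning |
|---|---|---|
| ε | 0.005 | score regularizer; same units as the weighted SD sum |
| ω family, q | equal | time-point weights; q ≥ 0 steepness, index 0 heaviest |
| k family, q | equal | sampling-time weights, regenerated per point when p_i varies |
| max_zero_frac | 0.2 | strict threshold of the per-stratum zero-fraction filter |
| k_sigma | 2.0 | outlier flagging range μ ± k_sigma·σ |
| B | 200 | permutations for the null distribution |
| noise quantile | 0.95 | pooled-null cutoff of the noise filter |
| n grid | 50,45,40,35,30 | top-n cuts for the lowest-FDR criterion |
| q grid | 0.1…1.0 step 0.1 | changing factors searched per parametric family |
| SVM | RBF, 5-fold × 50 | validation protocol; per-fold standardization |

Normalizing weight vectors to sum to 1 is a deliberate default: it gives ε
a scale-stable meaning when FDR values are compared across weight schemes
in the grid search. Raw (unnormalized) values stay available on the
`WeightScheme`.

## Permutation, FDR, and selection

Labels are shuffled within each (time point, sampling time) stratum,
preserving the design's per-stratum sample counts — the only shuffling
unit that keeps the time structure intact. The FDR at a top-n cut is
`min(1, E[V]/n)` with `E[V]` the mean count of null scores ≥ the n-th
largest observed score, across the B permutations; no π₀ correction is
applied, so the estimate is conservative under partial signal. An
exhaustive enumerator (`exhaustive_null`) exists for tiny datasets and is
used to verify the estimator exactly.

The noise filter retains features scoring above a pooled-null quantile
(default 0.95). Under exchangeable groups this retains ~5% of features by
construction; on planted-signal data it is a recall-oriented filter, and
the post-filter FDR curve is reported so a stricter criterion (e.g. FDR 0)
can be applied downstream.

Grid-search selection: global minimum of the lowest FDR over all
(k family, q_k, ω family, q_ω) cells; among tied minima, first the modal
family pair among the tied cells, then the smallest q_k, then the smallest
q_ω (the equal family counts as the q = 0 limit). Each cell derives its
permutation stream from (master seed, cell index), so results are
reproducible and adding cells never perturbs existing ones.

## Synthetic data

The generator draws control values from Normal(baseline, SD) and shifts
planted features in M by δ·SD, scaled by a divergence profile over time
points (step onset, linear ramp, or exponential decay away from index 0)
and attenuated by `storage_decay^j` across sampling times. Dropouts
(values set to 0) are injected before spikes, mirroring the order of the
two instrument artifacts. Presets: an animal-style design (N = 8, p = 1,
10+10 per point, step onset at the 5th point, 2% dropouts, 1% spikes) and
a cohort-style design (N = 5, p = 4, 6 C / 3 M per cell, exponential-decay
divergence, storage decay 0.8).

What the generator does **not** emulate: log-normal intensity skew beyond
what the non-negativity clip induces, correlated feature blocks
(co-eluting ions, shared pathways), batch drift, and missingness that is
informative rather than random. Passing tests therefore demonstrate the
method's statistical behavior under its own assumptions, not performance
on any real cohort.

## Numerical choices and degenerate inputs

- Sample SD uses denominator n−1; singleton strata get σ = 0 with a
  diagnostic instead of an error, so sparse cohort cells never crash
  scoring.
- Rank ties break by input feature order (stable sort), making every
  top-n list deterministic.
- Zero-weight time points (and zero k_j) are skipped entirely, so data at
  those points can never influence scores — the property the two-level
  workflow's explicit weights rely on.
- Outlier flagging uses the stratum's statistics *including* the outlier;
  replacements are rejection-sampled from a normal fitted to the in-range
  values and clipped at 0 (intensities are non-negative; the clip cannot
  leave the acceptance range).
- The strict `>` in the 20% zero rule means a stratum at exactly the
  threshold is retained.
- CSV round-trips are bit-exact (`float_precision="round_trip"` on read).

## Known limitations

- The μ ± 2σ outlier rule suffers masking: two or more coincident dropouts
  in one small stratum inflate σ enough that neither is flagged, leaving
  the stratum's SD inflated and the feature's score depressed. On the
  animal-style preset with 2% dropouts this costs the end-to-end pipeline
  roughly 10 points of top-30 recall relative to dropout-free data. A
  robust (median/MAD) variant would mitigate this but is deliberately out
  of scope.
- The SVM validation classifies samples pooled across all time points;
  when divergence only begins mid-course, pre-onset samples are
  intrinsically inseparable and cap the achievable accuracy well below
  100% even for perfectly recovered panels.
- FDR estimates at small B and small F are grainy (resolution 1/(B·n));
  the defaults (B = 200) match the intended operating range.
- Scoring is two-group only; multi-class designs and per-feature adaptive
  regularization (SAM's s₀ percentile tuning) are non-goals.
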