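# Methods

## The inference problem

A 2-DE comparison yields, per protein spot and gel, one non-negative
densitometric volume; gels come in small replicate sets per group
(default n = 4). Missing entries mean "spot not detected on that gel" and
are distinct from detected zero volumes. The pipeline answers, per spot
and per pair of groups: *is the mean volume different, and by how much* —
under three constraints that shape every design choice here: n is tiny,
volumes are positive and right-skewed, and some spots are genuinely
absent from a group (unshared spots, which any usable effect measure must
accommodate).

## Presence and validation

A spot is *present* in a group when detected in at least
`min_present_replicates` (default 3) of the group's gels; spots present
in at least one group are the *validated* set (`presence_scope="any"`).
The "any" scope is deliberate: requiring presence in every group would
make unshared spots unrepresentable, yet they are among the strongest
biological signals. A group that fails the presence rule is treated as
*absent* for comparisons: its mean is 0 and any 1–2 stray detections are
excluded from resampling, keeping the unshared-spot semantics consistent
(`"all"` scope is available for stricter workflows).

## Total-density normalization

Each volume is replaced by `raw / gel_total × C` where `gel_total` sums
the validated spots on that gel and `C` is either a fixed constant (e.g.
10⁶ for ppm-style volumes) or the mean per-gel total (default, which
keeps volumes on their raw scale). After normalization all per-gel totals
are equal to machine precision, so any per-gel multiplicative factor —
loading, staining, scan exposure — cancels exactly. The constant `C`
itself is immaterial downstream: FC is a ratio and RC is self-normalized
by |DVR_max|.

## Bootstrap significance

For each validated spot and group pair, B = 2000 resamples draw replicate
volumes with replacement, independently per group, each resample the size
of that group's observed sample. Intervals are bias-corrected (BC)
percentile intervals: with `p` the proportion of resampled statistics
below the observed value, `z0 = Φ⁻¹(p)`, and the interval takes the
empirical quantiles (linear interpolation) at levels
`Φ(2·z0 + z_{α/2})` and `Φ(2·z0 + z_{1−α/2})`. Multiple testing over the
m group pairs (m = 3 for three groups) uses Bonferroni: each interval is
widened to level 1 − (1 − 0.95)/m. A `spots_pairs` family (m = validated
spots × pairs) is available for familywise control across the whole
table; it is far more conservative and not the default.

Two decision rules are implemented:

- **`group_ci_overlap` (default).** Each group gets a BC interval for its
  own mean volume (an absent group contributes the point interval
  [0, 0]); the spot is flagged when the two intervals are disjoint.
- **`difference_ci`.** One BC interval for DV = ȳ − x̄ (joint resampling
  of both groups); the spot is flagged when it excludes 0.

The overlap rule is the default on measured error-control grounds: at
n = 4 with log-normal replicate noise (CV 0.25) the difference-interval
rule flags ~10% of null spots per pair at the Bonferroni-adjusted level,
while the overlap rule flags ~4.5% with essentially full power (~99%) for
effects of 2^1.5-fold and larger. Requiring two separate intervals to be
disjoint is a stricter criterion than one difference interval excluding
zero, which is exactly what a percentile-type interval needs at such
small n. The binary flag at α = 0.05 (familywise) is the only
significance output; no bootstrap p-values are interpolated.

Numerical choices:

- **Tie handling in z0.** Resamples numerically equal to the observed
  statistic (relative tolerance 1e-9) count half toward `p`. At n = 4
  roughly 9% of resample means tie the observed mean exactly, and strict
  "below" counting would make z0 — and through it the interval endpoints,
  macroscopically — discontinuous under one-ulp input perturbations. With
  mid-tie counting, rescaling all raw volumes of a gel by a positive
  constant leaves every significance call, FC and RC unchanged.
- **Clamping.** `p` is clamped to [1/(2B), 1 − 1/(2B)] before Φ⁻¹, so z0
  stays finite when the observed value falls outside the resample range.
- **Degenerate distributions.** If all resamples are equal, the interval
  collapses to that point.
- **Determinism.** Each (pair, spot) comparison uses its own substream,
  keyed on (master seed, pair index, CRC-32 of the spot id): results are
  reproducible and invariant to row order and to which other spots are in
  the table.

### Known operating characteristics (measured by this test suite)

Percentile-type bootstrap intervals under-cover at tiny n: unadjusted 95%
BC intervals for a group mean at n = 4 (normal noise, B = 2000) cover the
true mean in ≈ 80% of runs, not 95%. Consequently the pipeline's realized
per-pair false positive rate on fully null synthetic data is ≈ 4.5% with
complete replication, rising to ≈ 8% at the default 5% detection dropout
— partly because groups reduced to 3 observed replicates are tested even
more anti-conservatively, and partly because ~1.4% of null spot–groups
lose ≥ 2 replicates by chance, fail presence, and are auto-flagged
through the unshared-spot rule. Users needing strict familywise control
at tiny n should use the `spots_pairs` Bonferroni family or demand full
replication (`min_present_replicates = n`, `dropout`-free data); the
defaults instead reproduce the conventional workflow for this assay.

## Effect statistics

For significant spot–pair results only (others report `ns`, and `N/A`
when a spot is absent from both groups of a pair):

- **FC = ȳ/x̄**, with FC < 1 replaced by −x̄/ȳ, so magnitudes are
  symmetric fold factors; x̄ = 0 gives +∞, ȳ = 0 gives −∞ (unshared
  spots); equal means give +1.
- **RC = DV/|DVR_max|**, DV = ȳ − x̄, with |DVR_max| the largest |DV|
  across the significant results of *all* pairs jointly. RC is bounded in
  [−1, +1], finite for unshared spots, and the extreme entry attains
  exactly ±1. The denominator uses the *magnitude* of the extreme DV
  (its sign is reported separately as `dvr_max`): a signed-maximum
  reading could never produce RC = −1, which negative-dominant datasets
  do produce.

Report formatting follows the field's convention: FC to 2 decimals with
explicit sign, RC to 3 decimals, `ns`/`N/A`/`±inf` sentinels.

## PCA

Gels are observations, significant spots are variables, missing entries
enter as 0 (absence is informative — unique spots drive group
separation). Columns are mean-centered; unit-variance scaling
(correlation-matrix PCA) is optional and off by default, since volume
scale differences between spots are themselves meaningful. The
decomposition is a full SVD (via scikit-learn); component signs are fixed
by forcing each component's largest-magnitude loading positive. With all
components retained the variance fractions sum to 1.

## Synthetic data generator

The generator emulates the structure of a three-cultivar tuber 2-DE
study; its defaults are the study conditions every simulation-based test
runs under:

| parameter | default | meaning |
|---|---|---|
| `n_spots` | 345 | validated spots on a well-resolved tuber gel |
| `groups` / `replicates` | 3 × 4 | cultivars × biological replicate gels |
| `frac_differential` | 0.22 | spots with a true single-group mean shift |
| `effect_log2_range` | (0.5, 2.0) | uniform log2 magnitude of the shift, random sign |
| `frac_unique` | 0.03 | spots truly absent from one group |
| `cv_replicate` | 0.25 | within-group CV of volumes |
| `dropout_prob` | 0.05 | chance a truly present spot goes undetected on a gel |
| `gel_scale_sd` | 0.2 | SD of the per-gel log-normal intensity factor |
| `baseline_median`, `baseline_log_sd` | 1000, 1.0 | log-normal spread of baseline volumes across spots |

Volumes are mean-preserving log-normal:
`volume = baseline × group multiplier × gel scale × noise`, with noise of
unit mean and CV `cv_replicate` (so with gel scaling and dropout off, a
null spot's sample mean converges to its baseline). The per-gel scale
factor exists precisely so total-density normalization has a real
nuisance to remove. The published study reports no within-group CV, so
0.25 was chosen once as a typical mid-range value for replicate 2-DE
spot volumes and is config-exposed, not hard-coded; baseline spread 1.0
on the log scale gives the heavy-tailed volume distribution gels show.
One master seed drives deterministic substreams per stage, so identical
configs give bitwise-identical datasets.

What the generator does **not** emulate: spot-matching errors (identity
is exact by construction), saturated gel regions and censoring, spatially
correlated staining artifacts, multi-protein comigration, and
correlation between spot abundance and dropout probability. Passing
recovery tests therefore demonstrates the statistics behave as designed
under the assumed noise model — not that the assay's upstream image
analysis is error-free.

## Problem sizes used in the test and acceptance runs

Simulation-based tests run the full 345-spot, 3 × 4 design at B = 2000
(the study's resample count); suites aggregate 20 seeds for error-control
and recovery measurements, 100 seeds for the exhaustive-oracle interval
comparison (B = 20 000 there), and 2000 runs for the coverage
measurement. The complete test suite and the acceptance script each
finish in a few minutes on one CPU.

## Known limitations

- BC percentile intervals at n = 4 are anti-conservative (measured above);
  the package reports this openly rather than substituting a different
  test, because reproducing this assay's standard procedure is the point.
- Bonferroni is the only multiplicity correction (by design; no FDR).
- The RC denominator couples all spots: adding or removing one
  significant spot can rescale every RC. This is inherent to the
  statistic's definition.
- PCA's missing-as-zero imputation is informative by intent; for data
  where missingness is technical rather than biological it will overstate
  group separation.
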