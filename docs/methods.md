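# Methods

## Measurement model

Each skeletal element (pelvis or femur vestige) is defined by two landmarks
per side — anterior/posterior points for the pelvis, proximal/distal for the
femur — digitized on a 3D surface and exported as MeshLab picked-points XML.
Element length is the Euclidean distance between the two landmarks, rounded
half-to-even to 2 decimal places (mm).  Rounding happens exactly once, at
measurement time, and all downstream statistics consume the rounded values;
this is load-bearing, because specimens whose sides round to equal lengths
are classified symmetric (PA = 0.00) and excluded from the frequency test
while still counting toward N.  Rounding is IEEE-754 banker's rounding on
binary doubles, so decimal literals that look like exact ties (e.g. 0.005)
may round per their nearest binary representation.

Only intra-specimen distances are used, so no coordinate system, scale
calibration, or handedness is assumed beyond coordinates being mm.  Landmark
names are mapped to anatomy by an ordered regex rule table because exporters
do not share a naming convention; unmatched names are reported, never
silently dropped, and deactivated points are parsed but never mapped.
Breakage cannot be expressed in a landmark file, so broken-element flags come
from a per-specimen metadata sidecar (`specimens.csv`).

No allometric size correction is applied (percent asymmetry is assumed
isometric with body size), and no sex covariate exists (museum specimens
usually cannot be sexed non-destructively).

## Asymmetry statistic and direction classes

PA = 100·(R − L)/(R + L), rounded to 2 dp; PA < 0 ⇔ left side larger.  PA is
scale-free (invariant to multiplying both sides by k > 0, up to rounding) and
bounded in [−100, 100].  Direction is classified from the rounded value:
negative → left-larger, positive → right-larger, 0.00 → symmetric.

## Outlier screens

Lengths: per taxon × element × **side**, records more than 3 sample SDs
(n−1 denominator) from the side mean are flagged and excluded whole (both
sides — asymmetry needs both; the same specimen's other element is kept).
Sides are screened separately because a genuine directional bias would
inflate a pooled SD.  The screen is deliberately single-pass: mean and SD are
estimated once from all non-excluded values and flagging does not trigger
re-estimation, so a moderate value masked by a gross one survives.  The
comparison is strict (> 3 SD); zero SD or fewer than 3 records flags
nothing.  Flagging is advisory — the intended workflow is that a human
re-checks flagged digitizations, and the pipeline accepts an override list
that un-excludes records after inspection.

A second, optional screen applies the same 3-SD rule to the PA values per
taxon × element (reason `outlier_asymmetry`).  It is **off by default**: the
primary analysis screens lengths only, and the PA screen exists for post hoc
sensitivity reanalysis.  Whether published analyses of this kind removed
offending values or whole specimens is generally unstated; this package
removes the whole element record, the conservative choice given PA needs both
sides.

## Frequency test

The deliberate design decision in this package: the 50:50 frequency test is
computed as a chi square on the 2×2 table

        left   right
    obs  n_L    n_R
    exp   E      E        E = (n_L + n_R)/2  (may be half-integral)

with expected cell counts from the table margins and Yates continuity
correction, each cell contributing max(|O − Ê| − 0.5, 0)²/Ê, p from χ²(1).
This is what R's `chisq.test` does when handed a 2×2 matrix, and it — not the
plain one-sample goodness-of-fit Σ(O − E)²/E — reproduces the published
statistics for all nine reported count pairs (e.g. 48 vs 70 → 1.71, where the
uncorrected statistic is 4.10).  Properties worth noting: the statistic is
symmetric in (n_L, n_R), is exactly 0 whenever |n_L − n_R| ≤ 1 (the clamp at
zero matters here; scipy's `chi2_contingency` does not clamp and differs in
that regime), and the continuity correction makes the test conservative —
under a simulated null its rejection rate at α = 0.05 is well below 0.05.
An exact two-sided binomial test and the uncorrected goodness-of-fit are
available as labelled alternatives (`method=`).

## Magnitude test

Paired two-tailed t on raw left/right lengths: d = R − L, t = d̄/(s_d/√N),
df = N − 1, with zero-difference pairs retained (they are evidence of
symmetry, and df = N − 1 with N the full count matches the reported degrees
of freedom).  Whether such analyses pair raw lengths or PA values is usually
ambiguous — the sign is identical, magnitudes differ; raw lengths are the
default here (the literal reading of "left-side size vs right-side size") and
a one-sample t of PA against zero is available via `paired_on="pa"`.  When
s_d = 0 the statistic is undefined and reported as NaN rather than raising,
since it can arise in legitimate heavily-rounded data.  Reported alongside:
mean and SD of the per-individual PA values.  p-values are formatted
leading-zero-stripped at 3 dp (".191") only at the reporting layer; full
precision is kept internally.

Bonferroni correction divides the family α by the number of tests per
statistical approach (default 9, the taxon × element contrasts per test
family): 0.05/9 = 0.00556, reported as 0.006.

## Power analysis

Power of the 1-df frequency test at Cohen's effect size w and sample size N:
λ = N·w², power = P[X > c] with X ~ noncentral χ²(df, λ) and c the (1 − α)
central quantile — evaluated with scipy's `ncx2`.  At w = 0 the function
returns α exactly (special-cased rather than evaluating `ncx2` at zero
noncentrality).  `required_sample_size` inverts the curve by doubling bracket
plus integer bisection, returning the smallest N with power strictly above
the target; at w = 0.25, α = 0.05, df = 1 the crossing of 0.50 power is at
N = 62 (power 0.4907 at 60, 0.4971 at 61, 0.5034 at 62).  N is interpreted as
the count of informative (asymmetric) individuals — the same N entering the
frequency test; planning should anticipate symmetric individuals and
exclusions on top of it.  The power module covers only the chi-square
frequency test, not the paired t.

## Synthetic generator

The generative primitive is PA itself, so true parameters are directly
comparable to reported "mean (SD)" percent-asymmetry columns:

    S_i = mean_size · exp(ε_i),  ε_i ~ N(0, size_cv)     lognormal size, always positive
    P_i ~ N(mu_pa, sigma_pa)                              signed PA, %; negative = left-larger
    L_i = S_i (1 − P_i/100),  R_i = S_i (1 + P_i/100)  ⇒  PA(L_i, R_i) = P_i exactly

`mu_pa` is the directional asymmetry, `sigma_pa` the fluctuating-asymmetry
noise; size and asymmetry are independent (the isometry assumption).
Contamination multiplies one random side by `outlier_scale` with probability
`outlier_rate` per specimen — the gross digitization error the length screen
targets.  Generated lengths are stored at full precision; the 2-dp rounding
belongs to the measurement layer, which keeps the construction identity
PA(L_i, R_i) = round(P_i, 2) exact (rounding the two sides independently
first would perturb PA by up to ~0.1% at mm scale).  Landmark emission places
the two landmarks of each side exactly `length` apart, applies one random
rigid transform per specimen, and adds isotropic N(0, digit_noise) per
landmark; names follow the default naming rules so the default config maps
them back.  All randomness flows from the single `seed` (replicate seeds in
`recovery_experiment` are spawned from it deterministically).

Defaults are meant as realistic museum-study conditions, chosen once:
80 specimens (a sensible planning floor given the power analysis), 5 mm mean
vestige length, 20% size CV, mu_pa = 0 (null), sigma_pa = 2% (mid-range for
vestigial elements, whose reported FA SDs run roughly 0.6–7%), no noise or
contamination.

What the generator does **not** emulate: CT/meshing artifacts, ossification
variation, non-Gaussian FA (real FA is often leptokurtic), asymmetry–size
allometry, or missing/broken elements arising naturally.  Passing recovery
tests therefore validate the statistical machinery under the stated model,
not robustness to every property of real museum data.

## Numerical choices and degenerate inputs

- Sample SDs use the n−1 denominator throughout.
- A fully symmetric sample (no informative individuals) makes the frequency
  test raise, and zero-SD paired differences make t NaN; the pipeline
  propagates both rather than guessing.
- Outlier groups with < 3 records or zero SD are left untouched.
- The generator clips lengths at a hairline positive value if an extreme FA
  draw would cross ±100% asymmetry (only relevant at absurd sigma_pa).
- `required_sample_size` guarantees power(N) > target ≥ power(N − 1).

## Problem sizes used in validation

Simulation-based checks run at 300–1000 replicates of samples of 72–100
specimens (the scale of the real samples); the Monte-Carlo cross-check of the
power function uses 10⁶ draws (MC SE ≈ 0.0005), and the brute-force
cross-check of the chi-square statistic sweeps 1000 random count pairs up to
200 per side.  Convergence checks of the generator run up to 5000 specimens.

## Known limitations

- The frequency test's 2×2 construction treats the 50:50 expectation row as
  if it were observed data; that is precisely the published convention being
  reproduced, not an endorsement of it over the exact binomial test, which is
  one keyword away.
- Rank-magnitude plot data (sorted |PA| by direction class with class
  percentages) are the tested surface; the bundled matplotlib renderer is a
  convenience and makes no layout guarantees.
- Multi-element taxa are handled by repeated generator calls sharing specimen
  ids; the generator does not model within-specimen correlation between
  elements' asymmetries.
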