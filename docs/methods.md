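# Methods

## Model and procedure

One analysis unit is a (SNP, ethnicity stratum) pair with an accumulating
sequence of case-control studies. The pipeline is:

1. **Allele model.** Genotype person counts (mm, Mm, MM) are collapsed to
   allele counts: a study contributes `2·n_mm + n_Mm` minor and
   `2·n_MM + n_Mm` major alleles per arm. The minor allele is fixed by the
   external reference frequency table (per ancestry group), not re-derived
   from each study's counts, so effect directions cannot flip between
   studies of the same locus. Dominant/recessive/genotypic models are out
   of scope.
2. **Per-study effect.** Log odds ratio with the Woolf standard error
   `sqrt(1/a + 1/b + 1/c + 1/d)`. If any cell is zero, the continuity
   constant (default 0.5, Haldane–Anscombe) is added to all four cells of
   that table only. Tables with an empty margin (e.g. a monomorphic study)
   carry no information about the OR and are excluded with a logged
   warning.
3. **Cumulative random-effects pooling.** Studies are ordered by
   (publication year, study id) — the id as a deterministic tie-break —
   and the DerSimonian–Laird method-of-moments model is refitted after
   each study. No small-sample (Hartung–Knapp) correction is applied; DL
   is the estimator the sequential-monitoring tradition assumes.
4. **Information scale.** Information is the cumulative allele count
   (2 per person, both arms), matching the scale on which the z-statistics
   are computed. The required information size is the classic unpooled
   two-proportion formula at allele level,
   `2 (z_{1-α/2} + z_{pow})² (p₁(1−p₁) + p₂(1−p₂)) / (p₁−p₂)²`, with
   `p₂` the reference control MAF and `p₁` the case frequency implied by
   the anticipated OR; it is divided by (1 − heterogeneity adjustment).
   With the defaults (α 0.05, power 0.8, OR 1.5, adjustment 0.80) and
   MAF 0.3 this gives 843.94 alleles, inflated five-fold to 4219.7. The
   pooled-variance variant of the formula would differ by well under 1% at
   these parameter values; the unpooled sum is used throughout.
5. **Boundaries.** Two-sided monitoring boundaries come from the
   Lan–DeMets O'Brien–Fleming-type spending function
   `α*(t) = 2(1 − Φ(z_{1-α/2}/√t))`, evaluated at the actual information
   fractions of the looks (study arrival points), so arbitrary and unequal
   schedules are supported. Futility boundaries spend
   `β*(t) = 2(1 − Φ(z_{1-β}/√t)) · β / (2(1 − Φ(z_{1-β})))` under the
   design drift `z_{1-α/2} + z_{pow}`; they are non-binding (monitoring
   boundaries are computed ignoring them) and symmetric, and a look whose
   solved wedge value is negative reports no wedge (too little information
   to conclude futility).
6. **Verdict.** The first event in look order wins and is never revoked:
   a monitoring crossing gives `conclusive_risk` or
   `conclusive_protective` by the sign of z at the crossing look; futility
   entry or reaching the adjusted RIS without a crossing gives
   `conclusive_null` (both routes are reported in the per-look table);
   otherwise `inconclusive`. Because boundaries at look k depend only on
   fractions t₁..t_k, appending studies never changes earlier looks, so a
   conclusive verdict cannot be demoted by new data.

## Numerical scheme for the boundary recursion

The canonical process (`cov(Z_j, Z_k) = √(t_j/t_k)`, mean `δ√t_k`) is
integrated recursively: the sub-density of the process restricted to "no
stop so far" is tabulated on a fixed symmetric grid of 4001 nodes spanning
[−8, 8] in z; propagation between looks is the exact Gaussian-increment
convolution of the underlying Brownian motion, evaluated by trapezoid
quadrature with the truncation points entering as interpolated partial
cells (so boundaries need not lie on grid nodes). Each look's boundary is
solved by bisection until the look's crossing probability matches its
spending increment to 1e-6. A look whose spending increment is below that
tolerance receives the grid edge (an uncrossable boundary) and its
unspent α rolls forward — this happens at very early looks, where
O'Brien–Fleming spending is effectively zero. z₀.₉₇₅ is pinned to
1.959964 everywhere for bit-stable outputs.

Properties of this scheme worth knowing:

* a single look at t = 1 reproduces the fixed-sample critical value
  1.959964 to ~1e-5; with several looks the final boundary exceeds it
  slightly (e.g. 1.977 for looks at 0.5 and 1.0) — that is the spending
  correction, not error;
* boundary magnitudes are usually decreasing in t, but with looks packed
  close to full information the last boundary can tick up by a few
  hundredths (small spending increment against a highly correlated
  previous look); classification does not rely on monotonicity;
* solver accuracy is probability-scale: where the density near the
  boundary is thin (early looks), 1e-6 in probability corresponds to up
  to ~1e-3 in z;
* looks beyond fraction 1 are evaluated at fraction 1: they reuse the
  full-information monitoring value and carry no futility wedge (the
  RIS route of the null verdict already applies there);
* the multi-look futility wedge does not close exactly at the monitoring
  boundary at t = 1 (discrete β-spending leaves a small gap); with a
  single look the two coincide at 1.959964.

Boundary calibration is verified two independent ways in the tests:
rectangle probabilities of the correlated-look multivariate normal
(scipy's MVN integrator) and direct Monte-Carlo simulation of the
canonical process at 10⁶ draws.

## Synthetic-literature generator

`ScenarioConfig` fixes a (snp, ethnicity) truth: control MAF, true
allele-model OR, between-study SD τ of the log-OR, and per-study arm
sizes published one per year. Controls are trinomial draws from exact
Hardy–Weinberg proportions at the control MAF; each study draws its own
log-OR from Normal(ln OR, τ²), converts it to a case allele frequency by
inverting the odds-ratio identity, and draws case genotypes from
Hardy–Weinberg proportions at that frequency. Sampling at genotype level
keeps records in the format real literatures are extracted in while
matching the allele model on expectation. One root seed per scenario;
per-study streams are spawned deterministically from it, so the first k
studies are identical whether or not later ones are generated.

Deliberately not emulated: linkage disequilibrium, genotyping error,
departure from HWE (real control samples deviate; synthetic ones are
HWE-exact by construction), covariates/confounding, and publication
bias. Passing tests therefore demonstrate the statistical machinery's
calibration under the model's own assumptions, not robustness of real
extracted literatures to those violations.

## Defaults and why

| parameter | default | meaning |
|---|---|---|
| alpha | 0.05 | two-sided type-I error of the sequential design |
| power | 0.8 | 1 − β at the anticipated effect |
| assumed_or | 1.5 | anticipated minor-allele OR; typical candidate-gene effect size used for the information size |
| heterogeneity_adjustment | 0.80 | anticipated heterogeneity share; inflates the RIS by 1/(1−0.8) = 5, fixed a priori rather than estimated per SNP |
| continuity | 0.5 | Haldane–Anscombe constant for zero cells |
| grid_nodes / bisection_tol | 4001 / 1e-6 | boundary recursion resolution (above) |

The heterogeneity adjustment is interpreted as a fixed design input (a
diversity-style inflation), not a cap on the estimated I²; estimated τ²
and I² are still computed and reported at every look.

## Operating characteristics computed by the test suite and acceptance script

Problem sizes were chosen to characterise the method at realistic
candidate-gene scales: null literatures of 10 studies with 100 cases/100
controls each (cumulative information just under the adjusted RIS), power
replicates carrying exactly the unadjusted RIS, 2000 replicates per rate,
10⁶ draws per Monte-Carlo boundary check. The naive any-look |z| ≥ 1.96
rule rejects ~17% of null literatures; the sequential rule ~3%, and the
full verdict rule declares a false conclusive association at no more than
the design α.

One documented caveat: at the unadjusted RIS the design power of 0.80 is
achieved by the z-test on the full information (single-study replicates
measure 0.79–0.81). Splitting the same information across several studies
and pooling with DL yields 0.68–0.73, because the stochastic τ̂² inflates
the pooled SE even when the truth is homogeneous. This attenuation is a
known random-effects property and part of the rationale for inflating the
information size for heterogeneity; the suite freezes it as expected
behaviour.

## Known limitations

* Verdicts depend on the look schedule implied by publication order;
  literatures whose early studies are small spend almost no α early and
  are conservative at intermediate looks.
* The RIS formula assumes the allele-level two-proportion model with
  independent alleles (HWE in both arms); strong HWE violation in real
  data would misstate the information scale.
* No publication-bias correction: a biased literature yields a biased
  pooled OR, conclusively so if information suffices.
* The futility wedge is symmetric; asymmetric designs (e.g. one-sided
  harm monitoring) are not provided.
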