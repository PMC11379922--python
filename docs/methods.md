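# Methods

## Membership functions

Indicator values are scored on [0.1, 1.0]. The 0.1 floor (rather than 0)
keeps every indicator contributing to composite indices and keeps the
Nemerow minimum term bounded away from zero. Two families are used:

- **S-type** (SOM, AN, AP, AK, TP, TN): 0.1 below `m1`, linear
  `0.9 (x − m1)/(m2 − m1) + 0.1` on `[m1, m2)`, 1.0 from `m2`. Breakpoints
  are the packaged defaults (SOM 4–13 g·kg⁻¹, AN 5–15 mg·kg⁻¹, AP 3–10
  mg·kg⁻¹, AK 100–380 mg·kg⁻¹, TP 1–2 g·kg⁻¹, TN 1–2.5 g·kg⁻¹), all
  overridable through `Config`.
- **Parabolic** (pH 5.5/6.5/7.5/8.5, SMC 5.25/8/10/16 %, BD
  0.55/0.75/0.85/1.25): 0.1 outside `(x1, x4)`, ramps on `[x1, x2)` and
  `[x3, x4)`, plateau 1.0 on `[x2, x3)`.

Endpoint conventions the interval notation leaves open: exactly `x2` scores
1.0 (continuity from the rising ramp), exactly `x4` scores 0.1 (limit of the
falling ramp), and values above `x4` score 0.1 by symmetry with the lower
floor. AK is treated as S-type: its parameters form a rising pair and its
placement matches the other nutrient stocks. The packaged SMC breakpoints
(5.25, 8, 10, 16) are the only increasing parse of the source table's run-on
digits; they sit oddly against the 19–21 % optimum quoted for loess moisture
elsewhere in the same source — the transcription is kept as printed. BD's
units are recorded as printed (g·kg⁻¹) although the magnitudes suggest
g·cm⁻³; units are metadata only and never enter computation.

## MDS selection

PCA is performed by eigendecomposition of the Pearson correlation matrix
(not an SVD of the data), so the pipeline can be driven either by raw
samples or by a published correlation/loading table. Loadings are
`U_ik = v_ik √λ_k`; each component's sign is fixed so its largest-|loading|
entry is positive (sign never affects |loadings|, Norm values or selection).
Components are retained when `λ ≥ 1` **and** the variance share is ≥ 5 %;
the leading component is always kept (with a warning if it fails the rule).

Selection rules, all on absolute loadings (an indicator loading −0.8
"loads at 0.8"):

- group by component at |U| ≥ 0.6; a cross-loader joins the group whose
  already-assigned members have the smallest mean |r| with it; an indicator
  below the cutoff everywhere joins its largest-|loading| component;
- within each group, shortlist indicators with |U| ≥ 0.9 × the group
  maximum ("within 10 %", read multiplicatively);
- within a shortlist, if any pair has |r| > 0.5 keep the highest
  comprehensive load `CL_i = Σ_k U²_ik λ_k`, drop indicators with |r| > 0.5
  against it, and repeat on the remainder.

Redundancy is filtered *within* group shortlists only; representatives of
different components are never tested against each other (they were placed
in different groups precisely because they separate in loading space, and
cross-group correlations such as pH–BD can be high without making either
redundant for its own component). The Norm value `√CL` and `CL` itself rank
indicators identically, so either may be used; both are exposed. Ties in
maximum loading or comprehensive load break by the canonical indicator
order (pH, SOM, AN, AP, AK, TP, TN, SMC, BD), making the selection and its
audit log fully deterministic.

## Weights

Weights are communalities over the retained components,
`h²_i = Σ_k U²_ik`, normalized to sum to one. TDS weights come from the PCA
of all nine indicators; MDS weights from a fresh PCA of the selected subset
only, retaining components by the same rules. For a small MDS the retention
rule typically keeps a single component; how many components the original
analysis retained for its three-indicator panel is not recoverable from the
published numbers, so the from-data path simply documents its rule and the
fixture path uses the published communalities verbatim.

## Composite indices

- `WDSQI = Σ W_i S_i` — a convex combination of memberships, hence in
  [0.1, 1.0]. Computed per sample; a plot's value is its sample mean.
- `WDSQIN = sqrt((f̄² + f²_min)/2) · (n−1)/n` — in
  [0.1 (n−1)/n, (n−1)/n], never exceeding `f̄ (n−1)/n` with equality iff all
  memberships are equal (the pessimism property is tested). Plot aggregation
  defaults to averaging per-sample values; applying the formula to plot-mean
  memberships is exposed as an alternative. Neither aggregation reproduces
  the published per-plot values from the published per-sample memberships;
  the published plot *ordering* is reproduced by both and is what the tests
  assert.
- The historical maximum-based Nemerow form is kept for audit as
  `sqrt((P̄² + P²_max)/2)`; the asymmetric variant `sqrt(P̄ + P²_max/2)`
  that some sources print (almost certainly a typesetting slip, since the
  mean enters unsquared) is available behind `literal=True`.

Classification: > 0.8 Excellent, (0.7, 0.8] Good, (0.6, 0.7] Medium,
(0.4, 0.6] Deficient, ≤ 0.4 Destitute — boundaries belong to the lower
class, matching the "> 0.8 / 0.7–0.8 / …" convention.

CV sensitivity uses the pooled sample standard deviation (n−1) over all
samples: < 10 % insensitive, 10–50 % low, 50–100 % moderate, ≥ 100 % strong.

## Synthetic data

The generator draws each plot from a multivariate normal with the packaged
per-plot means/SDs and one shared correlation matrix (the pooled published
matrix; per-plot correlation structure is not published, and the shared
matrix is the simplest structure consistent with the data — it is exposed as
configuration). The printed matrix, rounded to 2–3 decimals, is marginally
indefinite (smallest eigenvalue ≈ −0.06); `repair_correlation` clips
negative eigenvalues and renormalizes the diagonal, changing entries by
< 0.03. Draws with any coordinate outside its physical bounds (pH in
(0, 14), all other indicators > 0) are rejected and redrawn — truncation by
rejection, not clamping, to avoid point masses at the bounds. Each plot's
stream derives from the master seed and a CRC of the plot id, so output is
bit-reproducible and invariant to plot ordering.

**What the generator does not emulate.** Marginals are (truncated) normal —
no skewness, no spatial autocorrelation, no measurement-error model. And the
truncation is not moment-preserving: for indicators whose mean sits within
~2 SD of zero (TP, TN and BD in the poorer plots), the truncated mean
exceeds the configured normal mean by up to ~0.1 SD, and because a draw is
rejected when *any* coordinate is out of bounds, the shift propagates to
correlated indicators in the same plot. At large n (hundreds of samples per
plot) this bias is resolvable against the Monte-Carlo standard error, so
empirical means in the unreclaimed plots sit a few SE above the configured
values; in the reclaimed plots (rejection probability < 1e-4) configured
moments are recovered within sampling noise. The test suite therefore
validates the sampler against what it actually targets — closed-form
truncated-normal moments (scipy `truncnorm`) under an identity correlation,
correlation recovery within ±0.1, and 3-SE/10 % moment recovery in the
low-truncation plots. Passing tests show the sampler is correct for its
stated distribution, not that real waste-dump data are truncated normals.

The end-to-end recovery harness reruns the full selection chain on
replicated synthetic studies; under the default structure SOM is the most
frequently selected indicator (its between-plot contrast dominates the
pooled variance) with inclusion frequencies around 0.4–0.6 across master
seeds, and the selected set is usually small (1–2 indicators) because the
strong between-plot mean differences drive most pairwise correlations above
the 0.5 redundancy threshold.

## Numerical choices and known inconsistencies in the reference tables

- "Agreement at printed precision" in tests means |difference| ≤ 1.5 × the
  last printed digit, because the source tables' own rounding is off by one
  ulp in places (e.g. a comprehensive load printing 3.691 where the loadings
  give 3.6917).
- The published loading matrix and correlation matrix are mutually
  inconsistent: the printed correlation matrix's leading eigenvalues are
  (5.61, 1.21) against printed (5.435, 1.204), a gap far exceeding what
  3-d.p. rounding of correlations can produce. The printed eigenvalues
  evidently derive from unpublished raw data. Both are packaged; the
  eigenstructure test documents the gap.
- The published pH loadings (−0.815, 0.872) imply a communality above 1,
  inconsistent with pH's printed communality 0.672, and the printed AN/AP
  communalities appear swapped relative to the loading matrix. Computed
  quantities are self-consistent; fixtures carry the printed numbers
  verbatim, and the reproduction tests exclude the inconsistent rows.
- Marginally indefinite printed correlation matrices are accepted by the
  PCA (eigenvalues are reported as-is; loadings use the non-negative part),
  but the synthetic generator requires a PSD matrix and points the user at
  `repair_correlation`.

## Problem sizes

The packaged case study is 5 plots × 5 samples × 9 indicators. Synthetic
checks use 5 samples/plot for pipeline-level tests, 25/plot × 100 replicates
for selection-frequency summaries, and 500–4000/plot for moment and
correlation recovery; all complete in seconds on one CPU.

## Limitations

- Selection thresholds (λ ≥ 1, 5 % variance, 0.6 loading, 10 % shortlist,
  r > 0.5) are conventions of this assessment framework, not estimated
  quantities; `Config` exposes them but offers no data-driven tuning.
- No factor rotation, parallel analysis, or missing-value imputation; input
  tables must be complete.
- The two weighted-additive index variants (TDS and MDS weights) are
  computed on membership scores; composite indices on raw standardized
  values are not implemented.
- Expert-opinion and unified index families are out of scope, as are
  spatial interpolation and chart rendering (the CLI exports plot-ready
  CSVs only).
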