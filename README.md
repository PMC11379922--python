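# wdsqi — soil quality indices for mine waste dumps

Waste dumps of open-pit mines — spoil piles of stripped topsoil and rock —
are the hardest substrate to revegetate: nutrients are scarce, pH is often
alkaline, and bulk density is far from any crop's optimum. Restoration
programs therefore need a defensible, repeatable way to condense a panel of
measured physicochemical indicators into a single soil quality index (SQI)
per plot, and to identify which few indicators carry most of the signal so
that future monitoring can be cheaper.

`wdsqi` implements that workflow for a nine-indicator panel (pH, soil
organic matter SOM, available N/P/K, total P and N, surface moisture
content, bulk density), following the soil management assessment framework
tradition:

1. **Membership scoring.** Each measured value x is mapped to a score
   S ∈ [0.1, 1.0] by a piecewise-linear function: monotone *S-type*
   `S = 0.9 (x − m₁)/(m₂ − m₁) + 0.1` for nutrient stocks, or *parabolic*
   (optimum plateau between x₂ and x₃, ramps on [x₁, x₂) and [x₃, x₄)) for
   pH, moisture and bulk density.
2. **Minimum data set (MDS) selection.** PCA of the indicators' Pearson
   correlation matrix; components with λ ≥ 1 explaining ≥ 5% of variance are
   retained; each indicator is scored by its comprehensive load
   `CL_i = Σ_k U²_ik λ_k` (its square root is the *Norm* value); indicators
   are grouped by component (|loading| ≥ 0.6, cross-loaders join the group
   they are least correlated with), each group is shortlisted to indicators
   within 10% of its top |loading|, and shortlisted pairs with |r| > 0.5 are
   collapsed onto the higher comprehensive load.
3. **Weighting.** Indicator weights are communalities
   `h²_i = Σ_k U²_ik` normalized to sum to one, computed separately for the
   full panel (TDS) and the selected subset (MDS).
4. **Indices.** The weighted additive index `WDSQI = Σ_i W_i S_i`, and the
   improved Nemerow index
   `WDSQIN = sqrt((f̄² + f²_min)/2) · (n−1)/n`, whose minimum term encodes
   the "barrel theory" that fertility is capped by the most deficient
   indicator. Values map to five fertility classes (> 0.8 Excellent, …,
   ≤ 0.4 Destitute).

The package ships transcriptions of the published reference tables for a
five-dump case study (plot statistics, correlation matrix, loadings,
communalities, per-sample memberships), so the whole pipeline runs with no
external data, plus a seeded synthetic generator that emulates the study
design (5 plots × 5 samples, truncated multivariate normal with plot-specific
means/SDs and a shared correlation structure).

## Worked example

```sh
wdsqi simulate --seed 1 --n-per-plot 5 --out samples.csv
wdsqi report samples.csv
```

prints (abridged):

```
MDS selection audit:
  retained components: ['PC1', 'PC2']
  ...
  PC1: members ['pH', 'SOM', 'AN', 'AP', 'AK', 'TP', 'TN', 'SMC']; top |loading| 0.916; shortlist (within 10%) ['SOM', 'AN', 'AP', 'AK', 'TN']
  PC1: keep SOM (highest comprehensive load 5.367); drop redundant ['AN', 'AP', 'AK', 'TN'] (|r| > 0.5)
  PC2: members ['BD']; top |loading| 0.728; shortlist (within 10%) ['BD']
  MDS = ['SOM', 'BD'] (size 2)

Per-plot indices:
            wdsqi_tds  wdsqi_mds  wdsqin  class_tds  class_mds class_nemerow
No.1           0.8366     0.9125  0.5547  Excellent  Excellent     Deficient
No.2           0.6015     0.4802  0.3770     Medium  Deficient     Destitute
No.3           0.4127     0.4669  0.2712  Deficient  Deficient     Destitute
No.4_upper     0.3258     0.2520  0.2161  Destitute  Destitute     Destitute
No.4_lower     0.8509     0.8522  0.5706  Excellent  Excellent     Deficient

MDS vs TDS regression: slope 1.1244, intercept -0.0881, R^2 0.8420
```

Reading it: organic matter dominates the first component and survives the
redundancy filter, bulk density alone represents the second — so monitoring
could focus on those two. The reclaimed dumps (No.1, No.2, No.4_lower) score
well above the unreclaimed ones (No.3, No.4_upper) on every index; the
Nemerow index is systematically harsher than the additive one because each
plot still has at least one badly deficient indicator (here pH). The
R² ≈ 0.84 regression confirms the two-indicator MDS tracks the full-panel
index.

The same machinery is available from Python:

```python
import wdsqi as w

samples = w.generate_samples(w.default_config(seed=1, n_per_plot=5))
report = w.run_pipeline(samples)
print(report.selection.selected)      # ['SOM', 'BD']
print(report.summary_table())
```

Run on the published per-sample membership table instead:

```python
memb = w.load_fixture("memberships")
nem = w.nemerow_table(memb)
print(nem.per_plot.sort_values(ascending=False))
# No.4_lower > No.1 > No.2 > No.3 > No.4_upper — the published ordering
```

## Layout

- `wdsqi.model` — domain types (`IndicatorSpec`, `SampleTable`, `Config`, …)
- `wdsqi.io` — CSV readers/writers, packaged reference tables
- `wdsqi.membership` — S-type and parabolic scoring
- `wdsqi.mds` — standardization, correlation PCA, Norm values, MDS selection
- `wdsqi.weighting` — communalities and normalized weights
- `wdsqi.sqi` — WDSQI, improved Nemerow, classification, CV sensitivity, validation
- `wdsqi.synthetic` — truncated-MVN study generator, PSD repair, recovery harness
- `wdsqi.pipeline` / `wdsqi.cli` — end-to-end runs and the `wdsqi` command

See `docs/methods.md` for the model's assumptions, parameter choices and
known limitations.
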