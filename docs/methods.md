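# Methods

## The trial and its model

The package analyses two-regime drought screens laid out as a randomized
complete block in **split-plot** arrangement: within each block, the
water regime (WS ≈ 45 % volumetric water content, WD ≈ 11 %) is applied
to whole plots, and genotypes (ecotypes) occupy sub-plots within a whole
plot. Watering is the hard-to-randomize factor in an irrigation trial,
so the regime is taken as the main-plot factor and ecotype as the
sub-plot factor throughout. The linear model for one trait is

    y_ijk = μ + block_i + regime_j + (block×regime)_ij
              + ecotype_k + (regime×ecotype)_jk + ε_ijk

with `(block×regime)` the whole-plot error (error a) and `ε` the
sub-plot error (error b). The regime F-test uses MS(error a); ecotype
and interaction use MS(error b). Sums of squares are the balanced
closed forms over cell means; balance is verified before any
decomposition and unbalanced data are rejected with the missing cells
listed, never silently dropped or imputed.

**LSD mean separation** is done within a water regime (screens report one
LSD per regime column): from the within-regime randomized-complete-block
ANOVA, `LSD = t(1−α/2, df_err) · √(2·MS_err/n)` with `n` the number of
blocks, default α = 0.05. Letter groups come from the standard
descending-mean sweep; two genotypes share no letter exactly when their
means differ by more than the LSD. No multiplicity correction is applied
beyond the LSD construction itself — consistent with screening practice
but anti-conservative with 35 genotypes; treat the letters as
descriptive. `CV% = 100·√MS_err / grand mean` from the same
decomposition.

## Stress responses

Percent change under stress is `(mean_WD − mean_WS)/mean_WS × 100`
(negative = reduction). When the input is a published table of rounded
means, cohort-level changes are computed from the table's **printed
grand-mean row**, not by re-averaging the rounded per-genotype means:
the printed row was derived from unrounded replicate data, and
re-averaging rounded means shifts some cohort percentages by more than a
tenth of a point. Reported values are rounded to one decimal,
round-half-even.

## Tolerance indices

The seven indices (MP, GMP, TOL, YSI, YI, SSI, STI; formulas in the
README) are computed on per-genotype mean dry-matter yield per plant.
Each index carries a ranking direction in metadata — ascending for the
loss measures SSI and TOL, descending otherwise — so "top-k tolerant"
queries cannot silently invert an index. Exact identities are enforced
by tests: GMP ≤ MP with equality iff Ys = Yp; mean(YI) = 1;
Σ STI · Ȳp² = Σ Ys·Yp; TOL/MP/GMP scale linearly with the yield unit
while YSI/YI/SSI/STI are unit-free. SSI is undefined (NaN, warned) when
the cohort loses no yield on average.

## PCA ranking and clustering

PCA operates on the genotype × trait matrix of means, **column
z-scored** (sample sd, ddof = 1) because traits span four orders of
magnitude (root length ~50 cm vs quantum yields ~0.2); an unstandardized
analysis would be an analysis of root length. Component m's
contribution is 100·λ_m/Σλ. Signs are fixed deterministically: the
largest-magnitude loading of each component is made positive. The
ranking value weights each genotype's component **scores** by the
component contributions in percent,
`Σ_{m≤4} c_m(%) × s(g,m)`, and genotypes are dense-ranked descending
with ties broken by identifier. Percentages (not proportions) are used
as weights; this matches the ±160 magnitude of published ranking values.

Hierarchical clustering is agglomerative on Euclidean distances of the
z-scored rows; Ward linkage by default (average and complete are
selectable) since screens typically name only the distance. Cluster
profiles report mean ± SEM per trait on the **original** scale, plus
cluster size and percent of cohort.

## The synthetic generator

`simulate_trial` emulates the screening design with known ground truth.
Each trait is generated on a link scale where effects are additive
Gaussian and mapped back, so domain invariants hold by construction:
log for positive traits and counts (counts rounded and floored at 0),
logit for quantum-yield proportions, logit of value/100 for relative
water content. The WD shift for genotype *k* is `m_k·Δ + g_k` where
`Δ = link(μ_WS(1+d)) − link(μ_WS)` reproduces the trait's average
relative change `d` under stress, `m_k ∈ {0.5, 1.0, 1.5}` is the
multiplier of the genotype's latent class (tolerant / moderate /
sensitive — tolerant lose half the average link-scale shift, sensitive
one-and-a-half times), and `g_k` is a small Gaussian interaction draw.
Default trait means and effects are calibrated to the packaged tables'
grand-mean rows; residual dispersions bracket their printed CV% rows.
The default cohort is 35 genotypes (10 tolerant, 15 moderate, 10
sensitive) in 5 blocks.

Two calibration properties define the defaults. First, a null
configuration (identity link, no genotype or interaction effects) gives
the ecotype F-test its nominal size — 5 % ± 2 % over 1,000 trials.
Second, the planted classes are recoverable the way a successful screen
separates genotypes: the class signal must dominate class-independent
genotype noise in log(STI), which fixes the dry-matter-yield genotype
standard deviation at 0.05 (link scale) next to the 0.5-step class
multipliers; top-10 STI selection then recovers ≥ 8 of the 10 tolerant
genotypes in well over 90 % of seeded trials. Randomness is split into
one substream per (trait, stratum) from the master seed, so adding a
trait never perturbs another trait's draws.

What the generator does **not** emulate: soil-moisture dynamics of the
28-day dry-down, temporal or spatial correlation within the greenhouse,
measurement-device error structure (fluorescence traits are i.i.d. on
the logit scale), or genotype-specific variance heterogeneity. Passing
recovery tests therefore show the statistics behave correctly when the
model's assumptions hold, not that a real screen of equal size has the
same power.

## Numerical choices

- Monte-Carlo sizes: 1,000 trials for the test-size check, 200 seeds for
  class recovery — enough for ±1.4 and ±2 percentage-point standard
  errors respectively on the estimated rates.
- p-values: two-sided from the F (ANOVA) and t (correlations)
  distributions; correlation p exact-zero is clamped at |r| = 1.
- SEM = sample sd (ddof = 1)/√n; 0 for singleton cells, with a warning.
- Matrices with missing cells drop the offending rows/columns with a
  warning — no imputation.
- The split-plot sub-plot SS is obtained by subtraction and clipped at
  zero against floating-point cancellation; additivity is tested to
  1e-8 relative.
- Ties: ranking ties break by genotype identifier; index-ranking ties
  preserve input order (stable mergesort).

## Fixture caveats

The packaged reference tables are transcribed from print and carry the
source's defects, documented in `fixture_notes.json`: one run-together
numeric resolved as mean 6.2 / SEM 0.37, two implausible SEMs resolved
by the obvious decimal shift, two left as printed for lack of an
unambiguous correction. The source's cluster-share percentages are
internally inconsistent with its listed cluster sizes; the sizes are
stored as listed and shares are always recomputed from sizes. No
per-genotype fresh-weight or yield table is printed, so fresh weight and
the index pipeline on real data are exercised only synthetically, and
the published PC scores cannot be recomputed from scratch (component
contributions beyond the first two are not printed) — only the
rank-order contract of the published ranking table is asserted.
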