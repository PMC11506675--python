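# Methods

`coexprot` analyses label-free (XIC) proteomics experiments laid out as
a watering-condition x sampling-day x ear-zone factorial, as in studies
of developing maize ovaries under moderate water deficit. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Experimental design

Samples sit in a 2 (condition: WW well-watered, WD water deficit) x 2
(day: silk emergence SE, five days later SE5) x 5 (ear zone, base to
tip) factorial with 3 biological replicates per cell. The cell
(WD, SE5, zone 5) is absent — ovaries at the ear tip abort under water
deficit before the second sampling — leaving 19 cells and 57 samples.
All machinery handles this unbalanced design explicitly.

## Quantification (peptide XIC to protein abundance)

A protein's relative abundance per sample is the sum of the XIC of its
retained peptides. Retention applies three rules in order:

1. **Specificity** — only peptides mapping to a single protein.
2. **Reproducibility** — missing fraction across all samples strictly
   below `min_missing_frac` (default 0.10).
3. **Coherence** — the retained peptides must all correlate pairwise
   with Pearson r above `min_pep_corr` (default 0.5). "Correlate with
   each other" does not by itself pick a subset, so we take the
   **maximum clique** of the peptide graph with edges at r > 0.5:
   exhaustive over maximal cliques up to 15 peptides, a degree-ordered
   greedy heuristic above; ties broken toward higher mean pairwise r,
   then lexicographic peptide ids. Pairwise r uses pairwise-complete
   samples; pairs sharing fewer than 3 samples fail the threshold.
   Proteins left with fewer than 2 peptides are dropped and logged.

Sums are partial when some retained peptides are missing in a sample
(the alternative — imputing or propagating missingness — would need a
tuning parameter); an entry is missing only when every retained peptide
is. Abundances are log2-transformed (XIC sums are approximately
log-normal; the log scale stabilises variance and makes the Gaussian
ANOVA and Pearson networks well specified) and then aligned by a
**median-of-ratios stand-in** for the original normalisation: each
sample is shifted so its median log-ratio to the per-protein median
profile is zero. Peptide-filter correlations themselves are computed on
the raw XIC scale, where the toy examples and oracles are defined.

## Exploratory analysis

All profile-level analyses use **cell means**: replicate averages per
(condition, day, zone), available-case when replicates are missing.

- **PCA** treats cells as observations and proteins as variables,
  centred and (by default) unscaled, matching the common default of the
  tools used for this analysis; a `scale` flag is exposed. Implemented
  by SVD with a deterministic sign convention.
- **K-means** (default k = 8) runs on per-protein z-scored profiles so
  clusters capture abundance *patterns*, not magnitudes. 25 restarts,
  best inertia kept; proteins are sorted by id before fitting so the
  assignment is independent of input order; fully deterministic given
  the seed.
- Cluster-vs-annotation association uses the Pearson chi-squared
  independence test on the clusters x level-1 bins table, without
  continuity correction (an r x c table); p-values are floored at the
  smallest positive double and reported as "<2.2e-16" past the
  conventional floor.

## Differential analysis

Per protein, log2 abundance is modelled as

    Y ~ mu + condition + day + zone
        + condition:day + condition:zone + day:zone + eps

with all factors categorical and **no three-way interaction**. Type III
(marginal) sums of squares are computed under sum-to-zero contrasts by
comparing the full model against the model lacking each term's
contrast columns; this is contrast-dependent, and sum-to-zero coding is
required for the marginal hypotheses to be meaningful. The missing
design cell makes the design unbalanced but leaves all six terms
estimable (residual df 41 at n = 3). Terms whose marginal hypothesis
loses rank under a protein's missing-data pattern are flagged with a
missing p-value rather than guessed.

The engine is vectorised: residual-maker matrices are built once per
design (and per missing-data pattern) and applied to all proteins at
once, which makes hundreds of simulated datasets cheap. It reproduces
R's `car::Anova(type=3)` to full precision on the study design (checked
in the test suite).

BH adjustment is applied **per model term across proteins** — six
separate families — because results are reported as per-effect counts;
`bh_per_term=False` pools all terms into one family instead. Effects
are significant at adjusted p strictly below alpha (default 0.05). The
"WD-affected" set is the union of the condition main effect and both
condition-involving interactions, with up/down direction taken from the
sign of the WD-WW difference of marginal means over the 9 day x zone
cells shared by both conditions.

## Co-expression networks

Within one condition, cell means vary only with developmental position,
so a correlated protein pair indicates coordination through ear
development. For every unordered pair among the P quantified proteins
(WW: 10 cells; WD: 9), Pearson r is computed on pairwise-complete
cells; the two-sided p comes from the exact t-transform with df = m-2
over m shared cells. Pairs with fewer than 4 shared cells (df <= 1) and
pairs involving a zero-variance profile are excluded and counted.
P-values are BH-adjusted over all P(P-1)/2 pairs **within one
condition** (the analysis produces one correlation matrix per
condition, which is the natural family); edges are pairs with adjusted
p < alpha, of either sign — the sign is kept on the edge. Correlation
p-values are floored at 1e-300. Network density is n_edges / (P(P-1)/2)
over the full protein universe, including unconnected nodes.

## Network comparison

- **Overlap**: under independence, a pair is an edge in both networks
  with probability p_A p_B, so the expected common-edge count is
  n_A n_B / C with C = P(P-1)/2. Significance is the one-sided tail of
  Binomial(C, p_A p_B) at the observed overlap — the minimal null
  consistent with the edge-probability framing; the original report
  gives only a floored p-value without naming a test.
- **Term-pair enrichment** (one network): with K(A,B) of the C possible
  pairs joining bins A and B (k_A k_B across bins, k(k-1)/2 within),
  the observed edge count under the no-preferential-connection null is
  hypergeometric (n_edges draws from C with K successes). Both
  one-sided tails are reported, each BH-adjusted across term pairs; no
  doubling. An edge counts for exactly one term pair (one endpoint in
  each bin; both endpoints for intra-pairs), so the decomposition
  partitions the edge set whenever the annotation partitions the nodes.
- **Connectivity change** (two networks): per term pair, the 2x2 table
  [[x_WW, n_WW - x_WW], [x_WD, n_WD - x_WD]] is tested by chi-squared
  with the Yates continuity correction by default (the default of the
  statistical ecosystem this analysis style comes from; switchable).
  Zero-margin tables are skipped with a reason. BH across term pairs;
  direction is the sign of the WD-vs-WW proportion change.
- **DEP bookkeeping**: edges are classed by how many endpoints are
  WD-affected proteins (0/1/2); the union row follows per class by
  inclusion-exclusion (A + B - common) and row totals close the table.
- **Degree deltas**: per protein, edges lost (in WW only) and gained
  (in WD only), with partner-bin tallies, sorted by total rewiring —
  this surfaces hub proteins whose edge losses dominate the change.

## Synthetic data generator

The generator is first-class, tested code and defines the conditions
under which the statistics are validated. It draws, on the log2 scale:

- **Baseline** mu ~ N(20, 1.5) per protein (typical log2 XIC-sum
  magnitudes), residual sigma = 0.25 by default.
- **Factorial effects** with sum-to-zero structure. The fraction of
  proteins affected by each term defaults to the prevalences reported
  for the real dataset (condition 481/800, day 327/800, zone 162/800,
  day x zone 52/800, condition x day 21/800, condition x zone 2/800).
  Effect magnitudes are U(0.5, 2) log2 units with random sign — the
  source reports no effect-size distribution, so these are declared
  defaults spanning modest to strong fold changes. Zone effects are
  monotone gradients over the five zones, mirroring the developmental
  gradient along the ear.
- **Co-expression modules**: disjoint protein sets loading on a latent
  N(0,1) factor drawn **per design cell** (not per sample), so
  replicate averaging preserves module correlation — networks are built
  on cell means. Condition-specific loadings (e.g. WD-only) create
  condition-specific co-expression.
- **Peptide observation**: XIC = coefficient x protein abundance x
  log-normal noise (sd 0.2 log2), with per-peptide missing
  probabilities (85% of peptides at U(0, 0.05), 15% at U(0.12, 0.30) so
  the reproducibility filter has real work), 10% uncorrelated outlier
  peptides drawn around the protein's mean level, and 10% non-specific
  peptides. The first two peptides of each protein are forced specific,
  non-outlier and low-missing so every protein stays quantifiable.

One global seed drives everything; sub-generators derive child seeds
deterministically, so a full pipeline run is byte-reproducible.

**What the generator does not emulate**: shared-peptide quantification,
retention-time drift and charge states, intensity-dependent missingness
(missingness is missing-completely-at-random per peptide), heavy-tailed
or correlated residuals, annotation errors, and any real biological
pathway structure. Passing recovery tests therefore shows the
statistics behave as designed under their own assumptions, not that
those assumptions hold for any particular real dataset.

## Calibration experiments and problem sizes

The published data-dependent numbers cannot be regenerated without the
raw deposition, so validation is property-based, at sizes chosen to
keep the experiments well-resolved yet quick:

- **Null FDR**: 200 fully null datasets of 500 proteins x 57 samples;
  on null data the false-discovery proportion is 1 whenever anything is
  called, so the empirical FDR per term is the fraction of datasets
  with at least one call, compared to 0.05 plus twice its Monte-Carlo
  SE.
- **Effect recovery**: 20 datasets of 400 proteins, half with planted
  condition effects of 3 sigma per level (6 sigma WD-WW difference);
  recall of planted effects and FDP among calls are averaged.
- **Module recovery**: 800 proteins with one WD-only module of 10
  proteins sharing a functional bin, plus four background modules
  active in both conditions (the 2x2 change test conditions on each
  network's edge total, so both networks need edges, as in real data).
- **Filter performance**: 200 proteins with 25% planted outlier
  peptides; removal rates of both filters are measured, the
  reproducibility rule exactly.

## Numerical choices

Rank decisions use `numpy.linalg.matrix_rank` defaults; projections use
the pseudoinverse, so rank-deficient reduced models degrade gracefully.
Type III SS are clipped at zero against roundoff. K-means inertia ties
resolve to the first-found restart (scikit-learn behaviour under a
fixed seed). Chi-squared p-values are floored at the smallest positive
double, correlation and overlap p-values at 1e-300; summaries render
anything below 2.2e-16 as "<2.2e-16". TSV output uses fixed float
formatting so identical runs are byte-identical.

## Known limitations

Pearson networks capture linear, marginal association only — no partial
correlations, shrinkage estimators or weighted (WGCNA-style) analysis.
The BH family choices (per term; per condition) are documented
conventions, not the only defensible ones, and are switchable where
reasonable. The normalisation is a declared stand-in, not a
reimplementation of the original method. The greedy clique heuristic
above 15 peptides is not guaranteed optimal (real proteins rarely
exceed it). Mixed models and a three-way interaction are out of scope
by design.
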