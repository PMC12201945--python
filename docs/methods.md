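# Methods

This note documents the models, conventions and numerical choices behind
`phycoflow`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Interaction coefficients

All three coefficients are *directed*: entry [primary p, secondary s]
describes the effect of the strain with first access to the algal
metabolite pool on the strain receiving the altered pool. Matrices are
stored [primary, secondary] and rendered with primaries as columns and
secondaries as rows, the conventional heatmap layout.

**ECI.** `ECI(s,p) = −Σ_m p_{m,s} p_{m,p} / Σ_m p_{m,s}²` over a shared
metabolite-feature ordering. It is a normalised projection of the
primary's consumption-proportion vector onto the secondary's: −1 when the
two vectors are identical (or the primary's is a positive multiple with
equality on the secondary's support — in particular, self-pairs), 0 when
the consumed sets are disjoint. ECI is linear in the primary's vector and
invariant to rescaling the secondary's. A secondary strain that consumes
nothing has no competition to experience; its column is reported as 0
with a validity flag rather than NaN so matrices stay complete.

**Consumption proportions.** p_{m,s} = clamp(1 − I_s/I_0, 0, 1), where
I_s and I_0 are mean feature intensities in isolate-inoculated and
uninoculated spent-medium samples. The "1 −" convention is deliberate:
full depletion must map to 1 and no change to 0 for the ECI anchor values
(self-pair → −1, disjoint → 0) to hold. The raw-ratio reading
(`convention="ratio"`) is kept for sensitivity analysis. By default
proportions are assigned only to features *called* consumed
(Student's t, pooled variance, Bonferroni over all feature × isolate
contrasts of the run, α = 0.05, I_s < I_0); everything else gets 0 so
noise and production cannot inflate overlap. Welch's test and other
correction methods are option flags. The Bonferroni family is all
contrasts in one analysis run and its size is recorded on each profile.

**Background filtering.** A feature is retained when, for at least one
non-blank sample group, its mean exceeds the extraction-blank mean and
the adjusted two-sample t-test p-value is below α. Positive- and
negative-ionisation features are concatenated with mode-prefixed IDs
(`Positive-0001`, ...); the filter treats them jointly, and the retained
count plus family size are recorded in the table's `meta` for per-mode
bookkeeping.

**Zero-mean edge cases.** I_0 = 0 with I_s > 0 yields a +inf log2fc
sentinel and a flag; both zero yields `unchanged` with log2fc 0.
Proportions are undefined at I_0 = 0 and reported as 0 with a flag.

**MRO.** Implemented exactly as the directed ratio
`|M_s ∩ M_p| / |M_s|` on supplied minimal-nutrient (or sole-carbon-
source) identifier sets — not the symmetric community formulation used by
genome-scale-model toolchains. Model reconstruction itself is out of
scope; sets arrive as JSON/TSV. An empty secondary set is an error.

**SI.** `SI = mean(G_{s,p}) / mean(G_{s,PtSM}) − 1`, a ratio of replicate
means. Ratio-of-means is the default because individual flow-cytometry
counts can be small and noisy; mean-of-ratios is available by flag.
Interactions are classified by sign (negative = competitive, positive =
facilitative) with an optional neutral band, default width 0 (strict
sign).

**Metric comparison.** Correlations (Spearman for SI~ECI, Pearson for
MRO~ECI) run over all ordered, pairwise-valid strain pairs; the diagonal
(intraspecific pairs) is included by default, so 10 strains give n = 100,
and can be excluded by flag. The fraction of pairs with A > B is reported
alongside (e.g. the share of SIs less negative than their ECIs); excluded
invalid cells are logged.

**Sole-carbon-source growth calls.** An OD600 series is smoothed with a
3-point moving average; growth is called when the rise above the initial
reading exceeds both 0.05 OD units and twice the blank's rise. Both
thresholds are parameters; the defaults are ordinary plate-reader
practice.

## Profile statistics

Isolates are embedded as signed log2 fold-change vectors with
non-significant entries zeroed (so distance reflects only called
consumption/production); ±inf sentinels are clipped to ±10. Distances
are Euclidean and clustering is average-linkage — the usual defaults for
profile heatmaps; both are configurable. Labels are sorted
lexicographically before linkage so merge order and tie-breaking are
deterministic regardless of input order. Dendrograms export to Newick
with branch lengths derived from merge heights.

The Mantel test correlates upper-triangle entries (Pearson by default,
Spearman optional), permuting the second matrix's labels. With n labels
and n! ≤ requested permutations the null is enumerated exhaustively
(identity included) and p is the exact tail probability; otherwise p =
(1 + #{r_perm ≥ r_obs}) / (1 + n_perm) from seeded random permutations.
One-sided (positive association) by default. Phylogenetic distances are
consumed as a precomputed matrix; tree inference is out of scope.

## Isotope calculations

Carbon ratios use the C2⁻ dimer convention: R = (¹²C¹³C/¹²C¹²C)/2,
because at low ¹³C abundance a dimer carries one heavy atom with
probability ≈ 2F(1−F) versus (1−F)² for none, so the count ratio is
≈ 2F/(1−F) = 2R. Nitrogen uses the CN⁻ monomer channels directly
(¹²C¹⁵N/¹²C¹⁴N), no factor of 2; ¹⁵N enrichment is reported as the atom
fraction R/(1+R) per cell.

C_net = 100·(F_cell − F_nat)/(F_alga − F_nat). Natural-abundance
defaults: ¹³C/¹²C = 0.011237, ¹⁵N/¹⁴N = 0.003676, both configurable; an
empirical F_nat from designated unlabelled control ROIs is preferred when
such ROIs exist. F_alga defaults to the median atom fraction of ROIs
labelled `alga` in the same run. Because the isotope composition of
exuded metabolites may differ from the measured enrichment of algal
cells, C_net is a comparative estimate between treatments, not an
absolute tracer budget. C_net is clamped to [0, 100] by default (small
negative excess is counting noise); the unclamped mode is kept for QC.
ROIs with a zero major-isotope count are flagged and carried as NaN
rather than aborting a run.

Treatment summaries report median, IQR and n, with pairwise Wilcoxon
rank-sum and a global Kruskal–Wallis test. For small samples the p-values
are exact: the rank-sum null is enumerated over all group assignments
(midranks for ties) while arrangements ≤ 2·10⁵; Kruskal–Wallis enumerates
the multinomial splits of the pooled sample (scipy provides only the
chi-square approximation). Larger samples fall back to the standard
approximations, and the method used is recorded in the output. A fully
tied pooled sample yields H = 0, p = 1.

**C_total.** The per-well contribution is N_cells · m_C(V̄) · C_net/100
summed over wells within a treatment (and microplate replicate when
present); m_C is linear at 148 fg C µm⁻³ by default with an allometric
a·V^b option. This linear combination of abundance, cell size and median
C_net is this package's own definition of total incorporation; the
conversion factor is exposed in the configuration. Between-treatment
ratios propagate replicate standard deviations as independent relative
errors in quadrature.

## Synthetic data

The generators emulate the experimental designs the pipeline consumes,
with ground truth returned for scoring. All are bit-reproducible under a
fixed seed; the pipeline derives independent per-stage seeds from one
root seed.

*Metabolome* (162 features, 10 isolates, 5 isolate / 12 control
replicates by default): per-feature baselines are lognormal (median 10⁶,
log-sd 1); blanks sit at a low instrument background (10³); isolate
expectations are `background + baseline·(1 − p) + production`. Replicate
noise is multiplicative lognormal with CV 0.10 (mean-preserving
parameterisation), matching typical LC–MS replicate scatter. Default
ground truth: each isolate consumes a random 30% of features with
proportions uniform on [0.3, 0.9] — roughly the observed prevalence of
changing features, with clearly measurable depletion where it occurs.
Consumption and production are mutually exclusive per (isolate, feature)
because the pipeline's call is sign-based; overlapping truth would be
unidentifiable.

*Sequential* (10 strains, 3 replicate wells, CV 0.10): expected count of
secondary s on primary p's medium is `baseline_s · (1 + SI[p,s])`, with
multiplicative lognormal noise and truncation at zero. The default true
SI matrix mixes 70% competitive pairs (uniform on [−1, 0]) with 30%
facilitative (uniform on [0, 0.5]), mirroring the observed prevalence of
competition-dominated pairs.

*NanoSIMS* (300 cells, 10⁶ expected major-isotope counts per ROI):
per-cell true C_net is lognormal with median 2.71% and ≈1 percentage
point spread; the expected atom fraction is
F = F_nat + (C_net/100)(F_alga − F_nat) with F_alga = 0.05 by default,
and ion counts are Poisson (¹²C¹³C at mean 2R·total, per the dimer
convention). Optional algal ROIs at the full labelling level provide the
endmember. Poisson counting is the standard ion-counting model; detector
dead-time and drift are upstream corrections and are not simulated.

*Uptake sets*: a shared core of `round(overlap · set_size)` nutrients
plus disjoint per-strain private pools, so every directed MRO equals the
requested overlap exactly (up to core rounding, ≤ 1/(2·set_size)); the
generator refuses universes too small for the disjoint construction.

*Consumer-resource model*: linear yields,
`G = Σ_m yield_m · p_sec,m · pool_m · (1 − p_prim,m if primary present)`.
The secondary's uptake fractions enter the growth sum explicitly (an
equivalent formulation absorbs them into the yields). For binary
secondary profiles with equal pools and yields the simulated SI equals
ECI(p_sec, p_prim) exactly — an algebraic identity the tests verify to
machine precision.

What the generators do *not* emulate: chromatographic artefacts,
ionisation suppression and missing-at-random dropouts in LC–MS; batch
effects; cell lysis contributing to the metabolite pool; chemotaxis,
diffusion through porous microplate walls, or algal physiology; dynamic
growth curves. Passing recovery tests therefore shows the estimators
invert the stated measurement models at realistic noise, not that they
are robust to every artefact of real data.

## Numerical choices and degenerate inputs

- Lognormal noise is parameterised as mean-preserving
  (µ = −σ²/2, σ² = ln(1+CV²)), so expectations match designs exactly.
- Identical constant samples in a t-test give p = 1 (no evidence), not
  NaN.
- Matrix validity flags distinguish "no data / undefined" cells from
  genuine zeros; comparisons use pairwise-complete cells and log
  exclusions.
- The SI estimator's sampling error is ≈ √(2/3)·CV·(1+SI) under the
  3-replicate design, so strongly competitive pairs (SI near −1) are
  recovered much more precisely than neutral or facilitative ones; the
  recovery tests compare observed coverage against a brute-force
  Monte-Carlo of the same sampling model.
- Problem sizes in the test and acceptance runs match the emulated bench
  designs (162 features × 10 isolates, 10 × 10 strain pairs over 200
  replicate simulations, 300 cells per treatment); these complete in a
  few minutes on one CPU.

## Limitations

- MRO operates on supplied nutrient sets; reconstruction quality of the
  upstream genome-scale models is outside the package's control.
- C_total's linear definition ignores within-well covariance of cell
  size and enrichment and any temporal turnover of biomass during the
  incubation; it is a snapshot estimate.
- The Mantel base statistic (Pearson vs Spearman) and the one-sidedness
  are conventions; both are exposed as options.
- ECI assumes consumption proportions measured in monoculture transfer
  to the pairwise setting (no induced metabolic shifts).
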