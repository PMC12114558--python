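# Methods

## The setting

Soils around closed oil wells in coastal deltas age under two stressors at
once: salinity (tracked here as electrical conductivity, EC, mS·cm⁻¹) and
residual polycyclic aromatic hydrocarbons (PAHs, mg·kg⁻¹ dry soil). As
vegetation re-establishes patchily, vegetated soils tend toward lower EC and
PAH burdens, higher catalase activity (CAT), and denser microbial
co-occurrence structure than adjacent bare soils. The package quantifies
each link in that chain: PAH toxicity, community diversity, functional-gene
abundance, environment–community association, and network architecture.

## Synthetic study generator

The generator (`pahsoil.synth`) emulates a 3-region × 2-cover design: regions
GA/GB/GC at increasing salinity, each contributing `samples_per_cell`
(default 10) vegetated and bare samples, i.e. 60 samples by default. All
group-level means default to the bundled field-survey summary
(`pahsoil.datasets.load_field_summary`): bare-region EC means
(1.25, 2.06, 7.23 mS·cm⁻¹), TPAH means (2.30, 2.04, 1.77 mg·kg⁻¹), and so
on. Vegetated cells scale these by multipliers (EC × 0.41, TPAH × 0.45,
CAT × 1.2) chosen to match the vegetated group means of the same summary.

**Noise.** Positive quantities get mean-one lognormal noise,
`exp(σz − σ²/2)` with σ = `noise_sd_log` (default 0.4), so configured means
are recovered exactly in expectation and σ = 0 switches noise off entirely.
pH is additive-normal around slightly alkaline region means.

**PAH profiles.** Sample totals are partitioned into an LMW fraction
(default 0.20, matching the survey's LMW/TPAH ratio) and an HMW remainder,
then across congeners by fixed weights (phenanthrene-dominated LMW, broad
4–6-ring HMW, as in aged petrogenic profiles) with per-congener jitter
rescaled so the 16 congeners sum *exactly* to the sample total.

**Abundances.** For genus g in sample s,

    log a_gs = b_g + m_g·EC_s + λ_s·F_{k(g),s} + σ_s·ε

with baseline b_g ~ N(0,1), per-genus niche slopes m_g (by default a
"salt-sensitive clade" of 30% of genera with slope −0.2 per mS·cm⁻¹, the
rest EC-neutral), a shared standard-normal factor F per (guild, sample) —
genera are assigned round-robin to `n_guilds` = 5 guilds — and cover-specific
loadings λ (bare 0.55, vegetated 0.90). Scores are closed into proportions
and drawn as multinomial counts at a fixed depth of 60,000 reads per sample.
Two deliberate choices here:

- *Latent guild factors rather than a Dirichlet-multinomial alone*: the
  network stage needs above-threshold Spearman correlations to exist by
  construction, and a pure Dirichlet-multinomial plants none. Note that a
  factor shared by **all** genera cancels under the compositional closure;
  guild structure is only expressible relative to other guilds.
- *Variance equalisation*: the idiosyncratic scale σ_s is set per sample so
  that λ_s² + σ_s² is constant across covers. Without this, the stronger
  vegetated loading mechanically lowers vegetated evenness and the
  EC–diversity association flips sign for the wrong reason. With it, the
  cover contrast changes correlation structure only, and the diversity
  gradient is attributable to the niche clade. The clade's slope (−0.2) and
  the loading contrast are sized so the generator's own recovery property
  holds: the configured signs (EC–Shannon negative; vegetated network denser
  than bare) are recovered by the full pipeline in ≥95% of 100 study seeds.

**Gene copies.** log₁₀ copies per gram = log₁₀(configured mean) + EC slope
(−0.08 log₁₀ per mS·cm⁻¹) + vegetation offset (+0.2 log₁₀) + N(0, σ) noise,
then mean-calibrated by the exact lognormal (Jensen) correction so the
linear-scale design mean equals the configured mean (4.02×10⁸ for 16S,
1.37×10⁶ for PAH-RHDα, 2.26×10⁵ for C12O copies·g⁻¹). Ct values are emitted
from the configured standard curve (slope −3.3219, intercept 38) so the
quantification module can be round-trip tested; a noiseless 10³–10⁸ dilution
series is bundled with every dataset.

**Reproducibility.** One study seed is expanded into named per-stage streams
via `numpy.random.SeedSequence` spawn keys (a fixed stage→index registry in
`pahsoil._seeds`), so identical (config, seed) give byte-identical bundles
and any single stage can be regenerated alone. The generating config is
stored as a `truth` record beside the data; tests never re-derive it.

**What the generator does not emulate**: read-level artefacts (no FASTQ,
chimeras or PCR error), spatial autocorrelation between sites, taxon-specific
16S copy-number variation, and any higher-moment structure beyond group
means/SDs (the field summary constrains only those). Passing tests therefore
certify the pipeline's statistics and bookkeeping on data *with* the
configured structure — not robustness to sequencing artefacts.

## PAH toxicity

LMW = {NAP, ACY, ACE, FLU, PHE, ANT} (2–3 rings); the remaining ten
congeners are HMW; TPAH = LMW + HMW exactly. TEQ_BaP = Σ cᵢ·TEFᵢ with TEFs
defaulting to the Nisbet & LaGoy convention (BaP = DahA = 1;
BaA/BbF/BkF/IndP = 0.1; ANT/CHR/BghiP = 0.01; the rest 0.001); any published
TEF set can be loaded from CSV. A nonzero congener missing from the TEF
table is an error, never a silent zero weight. Contamination classes follow
the four-tier total-PAH scheme with boundaries 0.2 / 0.6 / 1.0 mg·kg⁻¹ and a
strictly-greater-than rule for "heavily polluted"; a two-tier mode collapses
everything at or below 1.00 to "slightly polluted". Ingested summary tables
are checked for |LMW + HMW − TPAH| > 0.01 mg·kg⁻¹; violations (which occur
in published group-mean tables via rounding) warn rather than error.

## Diversity and ordination

Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even
when F₂ = 0 and equal to S_obs whenever F₁ ≤ 1; it requires integer counts
(the estimator is undefined on relative abundances, reported NaN there).
Shannon entropy uses natural log by default with the base as a parameter
(the platform convention behind any particular published value is rarely
stated). Rarefaction is available upstream of diversity but off by default.
Bray–Curtis is Σ|x−y|/Σ(x+y) per sample pair; an all-zero pair is reported
as distance 0 with a warning.

NMDS alternates isotonic (monotone, ties-averaged) regression of
configuration distances on dissimilarities with SMACOF updates
(scikit-learn's nonmetric SMACOF does the optimisation), takes the best of
20 seeded random restarts, centres the configuration, and reports Kruskal
stress-1, sqrt(Σ(d−d̂)²/Σd²), recomputed from the returned coordinates by
the package's own isotonic-regression stress function — so the reported
stress is exactly reproducible from the result object.

## qPCR

Ordinary least squares of Ct on log₁₀ copies over a ≥3-point dilution
series; efficiency 10^(−1/slope) − 1 (slope −3.3219 ⇔ perfect doubling).
Quantification inverts the curve, 10^((Ct−b)/a), times a single
`extraction_factor` collapsing soil mass, elution volume and template
dilution (default 1, i.e. copies-in-reaction reported as copies per gram,
logged as a reminder). Ct values outside the fitted range are flagged
extrapolated rather than rejected. No 16S copy-number-per-genome correction
is applied. Melting-curve/specificity checking is wet-lab QC, represented
only as an optional boolean flag on input rows.

## Association statistics

Spearman is mid-rank ties then Pearson on ranks with the t approximation
(n−2 df). Correlation grids carry raw p-values by default (the conventional
presentation for environment-factor heatmaps); Benjamini–Hochberg is a flag.
The Mantel statistic correlates upper off-diagonal vectors; the permutation
p is (1 + #{r_perm ≥ r_obs})/(1 + n_perm) under joint row/column permutation
of the second matrix, one-sided positive by default with 999 permutations,
Spearman by default — both parameters. An exact mode enumerates all n!−1
nontrivial permutations for n ≤ 8. RDA fits Ŷ by least squares on centred
(optionally standardised) explanatory variables, ordinated by SVD; each
variable's explained % is *marginal* — fitted alone,
trace(ŶᵥᵀŶᵥ)/trace(YᵀY)×100 — and ranked descending, matching the simple
"ranked by explains" presentation; forward selection and variance
partitioning are out of scope. Collinear columns are dropped with a warning
naming them. ANOVA/Tukey letters use the studentized-range HSD with an
insert-and-absorb compact letter display; groups sharing a letter are not
significantly different at α.

## Networks

Construction operates on genus-level relative abundances. Filtering removes
genera with cumulative relative abundance below 0.5% of the table total or
detected in fewer than 3 samples. Edges require |Spearman r| > 0.6 **and**
p < 0.01, both strict; the threshold is applied to the magnitude because
signed (negative) edges are part of the architecture, and the sign is kept
as an edge attribute. No multiple-testing correction on edge p-values by
default (matching the stated raw thresholds); BH is available behind a flag.
An optional top-N-by-mean-abundance pre-selection before correlation exists
but is disabled by default: published workflows describe both a top-100 rule
and node counts exceeding 100, so neither variant is asserted as canonical.

Topology: average degree 2m/n; mean local clustering (low-degree nodes count
0); average path length over the largest connected component (undefined on
an edgeless graph, reported NaN); modularity and modules from Louvain on the
unsigned, unweighted graph (networkx implementation, resolution 1.0,
best-of-10 seeded restarts); "major" modules hold ≥5% of nodes (the
published usage of *major* is undefined; this is configurable). The null
model is the uniform Erdős–Rényi G(n, m) ensemble at the real network's
exact node and edge counts, each replicate measured with the same topology
code path. The small-world/modularity verdict requires clustering and
modularity to exceed the null mean (z-scores reported) with Q > 0.4.
Average degree is *identical by construction* at equal (n, m) and is
reported as non-informative — a real network can never exceed its
equal-size null on this metric, whatever a results narrative may claim.
Keystone taxa are ranked by exact unweighted betweenness centrality, with an
option to exclude genus-unclassified taxa from the ranking, and ties broken
by degree then taxon id for determinism.

## Problem sizes and numerical choices

Default analyses run at the design scale the generator emulates (60 samples,
150 genera, 100-replicate nulls, 999 Mantel permutations); the repeated-seed
recovery analyses use 100 study seeds. Degenerate inputs are handled
explicitly rather than propagated: constant taxa are excluded from
correlation with a warning, an all-zero sample is an error for
normalisation and Shannon, infeasible G(n, m) requests error, and a network
too sparse to contain a 3-node component yields an empty keystone table in
the pipeline. Strict inequalities are used everywhere a published rule is
quoted with "exceeds"/"higher than".

## Known limitations

Compositional effects are not modelled out of the correlation networks (no
SparCC/SPIEC-EASI); the Erdős–Rényi null is not degree-preserving; Chao1 on
deeply sequenced synthetic data saturates near the configured genus count,
compressing richness contrasts; and the field-scale network sizes
(hundreds of nodes, thousands of edges) arise from sequencing depth and
taxon richness not reproducible at synthetic scale — the pipeline reproduces
the *contrasts* (vegetated denser than bare, small-world verdicts), not the
absolute counts.
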