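# Methods

## Study design emulated by the simulator

The package models a three-species comparison of pluripotent epiblast
development: three species (a mouse-like rodent and two ungulate-like
species) profiled by bulk RNA-seq at three in vivo stages — ICM (inner cell
mass), ERSE (post-implantation radially symmetric epiblast) and APE
(gastrulation-stage epiblast) — with 3 replicates per stage, plus a
mouse-like in vitro panel of three cultured pluripotent states (2i-mESC,
serum-mESC, mEpiSC), again with 3 replicates. All analyses run over a
1:1:1 orthologue universe: groups with exactly one gene per species,
re-keyed by `orthology.map_to_groups` with missing genes carried as NaN
(never zero — zero-imputation would fabricate downregulation). The overlap
universe N is the set of 1:1:1 groups quantified in every species' matrix
(complete cases), not the raw table size.

## Count model

Counts are negative binomial in the mean/dispersion parameterisation,
variance = mu + phi * mu^2, drawn as gamma–Poisson. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_orthologs` | 2000 | universe size N |
| `baseline_mean_log`, `baseline_sd_log` | 3.5, 1.0 | log-normal gene baselines (median ~33 counts, ~90% within 4–250) |
| `dispersion` | 0.1 | NB dispersion phi, a typical bulk RNA-seq biological CV² |
| `replicates_per_group` | 3 | per stage/condition |
| `library_size_range` | (0.7, 1.3) | uniform per-sample scale factor, exercising normalisation |
| `planted_fold` | 4.0 | effect magnitude f of planted DE |
| `n_conserved_up`, `n_conserved_down` | 50, 50 | per sequential transition, shared direction in all species |
| `n_species_specific` | 30 | per species per transition, random direction |
| `n_ground_state` | 10 | expressed in ICM and 2i only |
| `transition_fraction` | 0.65 | fraction of primed-pattern genes already shifted in serum |
| `n_invitro_specific` | 30 | per culture transition per direction, DE in vitro only |

Design choices within the generator:

- **Baselines are drawn independently per species.** Absolute expression
  diverges between species, so samples cluster by species before stage —
  the dominant structure of real cross-species data — and, under a null
  configuration, per-species test rankings are independent, which is what
  makes the conservation statistic's calibration checkable.
- **Planted effects persist into later stages.** An ICM→ERSE effect is also
  visible in ICM→APE; ERSE→APE signal comes only from its own planted
  block. This reproduces the qualitative pattern that most conserved
  changes concentrate at the first transition.
- **In vitro coupling.** Genes conserved at ICM→ERSE are planted in the
  2i→mEpiSC transition with the same direction. A `transition_fraction`
  subset of the upregulated ones (class `transition`) and of the
  downregulated ones are already shifted in serum cells, making serum-mESCs
  an intermediate state. Culture-specific genes (`n_invitro_specific`) are
  DE in vitro but flat in vivo; without them every in vitro DE set would be
  a subset of the conserved pool and all in vivo × in vitro grid cells
  would be equally enriched, leaving the grid ranking undefined.
- **Ground-state-restricted genes** keep their baseline in ICM and 2i and
  drop to a small leak mean (0.05 counts) elsewhere, avoiding degenerate
  all-zero rows; their baseline is floored at exp(`baseline_mean_log`) so
  the "expressed in 2i" flag is reliable.
- One `numpy.random.Generator` seeded from `seed` drives everything; equal
  configs give byte-identical output.

What the generator does **not** emulate: gene-wise dispersion variation,
gene length and GC effects, correlated co-expression modules, isoform
structure, amplification artefacts, batch effects. Passing tests therefore
demonstrate the statistical machinery under a clean NB world, not
robustness to every real-data pathology.

## Differential expression

Fold changes are mean-based on the CPM scale, log2((mean_B + c)/(mean_A +
c)) with pseudo-mean c = 0.5 CPM to keep zero-mean genes finite. Two tests
are available:

- **`nb_exact` (default).** Counts are rescaled to the geometric-mean
  library size and rounded; under equal means the group-A sum conditioned
  on the grand total is beta-binomial(total, n_A/phi, n_B/phi). The common
  dispersion phi is estimated by conditional maximum likelihood on
  within-group count splits: given its group total, a vector of iid NB
  counts is Dirichlet-multinomial with concentration 1/phi, independent of
  the group mean — so the estimate cannot be inflated by genuine DE.
  Two-sided p doubles the smaller tail (observed point in both tails,
  capped at 1). On NB null data (fold 1, phi 0.1, 3 vs 3) the empirical
  type-I error is ~0.04 at the 0.05 level, and the estimator recovers the
  generating dispersion (0.10 ± 0.01 at 2000 genes).
- **`welch_log`.** Welch's t on log2(CPM + 1). Also calibrated
  (~0.034), but with 3 replicates its ~4 degrees of freedom bound the
  attainable significance; at FDR-style thresholds it detects only a small
  fraction of fourfold effects. It is kept as a distribution-free
  robustness check and is the default ranking engine where only an
  ordering, not a threshold, is needed. The exact NB test is the default
  because a count model with shared dispersion is the appropriate tool at
  2–3 replicates — the same reasoning that underlies the standard
  exact-test DE packages.

Multiple testing is Benjamini–Hochberg per species per transition
("q-value" read as step-up FDR adjustment; Storey-type estimation is out of
scope). Directional calls need q ≤ 0.25 and linear fold change ≥ 1.5 (or ≤
1/1.5), both configurable. Genes with both groups all-zero get p = 1 and
fold change 0. Groups of fewer than two samples are rejected.

## Conservation enrichment

Expected k-way overlap under independent uniform sampling is prod(n_i) /
N^(k-1). Pairwise p-values are exact hypergeometric upper tails
(`scipy.stats.hypergeom.sf`, verified against exhaustive enumeration for
all universes up to N = 30). The three-way null is Monte Carlo: a draw of
the k-way overlap is generated as a chain of hypergeometric variables (the
running intersection against each next set), so each draw is O(k)
regardless of N and distribution-exact; p = (1 + exceedances)/(B + 1) with
recorded seed, B ≥ 1000 enforced. An analytic three-set construction was
deliberately not invented; the Monte-Carlo null realises exactly the stated
sampling model. Directions are analysed separately (up with up, down with
down), with a combined mode behind a flag; no multiple-testing correction is
applied across the enrichment grid (raw p-values are reported), BH across
cells available behind a flag.

Calibration note: under a null configuration, thresholded DE sets are
almost always empty — that is FDR control working — so the independence
calibration uses fixed-size rank-based sets (top 800 of 2000 by p per
species). Over 200 seeds the three-way enrichment median is ~1 and the
Monte-Carlo p-values are near-uniform.

## Sample structure and QC

Pearson correlation on pairwise-complete genes; average-linkage
agglomeration on 1 − r; PCA by SVD of the centered (optionally scaled)
samples × genes matrix of log2(CPM + 1), variance fractions summing to one
over retained components. Replicate QC excludes a sample when the median
correlation with same-group peers falls below 0.7 (stated default; the
threshold is a judgement call, singleton groups are never excluded).

## Predictor panel and scoring

The qualitative gene classes are codified as boolean rules over directional
DE calls and expressed flags (expressed = CPM ≥ 1 in at least half of a
group's samples, explicit and configurable since "expressed" has no
universal definition):

- naive: conserved down ICM→late (ERSE or APE) in ≥ `min_species` species
  (default 3; 2 admits two-species conservation) AND down 2i→mEpiSC;
- primed: the mirrored up pattern;
- transition: primed-pattern AND up already at 2i→serum;
- ground-state-restricted: naive-pattern AND expressed in 2i but in neither
  serum nor mEpiSC.

Classes are mutually exclusive (transition trumps primed,
ground-state-restricted trumps naive). Scoring z-scores each panel gene's
log2(CPM + 1) across the scored cohort and averages within
naive-associated (naive + ground-state-restricted) and primed-associated
(primed + transition) groups; delta = naive − primed with symmetric call
thresholds at ±0.5. At least 3 genes per class are required after id
mapping.

## Problem sizes and numerical choices

Tests and the acceptance script run at N = 2000 orthologue groups, 3
replicates, fold 4, dispersion 0.1 — the package's standard desk-scale
study — with 200 seeds for null calibration, 20 for recovery averages, and
Monte-Carlo nulls of 5000–10^5 draws depending on the precision the check
needs. Dispersion optimisation is bounded on log-phi in [1e-4, 10];
fold-change pseudo-mean 0.5; enrichment of an empty expectation is NaN;
zero observed overlap with positive expectation is reported as −inf log2
enrichment with p = 1.

## Known limitations

- The exact NB test assumes a common dispersion across genes; strongly
  gene-variable dispersion would need per-gene shrinkage estimation.
- Orthologue tables are taken as authoritative; many-to-many families are
  out of scope (only the 1:1:1 subset is analysed).
- No batch correction in the combined in vivo/in vitro analyses; matrices
  are concatenated on shared orthologues as-is.
- Panel scoring z-scores within the scored cohort, so scores are relative
  to that cohort, not an absolute scale.
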