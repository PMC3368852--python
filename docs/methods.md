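# Methods

`symassem` analyses *Symbiodinium*-type ITS2 sequence assemblages: multisets of
cloned ITS2 sequence variants tallied from individual coral samples (clone
libraries), used as a proxy for the symbiont community. The package covers the
full comparative workflow for parent-colony versus egg assemblages: library
screening, genetic distances, statistical-parsimony networks, overlap and
differentiation statistics, multifactor variance partitioning, host population
genetics and environmental comparisons.

## Screening

A variant observed in a dataset is retained iff

* it was published previously (an input flag), **or** it was recovered at
  least 3 times across at least 3 distinct samples; **and**
* it is not pseudogene-flagged.

The pseudogene flag (aberrant ITS2 secondary-structure fold, e.g. a deformed
helix IIIb) is an *input*: fold prediction belongs to specialist RNA-structure
tooling and is outside this statistical pipeline. The flag overrides published
status. "Distinct samples" means distinct sample ids — the adult and the egg
library of one colony are two samples, since they are independent clone
libraries. Screening happens once, dataset-wide, before every downstream
statistic including the percent similarity index; this ordering is the only
one consistent with published per-colony values that depend on a
pseudogene-excluded library.

## Distances

Genetic distance between variants is the simple pairwise difference count
(Hamming) on the input alignment — the alignment itself is never computed
here. Two gap conventions are provided: `fifth_state` (default; a gap is a
fifth character state, so gap/base differs and gap/gap matches) and `ignore`
(columns containing any gap are skipped). `fifth_state` matches the network
convention; the raw-count matrix feeds the AMOVA statistics, and its
element-wise square root (guarded by a metric tag against double application)
feeds the multifactor partition, mirroring the standard practice of
square-root-transforming distances before distance-based multivariate ANOVA.
Clone-level matrices expand each library to one row per clone, with the
distance between clones equal to the distance between their variants.

## Statistical-parsimony networks

The connection limit at confidence level `c` (default 0.95) is the largest
step count `j` whose probability of parsimony is at least `c`. Following the
statistical-parsimony framework of Templeton, Crandall & Sing (1992) — the
probability that `j` observed differences between two sequences of aligned
length `m` arose from exactly `j` substitutions — the probability is evaluated
under a Jukes–Cantor finite-sites model. Per-site substitution counts are
Poisson(θ); a site shows a difference with probability
D(θ) = ¾(1 − e^(−4θ/3)); the unknown pairwise divergence θ is integrated out
under a uniform prior on (0, 2] substitutions/site (the upper bound is far
beyond saturation and insensitive in practice):

    P(parsimony | j, m) = ∫ θ^j e^(−mθ) dθ / ∫ D(θ)^j (1 − D(θ))^(m−j) dθ.

Both integrals are evaluated on a fixed 4001-point grid in log space
(log-sum-exp); the test suite pins the values against an independent
closed-form/adaptive-quadrature evaluation. The limit is non-decreasing in
`m`, non-increasing in `c`, and approaches `m` as `c → 0`.

Network construction is a deterministic simplification of the TCS procedure:
candidate pairs are sorted by (steps, label order) and an edge is added iff
its step count is within the limit and it joins two components not yet
connected. Each subnetwork therefore carries a minimum-spanning forest of the
admissible connections; connected-component structure — the analytically
interpreted quantity — matches full TCS, while unsampled intermediate
haplotypes and alternative equal-length connections are not materialised.

## Percent similarity index

PSI (Renkonen/Wolda) between two screened libraries with relative abundance
vectors p, q is Σ_v min(p_v, q_v): 1 for identical composition, 0 for disjoint
label sets. It is symmetric and invariant to rescaling either library's
counts. Reported values use half-up rounding to 2 decimals, the convention of
printed summary tables (the raw proportion is always retained).

## Two-group AMOVA

Per-colony adult-versus-egg differentiation uses the distance form of AMOVA
(Excoffier et al. 1992) on squared clone distances:

    SS_total  = (1/N) Σ_{i<j} d²_ij            (all N clones)
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    SS_among  = SS_total − SS_within

with σ²_w = SS_within/(N−k), σ²_a = (MS_among − σ²_w)/n₀,
n₀ = (N − Σn_g²/N)/(k−1), and Φ = σ²_a/(σ²_a+σ²_w). Φ = 0 means identical
composition, Φ = 1 alternate fixation; negative estimates (SS_among below its
null expectation) are reported as-is, never truncated. Significance comes
from permuting clones between the groups with sizes fixed; the add-one rule
p = (1+x)/(1+n_perm) keeps p strictly positive, and p < 0.001 is attainable
from 999 permutations up.

## Multifactor partition

The nested multifactor analysis is McArdle–Anderson distance-based
partitioning. The squared distance matrix is Gower-centred,
G = −½·J·D²·J, with tr(G) the total SS. Terms are fitted sequentially
(Type I, in the published order); each term's SS is the trace of G projected
onto the term's incremental column space, so SS adds up to tr(G) exactly
(checked to 1e-8 on every fit). Nested terms such as Colony(Site) are encoded
as cross-classifications and inherit the nesting arithmetic from the
sequential projections; a term whose incremental rank is zero (confounded
with earlier terms) is a named error. Two built-in designs reproduce the
published term lists: four-factor Site/Year/Life-stage/Colony(Site) with all
interactions (11 terms) and three-factor Morphology/Life-stage/Colony(Morphology)
(5 terms), both defaulting to 10,000 permutations.

Pseudo-F uses the residual mean square as denominator. Mixed-model
expected-mean-square denominators (as in dedicated PERMANOVA software) are
deliberately not reconstructed — the published tables do not determine them —
so printed MS/Φ/p values of such software are not comparison targets; a
per-term `phi_like` effect size (SS_term/SS_total) and pseudo-F are both
reported, clearly labelled. Permutation is unrestricted over clones by
default, which is exact when clones are exchangeable under the null and an
approximation otherwise: when another factor carries a large real effect,
unrestricted permutation lets that effect leak into a null term's permuted
F, making its p conservative and mid-concentrated rather than uniform. The
calibration suite therefore checks uniformity in a fully null layout and
checks power/level jointly in the site-effect layout. `DesignSpec` terms can
instead declare whole libraries as exchangeable units (the metadata is then
permuted across samples and the model refitted per draw).

## Hierarchical diploid AMOVA

Host genotypes (two phased alleles per individual; phase inference is out of
scope) are partitioned over four strata — among groups, among samples within
groups, among individuals within samples, within individuals — on the 2N
allele copies, using the same distance formulation (allele distances default
to Hamming on the aligned fragment; a precomputed matrix may be supplied).
Variance components for arbitrary unbalanced layouts come from solving the
triangular expected-SS system with coefficients computed from cluster sizes;
strata with zero degrees of freedom collapse to zero, which also makes the
machinery exact for haploid/flat special cases (where Φ_AM reduces to the
two-group AMOVA Φ — a consistency test). Φ statistics are cumulative-component
ratios: Φ_AM = σ²_a/σ²_tot, Φ_AS(AM) = σ²_b/(σ²_b+σ²_c+σ²_e),
Φ_AI(AS(AM)) = σ²_c/(σ²_c+σ²_e), Φ_WI = (σ²_a+σ²_b+σ²_c)/σ²_tot. Negative
components are reported as-is. Per-level permutation p-values use
level-appropriate exchangeable units: samples among groups, individuals among
samples within groups, allele copies among individuals within samples, and
allele copies globally.

## Exact test of non-differentiation

The allele-by-population contingency table is tested conditionally on its
margins (Raymond & Rousset). The p-value is the null probability of tables no
more probable than the observed one. Tables with total count ≤ 12 are
enumerated completely (exact); larger tables use the 2×2 switch Markov chain
with Metropolis acceptance (acceptance ratio t_ij·t_kl/((t_il+1)(t_kj+1))),
1,000 burn-in steps, a default of 10,000 counted steps, and a seeded
generator. The chain estimate is floored at 1/steps so p is never zero. The
test suite requires chain/enumeration agreement within 0.02 at 100k steps.

## Environmental statistics

Per-site summaries are arithmetic mean, sample SD (n−1), minimum, maximum
and n. Between-site comparisons use the Kruskal–Wallis rank test with tie
correction (via `scipy.stats.kruskal`) — logger data quantised at 0.2 °C ties
heavily, so the correction matters. If every pooled observation is identical,
H = 0 and p = 1 by definition. H is invariant under strictly monotone
transforms of the pooled data.

## Synthetic data generator

The generator emulates the structure this analysis assumes, not any
particular reef:

* two clade ancestors (C, D) at a configurable inter-clade divergence
  (default 0.25 of sites — a stand-in; real inter-clade ITS2 divergence is
  not pinned by the emulated study);
* a few dominant variants per clade (default 2, spaced 3 edits apart) with
  satellite variants exactly 1–3 substitutions from a recorded dominant;
* aligned length default 320 (a parameter; nothing downstream assumes it);
* per-sample clone libraries of 7–13 clones drawn multinomially from
  Dirichlet-perturbed site-level community weights (Dirichlet-multinomial
  overdispersion, concentration parameter exposed) — clone libraries are
  small samples of an underlying community and the emulated study states no
  sampling model;
* clade-D-rich adult communities at designated sites; egg libraries either
  mirror the parental composition (`faithful`) or shift clade-D-rich parents
  toward clade C (`shifted`), emulating preferential transmission;
* optional pseudogene injection, a small synthetic diploid host genotype
  table, and site-shifted diel temperature/light series (quantised to 0.2 °C
  to reproduce logger ties).

Every stochastic decision (edit positions, mixing weights) is stored in a
truth record so tests can verify pipeline outputs against generator ground
truth. The same seed yields byte-identical bundles. The generator does not
model PCR/cloning bias, chimeras, within-colony spatial structure, or a
temporal model of year-to-year change (year effects are independent weight
redraws) — so green tests certify the statistical machinery under the stated
sampling model, not robustness to those real-data artefacts.

The published clone-count table ships as a programmatic fixture (64
libraries, 659 clones, 29 variants with the printed published/pseudogene
flags) with seeded synthetic placeholder sequences: count-only statistics
(screening, PSI, clade tallies) on this fixture are canonical; distance-based
statistics from it are not, because the true GenBank sequences are not
bundled.

## Numerical and reporting choices

* PSI reported as a proportion despite the historical "percent" name;
  half-up rounding at 2 dp for report tables.
* Permutation p-values always use the add-one rule; every permutation stream
  is seeded and recorded in run provenance.
* Degenerate inputs: zero total variance gives Φ = 0 (flagged); empty
  libraries after screening are explicit and rejected by all statistics;
  a sample containing a single individual is allowed but flagged.
* Calibration problem sizes: the default test suite uses 100–1000 simulation
  replicates with 199–499 permutations, and the two-group null calibration
  uses libraries of 10 clones per group — sizes chosen to make Monte-Carlo
  error small relative to the acceptance bands.

## Known limitations

* The connection-limit estimator adapts the statistical-parsimony
  probability to nucleotide data under Jukes–Cantor with a uniform divergence
  prior; other published operationalisations use restriction-site models and
  can give different absolute limits. Only component structure is treated as
  reproducible.
* Unrestricted clone permutation for main effects is approximate in the
  presence of strong other effects or colony-level heterogeneity
  (conservative in practice here); library-level exchangeable units are the
  provided remedy.
* Type I (sequential) SS makes term values order-dependent in unbalanced
  layouts; the published term order is used.
* ITS2 copy-number variation means assemblage statistics quantify sequence
  assemblages, not symbiont species diversity.
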