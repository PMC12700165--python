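# Methods

This note documents the models, conventions and numerical choices behind
`rumenaux`, and what the synthetic study design does and does not emulate.

## Study structure

The package targets longitudinal, genome-resolved rumen metagenomics: a
cohort of host animals sampled repeatedly from birth to maturity, with
genomes (MAGs) assembled per sample, quantified by read mapping, and
annotated with KEGG Orthologs.  The default sampling grid is 14 time
points (TP1–TP14) at days 2, 5, 15, 25, 50, 70, 100, 130, 170, 200, 300,
400, 700 and 750 after birth, spanning five diet phases: colostrum
(first days), milk replacer + grain (to day 60), starter grain (to day
90), a low-fiber ration (to day 180), a high-fiber ration (to ~day 725)
and a return to a low-fiber lactation ration.  TP7 (day 100) marks the
onset of the adult fibrous diet and is the default reference point for
persistence analyses.

## Species dereplication

Genomes are filtered at completeness ≥ 90% and contamination ≤ 5% (both
boundaries inclusive) and clustered into species as connected components
of the ANI graph thresholded at 0.95.  Single-linkage components replace
the two-stage greedy clustering of dedicated dereplication tools: the
component rule is deterministic, oracle-testable (it must equal
brute-force transitive closure), and identical to the greedy result
whenever within-species and between-species ANI distributions are
separated around the threshold — which holds for the synthetic data by
construction and for well-behaved real collections.  Borderline ANI
chains can differ between the two rules; that is a known limitation.

ANI input is symmetrized by taking the maximum of the two directed
values (directed estimates are near-symmetric; the maximum is
deterministic and conservative for linking).  Percent-vs-fraction
dialect is auto-detected (values above 1.5 are treated as percent).

Representatives maximize completeness − 5 × contamination, with ties
broken by larger N50 and then lexicographic genome id.  This is a
deliberate simplification of assembly-score formulas with N50/size
terms: downstream analyses use the representative only as a label, so
the simpler, fully specified score is preferred.  A species is *novel*
when every member genome comes from the study itself; overlap counts
report, for every exclusive dataset combination, the number of species
whose member datasets equal that combination (so counts partition the
species).

## Presence and abundance

Presence requires breadth of coverage ≥ 0.90, inclusive; the threshold
is a filter applied to quantification, so absent genomes have their
depth zeroed *before* per-sample closure to 1.  Depths are first scaled
by min(library sizes)/library size; since relative abundance closes each
sample anyway, this normalization matters only for outputs that use
depths directly.  Per-time-point group shares average the within-sample
group sums over that TP's samples — animals are equal replicates;
pooling depths instead would over-weight deeply sequenced samples — and
are rescaled to 100%.  Taxon aggregation sums member abundances at a
chosen rank, pooling unlabeled genomes as "Unclassified" and preserving
column sums.  Copy-number profiles (e.g. ABC transporter dosage) are
abundance-weighted sums of per-genome KO copy counts.

## Core assignment

Core genera must be supported by at least 2 of 3 sources: two published
core-taxa lists and a prevalence criterion (genus present in ≥ 80% of
hosts, inclusive).  A genome is flagged core on a single BLAST hit from
a core-genus 16S ESV with alignment length ≥ 250 bp and identity ≥ 90%
(both inclusive); the hit's own taxonomy is not additionally required to
match the ESV's genus — hit evidence alone decides, which keeps the rule
monotone in the hit set.

## Temporal clustering

Genome profiles are per-TP means of relative abundance (animals
averaged first; host identity explains little community variance in
this design, so per-sample profiles would mostly add animal noise).
Spearman ρ uses average ranks; pairs involving constant profiles are
undefined and set to 0.  Edges require ρ ≥ 0.75 — a value of exactly
0.75 survives.  Communities come from Louvain modularity maximization on
edge weights with a fixed seed (default 1) and resolution 1.0, both
exposed in the config; isolated genomes stay singleton clusters, which
are reported but excluded from cluster-level enrichment (a testable
cluster needs ≥ 2 genomes).  Cluster ids are renumbered by descending
size then smallest member, so labels are stable across runs.  Peak
annotation takes the argmax of the cluster's per-TP mean total (earliest
TP on ties) and the diet fed at that TP.

## Enrichment

All three enrichment analyses share one upper-tail hypergeometric core,
P(X ≥ k), X ~ Hypergeom(N, K, n), evaluated through scipy's log-space
survival function, and Benjamini–Hochberg step-up adjustment
q(i) = min over j ≥ i of p(j)·m/j, capped at 1.  BH is applied jointly
across all tests of one analysis (all families; all function × group
pairs; all cluster × function pairs) — the conservative reading when the
correction family is otherwise ambiguous.  Only over-representation is
tested; depletion is out of scope.  The counting unit differs by
analysis: representative genomes for family-level novelty enrichment,
genome–function incidences for group-level function enrichment, and
genes for per-cluster function enrichment, where the gene ratio k/n
accompanies each result.

## KEGG module completeness

DEFINITION strings parse into per-step boolean trees with this grammar:
top-level spaces separate steps; within an expression a space is again
an AND of sub-steps (inside parentheses), a comma is an OR, `+` joins
complex subunits (AND), `-` marks an optional component, `--` is a
placeholder step with no known enzyme, and parentheses group.
Precedence loosest-to-tightest is space < comma < `+`/`-`.  Note that a
parenthesized space group is one step whose sub-steps must all hold,
which is different from the same text at top level.  Optional components
never count for or against satisfaction (a step consisting only of
optional parts is vacuously satisfied); gap steps are never satisfied,
so modules containing them cannot reach completeness 1.  Nested module
references resolve one level deep against the definition table (treated
as satisfied iff the nested module is fully complete) and fall back to
an unsatisfied leaf with a warning when unresolved.

Completeness is *stepwise*: the fraction of top-level steps satisfied by
a genome's KO set — the headline metric of metabolism-estimation tools —
rather than fractional best-path scoring; the "complete" call uses a
configurable cutoff, default 0.75.  Stepwise completeness is monotone
under KO-set growth, which the tests exercise on ~10^3 random
(definition, set, superset) triples.

## Pathway complementarity

Two currencies quantify what an auxiliary genome adds to a target:

* completion gain per module, completeness(target ∪ aux) −
  completeness(target): non-negative by monotonicity and zero whenever
  the auxiliary KOs are a subset of the target's;
* metabolite gain, |scope(target ∪ aux)| − |scope(target)|, where scope
  expansion iterates "a reaction fires when all substrates are
  reachable" to a fixpoint from a seed metabolite set (reversible
  reactions fire both ways).  The default seed set is the substrates
  that are never products anywhere in the reaction table — a
  deterministic, dataset-independent choice; currency metabolites can be
  excluded via a configurable list at read time.

Both are computed because pathway-completion scores and
newly-producible-metabolite counts answer different questions (module
bookkeeping vs reachable chemistry); aggregation accepts either as the
gain source, defaulting to completion gain.  A genome *contributes* at a
TP when it has any positive gain over pairs whose two genomes are both
detected in at least one sample of that TP.  Module × TP aggregates
divide the summed gain by the number of distinct contributing auxiliary
genomes; TPs without contributors hold 0 and are excluded from the row's
z statistics.  Contributor ranking z-scales totals within each TP column
and orders rows by average-linkage hierarchical clustering on Euclidean
distances of the z-profiles.  Z-scores use the sample (n−1) denominator;
zero-variance or single-value slices map to zeros.  Persistent
contributors show positive gain at ≥ 2 distinct TPs after the configured
onset (default TP7).

## Synthetic study design

The generator emulates the structural features the pipeline must
recover, not sequencing data:

* **Catalog** — 40 auxiliary study genomes, each founding a novel
  (study-only) species; 20 non-auxiliary study genomes each sharing a
  species with one external-collection genome; 10 external-only species;
  a few redundant study MAGs and low-quality bins.  Within-species ANI ~
  U(0.955, 0.999), between-species ~ U(0.75, 0.93): the gap straddles
  0.95 so dereplication is oracle-exact and downstream tests isolate
  downstream logic.  Three planted families consist entirely of novel
  representatives; the rest mix groups, so exactly the planted families
  are enriched.
* **Abundance** — six temporal clusters (four auxiliary peaking at TPs
  1–7, two non-auxiliary peaking late) follow Gaussian bumps over the TP
  axis (width 1 TP, baseline 0.05) multiplied by per-genome lognormal
  noise (σ = 0.2); group totals are rescaled per TP to the planted
  auxiliary trajectory (0.95, 0.70, 0.45, then 0.27 from TP4); each of
  10 animals adds independent lognormal noise and samples are closed to
  1.  Breadth is ≥ 0.95 where a genome is present in truth and ≤ 0.5
  otherwise, so presence calls separate cleanly.  Library sizes vary
  (38–60 M reads) to exercise depth normalization.
* **Functions** — 24 modules with 2–5 steps over disjoint KO alphabets;
  the 15 planted complementarity pairs each use their own module whose
  final step is a two-subunit complex split across the pair (target:
  everything but one subunit; auxiliary: the missing subunit).  The
  split-complex construction is what makes the planted design exact —
  an auxiliary KO that completed a whole step on its own would register
  gains against every target.  Reaction chains (seed → intermediate →
  product) give each planted pair a metabolite gain of ≥ 1 and no
  unplanted pair any gain.  Group-function incidence tables plant two
  auxiliary-enriched and two non-auxiliary-enriched functions over an
  even background; per-cluster gene-count tables plant one marker
  function per temporal cluster.
* **Core** — core truth is 11 genomes/genera wired through the 2-of-3
  sources; distractor genera appear in exactly one source or below the
  prevalence cutoff; BLAST hits pass the length/identity filters exactly
  for core genomes.

Everything is drawn from one `numpy` Generator seeded by the config, so
identical configs give byte-identical bundles.  Default sizes (≤ 120
genomes, 24 modules, 140 samples) keep the full test suite and the
acceptance script in the seconds-to-minutes range.

What passing on synthetic data does **not** show: robustness to
compositional noise beyond lognormal, to ANI distributions overlapping
the species threshold, to incomplete/contaminated annotations, to
unbalanced sampling, or to the much larger scale of real genome
collections.  The generator's separations are intentionally clean so
that failures indict pipeline logic rather than data ambiguity.

## Pipeline and reproducibility

Stages run in dependency order; each records content checksums (not
timestamps) of its inputs plus the config, and re-runs skip stages whose
signatures match and whose outputs exist.  Logs go to standard error
only; every data output is a TSV with a header, floats printed to 10
significant digits so that write→read round-trips are exact at that
precision.  The Louvain seed is the single stochastic input of the
analysis stages; with it fixed, two runs from the same bundle are
byte-identical.

## Known limitations

* Single-linkage species clustering can chain through borderline ANI
  values where greedy centroid-based tools would split.
* Stepwise completeness is binary per step; partially present complexes
  contribute nothing ("pathwise" fractional scoring is not implemented).
* Scope expansion ignores stoichiometry, thermodynamics and flux; it is
  a reachability statement only, and pairs only (no ≥ 3-genome joint
  scopes).
* Group-level function enrichment treats genome–function incidences as
  exchangeable draws, ignoring phylogenetic correlation between genomes.
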