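# Methods

This note documents the models, algorithms, default parameters and design
choices behind `evonet`, a pipeline for studying the evolution of predicted
protein–protein interaction (PPI) networks across the five *Saccharomyces
sensu stricto* yeasts (*S. cerevisiae*, *S. paradoxus*, *S. mikatae*,
*S. kudriavzevii*, *S. bayanus*).

## Overview

The pipeline couples three ingredients:

1. a sequence-based PPI predictor (`pipe_engine`) that scores a query pair
   by how often pairs of 20-residue windows from the two queries co-occur
   in protein pairs already known to interact;
2. a neutral sequence-evolution simulator (`proteome_simulator`) that
   regenerates the four non-*cerevisiae* proteomes under a codon
   substitution + indel process in which mutations fall blindly with
   respect to interaction sites — the null model;
3. parsimony-based quantification of interaction gain/loss across the
   phylogeny (`network_evolution`), with conserved/rapidly-rewiring protein
   calls made against the replicate null distribution, plus GO enrichment
   (`enrichment`) and interactome cluster comparison (`cluster_compare`).

Because no deposited genome-scale dataset ships with the package, a
synthetic-data module (`synthetic_data`) generates databases and
five-species datasets with known planted structure, so that every stage —
including the end-to-end conservation call — is testable with exact ground
truth.

## Window co-occurrence prediction

The database is an undirected graph *G* over protein IDs. For a query pair
(A, B), every overlapping window `a_i` (length `w = 20`, step 1) of A is
compared against every window of every database protein; window similarity
is the PAM120 sum over aligned positions compared to an integer threshold.
Each database protein containing a window similar to `a_i` contributes its
graph neighbours to a list `R_i`; cell (i, j) of the `(|A|−w+1) ×
(|B|−w+1)` result matrix counts similar-window hits of `b_j` among the
proteins of `R_i`. The unknown residue X scores 0 against everything.

The scalar score is the maximum result-matrix cell (mean available as an
option): the strongest co-occurrence cell is the natural evidence summary
for a matrix of co-occurrence counts. Because the sequential construction
is orientation-asymmetric — the *second* protein's windows are tallied
against the *first* protein's neighbour lists, so a protein whose
interaction interface is unique in the database contributes evidence in
only one direction — `predict()` evaluates both orientations and takes the
stronger aggregate. This makes the prediction symmetric by construction
and deterministic, without touching the definition of the result matrix
itself.

**Similarity threshold (default 90).** The PAM120 sum of two random
20-mers is approximately normal with mean −21 and s.d. ≈ 12.5, while the
expected self-score of a 20-mer is ≈ 107 (mean diagonal ≈ 5.35), dropping
by ≈ 6.5 per substituted position. The default of 90 therefore declares
two windows similar when they are near-identical (roughly ≤ 3
substitutions apart), and the probability that two random windows pass is
negligible (< 1e-8). Two failure modes anchor this choice. Too low (≤ 50)
and (a) chance similarities flood the neighbour lists, so that unrelated
pairs accumulate co-occurrence counts comparable to genuine signal, and
(b) a planted interaction motif tolerates ~8 substitutions before its
similarity breaks, so the neutral simulation at sensu-stricto divergences
almost never disrupts an interaction and the null distribution of network
change carries no information. At genome scale, where hub degrees are an
order of magnitude larger than in the desk-scale fixtures, a laxer
threshold also yields an informative null, which is presumably why the
original engine could leave this constant tunable. The threshold is
exposed in `PipeConfig` and everything downstream recalibrates through
LOOCV.

**Decision threshold.** Following the study design, the decision threshold
is calibrated by leave-one-out cross-validation: every known edge is
scored with that edge (and only that edge) removed from *G*; negatives are
unordered non-edge pairs sampled uniformly without replacement; the
operating point is the smallest threshold achieving the target specificity
(0.995 by default). For cross-species interactome prediction the
calibrated threshold is floored at 2, because a score of 1 is attainable
from the query pair's own database entry alone (each query window matches
its own database copy, so a true database edge always yields cells of 1
via one neighbour); scores of 1 are self-evidence, not co-occurrence
evidence. Ties at the threshold count as positive.

## Null-model proteome simulation

Each gene evolves under a one-ratio (single ω) Goldman–Yang codon model:
rate from codon *u* to *v* is zero unless they differ at one position, and
otherwise proportional to π_v, multiplied by κ for transitions and ω for
non-synonymous changes; changes into stop codons have rate zero. The
61×61 generator is scaled to one expected substitution per codon per unit
branch length at stationarity, is time-reversible (detailed balance holds
exactly), and is simulated by exact stochastic simulation (Gillespie) per
codon site — no matrix-exponential discretisation error.

The *S. cerevisiae* sequence is held byte-identical and the other four
tips are generated by re-rooting the phylogeny at the *S. cerevisiae* leaf
and evolving outward; this is valid because the substitution model is
reversible. Indels are layered on each branch as a Poisson process with
rate `indel_rate × branch length × sequence length (codons)`; events act
on whole codons to preserve reading frame, lengths follow a discrete power
law with exponent α truncated at a maximum length, insertions and
deletions are equally likely, and inserted codons are drawn from π.
Deterministic seeding: replicate *r* of a multi-replicate run uses a
seed derived from `(seed, r)` via `numpy.random.SeedSequence`, so outputs
are reproducible and replicates are mutually independent.

Indel parameters are estimated from data by the package's own tooling:
`count_indel_events` reduces each maximal run of alignment columns with an
identical across-taxa gap pattern to one candidate event, reconstructs the
binary gap character by minimum change (exhaustive small parsimony, exact
for trees of this size), and assigns events to branches — deletions
preferred over insertions, then branches closer to the root, as a
deterministic tie-break. `fit_power_law` is the discrete maximum-likelihood
estimator with `x_min` fixed at 1 (fixing `x_min` keeps small indel samples
stable; the event length distribution starts at one codon by construction).

**Validation estimator.** `counting_dnds` is a modified Nei–Gojobori
counting estimator (κ-weighted site counting, pathway-averaged differences,
Jukes–Cantor correction). It shares no code path with the simulator and
serves as the independent oracle for ω recovery: 1,000 simulated 60-codon
genes at ω = 0.2, κ = 2 are recovered within ±0.05.

## Parsimony quantification of network change

For every interaction present in at least one species, `count_changes`
computes the minimum number of binary state changes on the rooted ladder
topology `(Sbay,(Skud,(Smik,(Spar,Scer))))` by dynamic programming
(Sankoff with unit costs). Two modes:

* `fitch` — standard small parsimony, free root; the maximum over the 31
  present-somewhere patterns is 2;
* `ancestral-present` (default) — the root state is fixed to "interaction
  present", reflecting that candidate interactions derive from an
  *S. cerevisiae* database; the maximum becomes 3.

Under the default, no pattern ever requires more than three changes. Note that the two modes can differ by more than one change
(pattern present-only-in-*Scer*: 1 vs 3); both are exhaustively verified
against enumeration over all internal-state assignments in the tests.

A protein's γ is the sum of a_ij over every profile containing it; its
degree is the partner count in the reference (*S. cerevisiae*)
interactome. Conservation calls use the strict rule: a protein is
*conserved* when its real γ is below γ in **all** replicate null datasets,
*rapid* when above all of them; equality with any replicate yields
*neither*, making the per-tail type-I rate exactly ≤ 1/(R+1). With 100
replicates that is a P < 0.01 criterion; the tests verify the
1/101 calibration by simulation.

## Enrichment

Protein-set enrichment uses the inclusive hypergeometric upper tail
P(X ≥ k) with the four counts (k annotated in the set, set size n, K
annotated in the universe, universe size N); only terms with k ≥ 1 are
reported and no multiple-testing correction is applied by default
(Benjamini–Hochberg is available behind a function call). The pair-based
variant treats unordered pairs as sampling units: an interaction carries a
term when both endpoints are annotated with it, K = C(K_t, 2) for a term
annotating K_t universe proteins, N = C(N_p, 2). Annotations are flat
protein→term maps — no DAG propagation — matching the direct-count
four-number scheme. Filter rules: p < 0.05, process-namespace terms,
k ≥ 3; for protein clusters the count rule relaxes to k ≥ 2 and function
terms are admitted.

## Cluster comparison

Cluster similarity is |a ∩ b| / max(|a|, |b|), always in [0, 1]; a real
cluster is unique when no cluster from any simulated replicate matches it
at ≥ 0.7 (inclusive). Community detection itself is out of scope —
clusters are consumed from membership files; the synthetic module plants
clusters with known uniqueness for testing.

## Synthetic data: what it emulates, and what it does not

`generate_database` produces a proteome with geometric length spread
around the *S. cerevisiae* mean of 467 residues (minimum 60) and an
interaction graph with heavy-tailed degree (Barabási–Albert preferential
attachment, m = 1, defaults: 80 proteins, ~80 edges). Interaction motifs
follow a domain–motif model: a hub protein carries a recognition-side
20-mer once, and each of up to 8 degree-one partners carries the
complementary 20-mer, one motif family per hub, covering at most 35% of
edges. Held-out co-occurrence signal for a family edge then equals the
number of sibling partners, and restricting partners to leaves keeps
families non-overlapping so no transitive co-occurrence arises between
unrelated pairs — the desk-scale analogue of sparse genome-scale networks.

`generate_five_species_dataset` back-translates the database proteome
(uniform synonymous codons), then evolves it over the clade tree with
per-gene defaults ω = 0.2, κ = 2, uniform sense-codon frequencies, indel
rate 0.02 events/codon/unit branch length, power-law length exponent 2.0
truncated at 30 codons, and branch lengths summing to ≈ 1.3 substitutions
per codon (root-to-*Sbay* path ≈ 0.66) — the divergence scale of the
clade under a one-ratio codon model. Selection is proxied by masking: the
motif codons of *conserved* families are excluded from substitution and
indel placement. Masking acts on whole families — the hub's interface and
all partner motifs — because γ-based conservation calls only have
statistical power for proteins whose entire neighbourhood is protected;
the conserved families are the largest ones (core-module conservation),
chosen deterministically by size at fraction 0.5.

The generator is an idealisation in known ways: real interaction
interfaces are not exact 20-mer copies shared across partners; real
selection attenuates rather than forbids interface substitutions; real
networks have correlated degree and length distributions and far higher
degree (genome-scale predicted yeast interactomes average ≈ 43 partners
per protein, versus ≈ 2 here, which is why genome-scale analyses can flag
low-degree proteins while the desk-scale power analysis concentrates on
hubs of ≥ 4 protected edges). Passing tests therefore demonstrate that the
machinery is correct and that the study design detects planted selection
under faithful-but-small conditions — not that the effect sizes match the
genome-scale study.

## Problem sizes used by the acceptance script

The script reruns the full synthetic study at the package defaults:
80-protein database, 20 null replicates (nominal per-tail null rate 1/21),
LOOCV with 150 sampled negatives, ω recovery over 1,000 60-codon genes,
power-law recovery over 10,000 draws, indel calibration over 1,000
replicate genes, and null-calibration of the classification rule over 500
proteins with 100 replicates. All randomness derives from the `--seed`
argument.

## Known limitations

* Exhaustive parsimony assignment for indel-event branch placement is
  exponential in internal-node count and guarded at 16 internal nodes —
  ample for the five-taxon design, not for large trees.
* The M0 process has no among-site rate variation by construction, and
  codon frequencies default to uniform unless supplied.
* LOOCV negatives are sampled uniformly from non-edges; with very dense
  graphs the rejection sampler degrades before erroring.
* The pair-enrichment universe is all C(N, 2) pairs; if the biological
  universe of "possible" interactions is smaller, p-values are
  conservative.
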