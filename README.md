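# evonet

Comparative evolution of predicted protein–protein interaction (PPI)
networks in the *Saccharomyces sensu stricto* yeasts.

Experimentally determined interactomes exist for very few species, which
makes the *evolution* of interaction networks hard to study: without a
null expectation for how much network change random mutation alone should
produce, conserved or rapidly rewiring parts of a network cannot be
identified. `evonet` implements a complete, testable version of a
simulation-based answer for five closely related yeasts (*S. cerevisiae*,
*S. paradoxus*, *S. mikatae*, *S. kudriavzevii*, *S. bayanus*):

* **Sequence-based PPI prediction.** A query pair (A, B) is scored by
  sliding 20-residue windows over both proteins and counting, in a result
  matrix of size (|A|−w+1) × (|B|−w+1), how often a window pair (a_i, b_j)
  co-occurs in protein pairs already known to interact (PAM120 window
  similarity against a database graph *G*). Leave-one-out cross-validation
  calibrates the decision threshold to a target specificity.
* **A null model of network evolution.** Each gene is re-evolved from the
  *S. cerevisiae* sequence along the clade phylogeny under a one-ratio
  Goldman–Yang codon model (per-gene ω, κ, codon frequencies π) with
  power-law–length, whole-codon indels — mutations land blindly with
  respect to interaction sites. Predicting interactomes on the simulated
  proteomes yields the distribution of apparent network change expected
  without selection on interactions.
* **Parsimony quantification.** For each interaction present in ≥ 1
  species, a_ij is the minimum number of gains/losses on the tree
  (root fixed to "present" by default, max 3 changes per pattern; free-root
  Fitch available, max 2); a protein's γ = Σ_j a_ij totals its PPI changes.
  Proteins whose real γ falls below (above) γ in *all* replicate null
  datasets are called conserved (rapidly evolving) — per-tail error
  1/(R+1).
* **Downstream analyses.** Species-specific interaction sets (real edges
  absent from every simulated replicate), the phylogeny-wide conserved
  core, hypergeometric GO enrichment for protein sets and for interaction
  *pairs*, Kendall τ-b and one-sided Fisher overlap tests, and cluster
  uniqueness against simulated interactomes (similarity
  |a∩b|/max(|a|,|b|), match at ≥ 0.7).

A synthetic-data module generates databases with planted interaction
motifs, five-species datasets with selection proxied by mutation-masked
motif sites, GO annotations with planted enrichments and cluster sets with
known uniqueness, so the entire pipeline runs and is validated without any
external download. See `docs/methods.md` for models, defaults and design
rationale.

## Worked example

```python
from evonet.data_io import Phylogeny
from evonet.pipeline import run_selection_power_study
from evonet.synthetic_data import DEFAULT_TREE_NEWICK

tree = Phylogeny.from_newick(DEFAULT_TREE_NEWICK)
study = run_selection_power_study(tree, n_replicates=20, seed=29)
print(f"decision threshold: {study.decision_threshold:g}")
print(f"LOOCV sensitivity at calibrated specificity: {study.loocv_sensitivity:.1%}")
print(f"reference interactome: {len(study.reference_interactome)} edges")
print(f"Sbay interactome, real vs simulated mean: "
      f"{study.real_sizes['Sbay']} vs {study.null_mean_sizes['Sbay']:.1f}")
print(f"protected hubs flagged conserved: "
      f"{study.n_masked_hubs_flagged}/{len(study.masked_hubs)} "
      f"(one-sided binomial P = {study.binomial_p:.2g})")
```

Output:

```
decision threshold: 2
LOOCV sensitivity at calibrated specificity: 31.6%
reference interactome: 29 edges
Sbay interactome, real vs simulated mean: 25 vs 15.8
protected hubs flagged conserved: 3/3 (one-sided binomial P = 0.00011)
```

Reading this: the engine, calibrated to ≥ 99.5% specificity on held-out
edges, recovers about a third of database edges (the motif-mediated ones,
essentially all of them). In the most diverged species the *real*
(selection-containing) dataset retains 25 of 29 reference interactions
while the neutral simulations retain 15.8 on average — purifying selection
on interfaces shows up as an excess of retained interactions. All three
hub proteins whose entire motif family was protected from mutation are
flagged conserved: their real γ is below every one of the 20 replicate
null γ values, far above the 1/21 ≈ 4.8% per-protein rate expected by
chance.

A command-line interface mirrors the library (`evonet io validate`,
`evonet predict`, `evonet loocv`, `evonet simulate`, `evonet gamma`,
`evonet classify`, `evonet overlap`, `evonet enrich`, `evonet
enrich-pairs`, `evonet clusters-unique`, `evonet synth`); run
`evonet --help` for details.

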