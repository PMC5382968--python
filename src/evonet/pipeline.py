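"""End-to-end orchestration: database -> interactomes -> gamma -> classification.

This mirrors the study design: a fixed interaction database and reference
proteome; per-species query proteomes (real or simulated); PIPE predictions
for a candidate pair list; presence/absence profiles across species;
parsimony change counts and per-protein gamma; and classification of the
real gamma values against the replicate null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .data_io import Phylogeny, Proteome, canonical_edge
from .network_evolution import (
    GammaRecord,
    build_presence_profiles,
    classify_proteins,
    compute_gamma,
)
from .pipe_engine import PipeConfig, PipeEngine, predict_interactome
from .proteome_simulator import SimulatedReplicate


def predict_species_interactomes(
    engine: PipeEngine,
    proteomes: Mapping[str, Proteome],
    candidate_pairs: Iterable[tuple[str, str]],
) -> dict[str, set[tuple[str, str]]]:
    """Predicted edge set per species for a fixed database engine."""
    pairs = [canonical_edge(*p) for p in candidate_pairs]
    return {
        species: predict_interactome(engine, proteome.sequences, pairs)
        for species, proteome in proteomes.items()
    }


def gamma_from_interactomes(
    interactomes: Mapping[str, set[tuple[str, str]]],
    tree: Phylogeny,
    mode: str = "ancestral-present",
    reference_species: str = "Scer",
) -> list[GammaRecord]:
    """Profiles -> parsimony change counts -> per-protein gamma."""
    profiles = build_presence_profiles(interactomes)
    if not profiles:
        return []
    return compute_gamma(profiles, tree, mode, reference_species)


@dataclass
class NullModelAnalysis:
    """Real gamma records, per-protein null gamma vectors, classifications."""

    real: list[GammaRecord]
    null: dict[str, list[int]]
    classifications: dict[str, str]
    real_interactomes: dict[str, set[tuple[str, str]]]
    null_interactomes: list[dict[str, set[tuple[str, str]]]]


def run_null_model_analysis(
    database_graph: nx.Graph,
    database_proteome: Proteome,
    real_proteomes: Mapping[str, Proteome],
    null_replicates: Sequence[SimulatedReplicate],
    tree: Phylogeny,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
    config: PipeConfig = PipeConfig(),
    mode: str = "ancestral-present",
    reference_species: str = "Scer",
) -> NullModelAnalysis:
    """Classify proteins by comparing real gamma against replicate nulls.

    Candidate pairs default to the database edges.  Proteins without a
    profile in some replicate get gamma 0 for that replicate (no inferred
    changes), so every real protein has a complete null vector.
    """
    pairs = (
        [canonical_edge(u, v) for u, v in database_graph.edges()]
        if candidate_pairs is None
        else [canonical_edge(*p) for p in candidate_pairs]
    )
    engine = PipeEngine(database_proteome.sequences, database_graph, config)
    real_inter = predict_species_interactomes(engine, real_proteomes, pairs)
    real_gamma = gamma_from_interactomes(real_inter, tree, mode, reference_species)

    null_inter: list[dict[str, set[tuple[str, str]]]] = []
    null_gamma_per_rep: list[dict[str, int]] = []
    for rep in null_replicates:
        inter = predict_species_interactomes(engine, rep.proteomes, pairs)
        null_inter.append(inter)
        recs = gamma_from_interactomes(inter, tree, mode, reference_species)
        null_gamma_per_rep.append({r.protein: r.gamma for r in recs})

    proteins = sorted({r.protein for r in real_gamma})
    null = {
        p: [rep.get(p, 0) for rep in null_gamma_per_rep] for p in proteins
    }
    classes = classify_proteins(real_gamma, null)
    return NullModelAnalysis(
        real=real_gamma,
        null=null,
        classifications={c.protein: c.label for c in classes},
        real_interactomes=real_inter,
        null_interactomes=null_inter,
    )


@dataclass
class SelectionPowerStudy:
    """Outcome of the synthetic end-to-end conservation power study."""

    decision_threshold: float
    loocv_sensitivity: float  # at the calibrated operating point
    loocv_specificity: float
    reference_interactome: set[tuple[str, str]]
    analysis: NullModelAnalysis
    masked_hubs: list[str]  # fully protected proteins with >= min_family edges
    n_masked_hubs_flagged: int
    binomial_p: float  # one-sided, against the 1/(R+1) null rate
    n_unprotected_flagged: int
    n_unprotected: int
    real_sizes: dict[str, int] = field(default_factory=dict)
    null_mean_sizes: dict[str, float] = field(default_factory=dict)


def run_selection_power_study(
    tree: Phylogeny,
    config=None,
    n_replicates: int = 20,
    seed: int = 0,
    n_negatives: int = 150,
    target_specificity: float = 0.995,
    min_family: int = 4,
    pipe_config: PipeConfig | None = None,
) -> SelectionPowerStudy:
    """Full synthetic study: does selection-proxy masking surface as
    conserved-protein calls against the simulated null?

    Builds a motif-planted database, evolves a masked (selection) dataset
    and ``n_replicates`` unmasked null datasets, calibrates the decision
    threshold by LOOCV at ``target_specificity`` (floored at 2: a score of
    1 is attainable from the query pair's own database entry alone),
    predicts all interactomes, computes gamma, classifies, and tests the
    flag rate of fully protected hub proteins against the nominal
    1/(n_replicates+1) rate.
    """
    from .pipe_engine import run_loocv
    from .synthetic_data import SynthConfig, generate_five_species_dataset

    if config is None:
        config = SynthConfig(seed=seed)
    dataset = generate_five_species_dataset(config, tree)
    base = pipe_config or PipeConfig()

    loocv = run_loocv(
        dataset.database.graph, dataset.database.proteome.sequences,
        n_negatives=n_negatives, config=base, seed=seed + 1,
    )
    calibrated = loocv.threshold_for_specificity(target_specificity)
    threshold = max(calibrated, 2.0)
    pc = PipeConfig(
        window=base.window,
        similarity_threshold=base.similarity_threshold,
        aggregator=base.aggregator,
        decision_threshold=threshold,
    )

    engine = PipeEngine(dataset.database.proteome.sequences, dataset.database.graph, pc)
    db_edges = [canonical_edge(u, v) for u, v in dataset.database.graph.edges()]
    reference = predict_interactome(
        engine, dataset.database.proteome.sequences, db_edges
    )
    nulls = dataset.null_replicates(n_replicates, seed=seed + 2)
    analysis = run_null_model_analysis(
        dataset.database.graph, dataset.database.proteome,
        dataset.real_replicate.proteomes, nulls, tree,
        candidate_pairs=reference, config=pc,
    )

    motif_edges = set(dataset.database.motifs)
    protected = (
        set().union(*dataset.conserved_edges) if dataset.conserved_edges else set()
    )
    fully = {
        p
        for p in protected
        if all(e in dataset.conserved_edges for e in motif_edges if p in e)
    }
    masked_hubs = sorted(
        p for p in fully if sum(p in e for e in motif_edges) >= min_family
    )
    flags = analysis.classifications
    k = sum(flags.get(p) == "conserved" for p in masked_hubs)
    if masked_hubs:
        binom_p = float(
            stats.binomtest(
                k, len(masked_hubs), 1.0 / (n_replicates + 1), alternative="greater"
            ).pvalue
        )
    else:
        binom_p = float("nan")
    unprotected = [p for p in flags if p not in protected]
    study = SelectionPowerStudy(
        decision_threshold=threshold,
        loocv_sensitivity=loocv.sensitivity_at(threshold),
        loocv_specificity=loocv.specificity_at(threshold),
        reference_interactome=reference,
        analysis=analysis,
        masked_hubs=masked_hubs,
        n_masked_hubs_flagged=k,
        binomial_p=binom_p,
        n_unprotected_flagged=sum(flags[p] == "conserved" for p in unprotected),
        n_unprotected=len(unprotected),
    )
    for sp in tree.leaf_labels():
        study.real_sizes[sp] = len(analysis.real_interactomes[sp])
        study.null_mean_sizes[sp] = float(
            np.mean([len(x[sp]) for x in analysis.null_interactomes])
        )
    return study
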