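"""Synthetic fixtures with the statistical structure the analysis assumes.

The generators emulate the inputs the pipeline consumes in production:

* a database proteome with geometric length spread around the yeast mean of
  467 residues and an interaction graph with heavy-tailed degree
  (preferential attachment);
* interaction-mediating 20-residue motif pairs embedded at recorded
  positions in interacting proteins, with each motif pair shared by several
  edges so that window co-occurrence carries signal;
* five-species datasets evolved from the database proteome under the M0 +
  indel null process, where a configurable fraction of motif sites is
  masked from mutation as a proxy for purifying selection on interaction
  interfaces;
* flat GO annotations with planted enrichments, and cluster files with
  planted dense clusters.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .cluster_compare import Cluster
from .data_io import GOAnnotationSet, Phylogeny, Proteome, canonical_edge
from .pipe_engine import ALPHABET
from .proteome_simulator import (
    CODON_AA,
    GeneModel,
    IndelModel,
    M0Params,
    SENSE_CODONS,
    SimulatedReplicate,
    simulate_replicates,
)

AA20 = ALPHABET[:20]  # the 20 canonical residues, no wildcard

#: Rooted ladder phylogeny of the sensu stricto clade with branch lengths in
#: expected substitutions per codon (total tree length ~1.3, Scer-Sbay path
#: ~0.66 -- the divergence scale of the clade under a one-ratio codon model).
DEFAULT_TREE_NEWICK = (
    "(Sbay:0.35,(Skud:0.28,(Smik:0.22,(Spar:0.12,Scer:0.10):0.06):0.08):0.07);"
)

#: Synonymous codon choices per amino acid (uniform back-translation).
_AA_CODONS: dict[str, list[str]] = {}
for _c, _aa in zip(SENSE_CODONS, CODON_AA):
    _AA_CODONS.setdefault(_aa, []).append(_c)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic fixtures.

    Defaults reflect the system being emulated: 467-residue mean protein
    length, 20-residue interaction motifs, a heavy-tailed interaction graph,
    and a moderate level of motif re-use so co-occurrence has signal.
    """

    n_proteins: int = 80
    mean_length: int = 467
    min_length: int = 60
    n_edges: int = 80
    motif_length: int = 20
    motif_fraction: float = 0.35  # upper bound on the motif-mediated edge share
    edges_per_motif: int = 8
    conservation_fraction: float = 0.5  # masked (selection-proxy) motif families
    n_go_terms: int = 50
    background_annotation_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.mean_length, self.n_edges, self.motif_length) < 1:
            raise ValueError("counts must be positive")
        for frac in (self.motif_fraction, self.conservation_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.motif_length > self.min_length:
            raise ValueError("motif length exceeds the minimum protein length")


@dataclass
class MotifPlacement:
    """Where a motif pair was embedded for one edge."""

    edge: tuple[str, str]
    motif_pair_id: int
    hub: str  # the protein carrying the recognition-side motif
    positions: dict[str, int]  # protein -> start offset (residues)
    motifs: dict[str, str]  # protein -> embedded motif sequence


@dataclass
class SyntheticDatabase:
    proteome: Proteome
    graph: nx.Graph
    motifs: dict[tuple[str, str], MotifPlacement]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _sample_lengths(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    spread = max(config.mean_length - config.min_length, 1)
    extra = rng.geometric(1.0 / spread, size=config.n_proteins) - 1
    return config.min_length + extra


def generate_database(config: SynthConfig) -> SyntheticDatabase:
    """Proteome + interaction graph with planted motif-mediated edges."""
    rng = np.random.default_rng(config.seed)
    ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    lengths = _sample_lengths(rng, config)
    sequences = {pid: _random_protein(rng, int(l)) for pid, l in zip(ids, lengths)}

    # heavy-tailed degree via preferential attachment
    m = max(1, round(config.n_edges / config.n_proteins))
    ba = nx.barabasi_albert_graph(config.n_proteins, m, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(ba, {i: ids[i] for i in range(config.n_proteins)})

    n_motif_target = round(config.motif_fraction * graph.number_of_edges())

    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}

    def place(pid: str, motif: str) -> int | None:
        L = len(sequences[pid])
        w = len(motif)
        for _ in range(50):
            start = int(rng.integers(0, L - w + 1))
            if all(start + w <= s or start >= e for s, e in occupied[pid]):
                occupied[pid].append((start, start + w))
                sequences[pid] = (
                    sequences[pid][:start] + motif + sequences[pid][start + w :]
                )
                return start
        return None

    # Domain-motif model: a hub protein carries the recognition-side motif
    # once; each of up to edges_per_motif degree-1 partners (substrates)
    # carries the complementary motif.  Co-occurrence signal for a held-out
    # edge then comes from the hub's remaining partners; restricting
    # partners to leaves keeps motif families non-overlapping, so no
    # transitive co-occurrence chains arise between unrelated pairs.
    motifs: dict[tuple[str, str], MotifPlacement] = {}
    assigned: set[tuple[str, str]] = set()
    pair_id = -1
    hubs = sorted(graph.nodes(), key=lambda n: (-graph.degree(n), n))
    for hub in hubs:
        if len(assigned) >= n_motif_target:
            break
        incident = sorted(
            canonical_edge(hub, nb)
            for nb in graph.neighbors(hub)
            if graph.degree(nb) == 1
            and canonical_edge(hub, nb) not in assigned
        )
        # one family per hub: a hub's interface recognizes one motif class
        group = incident[: config.edges_per_motif]
        if len(group) < 2:
            continue  # a single-edge motif family carries no held-out signal
        pair_id += 1
        m1 = _random_protein(rng, config.motif_length)
        m2 = _random_protein(rng, config.motif_length)
        pos_hub = place(hub, m1)
        if pos_hub is None:
            continue
        for edge in group:
            partner = edge[0] if edge[1] == hub else edge[1]
            pos_partner = place(partner, m2)
            if pos_partner is None:
                continue
            assigned.add(edge)
            motifs[edge] = MotifPlacement(
                edge=edge,
                motif_pair_id=pair_id,
                hub=hub,
                positions={hub: pos_hub, partner: pos_partner},
                motifs={hub: m1, partner: m2},
            )

    proteome = Proteome(species_label="Scer", sequences=sequences)
    return SyntheticDatabase(proteome=proteome, graph=graph, motifs=motifs)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """CDS for a protein with uniform synonymous codon choice."""
    return "".join(rng.choice(_AA_CODONS[aa]) for aa in protein)


@dataclass
class FiveSpeciesDataset:
    """A synthetic comparative dataset plus the ground truth behind it."""

    database: SyntheticDatabase
    tree: Phylogeny
    root_cds: dict[str, str]
    gene_models_real: dict[str, GeneModel]  # motif sites of conserved edges masked
    gene_models_null: dict[str, GeneModel]  # no masking
    real_replicate: SimulatedReplicate
    conserved_edges: set[tuple[str, str]]

    def null_replicates(self, n_replicates: int, seed: int) -> list[SimulatedReplicate]:
        return simulate_replicates(
            self.gene_models_null, self.tree, n_replicates, seed, root_label="Scer"
        )


def generate_five_species_dataset(
    config: SynthConfig,
    tree: Phylogeny,
    m0_defaults: M0Params | None = None,
    indel_defaults: IndelModel | None = None,
) -> FiveSpeciesDataset:
    """Evolve the database proteome over the tree with selection-proxy masking.

    A ``conservation_fraction`` of the motif families (a hub with its
    partner set) is marked conserved: the codons encoding every motif of
    the family are excluded from substitution and indel placement in the
    "real-like" dataset, realizing purifying selection on interaction
    interfaces.  Masking whole families mirrors the conservation of a
    complex or signalling module rather than of isolated edges.  The
    matching null models (no masking) are returned for generating replicate
    null datasets.
    """
    params = m0_defaults or M0Params(kappa=2.0, omega=0.2)
    indels = indel_defaults or IndelModel(rate=0.02, alpha=2.0, max_length=30)
    db = generate_database(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # the largest families are the conserved ones: purifying selection acts
    # on core modules (hubs with many maintained partners)
    family_sizes: dict[int, int] = {}
    for pl in db.motifs.values():
        family_sizes[pl.motif_pair_id] = family_sizes.get(pl.motif_pair_id, 0) + 1
    ranked = sorted(family_sizes, key=lambda f: (-family_sizes[f], f))
    n_conserved = math.ceil(config.conservation_fraction * len(ranked))
    conserved_families = set(ranked[:n_conserved])
    conserved_edges = {
        e for e, pl in db.motifs.items() if pl.motif_pair_id in conserved_families
    }

    protected: dict[str, np.ndarray] = {
        pid: np.zeros(len(seq), dtype=bool)
        for pid, seq in db.proteome.sequences.items()
    }
    for edge in conserved_edges:
        placement = db.motifs[edge]
        for pid, start in placement.positions.items():
            protected[pid][start : start + config.motif_length] = True

    root_cds = {
        pid: back_translate(seq, rng) for pid, seq in db.proteome.sequences.items()
    }
    gene_models_real = {
        pid: GeneModel(
            root_cds=root_cds[pid],
            params=params,
            indels=indels,
            protected_codons=protected[pid],
        )
        for pid in root_cds
    }
    gene_models_null = {
        pid: GeneModel(root_cds=root_cds[pid], params=params, indels=indels)
        for pid in root_cds
    }
    real_replicate = simulate_replicates(
        gene_models_real, tree, 1, int(rng.integers(2**31)), root_label="Scer"
    )[0]
    return FiveSpeciesDataset(
        database=db,
        tree=tree,
        root_cds=root_cds,
        gene_models_real=gene_models_real,
        gene_models_null=gene_models_null,
        real_replicate=real_replicate,
        conserved_edges=conserved_edges,
    )


def generate_go_annotations(
    universe: Iterable[str],
    n_terms: int,
    planted: Mapping[str, tuple[Iterable[str], float]] | None = None,
    seed: int = 0,
    background_p: float = 0.05,
) -> GOAnnotationSet:
    """Flat GO annotations with optional planted enrichments.

    Every term annotates each universe protein with probability
    ``background_p``; a planted term annotates its target-set members with
    probability min(1, background_p * odds).  Namespaces cycle
    process/function/component.  Planted odds below 1 are rejected.
    """
    universe = sorted(universe)
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    namespaces = ("process", "function", "component")
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    for term, (targets, odds) in planted.items():
        if odds < 1:
            raise ValueError(f"planted odds for {term} must be >= 1")
        if not set(targets) <= set(universe):
            raise ValueError(f"target set for {term} outside the universe")
        if term not in term_ids:
            term_ids.append(term)
    protein_terms: dict[str, set[str]] = {}
    term_namespace: dict[str, str] = {}
    term_name: dict[str, str] = {}
    for i, term in enumerate(term_ids):
        ns = namespaces[i % 3]
        if term in planted:
            ns = "process"  # planted signals live where the standard filter looks
        term_namespace[term] = ns
        term_name[term] = f"synthetic term {i}"
        target_set, odds = planted.get(term, (set(), 1.0))
        target_set = set(target_set)
        p_target = min(1.0, background_p * odds)
        for protein in universe:
            p = p_target if protein in target_set else background_p
            if rng.random() < p:
                protein_terms.setdefault(protein, set()).add(term)
    return GOAnnotationSet(
        protein_terms=protein_terms,
        term_namespace=term_namespace,
        term_name=term_name,
        universe=set(universe),
    )


def generate_cluster_sets(
    proteins: Sequence[str],
    n_clusters: int,
    mean_size: int,
    n_sim_sets: int,
    seed: int = 0,
    unique_fraction: float = 0.3,
) -> tuple[list[Cluster], list[list[Cluster]]]:
    """Real clusters plus simulated cluster sets with known uniqueness.

    A ``unique_fraction`` of the real clusters is never copied into the
    simulated sets; the remainder appear in (perturbed) form in every
    simulated set, so downstream uniqueness calls have exact ground truth.
    """
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    real: list[Cluster] = []
    for c in range(n_clusters):
        size = max(2, int(rng.poisson(mean_size)))
        members = rng.choice(proteins, size=min(size, len(proteins)), replace=False)
        real.append(Cluster(cluster_id=f"real{c:03d}", members=frozenset(members)))
    n_unique = round(unique_fraction * n_clusters)
    unique_ids = {c.cluster_id for c in real[:n_unique]}
    sim_sets: list[list[Cluster]] = []
    for s in range(n_sim_sets):
        sims: list[Cluster] = []
        for c in real:
            if c.cluster_id in unique_ids:
                continue
            members = set(c.members)
            # light perturbation that stays above the 0.7 match threshold
            if len(members) >= 4 and rng.random() < 0.5:
                members.discard(sorted(members)[0])
            sims.append(
                Cluster(
                    cluster_id=f"sim{s:03d}_{c.cluster_id}",
                    members=frozenset(members),
                    source=f"replicate{s}",
                )
            )
        sim_sets.append(sims)
    return real, sim_sets
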