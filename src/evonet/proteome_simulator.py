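"""Null-model proteome evolution: M0 codon substitution plus indels.

The null model evolves each gene's coding sequence outward from the
*S. cerevisiae* sequence (kept byte-identical) along a five-species tree,
under a one-ratio Goldman-Yang codon model (single omega per gene,
transition/transversion ratio kappa, stationary codon frequencies pi) with
whole-codon insertions and deletions whose lengths follow a discrete power
law.  Rooting the process at a tip is valid because the substitution model
is time-reversible.

Substitutions are placed with no reference to interaction sites; optional
codon masks (used by the synthetic-data generator as a selection proxy)
exclude sites from both substitution and indel placement.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .data_io import CodonAlignment, Phylogeny, Proteome, TreeNode

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

#: The 61 sense codons in lexicographic order; indices into rate matrices.
SENSE_CODONS = tuple(sorted(_GENETIC_CODE))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_GENETIC_CODE[c] for c in SENSE_CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_neighbors() -> list[tuple[int, int, bool, bool]]:
    """(u, v, is_transition, is_synonymous) for sense codons one change apart."""
    out = []
    for u, cu in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in BASES:
                if b == cu[pos]:
                    continue
                cv = cu[:pos] + b + cu[pos + 1 :]
                v = CODON_INDEX.get(cv)
                if v is None:  # stop codon: rate 0, outside the state space
                    continue
                out.append(
                    (
                        u,
                        v,
                        (cu[pos], b) in _TRANSITIONS,
                        _GENETIC_CODE[cu] == _GENETIC_CODE[cv],
                    )
                )
    return out


_NEIGHBORS = _codon_neighbors()


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class M0Params:
    """One-ratio codon-model parameters: kappa, omega, codon frequencies."""

    kappa: float
    omega: float
    pi: np.ndarray = field(default_factory=lambda: np.full(61, 1.0 / 61.0))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.pi.shape != (61,):
            raise ValueError("pi must have 61 entries (sense codons)")
        if (self.pi < 0).any():
            raise ValueError("pi must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1 within 1e-9")


@dataclass
class IndelModel:
    """Whole-codon indel process along branches.

    rate: expected indel events per codon site per unit branch length.
    alpha: discrete power-law exponent for event lengths (codons).
    max_length: truncation of the length distribution.
    insertion_fraction: probability an event is an insertion (rest deletions).
    """

    rate: float
    alpha: float = 2.0
    max_length: int = 30
    insertion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("indel rate must be >= 0")
        if self.alpha <= 1:
            raise ValueError("power-law exponent must be > 1")
        if self.max_length < 1:
            raise ValueError("max event length must be >= 1")
        if not 0 <= self.insertion_fraction <= 1:
            raise ValueError("insertion fraction must be in [0, 1]")

    def length_pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_length + 1, dtype=float)
        p = k ** (-self.alpha)
        return p / p.sum()


@dataclass
class IndelEvent:
    branch: str  # label of the node below the branch
    kind: str  # "insertion" | "deletion"
    length: int  # codons
    location: int  # codon offset in the sequence at event time

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------


def build_m0_generator(params: M0Params) -> np.ndarray:
    """61x61 Goldman-Yang rate matrix, scaled to one expected substitution
    per codon per unit branch length at stationarity.

    q_uv is zero for codon pairs differing at more than one position and for
    changes into stop codons; otherwise proportional to pi_v, multiplied by
    kappa for transitions and omega for nonsynonymous changes.
    """
    q = np.zeros((61, 61))
    for u, v, is_ts, is_syn in _NEIGHBORS:
        rate = params.pi[v]
        if is_ts:
            rate *= params.kappa
        if not is_syn:
            rate *= params.omega
        q[u, v] = rate
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices(61)] = -q.sum(axis=1)
    mu = -(params.pi * np.diag(q)).sum()
    if mu <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / mu


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------


def fit_power_law(lengths: Sequence[int]) -> float:
    """Discrete power-law MLE for the exponent alpha, with x_min fixed at 1.

    Maximizes sum log[x^-alpha / zeta(alpha)]; requires at least 10
    observations that are not all identical.
    """
    x = np.asarray(list(lengths), dtype=float)
    if x.size == 0 or (x.size and (x == x[0]).all()):
        raise ValueError("degenerate length distribution")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if (x < 1).any():
        raise ValueError("lengths must be positive integers")
    slog = np.log(x).sum()
    n = x.size

    def nll(alpha: float) -> float:
        return n * math.log(zeta(alpha)) + alpha * slog

    res = minimize_scalar(nll, bounds=(1.000001, 25.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# indel event inference by parsimony
# ---------------------------------------------------------------------------


def _min_change_assignment(
    tree: Phylogeny,
    leaf_states: Mapping[str, int],
    root_state: int | None = None,
) -> tuple[int, dict[str, int]]:
    """Exhaustive small parsimony over internal-node 0/1 assignments.

    Returns (min changes, chosen full assignment).  Ties are broken by
    preferring the root ungapped/present, then assignments whose state
    changes sit closest to the root.  Exponential in internal-node count;
    fine for the five-taxon trees this package targets.
    """
    internals = tree.internal_nodes()
    if len(internals) > 16:
        raise ValueError("tree too large for exhaustive parsimony")
    depth: dict[str, int] = {}

    def set_depth(n: TreeNode, d: int) -> None:
        depth[n.label] = d
        for c in n.children:
            set_depth(c, d + 1)

    set_depth(tree.root, 0)

    best: tuple | None = None
    for states in itertools.product((0, 1), repeat=len(internals)):
        assign = {n.label: s for n, s in zip(internals, states)}
        if root_state is not None and assign[tree.root.label] != root_state:
            continue
        assign.update({k: int(v) for k, v in leaf_states.items()})
        changes = 0
        change_depths = 0
        for node in tree.postorder():
            if node is tree.root:
                continue
            if assign[node.label] != assign[node.parent.label]:
                changes += 1
                change_depths += depth[node.label]
        key = (changes, assign[tree.root.label], change_depths)
        if best is None or key < best[0]:
            best = (key, assign)
    assert best is not None
    return best[0][0], best[1]


def count_indel_events(alignment: CodonAlignment, tree: Phylogeny) -> list[IndelEvent]:
    """Infer indel events from gap runs in a codon alignment by parsimony.

    Each maximal run of columns with an identical across-taxa gap pattern is
    one candidate event; the gap presence/absence is treated as a binary
    character reconstructed with minimum changes.  Event length is the run
    length converted to codons (rounded up).  A branch where the gap state
    flips contributes one event: gap gained means deletion, gap lost means
    insertion; ambiguous reconstructions prefer deletions, then branches
    closer to the root.
    """
    taxa = sorted(alignment.rows)
    if set(taxa) != set(tree.leaf_labels()):
        raise ValueError(
            f"alignment taxa {taxa} do not match tree leaves {sorted(tree.leaf_labels())}"
        )
    ncol = alignment.n_columns
    rows = {t: alignment.rows[t] for t in taxa}
    events: list[IndelEvent] = []
    col = 0
    while col < ncol:
        pattern = tuple(rows[t][col] == "-" for t in taxa)
        run_start = col
        while col < ncol and tuple(rows[t][col] == "-" for t in taxa) == pattern:
            col += 1
        if not any(pattern):
            continue
        run_len = col - run_start
        length_codons = math.ceil(run_len / 3)
        leaf_states = {t: int(g) for t, g in zip(taxa, pattern)}
        _, assign = _min_change_assignment(tree, leaf_states)
        for node in tree.postorder():
            if node is tree.root:
                continue
            parent_state = assign[node.parent.label]
            state = assign[node.label]
            if state != parent_state:
                events.append(
                    IndelEvent(
                        branch=node.label,
                        kind="deletion" if state == 1 else "insertion",
                        length=length_codons,
                        location=math.ceil(run_start / 3),
                    )
                )
    return events


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------


def encode_cds(cds: str) -> np.ndarray:
    """Encode a CDS string as sense-codon indices; stops are errors."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    idx = np.empty(len(codons), dtype=np.int64)
    for k, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} at codon position {k}")
        j = CODON_INDEX.get(c)
        if j is None:
            raise ValueError(f"invalid codon {c!r} at codon position {k}")
        idx[k] = j
    return idx


def decode_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def translate(cds: str) -> str:
    return "".join(CODON_AA[i] for i in encode_cds(cds))


class _M0Sampler:
    """Cached per-parameter machinery for exact (Gillespie) simulation."""

    def __init__(self, params: M0Params):
        q = build_m0_generator(params)
        self.rates = -np.diag(q).copy()
        probs = q.copy()
        np.fill_diagonal(probs, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = probs / self.rates[:, None]
        probs[self.rates == 0] = 0.0
        self.cum = np.cumsum(probs, axis=1)
        self.pi = params.pi

    def evolve(
        self,
        codons: np.ndarray,
        t: float,
        rng: np.random.Generator,
        protected: np.ndarray | None = None,
    ) -> np.ndarray:
        """Evolve codon states for duration t; exact stochastic simulation."""
        cur = codons.copy()
        if t <= 0 or cur.size == 0:
            return cur
        if protected is None:
            idx = np.arange(cur.size)
        else:
            idx = np.flatnonzero(~protected)
        time_left = np.full(idx.size, float(t))
        while idx.size:
            r = self.rates[cur[idx]]
            waits = np.where(r > 0, rng.exponential(1.0, size=idx.size) / np.where(r > 0, r, 1.0), np.inf)
            hit = waits < time_left
            idx = idx[hit]
            if not idx.size:
                break
            time_left = time_left[hit] - waits[hit]
            u = rng.random(idx.size)
            rows = self.cum[cur[idx]]
            cur[idx] = np.array(
                [np.searchsorted(rows[k], u[k], side="right") for k in range(idx.size)]
            )
        return cur


def _apply_indels(
    codons: np.ndarray,
    protected: np.ndarray,
    t: float,
    model: IndelModel,
    rng: np.random.Generator,
    branch_label: str,
    events_out: list[IndelEvent],
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-process indels along one branch, in whole codons.

    Deletions never remove protected codons and insertions never split a
    protected run (selection-proxy masking); a violating draw is re-drawn a
    few times and then skipped.
    """
    if model.rate <= 0 or t <= 0 or codons.size == 0:
        return codons, protected
    n_events = rng.poisson(model.rate * t * codons.size)
    if n_events == 0:
        return codons, protected
    pmf = model.length_pmf()
    for _ in range(n_events):
        kind = "insertion" if rng.random() < model.insertion_fraction else "deletion"
        length = int(rng.choice(np.arange(1, model.max_length + 1), p=pmf))
        placed = False
        for _attempt in range(20):
            if kind == "deletion":
                if codons.size <= length:
                    break
                start = int(rng.integers(0, codons.size - length + 1))
                if protected[start : start + length].any():
                    continue
                codons = np.delete(codons, slice(start, start + length))
                protected = np.delete(protected, slice(start, start + length))
                events_out.append(
                    IndelEvent(branch=branch_label, kind=kind, length=length, location=start)
                )
                placed = True
                break
            else:
                pos = int(rng.integers(0, codons.size + 1))
                if 0 < pos < codons.size and protected[pos - 1] and protected[pos]:
                    continue
                new = rng.choice(61, size=length, p=_normalized(model, rng))
                codons = np.insert(codons, pos, new)
                protected = np.insert(protected, pos, np.zeros(length, dtype=bool))
                events_out.append(
                    IndelEvent(branch=branch_label, kind=kind, length=length, location=pos)
                )
                placed = True
                break
        if not placed:
            logger.debug("skipped an indel event that could not be placed")
    return codons, protected


def _normalized(model: IndelModel, rng) -> np.ndarray:
    # insertions draw codons from the stationary distribution; the model
    # object does not carry pi, so uniform sense codons are used when the
    # caller did not attach one (attribute set by simulate_gene).
    pi = getattr(model, "_pi", None)
    if pi is None:
        return np.full(61, 1.0 / 61.0)
    return pi


@dataclass
class GeneSimulation:
    """Per-species simulated CDS and proteins for one gene."""

    gene_id: str
    cds: dict[str, str]
    proteins: dict[str, str]
    events: list[IndelEvent]


def _tip_rooted_traversal(
    tree: Phylogeny, root_label: str
) -> list[tuple[str, str, float]]:
    """Edges (parent_label, child_label, length) of the tree re-rooted at a tip."""
    leaf = tree.find_leaf(root_label)
    adj = tree.adjacency()
    edges: list[tuple[str, str, float]] = []
    seen = {leaf}
    stack = [leaf]
    while stack:
        node = stack.pop()
        for nbr, length in adj[node]:
            if nbr in seen:
                continue
            seen.add(nbr)
            edges.append((node.label, nbr.label, length))
            stack.append(nbr)
    return edges


def simulate_gene(
    root_cds: str,
    tree: Phylogeny,
    params: M0Params,
    indels: IndelModel,
    seed: int | np.random.Generator | np.random.SeedSequence,
    root_label: str = "Scer",
    protected_codons: np.ndarray | None = None,
    gene_id: str = "gene",
) -> GeneSimulation:
    """Simulate one gene over the tree, rooted at the ``root_label`` tip.

    The tip sequence stays byte-identical; every other species receives the
    codon states evolved along the connecting path, with indel events layered
    on as a Poisson process.  Deterministic for fixed (inputs, seed).
    """
    rng = np.random.default_rng(seed)
    root_idx = encode_cds(root_cds)
    sampler = _M0Sampler(params)
    indels._pi = params.pi  # insertions draw codons from the stationary pi
    if protected_codons is None:
        protected_root = np.zeros(root_idx.size, dtype=bool)
    else:
        protected_root = np.asarray(protected_codons, dtype=bool)
        if protected_root.shape != root_idx.shape:
            raise ValueError("protected mask length must equal codon count")

    state: dict[str, tuple[np.ndarray, np.ndarray]] = {
        root_label: (root_idx, protected_root)
    }
    events: list[IndelEvent] = []
    for parent, child, length in _tip_rooted_traversal(tree, root_label):
        codons, prot = state[parent]
        codons = sampler.evolve(codons, length, rng, protected=prot)
        codons, prot = _apply_indels(
            codons, prot.copy(), length, indels, rng, child, events
        )
        state[child] = (codons, prot)

    leaf_labels = set(tree.leaf_labels())
    cds = {
        label: decode_cds(state[label][0]) if label != root_label else root_cds
        for label in leaf_labels
    }
    proteins = {label: translate(s) for label, s in cds.items()}
    return GeneSimulation(gene_id=gene_id, cds=cds, proteins=proteins, events=events)


@dataclass
class GeneModel:
    """Everything needed to simulate one gene."""

    root_cds: str
    params: M0Params
    indels: IndelModel
    protected_codons: np.ndarray | None = None


@dataclass
class SimulatedReplicate:
    index: int
    proteomes: dict[str, Proteome]
    cds: dict[str, dict[str, str]]  # species -> gene -> CDS


def simulate_replicates(
    genes: Mapping[str, GeneModel],
    tree: Phylogeny,
    n_replicates: int,
    seed: int,
    root_label: str = "Scer",
) -> list[SimulatedReplicate]:
    """Generate replicate five-species proteomes, the tip species held fixed.

    Replicate r uses a seed deterministically derived from (seed, r), so the
    full output is reproducible and replicates are mutually independent.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for gid, model in genes.items():
        if model.params is None or model.indels is None:
            raise ValueError(f"gene {gid!r} is missing evolutionary parameters")
    species = tree.leaf_labels()
    replicates = []
    rep_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for r in range(n_replicates):
        gene_seeds = rep_seeds[r].spawn(len(genes))
        per_species: dict[str, dict[str, str]] = {s: {} for s in species}
        per_species_cds: dict[str, dict[str, str]] = {s: {} for s in species}
        for (gid, model), gseed in zip(sorted(genes.items()), gene_seeds):
            sim = simulate_gene(
                model.root_cds,
                tree,
                model.params,
                model.indels,
                gseed,
                root_label=root_label,
                protected_codons=model.protected_codons,
                gene_id=gid,
            )
            for s in species:
                per_species[s][gid] = sim.proteins[s]
                per_species_cds[s][gid] = sim.cds[s]
        proteomes = {
            s: Proteome(species_label=s, sequences=per_species[s]) for s in species
        }
        replicates.append(
            SimulatedReplicate(index=r, proteomes=proteomes, cds=per_species_cds)
        )
    return replicates


# ---------------------------------------------------------------------------
# counting-method dN/dS (validation estimator)
# ---------------------------------------------------------------------------


def _site_counts(kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-codon synonymous/nonsynonymous site counts, kappa-weighted."""
    syn = np.zeros(61)
    nonsyn = np.zeros(61)
    for u, cu in enumerate(SENSE_CODONS):
        for pos in range(3):
            wsum = 0.0
            wsyn = 0.0
            for b in BASES:
                if b == cu[pos]:
                    continue
                cv = cu[:pos] + b + cu[pos + 1 :]
                if cv in STOP_CODONS:
                    continue  # nonsense changes excluded from sites
                w = kappa if (cu[pos], b) in _TRANSITIONS else 1.0
                wsum += w
                if _GENETIC_CODE[cu] == _GENETIC_CODE[cv]:
                    wsyn += w
            if wsum > 0:
                syn[u] += wsyn / wsum
                nonsyn[u] += 1.0 - wsyn / wsum
    return syn, nonsyn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _GENETIC_CODE[cur] == _GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:  # all pathways pass through stops; count as nonsynonymous
        return 0.0, float(len(diff_pos))
    return syn_total / n_paths, nonsyn_total / n_paths


def counting_dnds(
    pairs: Iterable[tuple[str, str]], kappa: float = 1.0
) -> tuple[float, float, float]:
    """Pooled modified Nei-Gojobori dN/dS over aligned, equal-length CDS pairs.

    Site counting weights transitions by kappa; proportions are corrected
    with the Jukes-Cantor formula.  Returns (dN, dS, omega).  Independent of
    the simulation machinery -- used as a parameter-recovery oracle.
    """
    syn_sites_tab, nonsyn_sites_tab = _site_counts(kappa)
    S = N = Sd = Nd = 0.0
    for cds1, cds2 in pairs:
        if len(cds1) != len(cds2) or len(cds1) % 3:
            raise ValueError("pairs must be equal-length in-frame CDS")
        for i in range(0, len(cds1), 3):
            c1, c2 = cds1[i : i + 3], cds2[i : i + 3]
            u, v = CODON_INDEX[c1], CODON_INDEX[c2]
            S += (syn_sites_tab[u] + syn_sites_tab[v]) / 2.0
            N += (nonsyn_sites_tab[u] + nonsyn_sites_tab[v]) / 2.0
            sd, nd = _pathway_differences(c1, c2)
            Sd += sd
            Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no sites counted")
    pS = Sd / S
    pN = Nd / N

    def jc(p: float) -> float:
        if p >= 0.75:
            raise ValueError("substitution proportion too large to correct")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    dS = jc(pS)
    dN = jc(pN)
    if dS == 0:
        raise ValueError("dS is zero; omega undefined")
    return dN, dS, dN / dS
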