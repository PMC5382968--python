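"""Readers and writers for the external formats the pipeline touches.

Every table is tab-separated with a single header line; ``#`` comment lines
are permitted everywhere.  Interaction files are undirected: edges are stored
canonically as lexicographically ordered ID pairs.  GO annotations are flat
protein -> term maps (no DAG propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import networkx as nx
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
#: Amino-acid alphabet; 'X' is the unknown-residue wildcard.
AA_ALPHABET = frozenset(AA_LETTERS + "X")
NT_ALPHABET = frozenset("ACGT")
ALIGNED_NT_ALPHABET = frozenset("ACGT-")
GAP = "-"

GO_NAMESPACES = ("process", "function", "component")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Proteome:
    """A species' protein sequences keyed by unique protein ID."""

    species_label: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for protein {pid!r}")
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise FormatError(
                    f"illegal residue(s) {sorted(bad)} in protein {pid!r}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Proteome):
            return NotImplemented
        return (
            self.species_label == other.species_label
            and self.sequences == other.sequences
        )


@dataclass
class CodonAlignment:
    """Aligned coding sequences for one gene, one row per species."""

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"alignment rows for gene {self.gene_id!r} have unequal "
                f"lengths {sorted(lengths)}"
            )
        for taxon, row in self.rows.items():
            bad = set(row) - ALIGNED_NT_ALPHABET
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in row {taxon!r}"
                )
            ungapped = row.replace(GAP, "")
            if len(ungapped) % 3 != 0:
                raise FormatError(
                    f"ungapped length of row {taxon!r} not divisible by 3"
                )
            for i in range(0, len(ungapped) - 3, 3):
                if ungapped[i : i + 3] in STOP_CODONS:
                    raise FormatError(
                        f"internal stop codon at codon {i // 3} in row {taxon!r}"
                    )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass(eq=False)  # identity hash: nodes are unique tree positions
class TreeNode:
    label: str
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted tree with labeled leaves and non-negative branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._check()

    def _check(self) -> None:
        labels = [n.label for n in self.leaves()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise FormatError(f"duplicate leaf label(s): {sorted(dupes)}")
        for node in self.postorder():
            if node.length < 0:
                raise FormatError(f"negative branch length at {node.label!r}")

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    def adjacency(self) -> dict[TreeNode, list[tuple[TreeNode, float]]]:
        """Undirected node adjacency with edge lengths (for re-rooting)."""
        adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
        for node in self.postorder():
            adj.setdefault(node, [])
            for child in node.children:
                adj[node].append((child, child.length))
                adj.setdefault(child, []).append((node, child.length))
        return adj

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"no leaf labeled {label!r}")

    def newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            if n.is_leaf:
                core = n.label
            else:
                core = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n is self.root:
                return core
            return f"{core}:{n.length:g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"Newick parse error: {exc}") from exc
        counter = [0]

        def convert(dnode, parent: TreeNode | None) -> TreeNode:
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon else None
                if label is None:
                    raise FormatError("unlabeled leaf in Newick input")
            else:
                counter[0] += 1
                label = dnode.label or f"node{counter[0]}"
            length = dnode.edge.length
            if length is None:
                length = 0.0
                if parent is not None:
                    logger.warning(
                        "missing branch length above %r; defaulting to 0", label
                    )
            node = TreeNode(label=str(label).replace(" ", "_"), length=float(length))
            node.parent = parent
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        return cls(convert(dtree.seed_node, None))


@dataclass
class GOAnnotationSet:
    """Flat protein -> GO term annotations over a fixed protein universe."""

    protein_terms: dict[str, set[str]]
    term_namespace: dict[str, str]
    term_name: dict[str, str]
    universe: set[str]

    def __post_init__(self) -> None:
        outside = set(self.protein_terms) - self.universe
        if outside:
            raise FormatError(
                f"annotated protein(s) outside the universe: {sorted(outside)[:5]}"
            )
        for term, ns in self.term_namespace.items():
            if ns not in GO_NAMESPACES:
                raise FormatError(f"unknown namespace {ns!r} for term {term}")

    def proteins_with(self, term: str) -> set[str]:
        return {p for p, terms in self.protein_terms.items() if term in terms}

    def terms(self) -> set[str]:
        return set(self.term_namespace)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_ALPHABETS = {
    "protein": AA_ALPHABET,
    "nucleotide": NT_ALPHABET,
    "aligned": ALIGNED_NT_ALPHABET,
}


def read_fasta(path: str | Path, alphabet: str = "protein") -> dict[str, str]:
    """Read a FASTA file into an ordered ID -> sequence map.

    ``alphabet`` is one of ``protein`` (20 letters + X), ``nucleotide``
    (ACGT) or ``aligned`` (ACGT plus gaps).  Sequences are upper-cased;
    record order is preserved; duplicate IDs and illegal characters are
    errors.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    legal = _ALPHABETS[alphabet]
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate record ID {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        for offset, ch in enumerate(seq):
            if ch not in legal:
                raise FormatError(
                    f"illegal character {ch!r} at offset {offset} of record "
                    f"{rec.id!r} in {path}"
                )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    """Write sequences in canonical form: ``>id`` then ``width``-wrapped lines."""
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_proteome(path: str | Path, species_label: str | None = None) -> Proteome:
    label = species_label or Path(path).stem
    return Proteome(species_label=label, sequences=read_fasta(path, "protein"))


def read_codon_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    rows = read_fasta(path, "aligned")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"aligned rows of unequal length in {path}")
    return CodonAlignment(gene_id=gene_id or Path(path).stem, rows=rows)


def read_newick(path_or_text: str | Path) -> Phylogeny:
    """Read a rooted Newick tree from a file path or a literal string."""
    text = str(path_or_text)
    if not text.strip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    return Phylogeny.from_newick(text)


# ---------------------------------------------------------------------------
# interaction TSV
# ---------------------------------------------------------------------------


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Undirected edge as a lexicographically ordered ID pair."""
    return (a, b) if a <= b else (b, a)


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_interactions(path: str | Path) -> nx.Graph:
    """Read a two-column (optionally scored) TSV of protein-ID pairs.

    Edges are deduplicated treating (i, j) == (j, i); self-loops are dropped
    with a logged count.  The vertex set is the union of all endpoints.
    """
    path = Path(path)
    graph = nx.Graph()
    dropped_self = 0
    for lineno, fields in _data_lines(path):
        if fields[0].lower() in ("protein_a", "id_a", "proteina"):
            continue  # header
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise FormatError(
                f"{path}:{lineno}: expected 2 mandatory tab-separated fields, "
                f"got {len([f for f in fields if f])}"
            )
        a, b = fields[0], fields[1]
        graph.add_node(a)
        graph.add_node(b)
        if a == b:
            dropped_self += 1
            continue
        graph.add_edge(*canonical_edge(a, b))
    if dropped_self:
        logger.warning("%s: dropped %d self-loop row(s)", path, dropped_self)
    return graph


def write_interactions(path: str | Path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(canonical_edge(u, v) for u, v in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def edge_set(graph: nx.Graph) -> set[tuple[str, str]]:
    """Canonical edge set of a graph (sorted ID pairs)."""
    return {canonical_edge(u, v) for u, v in graph.edges()}


# ---------------------------------------------------------------------------
# GO annotations TSV
# ---------------------------------------------------------------------------


def read_go_annotations(path: str | Path, universe: Iterable[str]) -> GOAnnotationSet:
    """Read a flat TSV (protein_id, term_id, namespace, term_name).

    Rows for proteins outside ``universe`` are dropped with a logged count;
    a term carrying two different namespaces is an error.
    """
    path = Path(path)
    universe = set(universe)
    protein_terms: dict[str, set[str]] = {}
    term_namespace: dict[str, str] = {}
    term_name: dict[str, str] = {}
    dropped = 0
    for lineno, fields in _data_lines(path):
        if fields[0].lower() == "protein_id":
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        protein, term, ns, name = fields[0], fields[1], fields[2], fields[3]
        if ns not in GO_NAMESPACES:
            raise FormatError(f"{path}:{lineno}: unknown namespace {ns!r}")
        if term in term_namespace and term_namespace[term] != ns:
            raise FormatError(
                f"{path}:{lineno}: term {term} tagged with two namespaces "
                f"({term_namespace[term]!r} and {ns!r})"
            )
        term_namespace[term] = ns
        term_name.setdefault(term, name)
        if protein not in universe:
            dropped += 1
            continue
        protein_terms.setdefault(protein, set()).add(term)
    if dropped:
        logger.warning("%s: dropped %d row(s) for proteins outside the universe", path, dropped)
    return GOAnnotationSet(
        protein_terms=protein_terms,
        term_namespace=term_namespace,
        term_name=term_name,
        universe=universe,
    )


def write_go_annotations(path: str | Path, annotations: GOAnnotationSet) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\tnamespace\tterm_name\n")
        for protein in sorted(annotations.protein_terms):
            for term in sorted(annotations.protein_terms[protein]):
                fh.write(
                    f"{protein}\t{term}\t{annotations.term_namespace[term]}\t"
                    f"{annotations.term_name.get(term, '')}\n"
                )


# ---------------------------------------------------------------------------
# cluster membership TSV
# ---------------------------------------------------------------------------


def read_clusters(path: str | Path) -> dict[str, set[str]]:
    """Read cluster membership (cluster_id, protein_id; one row per member)."""
    path = Path(path)
    clusters: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if fields[0].lower() == "cluster_id":
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields")
        clusters.setdefault(fields[0], set()).add(fields[1])
    return clusters


def write_clusters(path: str | Path, clusters: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tprotein_id\n")
        for cid in sorted(clusters):
            for pid in sorted(clusters[cid]):
                fh.write(f"{cid}\t{pid}\n")


def validate_file(path: str | Path, kind: str) -> str:
    """Validate a file of the given kind; returns a short summary string."""
    path = Path(path)
    if kind == "proteome":
        p = read_proteome(path)
        return f"proteome OK: {len(p)} sequences"
    if kind == "cds":
        recs = read_fasta(path, "nucleotide")
        for pid, seq in recs.items():
            if len(seq) % 3:
                raise FormatError(f"CDS {pid!r} length not divisible by 3")
        return f"CDS OK: {len(recs)} sequences"
    if kind == "alignment":
        aln = read_codon_alignment(path)
        return f"alignment OK: {len(aln.rows)} rows x {aln.n_columns} columns"
    if kind == "tree":
        t = read_newick(path)
        return f"tree OK: {len(t.leaves())} leaves"
    if kind == "interactions":
        g = read_interactions(path)
        return f"interactions OK: {g.number_of_nodes()} proteins, {g.number_of_edges()} edges"
    if kind == "clusters":
        c = read_clusters(path)
        return f"clusters OK: {len(c)} clusters"
    raise ValueError(f"unknown kind {kind!r}")
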