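"""Sequential PIPE: sequence-window co-occurrence PPI prediction.

PIPE predicts whether two query proteins A and B interact by sliding a
20-residue window over each query and asking how often a pair of windows
(a_i, b_j) "co-occurs" in protein pairs already known to interact.  For each
window a_i, every database protein containing a similar window contributes
its interaction partners to a neighbour list R_i; cell (i, j) of the result
matrix then counts similar-window hits of b_j against the proteins of R_i.
Window similarity is a PAM120 sum over aligned positions compared to an
integer threshold.

The scalar prediction score is an aggregate of the result matrix (maximum
cell by default, mean as an alternative) compared against a decision
threshold that is normally calibrated by leave-one-out cross-validation to a
target specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import biotite.sequence as bioseq
import biotite.sequence.align as bioalign

try:  # compiled rolling-sum kernel; a numpy fallback is kept alongside
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .data_io import AA_LETTERS, canonical_edge

logger = logging.getLogger(__name__)

#: Residue order used for integer encoding; X (wildcard) is last.
ALPHABET = AA_LETTERS + "X"
_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_ENCODE_TABLE = np.full(128, -1, dtype=np.int16)
for _aa, _i in _INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i


def _build_pam120() -> np.ndarray:
    """21x21 integer PAM120 over ALPHABET; X scores 0 against everything."""
    alpha = bioseq.ProteinSequence.alphabet
    pam = bioalign.SubstitutionMatrix(alpha, alpha, "PAM120")
    m = np.zeros((21, 21), dtype=np.int32)
    for a in AA_LETTERS:
        for b in AA_LETTERS:
            m[_INDEX[a], _INDEX[b]] = int(pam.get_score(a, b))
    return m


#: Default similarity matrix (PAM120 with neutral X).
PAM120 = _build_pam120()


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into ALPHABET."""
    arr = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        pos = int(np.argmax(arr < 0))
        raise ValueError(f"illegal residue {seq[pos]!r} at position {pos}")
    return arr.astype(np.intp)


@dataclass(frozen=True)
class PipeConfig:
    """Tunable PIPE parameters.

    window: sliding-window length in residues (fully overlapping, step 1).
    similarity_threshold: minimum PAM120 window sum for two fragments to be
        called similar.
    aggregator: how the result matrix becomes one score ("max" or "mean").
    decision_threshold: score at or above which a pair is called interacting.
    """

    window: int = 20
    similarity_threshold: int = 90
    aggregator: str = "max"
    decision_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.aggregator not in ("max", "mean"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if not np.isfinite(self.similarity_threshold) or not np.isfinite(
            self.decision_threshold
        ):
            raise ValueError("thresholds must be finite")


@dataclass
class ResultMatrix:
    """The (|A|-w+1) x (|B|-w+1) window co-occurrence count matrix."""

    id_a: str
    id_b: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("result matrix entries must be non-negative")


@dataclass
class PredictionRecord:
    id_a: str
    id_b: str
    score: float
    decision: bool
    threshold: float


def score_fragment_pair(
    frag_a: str, frag_b: str, matrix: np.ndarray | None = None
) -> int:
    """Position-by-position substitution-matrix sum for two equal-length fragments."""
    if len(frag_a) != len(frag_b):
        raise ValueError(
            f"fragment length mismatch: {len(frag_a)} vs {len(frag_b)}"
        )
    m = PAM120 if matrix is None else matrix
    a = encode(frag_a)
    b = encode(frag_b)
    return int(m[a, b].sum())


def window_score_matrix(
    a_enc: np.ndarray, b_enc: np.ndarray, w: int, matrix: np.ndarray | None = None
) -> np.ndarray:
    """All-windows-vs-all-windows score matrix between two encoded sequences.

    Entry (i, j) is the substitution-sum of window i of the first sequence
    against window j of the second; both sequences must be at least ``w``
    long.
    """
    m = PAM120 if matrix is None else matrix
    na = len(a_enc) - w + 1
    nb = len(b_enc) - w + 1
    if na < 1 or nb < 1:
        raise ValueError("query shorter than window")
    site = m[a_enc[:, None], b_enc[None, :]]
    out = np.zeros((na, nb), dtype=np.int32)
    for k in range(w):
        out += site[k : k + na, k : k + nb]
    return out


def _hit_counts_numpy(
    q: np.ndarray, s: np.ndarray, w: int, matrix: np.ndarray, threshold: int
) -> np.ndarray:
    scores = window_score_matrix(q, s, w, matrix)
    return (scores >= threshold).sum(axis=1).astype(np.int32)


if _HAVE_NUMBA:

    @njit(nogil=True, fastmath=False)
    def _hit_counts_kernel(q, s, w, matrix, threshold, out):  # pragma: no cover
        na = q.shape[0] - w + 1
        nb = s.shape[0] - w + 1
        # walk every diagonal with a rolling window sum: O(|q| * |s|)
        for d in range(-(nb - 1), na):
            i = d if d > 0 else 0
            j = -d if d < 0 else 0
            if i >= na or j >= nb:
                continue
            total = 0
            for k in range(w):
                total += matrix[q[i + k], s[j + k]]
            out[i] += total >= threshold
            while i + 1 < na and j + 1 < nb:
                total += matrix[q[i + w], s[j + w]] - matrix[q[i], s[j]]
                i += 1
                j += 1
                out[i] += total >= threshold

    _PAM120_I32 = None

    def _hit_counts(q, s, w, matrix, threshold):
        global _PAM120_I32
        if matrix is PAM120:
            if _PAM120_I32 is None:
                _PAM120_I32 = np.ascontiguousarray(PAM120, dtype=np.int32)
            m = _PAM120_I32
        else:
            m = np.ascontiguousarray(matrix, dtype=np.int32)
        out = np.zeros(q.shape[0] - w + 1, dtype=np.int32)
        _hit_counts_kernel(q, s, w, m, threshold, out)
        return out

else:  # pragma: no cover
    _hit_counts = _hit_counts_numpy


def find_similar_source_proteins(
    window: str,
    proteome: Mapping[str, str],
    graph: nx.Graph,
    config: PipeConfig = PipeConfig(),
) -> set[str]:
    """Database proteins containing >= 1 window similar to the query window."""
    w = config.window
    if len(window) != w:
        raise ValueError(f"query window must have length {w}")
    q = encode(window)
    hits: set[str] = set()
    skipped = 0
    for pid in graph.nodes():
        seq = proteome.get(pid)
        if seq is None or len(seq) < w:
            skipped += 1
            continue
        scores = window_score_matrix(q, encode(seq), w)
        if (scores >= config.similarity_threshold).any():
            hits.add(pid)
    if skipped:
        logger.info("skipped %d protein(s) shorter than the window or unsequenced", skipped)
    return hits


class PipeEngine:
    """Precomputes window-hit counts between queries and the database.

    The expensive part of PIPE is scoring every query window against every
    window of every database protein; that quantity is independent of which
    edge is being tested, so it is cached per query sequence.  LOOCV edge
    removal then only touches the (cheap) adjacency step.
    """

    def __init__(
        self,
        proteome: Mapping[str, str],
        graph: nx.Graph,
        config: PipeConfig = PipeConfig(),
    ):
        self.config = config
        w = config.window
        self.db_ids = sorted(
            pid
            for pid in graph.nodes()
            if pid in proteome and len(proteome[pid]) >= w
        )
        skipped = set(graph.nodes()) - set(self.db_ids)
        if skipped:
            logger.info(
                "database: %d graph protein(s) without usable sequence skipped",
                len(skipped),
            )
        self._pos = {pid: i for i, pid in enumerate(self.db_ids)}
        self._db_enc = [encode(proteome[pid]) for pid in self.db_ids]
        n = len(self.db_ids)
        self.adjacency = np.zeros((n, n), dtype=bool)
        for u, v in graph.edges():
            if u in self._pos and v in self._pos and u != v:
                i, j = self._pos[u], self._pos[v]
                self.adjacency[i, j] = True
                self.adjacency[j, i] = True
        self._hit_cache: dict[str, np.ndarray] = {}

    def window_hit_counts(self, seq: str) -> np.ndarray:
        """(n_windows, n_db) matrix: similar-window hits per database protein."""
        cached = self._hit_cache.get(seq)
        if cached is not None:
            return cached
        w = self.config.window
        thr = self.config.similarity_threshold
        q = encode(seq)
        nwin = len(seq) - w + 1
        if nwin < 1:
            raise ValueError("query shorter than window")
        counts = np.zeros((nwin, len(self.db_ids)), dtype=np.int32)
        for col, enc in enumerate(self._db_enc):
            counts[:, col] = _hit_counts(q, enc, w, PAM120, thr)
        self._hit_cache[seq] = counts
        return counts

    def result_matrix(
        self,
        seq_a: str,
        seq_b: str,
        exclude_edge: tuple[str, str] | None = None,
        id_a: str = "A",
        id_b: str = "B",
    ) -> ResultMatrix:
        hits_a = self.window_hit_counts(seq_a)
        hits_b = self.window_hit_counts(seq_b)
        adj = self.adjacency
        if exclude_edge is not None:
            u, v = exclude_edge
            if u in self._pos and v in self._pos:
                adj = adj.copy()
                i, j = self._pos[u], self._pos[v]
                adj[i, j] = False
                adj[j, i] = False
        # R_i = union of neighbours of proteins holding a window similar to a_i.
        # float32 BLAS matmuls stay exact here: entries are small integers.
        r_ind = (hits_a > 0).astype(np.float32) @ adj.astype(np.float32)
        counts = (r_ind > 0).astype(np.float32) @ hits_b.astype(np.float32).T
        return ResultMatrix(
            id_a=id_a, id_b=id_b, counts=np.rint(counts).astype(np.int64)
        )

    def score(self, result: ResultMatrix) -> float:
        if self.config.aggregator == "max":
            return float(result.counts.max()) if result.counts.size else 0.0
        return float(result.counts.mean()) if result.counts.size else 0.0

    def predict_pair(
        self,
        id_a: str,
        seq_a: str,
        id_b: str,
        seq_b: str,
        exclude_edge: tuple[str, str] | None = None,
    ) -> PredictionRecord:
        """Symmetric prediction: the pair score pools both query orientations.

        The sequential result matrix is orientation-dependent (the second
        protein's windows are counted against the first protein's neighbour
        lists), so the pair is evaluated both ways and the stronger evidence
        wins; IDs are reported in lexicographic order.
        """
        if id_b < id_a:
            id_a, id_b = id_b, id_a
            seq_a, seq_b = seq_b, seq_a
        rm_ab = self.result_matrix(seq_a, seq_b, exclude_edge, id_a, id_b)
        rm_ba = self.result_matrix(seq_b, seq_a, exclude_edge, id_b, id_a)
        s = max(self.score(rm_ab), self.score(rm_ba))
        thr = self.config.decision_threshold
        return PredictionRecord(
            id_a=id_a, id_b=id_b, score=s, decision=s >= thr, threshold=thr
        )


# -- module-level functional surface ----------------------------------------


def compute_result_matrix(
    seq_a: str,
    seq_b: str,
    graph: nx.Graph,
    proteome: Mapping[str, str],
    config: PipeConfig = PipeConfig(),
) -> ResultMatrix:
    """One-shot result matrix for a query pair (builds a throwaway engine)."""
    return PipeEngine(proteome, graph, config).result_matrix(seq_a, seq_b)


def predict(
    seq_a: str,
    seq_b: str,
    graph: nx.Graph,
    proteome: Mapping[str, str],
    config: PipeConfig = PipeConfig(),
    id_a: str = "A",
    id_b: str = "B",
) -> PredictionRecord:
    return PipeEngine(proteome, graph, config).predict_pair(id_a, seq_a, id_b, seq_b)


def predict_interactome(
    engine: PipeEngine,
    query_proteome: Mapping[str, str],
    candidate_pairs: Iterable[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Edges among candidate pairs called interacting in a query proteome.

    The database (engine) stays fixed; the query sequences come from
    ``query_proteome`` (e.g. a simulated species).  Pairs whose sequences are
    missing or shorter than the window are skipped.
    """
    w = engine.config.window
    out: set[tuple[str, str]] = set()
    for a, b in candidate_pairs:
        sa, sb = query_proteome.get(a), query_proteome.get(b)
        if sa is None or sb is None or len(sa) < w or len(sb) < w:
            continue
        rec = engine.predict_pair(a, sa, b, sb)
        if rec.decision:
            out.add(canonical_edge(a, b))
    return out


# -- LOOCV -------------------------------------------------------------------


@dataclass
class LoocvResult:
    """Pooled scored list from leave-one-out cross-validation."""

    table: pd.DataFrame  # columns: id_a, id_b, score, label (1 pos / 0 neg)

    def roc(self) -> pd.DataFrame:
        """Sensitivity/specificity at every candidate threshold.

        Candidate thresholds are the distinct observed scores plus one value
        above the maximum (the all-negative operating point).  A pair is
        called positive when score >= threshold.
        """
        scores = self.table["score"].to_numpy()
        labels = self.table["label"].to_numpy()
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        thresholds = np.unique(scores)
        thresholds = np.append(thresholds, thresholds.max() + 1)
        rows = []
        for t in thresholds:
            sens = float((pos >= t).mean()) if len(pos) else float("nan")
            spec = float((neg < t).mean()) if len(neg) else float("nan")
            rows.append((float(t), sens, spec))
        return pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])

    def threshold_for_specificity(self, target: float) -> float:
        """Smallest threshold achieving at least the target specificity."""
        roc = self.roc()
        ok = roc[roc["specificity"] >= target]
        if ok.empty:
            raise ValueError(f"no threshold reaches specificity {target}")
        return float(ok["threshold"].iloc[0])

    def sensitivity_at(self, threshold: float) -> float:
        pos = self.table.loc[self.table["label"] == 1, "score"]
        return float((pos >= threshold).mean())

    def specificity_at(self, threshold: float) -> float:
        neg = self.table.loc[self.table["label"] == 0, "score"]
        return float((neg < threshold).mean())


def run_loocv(
    graph: nx.Graph,
    proteome: Mapping[str, str],
    n_negatives: int,
    config: PipeConfig = PipeConfig(),
    seed: int = 0,
) -> LoocvResult:
    """Score each known edge with that edge (only) removed, plus sampled non-edges.

    Negatives are unordered protein pairs sampled uniformly without
    replacement from the non-edges of the database graph.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("empty interaction graph")
    engine = PipeEngine(proteome, graph, config)
    ids = engine.db_ids
    n = len(ids)
    known = {canonical_edge(u, v) for u, v in graph.edges()}
    n_non_edges = n * (n - 1) // 2 - len(
        {e for e in known if e[0] in engine._pos and e[1] in engine._pos}
    )
    if n_negatives > n_non_edges:
        raise ValueError(
            f"n_negatives={n_negatives} exceeds the {n_non_edges} available non-edges"
        )
    rng = np.random.default_rng(seed)
    negatives: set[tuple[str, str]] = set()
    while len(negatives) < n_negatives:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = canonical_edge(ids[i], ids[j])
        if e in known or e in negatives:
            continue
        negatives.add(e)

    rows = []
    for u, v in sorted(known):
        if u not in engine._pos or v not in engine._pos:
            continue
        rec = engine.predict_pair(u, proteome[u], v, proteome[v], exclude_edge=(u, v))
        rows.append((rec.id_a, rec.id_b, rec.score, 1))
    for u, v in sorted(negatives):
        rec = engine.predict_pair(u, proteome[u], v, proteome[v])
        rows.append((rec.id_a, rec.id_b, rec.score, 0))
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "score", "label"])
    return LoocvResult(table=table)


def calibrate_decision_threshold(
    loocv: LoocvResult, config: PipeConfig, target_specificity: float = 0.995
) -> PipeConfig:
    """Return a config whose decision threshold hits the target specificity."""
    thr = loocv.threshold_for_specificity(target_specificity)
    return replace(config, decision_threshold=thr)
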