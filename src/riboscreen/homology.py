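"""Protein homology search: local alignment, E-values, cut-offs, MCL.

The screening stage mirrors a classical all-vs-query BLASTP workflow:
optimal Smith-Waterman local alignment under BLOSUM62 with affine gaps
(via Biopython's exact ``PairwiseAligner``), Karlin-Altschul expectation
values, the 40% similarity / 70% query-coverage / E < 1e-4 filter, and
Markov clustering (MCL) of the resulting similarity graph into
orthologous groups.

"Similarity" is the percentage of aligned columns with a positive
substitution score (BLAST "positives"); "identity" is exact matches.
Both are computed over the full local-alignment length, gap columns
included, matching BLAST tabular conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "HomologyHit",
    "align_local",
    "estimate_evalue",
    "passes_thresholds",
    "mcl_cluster",
]

#: the 20 standard residues plus X (unknown, scored 0 against everything)
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def _blosum62_with_neutral_x() -> substitution_matrices.Array:
    mat = substitution_matrices.load("BLOSUM62")
    mat = mat.copy()
    for aa in mat.alphabet:
        mat["X", aa] = 0.0
        mat[aa, "X"] = 0.0
    return mat


@dataclass
class ScoringScheme:
    """Alignment scoring and E-value statistics.

    Gap penalties follow the BLAST convention: a gap of length L costs
    ``gap_open + gap_extend * L``. ``K`` and ``lam`` are Karlin-Altschul
    parameters for the ungapped BLOSUM62 regime; they are documented,
    overridable constants rather than fitted values.
    """

    gap_open: float = 11.0
    gap_extend: float = 1.0
    K: float = 0.041
    lam: float = 0.267
    matrix: substitution_matrices.Array = field(
        default_factory=_blosum62_with_neutral_x
    )

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be strictly positive")
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score for the first gapped
        # residue, so BLAST-style open+extend maps onto it like this:
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class HomologyHit:
    """One query-vs-subject local alignment summary."""

    query_id: str
    subject_locus: str
    score: float
    pct_identity: float
    pct_similarity: float
    query_coverage: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= self.pct_similarity <= 100):
            raise ValueError("require 0 <= identity <= similarity <= 100")
        if not 0 <= self.query_coverage <= 100:
            raise ValueError("query coverage outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


def _validate_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters {sorted(bad)}")
    return seq


def align_local(
    query: str,
    subject: str,
    scheme: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    subject_locus: str = "subject",
    db_len: int | None = None,
) -> HomologyHit:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Identity and similarity are percentages of the alignment length
    (gap columns included); coverage is the aligned query span as a
    percentage of query length. ``db_len`` (total residues searched)
    feeds the E-value; it defaults to the subject length.
    """
    scheme = scheme or ScoringScheme()
    query = _validate_protein(query, "query")
    subject = _validate_protein(subject, "subject")
    aligner = scheme.aligner()
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        # no positive-scoring local alignment at all
        return HomologyHit(
            query_id, subject_locus, 0.0, 0.0, 0.0, 0.0, float("inf")
        )
    aln = alignments[0]
    q_blocks, s_blocks = aln.aligned
    ident = positives = aligned_cols = 0
    for (qs, qe), (ss, _se) in zip(q_blocks, s_blocks):
        for i in range(qe - qs):
            a, b = query[qs + i], subject[ss + i]
            aligned_cols += 1
            if a == b:
                ident += 1
            if scheme.matrix[a, b] > 0:
                positives += 1
    aln_len = aln.length  # includes gap columns
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    evalue = estimate_evalue(
        aln.score, len(query), db_len if db_len is not None else len(subject), scheme
    )
    return HomologyHit(
        query_id=query_id,
        subject_locus=subject_locus,
        score=float(aln.score),
        pct_identity=100.0 * ident / aln_len,
        pct_similarity=100.0 * positives / aln_len,
        query_coverage=100.0 * q_span / len(query),
        evalue=evalue,
    )


def estimate_evalue(
    score: float, query_len: int, db_len: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin-Altschul expectation value E = K * m * n * exp(-lambda * S)."""
    scheme = scheme or ScoringScheme()
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence/database lengths must be positive")
    return scheme.K * query_len * db_len * math.exp(-scheme.lam * score)


def passes_thresholds(
    hit: HomologyHit,
    *,
    min_similarity: float = 40.0,
    min_coverage: float = 70.0,
    max_evalue: float = 1e-4,
) -> bool:
    """Homology acceptance filter.

    Similarity and coverage cut-offs are inclusive (>=); the E-value
    bound is strict (<), mirroring its "less than" phrasing.
    """
    return (
        hit.pct_similarity >= min_similarity
        and hit.query_coverage >= min_coverage
        and hit.evalue < max_evalue
    )


def mcl_cluster(
    graph: nx.Graph | tuple[Sequence[Hashable], np.ndarray],
    inflation: float = 2.0,
    *,
    max_iter: int = 100,
    tol: float = 1e-6,
    self_loop: float = 1.0,
) -> list[set[Hashable]]:
    """Markov clustering of a weighted undirected similarity graph.

    Alternates expansion (matrix squaring) with inflation (elementwise
    power followed by column normalisation) until the matrix changes by
    less than ``tol`` or ``max_iter`` rounds. Self-loops of weight
    ``self_loop`` are added internally. Returns a disjoint partition of
    the nodes, each cluster sorted-stable by node label.
    """
    if inflation <= 1:
        raise ValueError("MCL inflation must be > 1")
    if isinstance(graph, nx.Graph):
        nodes = sorted(graph.nodes)
        m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    else:
        labels, m = graph
        nodes = list(labels)
        m = np.asarray(m, dtype=float)
    if m.size == 0:
        return []
    if (m < 0).any():
        raise ValueError("edge weights must be non-negative")
    n = len(nodes)
    m = m.copy()
    np.fill_diagonal(m, np.diag(m) + self_loop)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    # attractors are rows with any mass; assign each node to its
    # strongest attractor, merging attractors that share members
    assign = m.argmax(axis=0)
    parent = {i: i for i in range(n)}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(n):
        ri, rj = find(int(assign[j])), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, set[Hashable]] = {}
    for j in range(n):
        groups.setdefault(find(j), set()).add(nodes[j])
    return sorted(groups.values(), key=lambda s: sorted(map(str, s)))


def hits_to_table(hits: Sequence[HomologyHit]):
    """Export hits as a BLAST-tabular-style pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            (
                h.query_id,
                h.subject_locus,
                h.pct_identity,
                h.pct_similarity,
                h.query_coverage,
                h.evalue,
                h.score,
            )
            for h in hits
        ],
        columns=["qseqid", "sseqid", "pident", "ppos", "qcovs", "evalue", "bitscore"],
    )


def similarity_graph(
    hits: Mapping[tuple[str, str], HomologyHit] | Sequence[HomologyHit],
    *,
    weight_attr: str = "score",
) -> nx.Graph:
    """Build the undirected graph MCL consumes from passing hits."""
    g = nx.Graph()
    seq = hits.values() if isinstance(hits, Mapping) else hits
    for h in seq:
        w = getattr(h, weight_attr)
        if h.query_id != h.subject_locus:
            g.add_edge(h.query_id, h.subject_locus, weight=float(w))
        else:
            g.add_node(h.query_id)
    return g
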