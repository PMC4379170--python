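"""Pairwise sequence identity, similarity graphs and redundancy culling.

Two proteins are *redundant* at a threshold t when their pairwise
sequence identity is at least t percent.  The similarity graph connects
redundant pairs; a non-redundant dataset is a maximal independent set of
that graph, found by a deterministic max-degree culling heuristic.  The
threshold-sweep experiment retrains a forest on each non-redundant set
and evaluates it on both the non-redundant proteins (out-of-bag) and the
entire dataset (removed proteins scored by the full forest), mirroring
the question of how much information redundancy removal costs.

Identity defaults to a deterministic global alignment (match +1,
mismatch 0, affine gaps open -10 / extend -0.5), with identity = 100 x
matching columns / alignment columns; a precomputed identity matrix can
be supplied instead wherever one is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from . import purf

__all__ = [
    "pairwise_identity",
    "identity_matrix",
    "SimilarityGraph",
    "build_similarity_graph",
    "cull",
    "threshold_sweep",
    "read_fasta",
    "write_identity_matrix",
    "read_identity_matrix",
]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = 100 x matched columns / total alignment columns.
    Ambiguity codes match only when equal.  Symmetric; identical
    sequences score 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    counts = alignment.counts()
    columns = alignment.length
    return 100.0 * counts.identities / columns


def identity_matrix(
    sequences: Mapping[str, str],
    identity_fn: Callable[[str, str], float] | None = None,
) -> pd.DataFrame:
    """Symmetric percent-identity matrix over named sequences.

    ``identity_fn`` is the pluggable pairwise identity function
    (defaults to :func:`pairwise_identity`); the diagonal is 100.
    """
    identity_fn = identity_fn or pairwise_identity
    names = list(sequences)
    n = len(names)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            value = identity_fn(sequences[names[i]], sequences[names[j]])
            mat[i, j] = mat[j, i] = value
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass
class SimilarityGraph:
    """Vertices are accessions; edges link pairs with identity >= threshold."""

    vertices: list[str]
    adjacency: dict[str, set[str]]
    threshold: float

    @property
    def edges(self) -> set[frozenset]:
        return {
            frozenset((v, u))
            for v, neigh in self.adjacency.items()
            for u in neigh
        }


def build_similarity_graph(
    identity: pd.DataFrame, threshold: float
) -> SimilarityGraph:
    """Graph with an edge wherever pairwise identity >= threshold (no self-edges)."""
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (0, 100]")
    names = [str(n) for n in identity.index]
    mat = identity.to_numpy()
    adjacency: dict[str, set[str]] = {name: set() for name in names}
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= threshold:
                adjacency[names[i]].add(names[j])
                adjacency[names[j]].add(names[i])
    return SimilarityGraph(vertices=names, adjacency=adjacency,
                           threshold=threshold)


def cull(graph: SimilarityGraph) -> set[str]:
    """Deterministic maximal independent set of the similarity graph.

    Repeatedly removes the vertex with the most remaining neighbours
    (ties: lexicographically smallest accession) until no edges remain,
    then re-adds (in lexicographic order) any removed vertex with no kept
    neighbour, which guarantees maximality.  The kept set contains no
    edge and every removed vertex has a kept neighbour.
    """
    degrees = {v: len(neigh) for v, neigh in graph.adjacency.items()}
    adjacency = {v: set(neigh) for v, neigh in graph.adjacency.items()}
    removed: list[str] = []
    while True:
        max_degree = max(degrees.values(), default=0)
        if max_degree == 0:
            break
        victim = min(v for v, d in degrees.items() if d == max_degree)
        for neighbour in adjacency[victim]:
            adjacency[neighbour].discard(victim)
            degrees[neighbour] -= 1
        del adjacency[victim], degrees[victim]
        removed.append(victim)
    kept = set(degrees)
    # Max-degree removal can orphan a vertex whose neighbours were all
    # removed later; re-adding keeps the set independent and maximal.
    for vertex in sorted(removed):
        if not (graph.adjacency[vertex] & kept):
            kept.add(vertex)
    return kept


def threshold_sweep(
    table: pd.DataFrame,
    labels,
    identity: pd.DataFrame,
    thresholds: Sequence[float],
    rf_config: purf.RFConfig,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Redundancy-threshold sweep over a labelled feature table.

    Per threshold: cull the similarity graph, train a forest on the
    non-redundant subset, report its OOB G mean there, then classify the
    entire dataset (kept proteins by their OOB votes, removed proteins by
    the full forest) and report the confusion counts and G mean, plus the
    fraction of proteins remaining.  A threshold leaving a single class
    is flagged in the row rather than fatal.
    """
    y = pd.Series(np.asarray(labels, dtype=int), index=table.index)
    n_total = len(table)
    rows = []
    for threshold in thresholds:
        graph = build_similarity_graph(identity, threshold)
        kept = cull(graph)
        kept_index = [a for a in table.index if a in kept]
        removed_index = [a for a in table.index if a not in kept]
        y_kept = y.loc[kept_index]
        row = {
            "Threshold": threshold,
            "NonRedundantPos": int(y_kept.sum()),
            "NonRedundantUnl": int((1 - y_kept).sum()),
            "FractionRemaining": len(kept_index) / n_total,
        }
        if y_kept.nunique() < 2:
            row.update({"NonRedundantGMean": np.nan, "TP": 0, "FP": 0,
                        "TN": 0, "FN": 0, "EntireGMean": np.nan,
                        "Usable": False})
            rows.append(row)
            continue
        model = purf.train_forest(table.loc[kept_index], y_kept, rf_config)
        oob_preds = purf.oob_similarity(model, table.loc[kept_index])
        row["NonRedundantGMean"] = purf.confusion_from_predictions(
            oob_preds, y_kept, cutoff
        ).g_mean
        predictions = list(oob_preds)
        entire_labels = list(y_kept)
        if removed_index:
            predictions += purf.full_similarity(
                model, table.loc[removed_index]
            )
            entire_labels += list(y.loc[removed_index])
        entire = purf.confusion_from_predictions(
            predictions, entire_labels, cutoff
        )
        row.update({"TP": entire.tp, "FP": entire.fp, "TN": entire.tn,
                    "FN": entire.fn, "EntireGMean": entire.g_mean,
                    "Usable": True})
        rows.append(row)
    columns = ["Threshold", "NonRedundantPos", "NonRedundantUnl",
               "NonRedundantGMean", "TP", "FP", "TN", "FN",
               "EntireGMean", "FractionRemaining", "Usable"]
    return pd.DataFrame(rows)[columns]


def read_fasta(path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_identity_matrix(identity: pd.DataFrame, path) -> None:
    identity.to_csv(path, sep="\t")


def read_identity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
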