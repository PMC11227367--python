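"""Sparse GRN assembly at a target density, and evaluation.

All per-gene models together form a complete GRN with many regulators per
target; known regulatory networks are much sparser (reported densities are
typically between 0.001 and 0.1), so the E = floor(D * R * (T - 1)) most
important regulator-target pairs are kept, where D is the requested density
and R(T - 1) the size of a complete oriented GRN without self-loops.

Evaluation against a (possibly partial) gold standard restricts inferred
edges to regulators the standard assayed and gold edges to genes given as
input, then reports precision and recall of the intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EdgeList, GoldStandard, PriorMatrix

__all__ = [
    "DensitySpec",
    "EvalResult",
    "edge_count_for_density",
    "assemble_grn",
    "precision_recall",
    "out_degree_ranking",
    "prior_network_baseline",
]


def edge_count_for_density(density: float, n_regulators: int, n_targets: int) -> int:
    """Number of top edges satisfying a density: E = floor(D * R * (T - 1))."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    if n_regulators < 1 or n_targets < 1:
        raise ValueError("need at least one regulator and one target")
    return int(np.floor(density * n_regulators * (n_targets - 1)))


@dataclass
class DensitySpec:
    """Requested density resolved to an edge count for given R and T."""

    density: float
    n_regulators: int
    n_targets: int

    @property
    def total_edges(self) -> int:
        return self.n_regulators * (self.n_targets - 1)

    @property
    def n_edges(self) -> int:
        return edge_count_for_density(self.density, self.n_regulators, self.n_targets)


@dataclass
class EvalResult:
    """Precision/recall of an inferred GRN against a gold standard.

    ``precision``/``recall`` are NaN (and the matching flag False) when the
    restricted edge sets are empty, which is an undefined metric rather
    than zero.
    """

    precision: float
    recall: float
    n_eval_edges: int
    n_gold_edges: int
    n_true_positive: int

    @property
    def precision_defined(self) -> bool:
        return self.n_eval_edges > 0

    @property
    def recall_defined(self) -> bool:
        return self.n_gold_edges > 0


def assemble_grn(
    gene_importances: dict[str, pd.Series],
    density: float,
    n_regulators: int | None = None,
    n_targets: int | None = None,
) -> EdgeList:
    """Keep the globally most important edges at the requested density.

    ``gene_importances`` maps each target to its mean importance vector
    over repetitions (computed on standardized targets, hence comparable
    across genes). Only pairs with strictly positive importance are
    eligible; ties at the cutoff are broken lexicographically by
    (regulator, target) so assembly is deterministic.
    """
    triples = []
    regulators = set()
    for target, imp in gene_importances.items():
        for regulator, value in imp.items():
            regulators.add(regulator)
            if regulator != target and value > 0:
                triples.append((regulator, target, float(value)))
    if n_regulators is None:
        n_regulators = len(regulators)
    if n_targets is None:
        n_targets = len(gene_importances)
    n_edges = edge_count_for_density(density, n_regulators, n_targets)
    df = pd.DataFrame(triples, columns=["regulator", "target", "importance"])
    df = df.sort_values(
        by=["importance", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    if n_edges > len(df):
        warnings.warn(
            f"requested {n_edges} edges but only {len(df)} pairs have nonzero "
            "importance; returning all of them",
            stacklevel=2,
        )
        n_edges = len(df)
    kept = df.head(n_edges).reset_index(drop=True)
    total = n_regulators * (n_targets - 1)
    return EdgeList(edges=kept, density=len(kept) / total if total else 0.0)


def precision_recall(
    grn: EdgeList, gold: GoldStandard, input_genes=None
) -> EvalResult:
    """Precision and recall on the evaluable intersection.

    Inferred edges are restricted to regulators studied by the gold
    standard; gold edges are restricted to pairs whose both endpoints are
    in ``input_genes`` (no restriction when ``None``).
    """
    inferred = {
        (r, t) for r, t in grn.pairs() if r in gold.studied_regulators
    }
    if input_genes is None:
        gold_edges = set(gold.edges)
    else:
        genes = set(input_genes)
        gold_edges = {(r, t) for r, t in gold.edges if r in genes and t in genes}
    tp = inferred & gold_edges
    precision = len(tp) / len(inferred) if inferred else float("nan")
    recall = len(tp) / len(gold_edges) if gold_edges else float("nan")
    return EvalResult(
        precision=precision,
        recall=recall,
        n_eval_edges=len(inferred),
        n_gold_edges=len(gold_edges),
        n_true_positive=len(tp),
    )


def out_degree_ranking(grn: EdgeList, top_k: int = 25) -> pd.DataFrame:
    """Regulators ranked by out-degree (ties lexicographic), top_k rows.

    Hub regulators of the inferred network; the default keeps the 25 most
    connected ones.
    """
    if len(grn) == 0:
        return pd.DataFrame(columns=["regulator", "out_degree"])
    counts = (
        grn.edges.groupby("regulator")
        .size()
        .rename("out_degree")
        .reset_index()
        .sort_values(by=["out_degree", "regulator"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return counts.head(top_k)


def prior_network_baseline(prior: PriorMatrix) -> EdgeList:
    """The motif-only network: every pair with Pi = 1, unit importance.

    Serves as the reference line that pure prior knowledge achieves
    without any expression data.
    """
    pi = prior.pi
    rows, cols = np.nonzero(pi.to_numpy() == 1.0)
    triples = [
        (pi.index[i], pi.columns[j], 1.0)
        for i, j in zip(rows, cols)
        if pi.index[i] != pi.columns[j]
    ]
    df = pd.DataFrame(triples, columns=["regulator", "target", "importance"])
    total = len(pi.index) * max(len(pi.columns) - 1, 1)
    return EdgeList(edges=df, density=len(df) / total if total else 0.0)
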