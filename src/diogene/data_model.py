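"""Core containers and TSV readers/writers.

The canonical on-disk dialect is tab-separated text with a header row and a
header column, decimal point only. Expression matrices are genes x samples;
prior matrices are regulators x targets with entries in {0, 1/2, 1}; edge
lists and gold standards are two- or three-column tables.

A gene may be both a regulator and a target, but is never a candidate
predictor of itself: self-loops are excluded everywhere, consistent with a
complete oriented network of R(T-1) possible edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "PriorMatrix",
    "EdgeList",
    "GoldStandard",
    "read_expression_matrix",
    "read_prior_matrix",
    "read_edge_list",
    "write_edge_list",
]

PRIOR_LEVELS = (0.0, 0.5, 1.0)


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, bad values...)."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a flagged regulator subset.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, rows indexed by gene id, columns by sample id.
    regulator_ids : list of str
        Candidate regulators (the R regulators); must be rows of ``values``.
    target_ids : list of str, optional
        Genes modelled as targets (the T genes). Defaults to all genes.
    """

    values: pd.DataFrame
    regulator_ids: list[str]
    target_ids: list[str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        body = self.values.to_numpy()
        if not np.issubdtype(body.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        genes = set(self.values.index)
        missing = [r for r in self.regulator_ids if r not in genes]
        if missing:
            raise ValidationError(f"regulators absent from matrix: {missing}")
        _check_unique(self.regulator_ids, "regulator ids")
        if self.target_ids is None:
            self.target_ids = list(self.values.index)
        else:
            absent = [t for t in self.target_ids if t not in genes]
            if absent:
                raise ValidationError(f"targets absent from matrix: {absent}")
            _check_unique(self.target_ids, "target ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class PriorMatrix:
    """Regulator x target matrix of motif-evidence values Pi in {0, 1/2, 1}.

    1 marks a motif of the regulator found in the target promoter, 0 its
    absence, and 1/2 a regulator whose binding motif is unknown.
    """

    pi: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.pi.index, "prior regulator ids")
        _check_unique(self.pi.columns, "prior target ids")
        vals = self.pi.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("prior matrix contains missing values")
        bad = ~np.isin(vals, PRIOR_LEVELS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"prior value {vals[i, j]!r} at ({self.pi.index[i]}, "
                f"{self.pi.columns[j]}) not in {{0, 0.5, 1}}"
            )

    @property
    def regulator_ids(self) -> list[str]:
        return list(self.pi.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.pi.columns)

    def column(self, target: str, regulators: list[str]) -> np.ndarray:
        """Pi values for one target, aligned to ``regulators``."""
        return self.pi.loc[regulators, target].to_numpy(dtype=float)

    def write(self, path) -> None:
        self.pi.to_csv(path, sep="\t")


def _edge_sort(df: pd.DataFrame) -> pd.DataFrame:
    # decreasing importance, ties broken lexicographically for determinism
    return df.sort_values(
        by=["importance", "regulator", "target"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


@dataclass
class EdgeList:
    """Directed, scored regulator->target edges sorted by decreasing score."""

    edges: pd.DataFrame  # columns: regulator, target, importance
    density: float | None = None

    def __post_init__(self) -> None:
        required = ["regulator", "target", "importance"]
        if list(self.edges.columns[:3]) != required:
            raise ValidationError(f"edge table must have columns {required}")
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValidationError("edge list contains self-loops")
        if self.edges.duplicated(subset=["regulator", "target"]).any():
            raise ValidationError("edge list contains duplicate pairs")
        if (self.edges["importance"] < 0).any():
            raise ValidationError("importance scores must be nonnegative")
        self.edges = _edge_sort(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))


@dataclass
class GoldStandard:
    """Experimentally observed interactions, possibly partial.

    ``studied_regulators`` is the set of regulators the assay covered;
    inferred edges from other regulators can be neither confirmed nor
    falsified and are excluded from evaluation.
    """

    edges: set[tuple[str, str]]
    studied_regulators: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.studied_regulators:
            self.studied_regulators = {r for r, _ in self.edges}
        stray = {r for r, _ in self.edges} - self.studied_regulators
        if stray:
            raise ValidationError(
                f"gold edges from regulators outside studied set: {sorted(stray)}"
            )


def read_expression_matrix(path, regulator_list, target_list=None) -> ExpressionMatrix:
    """Load a genes x samples TSV and flag the regulators.

    Regulators absent from the matrix rows are dropped with a warning rather
    than failing, because regulator lists typically come from genome-wide
    TF databases and cover genes outside the analysed set.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(raw.columns):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValidationError(
                    f"non-numeric value {raw.iloc[i, j]!r} at row "
                    f"{raw.index[i]!r}, column {col!r}"
                ) from None
        raise
    _check_unique(values.index, "gene ids")
    present = [r for r in regulator_list if r in set(values.index)]
    absent = [r for r in regulator_list if r not in set(values.index)]
    if absent:
        warnings.warn(
            f"{len(absent)} regulator(s) not in expression matrix, dropped: "
            f"{absent[:10]}",
            stacklevel=2,
        )
    return ExpressionMatrix(values=values, regulator_ids=present, target_ids=target_list)


def read_prior_matrix(path) -> PriorMatrix:
    """Load a regulators x targets TSV of prior values in {0, 0.5, 1}."""
    pi = pd.read_csv(path, sep="\t", index_col=0)
    return PriorMatrix(pi=pi.astype(float))


def read_edge_list(path, studied_regulators=None) -> GoldStandard:
    """Load a two-column (regulator, target) TSV as a gold standard.

    Self-loop rows are dropped with a warning. ``studied_regulators``
    defaults to the regulators appearing in the file.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError("edge file needs at least two columns")
    reg, tgt = df.columns[0], df.columns[1]
    loops = df[reg] == df[tgt]
    if loops.any():
        warnings.warn(f"dropped {int(loops.sum())} self-loop edge(s)", stacklevel=2)
        df = df[~loops]
    edges = set(zip(df[reg].astype(str), df[tgt].astype(str)))
    studied = set(studied_regulators) if studied_regulators is not None else set()
    return GoldStandard(edges=edges, studied_regulators=studied)


def write_edge_list(grn: EdgeList, path) -> None:
    """Write a three-column TSV sorted by decreasing importance."""
    grn.edges.to_csv(path, sep="\t", index=False)


def read_scored_edge_list(path) -> EdgeList:
    """Load a (regulator, target, importance) TSV as an :class:`EdgeList`."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["regulator", "target", "importance"] + list(df.columns[3:])
    df["regulator"] = df["regulator"].astype(str)
    df["target"] = df["target"].astype(str)
    return EdgeList(edges=df[["regulator", "target", "importance"]])
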