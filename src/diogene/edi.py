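"""Effective data integration (EDI) and the permutation null dataset.

EDI quantifies how strongly a fitted model actually relies on
motif-supported regulators: regulators are ranked by *increasing*
importance (rank 1 = least important, ties get average ranks) and EDI is
the mean rank of the regulators with Pi = 1. It ranges from 1 (all
supported regulators useless to the model) to R (all supported regulators
at the top), and is undefined for a target with no supported regulator.

The null dataset breaks the link between expression and motif evidence by
permuting expression profiles *among regulator ids* with a derangement, so
every regulator keeps its correct motifs but carries the wrong expression
profile. Non-regulator rows are untouched. Under this null there is no
joint information between motifs and expression, which makes it the
reference against which a real gain from data integration is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import ExpressionMatrix

__all__ = ["EdiValue", "EdiUndefinedError", "compute_edi", "shuffle_regulator_profiles"]


class EdiUndefinedError(ValueError):
    """No motif-supported (Pi = 1) regulator: EDI cannot be computed.

    Callers treat this as the no-integration outcome (alpha_opt = 0).
    """


@dataclass
class EdiValue:
    target_id: str
    alpha: float
    edi: float
    n_supported: int

    def __post_init__(self) -> None:
        if self.n_supported < 1:
            raise EdiUndefinedError("EDI undefined without supported regulators")


def compute_edi(importances, pi_column, target_id: str = "", alpha: float = 0.0) -> EdiValue:
    """Mean rank (by increasing importance) of the Pi = 1 regulators."""
    imp = np.asarray(importances, dtype=float)
    pi = np.asarray(pi_column, dtype=float)
    if imp.shape != pi.shape:
        raise ValueError("importances and prior column must align")
    supported = pi == 1.0
    if not supported.any():
        raise EdiUndefinedError(
            f"target {target_id!r} has no motif-supported regulator"
        )
    ranks = rankdata(imp)  # average ranks; rank 1 = least important
    return EdiValue(
        target_id=target_id,
        alpha=float(alpha),
        edi=float(ranks[supported].mean()),
        n_supported=int(supported.sum()),
    )


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    while True:  # rejection sampling, acceptance ~ 1/e
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def shuffle_regulator_profiles(
    data: ExpressionMatrix, seed=None, allow_fixed_points: bool = False
) -> ExpressionMatrix:
    """Null dataset: permute expression profiles among the regulators.

    By default the permutation is a derangement, so *every* regulator is
    attributed a wrong profile; ``allow_fixed_points=True`` draws a plain
    uniform permutation instead.
    """
    regs = data.regulator_ids
    n_reg = len(regs)
    if n_reg < 2:
        raise ValueError("need at least 2 regulators to build a null dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_reg) if allow_fixed_points else _derangement(n_reg, rng)
    values = data.values.copy()
    values.loc[regs] = data.values.loc[[regs[i] for i in perm]].to_numpy()
    return ExpressionMatrix(
        values=values,
        regulator_ids=list(regs),
        target_ids=list(data.target_ids),
    )
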