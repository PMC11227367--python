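"""Encoding motif evidence and mapping it to model-specific weights.

A single scalar alpha in [0, 1] tunes the strength of data integration. At
alpha = 0 the prior is ignored (all regulators are treated equally, the
model uses expression alone); at alpha = 1 only regulators with a motif in
the target promoter (Pi = 1) keep full weight and motif-free regulators
(Pi = 0) are excluded from the model.

Between the two boundaries we interpolate linearly,

    w_r = (1 - alpha) + alpha * Pi(r, t),

which is the simplest mapping satisfying both boundary conditions and is
monotone in both alpha and Pi. The random forest uses w directly as the
sampling weight of each regulator at decision nodes; the LASSO uses the
reciprocal 1 / w as a per-regulator penalty factor (w = 0 meaning an
infinite penalty, i.e. removal from the design). The mapping is kept behind
this module's small surface so alternative schedules can be swapped in.

Unknown-motif regulators (Pi = 1/2) keep weight 1/2 at alpha = 1: absence
of evidence is not treated as evidence of absence, so they stay admissible
at full integration strength, merely disfavoured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import PRIOR_LEVELS, PriorMatrix, ValidationError

__all__ = [
    "IntegrationGrid",
    "default_grid",
    "encode_prior",
    "sampling_weights",
    "penalty_factors",
]


@dataclass
class IntegrationGrid:
    """Ordered grid of integration strengths, spanning 0 to 1."""

    alphas: np.ndarray = field(default_factory=lambda: np.round(np.linspace(0, 1, 11), 10))

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.ndim != 1 or len(a) < 2:
            raise ValidationError("alpha grid needs at least two values")
        if not (np.all(np.diff(a) > 0) and a[0] == 0.0 and a[-1] == 1.0):
            raise ValidationError("alpha grid must increase strictly from 0 to 1")
        self.alphas = a

    def __iter__(self):
        return iter(self.alphas)

    def __len__(self) -> int:
        return len(self.alphas)


def default_grid(step: float = 0.1) -> IntegrationGrid:
    """Evenly spaced grid from 0 to 1 with the given step (default 0.1)."""
    n = int(round(1.0 / step))
    return IntegrationGrid(np.round(np.linspace(0.0, 1.0, n + 1), 10))


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    return alpha


def _check_pi(pi_column: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi_column, dtype=float)
    if not np.isin(pi, PRIOR_LEVELS).all():
        raise ValidationError("prior column has values outside {0, 0.5, 1}")
    return pi


def encode_prior(
    motif_hits: set[tuple[str, str]],
    unknown_motif_regulators: set[str],
    regulator_ids: list[str],
    target_ids: list[str],
) -> PriorMatrix:
    """Build the prior matrix Pi from motif hits and unknown-motif regulators.

    Pi(r, t) = 1 where the motif of r was found in the promoter of t, 0 where
    it was not, and 1/2 on every row of a regulator with no known motif.
    """
    import pandas as pd

    hit_regs = {r for r, _ in motif_hits}
    overlap = hit_regs & set(unknown_motif_regulators)
    if overlap:
        raise ValidationError(
            f"regulators both in motif hits and unknown set: {sorted(overlap)}"
        )
    pi = pd.DataFrame(0.0, index=list(regulator_ids), columns=list(target_ids))
    for r in unknown_motif_regulators:
        if r in pi.index:
            pi.loc[r, :] = 0.5
    for r, t in motif_hits:
        if r in pi.index and t in pi.columns:
            pi.loc[r, t] = 1.0
    return PriorMatrix(pi=pi)


def sampling_weights(pi_column, alpha: float) -> np.ndarray:
    """Node-sampling weights for the weighted random forest.

    w_r = (1 - alpha) + alpha * Pi(r, t), returned unnormalized (the tree
    sampler normalizes over the candidates present at each node).
    """
    alpha = _check_alpha(alpha)
    pi = _check_pi(pi_column)
    return (1.0 - alpha) + alpha * pi


def penalty_factors(pi_column, alpha: float) -> np.ndarray:
    """Per-regulator L1 penalty factors for the weighted LASSO.

    The penalty factor is the reciprocal of the sampling weight; a zero
    weight maps to an infinite penalty, i.e. the regulator is removed from
    the design entirely.
    """
    w = sampling_weights(pi_column, alpha)
    pf = np.full_like(w, np.inf)
    nz = w > 0
    pf[nz] = 1.0 / w[nz]
    return pf
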