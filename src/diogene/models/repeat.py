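"""Repeated engine fits for one target gene.

One repetition of the forest engine fits an ensemble on the full sample set
and measures error out-of-bag; one repetition of the LASSO engine draws a
bootstrap sample, selects lambda by cross-validation on it, and measures
error on the out-of-bootstrap samples. In both cases the reported MSE is
normalized by the variance of the target gene expression, so 1.0 is the
error of the trivial mean predictor, and variable importance is a
permutation importance (mean decrease accuracy) on the same held-out
samples, clipped at zero.

Targets are standardized (zero mean, unit variance across samples) before
fitting, which makes the normalized MSE equal to the raw held-out MSE and
makes importances comparable across genes for global edge ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..data_model import ExpressionMatrix, PriorMatrix
from ..prior_weights import penalty_factors, sampling_weights
from .lasso import WeightedLasso
from .rf import WeightedRandomForestRegressor

__all__ = [
    "FitResult",
    "fit_weighted_rf",
    "fit_weighted_lasso",
    "repeat_fits",
    "refit_restricted",
    "candidate_regulators",
    "DEFAULT_REPETITIONS",
]

#: Default repetition counts per engine.
DEFAULT_REPETITIONS = {"weightedRF": 100, "weightedLASSO": 50}

_ENGINE_ALIASES = {
    "rf": "weightedRF",
    "weightedrf": "weightedRF",
    "lasso": "weightedLASSO",
    "weightedlasso": "weightedLASSO",
}


def canonical_engine(engine: str) -> str:
    name = _ENGINE_ALIASES.get(engine.lower())
    if name is None:
        raise ValueError(f"unknown engine {engine!r}; use 'weightedRF' or 'weightedLASSO'")
    return name


@dataclass
class FitResult:
    """Outcome of one engine repetition on one target gene."""

    target_id: str
    alpha: float
    repetition_index: int
    mse: float  # normalized: 1.0 == variance of the target expression
    importances: pd.Series  # nonnegative, indexed by candidate regulator
    seed: int

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be nonnegative")
        if (self.importances < 0).any():
            raise ValueError("importances must be nonnegative")


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def standardize(y: np.ndarray) -> np.ndarray:
    """Zero mean, unit (population) variance; constant profiles rejected."""
    y = np.asarray(y, dtype=float)
    sd = y.std()
    if sd == 0:
        raise ValueError("target expression is constant; cannot standardize")
    return (y - y.mean()) / sd


def candidate_regulators(data: ExpressionMatrix, gene: str) -> list[str]:
    """Regulators eligible to predict ``gene`` (the gene itself excluded)."""
    return [r for r in data.regulator_ids if r != gene]


def fit_weighted_rf(
    y,
    X,
    weights,
    regulator_ids=None,
    n_trees: int = 100,
    seed=None,
    target_id: str = "",
    alpha: float = 0.0,
    repetition_index: int = 0,
) -> FitResult:
    """One weighted-forest repetition: out-of-bag MSE and importances."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    var = y.var()
    if var == 0:
        raise ValueError("target expression is constant")
    ss = _as_seedseq(seed)
    forest = WeightedRandomForestRegressor(
        n_estimators=n_trees, feature_weights=weights, random_state=ss
    ).fit(X, y)
    if regulator_ids is None:
        regulator_ids = [f"x{j}" for j in range(X.shape[1])]
    imp = pd.Series(forest.permutation_importances_ / var, index=list(regulator_ids))
    return FitResult(
        target_id=target_id,
        alpha=float(alpha),
        repetition_index=repetition_index,
        mse=forest.oob_mse_ / var,
        importances=imp,
        seed=int(ss.generate_state(1)[0]),
    )


def fit_weighted_lasso(
    y,
    X,
    penalty,
    regulator_ids=None,
    cv_folds: int = 5,
    n_lambdas: int = 100,
    n_permutations: int = 5,
    seed=None,
    target_id: str = "",
    alpha: float = 0.0,
    repetition_index: int = 0,
) -> FitResult:
    """One weighted-LASSO repetition.

    Draws a bootstrap sample, cross-validates lambda on it, then measures
    normalized MSE and permutation importance on the out-of-bootstrap
    samples.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    var = y.var()
    if var == 0:
        raise ValueError("target expression is constant")
    ss = _as_seedseq(seed)
    ss_boot, ss_cv, ss_perm = ss.spawn(3)
    rng = np.random.default_rng(ss_boot)
    for _ in range(1000):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) >= 2:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw a bootstrap with out-of-bag samples")

    model = WeightedLasso(
        penalty_factor=penalty, n_lambdas=n_lambdas, cv=cv_folds, random_state=ss_cv
    ).fit(X[boot], y[boot])

    y_oob = y[oob]
    base_mse = float(np.mean((y_oob - model.predict(X[oob])) ** 2))

    p = X.shape[1]
    imp = np.zeros(p)
    rng_perm = np.random.default_rng(ss_perm)
    for j in np.flatnonzero(model.coef_ != 0):
        deltas = []
        for _ in range(n_permutations):
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng_perm.permutation(len(oob)), j]
            deltas.append(np.mean((y_oob - model.predict(Xp)) ** 2) - base_mse)
        imp[j] = max(0.0, float(np.mean(deltas)))

    if regulator_ids is None:
        regulator_ids = [f"x{j}" for j in range(p)]
    return FitResult(
        target_id=target_id,
        alpha=float(alpha),
        repetition_index=repetition_index,
        mse=base_mse / var,
        importances=pd.Series(imp / var, index=list(regulator_ids)),
        seed=int(ss.generate_state(1)[0]),
    )


def repeat_fits(
    engine: str,
    gene: str,
    data: ExpressionMatrix,
    prior: PriorMatrix,
    alpha: float,
    N: int | None = None,
    seed=None,
    **engine_kwargs,
) -> list[FitResult]:
    """Run ``N`` independent repetitions of an engine for one target gene.

    Defaults to 100 repetitions for the forest and 50 for the LASSO. Each
    repetition gets a distinct seed spawned from ``seed``, so the list is
    reproducible and independent of execution order.
    """
    engine = canonical_engine(engine)
    if N is None:
        N = DEFAULT_REPETITIONS[engine]
    if N < 2:
        raise ValueError("need at least 2 repetitions")
    regs = candidate_regulators(data, gene)
    if not regs:
        raise ValueError(f"no candidate regulators for {gene!r}")
    y = standardize(data.values.loc[gene].to_numpy(dtype=float))
    X = data.values.loc[regs].to_numpy(dtype=float).T
    pi_col = prior.column(gene, regs)

    ss = _as_seedseq(seed)
    children = ss.spawn(N)
    results = []
    for i, child in enumerate(children):
        if engine == "weightedRF":
            res = fit_weighted_rf(
                y,
                X,
                sampling_weights(pi_col, alpha),
                regulator_ids=regs,
                seed=child,
                target_id=gene,
                alpha=alpha,
                repetition_index=i,
                **engine_kwargs,
            )
        else:
            res = fit_weighted_lasso(
                y,
                X,
                penalty_factors(pi_col, alpha),
                regulator_ids=regs,
                seed=child,
                target_id=gene,
                alpha=alpha,
                repetition_index=i,
                **engine_kwargs,
            )
        results.append(res)
    return results


def refit_restricted(
    y,
    X,
    importances,
    k: int = 3,
    engine: str = "weightedRF",
    regulator_ids=None,
    seed=None,
    **engine_kwargs,
) -> FitResult:
    """Refit using only the top-k regulators by importance.

    Gives an error estimate at a sparsity comparable to penalized linear
    models that select few variables. With fewer than k regulators all are
    used. Ties at the cutoff are broken by regulator order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    engine = canonical_engine(engine)
    imp = np.asarray(importances, dtype=float)
    X = np.asarray(X, dtype=float)
    k = min(k, X.shape[1])
    top = np.sort(np.argsort(-imp, kind="stable")[:k])
    ids = (
        [regulator_ids[j] for j in top]
        if regulator_ids is not None
        else [f"x{j}" for j in top]
    )
    if engine == "weightedRF":
        return fit_weighted_rf(
            y, X[:, top], np.ones(k), regulator_ids=ids, seed=seed, **engine_kwargs
        )
    return fit_weighted_lasso(
        y, X[:, top], np.ones(k), regulator_ids=ids, seed=seed, **engine_kwargs
    )
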