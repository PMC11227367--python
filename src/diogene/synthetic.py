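"""Synthetic benchmark systems with known ground truth.

The generator emulates the inputs of a motif-guided GRN inference study: a
ground-truth directed regulator->target network, an expression matrix it
drives, a motif prior with controlled true/false positive rates, and a
partial gold standard covering only a subset of regulators (as in vitro
binding assays do).

Regulator profiles are i.i.d. standard normal across samples; each target
is a signed linear combination of its true regulators plus Gaussian noise
(optionally, a fraction of edges act through a saturating tanh to exercise
non-linear engines). Every target receives at least one regulator whenever
the edge budget allows — the modelled genes stand for transcriptionally
responsive genes, which are regulated by construction.

Default parameters describe a small but honestly noisy system: 20
regulators, 30 targets, 40 samples, truth density 0.1 (the upper end of
densities reported for real GRNs, appropriate when the gene universe is
tiny), noise standard deviation 0.5 on unit-scale signals, a prior with a
90% true positive and 2% false positive rate, and a tenth of regulators
with unknown motifs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .data_model import EdgeList, ExpressionMatrix, GoldStandard, PriorMatrix

__all__ = ["SynthParams", "SyntheticSystem", "generate", "generate_uninformative_prior"]


@dataclass
class SynthParams:
    """Generator settings; defaults are the package's benchmark conditions."""

    n_regulators: int = 20
    n_targets: int = 30
    n_samples: int = 40
    density: float = 0.1
    prior_tpr: float = 0.9  # P(Pi = 1 | true edge)
    prior_fpr: float = 0.02  # P(Pi = 1 | no edge)
    unknown_frac: float = 0.1  # fraction of regulators with unknown motif
    noise_sd: float = 0.5
    nonlinear_frac: float = 0.0
    gold_regulator_frac: float = 0.6
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticSystem:
    """A complete generated benchmark: truth, data, prior, gold standard."""

    truth: EdgeList
    data: ExpressionMatrix
    prior: PriorMatrix
    gold: GoldStandard
    params: SynthParams

    def write(self, directory) -> None:
        """Write all components as TSV files plus a YAML manifest."""
        import pathlib

        import yaml

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.data.write(directory / "expression.tsv")
        self.prior.write(directory / "prior.tsv")
        self.truth.edges.to_csv(directory / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.gold.edges), columns=["regulator", "target"]).to_csv(
            directory / "gold.tsv", sep="\t", index=False
        )
        (directory / "regulators.txt").write_text(
            "\n".join(self.data.regulator_ids) + "\n"
        )
        (directory / "targets.txt").write_text("\n".join(self.data.target_ids) + "\n")
        manifest = {
            "params": self.params.to_dict(),
            "gold_studied_regulators": sorted(self.gold.studied_regulators),
        }
        (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def _truth_edges(params: SynthParams, rng: np.random.Generator):
    """Sample exactly floor(D * R * (T - 1)) edges, >= 1 per target if possible."""
    R, T = params.n_regulators, params.n_targets
    total = R * (T - 1)
    n_edges = int(np.floor(params.density * total))
    if n_edges < 1:
        raise ValueError("no edges requested: density * R * (T - 1) < 1")
    n_edges = min(n_edges, R * T)
    regs = np.arange(R)
    edges: set[tuple[int, int]] = set()
    if n_edges >= T:
        for t in range(T):
            edges.add((int(rng.integers(0, R)), t))
    else:
        for t in rng.choice(T, size=n_edges, replace=False):
            edges.add((int(rng.integers(0, R)), int(t)))
    pool = [(r, t) for r in regs for t in range(T) if (r, t) not in edges]
    extra = n_edges - len(edges)
    if extra > 0:
        picks = rng.choice(len(pool), size=extra, replace=False)
        edges.update(pool[i] for i in picks)
    return sorted(edges)


def generate(params: SynthParams | None = None, **overrides) -> SyntheticSystem:
    """Generate a reproducible synthetic system from parameters.

    Keyword overrides update the defaults, e.g. ``generate(noise_sd=0.0)``.
    """
    if params is None:
        params = SynthParams(**overrides)
    elif overrides:
        params = SynthParams(**{**params.to_dict(), **overrides})
    R, T, n = params.n_regulators, params.n_targets, params.n_samples
    if R < 2 or T < 1:
        raise ValueError("need at least 2 regulators and 1 target")
    if n < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    reg_ids = [f"R{i + 1:03d}" for i in range(R)]
    tgt_ids = [f"T{j + 1:03d}" for j in range(T)]
    sample_ids = [f"S{k + 1:03d}" for k in range(n)]

    edges = _truth_edges(params, rng)
    effects = rng.uniform(0.5, 1.5, len(edges)) * rng.choice([-1.0, 1.0], len(edges))
    nonlinear = rng.random(len(edges)) < params.nonlinear_frac

    reg_expr = rng.standard_normal((R, n))
    tgt_expr = np.zeros((T, n))
    for (r, t), eff, nl in zip(edges, effects, nonlinear):
        contrib = np.tanh(reg_expr[r]) if nl else reg_expr[r]
        tgt_expr[t] += eff * contrib
    tgt_expr += params.noise_sd * rng.standard_normal((T, n))

    values = pd.DataFrame(
        np.vstack([reg_expr, tgt_expr]), index=reg_ids + tgt_ids, columns=sample_ids
    )
    data = ExpressionMatrix(values=values, regulator_ids=reg_ids, target_ids=tgt_ids)

    truth_df = pd.DataFrame(
        [(reg_ids[r], tgt_ids[t], abs(e)) for (r, t), e in zip(edges, effects)],
        columns=["regulator", "target", "importance"],
    )
    truth = EdgeList(edges=truth_df, density=len(edges) / (R * (T - 1)))

    n_unknown = int(np.floor(params.unknown_frac * R))
    unknown = set(rng.choice(R, size=n_unknown, replace=False).tolist())
    edge_set = {(r, t) for r, t in edges}
    pi = np.zeros((R, T))
    for r in range(R):
        if r in unknown:
            pi[r, :] = 0.5
            continue
        for t in range(T):
            rate = params.prior_tpr if (r, t) in edge_set else params.prior_fpr
            pi[r, t] = 1.0 if rng.random() < rate else 0.0
    prior = PriorMatrix(pi=pd.DataFrame(pi, index=reg_ids, columns=tgt_ids))

    n_gold_regs = max(1, int(np.ceil(params.gold_regulator_frac * R)))
    studied = {reg_ids[i] for i in rng.choice(R, size=n_gold_regs, replace=False)}
    gold_edges = {
        (reg_ids[r], tgt_ids[t]) for r, t in edges if reg_ids[r] in studied
    }
    gold = GoldStandard(edges=gold_edges, studied_regulators=studied)

    return SyntheticSystem(truth=truth, data=data, prior=prior, gold=gold, params=params)


def generate_uninformative_prior(system: SyntheticSystem, seed=None) -> PriorMatrix:
    """Negative-control prior: same Pi = 1 count, placed independently of truth.

    Unknown-motif rows (all 0.5) are preserved; the Pi = 1 entries of the
    remaining rows are redistributed uniformly at random over those rows'
    cells. Under this prior there is no joint information between motifs
    and expression, so a calibrated optimizer should almost never integrate.
    """
    rng = np.random.default_rng(seed)
    pi = system.prior.pi.to_numpy().copy()
    known_rows = np.flatnonzero(~(pi == 0.5).all(axis=1))
    n_ones = int((pi[known_rows] == 1.0).sum())
    pi[known_rows] = 0.0
    cells = [(r, c) for r in known_rows for c in range(pi.shape[1])]
    picks = rng.choice(len(cells), size=min(n_ones, len(cells)), replace=False)
    for i in picks:
        r, c = cells[i]
        pi[r, c] = 1.0
    return PriorMatrix(
        pi=pd.DataFrame(
            pi, index=system.prior.pi.index, columns=system.prior.pi.columns
        )
    )
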