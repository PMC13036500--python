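"""Leave-one-distribution-out validation and superensemble construction.

Given R distance-distribution restraints, R validation ensembles are fitted,
each omitting one distribution (the PRE set is never dropped — only the
sparse distance distributions need a sufficiency check).  The distribution
for the omitted restraint is then back-calculated from that ensemble and
compared to experiment.  Pooling the all-restraint ensemble with every
validation ensemble gives a superensemble, which is refit once against all
restraints.  The spread of any scalar descriptor across the validation
ensembles yields an uncertainty estimate: twice the standard deviation is
reported as the 95% confidence halfwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from flexens.io_formats import ConformerEnsemble
from flexens.metrics import DistanceDistribution, emd
from flexens.reweigh import (
    ConformerPredictions,
    FitResult,
    RestraintSet,
    backcalculate_distribution,
    fit_weights,
    prune_weights,
)

__all__ = ["ValidationSet", "jackknife", "build_superensemble", "uncertainty_estimates"]


@dataclass
class ValidationSet:
    """One pruned validation fit per omitted distance restraint."""

    omitted: list[tuple[str, str]]
    fits: list[FitResult]
    backcalculated: dict[tuple[str, str], DistanceDistribution]
    omitted_emd: dict[tuple[str, str], float]

    def __len__(self) -> int:
        return len(self.fits)


def jackknife(
    predictions: ConformerPredictions,
    observations: RestraintSet,
    prune_threshold: float = 0.01,
) -> ValidationSet:
    """Fit R validation ensembles, each omitting one distance distribution.

    Every validation fit runs the full balanced pipeline (single-objective
    minima, balanced fit, pruning with refit) with R-1 distributions and the
    complete PRE set, then back-calculates the omitted distribution and
    records its EMD to experiment.  Deterministic for a fixed pool order.
    """
    pairs = list(observations.deer)
    if len(pairs) < 2:
        raise ValueError("jackknife requires at least two distance restraints")
    fits, backs, emds = [], {}, {}
    for pair in pairs:
        fit = fit_weights(predictions, observations, "balanced", omit_deer=[pair])
        fit = prune_weights(
            fit, predictions, observations, prune_threshold, omit_deer=[pair]
        )
        back = backcalculate_distribution(predictions, pair, fit)
        fits.append(fit)
        backs[pair] = back
        emds[pair] = emd(observations.deer[pair], back)
    return ValidationSet(pairs, fits, backs, emds)


def build_superensemble(
    all_fit: FitResult,
    validation: ValidationSet,
    predictions: ConformerPredictions,
    observations: RestraintSet,
) -> FitResult:
    """Pool the all-restraint ensemble with every validation ensemble and
    refit once against all restraints.

    The pooled conformer set is the union (by conformer identity) of the
    retained sets.  The refit is evaluated against the union's own
    single-objective minima; the embedded all-restraint solution is kept as
    a fallback candidate, so the superensemble's balanced loss can never
    exceed the original solution's loss under the same normalization.
    """
    union = set(all_fit.indices.tolist())
    for fit in validation.fits:
        union.update(fit.indices.tolist())
    union_idx = np.array(sorted(union), dtype=int)
    # warm-start from the all-restraint solution embedded in the union
    w0 = np.full(union_idx.size, 1e-12)
    pos = {int(i): j for j, i in enumerate(union_idx)}
    for i, w in zip(all_fit.indices, all_fit.weights):
        w0[pos[int(i)]] = max(w, 1e-12)
    w0 = w0 / w0.sum()
    warm = fit_weights(predictions, observations, "balanced", subset=union_idx, w0=w0)
    cold = fit_weights(predictions, observations, "balanced", subset=union_idx)
    return warm if warm.loss <= cold.loss else cold


def uncertainty_estimates(
    validation: ValidationSet,
    pool: ConformerEnsemble,
    descriptors: dict[str, callable],
) -> dict[str, tuple[float, float]]:
    """Evaluate scalar descriptors on every validation ensemble.

    Returns ``{name: (mean, halfwidth)}`` where the halfwidth is twice the
    standard deviation across validation ensembles (95% confidence
    estimate).  Each descriptor receives a ConformerEnsemble (the retained
    pool subset carrying the validation fit's weights).
    """
    if len(validation) < 2:
        raise ValueError("need at least two validation ensembles")
    out = {}
    ensembles = [
        pool.subset(fit.indices, fit.weights) for fit in validation.fits
    ]
    for name, fn in descriptors.items():
        vals = np.array([float(fn(e)) for e in ensembles])
        out[name] = (float(vals.mean()), float(2.0 * vals.std()))
    return out
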