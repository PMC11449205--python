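"""Null-model comparison and error-rate estimation.

Observed population network statistics (mean degree, mean strength) are
compared against the empirical distribution of the same statistic over
many randomization iterations.  Detection of sociality is two-tailed at
alpha = 0.05: the observed mean is significant when it falls outside the
central 95% of the null values.  Z-scores quantify the size of the
deviation.  Replicated experiments over non-sociable and sociable
simulations yield false-positive and false-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .datasets import TrackingDataset
from .networks import interaction_threshold, network_means
from .randomize import downsample, path_shuffle, wrap_around
from .simulate import simulate

METRICS = ("mean_degree", "mean_strength")
ALPHA = 0.05


@dataclass
class NullDistribution:
    """Population-mean values of one metric over randomization iterations."""

    metric: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("null distribution must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null distribution contains non-finite values")

    @property
    def n_iterations(self) -> int:
        return len(self.values)


@dataclass
class NullComparison:
    """Observed statistic vs. a null distribution."""

    observed: float
    z: float              # NaN when the null has zero spread
    significant: bool
    direction: str        # 'above', 'below' or 'none'
    tail_fraction: float  # two-tailed empirical tail probability


def compare_to_null(observed: float, null: NullDistribution) -> NullComparison:
    """Two-tailed comparison of an observed population mean to its null.

    Significant when the observed value lies strictly outside the central
    95% of the null values (above the 97.5th or below the 2.5th empirical
    percentile).  z = (observed - mean(null)) / sd(null); reported as NaN
    for zero-variance nulls, where significance falls back to a strict
    comparison against the constant null value.
    """
    vals = null.values
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    z = (observed - float(np.mean(vals))) / sd if sd > 0 else float("nan")
    lo, hi = np.quantile(vals, [ALPHA / 2, 1 - ALPHA / 2])
    if observed > hi:
        significant, direction = True, "above"
    elif observed < lo:
        significant, direction = True, "below"
    else:
        significant, direction = False, "none"
    return NullComparison(
        observed=float(observed), z=z, significant=significant,
        direction=direction,
        tail_fraction=detection_likelihood(observed, null),
    )


def detection_likelihood(observed: float, null: NullDistribution) -> float:
    """Two-tailed empirical tail fraction of the observed value.

    ``2 * min(frac(null >= observed), frac(null <= observed))`` clipped to
    [0, 1]; values <= 0.05 count as detection of a social effect.
    """
    vals = null.values
    ge = float(np.mean(vals >= observed))
    le = float(np.mean(vals <= observed))
    return float(min(1.0, 2.0 * min(ge, le)))


@dataclass
class ExperimentResult:
    """One replicate of one experiment cell.

    ``descriptors`` fully determine the generating configuration (scenario,
    social flag and weight, randomization method and shift range, sampling
    frequency, replicate seed); ``comparisons`` maps each metric to its
    NullComparison and ``nulls`` to its NullDistribution.
    """

    descriptors: dict
    comparisons: dict
    nulls: dict = field(default_factory=dict, repr=False)

    @property
    def social(self) -> bool:
        return bool(self.descriptors["social"])

    def significant(self, metric: str) -> bool:
        return self.comparisons[metric].significant


def false_positive_rate(results: Sequence[ExperimentResult],
                        metric: str = "mean_strength") -> float:
    """Fraction of non-sociable replicates declaring significance (either
    direction): concluding social attraction or avoidance where none was
    simulated."""
    results = list(results)
    if not results:
        raise ValueError("no results supplied")
    if any(r.social for r in results):
        raise ValueError("false-positive rate is defined on non-sociable runs only")
    return sum(r.significant(metric) for r in results) / len(results)


def false_negative_rate(results: Sequence[ExperimentResult],
                        metric: str = "mean_strength") -> float:
    """Fraction of sociable replicates failing to declare significance."""
    results = list(results)
    if not results:
        raise ValueError("no results supplied")
    if any(not r.social for r in results):
        raise ValueError("false-negative rate is defined on sociable runs only")
    return sum(not r.significant(metric) for r in results) / len(results)


# -- experiment harness ------------------------------------------------------

def null_distributions(observed: TrackingDataset, method: str,
                       n_iterations: int, rng: np.random.Generator,
                       threshold: float, s: int | None = None,
                       window: int | None = None,
                       rule: str = "colocation") -> dict:
    """Null distributions of mean degree and mean strength for one method."""
    if method not in ("wrap", "shuffle"):
        raise ValueError("method must be 'wrap' or 'shuffle'")
    vals = {m: np.empty(n_iterations) for m in METRICS}
    for i in range(n_iterations):
        if method == "wrap":
            if s is None:
                raise ValueError("wrap-around requires a shift range s")
            rnd = wrap_around(observed, s=s, rng=rng)
        else:
            rnd = path_shuffle(observed, rng=rng, window=window)
        deg, stren = network_means(rnd.dataset, threshold, rule=rule)
        vals["mean_degree"][i] = deg
        vals["mean_strength"][i] = stren
    return {m: NullDistribution(metric=m, values=v) for m, v in vals.items()}


def run_single_experiment(cfg: SimConfig, method: str, n_iterations: int,
                          seed: int, s: int | None = None,
                          window: int | None = None,
                          points_per_day: int | None = None,
                          rule: str = "colocation",
                          observed: TrackingDataset | None = None,
                          keep_nulls: bool = False) -> ExperimentResult:
    """Simulate one observed dataset and test it against one null model.

    ``seed`` drives both the simulation and the randomization stream; pass
    ``observed`` to reuse an existing simulation (e.g. across methods).
    """
    if observed is None:
        observed = simulate(cfg.replace(seed=seed))
    data = observed
    if points_per_day is not None:
        data = downsample(data, points_per_day)
    threshold = interaction_threshold(cfg)
    obs_deg, obs_str = network_means(data, threshold, rule=rule)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    nulls = null_distributions(data, method, n_iterations, rng, threshold,
                               s=s, window=window, rule=rule)
    observed_by_metric = {"mean_degree": obs_deg, "mean_strength": obs_str}
    comparisons = {m: compare_to_null(observed_by_metric[m], nulls[m])
                   for m in METRICS}
    descriptors = {
        "hr_scenario": cfg.hr_scenario,
        "social": cfg.social,
        "social_weight": cfg.social_weight if cfg.social else 0.0,
        "method": method,
        "s": s,
        "window": window,
        "points_per_day": points_per_day,
        "rule": rule,
        "seed": seed,
        "n_iterations": n_iterations,
    }
    return ExperimentResult(descriptors=descriptors, comparisons=comparisons,
                            nulls=nulls if keep_nulls else {})


def run_experiment_grid(base: SimConfig,
                        methods: Iterable[str] = ("shuffle", "wrap"),
                        s_values: Iterable[int] = (5,),
                        social_weights: Iterable[float | None] = (None,),
                        points_per_day: Iterable[int | None] = (None,),
                        n_iterations: int = 100,
                        n_replicates: int = 20,
                        seed: int = 0,
                        rule: str = "colocation",
                        progress=None) -> list[ExperimentResult]:
    """Run the full factorial experiment grid.

    Each cell = (method, shift range for wrap, social weight, sampling
    frequency); each cell is replicated ``n_replicates`` times with fresh
    observed simulations.  A social weight of None keeps the base config's
    social flag; a number switches sociality on at that weight.  Fully
    reproducible from ``seed``.
    """
    root = np.random.default_rng(seed)
    results: list[ExperimentResult] = []
    for w in social_weights:
        cfg = base if w is None else base.replace(social=True, social_weight=w)
        for ppd in points_per_day:
            for rep in range(n_replicates):
                rep_seed = int(root.integers(2 ** 31))
                observed = simulate(cfg.replace(seed=rep_seed))
                for method in methods:
                    svals = list(s_values) if method == "wrap" else [None]
                    for s in svals:
                        res = run_single_experiment(
                            cfg, method, n_iterations, rep_seed, s=s,
                            points_per_day=ppd, rule=rule, observed=observed)
                        res.descriptors["replicate"] = rep
                        results.append(res)
                        if progress is not None:
                            progress(res)
    return results


def results_to_frame(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Tidy table: one row per result cell per metric."""
    rows = []
    for r in results:
        for metric, cmp in r.comparisons.items():
            row = dict(r.descriptors)
            row.update(metric=metric, observed=cmp.observed, z=cmp.z,
                       significant=cmp.significant, direction=cmp.direction,
                       tail_fraction=cmp.tail_fraction)
            rows.append(row)
    return pd.DataFrame(rows)
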