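"""Generic sampling-distribution machinery.

A *sampling distribution* is the collection of estimates an estimator would
produce over many repeated experiments drawn from the same population.  The
engine runs that experiment loop: draw a sample of size n, apply the
estimator, repeat ``n_iterations`` times, and keep the estimates (plus
p-values when the estimator is a test).  On top of that it offers the
distribution summaries and the significance-conditioning operations used to
illustrate publication-bias-style effect-size inflation.

Estimators are plain callables ``sample -> float`` or
``sample -> TestResult``; populations are any object with a
``sample(n, rng)`` method (see :mod:`sampdist.populations`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import TestResult

__all__ = [
    "SimulationGrid",
    "SamplingDistribution",
    "ConditionalDistribution",
    "simulate_sampling_distribution",
    "summarize",
    "condition_on_significance",
    "sign_error_rate",
    "two_experiment_difference",
    "to_tidy_frame",
]

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SimulationGrid:
    """Design of a simulation: sample sizes, iteration count, seed, alpha."""

    sample_sizes: tuple[int, ...]
    n_iterations: int = 10_000
    seed: int | np.random.SeedSequence | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sample_sizes)
        if not sizes:
            raise ValueError("sample_sizes must be non-empty")
        if any(n < 1 for n in sizes):
            raise ValueError("every sample size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        object.__setattr__(self, "sample_sizes", sizes)


@dataclass(frozen=True)
class SamplingDistribution:
    """Per-experiment estimates for one estimator at one sample size."""

    estimator_label: str
    sample_size: int
    estimates: np.ndarray
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        object.__setattr__(self, "estimates", est)
        if est.size == 0:
            raise ValueError("estimates must be non-empty")
        if self.p_values is not None:
            p = np.asarray(self.p_values, dtype=float)
            if p.shape != est.shape:
                raise ValueError("p_values must align with estimates")
            object.__setattr__(self, "p_values", p)

    @property
    def n_iterations(self) -> int:
        return self.estimates.size


@dataclass(frozen=True)
class ConditionalDistribution:
    """The subset of a sampling distribution surviving p <= alpha."""

    alpha: float
    retained: np.ndarray
    n_total: int
    retained_p_values: np.ndarray = field(default=None, repr=False)

    @property
    def retained_fraction(self) -> float:
        return self.retained.size / self.n_total


def _evaluate(estimator, population, n: int, rng: np.random.Generator):
    """Apply the estimator to a fresh draw, re-drawing on failure."""
    for attempt in range(_MAX_REDRAWS):
        sample = population.sample(n, rng)
        try:
            return estimator(sample)
        except ValueError as exc:
            logger.debug("estimator failed on draw (attempt %d): %s", attempt + 1, exc)
    raise RuntimeError(
        f"estimator failed on {_MAX_REDRAWS} consecutive draws at n={n}"
    )


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _label(estimator) -> str:
    return getattr(estimator, "__name__", type(estimator).__name__)


def simulate_sampling_distribution(
    population,
    estimator,
    grid: SimulationGrid,
    *,
    on_error: str = "redraw",
) -> list[SamplingDistribution]:
    """Run the experiment loop for every sample size in the grid.

    Returns one :class:`SamplingDistribution` per sample size, each holding
    ``grid.n_iterations`` estimates (and aligned p-values when the estimator
    returns a :class:`TestResult`).  ``on_error`` is ``"redraw"`` (default:
    draw a fresh sample when the estimator raises, keeping lengths aligned)
    or ``"raise"``.
    """
    if on_error not in ("redraw", "raise"):
        raise ValueError(f"on_error must be 'redraw' or 'raise', got {on_error!r}")
    streams = _seed_sequence(grid.seed).spawn(len(grid.sample_sizes))
    out = []
    for n, ss in zip(grid.sample_sizes, streams):
        rng = np.random.default_rng(ss)
        estimates = np.empty(grid.n_iterations)
        p_values: np.ndarray | None = None
        for i in range(grid.n_iterations):
            if on_error == "redraw":
                result = _evaluate(estimator, population, n, rng)
            else:
                result = estimator(population.sample(n, rng))
            if isinstance(result, TestResult):
                if p_values is None:
                    p_values = np.empty(grid.n_iterations)
                estimates[i] = result.estimate
                p_values[i] = result.p_value
            else:
                estimates[i] = float(result)
        out.append(
            SamplingDistribution(
                estimator_label=_label(estimator),
                sample_size=n,
                estimates=estimates,
                p_values=p_values,
            )
        )
    return out


def summarize(dist: SamplingDistribution, quantiles=(0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.Series:
    """Describe a sampling distribution: mean, SD, skewness and quantiles.

    The SD of a mean-estimator distribution is the empirical SEM.  Skewness
    is the adjusted Fisher–Pearson coefficient.
    """
    est = dist.estimates
    sd = float(np.std(est, ddof=1)) if est.size > 1 else 0.0
    out = {
        "estimator": dist.estimator_label,
        "sample_size": dist.sample_size,
        "n_iterations": est.size,
        "mean": float(np.mean(est)),
        "sd": sd,
        "skewness": float(stats.skew(est, bias=False)) if est.size > 2 and sd > 0 else (0.0 if sd == 0 else math.nan),
        "iqr": float(np.subtract(*np.percentile(est, [75, 25]))),
    }
    for q in quantiles:
        out[f"q{q:g}"] = float(np.quantile(est, q))
    return pd.Series(out)


def condition_on_significance(dist: SamplingDistribution, alpha: float = 0.05) -> ConditionalDistribution:
    """Keep only the estimates whose test reached p <= alpha.

    This emulates a literature that publishes only significant results: the
    retained distribution loses its centre (for a correlation under the
    null, everything inside ±critical r disappears, leaving a bimodal gap).
    """
    if dist.p_values is None:
        raise ValueError("distribution carries no p-values; run a test estimator")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    mask = dist.p_values <= alpha
    return ConditionalDistribution(
        alpha=alpha,
        retained=dist.estimates[mask],
        n_total=dist.n_iterations,
        retained_p_values=dist.p_values[mask],
    )


def sign_error_rate(dist: SamplingDistribution, alpha: float, true_sign: int) -> float:
    """Rate of significant results whose sign contradicts the true effect.

    The directional ("type III") error rate: the fraction of ALL iterations
    that are both significant at alpha and of sign opposite to
    ``true_sign`` (+1 or -1).
    """
    if true_sign not in (1, -1):
        raise ValueError("true_sign must be +1 or -1")
    if dist.p_values is None:
        raise ValueError("distribution carries no p-values; run a test estimator")
    wrong = np.sign(dist.estimates) == -true_sign
    return float(np.mean(wrong & (dist.p_values <= alpha)))


def two_experiment_difference(
    population,
    estimator,
    n: int,
    n_iterations: int = 10_000,
    seed: int | None = None,
) -> SamplingDistribution:
    """Sampling distribution of the difference between two independent experiments.

    Each iteration runs the same experiment twice and records
    estimate₁ − estimate₂; the result is symmetric about zero and √2 wider
    than the single-experiment distribution, and answers "how far apart can
    two replications of this study land?".
    """
    rng = np.random.default_rng(_seed_sequence(seed))
    diffs = np.empty(n_iterations)
    for i in range(n_iterations):
        a = _evaluate(estimator, population, n, rng)
        b = _evaluate(estimator, population, n, rng)
        ea = a.estimate if isinstance(a, TestResult) else float(a)
        eb = b.estimate if isinstance(b, TestResult) else float(b)
        diffs[i] = ea - eb
    return SamplingDistribution(
        estimator_label=f"diff[{_label(estimator)}]", sample_size=n, estimates=diffs
    )


def to_tidy_frame(dists: list[SamplingDistribution]) -> pd.DataFrame:
    """Stack sampling distributions into a tidy table.

    Columns: estimator, sample_size, iteration, estimate, p_value.
    """
    frames = []
    for d in dists:
        frames.append(
            pd.DataFrame(
                {
                    "estimator": d.estimator_label,
                    "sample_size": d.sample_size,
                    "iteration": np.arange(d.n_iterations),
                    "estimate": d.estimates,
                    "p_value": d.p_values if d.p_values is not None else np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
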