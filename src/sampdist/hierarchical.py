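"""Two-level (participants × trials) simulations.

Three pipelines that make the data-generating process explicit at both
levels of a typical within-participant experiment:

* beta-binomial group proportions — each participant's true accuracy comes
  from a beta distribution, their observed accuracy from Binomial(T, p)/T,
  and the group summary is the mean across P participants;
* two-level trimmed means for reaction times — 20% trimmed means across
  trials within each participant and condition, then a 20% trimmed mean
  across participants (robust at both levels because RT data are skewed at
  both levels);
* a pooled-conditions null — each participant's trials from both conditions
  are mixed into one pool and two pseudo-conditions are resampled from it,
  so the true between-condition difference is exactly zero; conditioning the
  resulting group differences on a significant one-sample Yuen test shows
  the winner's-curse gap around zero.

All pipelines accept either the parametric :class:`~sampdist.populations.RTPopulation`
or an empirical one loaded from trial-level data, and resample participants
with replacement before resampling trials (the hierarchy of a two-level
bootstrap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConditionalDistribution, SamplingDistribution, condition_on_significance
from .estimators import harrell_davis_quantile, yuen_one_sample
from .populations import BetaPopulation, RTPopulation, as_rng, pool_conditions

__all__ = [
    "TwoLevelDesign",
    "simulate_group_proportions",
    "simulate_group_trimmed_means",
    "simulate_null_by_pooling",
    "conditional_effect_summary",
    "trimmed_mean_rows",
]


@dataclass(frozen=True)
class TwoLevelDesign:
    """Numbers of participants (P) and trials per participant per condition (T)."""

    n_participants: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def trimmed_mean_rows(matrix: np.ndarray, trim: float = 0.2) -> np.ndarray:
    """Row-wise trimmed mean of a (participants × trials) matrix."""
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim proportion must lie in [0, 0.5), got {trim}")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[-1]
    g = int(math.floor(trim * n))
    if n - 2 * g < 1:
        raise ValueError(f"sample too small: {n} trials with trim={trim}")
    s = np.sort(matrix, axis=-1)
    return s[..., g : n - g].mean(axis=-1)


def _trimmed_mean_1d(values: np.ndarray, trim: float) -> float:
    return float(trimmed_mean_rows(values[None, :], trim)[0])


# ---------------------------------------------------------------------------
# proportions (beta-binomial)
# ---------------------------------------------------------------------------


def simulate_group_proportions(
    beta_pop: BetaPopulation,
    design: TwoLevelDesign,
    n_iterations: int = 20_000,
    seed: int | None = None,
) -> SamplingDistribution:
    """Sampling distribution of group-mean proportion correct.

    Each iteration draws P true accuracies from the beta population, an
    observed accuracy Binomial(T, p)/T for each participant, and averages
    across participants.  Precision grows faster with P than with T because
    between-participant variance is untouched by extra trials.
    """
    rng = as_rng(np.random.default_rng(seed))
    P, T = design.n_participants, design.n_trials
    p = beta_pop.sample(n_iterations * P, rng).reshape(n_iterations, P)
    correct = rng.binomial(T, p)
    group_means = (correct / T).mean(axis=1)
    return SamplingDistribution(
        estimator_label=f"group_mean_proportion[P={P},T={T}]",
        sample_size=P,
        estimates=group_means,
    )


# ---------------------------------------------------------------------------
# reaction times (two-level trimmed means)
# ---------------------------------------------------------------------------


def _participant_trial_matrix_parametric(
    rt_pop: RTPopulation, P: int, T: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(P, T) trial matrices for both conditions from fresh parametric participants."""
    params = rt_pop.draw_participants(P, rng)
    sigma = params["sigma"][:, None]
    tau = params["tau"][:, None]
    noise = rng.standard_normal((P, T))
    expo_w = rng.exponential(1.0, size=(P, T))
    expo_nw = rng.exponential(1.0, size=(P, T))
    word = params["mu_word"][:, None] + sigma * noise + tau * expo_w
    noise2 = rng.standard_normal((P, T))
    nonword = params["mu_nonword"][:, None] + sigma * noise2 + tau * expo_nw
    return np.clip(word, 1.0, None), np.clip(nonword, 1.0, None)


def _resample_participants(rt_pop: RTPopulation, P: int, rng, resample: bool) -> list[str]:
    roster = rt_pop.participants
    if not resample:
        return roster
    return [roster[i] for i in rng.integers(0, len(roster), size=P)]


def simulate_group_trimmed_means(
    rt_pop: RTPopulation,
    design: TwoLevelDesign,
    n_iterations: int = 5_000,
    seed: int | None = None,
    trim: float = 0.2,
    resample: bool = True,
) -> dict[str, SamplingDistribution]:
    """Two-level trimmed-mean sampling distributions per condition and difference.

    Per iteration: sample P participants (with replacement for empirical
    populations; fresh parameter draws for parametric ones), T trials per
    condition per participant, take the trimmed mean across trials within
    each condition, then the trimmed mean across participants.  Returns
    ``{"word": ..., "nonword": ..., "difference": ...}`` where the
    difference is nonword − word.

    ``resample=False`` (empirical populations only) is a degenerate switch:
    the full roster and every trial are used exactly once per iteration, so
    the pipeline reproduces the dataset's group trimmed means.
    """
    _check_two_level_trim(design, trim)
    rng = as_rng(np.random.default_rng(seed))
    P, T = design.n_participants, design.n_trials
    word_out = np.empty(n_iterations)
    nonword_out = np.empty(n_iterations)
    diff_out = np.empty(n_iterations)
    for i in range(n_iterations):
        if rt_pop.is_empirical:
            ids = _resample_participants(rt_pop, P, rng, resample)
            tm_w = np.empty(len(ids))
            tm_nw = np.empty(len(ids))
            for j, pid in enumerate(ids):
                w_pool = np.asarray(rt_pop.trials[pid]["word"], dtype=float)
                nw_pool = np.asarray(rt_pop.trials[pid]["nonword"], dtype=float)
                if resample:
                    w = rng.choice(w_pool, size=T, replace=True)
                    nw = rng.choice(nw_pool, size=T, replace=True)
                else:
                    w, nw = w_pool, nw_pool
                tm_w[j] = _trimmed_mean_1d(w, trim)
                tm_nw[j] = _trimmed_mean_1d(nw, trim)
        else:
            word_m, nonword_m = _participant_trial_matrix_parametric(rt_pop, P, T, rng)
            tm_w = trimmed_mean_rows(word_m, trim)
            tm_nw = trimmed_mean_rows(nonword_m, trim)
        word_out[i] = _trimmed_mean_1d(tm_w, trim)
        nonword_out[i] = _trimmed_mean_1d(tm_nw, trim)
        diff_out[i] = _trimmed_mean_1d(tm_nw - tm_w, trim)
    label = f"[P={P},T={T},trim={trim:g}]"
    return {
        "word": SamplingDistribution(f"group_tm_word{label}", P, word_out),
        "nonword": SamplingDistribution(f"group_tm_nonword{label}", P, nonword_out),
        "difference": SamplingDistribution(f"group_tm_diff{label}", P, diff_out),
    }


def simulate_null_by_pooling(
    rt_pop: RTPopulation,
    design: TwoLevelDesign,
    n_iterations: int = 5_000,
    seed: int | None = None,
    alpha: float = 0.05,
    trim: float = 0.2,
) -> tuple[SamplingDistribution, ConditionalDistribution]:
    """Null sampling distribution of group differences via condition pooling.

    Each participant's word and nonword trials are mixed into one pool and
    two pseudo-condition trial sets of size T are resampled from it, so the
    expected difference is zero by construction.  Each iteration summarizes
    participants by trial-level trimmed means, forms participant difference
    scores, takes their group trimmed mean, and tests it against zero with
    the one-sample Yuen test.  Returns the full difference distribution
    (with aligned p-values) and its p <= alpha conditional subset — bimodal,
    with an empty gap around zero carved out by the critical region.
    """
    _check_two_level_trim(design, trim)
    rng = as_rng(np.random.default_rng(seed))
    P, T = design.n_participants, design.n_trials
    diff_out = np.empty(n_iterations)
    p_out = np.empty(n_iterations)
    for i in range(n_iterations):
        if rt_pop.is_empirical:
            ids = _resample_participants(rt_pop, P, rng, resample=True)
            diffs = np.empty(len(ids))
            for j, pid in enumerate(ids):
                pool = pool_conditions(rt_pop.trials[pid]["word"], rt_pop.trials[pid]["nonword"])
                a = rng.choice(pool, size=T, replace=True)
                b = rng.choice(pool, size=T, replace=True)
                diffs[j] = _trimmed_mean_1d(a, trim) - _trimmed_mean_1d(b, trim)
        else:
            word_m, nonword_m = _participant_trial_matrix_parametric(rt_pop, P, T, rng)
            pool = np.concatenate([word_m, nonword_m], axis=1)  # (P, 2T) per-participant pools
            cols_a = rng.integers(0, 2 * T, size=(P, T))
            cols_b = rng.integers(0, 2 * T, size=(P, T))
            a = np.take_along_axis(pool, cols_a, axis=1)
            b = np.take_along_axis(pool, cols_b, axis=1)
            diffs = trimmed_mean_rows(a, trim) - trimmed_mean_rows(b, trim)
        res = yuen_one_sample(diffs, trim=trim, null_value=0.0)
        diff_out[i] = res.estimate
        p_out[i] = res.p_value
    dist = SamplingDistribution(
        estimator_label=f"group_tm_null_diff[P={P},T={T},trim={trim:g}]",
        sample_size=P,
        estimates=diff_out,
        p_values=p_out,
    )
    return dist, condition_on_significance(dist, alpha)


def conditional_effect_summary(
    conditional: ConditionalDistribution, probs=(0.5, 0.9)
) -> pd.Series:
    """Quantiles of the absolute retained differences.

    Summarizes how large the "significant" effects look: e.g. the median
    |difference| among surviving simulations and the size exceeded by the
    top 10% (prob 0.9).  An empty conditional set yields all-NaN values.
    """
    probs = [float(p) for p in probs]
    if any(not 0.0 < p < 1.0 for p in probs):
        raise ValueError("probs must lie in (0, 1)")
    index = [f"q{p:g}" for p in probs]
    if conditional.retained.size == 0:
        return pd.Series([math.nan] * len(probs), index=index, name="abs_difference")
    magnitudes = np.abs(conditional.retained)
    values = [harrell_davis_quantile(magnitudes, q=p) for p in probs]
    return pd.Series(values, index=index, name="abs_difference")


def _check_two_level_trim(design: TwoLevelDesign, trim: float) -> None:
    for level, count in (("trial", design.n_trials), ("participant", design.n_participants)):
        g = int(math.floor(trim * count))
        if count - 2 * g < 1:
            raise ValueError(
                f"sample too small at {level} level: {count} with trim={trim}"
            )
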