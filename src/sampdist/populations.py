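"""Data-generating processes for sampling-distribution simulations.

Each population class is a small frozen dataclass describing one of the
study's data-generating processes, together with a ``sample`` method that
draws one simulated experiment:

* :class:`LognormalPopulation` — a positively skewed, strictly positive
  measurement population (the kind of quantity — durations, amplitudes,
  concentrations — common in neuroscience and psychology).
* :class:`BivariateNormalPopulation` — standardized bivariate-normal pairs
  with a known population Pearson correlation ``rho``.
* :class:`BetaPopulation` — participant-level true proportions correct,
  feeding binomial trial counts in the hierarchical pipeline.
* :class:`OnsetPopulation` — ERP onset latencies (ms), either an empirical
  vector resampled with replacement or a shifted-gamma parametric stand-in.
* :class:`RTPopulation` — a two-level reaction-time process: per-participant
  ex-Gaussian trial distributions in two conditions (word / nonword), with
  participant-level parameter variability and a mostly-positive
  between-condition shift.

All samplers take a :class:`numpy.random.Generator` (or an integer seed) and
are bit-reproducible for fixed parameters, ``n`` and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LognormalPopulation",
    "BivariateNormalPopulation",
    "BetaPopulation",
    "OnsetPopulation",
    "RTPopulation",
    "ParticipantParams",
    "analytic_lognormal_moments",
    "sem_from_sigma",
    "pool_conditions",
    "load_onsets_csv",
    "load_rt_csv",
    "as_rng",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("word", "nonword")


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    """Coerce a seed (or an existing generator) into a ``numpy.random.Generator``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LognormalPopulation:
    """Lognormal observation population with log-scale location and scale.

    The default ``log_mean=0, log_sd=0.5`` gives a population mean of 1.13
    and SD of 0.604 (see :func:`analytic_lognormal_moments`).
    """

    log_mean: float = 0.0
    log_sd: float = 0.5

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValueError(f"log_sd must be > 0, got {self.log_sd}")

    def sample(self, n: int, rng=None) -> np.ndarray:
        _check_n(n)
        return as_rng(rng).lognormal(self.log_mean, self.log_sd, size=n)


@dataclass(frozen=True)
class BivariateNormalPopulation:
    """Standard bivariate normal pairs with population Pearson correlation ``rho``.

    Means are 0 and variances 1; ``rho`` fully determines the dependence.
    """

    rho: float = 0.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    def sample(self, n: int, rng=None) -> np.ndarray:
        """Draw ``n`` (x, y) pairs as an ``(n, 2)`` array."""
        _check_n(n)
        rng = as_rng(rng)
        z = rng.standard_normal((n, 2))
        # Cholesky factor of [[1, rho], [rho, 1]]
        y = self.rho * z[:, 0] + math.sqrt(1.0 - self.rho**2) * z[:, 1]
        return np.column_stack([z[:, 0], y])


@dataclass(frozen=True)
class BetaPopulation:
    """Beta distribution of participant-level true proportions correct.

    Parameterized by its mean and a concentration ``c`` so that the usual
    shape parameters are ``alpha = mean_p * c`` and ``beta = (1 - mean_p) * c``.
    The default (mean 0.7, concentration 10 → Beta(7, 3)) is negatively
    skewed and quite broad.
    """

    mean_p: float = 0.7
    concentration: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_p < 1.0:
            raise ValueError(f"mean_p must lie in (0, 1), got {self.mean_p}")
        if not self.concentration > 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")

    @property
    def alpha(self) -> float:
        return self.mean_p * self.concentration

    @property
    def beta(self) -> float:
        return (1.0 - self.mean_p) * self.concentration

    def sample(self, n: int, rng=None) -> np.ndarray:
        _check_n(n)
        return as_rng(rng).beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class OnsetPopulation:
    """Population of ERP onset latencies in milliseconds.

    Either *empirical* — a stored vector of onsets resampled with
    replacement — or *parametric*, a shifted gamma chosen to mimic the
    positive skew typical of onset distributions.  The parametric default
    (shift 40 ms, shape 2, scale 30 ms) has quartiles near 71/90/115 ms.
    """

    onsets: tuple[float, ...] | None = None
    shift: float = 40.0
    gamma_shape: float = 2.0
    gamma_scale: float = 30.0

    def __post_init__(self) -> None:
        if self.onsets is not None:
            arr = np.asarray(self.onsets, dtype=float)
            if arr.size == 0:
                raise ValueError("empirical onset population is empty")
            if not np.all(arr > 0):
                raise ValueError("all onsets must be > 0 ms")
            object.__setattr__(self, "onsets", tuple(float(v) for v in arr))
        else:
            if self.shift < 0:
                raise ValueError("shift must be >= 0 ms")
            if self.gamma_shape <= 0 or self.gamma_scale <= 0:
                raise ValueError("gamma_shape and gamma_scale must be > 0")

    @property
    def is_empirical(self) -> bool:
        return self.onsets is not None

    def sample(self, n: int, rng=None) -> np.ndarray:
        _check_n(n)
        rng = as_rng(rng)
        if self.is_empirical:
            return rng.choice(np.asarray(self.onsets, dtype=float), size=n, replace=True)
        return self.shift + rng.gamma(self.gamma_shape, self.gamma_scale, size=n)


@dataclass(frozen=True)
class ParticipantParams:
    """Ex-Gaussian trial parameters for one participant in both conditions (ms)."""

    mu_word: float
    mu_nonword: float
    sigma: float
    tau: float


@dataclass(frozen=True)
class RTPopulation:
    """Two-level reaction-time population: ex-Gaussian trials within participants.

    Trial RTs in each condition follow an ex-Gaussian (normal(mu, sigma)
    plus exponential(tau), tau > 0 giving positive skew).  Participants vary:
    their ``mu`` is drawn from a truncated normal around ``mu_word``; the
    word→nonword shift is participant-specific, Normal(``nonword_shift``,
    ``shift_sd``).  The defaults put trial means around 650 ms with an
    ~80 ms average lexicality effect whose between-participant spread makes
    roughly 96% of participants slower for nonwords — mimicking large
    lexical-decision datasets.

    Empirical mode: ``trials`` maps participant id → {condition: RT vector};
    participants and trials are then resampled with replacement.
    """

    mu_word: float = 500.0
    sigma: float = 50.0
    tau: float = 150.0
    nonword_shift: float = 80.0
    mu_between_sd: float = 50.0
    sigma_between_sd: float = 10.0
    tau_between_sd: float = 30.0
    shift_sd: float = 45.0
    trials: dict[str, dict[str, tuple[float, ...]]] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("sigma", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 ms")
        for name in ("mu_between_sd", "sigma_between_sd", "tau_between_sd", "shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trials is not None and len(self.trials) == 0:
            raise ValueError("empirical RT population has no participants")

    @property
    def is_empirical(self) -> bool:
        return self.trials is not None

    @property
    def participants(self) -> list[str]:
        if not self.is_empirical:
            raise ValueError("parametric RT population has no participant roster")
        return list(self.trials)

    def draw_participant(self, rng=None) -> ParticipantParams:
        """Draw one participant's ex-Gaussian parameters (parametric mode)."""
        rng = as_rng(rng)
        mu = _truncated_normal(rng, self.mu_word, self.mu_between_sd, low=0.0)
        sigma = _truncated_normal(rng, self.sigma, self.sigma_between_sd, low=0.0)
        tau = _truncated_normal(rng, self.tau, self.tau_between_sd, low=0.0)
        shift = rng.normal(self.nonword_shift, self.shift_sd)
        return ParticipantParams(mu_word=mu, mu_nonword=mu + shift, sigma=sigma, tau=tau)

    def draw_participants(self, n: int, rng=None) -> dict[str, np.ndarray]:
        """Vectorized draw of ``n`` participants' ex-Gaussian parameters.

        Returns arrays ``mu_word``, ``mu_nonword``, ``sigma``, ``tau`` of
        length ``n`` (parametric mode only).
        """
        _check_n(n)
        rng = as_rng(rng)
        mu = _truncated_normal_vec(rng, self.mu_word, self.mu_between_sd, low=0.0, size=n)
        sigma = _truncated_normal_vec(rng, self.sigma, self.sigma_between_sd, low=0.0, size=n)
        tau = _truncated_normal_vec(rng, self.tau, self.tau_between_sd, low=0.0, size=n)
        shift = rng.normal(self.nonword_shift, self.shift_sd, size=n)
        return {"mu_word": mu, "mu_nonword": mu + shift, "sigma": sigma, "tau": tau}

    def sample_trials(
        self,
        condition: str,
        n_trials: int,
        participant: ParticipantParams | str,
        rng=None,
    ) -> np.ndarray:
        """Sample one participant's trial RTs in one condition.

        ``participant`` is a :class:`ParticipantParams` (parametric mode) or a
        participant id (empirical mode, trials resampled with replacement).
        """
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        _check_n(n_trials)
        rng = as_rng(rng)
        if isinstance(participant, str):
            if not self.is_empirical:
                raise ValueError("participant id given but population is parametric")
            pool = np.asarray(self.trials[participant][condition], dtype=float)
            if pool.size == 0:
                raise ValueError(f"participant {participant!r} has no {condition} trials")
            return rng.choice(pool, size=n_trials, replace=True)
        mu = participant.mu_word if condition == "word" else participant.mu_nonword
        rt = rng.normal(mu, participant.sigma, size=n_trials) + rng.exponential(
            participant.tau, size=n_trials
        )
        return np.clip(rt, 1.0, None)  # RTs are strictly positive


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float, low: float) -> float:
    if scale == 0:
        return max(loc, low)
    for _ in range(1000):
        v = rng.normal(loc, scale)
        if v > low:
            return v
    return low  # pragma: no cover - pathological parameters


def _truncated_normal_vec(
    rng: np.random.Generator, loc: float, scale: float, low: float, size: int
) -> np.ndarray:
    if scale == 0:
        return np.full(size, max(loc, low))
    out = rng.normal(loc, scale, size=size)
    for _ in range(1000):
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(loc, scale, size=int(bad.sum()))
    out[out <= low] = low  # pragma: no cover - pathological parameters
    return out


def _check_n(n: int) -> None:
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")


# ---------------------------------------------------------------------------
# analytic helpers
# ---------------------------------------------------------------------------


def analytic_lognormal_moments(pop: LognormalPopulation) -> tuple[float, float]:
    """Closed-form mean and SD of a lognormal population.

    mean = exp(m + s²/2);  sd = sqrt((exp(s²) − 1) · exp(2m + s²))
    where ``m, s`` are the log-scale location and scale.  For the default
    population (0, 0.5) this gives (1.133, 0.604).
    """
    m, s = pop.log_mean, pop.log_sd
    mean = math.exp(m + s**2 / 2.0)
    sd = math.sqrt((math.exp(s**2) - 1.0) * math.exp(2.0 * m + s**2))
    return mean, sd


def sem_from_sigma(sigma: float, n: int) -> float:
    """Standard error of the mean, σ/√n."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return sigma / math.sqrt(n)


def pool_conditions(word_trials: Sequence[float], nonword_trials: Sequence[float]) -> np.ndarray:
    """Concatenate one participant's trials across conditions into one pool.

    Resampling two new "conditions" from this pool simulates a true null:
    zero expected between-condition difference.
    """
    w = np.asarray(word_trials, dtype=float)
    nw = np.asarray(nonword_trials, dtype=float)
    if w.size == 0 or nw.size == 0:
        raise ValueError("both condition trial vectors must be non-empty")
    return np.concatenate([w, nw])


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------


def load_onsets_csv(path: str | Path) -> OnsetPopulation:
    """Load an empirical onset population from a one-column CSV.

    Expects a header ``onset_ms`` and one latency (ms) per row.  Rows with
    non-numeric or non-positive values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    if "onset_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column 'onset_ms'")
    values = pd.to_numeric(df["onset_ms"], errors="coerce")
    keep = values.notna() & (values > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d invalid onset rows", path, dropped)
    kept = values[keep].to_numpy(dtype=float)
    if kept.size == 0:
        raise ValueError(f"{path}: no valid onset rows")
    return OnsetPopulation(onsets=tuple(kept))


def load_rt_csv(path: str | Path) -> RTPopulation:
    """Load an empirical two-condition RT population from a long-format CSV.

    Expects columns ``participant, condition, rt_ms`` with condition in
    {word, nonword}.  Non-positive or non-numeric RTs are dropped with a
    logged count; every retained participant must have trials in both
    conditions.
    """
    df = pd.read_csv(path)
    required = {"participant", "condition", "rt_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    bad_cond = ~df["condition"].isin(CONDITIONS)
    rts = pd.to_numeric(df["rt_ms"], errors="coerce")
    keep = rts.notna() & (rts > 0) & ~bad_cond
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("%s: dropped %d invalid RT rows", path, dropped)
    df = df.loc[keep].assign(rt_ms=rts[keep])
    if df.empty:
        raise ValueError(f"{path}: no valid RT rows")
    trials: dict[str, dict[str, tuple[float, ...]]] = {}
    for (pid, cond), group in df.groupby(["participant", "condition"], sort=True):
        trials.setdefault(str(pid), {})[str(cond)] = tuple(group["rt_ms"].to_numpy(dtype=float))
    complete = {p: t for p, t in trials.items() if set(t) == set(CONDITIONS)}
    incomplete = sorted(set(trials) - set(complete))
    if incomplete:
        logger.warning("%s: dropped participants missing a condition: %s", path, incomplete)
    if not complete:
        raise ValueError(f"{path}: no participant has trials in both conditions")
    return RTPopulation(trials=complete)
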