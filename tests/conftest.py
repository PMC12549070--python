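"""Shared fixtures: tiny toy populations and programmatic CSV fixtures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from sampdist.populations import as_rng


@dataclass(frozen=True)
class ConstantPopulation:
    """Degenerate population: every observation equals ``value``."""

    value: float = 3.0

    def sample(self, n: int, rng=None) -> np.ndarray:
        return np.full(n, self.value)


@dataclass(frozen=True)
class BinaryPairsPopulation:
    """(x, y) pairs on {0, 1}²: small samples often have zero variance.

    Exercises the engine's re-draw policy for estimator failures.
    """

    def sample(self, n: int, rng=None) -> np.ndarray:
        return as_rng(rng).integers(0, 2, size=(n, 2)).astype(float)


@pytest.fixture
def constant_population():
    return ConstantPopulation()


@pytest.fixture
def binary_pairs_population():
    return BinaryPairsPopulation()


@pytest.fixture
def onsets_csv(tmp_path):
    """Toy onset CSV: three valid rows plus one negative and one non-numeric."""
    path = tmp_path / "onsets.csv"
    path.write_text("onset_ms\n80\n90\n100\n-5\nnot_a_number\n")
    return path


@pytest.fixture
def rt_csv(tmp_path):
    """Toy trial-level RT CSV with two participants and both conditions."""
    rng = np.random.default_rng(42)
    lines = ["participant,condition,rt_ms"]
    for pid in ("p1", "p2"):
        base = 500 if pid == "p1" else 620
        for cond, shift in (("word", 0), ("nonword", 70)):
            for rt in base + shift + rng.exponential(120, size=30):
                lines.append(f"{pid},{cond},{rt:.1f}")
    lines.append("p1,word,-10")  # invalid row, should be dropped
    path = tmp_path / "rt.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
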