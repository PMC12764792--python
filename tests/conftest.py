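"""Shared fixtures: one session-scoped bank of simulation batches.

The expensive treatment batches (full replicates on the default landscape)
are computed once and shared by every test that needs them; replicate seeds
derive from a fixed root seed through the package's seed policy.
"""

from __future__ import annotations

import numpy as np
import pytest

from polyestab.config import SimulationConfig
from polyestab.engine import run_replicate
from polyestab.environment import generate_synthetic_environment
from polyestab.experiments import config_for_level, replicate_seed

ROOT_SEED = 7


class ReplicateBank:
    """Lazily computed, cached batches of replicates per (family, level)."""

    def __init__(self) -> None:
        self.base = SimulationConfig()
        self.grid = generate_synthetic_environment(self.base.env, self.base.env_seed)
        self._cache: dict[tuple[str, float, int], list] = {}

    def batch(self, family: str, level: float, n: int) -> list:
        """List of (ReplicateSummary, [EventRecord]) for replicates 0..n-1.

        Cached per replicate, so a larger request extends an earlier one.
        """
        cfg = None
        out = []
        for rep in range(n):
            key = (family, level, rep)
            if key not in self._cache:
                if cfg is None:
                    cfg = config_for_level(family, level, self.base)
                seed = replicate_seed(ROOT_SEED, family, level, rep)
                self._cache[key] = run_replicate(cfg, seed, grid=self.grid)
            out.append(self._cache[key])
        return out

    def spe_counts(self, family: str, level: float, n: int) -> np.ndarray:
        return np.array([s.spe_count for s, _ in self.batch(family, level, n)])

    def summaries(self, family: str, level: float, n: int) -> list:
        return [s for s, _ in self.batch(family, level, n)]


@pytest.fixture(scope="session")
def bank() -> ReplicateBank:
    return ReplicateBank()


@pytest.fixture(scope="session")
def default_grid(bank):
    return bank.grid


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
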